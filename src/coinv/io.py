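"""Genotype matrices for F2 inversion data.

An F2 cross between two inbred lines segregates each inversion locus into
three genotype classes: RR (homozygous for the reference orientation),
RI (heterozygous), and II (homozygous for the inverted orientation).
This module holds the tabular data model (individuals in rows, loci in
columns), TSV/CSV readers and writers, the rules that decide which loci and
locus pairs are analysable, and the presence/absence binarization of the
two dosage states (heterozygous, inverted homozygous) used by the
co-occurrence statistics.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Valid genotype codes, in the fixed row/column order used everywhere.
GENOTYPES = ("RR", "RI", "II")

#: Token emitted for missing genotypes on write.
MISSING_TOKEN = "NA"

HET = "HET"
HOM_INV = "HOM_INV"

#: Genotype code picked out by each dosage state.
STATE_CODE = {HET: "RI", HOM_INV: "II"}

#: Numeric suffix convention used in table-style labels: "_1" = heterozygous
#: state, "_2" = inverted-homozygous state.
STATE_SUFFIX = {HET: "1", HOM_INV: "2"}
SUFFIX_STATE = {v: k for k, v in STATE_SUFFIX.items()}


@dataclass(frozen=True)
class DosageState:
    """One presence/absence contrast of a locus: heterozygous carriers
    (HET ≙ RI) or inverted homozygotes (HOM_INV ≙ II).  The reference
    homozygote RR is the implicit complement and never a state itself."""

    locus: str
    state: str

    def __post_init__(self) -> None:
        if self.state not in STATE_CODE:
            raise ValueError(f"state must be one of {sorted(STATE_CODE)}, got {self.state!r}")

    @property
    def code(self) -> str:
        """Genotype code counted as 'present' for this state."""
        return STATE_CODE[self.state]

    @property
    def label(self) -> str:
        """Table-style label, e.g. ``Inv_40_1`` for the HET state of Inv_40."""
        return f"{self.locus}_{STATE_SUFFIX[self.state]}"

    @classmethod
    def from_label(cls, label: str) -> "DosageState":
        locus, _, suffix = label.rpartition("_")
        if suffix not in SUFFIX_STATE or not locus:
            raise ValueError(f"cannot parse dosage-state label {label!r}")
        return cls(locus, SUFFIX_STATE[suffix])


@dataclass
class GenotypeMatrix:
    """Individuals × loci table of genotype codes for one cross.

    ``data`` is a pandas DataFrame indexed by individual id with one column
    per locus; cells hold ``"RR"``/``"RI"``/``"II"`` or NaN for missing.
    """

    data: pd.DataFrame
    cross_id: str | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate individual ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate locus ids")
        vals = self.data.to_numpy(dtype=object).ravel()
        bad = {v for v in vals if isinstance(v, str) and v not in GENOTYPES}
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")

    @property
    def individuals(self) -> list[str]:
        return list(self.data.index)

    @property
    def loci(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_individuals(self) -> int:
        return len(self.data)

    def counts(self, locus: str) -> dict[str, int]:
        """Non-missing genotype counts at ``locus`` in RR/RI/II order."""
        col = self.data[locus]
        return {g: int((col == g).sum()) for g in GENOTYPES}


def _sep(path: Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if Path(path).suffix.lower() == ".csv" else "tsv"
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_genotype_matrix(
    path: str | Path, dialect: str | None = None, cross_id: str | None = None
) -> GenotypeMatrix:
    """Read a genotype matrix from TSV/CSV.

    The header row holds locus ids, the first column individual ids; an
    optional ``cross`` column supplies the cross id.  Codes are normalised
    case-insensitively; unknown tokens become missing with a logged count.
    """
    path = Path(path)
    sep = _sep(path, dialect)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header.strip():
        raise ValueError(f"empty genotype file: {path}")
    # pandas silently de-duplicates column names, so check the raw header
    cols = header.split(sep)[1:]
    dups = sorted({c for c in cols if cols.count(c) > 1})
    if dups:
        raise ValueError(f"duplicated locus header(s): {dups}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty genotype file: {path}") from exc
    if df.empty and df.columns.empty:
        raise ValueError(f"empty genotype file: {path}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicated individual id(s): {dups}")

    cross_cols = [c for c in df.columns if c.lower() == "cross"]
    if cross_cols:
        vals = df[cross_cols[0]].dropna().unique()
        if cross_id is None and len(vals) == 1:
            cross_id = str(vals[0])
        df = df.drop(columns=cross_cols)

    norm = df.apply(lambda s: s.str.strip().str.upper())
    known = norm.isin(GENOTYPES)
    missing_like = norm.isna() | norm.isin({MISSING_TOKEN, "", "NAN", "-", "."})
    unknown = int((~known & ~missing_like).to_numpy().sum())
    if unknown:
        logger.warning("%d unrecognised genotype token(s) in %s treated as missing", unknown, path)
    clean = norm.where(known, np.nan)
    return GenotypeMatrix(clean, cross_id=cross_id)


def write_genotype_matrix(
    m: GenotypeMatrix, path: str | Path, dialect: str | None = None
) -> None:
    """Write ``m`` in the same dialect the reader accepts (missing → NA)."""
    path = Path(path)
    out = m.data.fillna(MISSING_TOKEN)
    out.index.name = out.index.name or "individual"
    out.to_csv(path, sep=_sep(path, dialect))


def read_locus_meta(path: str | Path, dialect: str | None = None) -> pd.Series:
    """Read the two-column locus metadata table (locus_id, chromosome)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path, dialect), dtype=str)
    if df.shape[1] < 2:
        raise ValueError("locus metadata needs two columns: locus_id, chromosome")
    meta = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="chromosome")
    if meta.index.has_duplicates:
        raise ValueError("duplicate locus ids in metadata")
    return meta


def write_locus_meta(meta: pd.Series, path: str | Path, dialect: str | None = None) -> None:
    df = pd.DataFrame({"locus_id": meta.index, "chromosome": meta.values})
    df.to_csv(Path(path), sep=_sep(Path(path), dialect), index=False)


def segregating_loci(m: GenotypeMatrix) -> list[str]:
    """Loci with at least two distinct non-missing genotype classes.

    The rule is about observed genotype classes, not alleles: a locus showing
    only RR and II (no heterozygotes) still segregates.
    """
    out = []
    for locus in m.loci:
        if m.data[locus].dropna().nunique() >= 2:
            out.append(locus)
    return out


def binarize_state(m: GenotypeMatrix, s: DosageState) -> pd.Series:
    """Presence/absence vector of a dosage state over individuals.

    1.0 where the genotype equals the state's code, 0.0 for the other
    non-missing genotypes, NaN where the genotype is missing (missing
    individuals are dropped pairwise at contrast time).
    """
    if s.locus not in m.data.columns:
        raise KeyError(f"locus {s.locus!r} not in matrix")
    col = m.data[s.locus]
    out = (col == s.code).astype(float)
    out[col.isna()] = np.nan
    return out


def _state_valid(m: GenotypeMatrix, s: DosageState) -> bool:
    v = binarize_state(m, s).dropna()
    return len(v) > 0 and 0.0 < v.mean() < 1.0


def enumerate_valid_pairs(
    m: GenotypeMatrix, meta: pd.Series, level: str = "locus"
) -> list[tuple]:
    """Analysable unordered pairs at locus or dosage-state granularity.

    Locus level: pairs of segregating loci on different chromosomes.
    State level: pairs of dosage states of such loci where each state is
    present in at least one individual and absent in at least one.
    """
    seg = segregating_loci(m)
    missing_meta = [l for l in seg if l not in meta.index]
    if missing_meta:
        raise KeyError(f"no chromosome assignment for segregating loci: {missing_meta}")
    if level == "locus":
        return [
            (a, b)
            for a, b in itertools.combinations(seg, 2)
            if meta[a] != meta[b]
        ]
    if level == "state":
        states = [
            DosageState(l, st)
            for l in seg
            for st in (HET, HOM_INV)
            if _state_valid(m, DosageState(l, st))
        ]
        return [
            (sa, sb)
            for sa, sb in itertools.combinations(states, 2)
            if meta[sa.locus] != meta[sb.locus]
        ]
    raise ValueError(f"level must be 'locus' or 'state', got {level!r}")


def pair_space(n_loci: int) -> dict[str, int]:
    """Size of the unfiltered combinatorial space for ``n_loci`` loci.

    Counts unordered locus pairs and unordered pairs among the 2·n_loci
    dosage states by explicit enumeration (no segregation or chromosome
    filters applied).
    """
    loci = range(n_loci)
    states = range(2 * n_loci)
    return {
        "locus_pairs": sum(1 for _ in itertools.combinations(loci, 2)),
        "state_pairs": sum(1 for _ in itertools.combinations(states, 2)),
    }
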