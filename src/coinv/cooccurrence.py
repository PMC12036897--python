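"""Zero-centered co-occurrence indexes on binary dosage-state vectors.

Each pair of segregating loci yields a 3×3 genotype table; choosing one
dosage state per locus (heterozygous or inverted-homozygous, with the
reference homozygote RR as the absence class) slices out four 2×2
submatrices, one presence/absence contrast each:

    sub1 = (HET, HET)   sub2 = (HOM_INV, HOM_INV)
    sub3 = (HET, HOM_INV)   sub4 = (HOM_INV, HET)

Individuals carrying the genotype outside the chosen {RR, state} pair at
either locus are excluded from that contrast (see ``Table2x2.from_3x3``).

Two zero-centered association measures are computed per contrast:

* the centered Jaccard/Tanimoto index cJ/T = J − E[J], where J is the
  plain Jaccard similarity and E[J] its expectation under independence at
  the observed marginal frequencies; positive values mean coupling,
  negative repulsion;
* the affinity score α, the maximum-likelihood log odds of the noncentral
  (Fisher) hypergeometric model with both margins fixed — a
  prevalence-insensitive log-odds-ratio estimate, capped at ±10 for tables
  at the boundary of the support.

Significance: cJ/T by a bootstrap that permutes one vector uniformly
(equivalently, draws n11 from the central hypergeometric law, since the
index depends on the pair only through the 2×2 table and permutation fixes
both margins); α by the two-sided exact central-hypergeometric test
(minimum-likelihood rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .contingency import OmnibusResult, Table3x3, crosstab_3x3, omnibus_chi2_mc, posthoc_residuals
from .io import (
    GENOTYPES,
    HET,
    HOM_INV,
    DosageState,
    GenotypeMatrix,
    STATE_CODE,
)

#: submatrix index -> (state of locus A, state of locus B)
SUBMATRIX_STATES = {
    1: (HET, HET),
    2: (HOM_INV, HOM_INV),
    3: (HET, HOM_INV),
    4: (HOM_INV, HET),
}


@dataclass(frozen=True)
class Table2x2:
    """2×2 presence/absence table; n11 counts joint presence."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("negative counts")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def mA(self) -> int:
        return self.n11 + self.n10

    @property
    def mB(self) -> int:
        return self.n11 + self.n01

    def as_array(self) -> np.ndarray:
        return np.array([[self.n11, self.n10], [self.n01, self.n00]], dtype=float)

    @classmethod
    def from_vectors(cls, x, y) -> "Table2x2":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("vectors must have equal length")
        keep = ~(np.isnan(x) | np.isnan(y))  # pairwise-complete deletion
        x, y = x[keep].astype(bool), y[keep].astype(bool)
        return cls(
            int(np.sum(x & y)),
            int(np.sum(x & ~y)),
            int(np.sum(~x & y)),
            int(np.sum(~x & ~y)),
        )

    @classmethod
    def from_3x3(cls, table: np.ndarray, row_state: str, col_state: str) -> "Table2x2":
        """Slice one dosage-state submatrix out of a 3×3 genotype table.

        The reference homozygote RR is the absence class on both axes, so
        the submatrix is the 2×2 block {RR, state_A} × {RR, state_B};
        individuals carrying the third genotype at either locus do not
        enter this contrast.  This exclusion (rather than a row/column
        collapse) is what keeps the unaffected submatrices exactly at the
        independence null when viability selection hits a single genotype
        combination: within any block that avoids the selected cell the
        cell probabilities stay in product form.
        """
        t = np.asarray(table, dtype=float)
        i = GENOTYPES.index(STATE_CODE[row_state])
        j = GENOTYPES.index(STATE_CODE[col_state])
        return cls(int(round(t[i, j])), int(round(t[i, 0])),
                   int(round(t[0, j])), int(round(t[0, 0])))


def state_pair_table(
    m: GenotypeMatrix, state_a: DosageState, state_b: DosageState
) -> Table2x2:
    """2×2 submatrix for a dosage-state pair of one cross.

    Built from the pairwise-complete 3×3 genotype table with RR as the
    absence class on both axes.
    """
    tab, _ = crosstab_3x3(m, state_a.locus, state_b.locus)
    return Table2x2.from_3x3(tab, state_a.state, state_b.state)


def _jaccard(t: Table2x2) -> float:
    denom = t.n11 + t.n10 + t.n01
    return t.n11 / denom if denom > 0 else 0.0


def _expected_jaccard(t: Table2x2) -> float:
    p = t.mA / t.n
    q = t.mB / t.n
    denom = p + q - p * q
    return p * q / denom if denom > 0 else 0.0


def centered_jaccard_table(t: Table2x2) -> float:
    """cJ/T from a 2×2 table: J − E[J] with E[J] = pq/(p + q − pq)."""
    if t.n < 1:
        raise ValueError("empty table")
    if t.mA == 0 or t.mB == 0:
        raise ValueError("all-zero vector: invalid contrast")
    return _jaccard(t) - _expected_jaccard(t)


def centered_jaccard(x, y) -> float:
    """Centered Jaccard/Tanimoto index of two binary vectors."""
    return centered_jaccard_table(Table2x2.from_vectors(x, y))


def _null_n11(t: Table2x2, B: int, rng: np.random.Generator) -> np.ndarray:
    # uniform permutation of y fixes both margins, so n11 is hypergeometric
    return rng.hypergeometric(t.mA, t.n - t.mA, t.mB, size=B)


def _cjt_of_n11(n11: np.ndarray, t: Table2x2) -> np.ndarray:
    ej = _expected_jaccard(t)
    denom = t.mA + t.mB - n11
    j = np.where(denom > 0, n11 / np.maximum(denom, 1), 0.0)
    return j - ej


def jaccard_bootstrap_from_table(
    t: Table2x2, B: int = 10_000, rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> float:
    """Two-sided permutation-bootstrap p for the cJ/T of a 2×2 table."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    obs = centered_jaccard_table(t)
    null = _cjt_of_n11(_null_n11(t, B, rng), t)
    hits = int(np.sum(np.abs(null) >= abs(obs) - 1e-12))  # ties count as >=
    return (1 + hits) / (B + 1)


def jaccard_bootstrap_test(
    x, y, B: int = 10_000, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided bootstrap p-value for centered_jaccard(x, y)."""
    return jaccard_bootstrap_from_table(Table2x2.from_vectors(x, y), B=B, rng=rng, seed=seed)


@dataclass(frozen=True)
class AffinityResult:
    alpha: float
    p: float
    capped: bool


def affinity_alpha(t: Table2x2, cap: float = 10.0, mid_p: bool = False) -> AffinityResult:
    """Affinity score: conditional MLE of the log odds ratio.

    α maximises the noncentral hypergeometric likelihood
    P(n11 | n, mA, mB, odds = e^α) over α ∈ [−cap, +cap]; tables whose n11
    sits at the boundary of the attainable range return ±cap.  The p-value
    is the exact two-sided central-hypergeometric (Fisher) test with the
    minimum-likelihood tail rule; ``mid_p`` subtracts half the observed
    outcome's probability.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    if t.n < 1:
        raise ValueError("empty table")
    if not (0 < t.mA < t.n and 0 < t.mB < t.n):
        raise ValueError("degenerate margin: contrast invalid")

    kmin = max(0, t.mA + t.mB - t.n)
    kmax = min(t.mA, t.mB)
    capped = False
    if t.n11 >= kmax:
        alpha, capped = cap, True
    elif t.n11 <= kmin:
        alpha, capped = -cap, True
    else:
        def nll(a: float) -> float:
            return -stats.nchypergeom_fisher.logpmf(t.n11, t.n, t.mA, t.mB, np.exp(a))

        res = optimize.minimize_scalar(
            nll, bounds=(-cap, cap), method="bounded",
            options={"xatol": 1e-8},
        )
        alpha = float(np.clip(res.x, -cap, cap))

    p = float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])
    if mid_p:
        p -= 0.5 * float(stats.hypergeom.pmf(t.n11, t.n, t.mA, t.mB))
        p = max(p, 0.0)
    return AffinityResult(alpha=alpha, p=p, capped=capped)


@dataclass
class StatePairResult:
    """One 2×2 dosage-state contrast of a locus pair."""

    state_a: DosageState
    state_b: DosageState
    submatrix: int
    table: Table2x2
    cJT: float
    cJT_p: float
    alpha: float
    alpha_p: float
    alpha_capped: bool
    SR: float
    posthoc_p: float
    omnibus_p: float
    cross_id: str | None = None
    detected_by_all: bool = False


@dataclass
class PairResult:
    """Full analysis of one valid locus pair."""

    locus_a: str
    locus_b: str
    cross_id: str | None
    n: int
    table: Table3x3
    omnibus: OmnibusResult
    posthoc: pd.DataFrame
    contrasts: list[StatePairResult]
    skipped: list[tuple[int, str]]


def pairwise_contrasts(
    m: GenotypeMatrix,
    locus_a: str,
    locus_b: str,
    meta: pd.Series | None = None,
    B: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    expectation: str = "margins",
    cap: float = 10.0,
    level: float = 0.05,
) -> PairResult:
    """Decompose a locus pair into its four dosage-state contrasts.

    Builds the 3×3 table once (pairwise-complete individuals), runs the
    Monte-Carlo omnibus test and the standardized-residual post hocs, then
    emits the four 2×2 contrasts with cJ/T (+ bootstrap p), α (+ exact p)
    and the matching post-hoc cell.  Contrasts whose presence/absence
    vector is constant are skipped with a reason.  A contrast is flagged
    ``detected_by_all`` when the cJ/T, α and post-hoc p-values are all
    below ``level``.
    """
    if meta is not None:
        if meta.get(locus_a) == meta.get(locus_b):
            raise ValueError(
                f"{locus_a} and {locus_b} are on the same chromosome: pair invalid"
            )
    rng = rng if rng is not None else np.random.default_rng(seed)
    tab, n_used = crosstab_3x3(m, locus_a, locus_b)
    if n_used < 1:
        raise ValueError("no pairwise-complete individuals")
    seg_a = (tab.sum(axis=1) > 0).sum() >= 2
    seg_b = (tab.sum(axis=0) > 0).sum() >= 2
    if not (seg_a and seg_b):
        raise ValueError("both loci must segregate among pairwise-complete individuals")

    t3 = Table3x3(tab, mode=expectation)
    omni = omnibus_chi2_mc(t3, B=B, rng=rng)
    ph = posthoc_residuals(t3)

    contrasts: list[StatePairResult] = []
    skipped: list[tuple[int, str]] = []
    for sub, (st_a, st_b) in SUBMATRIX_STATES.items():
        t2 = Table2x2.from_3x3(tab, st_a, st_b)
        if t2.mA == 0 or t2.mA == t2.n:
            skipped.append((sub, f"{locus_a} state {st_a} constant"))
            continue
        if t2.mB == 0 or t2.mB == t2.n:
            skipped.append((sub, f"{locus_b} state {st_b} constant"))
            continue
        cjt = centered_jaccard_table(t2)
        cjt_p = jaccard_bootstrap_from_table(t2, B=B, rng=rng)
        aff = affinity_alpha(t2, cap=cap)
        cell = ph[(ph["row"] == STATE_CODE[st_a]) & (ph["col"] == STATE_CODE[st_b])].iloc[0]
        res = StatePairResult(
            state_a=DosageState(locus_a, st_a),
            state_b=DosageState(locus_b, st_b),
            submatrix=sub,
            table=t2,
            cJT=cjt,
            cJT_p=cjt_p,
            alpha=aff.alpha,
            alpha_p=aff.p,
            alpha_capped=aff.capped,
            SR=float(cell["SR"]),
            posthoc_p=float(cell["p_raw"]),
            omnibus_p=omni.p,
            cross_id=m.cross_id,
        )
        res.detected_by_all = (
            res.cJT_p < level and res.alpha_p < level and res.posthoc_p < level
        )
        contrasts.append(res)

    return PairResult(
        locus_a=locus_a,
        locus_b=locus_b,
        cross_id=m.cross_id,
        n=n_used,
        table=t3,
        omnibus=omni,
        posthoc=ph,
        contrasts=contrasts,
        skipped=skipped,
    )


def contrasts_frame(results: list[PairResult]) -> pd.DataFrame:
    """Long-format table of state-pair contrasts (Table-2 style columns)."""
    rows = []
    for pr in results:
        for c in pr.contrasts:
            rows.append(
                {
                    "cross": pr.cross_id,
                    "INV_1": c.state_a.label,
                    "INV_2": c.state_b.label,
                    "submatrix": c.submatrix,
                    "n": pr.n,
                    "chi2_global": pr.omnibus.stat,
                    "p_chi2_g": pr.omnibus.p,
                    "p_chi2_ph": c.posthoc_p,
                    "chi2_SR": c.SR,
                    "alpha": c.alpha,
                    "alpha_p": c.alpha_p,
                    "cJT": c.cJT,
                    "cJT_p": c.cJT_p,
                    "detected_by_all": c.detected_by_all,
                }
            )
    return pd.DataFrame(rows)
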