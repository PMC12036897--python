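"""Single-locus segregation-distortion tests.

F2 genotype counts (RR, RI, II) are tested against the Mendelian 1:2:1
expectation with a Williams-corrected G goodness-of-fit test.  The
segregation distortion value SDV = −log10(p) summarises effect size on a
log scale.  A sequential pair of chi-square tests separates gametic from
zygotic selection: χ²1 asks whether the two orientations are transmitted
1:1 (allele balance); χ²2 asks whether the genotype distribution itself is
distorted.  Distortion of the genotype distribution without (or beyond)
allele imbalance points at differential zygote survival rather than
transmission bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GENOTYPES, GenotypeMatrix, segregating_loci

LN10 = np.log(10.0)

MENDELIAN_F2 = (0.25, 0.5, 0.25)


@dataclass(frozen=True)
class GenotypeCounts:
    n_RR: int
    n_RI: int
    n_II: int

    def __post_init__(self) -> None:
        if min(self.n_RR, self.n_RI, self.n_II) < 0:
            raise ValueError("negative genotype counts")
        if self.N < 1:
            raise ValueError("need at least one individual")

    @property
    def N(self) -> int:
        return self.n_RR + self.n_RI + self.n_II

    def as_array(self) -> np.ndarray:
        return np.array([self.n_RR, self.n_RI, self.n_II], dtype=float)

    @classmethod
    def from_matrix(cls, m: GenotypeMatrix, locus: str) -> "GenotypeCounts":
        c = m.counts(locus)
        return cls(c["RR"], c["RI"], c["II"])


@dataclass(frozen=True)
class GTestResult:
    G: float
    q_williams: float
    df: int
    p: float
    SDV: float


@dataclass(frozen=True)
class ModeTestResult:
    chi1: float
    p1: float
    chi2: float
    p2: float
    df2: int
    mode: str          # "gametic" | "zygotic" | "none"
    variant: str
    degenerate: bool = False


def williams_q(N: int, k: int) -> float:
    """Williams' small-sample correction divisor for a k-category
    goodness-of-fit G test: q = 1 + (k² − 1)/(6·N·(k − 1))."""
    return 1.0 + (k * k - 1.0) / (6.0 * N * (k - 1.0))


def _g_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    # zero observed counts contribute 0 (x·ln x → 0 limit)
    mask = observed > 0
    return float(2.0 * np.sum(observed[mask] * np.log(observed[mask] / expected[mask])))


def williams_g_test(
    c: GenotypeCounts, expected: tuple[float, float, float] = MENDELIAN_F2
) -> GTestResult:
    """Williams-corrected G goodness-of-fit test of RR/RI/II counts.

    ``expected`` are the null genotype probabilities (Mendelian 1:2:1 by
    default).  SDV is computed through the log survival function so it
    stays finite when p underflows.
    """
    exp = np.asarray(expected, dtype=float)
    if not np.isclose(exp.sum(), 1.0):
        raise ValueError("expected probabilities must sum to 1")
    obs = c.as_array()
    E = exp * c.N
    q = williams_q(c.N, k=3)
    G = _g_statistic(obs, E) / q
    df = 2
    p = float(stats.chi2.sf(G, df))
    SDV = float(-stats.chi2.logsf(G, df) / LN10)
    return GTestResult(G=G, q_williams=q, df=df, p=p, SDV=SDV)


def allele_balance_chi2(c: GenotypeCounts) -> tuple[float, float]:
    """χ²1: are the two orientations transmitted in equal number?

    With nR = 2·n_RR + n_RI reference alleles and nI = n_RI + 2·n_II
    inverted alleles (nR + nI = 2N), the statistic is
    (nR − N)²/N + (nI − N)²/N, df 1.
    """
    nR = 2 * c.n_RR + c.n_RI
    nI = c.n_RI + 2 * c.n_II
    stat = (nR - c.N) ** 2 / c.N + (nI - c.N) ** 2 / c.N
    return float(stat), float(stats.chi2.sf(stat, 1))


def selection_mode_test(
    c: GenotypeCounts, variant: str = "one_two_one", alpha: float = 0.05
) -> ModeTestResult:
    """Sequential gametic/zygotic classification.

    χ²1 is the allele-balance statistic.  The second-stage χ²2 is a
    pluggable strategy with two variants:

    ``one_two_one``
        Pearson χ² of the genotype counts against (N/4, N/2, N/4), df 2.
    ``hwe_conditional``
        Pearson χ² against Hardy-Weinberg proportions at the *observed*
        allele frequency p̂ = nR/2N, df 1; isolates distortion of the
        genotype distribution beyond any allele imbalance.  Undefined when
        p̂ ∈ {0, 1} (flagged).

    Classification: zygotic if χ²2 is significant; gametic if only χ²1 is;
    none otherwise.
    """
    chi1, p1 = allele_balance_chi2(c)
    obs = c.as_array()
    degenerate = False
    if variant == "one_two_one":
        E = np.array(MENDELIAN_F2) * c.N
        chi2 = float(np.sum((obs - E) ** 2 / E))
        df2 = 2
        p2 = float(stats.chi2.sf(chi2, df2))
    elif variant == "hwe_conditional":
        phat = (2 * c.n_RR + c.n_RI) / (2 * c.N)
        qhat = 1.0 - phat
        df2 = 1
        if phat in (0.0, 1.0):
            chi2, p2, degenerate = float("nan"), float("nan"), True
        else:
            E = c.N * np.array([phat**2, 2 * phat * qhat, qhat**2])
            chi2 = float(np.sum((obs - E) ** 2 / E))
            p2 = float(stats.chi2.sf(chi2, df2))
    else:
        raise ValueError(f"unknown variant {variant!r}")

    if not degenerate and p2 < alpha:
        mode = "zygotic"
    elif p1 < alpha:
        mode = "gametic"
    else:
        mode = "none"
    return ModeTestResult(chi1, p1, chi2, p2, df2, mode, variant, degenerate)


def sd_table(
    m: GenotypeMatrix,
    expected: tuple[float, float, float] = MENDELIAN_F2,
    variant: str = "one_two_one",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-locus segregation-distortion table for one cross.

    One row per segregating locus with G, p, SDV, the sequential-test
    columns, and Benjamini-Hochberg adjusted p-values computed *within the
    cross*.  Rows are sorted by raw p.
    """
    if m.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    rows = []
    for locus in segregating_loci(m):
        c = GenotypeCounts.from_matrix(m, locus)
        g = williams_g_test(c, expected)
        mt = selection_mode_test(c, variant=variant, alpha=alpha)
        rows.append(
            {
                "locus": locus,
                "cross": m.cross_id,
                "n_RR": c.n_RR,
                "n_RI": c.n_RI,
                "n_II": c.n_II,
                "G": g.G,
                "p": g.p,
                "SDV": g.SDV,
                "chi1": mt.chi1,
                "p1": mt.p1,
                "chi2": mt.chi2,
                "p2": mt.p2,
                "mode": mt.mode,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["p_adj"] = multipletests(df["p"].values, method="fdr_bh")[1]
    return df.sort_values("p", kind="mergesort").reset_index(drop=True)
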