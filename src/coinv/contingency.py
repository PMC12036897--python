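"""3×3 and 2×2 contingency-table tests for locus pairs.

The omnibus test asks whether the genotypes at two unlinked loci are
independent across F2 individuals.  Because expected counts can be small
(the double inverted-homozygote class has Mendelian frequency 1/16), the
omnibus p-value is Monte-Carlo: the observed Pearson X² is referred to
replicate tables drawn under the null rather than the asymptotic χ²
distribution.  Two null/expectation framings are supported:

``margins``
    Expected counts from the observed margins; null replicates from the
    conditional distribution of tables with both margins fixed (Patefield's
    algorithm, the same null R's ``chisq.test(simulate.p.value=TRUE)`` uses).
``mendelian``
    Expected counts N·f_i·f_j with f = (1/4, 1/2, 1/4); null replicates are
    multinomial draws from the product frequencies.

Per-cell standardized residuals with Benjamini-Yekutieli correction and
relative contributions localise which genotype combination drives a
significant omnibus result.  A 2×2 G independence test supports the
replicated-G heterogeneity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GENOTYPES, GenotypeMatrix

MENDELIAN_F3 = np.array([0.25, 0.5, 0.25])


def crosstab_3x3(
    m: GenotypeMatrix, locus_a: str, locus_b: str
) -> tuple[np.ndarray, int]:
    """Observed 3×3 counts (rows = locus_a RR/RI/II, cols = locus_b), using
    pairwise-complete individuals only.  Returns (table, n_used)."""
    a = m.data[locus_a]
    b = m.data[locus_b]
    keep = a.notna() & b.notna()
    tab = np.zeros((3, 3), dtype=int)
    for i, ga in enumerate(GENOTYPES):
        for j, gb in enumerate(GENOTYPES):
            tab[i, j] = int(((a == ga) & (b == gb) & keep).sum())
    return tab, int(keep.sum())


@dataclass
class Table3x3:
    """3×3 observed-count table for a locus pair."""

    observed: np.ndarray
    mode: str = "margins"

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        if self.observed.shape != (3, 3) or (self.observed < 0).any():
            raise ValueError("observed must be a non-negative 3x3 table")
        if self.mode not in ("margins", "mendelian"):
            raise ValueError(f"mode must be 'margins' or 'mendelian', got {self.mode!r}")
        if self.N < 1:
            raise ValueError("empty table")

    @property
    def N(self) -> float:
        return float(self.observed.sum())

    @property
    def expected(self) -> np.ndarray:
        if self.mode == "margins":
            r = self.observed.sum(axis=1)
            c = self.observed.sum(axis=0)
            return np.outer(r, c) / self.N
        return self.N * np.outer(MENDELIAN_F3, MENDELIAN_F3)


def chi2_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    """Pearson X² over cells with positive expectation (degenerate cells
    contribute nothing)."""
    mask = expected > 0
    return float(np.sum((observed[mask] - expected[mask]) ** 2 / expected[mask]))


@dataclass(frozen=True)
class OmnibusResult:
    stat: float
    p: float
    B: int
    mode: str
    degenerate: bool = False


def omnibus_chi2_mc(
    t: Table3x3,
    B: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> OmnibusResult:
    """Monte-Carlo omnibus X² test of a 3×3 table.

    p = (1 + #{X²* ≥ X²}) / (B + 1) with replicate tables drawn under the
    null matching ``t.mode`` (see module docstring).  Deterministic for a
    fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    E = t.expected
    degenerate = bool((E == 0).any())
    obs_stat = chi2_statistic(t.observed, E)

    if t.mode == "margins":
        r = t.observed.sum(axis=1).astype(int)
        c = t.observed.sum(axis=0).astype(int)
        # drop empty rows/cols for the sampler; their cells cannot vary
        ri = np.flatnonzero(r)
        ci = np.flatnonzero(c)
        if len(ri) < 2 or len(ci) < 2:
            # only one non-empty row or column: margins determine the table
            return OmnibusResult(obs_stat, 1.0, B, t.mode, degenerate=True)
        reps = stats.random_table(r[ri], c[ci]).rvs(B, random_state=rng)
        reps = reps.reshape(B, len(ri), len(ci))
        Esub = E[np.ix_(ri, ci)]
        null_stats = ((reps - Esub) ** 2 / Esub).sum(axis=(1, 2))
    else:
        f9 = np.outer(MENDELIAN_F3, MENDELIAN_F3).ravel()
        reps = rng.multinomial(int(t.N), f9, size=B).reshape(B, 3, 3)
        null_stats = ((reps - E) ** 2 / E).sum(axis=(1, 2))

    hits = int(np.sum(null_stats >= obs_stat - 1e-12))
    p = (1 + hits) / (B + 1)
    return OmnibusResult(obs_stat, float(p), B, t.mode, degenerate)


def posthoc_residuals(t: Table3x3) -> pd.DataFrame:
    """Per-cell standardized residuals of a 3×3 table.

    SR_ij = (O − E)/sqrt(E·(1 − r_i/N)·(1 − c_j/N)); two-sided normal
    p-values corrected with Benjamini-Yekutieli over the nine cells
    (the contrasts share margins, hence are dependent); RC_ij is the cell's
    percentage contribution to the omnibus X².  Cells with E = 0 are
    reported as missing.
    """
    E = t.expected
    O = t.observed
    N = t.N
    r = O.sum(axis=1) / N
    c = O.sum(axis=0) / N
    stat = chi2_statistic(O, E)

    rows = []
    for i, ga in enumerate(GENOTYPES):
        for j, gb in enumerate(GENOTYPES):
            if E[i, j] <= 0:
                sr = praw = rc = np.nan
            else:
                denom = E[i, j] * (1.0 - r[i]) * (1.0 - c[j])
                sr = (O[i, j] - E[i, j]) / np.sqrt(denom) if denom > 0 else np.nan
                praw = 2.0 * stats.norm.sf(abs(sr)) if np.isfinite(sr) else np.nan
                rc = 100.0 * (O[i, j] - E[i, j]) ** 2 / E[i, j] / stat if stat > 0 else 0.0
            rows.append(
                {"row": ga, "col": gb, "cell": 3 * i + j + 1,
                 "observed": O[i, j], "expected": E[i, j],
                 "SR": sr, "RC": rc, "p_raw": praw}
            )
    df = pd.DataFrame(rows)
    ok = df["p_raw"].notna()
    df["p_BY"] = np.nan
    if ok.any():
        df.loc[ok, "p_BY"] = multipletests(df.loc[ok, "p_raw"].values, method="fdr_by")[1]
    return df


def g_independence(table: np.ndarray, williams: bool = False) -> tuple[float, int, float]:
    """G test of independence for a 2×2 table.

    G = 2·ΣO·ln(O/E) with margin-based expectations, df 1; zero observed
    cells contribute 0.  A table with an all-zero row or column carries no
    information about association: G = 0, df = 0, p = 1.

    ``williams`` divides G by the independence-test Williams correction
    q = 1 + (N/r₁ + N/r₂ − 1)(N/c₁ + N/c₂ − 1)/(6N).  Off by default:
    the replicated-G decomposition is additive only for raw G.
    """
    O = np.asarray(table, dtype=float)
    if O.shape != (2, 2) or (O < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    N = O.sum()
    if N < 1:
        raise ValueError("empty table")
    r = O.sum(axis=1)
    c = O.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        return 0.0, 0, 1.0
    E = np.outer(r, c) / N
    mask = O > 0
    G = float(2.0 * np.sum(O[mask] * np.log(O[mask] / E[mask])))
    G = max(G, 0.0)
    if williams:
        q = 1.0 + (N / r[0] + N / r[1] - 1.0) * (N / c[0] + N / c[1] - 1.0) / (6.0 * N)
        G /= q
    return G, 1, float(stats.chi2.sf(G, 1))
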