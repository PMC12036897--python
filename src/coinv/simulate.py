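"""Survival-rate table simulator and framework characterisation.

A 3×3 genotype table for two unlinked loci has Mendelian cell
probabilities f_e = outer((1/4, 1/2, 1/4), (1/4, 1/2, 1/4)).  Viability
selection on genotype combinations is modelled by per-cell survival rates
s_1..s_9 (row-major; cell 9 = double inverted homozygote, cell 8 = II at
locus A with RI at locus B):

    f_mod_i = f_e_i * s_i / sum_j f_e_j * s_j

Tables of survivors are multinomial draws of n individuals from f_mod.
Three presets reproduce the study conditions used to characterise the
statistical frameworks:

* ``null``: all s = 1 (Mendelian assortment);
* ``alt1``: s_9 = 0.2, others 1 (double-homozygote inviability);
* ``alt2``: s_8 = 0.2, s_9 = 1, others 0.7 (one deflated and one
  relatively inflated cell).

``evaluate_frameworks`` applies the omnibus Monte-Carlo χ² and the two
co-occurrence indexes (per submatrix) to every table, retaining the nine
p-value streams for distribution analysis.  Plain D/D′ linkage
disequilibrium metrics are provided for comparison studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .contingency import MENDELIAN_F3, Table3x3, chi2_statistic, omnibus_chi2_mc
from .cooccurrence import (
    SUBMATRIX_STATES,
    Table2x2,
    centered_jaccard_table,
    jaccard_bootstrap_from_table,
)


def mendelian_f9() -> np.ndarray:
    """Row-major Mendelian cell probabilities of the 3×3 genotype table."""
    return np.outer(MENDELIAN_F3, MENDELIAN_F3).ravel()


def modified_expectation(f_e: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Renormalised cell probabilities after viability selection."""
    f_e = np.asarray(f_e, dtype=float)
    s = np.asarray(s, dtype=float)
    if f_e.shape != s.shape:
        raise ValueError("f_e and s must have the same shape")
    if not np.isclose(f_e.sum(), 1.0):
        raise ValueError("f_e must sum to 1")
    if (s < 0).any():
        raise ValueError("survival rates must be non-negative")
    w = f_e * s
    tot = w.sum()
    if tot <= 0:
        raise ValueError("all-zero joint survival")
    return w / tot


@dataclass(frozen=True)
class SurvivalScenario:
    """One simulation condition: 9 survival rates + sampling sizes."""

    name: str
    survival: tuple = (1.0,) * 9
    n_individuals: int = 400
    n_tables: int = 5000
    seed: int | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if s.shape != (9,) or (s < 0).any() or not (s > 0).any():
            raise ValueError("survival must be 9 non-negative rates, not all zero")
        if self.n_individuals < 1 or self.n_tables < 1:
            raise ValueError("n_individuals and n_tables must be >= 1")

    @property
    def f_mod(self) -> np.ndarray:
        return modified_expectation(mendelian_f9(), np.asarray(self.survival))


def null_scenario(n_tables: int = 5000, n_individuals: int = 400,
                  seed: int | None = None) -> SurvivalScenario:
    return SurvivalScenario("null", (1.0,) * 9, n_individuals, n_tables, seed)


def alt1_scenario(n_tables: int = 2000, n_individuals: int = 400,
                  seed: int | None = None) -> SurvivalScenario:
    """Cell 9 (double inverted homozygote) deflated: survival 0.2."""
    s = [1.0] * 8 + [0.2]
    return SurvivalScenario("alt1", tuple(s), n_individuals, n_tables, seed)


def alt2_scenario(n_tables: int = 2000, n_individuals: int = 400,
                  seed: int | None = None) -> SurvivalScenario:
    """Cell 8 deflated (0.2), cell 9 kept at 1, remaining cells at 0.7."""
    s = [0.7] * 7 + [0.2, 1.0]
    return SurvivalScenario("alt2", tuple(s), n_individuals, n_tables, seed)


SCENARIOS = {"null": null_scenario, "alt1": alt1_scenario, "alt2": alt2_scenario}


def simulate_tables(
    sc: SurvivalScenario, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``sc.n_tables`` multinomial 3×3 tables of survivors.

    Returns an integer array of shape (n_tables, 3, 3); bit-reproducible
    under a fixed seed.
    """
    rng = rng if rng is not None else np.random.default_rng(sc.seed)
    flat = rng.multinomial(sc.n_individuals, sc.f_mod, size=sc.n_tables)
    return flat.reshape(sc.n_tables, 3, 3)


#: p-value streams produced per table.
FRAMEWORKS = (
    ["omnibus"]
    + [f"cJT_sub{k}" for k in SUBMATRIX_STATES]
    + [f"alpha_sub{k}" for k in SUBMATRIX_STATES]
)


def evaluate_frameworks(
    tables: np.ndarray,
    B_inner: int = 1000,
    seed: int | None = None,
    expectation: str = "mendelian",
) -> dict[str, np.ndarray]:
    """Apply the three frameworks to every 3×3 table.

    Returns the nine p-value streams (omnibus; cJ/T and α for each of the
    four submatrices).  Tables where a submatrix has a degenerate margin
    contribute NaN to that stream.  ``expectation`` picks the omnibus
    expectation/null mode; simulations default to ``mendelian`` because the
    data-generating expectations are known there.
    """
    tables = np.asarray(tables)
    if tables.ndim != 3 or tables.shape[1:] != (3, 3):
        raise ValueError("tables must have shape (n_tables, 3, 3)")
    if tables.shape[0] == 0:
        raise ValueError("no tables to evaluate")
    rng = np.random.default_rng(seed)

    out = {name: np.full(tables.shape[0], np.nan) for name in FRAMEWORKS}
    for i, tab in enumerate(tables):
        t3 = Table3x3(tab, mode=expectation)
        out["omnibus"][i] = omnibus_chi2_mc(t3, B=B_inner, rng=rng).p
        for sub, (st_a, st_b) in SUBMATRIX_STATES.items():
            t2 = Table2x2.from_3x3(tab, st_a, st_b)
            if not (0 < t2.mA < t2.n and 0 < t2.mB < t2.n):
                continue
            out[f"cJT_sub{sub}"][i] = jaccard_bootstrap_from_table(t2, B=B_inner, rng=rng)
            out[f"alpha_sub{sub}"][i] = float(
                stats.fisher_exact(t2.as_array(), alternative="two-sided")[1]
            )
    return out


def summarize_pvalues(pvals: dict[str, np.ndarray], level: float = 0.05) -> pd.DataFrame:
    """Rejection rate at ``level`` and KS distance from uniform per stream."""
    rows = []
    for name, p in pvals.items():
        p = np.asarray(p, dtype=float)
        ok = p[~np.isnan(p)]
        ks = stats.kstest(ok, "uniform").statistic if len(ok) else np.nan
        rows.append(
            {
                "framework": name,
                "n": len(ok),
                "rejection_rate": float(np.mean(ok < level)) if len(ok) else np.nan,
                "ks_distance": float(ks),
            }
        )
    return pd.DataFrame(rows)


def ld_metrics(gamete_freqs) -> tuple[float, float]:
    """Classical D and D′ from the four gamete frequencies (AB, Ab, aB, ab).

    D = p_AB − p_A·p_B; D′ normalises by the attainable extreme given the
    allele frequencies.  Monomorphic loci leave LD undefined.
    """
    p = np.asarray(gamete_freqs, dtype=float)
    if p.shape != (4,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
        raise ValueError("need 4 non-negative gamete frequencies summing to 1")
    pAB, pAb, paB, pab = p
    pA = pAB + pAb
    pB = pAB + paB
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic locus: LD undefined")
    D = pAB - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        return 0.0, 0.0
    return float(D), float(D / dmax)
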