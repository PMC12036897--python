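"""Characterising the three test frameworks with the survival-rate simulator.

Draws 3x3 genotype tables of 400 survivors under three conditions (null:
Mendelian; alt1: double-homozygote cell survival 0.2; alt2: cell 8 at 0.2,
cell 9 at 1.0, the rest at 0.7), applies the omnibus Monte-Carlo chi-square
and the two co-occurrence indexes per submatrix to every table, and prints
each p-value stream's rejection rate at 0.05 and Kolmogorov-Smirnov
distance from uniformity.  Scaled to 400 tables per scenario so it runs in
seconds; increase n_tables for tighter estimates.
"""

from coinv import evaluate_frameworks, simulate_tables, summarize_pvalues
from coinv.simulate import SCENARIOS

for name, make in SCENARIOS.items():
    scenario = make(n_tables=400, n_individuals=400, seed=11)
    tables = simulate_tables(scenario)
    pvals = evaluate_frameworks(tables, B_inner=1000, seed=12)
    summary = summarize_pvalues(pvals, level=0.05)
    print(f"--- scenario: {name} (survival rates {scenario.survival})")
    print(summary.round(3).to_string(index=False), "\n")

print(
    "Under the null every stream should reject ~5% of the time (slightly "
    "less for the discrete exact tests).  Under alt1 only the sub2 streams "
    "and the omnibus light up; under alt2 the omnibus merges both signals "
    "while sub2 and sub4 separate the inflated and deflated cells."
)
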