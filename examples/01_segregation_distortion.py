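"""Single-locus segregation distortion in a simulated F2 cross.

Simulates a cross of 300 plants over eight inversion loci, one of which is
a recessive lethal (no inverted homozygote survives), and prints the
per-locus distortion table: the Williams-corrected G statistic against the
Mendelian 1:2:1 expectation, its p-value, the segregation distortion value
SDV = -log10(p), and the gametic/zygotic classification from the
sequential chi-square test.  The lethal locus should dominate the table.
"""

from coinv import CrossConfig, sd_table, simulate_f2_cross

loci = [(f"Inv_{i + 1}", f"chr{i % 5 + 1}", True) for i in range(8)]
cfg = CrossConfig(
    cross_id="demo",
    n_individuals=300,
    loci=loci,
    single_locus_survival={"Inv_4": (1.0, 1.0, 0.0)},  # recessive lethal
    seed=42,
)
matrix, truth = simulate_f2_cross(cfg)

table = sd_table(matrix)
print(table.round(4).to_string(index=False))
print(
    "\nThe planted lethal (Inv_4, zero II survivors) tops the table with a "
    "large G/SDV and a 'zygotic' selection-mode call; the remaining loci "
    "should hover near p ~ uniform."
)
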