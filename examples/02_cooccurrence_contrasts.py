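"""Pairwise co-occurrence analysis of two unlinked inversions.

Simulates 400 F2 plants where the double inverted homozygote (II, II) has
survival 0.2 — a synthetic incompatibility — and decomposes the locus pair
into its four dosage-state contrasts.  For each contrast it prints the 2x2
submatrix, the centered Jaccard/Tanimoto index with its bootstrap p, and
the affinity score (noncentral hypergeometric log odds) with its exact p.
"""

from coinv import CrossConfig, pairwise_contrasts, simulate_f2_cross

survival = [1.0] * 9
survival[8] = 0.2  # cell 9 = (II, II)
cfg = CrossConfig(
    cross_id="demo",
    n_individuals=400,
    loci=[("Inv_A", "chr1", True), ("Inv_B", "chr2", True)],
    pair_survival={("Inv_A", "Inv_B"): tuple(survival)},
    seed=7,
)
matrix, _ = simulate_f2_cross(cfg)

result = pairwise_contrasts(matrix, "Inv_A", "Inv_B", B=10_000, seed=1)
print(f"omnibus X2 = {result.omnibus.stat:.2f}, Monte-Carlo p = {result.omnibus.p:.4f}\n")
for c in result.contrasts:
    t = c.table
    print(
        f"sub{c.submatrix} ({c.state_a.label} vs {c.state_b.label}): "
        f"[{t.n11} {t.n10} / {t.n01} {t.n00}]  "
        f"cJ/T = {c.cJT:+.3f} (p = {c.cJT_p:.4f})  "
        f"alpha = {c.alpha:+.2f} (p = {c.alpha_p:.4f})"
    )
print(
    "\nOnly sub2 — the contrast containing the deflated (II, II) cell — "
    "should show a clearly negative cJ/T and alpha (repulsion); the other "
    "three contrasts stay near zero because their 2x2 blocks avoid the "
    "selected genotype combination."
)
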