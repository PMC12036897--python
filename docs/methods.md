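# Methods

This note records the statistical models implemented in `coinv`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer would want
written down.

## Data model

Genotypes at an inversion locus in an F2 cross are categorical codes
RR / RI / II (reference homozygote, heterozygote, inverted homozygote);
missing entries are allowed and handled by pairwise-complete deletion at
contrast time (an individual missing at either locus of a pair is dropped
for that pair only). Codes are kept as strings rather than 0/1/2 dosages so
that II is never silently conflated with an allele count. A locus
*segregates* in a cross when at least two distinct genotype classes are
observed — a locus with only RR and II (no heterozygotes) still counts.
Pairwise analyses are restricted to segregating loci on different
chromosomes, so association cannot arise from physical linkage.

Each locus contributes two *dosage states*: HET (≙ RI) and HOM_INV (≙ II).
The reference homozygote RR is the implicit absence class and never a state
itself. In table-style labels the suffix `_1` denotes HET and `_2`
HOM_INV.

## Single-locus segregation distortion

The goodness-of-fit test against (¼, ½, ¼) is the G (log-likelihood ratio)
statistic with Williams' small-sample correction,
q = 1 + (k²−1)/(6N(k−1)), df = 2. Zero observed counts contribute 0 to the
sum (the x·ln x → 0 limit); no pseudo-counts or continuity corrections are
applied — the published worked examples are reproduced exactly under this
rule. SDV = −log10(p) is computed through the χ² log-survival function so
it remains finite for arbitrarily large G (for df 2, SDV = G/(2·ln 10)
exactly).

The sequential selection-mode test computes χ²₁ — the allele-balance
statistic 2(n_R − N)²/N with n_R = 2n_RR + n_RI, df 1 — and a second-stage
χ²₂ that is deliberately a *strategy point* with two variants:

* `one_two_one` (default): Pearson χ² of the genotype counts against
  (N/4, N/2, N/4), df 2;
* `hwe_conditional`: Pearson χ² against Hardy–Weinberg proportions at the
  observed allele frequency, df 1, which isolates genotype-distribution
  distortion net of allele imbalance (undefined and flagged when the
  observed allele frequency is 0 or 1).

Neither variant reproduces every published χ²₂ value we could check, and no
standard candidate formula does; the variant used is therefore recorded in
the output rather than hard-coded. Classification: *zygotic* when χ²₂ is
significant, *gametic* when only χ²₁ is, *none* otherwise (α = 0.05 by
default). Benjamini–Hochberg adjustment is applied within each cross, since
crosses are separate experiments.

## Pairwise contingency analysis

The omnibus test of a 3×3 genotype table uses the Pearson X² statistic with
a Monte-Carlo p-value, p = (1 + #{X²* ≥ X²})/(B + 1), because the double
inverted-homozygote cell has Mendelian expectation N/16 and asymptotic χ²
calibration is unreliable at realistic cross sizes. Two expectation/null
modes exist:

* `margins` (default for real data): expectations from observed margins;
  null replicates drawn from the conditional distribution of tables with
  both margins fixed via Patefield's algorithm (`scipy.stats.random_table`)
  — the same null that R's `chisq.test(simulate.p.value = TRUE)` samples.
  The uniform-over-tables alternative was considered and rejected: the
  conditional (multivariate hypergeometric) law is the canonical
  independence null, and the exhaustive-enumeration oracle in the tests
  uses its closed form ∏r_i!∏c_j!/(N!∏O_ij!).
* `mendelian` (default in simulations): expectations N·f_i·f_j with
  f = (¼, ½, ¼); null replicates are multinomial draws. Used where the
  data-generating expectations are known by construction.

Post hoc, each cell gets a standardized residual
SR = (O − E)/√(E(1 − r_i/N)(1 − c_j/N)) with a two-sided normal p-value,
corrected across the nine cells by Benjamini–Yekutieli (the cells share
margins and are therefore dependent), plus its percentage contribution
RC = 100·(O−E)²/E / X² to the omnibus statistic. Cells with E = 0 are
reported as missing.

## Dosage-state decomposition and co-occurrence indexes

A locus pair decomposes into four 2×2 submatrices indexed
sub1 = (HET, HET), sub2 = (HOM_INV, HOM_INV), sub3 = (HET, HOM_INV),
sub4 = (HOM_INV, HET). Cell numbering of the 3×3 is row-major with rows =
locus A, so the "9th cell" is (II, II) and the "8th" is (II, RI).

**The submatrix is the block {RR, state_A} × {RR, state_B}** — individuals
carrying the third genotype at either locus are excluded from that
contrast, and RR plays the role of absence. This choice is load-bearing:
if the 3×3 were instead *collapsed* onto plain state indicators over all
individuals, viability selection on a single genotype combination would
leak into the margins of every submatrix (e.g. survival 0.2 on (II, II)
gives the HET×HOM_INV collapse an odds ratio of 1.67 and ~50% spurious
rejection at n = 400). With the block construction, any submatrix that
avoids the selected cell retains exact product form and stays on the null
— which is also what makes the decomposition interpretable: each contrast
isolates exactly one genotype-combination effect.

*Centered Jaccard/Tanimoto.* J = n11/(n11 + n10 + n01) and
E[J] = pq/(p + q − pq) with p = mA/n, q = mB/n; cJ/T = J − E[J]. The
significance test permutes one vector uniformly, which fixes both margins;
since the statistic depends on the data only through the 2×2 table, the
permutation law of n11 is exactly Hypergeometric(n, mA, mB) and is sampled
directly (B = 10,000 by default; 1,000 inside large simulations). Ties
(|cJ/T*| equal to the observed value) count toward the tail —
conservative. The test suite validates the sampler against explicit
enumeration of all binary arrangements at small n.

*Affinity score.* α is the conditional MLE of the log odds under the
noncentral (Fisher) hypergeometric model with both margins fixed, found by
bounded scalar minimisation of the negative log-pmf (tolerance 1e-8) and
validated against a dense grid search. Tables with n11 at the boundary of
its attainable range have an infinite MLE and return ±cap (default 10,
configurable). The p-value is the exact two-sided central-hypergeometric
test with the minimum-likelihood tail rule (scipy's two-sided
`fisher_exact`); a mid-p option exists but is off by default. A contrast is
flagged "detected by all three" when the cJ/T bootstrap p, the exact α p
and the linked 3×3 post-hoc cell p are all below the significance level.

## Survival-rate simulator

Viability selection on genotype combinations is modelled by per-cell
survival rates s₁..s₉: f_mod = f_e·s / Σ f_e·s (scale-invariant in s).
Tables of survivors are multinomial draws of n individuals from f_mod —
the sampling law is the natural zygotic-viability reading of "survivors
among a fixed-size cohort" and is documented here as the definition.
Presets: `null` (all 1), `alt1` (s₉ = 0.2), `alt2` (s₈ = 0.2, s₉ = 1,
others 0.7). Defaults n = 400 individuals per table; 5,000 null and 2,000
alternative tables with an inner Monte-Carlo/bootstrap B of 1,000 — these
are the problem sizes the package's own distributional checks use, chosen
to give stable rejection-rate estimates at interactive runtimes; all are
configurable upward.

Expected behaviour, verified by the test suite: all nine p-value streams
(omnibus + 2 indexes × 4 submatrices) approximately uniform under the null;
under alt1 only the sub2 streams and the omnibus deviate; under alt2 sub2
and sub4 deviate and the omnibus merges both signals. The discrete exact
tests are mildly conservative (attainable size ≈ 0.04 at these margins),
which the uniformity checks accommodate with a fixed one-percentage-point
allowance below the binomial interval; anti-conservativeness is not
allowed any slack. Classical D and D′ on gamete frequencies are provided
for comparison studies only.

## Networks, motifs, replicated G

Dosage states are nodes; each contrast contributes an edge weighted by its
cJ/T with `significant` = raw bootstrap p < 0.05, plus an omnibus BH flag
per locus pair. Node importance is eigenvector centrality on the
absolute-weight graph (association strength matters, not sign). Motifs are
connected induced subgraphs on 3 nodes (path, triangle) and 4 nodes (path,
star, cycle, tadpole, diamond, clique); the census is delegated to igraph's
isomorphism-class counter and cross-validated against brute-force subset
enumeration. Aliases s.3.x / s.4.x order the classes within each size by
edge count then sorted degree sequence; the canonical
(size, edges, degree-sequence) label is the ground truth and the aliases
are cosmetic. The null model is degree-preserving double-edge-swap
rewiring, 10·|E| attempted swaps per replicate and R = 1,000 replicates by
default (a mixing-vs-runtime compromise; both configurable). Significance
is one-sided over-representation, p = (1 + #{null ≥ obs})/(R + 1), BH
corrected after excluding classes with observed counts below the
min-count threshold (default 200); graphs too sparse to rewire fall back
to the original graph and are effectively non-significant.

The replicated G test for one state pair across crosses sums per-cross 2×2
independence G statistics (G_total, df = Σdf_i), computes G_pooled on the
element-wise summed table (df 1), and takes G_het = G_total − G_pooled
(df = Σdf_i − 1). No Williams correction is applied inside this
decomposition: additivity G_total = G_pooled + G_het holds only for raw G
(a corrected 2×2 variant exists as an option for sensitivity analysis).
Because each cross estimates its own margins, G_het can be mildly negative;
it is reported as computed. A cross with a degenerate margin contributes
G = 0 with df 0. The SDV-interaction summary relates each locus's SDV to
the number of pairwise tests with raw p < 0.05 involving it and to their
mean p, via Spearman rank correlations (undefined and reported missing for
constant inputs).

## Synthetic cross generator

The generator draws independent per-locus Mendelian genotypes, multiplies
the applicable survival rates (single-locus per-genotype and pairwise
per-combination), and rejection-samples until the target number of
survivors is reached — zygotic selection only, matching the inference that
observed distortion reflects differential plant survival; gametic
distortion is not simulated. Loci are unlinked even within a chromosome
label because the analysis only ever tests cross-chromosome pairs. The
default nine-cross design mirrors the real panel: survivor cohorts of
92–188 plants, 64 loci on 14 chromosomes, three loci segregating in every
cross, the rest segregating per cross with probability 0.68 (making ≈46%
of locus pairs valid, matching the published pair accounting), missing
rate 0.02, and — unless disabled — one planted recessive lethal plus two
planted (II, II) incompatibilities with survival 0.2.

What the generator does **not** emulate: genotyping error structure,
linkage and recombination maps, gametic-phase effects, family structure
within a cross, and any correlation between missingness and genotype.
Passing tests therefore demonstrate correctness of the statistics under
the stated selection model, not robustness to those real-data features.

## Numerical and degenerate-input conventions

* Monte-Carlo and bootstrap p-values use the +1 smoothing
  (1 + hits)/(B + 1), so p ∈ [1/(B+1), 1]; tie comparisons use a 1e-12
  slack and count toward the tail.
* All stochastic stages accept either a seed or a shared
  `numpy.random.Generator`; pipelines derive stage seeds from one master
  seed, making outputs a pure function of (inputs, config, seed).
* Degenerate cases are flagged rather than silently dropped: empty
  rows/columns in the omnibus (statistic over non-degenerate cells),
  E = 0 post-hoc cells (missing), degenerate 2×2 margins (contrast
  invalid), unswappable graphs (null = original), constant SDV
  (correlation undefined).

## Known limitations

* The second-stage χ²₂ of the selection-mode test is a documented strategy
  point, not a settled formula (see above).
* The bootstrap/permutation schemes of the upstream R implementations of
  the co-occurrence tests are not published in detail; the schemes defined
  here (margin-preserving permutation; exact conditional test) are the
  package's definitions.
* Monte-Carlo p-values have resolution 1/(B+1); multiple-testing behaviour
  at very small levels requires raising B.
* Motif enrichment conditions only on the degree sequence; other graph
  features (chromosome constraints, sign structure) are not preserved by
  the null.
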