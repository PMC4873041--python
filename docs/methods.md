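# Methods

## The conserved-proximity model

The unit of comparison is the orthology class (COG). Within one genome, the
distance between two genes is measured between the integer midpoints of
their coordinates, `floor((start+end)/2)`, on a formally circularized
chromosome (the circular-minimum distance is used whether or not the
chromosome is annotated circular). Distances are normalized to a common
scale by capping at L/2 and dividing: x = min(1, 2d/L) with **L = 500 kb**.
Genes on distinct chromosomes, and pairs where one COG is absent, get
x = 1. The cap matters: real bacterial chromosomes are several times longer
than L, so a random pair lands beyond the cap (x = 1) most of the time and
the informative part of the distribution is the uniform stretch below it.
If a simulated chromosome is made *shorter* than L, every pair in every
genome trivially satisfies x ≤ x_max < 1 and the scan statistic acquires a
degenerate point mass at x_max^M′; the synthetic defaults therefore put
1000 genes (1.1 Mb) on the chromosome rather than a few hundred.

**Phylogenetic weights.** Inter-genome distances are D = 1 − S, where S is
the mean fraction of identical residues over shared un-gapped columns of
single-copy marker-gene alignments (ten markers in the intended corpus;
the matrix can also be supplied precomputed). Each genome is weighted
ω_g = 1/|{h : D_gh < δ}| with **δ = 0.25**, itself included — a clade of k
near-identical strains carries total weight ≈ 1 — and M′ = Σ ω_g is the
effective genome number. Missing distance entries fail fast rather than
being imputed.

**Per-pair statistic.** For genomes containing both COGs, the weighted
count M_ij(x) = Σ ω_g 1(x_ij ≤ x) is compared with the binomial null
through π_ij(x) = I_x(M_ij(x), M′_ij − M_ij(x) + 1), the regularized
incomplete beta function evaluated at real-valued (weighted) counts. The
scan evaluates π only at the observed per-genome variates below 1 — between
observations M(x) is constant and I_x increases in x, so the minimum must
sit on an observation. Multi-copy COGs enter through the nearest copy:
with n copies of the partner COG, p = 1 − (1 − x_min)^n is the
probability-integral transform of the minimum of n uniforms, so the
single-copy machinery applies to p unchanged. Directions (conditioning on
i vs on j) are symmetrized by the maximum. Pairs with the same COG on both
sides are rejected (self-synteny is undefined), and pairs jointly present
in fewer than two genomes are assigned π̂ = 1 without computation.

**Null and threshold.** The positional null redraws gene positions
uniformly per chromosome, preserving copy numbers and weights, and
recomputes π̂; when more null values are requested than COG pairs exist,
independent randomization replicates are concatenated. The density of
y = −ln π̂ has an exponential stretch e^(−ay) beginning just past its mode;
at large y it crosses over to the universal slope 1 (in natural-log units)
forced by P(π̂ ≤ ε) ≥ ε, since each candidate threshold's p-value is
marginally uniform. The fit therefore uses the **early tail**: a fixed-width
histogram (bin 0.25) between the 75th and 99th percentiles of y, least
squares on log counts, empty bins dropped. Fitting a window placed deeper
into the tail (e.g. 90th–99.9th percentiles) lands in the crossover region
and systematically underestimates the early-tail exponent. The exponent is
reported both in natural-log units (a) and per decade of π̂
(a·ln 10), the scale on which tail plots are conventionally drawn.

The false-positive fraction at threshold π is σ_fp = π^a (integrating the
fitted tail); the significant fraction σ_s(π) is the empirical fraction of
pairs with π̂ ≤ π. The threshold π* is the **largest observed** π̂ with
σ_fp/σ_s ≤ FDR, default **FDR = 0.005**. Significance is inclusive
(π̂ ≤ π*): the calibration defines σ_s inclusively, and on gridded
synthetic data many true pairs tie exactly at π*.

**Reference value.** At M′ = 500 independent unit-weight genomes with 4 Mb
chromosomes, the fitted exponent is ≈ 3.2 per decade (≈ 1.4 natural); this
is the quantity `scripts/acceptance.py` recomputes (120 000 pairs, ~15 s).
The exponent is a property of the scan statistic and the corpus geometry:
it falls with shorter chromosomes (weaker censoring at x = 1) and rises
steeply when the weights are fractional, because down-weighted independent
genomes make each candidate p-value conservative. A corpus of equally
weighted, independent genomes is the configuration that the "same effective
number of genomes" null describes.

## Segments

A synteny segment is a maximal run of consecutive genes on one chromosome
such that every pair of COG-annotated members is significant. Genes without
a COG label are skipped by the pairwise condition but remain inside the
genomic span; member pairs carrying the same COG are likewise skipped.
Maximality means no flanking annotated gene extends the run, so segments
may overlap and a gene may sit in several segments or none. The builder is
a two-pointer scan (the pairwise-clique property is hereditary under
shrinking windows) with wrap-around on circular chromosomes; an independent
checker re-verifies the clique and maximality invariants against the pair
table, and the test suite proves equivalence with brute-force interval
enumeration on small chromosomes.

## Synthetic data

The generator's defaults define the study conditions used throughout the
tests.

* **Tree**: random-merge topology with sorted-uniform merge depths,
  distances rescaled to span [0, 0.5]. The uniform depth law keeps the
  number of lineages deeper than δ/2 — and hence M′ — at a realistic
  fraction of the corpus (≈ 23 of 50); a Kingman depth law would collapse
  M′ to ~3 regardless of scaling because almost all lineages coalesce
  immediately on the coalescent timescale.
* **Genomes**: 50 genomes, 1000 COGs, genes of 1 kb separated by 100 bp
  gaps on one circular chromosome (1.1 Mb). Twenty 5-gene clusters are
  planted. Evolution along each branch draws
  Poisson(rate · branch length · n_genes) single-gene relocations
  (rate 10 per unit branch length per gene); an event hitting a cluster
  gene relocates the whole block with probability equal to the cluster's
  retention, and otherwise extracts that gene from the cluster as a
  singleton. Copy numbers are drawn per COG per genome from a configurable
  law (default: always single copy); strands are i.i.d. uniform except
  inside clusters, where consecutive members are co-directional with
  probability 0.9.
* **Expression**: a_si = √ρ_op·z_op + √ρ_seg·z_seg + √ρ_f·Σ_f L z_f +
  noise, with independent standard-normal latents per condition and the
  noise variance balanced so every gene has unit variance (genes outside
  clusters get a private segment latent). Defaults: 400 conditions,
  ρ_op = 0.4, ρ_seg = 0.25, ρ_f = 0.15 — the intra-operon value matches
  what compendium-scale expression data typically show, and the sum stays
  below 1. Factors (TFs and sigma factors) attach to two clusters each,
  disjointly, and directly regulate one operon per attached cluster; an
  optional housekeeping sigma factor regulates a configurable fraction of
  all operons. Closed forms: same-operon pairs correlate at
  ρ_op + ρ_seg (+ ρ_f), same-segment different-operon pairs at ρ_seg (+ ρ_f),
  cross-segment pairs sharing a factor at ρ_f.
* **Tracks**: binding-region midpoints are placed with density multiplied
  by `border_enrichment` (default 5) within 3 kb of planted-cluster
  borders. Coverage is emitted per condition (default 7): co-directional
  consecutive operons read through with probability `readthrough_prob_in`
  (0.8) inside clusters and `readthrough_prob_out` (0.1) outside; a
  read-through run shares one log-normal expression level per condition,
  its internal gaps receive 30 % of that level on the sense strand, and
  the antisense strand carries independent exponential noise. Long
  transcriptional units are the maximal read-through runs; short ones are
  the operons. Read-through studies use 300 bp gene gaps so that
  inter-operonic regions clear the > 100 bp junction filter that excludes
  annotation artifacts.

What the generator does **not** emulate: sequence evolution (distances are
tree-derived, markers synthetic), within-operon distance-dependent decay of
co-expression, realistic read sampling (coverage is emitted directly),
operon structure conserved across genomes, or horizontal transfer. Passing
tests therefore demonstrate the correctness and calibration of the
machinery under the model's own assumptions, not the biological claims on
real corpora.

## Downstream analyses

* **Γ(d)**: mean co-expression over gene pairs binned by circular midpoint
  distance (half-width 0.5 kb), under composable boolean pair filters
  (different-operon, segment co-membership, orientation class, regulation
  status). "Not regulated" means absent from the regulon table.
* **Seg-regulation**: a segment's seg-TFs/seg-SFs are the factors directly
  regulating at least one member operon; cross-segment pairs are classed by
  exact equality of (unions of) seg-factor sets. For genes in several
  segments the union over their segments is compared.
* **Orientation**: DI = Dir(in)/Conv(in) − Dir(out)/Conv(out) and
  CoDI = Codir(in)/(Conv+Dir)(in) − (out), over adjacent gene pairs with
  "in" meaning a shared segment; on a full circular chromosome
  Dir = Conv exactly, asserted as a self-check. k-operon segment
  configurations (k = 2: codirectional/divergent/convergent; k = 3: four
  patterns canonical up to strand-reversal) are tested against cyclic
  translations of the operon orientation sequence, exhaustively up to 10⁴
  operons, with Gaussian z-scores and |z| > 1.65 flags.
* **Border profiles**: per segment, ρ_k(x) averages the binding indicator
  at x1+x and mirrored x2−x (positive offsets point inward), normalized to
  Σ_x ρ_k = 1; the segment average divides by the number of segments.
  Window ±5 kb, bin 50 bp by default. Borders prefer annotated TSS/stop
  positions within 500 bp and fall back to span ends. Region-level
  enrichment near borders (margin 3 kb, midpoint-to-border) and domain
  overlap use a rotation null with p = (1+#{null ≥ obs})/(1+n). Operon
  inclusion uses the gene-translation null with a mid-rank p-value:
  translation counts are heavily tied, and the plain permutation form is
  then structurally conservative (its p-values could never be uniform).
* **Read-through**: junctions are co-directional consecutive operon pairs
  with inter-operonic region (upstream stop to assigned downstream TSS;
  fallback first-gene start) longer than 100 bp. Region expression is
  log2(mean per-base coverage + 1) — base and pseudocount are conventions,
  stated here because the quantity is otherwise only defined up to them.
  Correlations of expr(I) with expr(g) pool junction × condition points,
  stratified in/out of segments and sense/antisense, within unit-width
  bins of expr(g) (minimum 10 points) plus a pooled value.

## Numerical choices and edge cases

* Incomplete-beta tail values agree with exact binomial survival sums to
  10⁻¹² over the full integer grid up to 50 trials (tested); real-valued
  weighted counts generalize the same formula.
* Quantile normalization assigns tied entries the mean of their rank span's
  target values; it is idempotent. Genes with missing values are the
  caller's responsibility (the normalizer rejects NaNs).
* Zero-variance expression profiles yield NaN correlations, flagged rather
  than silently zeroed; Γ bins with no pairs are absent, not zero.
* Degenerate translation nulls (zero variance, e.g. all operons
  codirectional) are reported with z = NaN and a `degenerate` flag.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit arguments; identical seeds give bit-identical outputs.

## Problem sizes

The test suite runs a 50-genome, 1000-COG recovery study (≈ 5·10⁵ pairs,
null of 5·10⁴, ~40 s), 2·10⁵ KS-replicates for null calibration, and a
10⁵-pair tail study at M′ = 500; the acceptance script uses 1.2·10⁵ pairs.
These sizes give standard errors comfortably inside the stated tolerances
(the tail exponent varies by ±0.04 across seeds at this size).

## Known limitations

* The per-pair scan is vectorized for single-copy COGs; pairs involving
  multi-copy COGs fall back to a per-pair path, so corpora dominated by
  large paralog families will be slower.
* The FDR calibration assumes the empirical corpus contains a genuine null
  bulk; corpora where nearly all pairs are conserved (tiny or highly
  clonal collections) make σ_s uninformative.
* The exponential-tail exponent depends on corpus geometry (chromosome
  length relative to L, weight composition); thresholds should always be
  calibrated against the matched null that `simulate_null` provides, not
  transplanted between corpora.
* Linear chromosomes are formally circularized in all distance
  computations, which slightly shortens distances near their ends.
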