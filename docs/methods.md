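# Methods

This note documents the statistical procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Consensus expression model

**Replicate merging.** Samples sharing a structure annotation within a donor
are averaged arithmetically on the stored scale (linear or log2, recorded in
`scale_flag`). Because the subsequent z-transform is location/scale
invariant per gene row, the choice of scale does not affect the calls; the
flag exists so exported matrices are interpretable.

**z-scoring.** Each row (probe or gene) is standardized over the donor's
sampled structures with the sample standard deviation (denominator n−1).
Constant rows are set to all-zero z with a warning; rows with fewer than two
sampled values are dropped. Note a structural attenuation: a cell carrying a
true shift of c·SD appears at |z| somewhat below c, because the shifted
cells inflate their own row's standard deviation. With 3 shifted cells of
c = 4 among ~160 sampled structures the attenuation is mild (mean planted
z ≈ 3.4); among ~40 structures it pulls the mean near 2.6. Recovery claims
are therefore stated at study scale (≈190 structures).

**Thresholding.** Signed calls use |z| ≥ 2.0 with the boundary inclusive
(z = 2.0 is a call). The threshold is a parameter (`z_threshold`, in SD
units, default 2.0).

**Probe collapse.** Each gene is represented by the single probe with
maximal variance of its structure-level expression pooled across all
donors. Pooling across donors (rather than per donor) keeps the
representative probe identical in every donor, which the consensus step
requires. Ties break to the lexicographically smallest probe id and are
logged.

**Consensus criteria.** For each (gene, structure): k = number of donors
whose (merged, collapsed) matrix covers the cell; up/down = counts of
+1/−1 donor calls. A consensus call requires k ≥ the criterion's sampling
floor, max(up, down) ≥ the required support at k, and min(up, down) = 0 —
any significantly opposing donor vetoes the call (strict
unidirectionality). Presets:

- **MD1** — floor 2, support ⌈2k/3⌉. The two-thirds fraction is rounded up
  (k = 5 needs 4 donors); rounding direction was an open choice and ceiling
  is the stricter reading.
- **MD2** — floor = cohort size, support = k (all donors, unanimous).
- **MD3** — floor 2; support = k for k ≤ 4, ⌈2k/3⌉ for k ≥ 5.
- **MD4** — floor 4, support ⌈2k/3⌉.

MD1's "two-thirds of donors" phrasing admits a second reading in which the
sampling floor itself is two-thirds of the cohort (k ≥ 4 for six donors);
the preset uses floor 2 — consistent with MD4 being the same rule
restricted to k ≥ 4 — and `ConsensusCriteria.min_donors_sampled` makes the
other reading a one-field change. The presets provably nest
(MD2 ⊆ MD3 ⊆ MD1, MD4 ⊆ MD1), which the tests assert on random inputs.

At the default synthetic conditions (6 donors, structure sampling
probability 0.85) the MD1 per-cell false-call probability on pure noise is
about 2×10⁻⁴, dominated by structures sampled in exactly 3 donors where
2 agreeing donors suffice.

## Clustering

Genes with consensus calls in at least 5 structures are retained (boundary
inclusive); structures left with no call among retained genes are dropped.
Similarity is the uncentered correlation Σxy/√(Σx²·Σy²) — the cosine about
zero, with no mean subtraction — and a zero-norm vector is defined to have
similarity 0 (warned). Linkage is UPGMA: inter-cluster distance is the
unweighted mean of all cross-pair dissimilarities d = 1 − s, computed via
`scipy.cluster.hierarchy.linkage(..., "average")` and verified in the tests
against a naive O(n³) re-implementation. Clustering operates on expression
values (donor-averaged z by convention); the consensus calls only gate
inclusion. Output includes plain-text CDT/GTR/ATR files for TreeView-style
viewers.

## Coexpression network

Unsigned soft-threshold adjacency a_ij = |pearson(g_i, g_j)|^β with β = 9
(the conventional unsigned default; signed networks are out of scope).
Topological overlap uses the standard unsigned form

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),  TOM_ii = 1

with zero-diagonal connectivities k. Modules come from average-linkage
clustering of 1 − TOM with a **static height cut** plus a minimum module
size (default 30); clusters below the minimum are left unassigned (label 0)
and surviving modules are numbered by decreasing size. A static cut was
chosen over adaptive branch-cutting deliberately: it is a one-parameter,
exactly reproducible rule whose behaviour the tests can pin down
(planted-block partitions are recovered with adjusted Rand ≥ 0.95), at the
cost of less flexibility on nested module structure — module counts are
therefore not comparable to adaptive-cut analyses.

Each module's eigengene is the first right singular direction of the
row-standardized module submatrix, sign-oriented to correlate positively
with the module's mean profile; its variance-explained fraction is
s₁²/Σs². kME is the Pearson correlation of a gene's profile with its
module eigengene; K-within is the sum of a gene's TOMs with co-members
(self excluded).

## Enrichment

Over-representation of a query gene set in a term is the upper-tail
hypergeometric probability P[X ≥ k] for overlap k, term size K, query size
n, background N. The background defaults to all genes on the array.
Multiple testing uses Benjamini–Hochberg by default (Bonferroni available);
BH was chosen as the de-facto default of the enrichment tools this module
replaces. Results sort by (p, term_id) so ties are deterministic.

## Classification harness

Positives are disease-evidence genes restricted to high-confidence
categories (syndromic, replicated — configurable); negatives are
brain-elevated genes minus "group enriched" genes minus any positives.
Feature vectors are the genes' model expression profiles (donor-averaged z
per structure); cells never measured for a gene are imputed as 0 on the z
scale (logged). Using continuous z rather than the {−1,0,+1} calls keeps
more ranking information; the call matrix can be substituted by passing it
as the expression input.

Evaluation is two-step: a stratified 80/20 split (per class, shuffled, cut
at round(0.8·n); e.g. 219/830 positives/negatives → train 175/664, test
44/166), stratified 10-fold cross-validation on the training portion with
pooled-prediction aggregate metrics, then held-out test metrics. ROC
curves sweep all score thresholds with ties grouped; the trapezoid AUC
equals the Mann–Whitney concordance probability with ties counted ½
(asserted to 1e-12 in tests). The default learner is a seeded
scikit-learn random forest behind a fit/predict_proba interface; any
learner honouring that contract can be substituted. Unlabeled genes can be
ranked by positive-class probability as novel candidates.

## Synthetic data generator

The generator emulates the *shape* of a multi-donor brain microarray
study: 6 donors; 190 structures; each donor samples each structure
independently with probability 0.85 (so structures are covered by variable
donor subsets, the situation the k-dependent consensus rules exist for);
1 + Poisson(1) replicate samples per sampled structure; 2 probes per gene.
Per donor, gene and structure, the latent value is
mu_g + N(0, noise_sd) + shift, with mu_g ~ U(6, 12) (log2-intensity-like),
noise_sd = 1, and shift = direction × effect_size × noise_sd for planted
cells in carrier donors. Probes report the gene value scaled toward the
baseline by a per-probe gain (designated probe 1.0, others 0.6) plus
replicate noise (SD 0.25); the gain design makes the max-variance
representative probe deterministic, and because z-scores are scale
invariant it does not distort the planted signal. Noise is Gaussian
because the pipeline consumes only standardized deviations, which makes
tail calibration analytic; carrier-donor selection uses a separate RNG
stream so a zero-effect signal reproduces a signal-free run bit-exactly.

Not emulated: spatial autocorrelation between neighbouring structures,
donor-level covariates (age, sex), probe-specific binding biases,
heavy-tailed intensity noise, and any real anatomical ontology (the
generated ontology is a synthetic two-level forest). Passing recovery
tests therefore demonstrates correctness of the algorithms under the
stated generative model, not performance on real atlas data.

## Problem sizes and numerical choices

Tests and the acceptance script run the consensus recovery at
6 × 190 × 2000 (donors × structures × genes), module recovery on
3 blocks × 40 genes × 60 structures (within-block r = 0.9), and the
classifier on 400 genes × 80 structures with a 60-gene planted positive
class — sizes chosen so each check exercises the study-scale geometry
while completing in seconds. Tolerances: exact algebraic identities are
asserted at 1e-12, UPGMA heights at 1e-10 (accumulated averaging error),
stochastic calibration checks within 2–5 standard errors. Degenerate
inputs (constant rows, zero-norm vectors, rank-0 modules, constant scores)
are defined explicitly and warned or raised as documented in each
docstring rather than propagating NaN.
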