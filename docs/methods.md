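# Methods

This note records the models, estimators, parameter choices and numerical
conventions behind spongenet, and what the synthetic testbed does and does
not establish about real data.

## The sponge statistic

For a triplet (lncRNA *z*, miRNA *x*, mRNA *y*) the score is
ΔI = I[x; y | z] − I[x; y], estimated by plug-in on discretized profiles in
log base 2 (bits). Discretization is equal-frequency binning on ranks with
ties broken by stable input order; bin sizes differ by at most one. The
estimator is deliberately the transparent one — a binned plug-in rather
than a rank-kNN estimator — because every value can be checked against a
brute-force summation over contingency cells, which the test suite does
exhaustively for small tables.

Defaults: 6 bins for the miRNA and mRNA profiles (≈ n^(1/3) at cohort
scale) and 3 bins for the conditioning lncRNA, so each stratum keeps enough
samples for a within-stratum joint distribution. Plug-in MI and CMI are
non-negative by construction; tiny negative values from floating-point
round-off are clipped to zero. ΔI itself may be negative.

Significance: the lncRNA profile alone is permuted across samples (500
permutations by default) and p = (1 + #{null ΔI ≥ observed}) / (B + 1) —
one-sided toward positive ΔI (sponging predicts CMI > MI), add-one so p is
never zero, ties counted as exceedances. The observed CMI is computed
through the same batched code path as the null draws so exact float ties
compare correctly. Two estimator facts shape the test's behaviour at desk
scale:

* chance stratification inflates the plug-in CMI by roughly
  (B_z−1)(B_x−1)(B_y−1)/(2n ln 2) bits, so the permutation null is centred
  well above zero at n of a few hundred — the test compares against that
  null, not against zero;
* informative stratification concentrates the within-stratum joint tables,
  which *reduces* this finite-sample inflation, so the observed ΔI needs a
  genuine conditional-dependence gain to beat the null. Marginal sponge
  effects are therefore harder to detect at small n than the asymptotic
  ΔI would suggest.

Sponge screening is run within a single condition (tumor samples in the
pipeline). Mixing tumor and normal samples lets the group contrast dominate
both MI and CMI, which masks the sponge geometry; within-condition
inference measures the regulatory coupling itself.

## Synthetic cohort model

Counts are negative-binomial: feature i, sample j has mean
lib_j · 2^{M_ij} and variance μ + φμ² (dispersion φ = 0.1 by default,
per-feature override available). Per-feature base levels are lognormal
(log2 mean 6, sd 1.5); library-size factors are lognormal with σ = 0.15.
Latent log2 means M compose additively:

* **DE features** (a 20% fraction per RNA class by default) shift by
  ±2 log2 units in tumors.
* **Sponge triplets**: lncRNA and miRNA get independent latent axes
  (sd 1.5 log2 units). Free miRNA is f = m · (1 − s · u) where m is the
  latent miRNA abundance, u the rank-scaled lncRNA level and s the sponge
  strength; the target mRNA mean is multiplied by exp(−k · f / mean(f)),
  so k (default 3) is the log-repression at the average free-miRNA level.
  Tumor shifts for triplet members follow ceRNA-consistent directions
  (lncRNA and target together, miRNA opposite), so the group contrast
  reinforces rather than scrambles the within-condition sponge geometry.
  Triplet members are kept well expressed (base floored at the cohort's
  log2 mean): lowly expressed candidates are noise-dominated and are not
  what a ceRNA screen operates on.
* **Stage features** add a monotone offset (+1 log2 per stage step by
  default) across stages II → III → IV; stage labels follow the 116:238:8
  composition of the emulated cohort.
* **LNM signal** enters two ways: standalone markers shifted by 1 log2 in
  LNM-positive tumors, and coexpression-module factors whose mean shifts by
  one factor-SD in LNM tumors — so whole modules are weakly informative,
  the situation the hub-gene → classifier chain is designed for. The LNM
  rate defaults to 75/367.
* **Modules** share a latent factor: members are
  1.5 · (√ρ · F + √(1−ρ) · ε) around their base, giving pairwise latent
  correlation ρ (default 0.9; counting noise attenuates the observed
  correlation to ≈ 0.9ρ at these expression levels). Module members are
  likewise floored to adequate expression.

One global seed drives a hierarchy of independent substreams (design,
means, biological noise, modules, sponge latents, library sizes, counts),
so the same seed is bit-reproducible and enlarging one block does not
reshuffle the others. Companion generators emit interaction tables (planted
edges present in all three target tables, decoy triplets over DE features,
plus noise pairs that the three-way intersection mostly removes) and
drug × gene rank matrices with planted signature-reversing drugs.

What the generator does **not** emulate: batch effects and other technical
structure, isoform-level signal, alias/identifier noise in interaction
databases, dependence between miRNA pools across triplets, or copy-number
and methylation layers. Passing tests establish that each algorithm
recovers the structure it is designed for under a faithful noise model —
not that the thresholds are optimal for any particular real cohort.

## Differential expression

Counts are normalized to log2(CPM + 0.5); an optional quantile
normalization assigns every sample the mean sorted profile. The location
test is Welch's t on normalized values with Benjamini–Hochberg correction
across all features tested; the test is a pluggable callable so a
negative-binomial exact test can be substituted without touching the
filtering rule. Calls are strict: up means log2FC > 1.5 **and** FDR < 0.05
(down symmetric). log2FC is the difference of group means on the log2-CPM
scale, so swapping the groups negates it exactly.

## Network assembly

Identifier matching is string-based after trimming and case-folding — no
alias resolution, which is database-specific. miRNA–mRNA edges must appear
in all three prediction tables; duplicates are dropped on load with a
logged count. The assembled network keeps only miRNAs bridging ≥ 1 lncRNA
and ≥ 1 mRNA; triplet enumeration is the product over each miRNA's partner
sets, deduplicated and sorted, so assembly is order-invariant and exports
diff cleanly (SIF plus a node-attribute table).

## Stage screening

All pairwise two-sample KS tests among stages with ≥ 2 samples (smaller
arms are dropped with a warning — stage IV arms are often tiny); the
per-feature combined p is the Bonferroni-scaled minimum over pairs, then BH
across features, significant at strict `<`. The combination is slightly
conservative (measured type-I fraction ≈ 0.03–0.05 at nominal 0.05). How
the original three-group comparison was combined is not specified anywhere;
pairwise-KS-with-Bonferroni uses only the named test and errs conservative.

## Coexpression

Unsigned soft adjacency |pearson|^β with β = 12 taken as given (no
scale-free fit diagnostics), zero diagonal, constant features zeroed with a
warning. Modules come from average-linkage clustering of 1 − adjacency
with a static cut at height 0.995: at β = 12 the adjacency of uncorrelated
features is ≈ 0, so unrelated features sit at distance ≈ 1 and the cut
height mainly decides how weak a module member may be
(1 − 0.995 = 0.005 ⇒ mean |cor| ≈ 0.64 to the block). Static cutting is
deterministic and dependency-free; the height is exposed. Clusters below
`min_size` become an explicit "unassigned" bucket. The eigengene is the
first principal component of the module's standardized expression,
sign-oriented so mean kME ≥ 0; kME is each gene's correlation with the
eigengene. Degree is computed on the *thresholded* adjacency
(a ≥ cutoff), matching the joint use of a 0.8 cutoff with a degree rule,
and the hub rule is strict (degree > 10). Note the arithmetic consequence:
adjacency ≥ 0.8 at β = 12 requires |cor| ≥ 0.8^(1/12) ≈ 0.9816, which
noisy count data rarely reach — the pipeline logs a fallback to module
members when no hub qualifies, and the cutoff is a config value for
deliberate relaxation. A topological overlap transform is intentionally not
applied.

## LNM classifiers

Labels are +1 (non-LNM) and −1 (LNM); LNM is the positive class for
precision. Descriptor screening deletes |r| < 0.1 against the label
(undefined correlations from constant descriptors are deleted with a
warning), with an optional second stage keeping correlation-test p < 0.05 —
both stages exist because the original screen is described both ways; they
are toggleable. The four learners are scikit-learn's LogisticRegression
(L2, standardized inputs), RandomForest (100 trees, √p features per
split), kNN (k = 5, Euclidean on standardized features) and GaussianNB —
all configuration-level choices, since the original canvas defaults are
unrecorded. Metrics (AUC, precision, accuracy) are computed on predictions
pooled across held-out folds rather than averaged per fold, which is stable
under small folds; schemes are stratified 5-fold CV, ten stratified
3:2 random splits, and leave-one-out, all driven by one seed. "Precision"
is reported as positive predictive value with accuracy alongside, since
the original metric name is ambiguous. Calibration points are (mean
predicted probability, observed rate) in ten equal-width bins of pooled
out-of-fold probabilities; empty bins are skipped.

## Connectivity scoring

For a gene set at ascending ranks V(1..t) in an n-gene drug ranking,
a = max_j(j/t − V(j)/n) and b = max_j(V(j)/n − (j−1)/t); the enrichment
score is a if a > b else −b. Exact consequences of this (Lamb-style)
running statistic, which the tests pin down: a top-t set scores 1 − t/n
(reaching 1 − 1/n at t = 1); a bottom-t set scores −(1 − (t−1)/n − ... ) =
−((n − t + 1)/n), e.g. −0.96 at t = 5, n = 100; and rank reversal
flips the score only up to the 1/n discretization, with exact a = b ties
breaking the symmetry entirely. The combined score is 0 when ES_up and
ES_down share a sign, otherwise (ES_up − ES_down)/2 — negative marks a
signature-reversing drug. Because the same-sign rule puts a point mass at
zero, permutation p-values are computed one-sided on the *raw* combined
statistic (no zero rule) against random gene-set draws of the same sizes;
that statistic is continuous under the null, so null p-values are uniform.
Replicate instances of a drug are averaged into `mean_score`; the reported
`enrichment_score` comes from the instance-pooled profile (ranks averaged
across instances, re-ranked), switchable to the largest-magnitude instance.

## Pipeline

Eight stages (simulate → diffexpr → assemble → sponge → progression →
coexpress → classify → cmapscreen) run from one validated config
(pydantic; unknown keys rejected, each parameter range-checked) whose
defaults are the published parameter set — log2FC 1.5, FDR 0.05, 500
permutations, β 12, cutoff 0.8, degree 10, |r| 0.1, alphas 0.01/0.05 — on
a 200-sample fixture. The coexpression stage pools the top 150 mRNAs by
LNM-contrast p-value; the drug stage caps the query signature at 50 genes
per direction by FDR. One global seed is split into per-stage substreams;
every table is written with a fixed float format; the manifest records
parameter echoes, per-stage row counts and SHA-256 digests, so identical
configs reproduce identical bytes. Stage failures raise a typed error
carrying the stage name and a machine-readable code.

## Problem sizes

The bundled test and acceptance workloads use desk-scale problems chosen to
make each property measurable with comfortable margins: cohorts of 100–550
samples and 200–400 features, 500 null triplets at n = 200 for calibration,
10-seed replications for recovery and operating-characteristic checks, and
500-drug null matrices for p-value uniformity.

## Known limitations

The DE engine is a transparent Welch-t approximation, not an NB GLM with
dispersion shrinkage or TMM normalization. The binned plug-in MI estimator
trades efficiency for verifiability; a rank-kNN estimator would have more
power per sample. Static tree cutting will not resolve nested or
overlapping modules the way dynamic hybrid cutting can. The connectivity
screen fixes one self-contained scoring convention and makes no claim
about any external service's internals. None of the planted-recovery
results transfer guarantees to real cohorts with batch structure or
identifier noise.
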