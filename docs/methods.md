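# Methods

This note records the models and procedures the package implements, the
defaults it ships with and why, and what its validation on synthetic data
does and does not establish.

## Timing model and clustering

The timing proxy is the variant allele frequency: under neutral-ish bulk
sequencing assumptions, mutations acquired earlier are more clonal and
show higher VAF. For each patient we average the VAFs of mutations falling
in genes assigned to each of the ten canonical hallmarks (a mutation in a
gene mapped to several hallmarks contributes to each), rank hallmarks by
descending mean VAF (rank 1 = inferred earliest, ties averaged), and
cluster patients on the 10-dimensional mean-VAF vectors.

Clustering is mean-centred PCA (full SVD, every component retained — so
k-means on the scores is exactly k-means on the centred data, which a
fixture test verifies) followed by k-means (k-means++ initialisation,
`n_init=25` restarts, 300 Lloyd iterations, tolerance 1e-6, fixed seed,
default 123). The cluster count comes from the elbow of the WSS curve,
formalised as the k maximising the second forward difference
WSS(k−1) − 2·WSS(k) + WSS(k+1), ties to the smallest k; a near-linear
curve is flagged as "no clear elbow". Silhouette widths (Euclidean) are
reported per sample and on average as clustering QC. The cluster whose
mean genome-instability rank is lower is named EGI, the other LGI; the
margin between the two cluster means is reported as a labelling
confidence diagnostic, and exactly equal means raise an error rather than
an arbitrary label.

Design choices where the method was genuinely open:

- *No variance scaling before PCA.* All ten features are mean VAFs on the
  same [0, 1] scale; scaling would up-weight the noisiest hallmarks. The
  profile matrix is exposed so callers can standardise first if desired.
- *Patients missing any hallmark are dropped from clustering* (logged),
  not imputed, by default; `impute=True` fills missing hallmarks with the
  patient's overall mean VAF instead. Dropping is conservative: imputation
  with the overall mean fabricates a mid-pack rank for the missing
  hallmark.
- *Tie ranks are averaged* (standard mid-rank convention).

## SBS96 classification and signature refitting

Substitutions are collapsed to the pyrimidine strand (purine references
are reverse-complemented together with their trinucleotide context),
giving 6 substitution classes × 16 flank combinations = 96 channels in
the COSMIC ordering (C>A block first, alphabetical flanks). Insertions,
deletions, multi-base variants and records whose context disagrees with
the reference base are rejected and counted by reason. Samples with fewer
than 50 classified mutations are excluded before refitting — below that,
a 96-channel decomposition is unreliable.

Refitting follows the deconstructSigs scheme: the observed spectrum is
normalised to fractions; starting from zero weights, each iteration
golden-section-optimises every signature's weight in [0, 1] holding the
others fixed and commits the single update that most reduces the
sum-of-squared reconstruction error, stopping when the improvement falls
below `tol = 1e-3`. Weights below `trim = 0.06` of the total are zeroed
and the survivors refit (repeated until all retained weights clear the
threshold); if the weights sum above 1 they are renormalised, and
`unexplained = max(0, 1 − Σw)` is reported along with the final SSE. Both
constants are configurable; 0.06/1e-3 are the published defaults of the
refitting scheme. No trinucleotide background (exome↔genome) correction
is applied by default. A nonnegative-least-squares fit over the full
catalog serves as an independent oracle in the tests, never as the
implementation.

Dominant signatures are the per-sample argmax of the fitted SBS weights
or of a supplied CN exposure row; exact ties resolve to the
lexicographically smallest name with a tie flag. CN signature extraction
itself is out of scope — exposures are consumed as input, and a supplied
CN catalog is only checked for the 48-channel dimension.

## Association statistics

- **Contingency**: per signature, a 2×2 (dominant vs not × EGI/LGI).
  Pearson chi-square without continuity correction when every expected
  cell is ≥ 5, otherwise two-sided Fisher's exact (sum of hypergeometric
  probabilities ≤ the observed table's — the R convention). BH adjustment
  is applied within each family (CN and SBS separately). Zero-margin
  tables return p = 1 flagged degenerate.
- **Bootstrap comparison**: R = 1000 replicates resample patients with
  replacement *within* each cluster (sizes preserved; patient-level
  resampling is the only unit that preserves the count statistic's
  sampling variability) and record per-signature dominant counts. The two
  replicate distributions are compared with the two-sample
  Anderson–Darling test (midrank tie handling; statistic identical to the
  standard k-sample implementation, verified against it). For pooled
  n ≤ 12 the p-value is an exhaustive permutation enumeration; otherwise
  the Scholz–Stephens critical-value interpolation, extrapolated on its
  monotone branch rather than clipped to [0.001, 0.25] so that BH
  downstream sees informative tail p-values. Effect size is Cohen's d
  (pooled SD, n−1 denominators) with the large-sample normal CI,
  SE = √((nx+ny)/(nx·ny) + d²/(2(nx+ny−2))), binned
  negligible/small/medium/large at |d| = 0.2/0.5/0.8 (exact noncentral-t
  CIs are not implemented).
- **Logistic odds ratios**: one univariate logistic model per feature,
  cluster (LGI = 1) on the feature's native scale, no covariates; Wald
  95% CIs; Bonferroni across features. Quasi-complete separation is
  detected (non-convergence or diverging slope) and reported as a bounded
  OR with a flag; constant features return OR = 1 flagged degenerate.
  OR > 1 reads "LGI-associated", OR < 1 "EGI-associated".
- **Mann–Whitney hallmark comparison**: per hallmark, two-sided test of
  the per-patient mean VAFs between clusters, exact enumeration when both
  groups have n ≤ 8 without ties, otherwise the tie-corrected normal
  approximation; BH across the ten hallmarks; the reported estimate is
  the median VAF difference (LGI − EGI).
- **Substitution–VAF control**: SNVs in hallmark genes grouped by
  (gene, pyrimidine-normalised substitution class); per class, Pearson
  correlation across genes between occurrence count and mean VAF (classes
  in < 3 genes skipped). A strong correlation would indicate the VAF
  clustering is confounded by substitution load.

## Synthetic cohorts

The generator plants the structure the pipeline must recover. Per patient,
latent hallmark mean VAFs are a decreasing rank-indexed base sequence
(0.35 down to 0.2375 in steps of 0.0125) permuted by the group's hallmark
order, plus N(0, 0.012) noise clipped to (0.01, 0.99). The default orders
put genome instability first in EGI and fifth in LGI, with
immune-evasion/inflammation leading in LGI — a four-rank shift, i.e.
between-group per-hallmark mean differences of at most ~0.05, the scale
of the cluster differences the analysis is designed to resolve. Mutation
counts are Poisson (mean 12 per hallmark per patient, so ~120 mutations
per patient, comfortably above the 50-mutation filter); per-mutation VAFs
are Beta jitter around the hallmark mean (concentration 120); contexts
are sampled from the 96-channel distribution implied by the group's SBS
mixture against a sparse synthetic catalog (each signature concentrated
on ~10 disjoint channels, so mixtures are well-posed), half emitted on the
purine strand to exercise strand normalisation. One dominant CN signature
per patient is drawn from group-specific probabilities (defaults favour
CN17/CN11 in EGI and CN1 in LGI at roughly 3–4× relative risk) and
encoded as an exposure row whose argmax is that signature. Features are
Gaussian with group-shifted means (standardised shifts ≈ 0.4–0.6,
directions mirroring the planted biology). Defaults: 200 patients per
group; everything reproducible from one seed. `generate_null_cohort`
applies the EGI settings to both groups while keeping labels, for type-I
calibration.

What the generator does *not* emulate: tumor purity and copy-number
distortion of VAF, subclonal architecture, per-patient mixture
heterogeneity (SBS mixtures are constant within a group, so within-group
dominant-SBS variability comes only from sampling noise), cancer-type
structure, and realistic immune-fraction distributions. Passing tests
therefore demonstrate correctness of the algorithms and calibration of
the statistics under a favourable generative model — not robustness to
the confounders of real cohorts.

## Numerical and degenerate-input choices

Golden-section searches run to an interval of 1e-7; the greedy refit caps
at 100 iterations. k-means restarts make the WSS curve nonincreasing in
practice; violations are logged, not repaired. Fisher's two-sided p uses
a 1+1e-9 relative tolerance when summing tables as extreme as observed
(guarding float comparison of hypergeometric masses). The AD statistic of
a constant pooled sample is degenerate (p = 1, flagged). All TSV output
uses `%.17g` floats, which round-trips IEEE doubles exactly and makes
repeated runs byte-identical.

## Validation sizes

The shipped checks use the sizes they state: 200 patients/group for
clustering recovery, 10,000 sampled mutations for mixture refitting, 200
simulated null cohorts (100/group) for false-positive calibration and 200
cohorts (300/group) for relative-risk-3 detection power. These sizes give
stable Monte-Carlo estimates while keeping a full validation run around a
minute on one CPU.
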