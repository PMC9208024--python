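# Methods

This note documents the models, numerical conventions and design choices
behind `scfc`, and what the synthetic-data studies do and do not show.

## Functional connectivity: the corrected amplitude envelope correlation

Source-level MEG signals are analyzed as one concatenated recording: the
first `n_epochs × epoch_samples` samples are selected (defaults 13 ×
16,384 at 1250 Hz, ≈ 170 s), concatenated, and processed as a whole.
Filtering and envelope extraction therefore see epoch boundaries; the
resulting edge effects are negligible at these lengths and are accepted
rather than handled per epoch.

Band-pass filtering is a pure spectral projection: forward FFT, zeroing
of every bin outside the band, inverse FFT. Bins satisfy
`low ≤ f < high` (half-open), so the default bands theta (4–8 Hz),
alpha1 (8–10 Hz) and alpha2 (10–13 Hz) partition 4–13 Hz without
double-counting shared endpoints. The projection is exactly idempotent
and rejects out-of-band power to machine precision; in-band components
that are periodic in the analysis window pass through unchanged.

The AECc of a signal pair is the average of two directed values. For the
direction "y corrected for x": the band-filtered y is orthogonalized
against the band-filtered x by removing its zero-lag least-squares
projection in the time domain, both signals' Hilbert amplitude envelopes
are taken, and their Pearson correlation is computed. Averaging the two
directions is the standard construction and the only one that yields a
symmetric matrix. Envelopes are correlated raw (no log transform, no
downsampling; downsampling is a common variant and could be added as an
estimator option, but the default correlates full-rate envelopes). A
directed term whose residual is identically zero (perfect collinearity)
contributes 0 with a warning instead of propagating NaN.

Matrices are rescaled elementwise by `(AECc + 1)/2`, mapping `[−1, 1]`
onto `[0, 1]` so downstream averages operate on non-negative weights;
independent signals therefore sit near 0.5, not 0.

`fc_matrix` computes all pairs from one filtering/analytic-signal pass
per channel, using the linearity of the Hilbert transform: the analytic
signal of an orthogonalized residual is the same linear combination of
per-channel analytic signals. This is exactly equivalent to the naive
per-pair loop (tested to 1e−10) and makes a 78-node, 213k-sample subject
tractable in tens of seconds.

Whole-brain FC is the mean over all unordered region pairs. Relative
band power is periodogram power inside `[low, high)` divided by total
power excluding DC, averaged over channels.

## Structural connectomes and tract-length stratification

A connectome is a symmetric mean-FA matrix (0 = absent tract) with a
matching tract-length matrix. Matrices are unthresholded; an edge is
"present" iff FA > 0 (a configurable presence floor exists for data
whose absent edges are encoded as small positives). Sparsity is the
fraction of absent upper-triangle edges. Whole-brain SC averages FA over
present edges only — FA is a per-tract mean, so absent tracts are
missing data, not zeros; averaging over all pairs is available as an
option.

Short/long-range thresholds are the 25th and 75th percentiles (linear
interpolation between order statistics) of present-edge tract lengths
pooled over all healthy-control subjects — pooling, rather than
averaging per-subject quartiles, matches the idea of one group-level
length histogram. Classification uses strict inequalities; an edge whose
length equals a threshold is present but unclassified. Fixed threshold
overrides can be supplied to reproduce published class definitions.

## Coupling statistics

Within-subject coupling is the Pearson correlation of a subject's FA and
FC values over one edge class, using the subject's own presence mask
intersected with the group-level length classes — the only
self-consistent choice when per-subject matrices are unthresholded.
Correlations require ≥ 3 edges; fewer yields NaN with a warning and
listwise exclusion downstream. Between-subject correlations relate
per-subject mean SC to mean FC across a group's subjects; p-values use
the exact t transform with n − 2 degrees of freedom. Cross-class
variants (mean SC of one class vs mean FC of another) probe whether the
classes carry distinct information.

## Group statistics and ROC

Group comparisons are OLS linear models with reference-coded group
indicators plus covariates (age + sex for coupling outcomes; age + sex +
education, as a binary low/high indicator, for SC/FC outcomes). The
omnibus group effect is the F test on the indicator block; pairwise
contrasts are tested on the same adjusted model (not two-group refits),
with unadjusted p-values interpreted only when the omnibus passes its
Bonferroni-adjusted alpha (α/2 for the two range classes, α/3 for the
three pairwise comparisons). Adjusted means are model predictions at the
sample-mean covariate values.

ROC analysis uses the rank-based (Mann–Whitney) AUC with ties counted
1/2, oriented so that higher scores predict impairment. The p-value
against AUC = 0.5 uses a normal approximation with the Hanley–McNeil
standard error evaluated under the null — the reference SPSS variant is
unspecified, so the choice is documented here and a within-class
bootstrap p is available as an option. The optimal cutoff maximizes
sensitivity + specificity over observed thresholds (predict positive at
score ≥ cutoff), ties broken toward the lower threshold.

The cognitive impairment rule is deterministic: a patient is CI when at
least two of seven domain z-scores (computed against healthy-control
norms) are ≤ −2, otherwise CP. Missing domains raise an error rather
than being imputed.

## Pipeline order and gating

Stages run in the canonical order listed in `scfc.pipeline`. Band gating
uses raw p < 0.05 on the whole-brain between-subject correlation in
either patients or controls; only gated bands are explored further, and
skipped stages are logged. Choice of Pearson vs Spearman for clinical
correlations is an explicit argument, never an automatic normality test.
Every output table carries a hash of the full configuration, and a fixed
seed makes runs byte-reproducible end to end.

## The synthetic cohort generator

The generator's defaults encode the study conditions: 40 HC / 46 CP /
33 CI subjects, 78 cortical nodes, 13 epochs of 16,384 samples at
1250 Hz, theta/alpha1/alpha2 bands with coupling planted in theta.

* **Tract lengths.** One shared template per cohort: Beta(2, 4) draws
  mapped onto 10–250 mm — a right-skewed, unimodal, bounded shape
  consistent with empirical tract-length histograms. Subjects deviate
  from the template by N(0, 2 mm) jitter, so group-level thresholds
  apply meaningfully to every subject.
* **FA.** `fa_base (0.50) + subject offset − 3·10⁻⁴/mm · length` plus
  N(0, 0.02) edge noise, clipped to [0, 1]; CI subjects lose a further
  0.03 on long-range edges (above the within-subject 75th length
  percentile), emulating preferential long-tract damage. 15% of edges
  are absent. The per-subject offset (SD 0.012) creates between-subject
  SC variation.
* **Planted coupling.** On present edges the target envelope correlation
  is affine in FA with a group-specific slope (HC 0.2, CP 0.35, CI 0.9)
  around a base level of 0.25, plus N(0, 0.05) edge noise; the planted
  headline is the ordering (stronger coupling with impairment).
  Slopes are free parameters because no quantitative effect size beyond
  group means is available; the defaults were sized by a power analysis
  so that a 15/15/15 cohort detects the CI-vs-HC contrast reliably —
  deliberately stronger than a realistic clinical effect, so that
  replicated desk-scale studies are decisive.
* **Between-subject relation.** A subject's overall FC level moves
  opposite to their FA offset (slope −1.2, level noise SD 0.012),
  planting the negative SC-FC correlation that the band gate must
  detect.
* **Signals.** Latent slow Gaussian drivers (band-limited below 1 Hz)
  are mixed through the symmetric matrix square root of the target
  correlation matrix (projected to the nearest PSD correlation matrix
  when edge-wise planting makes it slightly indefinite), shifted,
  floored at 0.05, and used to amplitude-modulate independent
  band-limited noise carriers (modulation depth 0.4, 5% broadband
  additive noise). Estimated AECc is attenuated relative to the target —
  rectification and orthogonalization both shrink correlations — but
  monotone in it; the map is characterized empirically in tests rather
  than assumed to be the identity.
* **Fast realization.** `mode="fc"` skips signal synthesis and takes the
  planted correlation as the AECc estimate (null bands get pure
  estimation noise). Replicated calibration studies use this idealized
  estimator; single-subject and recovery tests use the full signal path.
* **Cognition and demographics.** CI subjects get 2–5 domains forced
  below −2; CP/HC profiles are resampled so at most one domain crosses
  the threshold, making labels exactly consistent with the rule. Age,
  sex and education distributions follow the study's descriptive table.

### What the synthetic studies show — and what they do not

Passing tests demonstrate that the estimators and statistics are correct
and calibrated under the generative model: linear SC→FC planting,
Gaussian noise, a single planted band, no spatial autocorrelation of
leakage, no volume-conduction geometry, no head-motion or physiological
artifacts, and cognitive scores that follow the labeling rule exactly.
They do not validate the neuroscientific claims on real MEG/dMRI data,
where leakage is spatially structured, SC-FC relations are nonlinear and
regionally heterogeneous, and effect sizes are far smaller.

## Numerical and degenerate-input conventions

* Quantiles: NumPy's linear interpolation (`(n−1)p` positioning), stated
  so results are bit-reproducible across implementations.
* Constant vectors raise errors naming the offending side; too-few-edge
  correlations return flagged NaN; empty edge-class selections raise.
* A typeset artifact in the source description of the rescaling
  ("AECc+12") is implemented as `(AECc + 1)/2`, the only reading that
  maps `[−1, 1]` to `[0, 1]` and avoids negative values.
* Rank-deficient design matrices are rejected with the offending columns
  named; groups need ≥ 2 subjects each.
* The Monte-Carlo studies use reduced problem sizes chosen as the
  package's own defaults for desk-scale verification: 500 null
  replicates at 15/15/15 subjects for type-I calibration, 100 planted
  replicates for effect recovery, 20-replicate averages for envelope
  recovery at full 213k-sample series length.

## Known limitations

* No sensor-space processing, artifact rejection or source
  reconstruction: the library starts from source-level time series.
* No regional (per-node) coupling maps, partial correlations controlling
  for distance, or alternative FC metrics (PLI, coherence).
* The envelope generator plants correlations in one band per cohort;
  multi-band planting would require joint PSD repair across bands.
* The Hanley–McNeil null SE is conservative for very small classes; use
  the bootstrap option when n per class is below ~10.
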