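# Methods

`crtsig` implements a pipeline for deriving and evaluating a treatment-response
gene signature from heterogeneous transcriptomic cohorts of locally advanced
rectal cancer (LARC) treated with neoadjuvant chemoradiotherapy (nCRT), and for
analyzing paired tumor/stroma digital-spatial-profiling (DSP) data from
pre-treatment biopsies. Every stage can be driven by a synthetic-cohort
generator with known ground truth, so the statistical behavior of the whole
chain is testable without external downloads.

## Response labels

Pathological response is harmonized to the Mandard tumor-regression grade
(TRG): grades 1-2 are responders, grades 4-5 non-responders, and grade 3
(pathological mid-responders) is excluded from every supervised step. The
mapping lives in `crtsig.cohort.TRG_RESPONSE_MAP` and is configurable.

## Cross-platform harmonization

Microarray intensities and RNA-seq counts have incompatible distributions, and
global batch correction across platform families either fails to remove the
platform effect or destroys signal. The pipeline therefore uses the
conservative transform: `log2(x+1)` on raw counts (intensity cohorts are
assumed already log-scale; a flag forces the transform for raw intensities,
and the synthetic generator's intensity cohorts use it), then per-gene mean
centering and standardization *within each dataset* ((n-1)-denominator SD),
then merging on the shared gene set. Any additive gene-wise batch offset and
multiplicative scale difference is removed exactly by construction; genes with
zero variance in any dataset are dropped as uninformative. The per-(dataset,
gene) means and SDs are stored so held-out samples of a known dataset can be
projected reproducibly.

## Cross-validated differential expression

Feature selection runs a per-gene linear model of harmonized expression on
batch indicators plus a responder indicator, `~ batch + response`, inside a
cross-validation loop: samples are split into 10 folds stratified by response,
and the model is fitted on every combination of 8 of the 10 folds — C(10,8) =
45 runs. Per gene, the maximum and the mean p-value over runs are recorded
(max-thresholding is equivalent to intersecting the per-run significant
lists); the signature uses the looser mean-p < 0.05 rule to give the
classifiers a wider search space, applied to two analyses (all datasets and a
configurable dataset subset) whose gene lists are intersected. Gene order is
deterministic: ascending mean p of the all-dataset analysis, ties broken by
gene id. No multiple-testing correction enters selection (BH-adjusted columns
are reported for transparency only).

Per-gene tests use empirical-Bayes moderated t-statistics: with residual
variance s_g^2 on d_g degrees of freedom and a scaled inverse-chi-square prior
(d0, s0^2) estimated by the method of moments on log s_g^2 across genes
(trigamma inversion by Newton iteration), the posterior variance is
s~_g^2 = (d0 s0^2 + d_g s_g^2)/(d0 + d_g) and t = beta/(s~_g sqrt(v)) is
referred to t with d0 + d_g df. When the observed spread of log-variances does
not exceed chi-square sampling noise, d0 = infinity and all genes share the
pooled variance. The closed forms were cross-checked against an independent
R implementation of the same moderated statistics (agreement to ~1e-15 on a
fixed fixture) and are tested against an in-suite brute-force oracle. A plain
ordinary-least-squares mode (`moderated=False`) is kept for ablation. Batch
columns aliased with the response (a dataset entirely inside one class) are
dropped with a warning; selection seeds for the two analyses are independent
and recorded.

## Signature evaluation

Two classifiers are evaluated on the selected genes under outer 5-fold
stratified cross-validation with tuning confined to each training split:

- **L2 (ridge) logistic regression** — penalty lambda tuned by inner 5-fold
  cross-validated AUC over a 20-point log-spaced grid on [1e-4, 1e2]
  (scikit-learn `LogisticRegression`, C = 1/lambda).
- **Random forest** — 500 trees fixed; features-per-split tuned over a
  20-point grid spanning 1..p by *out-of-bag* AUC. OOB estimation is the
  natural inner resampling for a bagged ensemble and avoids refitting the
  forest 100 extra times per fold; for the sample sizes here it ranks
  hyperparameters the same way an inner CV does.

The reported performance is the mean and (n-1) SD of the five out-of-fold
AUCs, where AUC is computed in its Mann-Whitney form (midranks, exact tie
handling). Outer folds are stratified to preclude single-class test folds.
`score_samples` projects new cohorts with the stored transform and tolerates
up to 20% missing signature genes by imputing the harmonized mean (0).

## Subtype association

Associations between a binary molecular-subtype label (e.g. CMS3 vs CMS4,
iCMS2 vs iCMS3 — labels produced by external classifiers and consumed as
annotation) and response use the ordinary chi-square test of independence on
the 2x2 table, without continuity correction by default; the Yates-corrected
variant is a flag.

## Spatial QC and normalization

Segment QC applies the study thresholds exactly as stated, with ">"-phrased
rules strict and "minimum of"-phrased rules inclusive: raw reads >= 1000,
trimmed > 80%, stitched > 80%, aligned > 75%, saturation > 50%, per-segment
geometric mean of negative-control probes >= 1 (the per-segment reading of
the "minimum negative control count of 1" rule), no-template-control count
<= 9000, nuclei >= 20, area >= 1000 um^2. Probe QC flags local outliers per
target and segment with an iterated two-sided Grubbs test at alpha = 0.01 on
log2(count+1) (targets with < 3 probes are skipped; note Grubbs at n = 3 and
alpha = 0.01 cannot flag anything, a property of the critical value), and
removes a probe globally when its geometric mean falls below 10% of the mean
of its target's probes (negatives exempt) or when it is locally flagged in
more than 20% of segments. Gene-level counts are per-segment geometric means
of surviving probes (counts clipped at 0.5 before logs, the DSP-toolkit
convention). The per-segment limit of quantification is
geomean(negatives) x gSD(negatives)^2, floored at 2; detection is count >
LOQ, strict. Segments detecting < 10% of genes are removed first, then genes
detected in < 10% of surviving segments. Q3 normalization divides each
segment by Q3_s / geomean(Q3) with type-7 (linear-interpolation) quartiles,
so the geometric mean of normalized Q3s equals the original geometric mean.

## Mixed models, consensus and categories

Each gene's log2 Q3-normalized expression is modeled as
`y = mu + tumor + response:tumor + response:stroma + u_patient + eps` with a
patient random intercept absorbing patient and batch technical variability
(batch is deliberately not a separate term). The parametrization yields the
within-compartment responder-minus-non-responder contrasts directly; the
interaction is their difference (a planted +1.5/-1.5 opposing gene gives an
interaction of +3 under this sign convention). Fitting is REML, profiled over
the variance ratio after an orthonormal within/between-patient rotation that
is shared across genes, which makes per-gene fits ~3 ms; estimates, SEs,
Satterthwaite degrees of freedom (gradient of the contrast variance against
the inverse observed REML information, both by central differences) and
p-values agree with lme4/lmerTest to ~1e-9 on a frozen fixture and with
statsmodels MixedLM on random data. Boundary fits (variance ratio below 1e-6)
are refitted as fixed-effects OLS and flagged `singular`, with residual df; a
residual-df fallback replaces Satterthwaite when the numerical information is
degenerate. p-values are BH-adjusted per contrast family (tumor, stroma,
interaction) across genes.

Marker robustness uses patient resampling: five bootstrap draws of patients
with replacement (without-replacement subsampling is a mode), refitting all
genes per draw, collecting genes whose smallest family q-value is below 0.05
(the min-q rule; the per-run significance family is configurable), and
reporting only genes significant in every run. Resampled duplicate patients
become distinct random-effect levels; single-class draws are redrawn.

Categories follow from the full-data fits: both compartments significant with
the same effect sign -> `both`, with opposite signs -> `opposing`; one
compartment significant -> `tumor_only`/`stroma_only`; otherwise a
significant interaction with opposite signs -> `opposing`; else `none`. A
strongly opposing gene is individually significant in both compartments, so
opposite-sign double significance must map to `opposing`, not fall through.

Pseudo-bulk profiles average tumor and stroma segments per patient on the
linear scale, weighted by nuclei counts; patients with a single available
compartment pass that compartment through unchanged; log2(v+1) is applied
afterwards.

## Synthetic cohorts

**Bulk.** Each dataset draws gene baselines log-normally (log2 mean 6, SD
1.5), gene-wise additive batch offsets (SD 0.8) and multiplicative scale
jitter (SD 0.1 on the log), TRG grades per sample from a distribution with
45% responders among evaluable patients and 15% mid-responders (matching the
attrition of a realistic multi-cohort LARC collection), and planted genes
shifted +/- lfc/2 by response (mid-responders sit at 0). Intensity platforms
add Gaussian log2 noise (SD 1.0) and exponentiate; count platforms draw
negative binomials (dispersion 0.15) around the log-normal means. Defaults of
2 datasets x 60 samples reflect typical GEO series sizes; all values are
configurable and validated.

**Spatial.** Each of 50 patients contributes one tumor and one stroma
segment (dropout configurable) with response split 50/50, per-gene patient
random intercepts (SD 0.5), a gene-specific tumor/stroma baseline separation
(SD 1.0, producing the expected compartment DEG structure), gene-segment
noise (SD 0.7), 4 probes per target with persistent efficiencies
(lognormal SD 0.15, clipped at 2 sigma) and per-probe-segment lognormal
overdispersion (SD 0.3) on top of Poisson counting noise, and 20 Poisson
negative-control probes with shared mean 3. QC sabotage is explicit: a
configured fraction of segments violates exactly one named threshold, and a
configured fraction of probes (at most one per target, only on targets with
baseline log2 >= 5) has its efficiency set to 2%. The clipping, the noise
floor and the expression-eligibility rule exist so that "the QC removes
exactly the injected failures" is a well-posed property: without them the
generator occasionally produces genuine outlier probes that the QC correctly
removes, or injects "failures" on near-background targets that no defensible
rule could detect.

What the generators do *not* emulate: probe sequences and GC/length biases,
count-depth (library-size) variation, correlated gene modules, image/ROI
geometry, and real platform-specific probe annotation drift. Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under the stated generative assumptions, not performance on any
real cohort.

## Problem sizes used by tests and the acceptance script

Null calibration uses 2,000 genes across three datasets of 67 samples (two
intensity, one count); signal recovery plants 20 genes (|lfc| = 1.5, balanced
signs) in 2,000 genes across an intensity and a count dataset of 150 samples
each; the spatial experiments use 50 patients and a 200-target panel with 24
planted markers (8 per category, |lfc| 1.5-2, balanced signs), replicated 20
times for the recovery study. Balanced planted signs matter at this panel
scale: Q3 normalization assumes most genes unchanged, and a small panel with
a quarter of its genes shifted in one direction leaks a systematic
pseudo-effect into every null gene — at the scale of real whole-transcriptome
panels the same leakage is negligible.

## Known limitations

- Bootstrap consensus on a fixed cohort cannot reject a null gene whose
  chance association is large in the original draw: resamples share most
  patients, so such genes persist in all runs. With ~176 null genes we
  observe ~1 consensus null per simulated cohort. Consensus shrinks
  instability, it does not guarantee purity.
- BH adjustment is applied per contrast family; the min-q consensus rule
  spans three families without cross-family correction (configurable).
- The Satterthwaite machinery assumes the two-variance-component structure;
  crossed random effects or per-compartment residual variances are out of
  scope.
- Probe re-annotation, RUV/ComBat batch correction, CMS/iCMS/RSS
  classification and pathway enrichment are deliberately outside the package;
  subtype labels are consumed as input.
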