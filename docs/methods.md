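# Methods

`uameth` implements the computational analysis of a longitudinal
two-compartment (peripheral-blood and synovial-fluid) monocyte DNA
methylome cohort in early undifferentiated arthritis (UA): probe filtering
and normalization, empirical-Bayes differential methylation, genomic-context
enrichment, disease-activity (DAS28) correlation and reversion, a
methylation-based DAS28 predictor, and promoter-capture interaction
integration — all exercised end-to-end on a seeded synthetic cohort
generator.

## Measurement model and scales

A methylation array reports a beta value per CpG and sample, the methylated
fraction in [0, 1]. Betas are bounded and heteroskedastic, so all inference
runs on M-values, M = log2(β / (1 − β)), with β clipped to
(1e-6, 1 − 1e-6) to keep the logit finite. Effect sizes are reported as
Δβ — the difference of group mean betas, contrast minus reference — because
Δβ is the interpretable clinical scale; a probe is "hyper" when Δβ > 0.
Whether the original quantile step operated on intensities or β is not
derivable from array output alone; this package quantile-normalizes β and
documents that choice.

One desk-scale caveat: on the synthetic cohort ~5% of probes carry planted
effects (25-fold denser than a real array's differential fraction), so
quantile normalization — which equalizes whole-column distributions —
noticeably redistributes planted mass and dilutes the hyper/hypo direction
bias. The recovery and calibration analyses therefore run on the (already
commensurable) raw synthetic betas; the normalization step remains part of
the real-data path (and the orchestrated pipeline) and is tested on its
own contract.

Probe filtering removes SNP-coincident CpGs (genotype confounds the
methylation signal), chrX/chrY probes (sex-driven discordancy), and a
caller-supplied detection-failure list (detection p-values need raw
intensities, which are out of scope). Quantile normalization maps every
sample onto the mean order-statistic distribution; ties receive the mean of
the reference quantiles they span. Z-scoring uses the sample (n − 1)
standard deviation, applied within each batch independently.

## Differential methylation

Per probe, (weighted) OLS of M on a design built from the sample sheet: a
two-level contrast or a three-level one-way layout, optional numeric
covariates (DAS28), and an optional subject-pairing factor expanded to
blocking dummies. Residual variances are shrunk by the standard
empirical-Bayes scaled-inverse-chi-square model: hyperparameters (d0, s0²)
are estimated by matching the mean and variance of log s_g² to the
log-scaled-F model, inverting the trigamma function by Newton iteration
(tolerance 1e-8); d0 = ∞ when the log-variance spread does not exceed
sampling noise, in which case the moderated t reduces to the pooled-variance
ordinary t. The posterior variance
s̃² = (d0·s0² + d·s²)/(d0 + d) enters t̃ = β̂/(s̃√v) with d0 + d degrees of
freedom. The three-group "any difference" layout uses the analogous
moderated F over the two group coefficients.

Per-sample reliability weights (array weights) are estimated by an
iteratively reweighted scheme: fit weighted OLS per probe, set each sample's
variance factor to the mean leverage-standardized squared residual across
probes (r²_wj / (s_g²(1 − h_jj))) as a multiplicative correction to the
current factor, normalize to geometric mean 1, damp with exponent 0.8 and
clip to [1e-3, 1e3], iterate to relative change < 1e-6 (max 50 rounds).
The leverage term is essential: without it, a heavily weighted sample pulls
the fit toward itself, its residuals shrink for geometric rather than
statistical reasons, and the iteration diverges.

DMP calling retains FDR < 0.05 (Benjamini-Hochberg, NaN-propagating) plus an
optional |Δβ| ≥ 0.15 cutoff (used for the blood-vs-SF contrast). Top-k
selection orders by p, then |t| descending, then probe id — deterministic
under input permutation. Regions (DMRs) chain same-chromosome,
same-direction DMPs by single linkage with a gap cutoff (default 1000 bp,
min 2 probes); no claim of a formal DMR test is made.

## Enrichment

All enrichments are Fisher's exact tests of a foreground DMP set against
the full probe annotation (the array background), BH-adjusted across
strata. The two-sided p uses the probability-mass rule. Zero-cell odds
ratios are reported as +∞/0/NaN sentinels; a Haldane +0.5 flag exists.
Conventions: intervals are 0-based half-open; a probe point is
[pos − 1, pos).

* Chromatin states: the segmentation is a partition; probes outside every
  segment form an "Unsegmented" stratum. Foreground must be a proper subset
  of the background.
* SNP proximity: a probe is trait-proximal when ≥ 1 trait SNP lies within
  the window around it. "A 1 Mbp window around the coordinate" is read as
  ±500 kb (total 1 Mbp); a flag switches to ±1 Mbp.
* Signal windows: the flank (1 or 2 kb) is cut into 100 bp offset bins;
  a probe hits a bin when the bin overlaps ≥ 1 peak. The bin at offset 0 is
  the headline statistic.
* Top-list overlap: percentage uses the combined total |A| + |B| as the
  denominator (two identical k-lists = 50%).

## Disease activity

DAS28 categories close the upper interval end: remission < 2.6,
low [2.6, 3.2], moderate (3.2, 5.1], high (5.1, ∞). Spearman correlation
uses mid-ranks; p comes from the t transform with n − 2 df, or the exact
permutation distribution for n ≤ 9. The genome-wide screen retains probes
with |ρ| ≥ 0.7 AND p ≤ 1e-3 over DAS28-bearing samples (rank-based, so the
β-vs-M choice is immaterial). Cross-compartment concordance is a Fisher
test of joint membership over the probe universe, reported as log2 OR, plus
the fraction of blood-correlated CpGs also correlated in SF, split by sign.
Reversion analysis computes per patient the change in mean z-scored β over
a CpG set between two visits against the change in DAS28, with
positively and negatively correlated sets analyzed separately.

At the study's sample size (20 patients), the joint screen has a null pass
probability of about 6e-4 per probe — the |ρ| ≥ 0.7 constraint binds, since
its two-sided p at n = 20 is already below 1e-3. A 10k-probe array
therefore contributes roughly six spurious retentions per screen; the
predictor pipeline below must tolerate them.

## DAS28 predictor

Pipeline: correlation screen → OLS of DAS28 on all retained CpG betas,
keeping coefficients with p < 0.05 (falling back to the full candidate set
when collinearity masks every individual coefficient) → lmg
relative-importance ranking → bidirectional AIC stepwise selection starting
from the full candidate model → greedy collinearity pruning (drop any CpG
with |r| ≥ 0.5 against an already kept one, in importance order) → nested
models of sizes 1..7 in importance order → seeded 5-fold cross-validation
(stratified by DAS28 quartile; flag to disable) → the size with the best
mean per-fold R² wins, ties to the smaller size.

lmg importance is the Shapley-style decomposition of the full-model R²: the
average R² gain of a predictor over all orders of model entry. It is exact
via the subset formulation for p ≤ 12 (2^p cached fits) and seeded
Monte-Carlo over ≥ 5000 orderings beyond; the importances sum to the
full-model R² to 1e-10. AIC is n·ln(RSS/n) + 2(k + 1) with the additive
constant dropped (only differences matter). Evaluation R² is the squared
Pearson correlation between predicted and observed DAS28 with its p-value;
1 − RSS/TSS is reported alongside.

When the screen returns more CpGs than the sample supports (p ≥ n − 1), the
default keeps the n − 2 strongest correlations with a warning
(`on_excess="trim"`); `on_excess="error"` raises instead, instructing a
tighter pre-filter.

A structural fact shapes this module's recovery behavior: three predictors
each truly correlating ρ with one response must pairwise correlate at least
(3ρ² − 1)/2, which exceeds 0.5 as soon as ρ > 0.8165. The ρ ≥ 0.7 screen
and the r < 0.5 pruning therefore pin any recoverable 3-CpG panel into the
narrow band ρ ∈ (0.7, 0.82), and both thresholds must be cleared by
*sample* correlations whose noise is ~1/√n. At n = 20 that noise (≈ 0.24
Fisher units) dwarfs the feasible margin; the panel geometry only becomes
reliably recoverable at a few hundred samples. The predictor-recovery study
(`predictor_recovery_config`) consequently uses 200 + 200 patients with the
true Spearman correlation placed near 0.76 and true pairwise correlation
near 0.41 — roughly two standard errors inside each threshold.

## Promoter-capture integration

Interactions whose bait end overlaps a TSS contribute one (probe, gene)
pair per DMP falling inside the non-bait fragment. DMPs inside the bait
fragment itself are promoter-proximal, not distal partners, and are
excluded by default (flag to include). Interactions with no TSS on either
end are skipped and counted in the log.

## Synthetic cohort generator

The generator is the package's study-conditions definition, not a fixture:
15 healthy donors (HD), 10 good-prognosis (GP) and 10 poor-prognosis (PP)
patients, four 6-monthly blood visits, one baseline SF sample for 16
patients, 10 000 probes (2% on chrX/Y, 1% SNP-flagged) on a synthetic
genome of 22 autosomes + X + Y at 25 Mbp each. The chromosome length is
chosen so that ±500 kb SNP windows around ~150 SNPs per trait cover a
minority of the genome — on a smaller genome the windows saturate and no
proximity contrast survives.

Baseline β per probe is a three-component mixture — Beta(2,20), Beta(20,2),
Beta(5,5) with weights 0.4/0.4/0.2 — matching the bimodal-with-shoulder
shape of real methylomes. All effects are planted on the M scale:

* **UA effects** (300 probes): magnitude ~ N(1, 0.25²) floored at 0.25
  M-units, positive (hyper) with probability 0.90, applied to every
  patient.
* **Prognosis effects** (200 probes): GP shifted by δ, PP by 2δ
  (cumulative HD < GP < PP), same direction bias.
* **Reversion**: both effect families decay per visit as decay^(v−1), GP
  0.55 and PP 0.65 per visit, mimicking normalization toward healthy
  levels under spontaneous remission (GP) or treatment (PP).
* **Activity CpGs** (40 probes): DAS28 is generated as the probability
  transform of a standard-normal composite of three equicorrelated latent
  activity facets (correlation 0.40) — mirroring the clinical score's
  composite definition — so visit-1 DAS28 is uniform on [3.2, 7.0].
  "Strong" CpGs (4 replicates per facet by default, as co-methylated CpGs
  of one locus) track a single facet with slope 1.0; "weak" CpGs couple
  linearly to the score with slope 0.08. 60% of slopes are negative. A
  deterministic 75% of each block also carries the coupling in SF (where
  the composite drive dominates the facet-specific variation). This
  composite structure is what lets CpGs correlate strongly with DAS28
  while pairwise correlations stay below the predictor's 0.5 bound — a
  single-factor model cannot.
* **SF shifts** (200 probes with baseline β in (0.2, 0.8)): 1.5 M-units
  toward β = 0.5, giving |Δβ| ≥ 0.15 in expectation — the
  macrophage-like remodeling of synovial monocytes.
* **DAS28 dynamics**: per-visit decay toward a floor of 1.5 (GP factor
  0.50, PP 0.72 — spontaneous remitters fall faster) with N(0, 0.15)
  noise; one PP patient increases by 0.4 per visit and is flagged
  untreated, reproducing the single activity riser without DMARD therapy.
  HD DAS28 is missing. Later-visit facet values reuse the patient's fixed
  facet profile with the visit's (inverse-transformed) activity level, so
  methylation at activity CpGs follows the clinical trajectory.
* **Noise**: Gaussian on the M scale, sd 0.25 × √(sample variance factor);
  factors are uniform on [0.7, 1.4] per sample (array-quality
  heterogeneity).

The genomic-context generator emits a 15-state segmentation (standard
Roadmap-style labels) built probe-first — each probe's state colors the
segment between the midpoints to its neighbors, so the map is an exact
partition — with Enh membership boosted on truth DMPs to a configured odds
ratio (default 4 against a 10% background); per-trait SNP catalogs with one
arthritis-like trait placing 60% of its SNPs within the window of truth
DMPs and four control traits uniform; peaks covering 60% of truth-DMP
central bins plus 5% background; and promoter-capture interactions whose
planted other-ends each contain exactly one planted probe (verified at
build time), so pair recovery is exact.

### What the generator does not emulate

Raw intensities, detection p-values, dye/batch chemistry, probe
cross-reactivity, cell-composition heterogeneity, genomic autocorrelation
of methylation beyond planted regions, linkage structure among SNPs, and
realistic ChromHMM segment-length distributions. Passing tests demonstrate
that the pipeline recovers known structure under its own statistical
assumptions (Gaussian M-value noise, independent probes); they do not
certify performance on real arrays.

## Problem sizes and numerical choices

Checks run at the study's own scale wherever the statistics allow: 10 000
probes, 15 vs 20 samples for calibration (null p-value uniformity by
Kolmogorov-Smirnov; empirical FDR and sensitivity averaged over five
seeds), the default cohort for enrichment/interaction recovery, and pooled
five-seed aggregates for the activity screen (at n = 20, all replicates of
one facet share that facet's realized sample correlation, so per-cohort
retention counts are inherently volatile). The predictor dimensionality
study uses the enlarged recovery cohort described above. Other conventions:
β clipping ε = 1e-6; trigamma inversion tolerance 1e-8; quantile-tie rule
as above; stepwise improvement threshold 1e-10; CV ties to the smaller
model; seeds flow from a single integer through `numpy.random.default_rng`.

## Known limitations

Δβ is computed on group means of raw-scale β, not back-transformed M means.
The DMR chaining is a heuristic, not an inferential procedure. The
predictor's coefficient-significance pre-filter loses power under heavy
collinearity (masked replicates) and then falls back to the full candidate
set. Wilcoxon exact p is only used for tie-free samples with n ≤ 20.
Interaction distance is reported as −1 for trans pairs.
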