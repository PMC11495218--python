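# Methods

This note documents the models, conventions and numerical choices behind
`ieeg_focality`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic experiments do and do not show.

## Problem setting

Patients with drug-resistant epilepsy undergo intracranial EEG (iEEG)
evaluation to decide whether their epileptic network is *focal* (amenable to
resection or ablation) or *non-focal* (bifocal, multi-focal, broad or
non-localized onsets, usually steered toward neurostimulation). The package
quantifies focality from **interictal** (between-seizure) recordings alone:

1. per-channel spectral and connectivity features of short interictal clips;
2. Z-scored abnormality of those features against a normative atlas;
3. two spatial statistics — the dispersion of the implant and the dispersion
   of its abnormality — combined with a pre-implant clinical score
   ("5-SENSE", consumed as a scalar in [0, 1]) in cross-validated logistic
   models that predict focality.

## Signal features

Clips are bipolar re-referenced along each shank (adjacent contacts; channels
whose member contacts are in white matter or outside the brain are excluded;
channel position is the contact midpoint; the midpoint ROI falls to the
anode's parcel on disagreement, since the midpoint is equidistant from both
contacts). Preprocessing is a zero-phase third-order Butterworth band-pass
0.5–80 Hz, a 60 Hz IIR notch (Q = 30; zero-phase), and polyphase resampling
to exactly 200 Hz. Zero-phase filtering is a deliberate choice: forward-
backward application avoids band-dependent group delay that would distort
cross-channel phase relationships; the amplitude response is the squared
single-pass response.

Spectral estimates use Welch averaging with 2 s Hamming windows and 1 s
overlap. Band edges are half-open `[lo, hi)` with bin membership by bin
centre, so the five canonical bands (delta 0.5–4, theta 4–8, alpha 8–12,
beta 12–30, gamma 30–80 Hz) partition the analysis range and relative powers
sum to one by construction. Because "relative broadband power" is
identically 1, the broadband feature is stored as **absolute** 0.5–80 Hz
power and log10-transformed before atlas statistics and scoring to tame its
right skew. Magnitude-squared coherence is computed from Welch cross-spectra
with identical windowing; the band value is the mean MSC over the band's
bins (averaging rather than integrating makes the value a unitless quantity
in [0, 1] regardless of bandwidth). With K ≈ 59 windows on a 60 s clip, the
MSC estimator bias for independent signals is roughly 1/K, which motivates
the 0.15 ceiling used in the independence checks.

A wake detector is provided for real recordings: per window, the
channel-median of log10(alpha/delta) power, z-normalized across the
recording, with windows at or above −0.40 flagged awake. The normalization
is a documented stand-in — the cited detector's exact normalization is not
specified in the source material we reimplement — and the threshold is a
config knob. Interictal clip selection draws non-overlapping 60 s windows
uniformly at random from awake periods, at least 72 h after implantation and
2 h from any seizure, on a clip-length grid (which enforces
non-overlap by construction); a shortfall returns every eligible window
with a warning.

## Normative atlas and abnormality weights

The atlas stores, per (ROI, band), the mean and SD of relative band power
over all normal channel-clips, and per (unordered ROI pair, band) the same
for coherence. Entries need at least `min_n = 5` samples and positive
variance; channels or connections without a usable entry are *unscorable*
and carried as missing, never as silent zeros. A provenance check refuses to
score a subject against an atlas it contributed to; calibration analyses can
override this explicitly (`allow_self=True`).

Per clip, a channel's Z-score is `(value − atlas mean) / atlas SD`. Over the
20 clips this yields a Z distribution which is collapsed to one
non-negative weight per channel per (band, measure):

* power: median over clips of |Z|;
* coherence: per clip, the mean |Z| over the channel's scored incident
  connections (an edge→node collapse, needed because the spatial statistic
  lives on contacts, not edges), then the median over clips.

The absolute value is taken because both hypo- and hyper-normal activity are
abnormal, and the downstream weighted statistic requires non-negative
weights; the median is chosen for robustness to occasional artifactual
clips (a mean reduction is available via `reduction="mean"`).

## Spatial statistics

For contact positions (xᵢ, yᵢ, zᵢ), the **standard distance** (implant
distance) is

    SD = sqrt( Σ(xᵢ−X̄)²/n + Σ(yᵢ−Ȳ)²/n + Σ(zᵢ−Z̄)²/n ),

the square root of summed per-axis *population* (1/n) variances — the
printed formula divides by n, not n−1. The **weighted standard distance**
(abnormality distance) replaces the mean centre with the weighted centre
X̄_w = Σwᵢxᵢ/Σwᵢ and weights each squared deviation by wᵢ/Σwᵢ. Both equal
the trace of the (weighted) covariance under the square root, hence are
invariant to rigid motion, scale linearly with coordinates, and WSD is
invariant to rescaling all weights. By default both are computed over
grey-matter bipolar channel midpoints — consistent with where abnormality is
defined; computing SD over raw contacts instead is a documented alternative
(the underlying ambiguity: exclusion of white-matter electrodes is stated
before any feature work, but the implant-distance prose says only "between
iEEG contacts"). Channels missing a weight are excluded from that map's WSD
pairwise, not imputed, and never removed from SD.

Each patient's feature vector is: the 5-SENSE score, the implant distance,
and 12 abnormality distances (6 bands × {power, coherence}).

## Prediction models and statistics

Three nested L1-penalized logistic regressions (inverse regularization
strength C = 1, liblinear): 5-SENSE only; 5-SENSE + implant distance;
5-SENSE + implant distance + 12 abnormality distances. The full model
includes the implant distance because the combined model is described as
combining all three feature families; a flag (`include_implant_in_full`)
reproduces the stricter reading without it. Features are standardized to the
training fold's mean/SD inside each leave-one-out fold — without this, a
shared L1 penalty across mm-scaled and score-scaled features is
meaningless. Each patient's probability of focality is predicted by the
model trained on the other n−1 patients; per-fold coefficients are kept and
summarized as mean ± SD.

Model AUCs carry DeLong 95% confidence intervals (structural-components
variance, Wald interval truncated to [0, 1]); the implementation agrees with
R's pROC to numerical precision. Paired model comparisons use DeLong's test
on the covariance of structural components; identical score vectors return
p = 1 by convention. The three sequential comparisons (full vs 5-SENSE,
full vs 5-SENSE+implant, 5-SENSE+implant vs 5-SENSE) form one
Holm-Bonferroni family. The ROC operating point maximizes Youden's J with
ties broken toward higher sensitivity (the "optimal operating point" is not
otherwise pinned down; sensitivity is what the use case prioritizes).
Univariate comparisons report Cohen's d (pooled, n−1 weighting),
Mann-Whitney U with AUC = U/(n₁n₂), and two-tailed p. Cohort tables use
Yates-corrected chi-square for 2×2 contrasts and the U-test for continuous
variables — the continuity correction is what reproduces the published
cohort-table p-values. Subgroup analyses (surgical outcome, implant type,
non-focal subtype) apply the U-test/AUC machinery to the full model's
predictions, Holm-corrected within each analysis family; subgroups under
3 patients are reported as insufficient rather than tested.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes, with
known ground truth, and nothing more.

**Geometry.** Linear shanks of equally spaced contacts (default 8 contacts
at 3.5 mm) in a spherical head volume (radius 70 mm). Focal patients'
shank targets scatter within ~16 mm of a seed point; non-focal patients
within a ~70 mm diameter (bifocal: two midline-mirrored clusters;
multi-focal: three). A per-patient log-normal multiplier
(`dispersion_jitter_sigma = 0.45`) on the scatter radius makes the
class-conditional implant-dispersion distributions overlap — clinical
cohorts report an implant-distance discrimination of AUC ≈ 0.7, not the
near-perfect separation that fixed radii would produce. ROIs are assigned by
nearest of `n_rois` fixed centres (a deterministic stand-in for an
MRI-based parcellation, which is out of scope); ~15% of contacts are
flagged white matter solely to exercise the exclusion rule.

**Signals.** Each contact carries 1/f-shaped Gaussian background (spectral
support up to 95 Hz — content above the 80 Hz analysis edge would be
discarded by the pipeline) plus an alpha-band component at 0.35 relative
amplitude, scaled by a per-channel log-normal gain emulating impedance
variation. Noise is generated directly in the frequency domain (complex
Gaussian bins, single inverse rFFT), equivalent in law to filtered white
noise. Epileptic contacts receive: (i) independent band-limited noise whose
amplitude is solved, against numerically estimated null statistics of this
same generator, so the *bipolar* relative band power shifts by
`power_effect` null-SDs (a joint solve across injected bands, accounting for
the coherent source's own power); and (ii) a shared band-limited source
entering adjacent contacts with alternating sign — bipolar differencing
would cancel an equal-gain common source — scaled so epileptic pairs reach a
coherence `coherence_effect` null-SDs above the null mean. Because the five
relative powers sum to one, a positive shift cannot be injected into every
band at once; a scalar `power_effect` targets delta and gamma (slowing plus
high-frequency elevation, the bands most associated with epileptic tissue),
and a scalar `coherence_effect` targets beta. Dict-valued effects select
other bands.

**Covariates.** The 5-SENSE-like score is class-conditional normal (focal
0.61 ± 0.15, non-focal 0.50 ± 0.15, clipped to [0, 1]; the implied Cohen's d
≈ 0.72 matches the published pre-implant discrimination), with a weak
negative within-class coupling (ρ = −0.15) to standardized implant
dispersion, yielding cohort-level score-dispersion correlations around
−0.2. Therapy is sampled at the published surgical rates (52/65 focal,
11/36 non-focal), outcomes with focality-dependent seizure-freedom
probability (0.65 vs 0.35), implant type at roughly the published ECOG/SEEG
mix. Cohort defaults: 101 patients, 65 focal.

**Determinism.** One integer seed; every patient draws from an independent
substream keyed by (seed, patient index, stream), so cohorts are
byte-reproducible and individual patients are stable under cohort-size
changes. Clips are regenerated on demand from the substream rather than
stored.

**Problem sizes.** The full study conditions are 20 one-minute clips at
512 Hz. End-to-end analyses in the test-suite and the acceptance script use
the package's reduced size (`CohortConfig.scaled_down()`: 10 s clips at
400 Hz, 3–5 shanks), which preserves every pipeline stage and the cohort
structure while a complete 101-patient study runs in under a minute on one
CPU.

## What the synthetic experiments show — and what they do not

Passing parameter-recovery tests show the pipeline *recovers what the
generator injects*: band-power and coherence Z-shifts at epileptic contacts,
class differences in implant and abnormality dispersion, and the resulting
advantage of the combined model over the pre-implant score. They do not show
clinical validity: the generator has stationary Gaussian signals, no spikes,
high-frequency oscillations, artifacts or sleep cycling; a geometric rather
than anatomical parcellation; and an atlas drawn from the same signal model
as the patients, which understates the cross-site heterogeneity a real
normative atlas must absorb.

## Known statistical limitations

Leave-one-out predictions are not exchangeable under a null of uninformative
features: the training-fold prevalence `(n_pos − yᵢ)/(n−1)` and the refit
coefficients (through a leverage term) are both deterministically
anti-correlated with the held-out label. Cross-validated AUCs of pure-noise
models therefore fall *below* 0.5 by an amount that depends on model
dimension (≈0.27 / 0.24 / 0.44 for the 1-, 2- and 14-feature models at
n = 101 in our measurements), and paired DeLong tests between such
prediction sets detect these systematic differences far more often than the
nominal level. Centring predictions on the training-fold prevalence removes
only part of the bias, and the remainder cannot be removed without using the
held-out label itself. Consequently: (a) the model-comparison machinery is
anticonservative when all candidate models are near-uninformative — in that
regime its rejections should not be read as evidence; and (b) comparisons
between models of different dimension inherit a bias component (~0.1 AUC in
the null measurements above) on top of any real signal. With genuinely
informative features, as in the synthetic studies and the clinical setting
the package mirrors, the bias is small relative to the effects of interest,
but it is a real caveat on borderline model comparisons.

Other limitations: the notch Q, wake-detector normalization, |Z|-median
reduction, edge→node coherence collapse and Youden tie-break are all
conventions chosen where the source procedure is underspecified; each is a
config switch or documented default. DeLong Wald intervals undercover
slightly in small samples (measured 94.4% at n = 50/50, nominal 95%).
Degenerate inputs are handled by refusal rather than repair: zero-variance
atlas entries are dropped, all-zero weight maps and single-class CV folds
raise, and unscorable channels propagate as missing values.
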