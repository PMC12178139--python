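# Methods

`neurostate` re-implements, as a tested pipeline over synthetic data, a
multimodal analysis of brain-state dynamics in a pre/post motor-
rehabilitation cohort: EEG microstates, fMRI coactivation patterns
(CAPs), group × time statistics with clinical correlation, and SVM
prediction of treatment response. This note documents the models, the
generator, the numerical choices, and what the tests do and do not show.

## EEG microstates

Resting EEG is modeled as a sequence of quasi-stable scalp topographies.
The pipeline follows the standard workflow:

- **GFP and peak maps.** Global field power is the spatial population SD
  of the average-referenced potential; topographies at strict local GFP
  maxima (endpoints excluded) enter clustering, because they carry the
  best topographic signal-to-noise. Back-fitting labels *every* sample.
- **Modified k-means.** Polarity-invariant: a map joins the template
  maximizing squared spatial (Pearson) correlation, and the template
  update is the dominant eigenvector of the assigned maps' channel
  outer-product sum. The objective is total GEV, the GFP²-weighted mean
  squared correlation. Convergence: relative GEV change < 1e-7 or 200
  iterations; an emptied cluster is re-seeded from the worst-explained
  map; best of `n_restarts` random initializations wins. All of this is
  deterministic given a seed.
- **Model selection.** The predictive-residual cross-validation
  criterion CV(k) = σ̂²ₖ · ((C−1)/(C−1−k))², with C channels and σ̂²ₖ the
  mean residual variance of maps about their polarity-aligned templates;
  the k minimizing CV is selected (ties and numerically-zero criteria
  resolve to the smallest k).
- **Group maps and sorting.** Individual template sets are pooled and
  re-clustered (second level); group maps are sorted to built-in
  canonical A–D motifs by the permutation maximizing summed |corr|
  (exhaustive, guarded at k ≤ 6), with signs flipped positive.
- **Back-fitting and smoothing.** Samples take the label of the template
  with maximal |corr|. Segments shorter than 30 ms are then removed
  iteratively: the shortest offending segment (earliest on ties) is
  relabeled to whichever neighbor's template better explains its
  samples, until every segment is ≥ round(30 ms · fs).
- **Metrics.** Coverage (time share), occurrence (episodes/s), mean
  duration (ms), per-state GEV, and the segment-level transition matrix
  P(s→s′) conditioned on a change (zero diagonal). By construction
  coverage = occurrence × duration exactly. A per-sample transition
  variant (self-transitions included) is intentionally not the default:
  the reported A→C-style quantities are between-state.

`preprocess` (zero-phase Hamming-window FIR band-pass 1–30 Hz, polyphase
resampling to 500 Hz, average reference) is provided for raw inputs; the
synthetic recordings are generated already band-limited and referenced,
so the cohort drivers skip it.

## fMRI coactivation patterns

ROI time series (frames × ROIs, TR = 2 s) are z-scored per ROI within
each run. Frames from all subjects and both timepoints are pooled and
clustered once with cosine-distance k-means (k = 14; unit-normalized
frames; centroid = unit-normalized mean; best restart by total
within-cluster distance; emptied clusters re-seeded from the
worst-fitting frame), so pre and post metrics share one state space.
Each CAP's ROI-wise z-map (mean of its assigned frames) is tested
against zero median with Wilcoxon signed-rank tests, Bonferroni across
ROIs; the CAP is named `NETa+ NETb-` from the highest/lowest
network-mean z over the Yeo-7 networks. Temporal metrics per run and
state: fractional occupancy, mean dwell time (s; 0 when absent, with a
presence flag), and appearance rate (entries/min); FO = dwell × rate/60
exactly. Sliding-window Pearson FC is provided as a diagnostic only and
does not feed the clustering.

## Group statistics

Responders are subjects whose MDS-UPDRS III total drops by strictly more
than 3.25 points (the minimal clinically important difference; with
integer scores this is ≥ 4). Univariate comparisons route through
Shapiro–Wilk at α = 0.05 (paired: on differences) to t tests or
Wilcoxon/Mann–Whitney (exact p for n ≤ 25 without ties, tie-corrected
normal approximation otherwise); zero-variance paired data return a
flagged degenerate result with p = 1 rather than raising. Neural metrics
use a two-level mixed (split-plot) ANOVA — between: group; within:
timepoint — with F(1, n−2) tests and ηp² computed against each effect's
own error stratum; the decomposition conserves the total sum of squares
exactly and matches pingouin on unbalanced designs. Significant
interactions are followed by four Bonferroni-corrected simple effects.
Spearman correlations are computed over explicitly declared families
(the family size is an argument, never inferred).

## The synthetic cohort

No patient data are deposited, so a generator with known ground truth
stands in. Defaults follow the study conditions where stated: 24
responders + 28 nonresponders; EEG 180 s at 500 Hz band-limited 1–30 Hz
(32-channel default layout on a left-right symmetric disk grid); BOLD
240 frames at TR 2 s over 100 ROIs in 7 networks; k = 4 EEG states,
k = 14 CAP states; clinical scores drawn at the published group × time
moments and rounded to integer points.

- **EEG.** A segment-level semi-Markov process (gamma dwell times,
  shape 4, mean 80 ms) selects among four canonical templates (A/B:
  mirror-image diagonals, C: anterior–posterior gradient, D: fronto-
  central peak; unit GFP). Each episode multiplies its template by a
  10 Hz sinusoidal carrier with random phase, so the clean GFP envelope
  is the rectified sinusoid. The *signed* carrier is used (all analysis
  steps are polarity-invariant): rectification would put a per-episode
  DC offset into the signal that high-pass filtering smears across
  neighboring episodes, corrupting the correspondence between waveform
  and stored labels. For the same reason only the noise — spatially
  correlated (squared-exponential kernel over the layout) Gaussian —
  passes the explicit 1–30 Hz zero-phase Butterworth; the gated carrier
  is narrow-band by construction (~95% of energy in band). SNR is the
  ratio of band-limited signal GFP power to noise GFP power, 5 dB by
  default; at 60 dB, back-fitting the true templates recovers > 99% of
  sample labels, the residual being boundary samples and true episodes
  shorter than the 30 ms rule.
- **BOLD.** 14 patterns (+1 on the activated network's ROIs, −1 on the
  deactivated's, unit norm), including the named DAN+ VAN−, VAN+ DAN−,
  FPN+ VN− and SMN+ FPN− pairs; a frame-level Markov chain with
  per-state mean dwell 4 frames; frame = amplitude (2.5) × pattern +
  N(0, 0.5) per ROI. The amplitude makes a single frame correlate ~0.45
  with its pattern — strong enough that pooled clustering recovers the
  patterns (mean cosine ≥ 0.95), weak enough that single-frame
  assignment stays noisy, as in real CAP data.
- **Injected effects.** Post-treatment, responders get microstate-C
  occupancy × 0.8, microstate-D occupancy × 1.25, +0.05 absolute on the
  A→D and B→D transition probabilities, and DAN+ VAN− dwell × 1.3;
  nonresponders get the reciprocal factors and the opposite boost.
  Target occupancies are converted to zero-diagonal segment chains by a
  calibrated fixed-point construction, so the injected occurrence ratios
  are exact in expectation. Responders also differ at baseline (more C,
  less D, shorter DAN+ VAN− dwell) — this is what makes the *pre*
  features predictive of response, mirroring the reported baseline group
  differences and single-modality predictive power. Responders are
  heterogeneous: an EEG-silent subset (30% by default) shows no baseline
  microstate contrast but a strong dwell contrast, while typical
  responders carry mainly the microstate contrast. A
  multimodal-over-unimodal accuracy hierarchy *requires* this kind of
  non-redundancy: were both modalities conditionally independent
  surrogates of the same label, combining them would add almost
  nothing.
- **Subject spread and clinical coupling.** Each subject's factors are
  the group base times a mean-preserving lognormal jitter (SD 0.35 log
  units for EEG, 0.25 for the CAP factor — smaller because dwell is
  estimated from only ~4 visits per run). The jitter latents come from a
  Gaussian copula shared with the clinical latent at the configured
  Spearman targets (+0.409 C, −0.393 D, −0.334 dwell), so clinical
  change rates are rank-coupled to the injected effect sizes; the
  coupling is conditional on group, and matched only in expectation.
  Pooled (unstratified) change-rate correlations are instead dominated
  by the group separation and need not carry the configured sign.
  Responder reductions are forced past the MCID (truncated-normal
  quantile transform of the clinical latent), nonresponders are kept
  inside it, so the stratification rule recovers the generated labels
  exactly.

**What the generator does not emulate:** volume conduction and leadfield
mixing, 1/f spectra and alpha reactivity, HRF convolution and scanner
drift, motion artifacts, missing visits, medication state. Passing
recovery tests therefore shows the *pipeline* is correct and powered
under the stated state-space model, not that effects of this size are
detectable in real recordings.

## Prediction

Responder vs nonresponder SVM (RBF default) on up to four baseline
features, under stratified nested 5 × 5-fold cross-validation repeated 5
times. Inside every outer training fold: standardization is fitted,
hyperparameters (C, γ) are selected by inner CV — deterministic 5 × 5
log-grid by default, expected-improvement Bayesian search (30
evaluations) selectable — and the decision threshold maximizes Youden's
J on pooled inner-fold decision values. Outer predictions pool into one
confusion matrix per repetition; accuracy/sensitivity/specificity are
reported as mean ± SE (SD/√reps) with responder as the positive class.
Class imbalance (24/28) is handled by inverse-frequency class weights.
Feature-set comparisons share identical outer splits. An audit assertion
verifies no outer test index is touched before prediction.

## Numerical and scale choices

Deterministic tie-breaks throughout: earliest index wins (assignment
ties, equal-length shortest segments, equidistant centroids via argmax).
Low-GFP samples are labeled like any other (no rejection threshold).
Exhaustive template sorting is guarded at k ≤ 6. EDF export uses 16-bit
symmetric physical scaling per channel, so round-trip error is bounded
by the quantization step.

Desk-scale problem sizes used by the analysis scripts and the seeded
acceptance checks — 30–60 s EEG, 16–32 channels, 3–10 clustering
restarts, 8 pooled BOLD runs for centroid recovery — were chosen so a
full cohort analysis runs in minutes on one CPU; noise levels, SNR,
effect sizes, group sizes and the BOLD scan length always stay at the
study-condition defaults. The k-selection check runs at the full default
scale (180 s, 32 channels, 50 restarts).

## Known limitations

- The DAN+ VAN− dwell-time interaction is under-powered by design of the
  measurement itself: with k = 14 states, 240 frames and mean dwell 4
  frames, a run contains only ~4 visits of the target state, and the
  dwell estimator's sampling noise caps detection power near 75% even
  with no between-subject spread. The detection-power suite documents
  this: the occurrence interactions reach full power, the dwell
  interaction does not.
- Accuracies of the feature-set comparison depend strongly on the
  assumed baseline separations, which the study reports only indirectly
  (through its own classifier's performance); the suite checks the
  accuracy *ordering* across feature sets, not absolute values.
- The pooled-cohort Spearman magnitudes reported on real data are not
  reproducible from group-level summary statistics; the generator
  matches the configured coupling sign conditionally on group, in
  expectation only.
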