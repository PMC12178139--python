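# neurostate

Spatiotemporal brain-state dynamics for a pre/post motor-rehabilitation
cohort in Parkinson's disease: EEG microstate analysis, fMRI
coactivation patterns (CAPs), group × time statistics with clinical
correlation, and SVM prediction of treatment response — with a
synthetic-cohort generator (known ground truth) standing in for the
study's non-deposited patient data.

## The problem

Two weeks of multidisciplinary intensive rehabilitation therapy improve
motor symptoms in some Parkinson's patients (responders: MDS-UPDRS III
reduction > 3.25 points, the minimal clinically important difference)
but not others. The analysis asks whether sub-second EEG dynamics and
fMRI network coactivations (a) reorganize differently in responders vs
nonresponders and (b) predict response from baseline.

## The models

**EEG microstates.** Resting EEG is a sequence of quasi-stable scalp
topographies. Topographies at global-field-power peaks are clustered by
polarity-invariant *modified k-means*: assignment maximizes squared
spatial correlation corr²(v, T), the template update is the dominant
eigenvector of the assigned maps' outer-product sum, and the objective
is the global explained variance

GEV = Σₜ GFP(t)²·corr²(vₜ, T₍label(t)₎) / Σₜ GFP(t)².

The number of classes minimizes the cross-validation criterion
CV(k) = σ̂²ₖ·((C−1)/(C−1−k))². Group maps are sorted to the canonical
A–D taxonomy and back-fitted to every sample, with segments < 30 ms
merged away; per state the pipeline reports GEV, coverage, occurrence,
mean duration and the between-state transition matrix.

**fMRI CAPs.** Z-scored ROI frames (Yeo-7 networks, TR = 2 s) from all
runs are pooled and clustered with cosine k-means (k = 14); each CAP is
named from its network-level z-map ("DAN+ VAN−") with Wilcoxon
signed-rank significance, and each run yields fractional occupancy,
dwell time and appearance rate per CAP.

**Statistics and prediction.** Metric changes are tested with a 2 × 2
mixed ANOVA (group × timepoint) with partial η², Bonferroni simple
effects, and Shapiro–Wilk-routed univariate tests; clinical coupling
uses Spearman correlations over declared families. A binary SVM under
repeated stratified nested 5-fold cross-validation (standardization,
hyperparameter search and Youden-threshold choice all inside the
training folds) compares clinical, EEG, fMRI and multimodal baseline
feature sets.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_eeg_microstates.py
python analysis/03_fmri_caps.py
python analysis/04_group_statistics.py
python analysis/05_predict_response.py
```

`01` generates the synthetic cohort (24 responders + 28 nonresponders,
pre/post EEG and ROI BOLD plus integer clinical scores) and writes the
small artifacts under `results/data/`. `02` confirms the CV criterion
selects k = 4 microstate classes and writes per-subject temporal
metrics; `03` identifies the 14 named CAPs; `04` stratifies responders
(24/52 = 46.2%), tests the group × time interactions and the clinical
correlations; `05` compares the feature sets.

Example output of `04` on the default cohort (seed 11):

```
responders: 24/52 (46.2%)

group x time interactions:
         metric      effect       F      p  eta_p2
   occurrence_A interaction  0.2555 0.6154  0.0051
   occurrence_B interaction  0.0490 0.8256  0.0010
   occurrence_C interaction 46.3472 0.0000  0.4810
   occurrence_D interaction 73.4964 0.0000  0.5951
     coverage_C interaction 47.6475 0.0000  0.4880
     coverage_D interaction 72.4690 0.0000  0.5917
dwell_DAN+ VAN- interaction  0.5262 0.4716  0.0104
```

Reading: the injected treatment effects — microstate C occupancy falling
and D rising in responders, with the reverse in nonresponders — surface
as large group × time interactions on occurrence/coverage of C and D
(ηp² ≈ 0.5), while the untouched microstates A and B stay flat. The
DAN+ VAN− dwell-time interaction does not reach significance on this
particular cohort: with 14 states and 240 frames a run contains only a
handful of visits to the target state, so this effect is intrinsically
under-powered (see `docs/methods.md`). `05` then separates responders
from nonresponders from baseline features alone (EEG 75.0 ± 0.9%,
multimodal 73.9 ± 1.3%, clinical 61.5 ± 2.0%, fMRI 56.9 ± 2.0% on this
cohort).

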