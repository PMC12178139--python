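"""Shared settings of the analysis runs.

One desk-scale synthetic cohort stands in for the study's (non-deposited)
patient data: 24 responders + 28 nonresponders, each with pre/post
resting EEG (60 s, 32 channels, 500 Hz, 5 dB SNR) and pre/post ROI BOLD
(240 frames, TR 2 s, 100 ROIs).  Every script regenerates the cohort from
the same seed instead of shipping waveforms on disk.
"""

from pathlib import Path

from neurostate import synthetic as syn

COHORT_SEED = 11
RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"


def study_cohort() -> syn.SyntheticCohort:
    return syn.simulate_cohort(
        seed=COHORT_SEED,
        eeg_params=syn.EEGSimParams(duration_s=60, n_channels=32),
        bold_params=syn.BOLDSimParams(),
    )
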