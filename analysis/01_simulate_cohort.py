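"""Generate the synthetic study cohort and export its small artifacts.

Writes the clinical cohort TSV, the ROI atlas, the generator's true
per-subject metric table, and one example EEG recording in both matrix+
sidecar and EDF form (to exercise the IO paths).  Waveforms for all 104
recordings are not stored: downstream scripts regenerate them
bit-identically from the cohort seed.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import DATA, study_cohort

from neurostate import io_formats as io


def main():
    DATA.mkdir(parents=True, exist_ok=True)
    cohort = study_cohort()

    io.write_cohort(cohort.clinical, DATA / "cohort.tsv")
    io.write_atlas(cohort.atlas, DATA / "atlas.tsv")
    cohort.true_metric_frame().to_csv(DATA / "true_metrics.tsv", sep="\t",
                                      index=False, float_format="%.6g")

    # waveform examples are large; they go to scratch/, not results/
    scratch = DATA.parent.parent / "scratch" / "examples"
    scratch.mkdir(parents=True, exist_ok=True)
    example = cohort.eeg_recording("S01", "pre")
    io.write_eeg_matrix(example, scratch / "S01_pre_eeg.tsv")
    step = io.write_eeg_edf(example, scratch / "S01_pre_eeg.edf")
    roi = cohort.bold_table("S01", "pre")
    io.write_roi_table(roi, scratch / "S01_pre_bold.tsv")

    n_resp = sum(s.group == "responder" for s in cohort.subjects)
    print(f"cohort: {len(cohort.subjects)} subjects "
          f"({n_resp} responders / {len(cohort.subjects) - n_resp} "
          f"nonresponders), 2 timepoints each")
    print(f"example EEG: {example.n_channels} ch x {example.n_samples} "
          f"samples at {example.fs:g} Hz; EDF quantization step "
          f"{step:.4f} uV")
    print(f"example BOLD: {roi.n_frames} frames x {roi.n_rois} ROIs at "
          f"TR {roi.tr:g} s")
    print(f"tables in {DATA}; waveform examples in {scratch}")


if __name__ == "__main__":
    main()
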