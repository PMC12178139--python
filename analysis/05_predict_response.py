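"""Responder prediction from baseline features (nested-CV SVM).

Assembles the four baseline features (MDS-UPDRS III, microstate C and D
occurrence, DAN+ VAN- dwell time) from the measured metric tables, then
evaluates clinical-only, EEG, fMRI and multimodal feature sets under
5 x 5-fold nested cross-validation repeated 5 times with shared splits,
reporting accuracy / sensitivity / specificity as mean +- SE.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import DATA, RESULTS

import pandas as pd

from neurostate import io_formats as io
from neurostate import prediction as pred


def main():
    cohort_table = io.read_cohort(DATA / "cohort.tsv")
    msm = pd.read_csv(RESULTS / "microstate_metrics.tsv", sep="\t")
    capm = pd.read_csv(RESULTS / "cap_metrics.tsv", sep="\t")

    metrics = msm.merge(
        capm[["subject_id", "timepoint", "dwell_DAN+ VAN-"]],
        on=["subject_id", "timepoint"], how="left").rename(
        columns={"dwell_DAN+ VAN-": "cap_dwell_DANpVANm"})

    tables = [pred.build_feature_table(metrics, cohort_table.frame, fs)
              for fs in ("clinical", "eeg", "fmri", "multimodal")]
    reports = pred.compare_feature_sets(tables, outer=5, inner=5,
                                        repetitions=5, seed=1)

    frame = pd.DataFrame([r.to_dict() for r in reports])
    print("nested-CV performance by feature set (mean +- SE, %):")
    print(frame.to_string(index=False))
    io.write_report({r.feature_set: r.to_dict() for r in reports},
                    RESULTS / "prediction_report.json")
    print(f"\nwrote {RESULTS / 'prediction_report.json'}")


if __name__ == "__main__":
    main()
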