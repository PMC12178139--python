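"""fMRI CAP stage: pooled cosine k-means, naming, temporal metrics.

Regenerates the cohort, z-scores each run, clusters all frames into 14
coactivation patterns, names each from its network-level z-map, and
writes per-run fractional occupancy, dwell time and appearance rate.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RESULTS, study_cohort

import pandas as pd

from neurostate import pipeline as pl


def main():
    RESULTS.mkdir(parents=True, exist_ok=True)
    cohort = study_cohort()
    metrics, capset = pl.run_cap_pipeline(cohort, k=14, n_restarts=10,
                                          seed=0)
    metrics.to_csv(RESULTS / "cap_metrics.tsv", sep="\t", index=False,
                   float_format="%.6g")
    pd.DataFrame(capset.centroids, index=capset.names,
                 columns=capset.roi_ids).to_csv(
        RESULTS / "cap_centroids.tsv", sep="\t", float_format="%.4g")

    print("identified CAPs:", ", ".join(sorted(capset.names)))
    col = pl.cap_metric_column(capset, "dwell")
    summary = metrics.groupby(["group", "timepoint"])[col].mean().round(2)
    print(f"\nmean {col} (s) by group x timepoint:")
    print(summary)
    print(f"\nwrote {RESULTS / 'cap_metrics.tsv'} ({len(metrics)} rows)")


if __name__ == "__main__":
    main()
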