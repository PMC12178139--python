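"""Group x time statistics and clinical correlations.

Stratifies the cohort by the 3.25-point MCID rule, runs the 2 x 2 mixed
ANOVA (group x timepoint) with partial eta squared on the microstate and
CAP metrics, follows significant interactions with Bonferroni-corrected
simple effects, and correlates clinical reduction rates with neural
change rates (Spearman, Bonferroni over the declared family).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import DATA, RESULTS

import numpy as np
import pandas as pd

from neurostate import group_stats as gs
from neurostate import io_formats as io


def main():
    cohort_table = io.read_cohort(DATA / "cohort.tsv")
    msm = pd.read_csv(RESULTS / "microstate_metrics.tsv", sep="\t")
    capm = pd.read_csv(RESULTS / "cap_metrics.tsv", sep="\t")

    labeled, summary = gs.stratify_responders(cohort_table)
    print(f"responders: {summary['n_responders']}/{summary['n_subjects']} "
          f"({summary['responder_rate_pct']}%)")

    dwell_col = [c for c in capm.columns if c == "dwell_DAN+ VAN-"][0]
    targets = [(msm, c) for c in
               ("occurrence_A", "occurrence_B", "occurrence_C",
                "occurrence_D", "coverage_C", "coverage_D")]
    targets += [(capm, dwell_col)]

    rows = []
    for frame, col in targets:
        piv = frame.pivot_table(index=["subject_id", "group"],
                                columns="timepoint", values=col).dropna()
        groups = np.array([g for _, g in piv.index])
        res = gs.mixed_anova_2x2(piv["pre"].to_numpy(),
                                 piv["post"].to_numpy(), groups)
        inter = res["interaction"]
        rows.append({"metric": col, "effect": "interaction", "F": inter.F,
                     "p": inter.p, "eta_p2": inter.eta_p2})
        if inter.p < 0.05:
            simple = gs.simple_effects(piv["pre"].to_numpy(),
                                       piv["post"].to_numpy(), groups,
                                       family_size=4)
            for name, r in simple.items():
                rows.append({"metric": col, "effect": name,
                             "F": r.statistic, "p": r.p,
                             "eta_p2": np.nan})
    stats = pd.DataFrame(rows)
    stats.to_csv(RESULTS / "group_stats.tsv", sep="\t", index=False,
                 float_format="%.5g")
    inter_rows = stats[stats.effect == "interaction"]
    print("\ngroup x time interactions:")
    print(inter_rows.round(4).to_string(index=False))

    # clinical coupling: reduction rate vs neural change rates
    wide = cohort_table.pivot("mds_updrs3_total")
    red = gs.reduction_rate(wide["pre"].to_numpy(), wide["post"].to_numpy())
    red = pd.Series(red, index=wide.index)
    pairs = []
    for frame, col in [(msm, "occurrence_C"), (msm, "occurrence_D"),
                       (capm, dwell_col)]:
        piv = frame.pivot_table(index="subject_id", columns="timepoint",
                                values=col).dropna()
        ch = gs.change_rate(piv["pre"].to_numpy(), piv["post"].to_numpy())
        idx = piv.index.intersection(red.index)
        pairs.append(("updrs3_reduction_rate", red.loc[idx].to_numpy(),
                      f"{col}_change_rate",
                      pd.Series(ch, index=piv.index).loc[idx].to_numpy()))
    corrs = gs.spearman_family(pairs)
    corr_frame = pd.DataFrame([vars(c) for c in corrs])
    corr_frame.to_csv(RESULTS / "clinical_correlations.tsv", sep="\t",
                      index=False, float_format="%.4g")
    print("\nclinical correlations (Spearman):")
    print(corr_frame.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
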