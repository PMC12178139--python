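"""End-to-end drivers tying the stages together for a whole cohort.

These functions are what the numbered analysis scripts (and the
acceptance checks) call: EEG recordings -> per-subject microstate metrics
on canonically sorted group templates; ROI BOLD runs -> pooled CAP
clustering and per-run temporal metrics; metric tables -> group x time
statistics.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import caps, group_stats, microstates
from .io_formats import EEGRecording
from .synthetic import SyntheticCohort


def microstate_subject_metrics(rec: EEGRecording,
                               templates: microstates.MicrostateTemplateSet,
                               min_duration_ms: float = 30.0) -> dict:
    """Back-fit one recording on fixed templates and return its metrics."""
    gfp = microstates.compute_gfp(rec)
    seg = microstates.backfit(rec, templates, min_duration_ms=min_duration_ms)
    met = microstates.compute_microstate_metrics(seg, gfp,
                                                 labels=templates.labels)
    return met.to_dict()


def run_microstate_pipeline(cohort: SyntheticCohort, k: int = 4,
                            n_restarts_subject: int = 5,
                            n_restarts_group: int = 20,
                            seed: int = 0,
                            template_scope: str = "pooled") -> pd.DataFrame:
    """Full microstate stage over a synthetic cohort.

    Per recording: GFP peaks -> individual modified k-means templates.
    Individual templates are then pooled into group model maps (either one
    pooled set, or one per group x timepoint stratum), sorted to the
    canonical A-D reference, and back-fitted to every recording.  Returns
    a long DataFrame (one row per subject x timepoint) of temporal
    metrics.
    """
    if template_scope not in ("pooled", "condition"):
        raise ValueError("template_scope must be 'pooled' or 'condition'")
    rng = np.random.default_rng(seed)
    reference = microstates.canonical_reference(
        cohort.eeg_params.n_channels, cohort.positions)
    individual: dict[tuple[str, str], microstates.MicrostateTemplateSet] = {}
    recordings: dict[tuple[str, str], EEGRecording] = {}
    for spec in cohort.subjects:
        for tp in ("pre", "post"):
            rec = cohort.eeg_recording(spec.subject_id, tp)
            gfp = microstates.compute_gfp(rec)
            peaks = microstates.extract_gfp_peaks(gfp)
            maps = rec.data[:, peaks].T
            tset = microstates.modified_kmeans(
                maps, k, n_restarts=n_restarts_subject,
                seed=int(rng.integers(2 ** 31)))
            individual[(spec.subject_id, tp)] = tset
            recordings[(spec.subject_id, tp)] = rec

    strata: dict[tuple[str, str], microstates.MicrostateTemplateSet] = {}
    if template_scope == "pooled":
        group_set = microstates.build_group_templates(
            list(individual.values()), k=k, n_restarts=n_restarts_group,
            seed=int(rng.integers(2 ** 31)))
        group_set = microstates.sort_templates(group_set, reference)
        for spec in cohort.subjects:
            for tp in ("pre", "post"):
                strata[(spec.group, tp)] = group_set
    else:
        for grp in ("responder", "nonresponder"):
            for tp in ("pre", "post"):
                sets = [individual[(s.subject_id, tp)]
                        for s in cohort.subjects if s.group == grp]
                gset = microstates.build_group_templates(
                    sets, k=k, n_restarts=n_restarts_group,
                    seed=int(rng.integers(2 ** 31)))
                strata[(grp, tp)] = microstates.sort_templates(gset,
                                                               reference)

    rows = []
    for spec in cohort.subjects:
        for tp in ("pre", "post"):
            tset = strata[(spec.group, tp)]
            row = {"subject_id": spec.subject_id, "group": spec.group,
                   "timepoint": tp}
            row.update(microstate_subject_metrics(
                recordings[(spec.subject_id, tp)], tset))
            rows.append(row)
    return pd.DataFrame(rows)


def run_cap_pipeline(cohort: SyntheticCohort, k: int = 14,
                     n_restarts: int = 5, seed: int = 0
                     ) -> tuple[pd.DataFrame, caps.CAPSet]:
    """Full CAP stage over a synthetic cohort.

    Pools z-scored frames from all runs, clusters them once (so pre and
    post metrics live in one state space), names each CAP from its
    network-level z-map, and computes per-run temporal metrics.  Returns
    the long metric table and the annotated CAP set.
    """
    tables = []
    keys = []
    for spec in cohort.subjects:
        if not spec.has_fmri:
            continue
        for tp in ("pre", "post"):
            table = caps.zscore_roi(cohort.bold_table(spec.subject_id, tp))
            tables.append(table)
            keys.append((spec.subject_id, spec.group, tp))
    frames = np.vstack([t.data for t in tables])
    capset = caps.cap_cluster(frames, cohort.roi_ids, k=k,
                              n_restarts=n_restarts, seed=seed)
    # pooled frame labels for z-maps / naming
    states = np.concatenate([caps.assign_frames(t, capset).states
                             for t in tables])
    capset = caps.cap_zscores(frames, states, capset, cohort.atlas)
    rows = []
    for table, (sid, grp, tp) in zip(tables, keys):
        seq = caps.assign_frames(table, capset)
        met = caps.cap_temporal_metrics(seq)
        row = {"subject_id": sid, "group": grp, "timepoint": tp}
        row.update(met.to_dict(capset.names))
        rows.append(row)
    return pd.DataFrame(rows), capset


def cap_metric_column(capset: caps.CAPSet, metric: str,
                      name: str = "DAN+ VAN-") -> str:
    """Column key of a named CAP's metric in the pipeline table."""
    if name not in (capset.names or []):
        raise KeyError(f"no CAP named '{name}' in this solution")
    return f"{metric}_{name}"


def interaction_table(metrics: pd.DataFrame,
                      columns: Sequence[str]) -> pd.DataFrame:
    """Mixed 2x2 ANOVA (group x time) for each metric column.

    Returns one row per metric x effect with F, df, p and partial eta
    squared; subjects missing a timepoint are dropped per metric.
    """
    rows = []
    for col in columns:
        piv = metrics.pivot_table(index=["subject_id", "group"],
                                  columns="timepoint", values=col)
        piv = piv.dropna()
        groups = np.array([g for _, g in piv.index])
        res = group_stats.mixed_anova_2x2(piv["pre"].to_numpy(),
                                          piv["post"].to_numpy(), groups)
        for eff, r in res.items():
            rows.append({"metric": col, "effect": eff, "F": r.F,
                         "df1": r.df[0], "df2": r.df[1], "p": r.p,
                         "eta_p2": r.eta_p2})
    return pd.DataFrame(rows)
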