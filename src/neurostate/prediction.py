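"""Responder prediction from baseline features with a nested-CV SVM.

Four baseline (pre-treatment) features carry the signal of interest:
MDS-UPDRS III total, microstate C occurrence, microstate D occurrence and
the dwell time of the DAN+ VAN- coactivation pattern.  A binary SVM (RBF
kernel by default) is evaluated under repeated stratified nested 5-fold
cross-validation: feature standardization, hyperparameter search over
(C, gamma) and decision-threshold selection (Youden's J on inner-fold
decision values) all happen strictly inside each outer training fold.
Outer-fold predictions are pooled into per-repetition confusion matrices;
accuracy, sensitivity and specificity are reported as mean +- SE over
repetitions (responder is the positive class).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

FEATURE_SETS = {
    "clinical": ["updrs3_pre"],
    "eeg": ["occ_C_pre", "occ_D_pre"],
    "fmri": ["cap_dwell_pre"],
    "multimodal": ["occ_C_pre", "occ_D_pre", "cap_dwell_pre"],
    "all": ["updrs3_pre", "occ_C_pre", "occ_D_pre", "cap_dwell_pre"],
}

DEFAULT_GRID = np.logspace(-2, 4, 5)      # C values
DEFAULT_GAMMA = np.logspace(-3, 1, 5)     # RBF widths


@dataclasses.dataclass
class FeatureTable:
    """One row per subject: baseline features plus the responder label."""
    frame: pd.DataFrame
    feature_set: str
    feature_columns: list[str]
    dropped: list[str] = dataclasses.field(default_factory=list)

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return (self.frame["group"] == "responder").to_numpy()


@dataclasses.dataclass
class ClassifierReport:
    feature_set: str
    accuracy_mean: float
    accuracy_se: float
    sensitivity_mean: float
    sensitivity_se: float
    specificity_mean: float
    specificity_se: float
    per_repetition: pd.DataFrame
    chosen_params: list
    fold_assignments: list           # per repetition: test-index arrays

    def to_dict(self) -> dict:
        return {"feature_set": self.feature_set,
                "accuracy": f"{self.accuracy_mean:.2f} +- {self.accuracy_se:.2f}",
                "sensitivity": f"{self.sensitivity_mean:.2f} +- {self.sensitivity_se:.2f}",
                "specificity": f"{self.specificity_mean:.2f} +- {self.specificity_se:.2f}"}


def build_feature_table(metrics: pd.DataFrame, cohort_frame: pd.DataFrame,
                        feature_set: str = "all") -> FeatureTable:
    """Inner-join baseline features across modalities.

    ``metrics`` is a long per-subject table that must contain, at the pre
    timepoint, the columns needed by ``feature_set`` (occurrence_C,
    occurrence_D, cap_dwell_DANpVANm as available).  Subjects missing any
    selected feature are dropped and recorded in ``dropped``.
    """
    if feature_set not in FEATURE_SETS:
        raise KeyError(f"unknown feature set '{feature_set}'")
    pre = metrics[metrics["timepoint"] == "pre"].set_index("subject_id")
    clin = cohort_frame[cohort_frame["timepoint"] == "pre"].set_index(
        "subject_id")
    rows = {}
    rename = {"updrs3_pre": None, "occ_C_pre": "occurrence_C",
              "occ_D_pre": "occurrence_D",
              "cap_dwell_pre": "cap_dwell_DANpVANm"}
    feats = FEATURE_SETS[feature_set]
    frame = pd.DataFrame(index=clin.index)
    frame["group"] = clin["group"]
    frame["updrs3_pre"] = clin["mds_updrs3_total"]
    for col, src in rename.items():
        if src is not None and src in pre.columns:
            frame[col] = pre[src]
    missing_cols = [c for c in feats if c not in frame.columns]
    if missing_cols:
        raise KeyError(f"metrics table lacks feature(s): {missing_cols}")
    keep = frame[feats].notna().all(axis=1)
    dropped = sorted(frame.index[~keep])
    frame = frame[keep]
    if frame.empty:
        raise ValueError("empty join: no subject has all selected features")
    out = frame.reset_index()[["subject_id", "group", *feats]]
    return FeatureTable(frame=out, feature_set=feature_set,
                        feature_columns=feats, dropped=dropped)


# ---------------------------------------------------------------------------

def _youden_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Decision threshold maximizing sensitivity + specificity on given
    decision values (midpoint between consecutive candidates; earliest
    maximum wins)."""
    order = np.argsort(scores)
    s, t = scores[order], y[order]
    cands = np.concatenate([[s[0] - 1.0], (s[1:] + s[:-1]) / 2.0,
                            [s[-1] + 1.0]])
    n_pos = t.sum()
    n_neg = len(t) - n_pos
    best_j, best_thr = -np.inf, 0.0
    for thr in cands:
        pred = scores > thr
        sens = np.sum(pred & y) / n_pos if n_pos else 0.0
        spec = np.sum(~pred & ~y) / n_neg if n_neg else 0.0
        j = sens + spec
        if j > best_j + 1e-12:
            best_j, best_thr = j, thr
    return best_thr


def _evaluate_params(folds, y, params, kernel, class_weight):
    """Pooled inner-fold decision values under one hyperparameter setting,
    plus the Youden threshold and the resulting balanced accuracy."""
    scores = np.empty(len(y))
    for Xtr, Xte, tr, te in folds:
        clf = SVC(kernel=kernel, class_weight=class_weight, **params)
        clf.fit(Xtr, y[tr])
        scores[te] = clf.decision_function(Xte)
    thr = _youden_threshold(scores, y)
    pred = scores > thr
    bal = (np.mean(pred[y]) + np.mean(~pred[~y])) / 2.0
    return bal, thr


def _inner_select(X: np.ndarray, y: np.ndarray, inner: int, rng,
                  kernel: str, class_weight,
                  search: str = "grid") -> tuple[dict, float]:
    """Inner-CV hyperparameter search and decision-threshold choice.

    ``search`` is "grid" (deterministic log-grid, the default) or "bayes"
    (expected-improvement Gaussian-process search over log-uniform
    (C, gamma), 30 evaluations).  Returns the winning parameters and the
    Youden threshold computed from their pooled inner-fold decision
    values.  Standardization is fit inside each inner training fold.
    """
    skf = StratifiedKFold(n_splits=inner, shuffle=True,
                          random_state=int(rng.integers(2 ** 31)))
    folds = []
    for tr, te in skf.split(X, y):
        scaler = StandardScaler().fit(X[tr])
        folds.append((scaler.transform(X[tr]), scaler.transform(X[te]),
                      tr, te))
    if search == "bayes" and kernel != "linear":
        return _bayes_select(folds, y, rng, kernel, class_weight)
    if kernel == "linear":
        grid = [{"C": c} for c in DEFAULT_GRID]
    else:
        grid = [{"C": c, "gamma": g}
                for c in DEFAULT_GRID for g in DEFAULT_GAMMA]
    best = None
    for params in grid:
        bal, thr = _evaluate_params(folds, y, params, kernel, class_weight)
        if best is None or bal > best[0] + 1e-12:
            best = (bal, params, thr)
    return best[1], best[2]


def _bayes_select(folds, y, rng, kernel, class_weight,
                  n_init: int = 10, n_total: int = 30):
    """Expected-improvement search over log10(C) in [-2, 4] and
    log10(gamma) in [-3, 1]."""
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern
    from scipy.stats import norm as _norm

    lo = np.array([-2.0, -3.0])
    hi = np.array([4.0, 1.0])
    pts, vals, thrs = [], [], []

    def probe(u):
        params = {"C": 10 ** u[0], "gamma": 10 ** u[1]}
        bal, thr = _evaluate_params(folds, y, params, kernel, class_weight)
        pts.append(u)
        vals.append(bal)
        thrs.append(thr)

    for _ in range(n_init):
        probe(lo + (hi - lo) * rng.uniform(size=2))
    gp = GaussianProcessRegressor(kernel=Matern(nu=2.5), alpha=1e-3,
                                  normalize_y=True)
    for _ in range(n_total - n_init):
        gp.fit(np.array(pts), np.array(vals))
        cand = lo + (hi - lo) * rng.uniform(size=(256, 2))
        mu, sd = gp.predict(cand, return_std=True)
        best_val = max(vals)
        z = (mu - best_val) / np.maximum(sd, 1e-9)
        ei = (mu - best_val) * _norm.cdf(z) + sd * _norm.pdf(z)
        probe(cand[int(np.argmax(ei))])
    i = int(np.argmax(vals))
    return {"C": 10 ** pts[i][0], "gamma": 10 ** pts[i][1]}, thrs[i]


def nested_cv_svm(table: FeatureTable, outer: int = 5, inner: int = 5,
                  repetitions: int = 5, seed: int = 0,
                  kernel: str = "rbf",
                  class_weight: str | None = "balanced",
                  search: str = "grid",
                  fold_plan: Optional[list] = None) -> ClassifierReport:
    """Repeated stratified nested cross-validation of the responder SVM.

    Standardization, hyperparameter selection and the decision threshold
    are all fitted inside each outer training fold; outer test folds are
    only ever touched at prediction time (asserted).  ``fold_plan`` allows
    sharing identical outer splits across feature-set variants.
    """
    X, y = table.X, table.y
    n = len(y)
    if n < max(outer, 10):
        raise ValueError("too few subjects for nested CV")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    rep_rows = []
    chosen = []
    fold_assignments = []
    for rep in range(repetitions):
        if fold_plan is not None:
            splits = fold_plan[rep]
        else:
            skf = StratifiedKFold(n_splits=outer, shuffle=True,
                                  random_state=int(rng.integers(2 ** 31)))
            splits = list(skf.split(X, y))
        pred = np.empty(n, dtype=bool)
        touched = np.zeros(n, dtype=bool)
        for tr, te in splits:
            assert not np.any(touched[te]), "outer test fold reused"
            params, thr = _inner_select(X[tr], y[tr], inner, rng, kernel,
                                        class_weight, search=search)
            scaler = StandardScaler().fit(X[tr])
            clf = SVC(kernel=kernel, class_weight=class_weight, **params)
            clf.fit(scaler.transform(X[tr]), y[tr])
            pred[te] = clf.decision_function(
                scaler.transform(X[te])) > thr
            touched[te] = True
            chosen.append({"repetition": rep, **params, "threshold": thr})
        assert touched.all()
        tp = np.sum(pred & y)
        tn = np.sum(~pred & ~y)
        rep_rows.append({
            "repetition": rep,
            "accuracy": 100.0 * (tp + tn) / n,
            "sensitivity": 100.0 * tp / y.sum(),
            "specificity": 100.0 * tn / (~y).sum(),
        })
        fold_assignments.append([te for _, te in splits])
    reps = pd.DataFrame(rep_rows)

    def ms(col):
        v = reps[col].to_numpy()
        return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v))
                                      if len(v) > 1 else 0.0)

    acc, acc_se = ms("accuracy")
    sens, sens_se = ms("sensitivity")
    spec, spec_se = ms("specificity")
    return ClassifierReport(feature_set=table.feature_set,
                            accuracy_mean=acc, accuracy_se=acc_se,
                            sensitivity_mean=sens, sensitivity_se=sens_se,
                            specificity_mean=spec, specificity_se=spec_se,
                            per_repetition=reps, chosen_params=chosen,
                            fold_assignments=fold_assignments)


def compare_feature_sets(tables: Sequence[FeatureTable], outer: int = 5,
                         inner: int = 5, repetitions: int = 5,
                         seed: int = 0) -> list[ClassifierReport]:
    """Evaluate several feature sets on identical subjects and identical
    outer splits; reports are returned ranked by mean accuracy."""
    subj_sets = {tuple(t.frame["subject_id"]) for t in tables}
    if len(subj_sets) != 1:
        raise ValueError("feature tables must cover identical subjects")
    y = tables[0].y
    rng = np.random.default_rng(seed)
    fold_plan = []
    for _ in range(repetitions):
        skf = StratifiedKFold(n_splits=outer, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        fold_plan.append(list(skf.split(np.zeros((len(y), 1)), y)))
    reports = [nested_cv_svm(t, outer=outer, inner=inner,
                             repetitions=repetitions, seed=seed,
                             fold_plan=fold_plan) for t in tables]
    return sorted(reports, key=lambda r: -r.accuracy_mean)
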