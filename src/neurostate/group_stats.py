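"""Responder stratification and group x time statistics.

The clinical rule stratifies subjects into responders and nonresponders
by a strict > 3.25-point pre-to-post reduction in MDS-UPDRS III (the
minimal clinically important difference).  Univariate comparisons are
routed by Shapiro-Wilk normality (parametric t tests vs Wilcoxon /
Mann-Whitney), neural metrics are tested with a 2 x 2 mixed-design ANOVA
(between: group; within: timepoint) reporting partial eta squared, with
Bonferroni-corrected simple effects, and clinical-neural coupling is
quantified with Spearman rank correlations over explicit families.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import scipy.stats

from .io_formats import CohortTable

MCID_POINTS = 3.25   # minimal clinically important difference, MDS-UPDRS III


@dataclasses.dataclass
class StratificationRule:
    threshold: float = MCID_POINTS

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclasses.dataclass
class TestResult:
    test: str          # routed test name
    statistic: float
    p: float
    n: int
    note: str = ""


@dataclasses.dataclass
class ANOVAResult:
    effect: str        # "group" | "time" | "interaction"
    F: float
    df: tuple[int, int]
    p: float
    eta_p2: float
    ss_effect: float
    ss_error: float


@dataclasses.dataclass
class CorrelationResult:
    x: str
    y: str
    rho: float
    p: float
    p_bonferroni: float
    n: int


# ---------------------------------------------------------------------------

def stratify_responders(cohort: CohortTable,
                        rule: StratificationRule = StratificationRule()
                        ) -> tuple[CohortTable, dict]:
    """Label each subject responder/nonresponder by the MCID rule.

    A subject is a responder iff (pre - post) MDS-UPDRS III > threshold.
    Returns the relabeled table and a summary with counts and rate (%).
    """
    wide = cohort.pivot("mds_updrs3_total")
    missing = wide.index[wide.isna().any(axis=1)].tolist()
    if missing:
        raise ValueError(f"subject(s) missing a timepoint: {missing}")
    delta = wide["pre"] - wide["post"]
    label = np.where(delta > rule.threshold, "responder", "nonresponder")
    lab_map = dict(zip(wide.index, label))
    frame = cohort.frame.copy()
    frame["group"] = frame["subject_id"].map(lab_map)
    n_resp = int((label == "responder").sum())
    n = len(label)
    summary = {"n_subjects": n, "n_responders": n_resp,
               "n_nonresponders": n - n_resp,
               "responder_rate_pct": round(100.0 * n_resp / n, 1)}
    return CohortTable(frame), summary


def reduction_rate(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    """(pre - post) / pre; positive when the score improved (decreased)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    out = np.full(pre.shape, np.nan)
    ok = pre != 0
    out[ok] = (pre[ok] - post[ok]) / pre[ok]
    return out


def change_rate(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    """(post - pre) / pre; positive when the metric increased."""
    return -reduction_rate(pre, post)


# ---------------------------------------------------------------------------

def route_and_test(a: np.ndarray, b: np.ndarray, paired: bool,
                   alpha: float = 0.05) -> TestResult:
    """Shapiro-Wilk-routed two-sample comparison.

    Paired data are tested for normality on the differences; two
    independent samples on each sample.  Normal data go to the paired /
    independent t test, otherwise to Wilcoxon signed-rank / Mann-Whitney U
    (exact p for n <= 25 without ties, normal approximation with tie
    correction beyond).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(len(a), len(b)) < 3:
        raise ValueError("need at least 3 observations per sample")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        d = a - b
        if np.allclose(d, d[0]):
            if np.allclose(d, 0):
                return TestResult("degenerate", 0.0, 1.0, len(a),
                                  note="zero-variance paired differences; "
                                       "p=1 by convention")
            # constant nonzero shift: report it without a distribution
            return TestResult("degenerate", np.inf, 0.0, len(a),
                              note="constant nonzero paired differences")
        normal = scipy.stats.shapiro(d).pvalue > alpha
        if normal:
            res = scipy.stats.ttest_rel(a, b)
            return TestResult("paired t", float(res.statistic),
                              float(res.pvalue), len(a))
        nz = d[d != 0]
        ties = len(np.unique(np.abs(nz))) < len(nz)
        method = "exact" if (len(nz) <= 25 and not ties) else "approx"
        res = scipy.stats.wilcoxon(a, b, zero_method="wilcox", method=method)
        return TestResult("wilcoxon", float(res.statistic),
                          float(res.pvalue), len(a))
    # independent samples
    if np.allclose(a, a[0]) and np.allclose(b, b[0]):
        same = np.allclose(a[0], b[0])
        return TestResult("degenerate", 0.0 if same else np.inf,
                          1.0 if same else 0.0, len(a) + len(b),
                          note="zero-variance samples")
    normal = (scipy.stats.shapiro(a).pvalue > alpha
              and scipy.stats.shapiro(b).pvalue > alpha)
    if normal:
        res = scipy.stats.ttest_ind(a, b)
        return TestResult("independent t", float(res.statistic),
                          float(res.pvalue), len(a) + len(b))
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 25 and not ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, method=method)
    return TestResult("mann-whitney", float(res.statistic),
                      float(res.pvalue), len(a) + len(b))


# ---------------------------------------------------------------------------

def mixed_anova_2x2(pre: np.ndarray, post: np.ndarray,
                    group: np.ndarray) -> dict[str, ANOVAResult]:
    """Two-level mixed-design (split-plot) ANOVA with partial eta squared.

    ``pre``/``post`` are per-subject values; ``group`` a binary label
    array.  The between stratum tests group on subject means; the within
    stratum tests time and group x time on subject pre-post differences.
    Each effect's eta_p2 uses its own error stratum.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    group = np.asarray(group)
    levels = list(dict.fromkeys(group))
    if len(levels) != 2:
        raise ValueError("group must have exactly 2 levels")
    if not (len(pre) == len(post) == len(group)):
        raise ValueError("pre, post and group must align per subject")
    n = len(pre)
    masks = [group == lv for lv in levels]
    sizes = np.array([m.sum() for m in masks])
    if sizes.min() < 2:
        raise ValueError("need at least 2 subjects per group")

    subj_mean = (pre + post) / 2.0
    grand = np.concatenate([pre, post]).mean()
    # between-subject stratum (2 observations per subject)
    ss_group = 2.0 * sum(s * (subj_mean[m].mean() - grand) ** 2
                         for s, m in zip(sizes, masks))
    ss_subj = 2.0 * sum(((subj_mean[m] - subj_mean[m].mean()) ** 2).sum()
                        for m in masks)
    # within-subject stratum, via differences d = post - pre
    d = post - pre
    dbar = d.mean()
    ss_time = n * dbar ** 2 / 2.0
    ss_int = sum(s * (d[m].mean() - dbar) ** 2 for s, m in zip(sizes, masks)) / 2.0
    ss_err_w = sum(((d[m] - d[m].mean()) ** 2).sum() for m in masks) / 2.0

    df_err = n - 2

    def make(effect, ss_eff, ss_err):
        if ss_err == 0:
            f = np.inf if ss_eff > 0 else 0.0
            p = 0.0 if ss_eff > 0 else 1.0
        else:
            f = (ss_eff / 1.0) / (ss_err / df_err)
            p = float(scipy.stats.f.sf(f, 1, df_err))
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        return ANOVAResult(effect=effect, F=float(f), df=(1, df_err), p=p,
                           eta_p2=float(eta), ss_effect=float(ss_eff),
                           ss_error=float(ss_err))

    return {"group": make("group", ss_group, ss_subj),
            "time": make("time", ss_time, ss_err_w),
            "interaction": make("interaction", ss_int, ss_err_w)}


def anova_total_ss(pre: np.ndarray, post: np.ndarray) -> float:
    """Total sum of squares of all observations about the grand mean."""
    allv = np.concatenate([np.asarray(pre, float), np.asarray(post, float)])
    return float(((allv - allv.mean()) ** 2).sum())


def simple_effects(pre: np.ndarray, post: np.ndarray, group: np.ndarray,
                   family_size: int = 4) -> dict[str, TestResult]:
    """Four Bonferroni-corrected contrasts after a significant interaction:
    pre-vs-post within each group (paired) and group-vs-group at each
    timepoint (independent)."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    group = np.asarray(group)
    levels = list(dict.fromkeys(group))
    if len(levels) != 2:
        raise ValueError("group must have exactly 2 levels")
    out: dict[str, TestResult] = {}
    for lv in levels:
        m = group == lv
        res = route_and_test(pre[m], post[m], paired=True)
        res.p = min(1.0, res.p * family_size)
        out[f"pre_vs_post[{lv}]"] = res
    for tp, vals in (("pre", pre), ("post", post)):
        res = route_and_test(vals[group == levels[0]],
                             vals[group == levels[1]], paired=False)
        res.p = min(1.0, res.p * family_size)
        out[f"{levels[0]}_vs_{levels[1]}[{tp}]"] = res
    return out


# ---------------------------------------------------------------------------

def spearman_family(pairs: Sequence[tuple[str, np.ndarray, str, np.ndarray]],
                    family_size: int | None = None
                    ) -> list[CorrelationResult]:
    """Spearman rank correlations over a declared family of variable pairs.

    Each pair is (x_name, x_values, y_name, y_values).  p values use the
    t approximation; Bonferroni multiplies by ``family_size`` (defaults to
    the number of pairs) capped at 1.
    """
    if family_size is None:
        family_size = len(pairs)
    out = []
    for xn, x, yn, y in pairs:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if len(x) != len(y) or len(x) < 5:
            raise ValueError("need >= 5 paired observations")
        if np.all(x == x[0]) or np.all(y == y[0]):
            raise ValueError(f"constant variable in pair ({xn}, {yn}); "
                             "Spearman undefined")
        rho, p = scipy.stats.spearmanr(x, y)
        out.append(CorrelationResult(x=xn, y=yn, rho=float(rho), p=float(p),
                                     p_bonferroni=min(1.0, float(p) * family_size),
                                     n=len(x)))
    return out
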