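"""fMRI coactivation-pattern (CAP) pipeline on ROI time series.

Frames from all subjects and both timepoints are z-scored per ROI within
each run, pooled, and clustered with cosine-distance k-means (k = 14 by
default, many random restarts, best restart by total within-cluster
distance).  Each CAP is characterized by a ROI-wise z-map tested against
zero median with Wilcoxon signed-rank tests (Bonferroni across ROIs), and
named after its most activated and most deactivated Yeo-7 networks
("DAN+ VAN-").  Per subject and state the temporal metrics are fractional
occupancy, mean dwell time and appearance rate.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import scipy.stats

from .io_formats import AtlasMap, ROITimeSeriesTable, NETWORKS


class ZeroVarianceError(ValueError):
    """Raised when an ROI has no variance to standardize."""


@dataclasses.dataclass
class CAPSet:
    """k unit-norm CAP centroids over a fixed ROI order."""
    centroids: np.ndarray               # k x ROIs, unit Euclidean norm
    roi_ids: Sequence[str]
    objective: float = np.nan           # total within-cluster cosine distance
    zmaps: Optional[np.ndarray] = None          # k x ROIs mean z per ROI
    significant: Optional[np.ndarray] = None    # k x ROIs bool mask
    names: Optional[list[str]] = None           # "DAN+ VAN-" style

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


@dataclasses.dataclass
class CAPStateSequence:
    """Per-frame CAP index (0-based) for one subject x timepoint run."""
    states: np.ndarray
    tr: float
    k: int
    subject_id: str = ""
    timepoint: str = "pre"


@dataclasses.dataclass
class CAPMetrics:
    """Per-state temporal statistics for one run."""
    fractional_occupancy: np.ndarray
    dwell_time: np.ndarray              # seconds; 0 when state absent
    appearance_rate: np.ndarray         # entries per minute
    present: np.ndarray                 # bool, state occurred at all

    def to_dict(self, names: Sequence[str] | None = None) -> dict:
        k = len(self.fractional_occupancy)
        names = names or [f"CAP{i + 1}" for i in range(k)]
        out = {}
        for i, nm in enumerate(names):
            out[f"fo_{nm}"] = float(self.fractional_occupancy[i])
            out[f"dwell_{nm}"] = float(self.dwell_time[i])
            out[f"rate_{nm}"] = float(self.appearance_rate[i])
        return out


@dataclasses.dataclass
class WindowedFCSeries:
    """Sliding-window ROI x ROI Pearson correlation matrices (diagnostic)."""
    matrices: np.ndarray                # n_windows x ROIs x ROIs
    window: int
    step: int


# ---------------------------------------------------------------------------

def zscore_roi(table: ROITimeSeriesTable) -> ROITimeSeriesTable:
    """Standardize each ROI column to mean 0, population SD 1 within the run."""
    sd = table.data.std(axis=0)
    bad = [table.roi_ids[i] for i in np.flatnonzero(sd == 0)]
    if bad:
        raise ZeroVarianceError(f"zero-variance ROI(s): {', '.join(bad)}")
    data = (table.data - table.data.mean(axis=0)) / sd
    return ROITimeSeriesTable(data=data, tr=table.tr, roi_ids=table.roi_ids,
                              subject_id=table.subject_id,
                              timepoint=table.timepoint)


def sliding_window_fc(table: ROITimeSeriesTable, window: int = 20,
                      step: int = 1) -> WindowedFCSeries:
    """Time-resolved functional connectivity (Pearson r per window)."""
    if window < 3:
        raise ValueError("window must be at least 3 frames")
    if window > table.n_frames:
        raise ValueError("window longer than the run")
    n_win = (table.n_frames - window) // step + 1
    mats = np.empty((n_win, table.n_rois, table.n_rois))
    for w in range(n_win):
        chunk = table.data[w * step:w * step + window]
        mats[w] = np.corrcoef(chunk, rowvar=False)
    return WindowedFCSeries(matrices=mats, window=window, step=step)


def _unit_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("all-zero frame cannot be cosine-normalized")
    return x / norms


def _cosine_kmeans_once(unit: np.ndarray, k: int, rng, max_iter=300, tol=1e-9):
    n = unit.shape[0]
    centroids = unit[rng.choice(n, size=k, replace=False)].copy()
    prev = np.inf
    for _ in range(max_iter):
        sim = unit @ centroids.T
        assign = np.argmax(sim, axis=1)
        # empty cluster -> reseed from the frame farthest from its centroid
        dists = sim[np.arange(n), assign].copy()
        for c in range(k):
            if not np.any(assign == c):
                worst = int(np.argmin(dists))
                assign[worst] = c
                dists[worst] = np.inf
        for c in range(k):
            m = unit[assign == c].mean(axis=0)
            nm = np.linalg.norm(m)
            centroids[c] = m / nm if nm > 0 else unit[rng.integers(n)]
        sim = unit @ centroids.T
        assign = np.argmax(sim, axis=1)
        obj = float(np.sum(1.0 - sim[np.arange(n), assign]))
        if prev - obj < tol * max(prev, 1.0):
            prev = obj
            break
        prev = obj
    return centroids, assign, prev


def cap_cluster(frames: np.ndarray, roi_ids: Sequence[str], k: int = 14,
                n_restarts: int = 50, seed: int | None = None) -> CAPSet:
    """Cosine-distance k-means over pooled z-scored frames.

    Frames are unit-normalized; d(x, c) = 1 - cos(x, c); the centroid is
    the unit-normalized mean of its assigned frames; the restart with the
    minimal total within-cluster distance wins.
    """
    frames = np.asarray(frames, dtype=float)
    if k > frames.shape[0]:
        raise ValueError(f"k={k} exceeds number of frames {frames.shape[0]}")
    unit = _unit_rows(frames)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        cents, assign, obj = _cosine_kmeans_once(unit, k, rng)
        if best is None or obj < best[2]:
            best = (cents, assign, obj)
    cents, _, obj = best
    return CAPSet(centroids=cents, roi_ids=list(roi_ids), objective=obj)


def assign_frames(table: ROITimeSeriesTable, caps: CAPSet) -> CAPStateSequence:
    """Nearest centroid by cosine similarity; ties go to the lower index."""
    if list(table.roi_ids) != list(caps.roi_ids):
        raise ValueError("ROI order mismatch between table and CAP set")
    unit = _unit_rows(table.data)
    sim = unit @ caps.centroids.T
    states = np.argmax(sim, axis=1)          # argmax takes first max: tie rule
    return CAPStateSequence(states=states, tr=table.tr, k=caps.k,
                            subject_id=table.subject_id,
                            timepoint=table.timepoint)


def subject_mean_maps(table: ROITimeSeriesTable,
                      seq: CAPStateSequence) -> np.ndarray:
    """Per-subject CAP maps: mean of the subject's frames assigned to each
    state (NaN rows for states the subject never visits)."""
    out = np.full((seq.k, table.n_rois), np.nan)
    for s in range(seq.k):
        mask = seq.states == s
        if mask.any():
            out[s] = table.data[mask].mean(axis=0)
    return out


def cap_zscores(frames: np.ndarray, states: np.ndarray, caps: CAPSet,
                atlas: AtlasMap, alpha: float = 0.05) -> CAPSet:
    """ROI-wise CAP z-maps, Wilcoxon significance and network naming.

    For each CAP the z-map is the mean of its assigned (z-scored) frames
    per ROI; each ROI is tested against zero median with a Wilcoxon
    signed-rank test, Bonferroni-corrected across ROIs within the CAP.
    The CAP name is "<argmax network>+ <argmin network>-" on network-mean z.
    """
    frames = np.asarray(frames, dtype=float)
    k, rois = caps.k, list(caps.roi_ids)
    atlas.check_covers(rois)
    net_idx = {net: [i for i, r in enumerate(rois) if atlas[r] == net]
               for net in NETWORKS}
    zmaps = np.full((k, len(rois)), np.nan)
    sig = np.zeros((k, len(rois)), dtype=bool)
    names: list[str] = []
    for c in range(k):
        mask = states == c
        n_frames = int(mask.sum())
        if n_frames == 0:
            names.append("(empty)")
            continue
        sub = frames[mask]
        zmaps[c] = sub.mean(axis=0)
        if n_frames >= 5:
            for j in range(len(rois)):
                col = sub[:, j]
                if np.allclose(col, 0):
                    p = 1.0
                else:
                    p = scipy.stats.wilcoxon(col, zero_method="wilcox",
                                             method="auto").pvalue
                sig[c, j] = p * len(rois) < alpha
        netz = {net: zmaps[c, idx].mean() for net, idx in net_idx.items()
                if idx}
        hi = max(netz, key=netz.get)
        lo = min(netz, key=netz.get)
        names.append(f"{hi}+ {lo}-")
    return CAPSet(centroids=caps.centroids, roi_ids=rois,
                  objective=caps.objective, zmaps=zmaps, significant=sig,
                  names=names)


def cap_temporal_metrics(seq: CAPStateSequence) -> CAPMetrics:
    """Fractional occupancy, mean dwell time (s) and appearance rate (/min)."""
    states = np.asarray(seq.states)
    if len(states) == 0:
        raise ValueError("empty state sequence")
    n = len(states)
    k = seq.k
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    run_states = states[starts]
    run_lens = ends - starts
    fo = np.bincount(states, minlength=k) / n
    runs = np.zeros(k)
    run_total = np.zeros(k)
    for s, ln in zip(run_states, run_lens):
        runs[s] += 1
        run_total[s] += ln
    dwell = np.where(runs > 0, run_total / np.maximum(runs, 1) * seq.tr, 0.0)
    rate = runs / (n * seq.tr / 60.0)
    return CAPMetrics(fractional_occupancy=fo, dwell_time=dwell,
                      appearance_rate=rate, present=runs > 0)
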