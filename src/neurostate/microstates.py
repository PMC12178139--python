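"""EEG microstate pipeline.

Implements the standard resting-state microstate workflow: optional FIR
band-pass and resampling, global field power (GFP), GFP-peak topography
extraction, polarity-invariant modified k-means with random restarts,
cross-validation-based selection of the number of classes, second-level
group templates, canonical A-D sorting, back-fitting with a minimum-
duration smoothing rule, and the temporal metrics (GEV, coverage,
occurrence, mean duration, transition probabilities).

Conventions
-----------
Spatial correlation between two average-referenced topographies is the
Pearson correlation across channels; polarity is ignored throughout
(assignment by squared correlation), which is what makes the k-means
"modified".  The clustering template of a class is the dominant
eigenvector of the channel covariance of its assigned maps.
"""

from __future__ import annotations

import dataclasses
import heapq
import itertools
from typing import Optional, Sequence

import numpy as np
import scipy.signal

from .io_formats import EEGRecording, SamplingRateError
from .templates import average_reference, canonical_templates, unit_gfp

DEFAULT_LABELS = "ABCDEFGH"


class NyquistError(SamplingRateError):
    """Sampling rate too low for the requested filter band."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GFPSeries:
    """Per-sample global field power (spatial population SD, microvolts)."""
    values: np.ndarray
    fs: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("GFP values must be non-negative")


@dataclasses.dataclass
class MicrostateTemplateSet:
    """k unit-GFP, average-referenced template topographies."""
    maps: np.ndarray                    # k x channels
    labels: Sequence[str]
    gev_total: float = np.nan
    provenance: str = "individual"

    def __post_init__(self):
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        self.labels = list(self.labels)
        if len(self.labels) != self.maps.shape[0]:
            raise ValueError("one label per map required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclasses.dataclass
class MicrostateSegmentation:
    """Per-sample microstate labels plus the run-length segment view."""
    labels: np.ndarray                  # per-sample state index
    segments: list                      # (state, start, length) runs
    fs: float
    corr: np.ndarray                    # per-sample |corr| to winning template
    corr_all: Optional[np.ndarray] = None   # n_samples x k |corr| matrix
    k: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.labels)


@dataclasses.dataclass
class MicrostateMetrics:
    """Per-state temporal statistics of one segmentation."""
    labels: Sequence[str]
    gev: np.ndarray                     # fraction of GFP-weighted variance
    coverage: np.ndarray                # fraction of labeled time
    occurrence: np.ndarray              # segments per second
    duration: np.ndarray                # mean segment length, ms
    transition_matrix: np.ndarray       # k x k, zero diagonal, rows sum to 1

    def to_dict(self) -> dict:
        out = {}
        for i, lab in enumerate(self.labels):
            out[f"gev_{lab}"] = float(self.gev[i])
            out[f"coverage_{lab}"] = float(self.coverage[i])
            out[f"occurrence_{lab}"] = float(self.occurrence[i])
            out[f"duration_{lab}"] = float(self.duration[i])
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                if i != j:
                    out[f"p_{a}{b}"] = float(self.transition_matrix[i, j])
        return out


# ---------------------------------------------------------------------------
# preprocessing and GFP
# ---------------------------------------------------------------------------

def preprocess(rec: EEGRecording, band: tuple[float, float] = (1.0, 30.0),
               target_fs: float = 500.0) -> EEGRecording:
    """Zero-phase FIR band-pass, resample, and average-reference.

    The FIR is a Hamming-window design with ~1 Hz transition bands applied
    forward and backward (zero phase).  Resampling is polyphase.
    """
    lo, hi = band
    if rec.fs < 2 * hi:
        raise NyquistError(
            f"fs={rec.fs} Hz cannot represent a {hi} Hz band edge")
    numtaps = int(3.3 * rec.fs / max(lo, 0.5))
    numtaps = min(numtaps, (rec.n_samples - 1) // 3)  # filtfilt pad bound
    if numtaps % 2 == 0:
        numtaps -= 1
    taps = scipy.signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=rec.fs)
    data = scipy.signal.filtfilt(taps, 1.0, rec.data, axis=1)
    if target_fs and target_fs != rec.fs:
        from fractions import Fraction
        frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
        data = scipy.signal.resample_poly(data, frac.numerator,
                                          frac.denominator, axis=1)
        fs = rec.fs * frac.numerator / frac.denominator
    else:
        fs = rec.fs
    data = data - data.mean(axis=0, keepdims=True)   # average reference
    return EEGRecording(data=data, fs=fs, channel_names=rec.channel_names,
                        positions=rec.positions, subject_id=rec.subject_id,
                        timepoint=rec.timepoint)


def compute_gfp(rec: EEGRecording) -> GFPSeries:
    """GFP(t) = population SD across channels of the referenced potential."""
    if rec.n_channels < 2:
        raise ValueError("GFP needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return GFPSeries(values=data.std(axis=0), fs=rec.fs)


def extract_gfp_peaks(gfp: GFPSeries) -> np.ndarray:
    """Indices of strict local maxima of the GFP series (endpoints excluded)."""
    v = gfp.values
    if len(v) < 3:
        raise ValueError("series too short for peak extraction")
    interior = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    return np.flatnonzero(interior) + 1


# ---------------------------------------------------------------------------
# modified k-means
# ---------------------------------------------------------------------------

def _prep_maps(maps: np.ndarray):
    """Center maps, return (unit-L2 rows, L2 norms)."""
    maps = average_reference(maps)
    norms = np.linalg.norm(maps, axis=1)
    if np.any(norms == 0):
        raise ValueError("degenerate all-zero map(s) in input")
    return maps / norms[:, None], norms


def _gev(weights2: np.ndarray, corr: np.ndarray) -> float:
    """GFP-squared-weighted mean squared correlation."""
    return float(np.sum(weights2 * corr ** 2) / np.sum(weights2))


def _dominant_eigvec(unit_maps: np.ndarray) -> np.ndarray:
    """Dominant eigenvector of the channel outer-product sum of the rows."""
    s = unit_maps.T @ unit_maps
    w, v = np.linalg.eigh(s)
    vec = v[:, -1]
    return vec / np.linalg.norm(vec)


def _kmeans_once(unit_maps, weights2, k, rng, max_iter, tol):
    n = unit_maps.shape[0]
    idx = rng.choice(n, size=k, replace=False)
    templates = unit_maps[idx].copy()
    prev = -np.inf
    for _ in range(max_iter):
        corr = unit_maps @ templates.T                    # n x k
        assign = np.argmax(corr ** 2, axis=1)
        best = np.abs(corr[np.arange(n), assign])
        # empty cluster -> reseed from the worst-explained map
        for c in range(k):
            if not np.any(assign == c):
                worst = int(np.argmin(best))
                assign[worst] = c
                best[worst] = 1.0
        for c in range(k):
            templates[c] = _dominant_eigvec(unit_maps[assign == c])
        corr = unit_maps @ templates.T
        assign = np.argmax(corr ** 2, axis=1)
        obj = _gev(weights2, corr[np.arange(n), assign])
        if obj - prev < tol * max(abs(prev), 1e-12) and obj >= prev:
            prev = obj
            break
        prev = obj
    return templates, assign, prev


def modified_kmeans(maps: np.ndarray, k: int, n_restarts: int = 50,
                    seed: int | None = None, max_iter: int = 200,
                    tol: float = 1e-7,
                    labels: Sequence[str] | None = None) -> MicrostateTemplateSet:
    """Polarity-invariant k-means over topographic maps.

    Assignment maximizes squared spatial correlation; the template update
    is the dominant eigenvector of the assigned maps' outer-product sum.
    The best of ``n_restarts`` random initializations by total GEV is
    returned, with maps scaled to unit GFP.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    n, n_ch = maps.shape
    if k > n:
        raise ValueError(f"k={k} exceeds number of maps n={n}")
    unit_maps, norms = _prep_maps(maps)
    weights2 = (norms / np.sqrt(n_ch)) ** 2              # GFP^2 weights
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        templates, assign, obj = _kmeans_once(unit_maps, weights2, k, rng,
                                              max_iter, tol)
        if best is None or obj > best[2]:
            best = (templates, assign, obj)
    templates, _, obj = best
    out_maps = unit_gfp(templates)
    if labels is None:
        labels = [DEFAULT_LABELS[i] if i < len(DEFAULT_LABELS) else f"S{i}"
                  for i in range(k)]
    return MicrostateTemplateSet(maps=out_maps, labels=labels,
                                 gev_total=obj, provenance="individual")


def template_gev(maps: np.ndarray, tset: MicrostateTemplateSet) -> float:
    """Total GEV of a fixed template set on a collection of maps."""
    unit_maps, norms = _prep_maps(maps)
    weights2 = norms ** 2
    tmpl = unit_gfp(tset.maps)
    tmpl = tmpl / np.linalg.norm(tmpl, axis=1, keepdims=True)
    corr = unit_maps @ tmpl.T
    best = np.max(np.abs(corr), axis=1)
    return _gev(weights2, best)


def select_k_cv(maps: np.ndarray, k_range: Sequence[int] = range(2, 9),
                n_restarts: int = 50, seed: int | None = None
                ) -> tuple[int, dict[int, float]]:
    """Choose the number of clusters by the predictive-residual CV criterion.

    CV(k) = sigma2_k * ((C-1)/(C-1-k))**2 with C the channel count and
    sigma2_k the mean residual variance of the maps about their assigned
    polarity-aligned templates; the k minimizing CV is returned.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    maps = average_reference(maps)
    n, n_ch = maps.shape
    k_range = list(k_range)
    if max(k_range) >= n_ch - 1:
        raise ValueError("k_range exceeds channel-count bound C-1")
    if max(k_range) > n:
        raise ValueError("k_range exceeds number of maps")
    rng = np.random.default_rng(seed)
    criterion: dict[int, float] = {}
    for k in k_range:
        tset = modified_kmeans(maps, k, n_restarts=n_restarts,
                               seed=int(rng.integers(2 ** 31)))
        tmpl = tset.maps / np.linalg.norm(tset.maps, axis=1, keepdims=True)
        corr = maps @ tmpl.T
        assign = np.argmax(corr ** 2, axis=1)
        proj = corr[np.arange(n), assign]
        resid = np.sum(maps ** 2) - np.sum(proj ** 2)
        sigma2 = resid / (n * (n_ch - 1))
        criterion[k] = sigma2 * ((n_ch - 1) / (n_ch - 1 - k)) ** 2
    # smallest k within numerical dust of the minimum wins (degenerate
    # noiseless inputs give zero criteria for every k >= k_true)
    best = min(criterion.values())
    tol = best + 1e-9 * float(np.mean(maps ** 2))
    k_star = min(kk for kk, v in criterion.items() if v <= tol)
    return k_star, criterion


def build_group_templates(sets: Sequence[MicrostateTemplateSet], k: int = 4,
                          n_restarts: int = 50, seed: int | None = None
                          ) -> MicrostateTemplateSet:
    """Second-level clustering of individual template maps into group maps."""
    n_ch = {s.n_channels for s in sets}
    if len(n_ch) != 1:
        raise ValueError(f"mixed channel counts across template sets: {n_ch}")
    stacked = np.vstack([unit_gfp(s.maps) for s in sets])
    out = modified_kmeans(stacked, k, n_restarts=n_restarts, seed=seed)
    out.provenance = "group"
    return out


def sort_templates(tset: MicrostateTemplateSet,
                   reference: MicrostateTemplateSet,
                   allow_large_k: bool = False) -> MicrostateTemplateSet:
    """Order and sign-align templates to a reference set.

    The permutation maximizing the summed absolute spatial correlation to
    the reference is found exhaustively (guarded at k <= 6); signs are
    flipped so each correlation to its reference map is positive; ties go
    to the lexicographically smallest permutation.
    """
    if tset.k != reference.k:
        raise ValueError("template sets must share k")
    if tset.n_channels != reference.n_channels:
        raise ValueError("template sets must share the channel space")
    k = tset.k
    if k > 6 and not allow_large_k:
        raise ValueError("exhaustive sorting guarded at k <= 6")
    a = tset.maps / np.linalg.norm(tset.maps, axis=1, keepdims=True)
    b = reference.maps / np.linalg.norm(reference.maps, axis=1, keepdims=True)
    corr = a @ b.T                                       # tset x reference
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(k)):
        score = sum(abs(corr[perm[j], j]) for j in range(k))
        if score > best_score + 1e-12:
            best_score, best_perm = score, perm
    new_maps = tset.maps[list(best_perm)].copy()
    for j in range(k):
        if corr[best_perm[j], j] < 0:
            new_maps[j] = -new_maps[j]
    return MicrostateTemplateSet(maps=new_maps, labels=list(reference.labels),
                                 gev_total=tset.gev_total,
                                 provenance=tset.provenance)


def canonical_reference(n_channels: int,
                        positions: np.ndarray | None = None
                        ) -> MicrostateTemplateSet:
    """Built-in A-D sorting reference on the given montage."""
    maps, _ = canonical_templates(n_channels, positions)
    return MicrostateTemplateSet(maps=maps, labels=list("ABCD"),
                                 provenance="canonical")


# ---------------------------------------------------------------------------
# back-fitting and metrics
# ---------------------------------------------------------------------------

def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode labels into (state, start, length) triples."""
    if len(labels) == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def _smooth_segments(labels: np.ndarray, corr_all: np.ndarray,
                     min_len: int) -> np.ndarray:
    """Remove segments shorter than ``min_len`` samples.

    Repeatedly relabels the shortest offending segment (earliest on ties)
    to whichever adjacent segment's template explains its samples better
    (higher mean absolute correlation); boundary segments merge inward.
    """
    if min_len <= 1:
        return labels
    runs = _runs(labels)
    if len(runs) <= 1:
        return labels
    # doubly linked segment list
    seg = {i: [st, s, ln, i - 1 if i else None,
               i + 1 if i + 1 < len(runs) else None]
           for i, (st, s, ln) in enumerate(runs)}
    heap = [(ln, s, i) for i, (st, s, ln) in enumerate(runs) if ln < min_len]
    heapq.heapify(heap)
    cum = np.cumsum(np.abs(corr_all), axis=0)   # prefix sums per template

    def mean_corr(start, length, state):
        hi = cum[start + length - 1, state]
        lo = cum[start - 1, state] if start else 0.0
        return (hi - lo) / length

    while heap:
        ln, s, i = heapq.heappop(heap)
        node = seg.get(i)
        if node is None or node[2] != ln or node[1] != s:
            continue                                     # stale heap entry
        if len(seg) <= 1:
            break
        state, start, length, prev, nxt = node
        cand = []
        if prev is not None:
            cand.append((mean_corr(start, length, seg[prev][0]), prev))
        if nxt is not None:
            cand.append((mean_corr(start, length, seg[nxt][0]), nxt))
        # higher mean |corr| wins; tie -> earlier neighbor (the left one)
        cand.sort(key=lambda t: (-t[0], seg[t[1]][1]))
        target = cand[0][1]
        node[0] = seg[target][0]
        # merge with equal-state neighbors
        for nb in (node[3], node[4]):
            if nb is not None and nb in seg and seg[nb][0] == node[0]:
                other = seg.pop(nb)
                node[1] = min(node[1], other[1])
                node[2] += other[2]
                if other[1] < start:
                    node[3] = other[3]
                    if other[3] is not None:
                        seg[other[3]][4] = i
                else:
                    node[4] = other[4]
                    if other[4] is not None:
                        seg[other[4]][3] = i
        if node[2] < min_len:
            heapq.heappush(heap, (node[2], node[1], i))
    out = np.empty_like(labels)
    for state, start, length, _, _ in seg.values():
        out[start:start + length] = state
    return out


def backfit(rec: EEGRecording, tset: MicrostateTemplateSet,
            min_duration_ms: float = 30.0) -> MicrostateSegmentation:
    """Label every sample by maximal absolute spatial correlation, then
    enforce the minimum segment duration by merge smoothing."""
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    if rec.n_channels != tset.n_channels:
        raise ValueError("recording and templates have different channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(data, axis=0)
    norms[norms == 0] = 1.0
    unit = data / norms
    tmpl = tset.maps / np.linalg.norm(tset.maps, axis=1, keepdims=True)
    corr_all = np.abs(tmpl @ unit).T                    # n_samples x k
    labels = np.argmax(corr_all, axis=1)
    min_len = int(round(min_duration_ms * rec.fs / 1000.0))
    labels = _smooth_segments(labels, corr_all, min_len)
    corr = corr_all[np.arange(len(labels)), labels]
    return MicrostateSegmentation(labels=labels, segments=_runs(labels),
                                  fs=rec.fs, corr=corr, corr_all=corr_all,
                                  k=tset.k)


def compute_microstate_metrics(seg: MicrostateSegmentation, gfp: GFPSeries,
                               labels: Sequence[str] | None = None
                               ) -> MicrostateMetrics:
    """Coverage, occurrence, mean duration, GEV and transition matrix."""
    if seg.n_samples == 0:
        raise ValueError("segmentation has no labeled samples")
    if len(gfp.values) != seg.n_samples:
        raise ValueError("GFP series and segmentation length differ")
    k = seg.k or int(seg.labels.max()) + 1
    n = seg.n_samples
    total_s = n / seg.fs
    coverage = np.zeros(k)
    occurrence = np.zeros(k)
    duration = np.zeros(k)
    gev = np.zeros(k)
    g2 = gfp.values ** 2
    g2_total = g2.sum()
    seg_counts = np.zeros(k)
    seg_samples = np.zeros(k)
    for state, start, length in seg.segments:
        seg_counts[state] += 1
        seg_samples[state] += length
    for s in range(k):
        coverage[s] = seg_samples[s] / n
        occurrence[s] = seg_counts[s] / total_s
        if seg_counts[s]:
            duration[s] = seg_samples[s] / seg_counts[s] / seg.fs * 1000.0
        mask = seg.labels == s
        if g2_total > 0 and mask.any():
            gev[s] = np.sum(g2[mask] * seg.corr[mask] ** 2) / g2_total
    trans = np.zeros((k, k))
    states = [st for st, _, _ in seg.segments]
    for a, b in zip(states[:-1], states[1:]):
        trans[a, b] += 1
    row = trans.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        trans = np.where(row > 0, trans / row, 0.0)
    if labels is None:
        labels = [DEFAULT_LABELS[i] if i < len(DEFAULT_LABELS) else f"S{i}"
                  for i in range(k)]
    return MicrostateMetrics(labels=list(labels), gev=gev, coverage=coverage,
                             occurrence=occurrence, duration=duration,
                             transition_matrix=trans)
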