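"""Synthetic pre/post rehabilitation cohort with known ground truth.

Generates the three coupled data streams the pipeline consumes:

* resting EEG built from four canonical microstate topographies driven by
  a segment-level semi-Markov process (gamma-distributed dwell episodes),
  a rectified-sinusoid GFP envelope, spatially correlated noise at a
  configurable GFP-power SNR, band-limited to 1-30 Hz;
* ROI BOLD built from a library of 14 network-pair coactivation patterns
  driven by a frame-level Markov chain at TR = 2 s;
* integer clinical scores (MDS-UPDRS III total and subscales, PDQ-39)
  drawn from the published group moments, with the responder pre-post
  reduction forced past the 3.25-point MCID and clinical change rates
  rank-coupled to the injected neural effect sizes through a Gaussian
  copula.

Responders receive post-treatment state dynamics with microstate-C
occupancy scaled down, microstate-D occupancy scaled up, an absolute
boost of the A/B -> D transition probabilities and a longer dwell time of
the DAN+ VAN- coactivation pattern; nonresponders receive the reversed
effects.  Every simulated object is reproducible bit-for-bit from its
seed, and the realized state sequences (the ground truth) are stored so
recovery can be scored without re-simulation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .io_formats import (AtlasMap, CohortTable, EEGRecording, NETWORKS,
                         ROITimeSeriesTable, COHORT_SCORE_COLUMNS)
from .templates import canonical_templates, disk_layout

EEG_STATES = ("A", "B", "C", "D")

# (activated, deactivated) network pairs; index 0 is the DAN+ VAN- pattern
# whose dwell time carries the injected treatment effect
CAP_PATTERN_PAIRS = [
    ("DAN", "VAN"), ("VAN", "DAN"), ("FPN", "VN"), ("SMN", "FPN"),
    ("VN", "DMN"), ("DMN", "VN"), ("SMN", "DAN"), ("LN", "DMN"),
    ("DMN", "LN"), ("VAN", "SMN"), ("FPN", "DMN"), ("DMN", "FPN"),
    ("LN", "VN"), ("DAN", "SMN"),
]

# group x timepoint clinical score moments (mean, SD), integer points
CLINICAL_MOMENTS = {
    "responder": {
        "mds_updrs3_total": {"pre": (40.42, 11.02), "post": (33.79, 10.93)},
        "tremor": {"pre": (4.21, 3.93), "post": (3.54, 3.50)},
        "bradykinesia": {"pre": (19.92, 7.23), "post": (15.46, 6.65)},
        "rigidity": {"pre": (9.75, 2.19), "post": (9.33, 1.97)},
        "axial": {"pre": (6.54, 3.68), "post": (5.46, 2.90)},
        "pdq39": {"pre": (23.60, 9.92), "post": (15.17, 9.29)},
    },
    "nonresponder": {
        "mds_updrs3_total": {"pre": (36.25, 10.76), "post": (37.11, 11.90)},
        "tremor": {"pre": (3.50, 3.67), "post": (4.00, 4.39)},
        "bradykinesia": {"pre": (18.71, 6.14), "post": (18.93, 6.46)},
        "rigidity": {"pre": (8.75, 1.82), "post": (9.14, 2.09)},
        "axial": {"pre": (5.29, 2.57), "post": (5.04, 2.89)},
        "pdq39": {"pre": (24.19, 8.85), "post": (20.49, 10.15)},
    },
}

MCID = 3.25


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EEGSimParams:
    n_channels: int = 32
    fs: float = 500.0
    duration_s: float = 180.0
    n_states: int = 4
    mean_duration_ms: float = 80.0
    duration_shape: float = 4.0
    gfp_carrier_hz: float = 10.0
    snr_db: float = 5.0
    band: tuple[float, float] = (1.0, 30.0)

    def __post_init__(self):
        if self.n_channels < 8:
            raise ValueError("need at least 8 channels")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fs must be an integer")
        if self.mean_duration_ms < 30:
            raise ValueError("mean state duration must be >= 30 ms")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclasses.dataclass
class BOLDSimParams:
    n_rois: int = 100
    n_frames: int = 240
    tr: float = 2.0
    n_states: int = 14
    mean_dwell_frames: float = 4.0
    noise_sd: float = 0.5
    amplitude: float = 2.5

    def __post_init__(self):
        if self.n_frames < 30:
            raise ValueError("need at least 30 frames")
        if self.n_rois < len(NETWORKS):
            raise ValueError("each network needs at least one ROI")


@dataclasses.dataclass
class CohortEffects:
    n_responders: int = 24
    n_nonresponders: int = 28
    occurrence_C_factor: float = 0.8      # responder post multiplier, < 1
    occurrence_D_factor: float = 1.25     # responder post multiplier, > 1
    transition_AB_to_D_boost: float = 0.05   # absolute, responder post
    dwell_DANpVANm_factor: float = 1.3    # responder post multiplier, > 1
    # pooled-cohort Spearman targets between clinical reduction rate and the
    # neural change rates (signs follow the observed clinical correlations)
    coupling_rho_C: float = 0.409
    coupling_rho_D: float = -0.393
    coupling_rho_cap: float = -0.334
    # log-scale between-subject spread of the injected factors; the CAP
    # spread is kept smaller because dwell time is estimated from far
    # fewer state visits than the EEG occurrences
    eeg_jitter_sd: float = 0.35
    cap_jitter_sd: float = 0.25
    baseline_jitter_sd: float = 0.15      # subject baseline occupancy spread
    # Baseline (pre-treatment) group contrasts, applied to responders:
    # responders start with more microstate C, less microstate D and a
    # shorter DAN+ VAN- dwell than nonresponders, which is what makes
    # the baseline features predictive of response.  Responders are
    # heterogeneous: an "EEG-silent" subset carries the dwell marker
    # predominantly and shows no microstate baseline contrast, so the
    # two modalities are non-redundant and their combination predicts
    # response better than either alone.
    baseline_occ_C_factor: float = 1.35
    baseline_occ_D_factor: float = 0.55
    baseline_cap_dwell_factor: float = 0.7        # typical responders
    baseline_cap_dwell_factor_silent: float = 0.35  # EEG-silent responders
    eeg_silent_fraction: float = 0.3
    # when True, draw both groups' clinical scores from pooled moments so
    # the clinical baseline carries no group signal
    equalize_baseline_clinical: bool = False

    def __post_init__(self):
        if min(self.n_responders, self.n_nonresponders) < 2:
            raise ValueError("group sizes must be >= 2")
        for f in (self.occurrence_C_factor, self.occurrence_D_factor,
                  self.dwell_DANpVANm_factor):
            if f <= 0:
                raise ValueError("factors must be positive")
        for r in (self.coupling_rho_C, self.coupling_rho_D,
                  self.coupling_rho_cap):
            if abs(r) > 1:
                raise ValueError("infeasible coupling |rho| > 1")


@dataclasses.dataclass
class StateSequenceTruth:
    """Realized state sequence of one simulated recording plus summaries."""
    labels: np.ndarray                  # per-sample / per-frame state index
    transition_generative: np.ndarray   # the chain the sequence was drawn from
    occurrence: np.ndarray              # episodes per second
    duration_ms: np.ndarray             # mean episode length
    coverage: np.ndarray                # fraction of samples
    transition_empirical: np.ndarray    # segment-level conditional frequencies


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def make_canonical_templates(n_channels: int = 32,
                             positions: np.ndarray | None = None
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Four unit-GFP canonical microstate maps (A-D) on a 2-D layout."""
    return canonical_templates(n_channels, positions)


def uniform_segment_chain(n_states: int) -> np.ndarray:
    """Zero-diagonal row-stochastic matrix with uniform off-diagonal mass."""
    p = np.full((n_states, n_states), 1.0 / (n_states - 1))
    np.fill_diagonal(p, 0.0)
    return p


def _stationary(p: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(p.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def segment_chain_for_occupancy(pi_target: np.ndarray,
                                n_iter: int = 40) -> np.ndarray:
    """Zero-diagonal chain whose stationary distribution matches a target.

    Uses the P(i->j) = q_j / (1 - q_i) construction with q calibrated by
    fixed-point iteration so the realized stationary hits ``pi_target``.
    """
    pi_target = np.asarray(pi_target, dtype=float)
    pi_target = pi_target / pi_target.sum()
    q = pi_target.copy()
    p = None
    for _ in range(n_iter):
        p = q[None, :] / (1.0 - q[:, None])
        np.fill_diagonal(p, 0.0)
        p = p / p.sum(axis=1, keepdims=True)
        mu = _stationary(p)
        q = q * (pi_target / np.maximum(mu, 1e-12))
        q = np.clip(q / q.sum(), 1e-6, 0.9)
    return p


def boost_transitions(p: np.ndarray, pairs: Sequence[tuple[int, int]],
                      boost: float) -> np.ndarray:
    """Add an absolute boost to given (from, to) entries; other off-diagonal
    entries of the row are rescaled so the row stays stochastic."""
    p = p.copy()
    for i, j in pairs:
        new = np.clip(p[i, j] + boost, 0.0, 0.95)
        others = [c for c in range(p.shape[1]) if c != i and c != j]
        rest = p[i, others].sum()
        if rest <= 0:
            raise ValueError("row has no mass to rebalance")
        p[i, others] *= (1.0 - new) / rest
        p[i, j] = new
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("boost pushed probabilities outside [0, 1]")
    return p


def semi_markov_labels(rng: np.random.Generator, transition: np.ndarray,
                       mean_duration_samples: np.ndarray, shape: float,
                       n_samples: int) -> np.ndarray:
    """Per-sample labels from a segment-level semi-Markov process."""
    transition = np.asarray(transition, dtype=float)
    k = transition.shape[0]
    if np.any(np.abs(transition.sum(axis=1) - 1) > 1e-9):
        raise ValueError("transition rows must sum to 1")
    if np.any(np.diag(transition) > 0):
        raise ValueError("segment-level chain must have zero diagonal")
    mean_duration_samples = np.broadcast_to(
        np.asarray(mean_duration_samples, dtype=float), (k,))
    labels = np.empty(n_samples, dtype=np.int8)
    state = int(rng.integers(k))
    pos = 0
    while pos < n_samples:
        dur = rng.gamma(shape, mean_duration_samples[state] / shape)
        dur = max(1, int(round(dur)))
        labels[pos:pos + dur] = state
        pos += dur
        state = int(rng.choice(k, p=transition[state]))
    return labels


def _sequence_summary(labels: np.ndarray, k: int, rate_hz: float,
                      generative: np.ndarray) -> StateSequenceTruth:
    n = len(labels)
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    seg_states = labels[starts]
    seg_lens = ends - starts
    occ = np.zeros(k)
    cov = np.zeros(k)
    dur = np.zeros(k)
    for s in range(k):
        m = seg_states == s
        occ[s] = m.sum() / (n / rate_hz)
        cov[s] = seg_lens[m].sum() / n
        if m.any():
            dur[s] = seg_lens[m].mean() / rate_hz * 1000.0
    trans = np.zeros((k, k))
    for a, b in zip(seg_states[:-1], seg_states[1:]):
        trans[a, b] += 1
    row = trans.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        trans = np.where(row > 0, trans / row, 0.0)
    return StateSequenceTruth(labels=labels, transition_generative=generative,
                              occurrence=occ, duration_ms=dur, coverage=cov,
                              transition_empirical=trans)


def _bandpass(data: np.ndarray, fs: float,
              band: tuple[float, float]) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (generator-side)."""
    import scipy.signal
    sos = scipy.signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return scipy.signal.sosfiltfilt(sos, data, axis=-1)


def _spatial_noise(rng: np.random.Generator, positions: np.ndarray,
                   n_samples: int, length_scale: float = 0.4) -> np.ndarray:
    """Channel-correlated Gaussian noise (squared-exponential kernel)."""
    d2 = np.sum((positions[:, None, :] - positions[None, :, :]) ** 2, axis=-1)
    k = np.exp(-d2 / (2 * length_scale ** 2)) + 1e-6 * np.eye(len(positions))
    chol = np.linalg.cholesky(k)
    return chol @ rng.standard_normal((len(positions), n_samples))


def synthesize_eeg(labels: np.ndarray, templates: np.ndarray,
                   params: EEGSimParams,
                   rng: np.random.Generator,
                   positions: np.ndarray | None = None) -> EEGRecording:
    """Render a labeled state sequence into a band-limited EEG recording.

    Each dwell episode multiplies its template with a sinusoidal carrier
    at the GFP carrier frequency (random phase per episode), so the GFP
    envelope of the clean signal is the rectified sinusoid; spatially
    correlated noise is added at ``snr_db`` (ratio of band-limited signal
    GFP power to noise GFP power, in dB).  The signed carrier is used
    rather than its rectification because the rectified waveform carries
    a per-episode DC offset that the 1 Hz high-pass would smear across
    neighboring episodes; every downstream step is polarity-invariant,
    so the two parameterizations are equivalent up to that artifact.

    The clean signal is narrow-band by construction (a gated sinusoid at
    the carrier frequency keeps ~95% of its energy inside 1-30 Hz), so
    only the noise passes through the explicit band-pass: filtering the
    gated carrier would smear state boundaries across samples and make
    the stored ground-truth labels unfaithful to the waveform.
    """
    n = len(labels)
    k, n_ch = templates.shape
    if positions is None:
        positions = disk_layout(n_ch)
    t = np.arange(n) / params.fs
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    carrier = np.empty(n)
    for s, e in zip(starts, ends):
        phase = rng.uniform(0, 2 * np.pi)
        carrier[s:e] = np.sin(
            2 * np.pi * params.gfp_carrier_hz * t[s:e] + phase)
    activation = np.zeros((k, n))
    activation[labels, np.arange(n)] = carrier
    signal = templates.T @ activation                     # channels x samples
    noise = _spatial_noise(rng, positions, n)
    noise = _bandpass(noise, params.fs, params.band)
    gfp2 = lambda x: np.mean((x - x.mean(axis=0)).std(axis=0) ** 2)
    scale = np.sqrt(gfp2(signal) /
                    (gfp2(noise) * 10 ** (params.snr_db / 10.0)))
    data = signal + scale * noise
    data -= data.mean(axis=0, keepdims=True)
    return EEGRecording(data=data, fs=params.fs,
                        channel_names=[f"CH{i + 1:02d}" for i in range(n_ch)],
                        positions=positions)


def simulate_eeg_subject(params: EEGSimParams, templates: np.ndarray,
                         transition: np.ndarray, seed: int | None = None,
                         positions: np.ndarray | None = None
                         ) -> tuple[EEGRecording, StateSequenceTruth]:
    """One subject's semi-Markov microstate EEG plus its ground truth."""
    rng = np.random.default_rng(seed)
    mean_samples = params.mean_duration_ms / 1000.0 * params.fs
    labels = semi_markov_labels(rng, transition,
                                np.full(params.n_states, mean_samples),
                                params.duration_shape, params.n_samples)
    truth = _sequence_summary(labels, params.n_states, params.fs, transition)
    rec = synthesize_eeg(labels, templates, params, rng, positions)
    return rec, truth


# ---------------------------------------------------------------------------
# BOLD / CAP side
# ---------------------------------------------------------------------------

def assign_networks(n_rois: int) -> tuple[list[str], AtlasMap]:
    """Round-robin assignment of ROI ids to the seven networks."""
    roi_ids = [f"ROI{i + 1:03d}" for i in range(n_rois)]
    atlas = AtlasMap({rid: NETWORKS[i % len(NETWORKS)]
                      for i, rid in enumerate(roi_ids)})
    return roi_ids, atlas


def make_cap_patterns(n_rois: int) -> tuple[np.ndarray, list[str],
                                            list[str], AtlasMap]:
    """14 network-pair coactivation patterns (+1 activated network ROIs,
    -1 deactivated, 0 elsewhere, unit-normalized)."""
    roi_ids, atlas = assign_networks(n_rois)
    net_idx = {net: [i for i, r in enumerate(roi_ids) if atlas[r] == net]
               for net in NETWORKS}
    patterns = np.zeros((len(CAP_PATTERN_PAIRS), n_rois))
    names = []
    for p, (act, deact) in enumerate(CAP_PATTERN_PAIRS):
        patterns[p, net_idx[act]] = 1.0
        patterns[p, net_idx[deact]] = -1.0
        patterns[p] /= np.linalg.norm(patterns[p])
        names.append(f"{act}+ {deact}-")
    return patterns, names, roi_ids, atlas


def markov_chain_for_dwell(n_states: int,
                           mean_dwell_frames: np.ndarray) -> np.ndarray:
    """Frame-level chain with per-state mean run length ``d`` (p_stay =
    1 - 1/d) and uniform exits."""
    d = np.broadcast_to(np.asarray(mean_dwell_frames, dtype=float),
                        (n_states,))
    if np.any(d < 1):
        raise ValueError("mean dwell must be >= 1 frame")
    p = np.zeros((n_states, n_states))
    for i in range(n_states):
        stay = 1.0 - 1.0 / d[i]
        p[i, :] = (1.0 - stay) / (n_states - 1)
        p[i, i] = stay
    return p


def markov_labels(rng: np.random.Generator, chain: np.ndarray,
                  n_frames: int) -> np.ndarray:
    k = chain.shape[0]
    labels = np.empty(n_frames, dtype=np.int8)
    state = int(rng.integers(k))
    for f in range(n_frames):
        labels[f] = state
        state = int(rng.choice(k, p=chain[state]))
    return labels


def simulate_bold_subject(params: BOLDSimParams, cap_patterns: np.ndarray,
                          chain: np.ndarray, roi_ids: Sequence[str],
                          seed: int | None = None
                          ) -> tuple[ROITimeSeriesTable, StateSequenceTruth]:
    """One run of CAP-structured ROI BOLD plus its ground truth."""
    if cap_patterns.shape[1] != params.n_rois:
        raise ValueError("pattern / ROI dimension mismatch")
    rng = np.random.default_rng(seed)
    labels = markov_labels(rng, chain, params.n_frames)
    truth = _sequence_summary(labels, params.n_states, 1.0 / params.tr, chain)
    data = params.amplitude * cap_patterns[labels]
    data = data + params.noise_sd * rng.standard_normal(data.shape)
    table = ROITimeSeriesTable(data=data, tr=params.tr, roi_ids=list(roi_ids))
    return table, truth


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def _truncnorm_ppf(u, mean, sd, lower=-np.inf, upper=np.inf):
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return scipy.stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


@dataclasses.dataclass
class SubjectSpec:
    """Per-subject generative settings, sufficient to resynthesize."""
    subject_id: str
    group: str
    has_fmri: bool
    eeg_transition: dict                # timepoint -> 4x4 chain
    eeg_occupancy: dict                 # timepoint -> target occupancy
    bold_dwell: dict                    # timepoint -> per-state dwell frames
    seeds: dict                         # (modality, timepoint) -> int
    injected: dict = dataclasses.field(default_factory=dict)
    # injected: the subject's true effect sizes ("occ_C", "occ_D",
    # "cap_dwell" post/pre factors), i.e. the quantities the clinical
    # change rates are rank-coupled to


class SyntheticCohort:
    """A full simulated pre/post cohort with lazy signal synthesis.

    State sequences, clinical scores and ground-truth summaries are drawn
    eagerly (they are small); the EEG waveforms and BOLD tables are
    rendered on demand from stored child seeds, bit-reproducibly.
    """

    def __init__(self, effects: CohortEffects, eeg_params: EEGSimParams,
                 bold_params: BOLDSimParams, seed: int,
                 missing_fmri_subjects: int = 0):
        self.effects = effects
        self.eeg_params = eeg_params
        self.bold_params = bold_params
        self.seed = seed
        rng = np.random.default_rng(seed)

        self.templates, self.positions = make_canonical_templates(
            eeg_params.n_channels)
        (self.cap_patterns, self.cap_names, self.roi_ids,
         self.atlas) = make_cap_patterns(bold_params.n_rois)
        self.cap_effect_state = 0        # index of the DAN+ VAN- pattern

        n = effects.n_responders + effects.n_nonresponders
        groups = (["responder"] * effects.n_responders
                  + ["nonresponder"] * effects.n_nonresponders)
        sids = [f"S{i + 1:02d}" for i in range(n)]
        no_fmri = set(sids[-missing_fmri_subjects:]) if missing_fmri_subjects else set()

        # Gaussian copula: clinical latent + three neural latents with the
        # configured Spearman targets (converted to Pearson correlations)
        rhos = np.array([effects.coupling_rho_C, effects.coupling_rho_D,
                         effects.coupling_rho_cap])
        r = 2 * np.sin(np.pi * rhos / 6)
        cov = np.eye(4)
        cov[0, 1:] = cov[1:, 0] = r
        z = rng.multivariate_normal(np.zeros(4), cov, size=n,
                                    method="cholesky")
        z_clin, z_c, z_d, z_cap = z.T

        self.subjects: list[SubjectSpec] = []
        self.truth: dict[tuple[str, str, str], StateSequenceTruth] = {}
        rows = []

        def jitter(zz, s):
            # mean-preserving lognormal subject spread around the group base
            return float(np.exp(s * zz - s ** 2 / 2))

        for i, (sid, grp) in enumerate(zip(sids, groups)):
            resp = grp == "responder"
            # group base factors; nonresponders get the reversed direction
            base_c = effects.occurrence_C_factor
            base_d = effects.occurrence_D_factor
            base_cap = effects.dwell_DANpVANm_factor
            boost = effects.transition_AB_to_D_boost
            if not resp:
                base_c, base_d = 1 / base_c, 1 / base_d
                base_cap, boost = 1 / base_cap, -boost
            # the copula latents carry the clinical coupling; the jitter is
            # applied to the group base, never to its reciprocal, so the
            # group mean factor equals the configured base in both groups
            f_c = base_c * jitter(z_c[i], effects.eeg_jitter_sd)
            f_d = base_d * jitter(z_d[i], effects.eeg_jitter_sd)
            f_cap = base_cap * jitter(z_cap[i], effects.cap_jitter_sd)

            def apply_occ(pi, fc, fd):
                out = pi.copy()
                out[2] = np.clip(pi[2] * fc, 0.02, 0.6)
                out[3] = np.clip(pi[3] * fd, 0.02, 0.6)
                out[:2] = pi[:2] * (1.0 - out[2] - out[3]) / pi[:2].sum()
                return out

            n_silent = int(round(effects.eeg_silent_fraction
                                 * effects.n_responders))
            silent = resp and i < n_silent
            base = rng.lognormal(0.0, effects.baseline_jitter_sd, size=4)
            pi_base = base / base.sum()
            if resp and not silent:
                # baseline microstate contrast of the typical responders
                pi_pre = apply_occ(pi_base, effects.baseline_occ_C_factor,
                                   effects.baseline_occ_D_factor)
            else:
                pi_pre = pi_base
            pi_post = apply_occ(pi_pre, f_c, f_d)
            chains = {"pre": segment_chain_for_occupancy(pi_pre)}
            p_post = segment_chain_for_occupancy(pi_post)
            if abs(boost) > 1e-12:
                b = boost if boost > 0 else max(boost, -0.9 * min(
                    p_post[0, 3], p_post[1, 3]))
                p_post = boost_transitions(p_post, [(0, 3), (1, 3)], b)
            chains["post"] = p_post

            d0 = self.bold_params.mean_dwell_frames
            dwell_pre = np.full(bold_params.n_states, float(d0))
            if resp:
                f_base = (effects.baseline_cap_dwell_factor_silent if silent
                          else effects.baseline_cap_dwell_factor)
                dwell_pre[self.cap_effect_state] = max(1.2, d0 * f_base)
            dwell_post = dwell_pre.copy()
            dwell_post[self.cap_effect_state] = max(
                1.2, dwell_pre[self.cap_effect_state] * f_cap)
            seeds = {key: int(rng.integers(2 ** 31))
                     for key in (("eeg", "pre"), ("eeg", "post"),
                                 ("bold", "pre"), ("bold", "post"))}
            spec = SubjectSpec(subject_id=sid, group=grp,
                               has_fmri=sid not in no_fmri,
                               eeg_transition=chains,
                               eeg_occupancy={"pre": pi_pre, "post": pi_post},
                               bold_dwell={"pre": dwell_pre,
                                           "post": dwell_post},
                               seeds=seeds,
                               injected={"occ_C": f_c, "occ_D": f_d,
                                         "cap_dwell": f_cap})
            self.subjects.append(spec)

            # realized state sequences and their ground-truth summaries
            mean_samples = (eeg_params.mean_duration_ms / 1000.0
                            * eeg_params.fs)
            for tp in ("pre", "post"):
                srng = np.random.default_rng(spec.seeds[("eeg", tp)])
                labels = semi_markov_labels(
                    srng, chains[tp],
                    np.full(eeg_params.n_states, mean_samples),
                    eeg_params.duration_shape, eeg_params.n_samples)
                self.truth[(sid, tp, "eeg")] = _sequence_summary(
                    labels, eeg_params.n_states, eeg_params.fs, chains[tp])
                if spec.has_fmri:
                    brng = np.random.default_rng(spec.seeds[("bold", tp)])
                    chain = markov_chain_for_dwell(
                        bold_params.n_states, spec.bold_dwell[tp])
                    blabels = markov_labels(brng, chain, bold_params.n_frames)
                    self.truth[(sid, tp, "bold")] = _sequence_summary(
                        blabels, bold_params.n_states, 1.0 / bold_params.tr,
                        chain)

            # clinical scores: pre from group moments, post anchored by a
            # copula-ranked reduction forced across / kept inside the MCID
            mom = CLINICAL_MOMENTS[grp]
            u_clin = scipy.stats.norm.cdf(z_clin[i])
            if effects.equalize_baseline_clinical:
                w = effects.n_responders / n
                m = (w * CLINICAL_MOMENTS["responder"]
                     ["mds_updrs3_total"]["pre"][0]
                     + (1 - w) * CLINICAL_MOMENTS["nonresponder"]
                     ["mds_updrs3_total"]["pre"][0])
                sd = 10.9
            else:
                m, sd = mom["mds_updrs3_total"]["pre"]
            pre_total = int(round(_truncnorm_ppf(rng.uniform(), m, sd,
                                                 lower=8, upper=90)))
            d_mean = (mom["mds_updrs3_total"]["pre"][0]
                      - mom["mds_updrs3_total"]["post"][0])
            if resp:
                delta = _truncnorm_ppf(u_clin, d_mean, 3.0, lower=3.51,
                                       upper=min(25.0, pre_total - 1))
            else:
                delta = _truncnorm_ppf(u_clin, d_mean, 3.0,
                                       lower=-15.0, upper=3.49)
            post_total = int(np.clip(round(pre_total - delta), 0, 120))
            scores = {"pre": {"mds_updrs3_total": pre_total},
                      "post": {"mds_updrs3_total": post_total}}
            for col in ("tremor", "bradykinesia", "rigidity", "axial",
                        "pdq39"):
                for tp in ("pre", "post"):
                    m, sd = mom[col][tp]
                    v = int(round(_truncnorm_ppf(rng.uniform(), m, sd,
                                                 lower=0, upper=60)))
                    if col != "pdq39":
                        v = min(v, scores[tp]["mds_updrs3_total"])
                    scores[tp][col] = v
            for tp in ("pre", "post"):
                rows.append({"subject_id": sid, "group": grp,
                             "timepoint": tp, **scores[tp]})

        frame = pd.DataFrame(rows)
        frame = frame[["subject_id", "group", "timepoint",
                       *COHORT_SCORE_COLUMNS]]
        self.clinical = CohortTable(frame)

    # -- lazy synthesis ----------------------------------------------------

    def _spec(self, subject_id: str) -> SubjectSpec:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def eeg_recording(self, subject_id: str, timepoint: str) -> EEGRecording:
        spec = self._spec(subject_id)
        truth = self.truth[(subject_id, timepoint, "eeg")]
        rng = np.random.default_rng(spec.seeds[("eeg", timepoint)])
        # reproduce the sequence draw so the waveform rng state matches
        mean_samples = (self.eeg_params.mean_duration_ms / 1000.0
                        * self.eeg_params.fs)
        semi_markov_labels(rng, spec.eeg_transition[timepoint],
                           np.full(self.eeg_params.n_states, mean_samples),
                           self.eeg_params.duration_shape,
                           self.eeg_params.n_samples)
        rec = synthesize_eeg(truth.labels, self.templates, self.eeg_params,
                             rng, self.positions)
        rec.subject_id = subject_id
        rec.timepoint = timepoint
        return rec

    def bold_table(self, subject_id: str,
                   timepoint: str) -> ROITimeSeriesTable:
        spec = self._spec(subject_id)
        if not spec.has_fmri:
            raise KeyError(f"{subject_id} has no fMRI record")
        truth = self.truth[(subject_id, timepoint, "bold")]
        rng = np.random.default_rng(spec.seeds[("bold", timepoint)])
        markov_labels(rng, truth.transition_generative,
                      self.bold_params.n_frames)
        data = self.bold_params.amplitude * self.cap_patterns[truth.labels]
        data = data + self.bold_params.noise_sd * rng.standard_normal(
            data.shape)
        table = ROITimeSeriesTable(data=data, tr=self.bold_params.tr,
                                   roi_ids=list(self.roi_ids),
                                   subject_id=subject_id,
                                   timepoint=timepoint)
        return table

    # -- ground-truth summaries -------------------------------------------

    def true_metric_frame(self) -> pd.DataFrame:
        """Long table of the generator's per-recording true metric values."""
        rows = []
        for spec in self.subjects:
            for tp in ("pre", "post"):
                t = self.truth[(spec.subject_id, tp, "eeg")]
                row = {"subject_id": spec.subject_id, "group": spec.group,
                       "timepoint": tp}
                for s, lab in enumerate(EEG_STATES):
                    row[f"occurrence_{lab}"] = t.occurrence[s]
                    row[f"duration_{lab}"] = t.duration_ms[s]
                    row[f"coverage_{lab}"] = t.coverage[s]
                row["p_AD"] = t.transition_empirical[0, 3]
                row["p_BD"] = t.transition_empirical[1, 3]
                if spec.has_fmri:
                    b = self.truth[(spec.subject_id, tp, "bold")]
                    row["cap_dwell_DANpVANm"] = _dwell_of_state(
                        b.labels, self.cap_effect_state, self.bold_params.tr)
                rows.append(row)
        return pd.DataFrame(rows)


def _dwell_of_state(labels: np.ndarray, state: int, tr: float) -> float:
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    lens = [e - s for s, e in zip(starts, ends) if labels[s] == state]
    return float(np.mean(lens) * tr) if lens else 0.0


def simulate_cohort(effects: CohortEffects | None = None,
                    eeg_params: EEGSimParams | None = None,
                    bold_params: BOLDSimParams | None = None,
                    seed: int = 0,
                    missing_fmri_subjects: int = 0) -> SyntheticCohort:
    """Build a full synthetic pre/post cohort (see module docstring)."""
    return SyntheticCohort(effects or CohortEffects(),
                           eeg_params or EEGSimParams(),
                           bold_params or BOLDSimParams(), seed,
                           missing_fmri_subjects=missing_fmri_subjects)
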