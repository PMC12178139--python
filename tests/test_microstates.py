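"""Microstate pipeline: GFP, peaks, modified k-means, sorting, back-fit,
temporal metrics — each checked against trivial cases and independent
brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurostate import microstates as ms
from neurostate.io_formats import EEGRecording
from neurostate.templates import unit_gfp


def make_rec(data, fs=500.0):
    return EEGRecording(data=np.asarray(data, float), fs=fs,
                        channel_names=[f"c{i}" for i in
                                       range(np.asarray(data).shape[0])])


# ---------------------------------------------------------------------------
# preprocessing / GFP / peaks
# ---------------------------------------------------------------------------

class TestPreprocess:
    def test_50hz_sine_removed(self, rng):
        fs = 500.0
        t = np.arange(int(4 * fs)) / fs
        data = np.outer(rng.normal(size=8), np.sin(2 * np.pi * 50 * t))
        out = ms.preprocess(make_rec(data, fs), target_fs=fs)
        core = slice(int(fs), int(3 * fs))      # skip filter edges
        assert (np.sqrt((out.data[:, core] ** 2).mean())
                < 0.01 * np.sqrt((data[:, core] ** 2).mean()))

    def test_passband_identity(self, rng):
        fs = 500.0
        t = np.arange(int(6 * fs)) / fs
        sig = np.sin(2 * np.pi * 10 * t) + 0.5 * np.sin(2 * np.pi * 4 * t)
        data = np.outer(rng.normal(size=8), sig)
        ref = data - data.mean(axis=0)
        out = ms.preprocess(make_rec(data, fs), target_fs=fs)
        core = slice(int(2 * fs), int(4 * fs))
        err = np.abs(out.data[:, core] - ref[:, core]).max()
        assert err < 0.05 * np.abs(ref[:, core]).max()

    def test_nyquist_error(self):
        with pytest.raises(ms.NyquistError):
            ms.preprocess(make_rec(np.zeros((8, 100)), fs=40.0))


class TestGFP:
    def test_equal_channels_zero(self):
        rec = make_rec(np.ones((4, 10)))
        assert np.all(ms.compute_gfp(rec).values == 0)

    def test_two_channel_plus_minus_one(self):
        rec = make_rec(np.array([[1.0], [-1.0]]))
        assert ms.compute_gfp(rec).values[0] == pytest.approx(1.0)

    def test_matches_direct_formula(self, rng):
        data = rng.normal(size=(8, 50))
        got = ms.compute_gfp(make_rec(data)).values
        v = data - data.mean(axis=0)
        want = np.sqrt((v ** 2).mean(axis=0))    # oracle: RMS about mean
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            ms.compute_gfp(make_rec(np.ones((1, 10))))


class TestGFPPeaks:
    def test_monotone_series_empty(self):
        gfp = ms.GFPSeries(values=np.arange(10.0), fs=100)
        assert len(ms.extract_gfp_peaks(gfp)) == 0

    def test_alternating_series(self):
        gfp = ms.GFPSeries(values=np.array([0, 1, 0, 1, 0.0]), fs=100)
        assert list(ms.extract_gfp_peaks(gfp)) == [1, 3]

    def test_matches_neighbor_scan(self, rng):
        t = np.linspace(0, 5, 1000)
        v = np.abs(np.sin(7 * t) + 0.5 * np.sin(13 * t + 1))
        got = list(ms.extract_gfp_peaks(ms.GFPSeries(values=v, fs=200)))
        want = [i for i in range(1, len(v) - 1)
                if v[i] > v[i - 1] and v[i] > v[i + 1]]   # O(n) oracle
        assert got == want


# ---------------------------------------------------------------------------
# modified k-means and model selection
# ---------------------------------------------------------------------------

def brute_force_gev(maps, k):
    """Exhaustive-partition optimum of the modified k-means objective."""
    maps = maps - maps.mean(axis=1, keepdims=True)
    n, n_ch = maps.shape
    norms = np.linalg.norm(maps, axis=1)
    unit = maps / norms[:, None]
    w2 = norms ** 2
    best = 0.0
    for assign in itertools.product(range(k), repeat=n):
        assign = np.array(assign)
        if len(set(assign)) < k:
            continue
        num = 0.0
        for c in range(k):
            sub = unit[assign == c]
            s = sub.T @ sub
            lam = np.linalg.eigvalsh(s)[-1]
            tmpl = np.linalg.eigh(s)[1][:, -1]
            corr = unit[assign == c] @ tmpl
            num += np.sum(w2[assign == c] * corr ** 2)
        best = max(best, num / w2.sum())
    return best


class TestModifiedKMeans:
    def test_two_orthogonal_templates_recovered(self, rng):
        t1 = unit_gfp(rng.normal(size=(1, 16)))[0]
        t2 = rng.normal(size=16)
        t2 = t2 - t2.mean() - t1 * (t1 @ t2) / (t1 @ t1)
        t2 = unit_gfp(t2[None, :])[0]
        signs = rng.choice([-1, 1], size=40)
        maps = np.vstack([signs[i] * (t1 if i % 2 else t2)
                          for i in range(40)])
        out = ms.modified_kmeans(maps, k=2, n_restarts=10, seed=0)
        corr = np.abs((out.maps / np.linalg.norm(out.maps, axis=1,
                                                 keepdims=True))
                      @ np.vstack([t1, t2]).T
                      / np.linalg.norm(t1))
        assert out.gev_total == pytest.approx(1.0)
        # each true template matched by exactly one output map
        assert sorted(np.max(corr, axis=0).round(6)) == [1.0, 1.0]

    def test_k_equals_n_gev_one(self, rng):
        maps = rng.normal(size=(4, 12))
        out = ms.modified_kmeans(maps, k=4, n_restarts=5, seed=1)
        assert out.gev_total == pytest.approx(1.0)

    def test_matches_exhaustive_partition_optimum(self, rng):
        """Best-of-restarts GEV equals the brute-force optimum (n=6, k=2)."""
        maps = rng.normal(size=(6, 8))
        out = ms.modified_kmeans(maps, k=2, n_restarts=30, seed=2)
        want = brute_force_gev(maps, 2)
        assert out.gev_total == pytest.approx(want, abs=1e-9)

    def test_polarity_invariance(self, rng):
        maps = rng.normal(size=(30, 16))
        flip = rng.choice([-1.0, 1.0], size=30)
        a = ms.modified_kmeans(maps, k=3, n_restarts=10, seed=3)
        b = ms.modified_kmeans(maps * flip[:, None], k=3, n_restarts=10,
                               seed=3)
        assert a.gev_total == pytest.approx(b.gev_total, abs=1e-9)

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            ms.modified_kmeans(rng.normal(size=(3, 8)), k=4)

    def test_maps_unit_gfp(self, rng):
        out = ms.modified_kmeans(rng.normal(size=(30, 10)), k=3,
                                 n_restarts=5, seed=0)
        np.testing.assert_allclose(out.maps.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(out.maps.std(axis=1), 1, atol=1e-10)

    def test_gev_nondecreasing_in_k(self, rng):
        maps = rng.normal(size=(60, 12))
        gev = [ms.modified_kmeans(maps, k=k, n_restarts=10,
                                  seed=4).gev_total for k in (2, 3, 4, 5)]
        assert all(b >= a - 1e-9 for a, b in zip(gev, gev[1:]))


class TestSelectK:
    def test_two_template_data_selects_two(self, rng):
        t = unit_gfp(rng.normal(size=(2, 16)))
        maps = np.vstack([t[i % 2] * rng.choice([-1, 1])
                          for i in range(60)])
        k_star, crit = ms.select_k_cv(maps, range(2, 6), n_restarts=10,
                                      seed=0)
        assert k_star == 2

    def test_single_k_range(self, rng):
        maps = rng.normal(size=(30, 12))
        k_star, crit = ms.select_k_cv(maps, [2], n_restarts=5, seed=0)
        assert k_star == 2 and set(crit) == {2}

    def test_channel_bound(self, rng):
        with pytest.raises(ValueError):
            ms.select_k_cv(rng.normal(size=(30, 8)), range(2, 9))


class TestSortTemplates:
    def test_aligned_identity(self, canonical32):
        maps, _ = canonical32
        ref = ms.MicrostateTemplateSet(maps=maps, labels=list("ABCD"))
        out = ms.sort_templates(ref, ref)
        np.testing.assert_allclose(out.maps, ref.maps)
        assert out.labels == list("ABCD")

    def test_recovers_inverse_permutation(self, canonical32):
        maps, _ = canonical32
        perm = [2, 0, 3, 1]
        shuffled = ms.MicrostateTemplateSet(maps=maps[perm],
                                            labels=list("WXYZ"))
        ref = ms.MicrostateTemplateSet(maps=maps, labels=list("ABCD"))
        out = ms.sort_templates(shuffled, ref)
        np.testing.assert_allclose(out.maps, maps, atol=1e-12)

    def test_matches_hungarian_oracle(self, rng):
        from scipy.optimize import linear_sum_assignment
        a = unit_gfp(rng.normal(size=(4, 20)))
        b = unit_gfp(rng.normal(size=(4, 20)))
        tset = ms.MicrostateTemplateSet(maps=a, labels=list("WXYZ"))
        ref = ms.MicrostateTemplateSet(maps=b, labels=list("ABCD"))
        out = ms.sort_templates(tset, ref)
        an = a / np.linalg.norm(a, axis=1, keepdims=True)
        bn = b / np.linalg.norm(b, axis=1, keepdims=True)
        cost = -np.abs(an @ bn.T)
        rows, cols = linear_sum_assignment(cost)
        # oracle: total |corr| of the optimal assignment
        want = -cost[rows, cols].sum()
        got = sum(abs(np.corrcoef(out.maps[j], b[j])[0, 1])
                  for j in range(4))
        assert got == pytest.approx(want, abs=1e-9)

    def test_sign_flipped_positive(self, canonical32):
        maps, _ = canonical32
        ref = ms.MicrostateTemplateSet(maps=maps, labels=list("ABCD"))
        neg = ms.MicrostateTemplateSet(maps=-maps, labels=list("ABCD"))
        out = ms.sort_templates(neg, ref)
        for j in range(4):
            assert np.corrcoef(out.maps[j], maps[j])[0, 1] > 0

    def test_large_k_guard(self, rng):
        maps = unit_gfp(rng.normal(size=(7, 20)))
        t = ms.MicrostateTemplateSet(maps=maps, labels=list("ABCDEFG"))
        with pytest.raises(ValueError):
            ms.sort_templates(t, t)


class TestGroupTemplates:
    def test_identical_subjects(self, canonical32):
        maps, _ = canonical32
        sets = [ms.MicrostateTemplateSet(maps=maps, labels=list("ABCD"))
                for _ in range(5)]
        out = ms.build_group_templates(sets, k=4, n_restarts=10, seed=0)
        ref = ms.MicrostateTemplateSet(maps=maps, labels=list("ABCD"))
        sorted_out = ms.sort_templates(out, ref)
        for j in range(4):
            assert abs(np.corrcoef(sorted_out.maps[j],
                                   maps[j])[0, 1]) > 0.999
        assert out.gev_total == pytest.approx(1.0)

    def test_mixed_channel_counts_rejected(self, rng):
        a = ms.MicrostateTemplateSet(maps=unit_gfp(rng.normal(size=(4, 16))),
                                     labels=list("ABCD"))
        b = ms.MicrostateTemplateSet(maps=unit_gfp(rng.normal(size=(4, 8))),
                                     labels=list("ABCD"))
        with pytest.raises(ValueError):
            ms.build_group_templates([a, b])


# ---------------------------------------------------------------------------
# back-fitting and metrics
# ---------------------------------------------------------------------------

class TestBackfit:
    def test_pure_template_single_segment(self, canonical32):
        maps, _ = canonical32
        data = np.outer(maps[0], np.sin(np.linspace(0.3, 60, 1000)))
        rec = make_rec(data)
        tset = ms.MicrostateTemplateSet(maps=maps, labels=list("ABCD"))
        seg = ms.backfit(rec, tset)
        met = ms.compute_microstate_metrics(seg, ms.compute_gfp(rec))
        assert len(seg.segments) == 1
        assert met.coverage[0] == pytest.approx(1.0)

    def test_short_middle_segment_absorbed(self, canonical32):
        """A(100 ms) B(10 ms) A(100 ms) at 500 Hz collapses to a single A
        segment of 210 ms; nothing under 30 ms survives."""
        maps, _ = canonical32
        fs = 500.0
        lab = np.array([0] * 50 + [1] * 5 + [0] * 50)
        carrier = np.sin(2 * np.pi * 10 * np.arange(len(lab)) / fs + 0.7)
        data = maps[lab].T * carrier
        seg = ms.backfit(make_rec(data, fs),
                         ms.MicrostateTemplateSet(maps=maps,
                                                  labels=list("ABCD")))
        assert len(seg.segments) == 1
        assert seg.segments[0] == (0, 0, 105)
        min_len = int(round(30 * fs / 1000))
        assert all(s[2] >= min_len for s in seg.segments)

    def test_zero_threshold_is_identity(self, canonical32, rng):
        maps, _ = canonical32
        data = rng.normal(size=(32, 400))
        rec = make_rec(data)
        tset = ms.MicrostateTemplateSet(maps=maps, labels=list("ABCD"))
        raw = ms.backfit(rec, tset, min_duration_ms=0)
        # raw labels = plain argmax of |corr|
        v = data - data.mean(axis=0)
        un = v / np.linalg.norm(v, axis=0)
        tn = maps / np.linalg.norm(maps, axis=1, keepdims=True)
        assert np.array_equal(raw.labels, np.argmax(np.abs(tn @ un), axis=0))

    def test_consecutive_segments_distinct(self, canonical32, rng):
        maps, _ = canonical32
        rec = make_rec(rng.normal(size=(32, 2000)))
        seg = ms.backfit(rec, ms.MicrostateTemplateSet(maps=maps,
                                                       labels=list("ABCD")))
        states = [s for s, _, _ in seg.segments]
        assert all(a != b for a, b in zip(states, states[1:]))
        min_len = int(round(30 * rec.fs / 1000))
        assert all(ln >= min_len for _, _, ln in seg.segments)

    def test_channel_mismatch(self, canonical32, rng):
        maps, _ = canonical32
        with pytest.raises(ValueError):
            ms.backfit(make_rec(rng.normal(size=(16, 100))),
                       ms.MicrostateTemplateSet(maps=maps,
                                                labels=list("ABCD")))


class TestMetrics:
    def _seg_from_labels(self, labels, fs, k=4):
        labels = np.asarray(labels)
        corr = np.ones(len(labels))
        runs = ms._runs(labels)
        return ms.MicrostateSegmentation(labels=labels, segments=runs,
                                         fs=fs, corr=corr, k=k)

    def test_single_two_second_segment(self):
        seg = self._seg_from_labels(np.zeros(1000, int), fs=500.0)
        gfp = ms.GFPSeries(values=np.ones(1000), fs=500.0)
        met = ms.compute_microstate_metrics(seg, gfp)
        assert met.coverage[0] == pytest.approx(1.0)
        assert met.occurrence[0] == pytest.approx(0.5)
        assert met.duration[0] == pytest.approx(2000.0)

    def test_strict_alternation(self):
        lab = np.tile(np.r_[np.zeros(50, int), np.ones(50, int)], 50)
        seg = self._seg_from_labels(lab, fs=500.0)
        gfp = ms.GFPSeries(values=np.ones(len(lab)), fs=500.0)
        met = ms.compute_microstate_metrics(seg, gfp)
        assert met.coverage[0] == pytest.approx(0.5)
        assert met.occurrence[0] == pytest.approx(5.0)
        assert met.duration[0] == pytest.approx(100.0)
        assert met.transition_matrix[0, 1] == pytest.approx(1.0)
        assert met.transition_matrix[1, 0] == pytest.approx(1.0)

    def test_segment_chain_transition_recovery(self, rng):
        """Empirical transition matrix within 0.03 of the generating
        segment-level chain (20000 segments)."""
        p = np.array([[0, .5, .3, .2], [.1, 0, .6, .3],
                      [.25, .25, 0, .5], [.4, .2, .4, 0]])
        cum = p.cumsum(axis=1)
        states = [0]
        u = rng.uniform(size=20000)
        for i in range(19999):
            states.append(int(np.searchsorted(cum[states[-1]], u[i])))
        lab = np.repeat(states, 3)
        seg = self._seg_from_labels(lab, fs=500.0)
        met = ms.compute_microstate_metrics(
            seg, ms.GFPSeries(values=np.ones(len(lab)), fs=500.0))
        assert np.abs(met.transition_matrix - p).max() < 0.03 + 1e-9

    @given(st.lists(st.integers(0, 3), min_size=10, max_size=300),
           st.sampled_from([100.0, 250.0, 500.0]))
    @settings(max_examples=40, deadline=None)
    def test_identity_coverage_occurrence_duration(self, labels, fs):
        """coverage == occurrence (1/s) * duration (s) exactly, per state,
        and coverages sum to 1."""
        seg = self._seg_from_labels(labels, fs=fs)
        gfp = ms.GFPSeries(values=np.ones(len(labels)), fs=fs)
        met = ms.compute_microstate_metrics(seg, gfp)
        assert met.coverage.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(
            met.coverage, met.occurrence * met.duration / 1000.0,
            atol=1e-12)
        occupied = met.occurrence > 0
        states = [s for s, _, _ in seg.segments]
        for s in np.flatnonzero(occupied):
            if any(a == s for a in states[:-1]):
                assert met.transition_matrix[s].sum() == pytest.approx(1.0)

    def test_empty_segmentation_rejected(self):
        seg = ms.MicrostateSegmentation(labels=np.array([], dtype=int),
                                        segments=[], fs=500.0,
                                        corr=np.array([]), k=4)
        with pytest.raises(ValueError):
            ms.compute_microstate_metrics(
                seg, ms.GFPSeries(values=np.array([]), fs=500.0))
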