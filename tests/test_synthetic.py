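"""Generator contracts: canonical maps, semi-Markov EEG, CAP BOLD, cohort."""

import numpy as np
import pytest

from neurostate import microstates as ms
from neurostate import synthetic as syn
from neurostate import group_stats as gs


class TestCanonicalTemplates:
    def test_average_referenced_unit_gfp(self):
        for n_ch in (8, 16, 32, 64):
            maps, _ = syn.make_canonical_templates(n_ch)
            np.testing.assert_allclose(maps.mean(axis=1), 0, atol=1e-12)
            np.testing.assert_allclose(maps.std(axis=1), 1, atol=1e-12)

    def test_pairwise_correlation_below_09(self):
        maps, _ = syn.make_canonical_templates(32)
        corr = np.corrcoef(maps)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.9)

    def test_map_b_is_left_right_flip_of_a(self):
        """B equals A evaluated on the x-mirrored layout (flip oracle)."""
        maps, pos = syn.make_canonical_templates(32)
        flipped = pos * np.array([-1.0, 1.0])
        # mirror partner of each channel on the symmetric layout
        idx = [int(np.argmin(np.sum((pos - f) ** 2, axis=1)))
               for f in flipped]
        a_flipped = maps[0][idx]
        assert np.corrcoef(maps[1], a_flipped)[0, 1] > 0.98

    def test_too_few_channels(self):
        with pytest.raises(ValueError):
            syn.make_canonical_templates(4)


class TestSemiMarkovEEG:
    def test_determinism(self, canonical32):
        maps, _ = canonical32
        p = syn.EEGSimParams(duration_s=5)
        chain = syn.uniform_segment_chain(4)
        r1, t1 = syn.simulate_eeg_subject(p, maps, chain, seed=11)
        r2, t2 = syn.simulate_eeg_subject(p, maps, chain, seed=11)
        assert np.array_equal(r1.data, r2.data)
        assert np.array_equal(t1.labels, t2.labels)

    def test_high_snr_backfit_recovers_labels(self, canonical32):
        """At +60 dB the true-template back-fit matches the ground-truth
        sequence on >99% of samples."""
        maps, _ = canonical32
        p = syn.EEGSimParams(duration_s=30, snr_db=60,
                             mean_duration_ms=100)
        rec, truth = syn.simulate_eeg_subject(
            p, maps, syn.uniform_segment_chain(4), seed=1)
        tset = ms.MicrostateTemplateSet(maps=maps, labels=list("ABCD"))
        seg = ms.backfit(rec, tset)
        assert np.mean(seg.labels == truth.labels) > 0.99

    def test_uniform_chain_transition_frequencies(self, canonical32):
        maps, _ = canonical32
        p = syn.EEGSimParams(duration_s=180)
        _, truth = syn.simulate_eeg_subject(
            p, maps, syn.uniform_segment_chain(4), seed=3)
        emp = truth.transition_empirical
        off = emp[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off - 1.0 / 3.0) < 0.05)

    def test_diagonal_chain_rejected(self, canonical32):
        maps, _ = canonical32
        bad = np.full((4, 4), 0.25)
        with pytest.raises(ValueError):
            syn.simulate_eeg_subject(syn.EEGSimParams(duration_s=2),
                                     maps, bad, seed=0)

    def test_band_limited_and_average_referenced(self, canonical32):
        maps, _ = canonical32
        rec, _ = syn.simulate_eeg_subject(
            syn.EEGSimParams(duration_s=10), maps,
            syn.uniform_segment_chain(4), seed=5)
        np.testing.assert_allclose(rec.data.mean(axis=0), 0, atol=1e-9)
        import scipy.signal
        f, psd = scipy.signal.welch(rec.data, fs=rec.fs, nperseg=2048,
                                    axis=-1)
        total = psd.sum()
        inband = psd[:, (f >= 0.5) & (f <= 35)].sum()
        assert inband / total > 0.9


class TestChainConstruction:
    def test_occupancy_targeting(self):
        pi = np.array([0.24, 0.24, 0.2, 0.32])
        p = syn.segment_chain_for_occupancy(pi)
        np.testing.assert_allclose(p.sum(axis=1), 1, atol=1e-9)
        assert np.all(np.diag(p) == 0)
        np.testing.assert_allclose(syn._stationary(p), pi, atol=1e-3)

    def test_boost_keeps_rows_stochastic(self):
        p = syn.uniform_segment_chain(4)
        b = syn.boost_transitions(p, [(0, 3), (1, 3)], 0.05)
        np.testing.assert_allclose(b.sum(axis=1), 1, atol=1e-12)
        assert b[0, 3] == pytest.approx(p[0, 3] + 0.05)
        assert np.all(b >= 0) and np.all(b <= 1)


class TestBOLD:
    def test_noiseless_nearest_centroid_exact(self):
        bp = syn.BOLDSimParams(noise_sd=0.0)
        patterns, _, roi_ids, _ = syn.make_cap_patterns(bp.n_rois)
        chain = syn.markov_chain_for_dwell(14, np.full(14, 4.0))
        table, truth = syn.simulate_bold_subject(bp, patterns, chain,
                                                 roi_ids, seed=2)
        sim = (table.data / np.linalg.norm(table.data, axis=1,
                                           keepdims=True)) @ patterns.T
        assert np.array_equal(np.argmax(sim, axis=1), truth.labels)

    def test_mean_run_length_two_state(self):
        """Empirical mean run length within 20% of the dwell parameter."""
        chain = syn.markov_chain_for_dwell(2, np.full(2, 4.0))
        rng = np.random.default_rng(0)
        labels = syn.markov_labels(rng, chain, 240 * 40)
        change = np.flatnonzero(np.diff(labels)) + 1
        lens = np.diff(np.concatenate([[0], change, [len(labels)]]))
        assert abs(lens.mean() - 4.0) / 4.0 < 0.2

    def test_determinism(self):
        bp = syn.BOLDSimParams()
        patterns, _, roi_ids, _ = syn.make_cap_patterns(bp.n_rois)
        chain = syn.markov_chain_for_dwell(14, np.full(14, 4.0))
        t1, _ = syn.simulate_bold_subject(bp, patterns, chain, roi_ids,
                                          seed=5)
        t2, _ = syn.simulate_bold_subject(bp, patterns, chain, roi_ids,
                                          seed=5)
        assert np.array_equal(t1.data, t2.data)

    def test_dimension_mismatch(self):
        bp = syn.BOLDSimParams(n_rois=100)
        patterns, _, roi_ids, _ = syn.make_cap_patterns(50)
        chain = syn.markov_chain_for_dwell(14, np.full(14, 4.0))
        with pytest.raises(ValueError):
            syn.simulate_bold_subject(bp, patterns, chain, roi_ids, seed=0)


class TestCohort:
    def test_composition_and_invariants(self, small_cohort):
        coh = small_cohort
        assert len(coh.subjects) == 52
        groups = [s.group for s in coh.subjects]
        assert groups.count("responder") == 24
        assert groups.count("nonresponder") == 28
        assert len(coh.clinical.frame) == 104
        # responder reductions beyond the MCID, nonresponders inside it
        wide = coh.clinical.pivot("mds_updrs3_total")
        delta = wide["pre"] - wide["post"]
        for s in coh.subjects:
            if s.group == "responder":
                assert delta[s.subject_id] > syn.MCID
            else:
                assert delta[s.subject_id] <= syn.MCID

    def test_determinism(self):
        kw = dict(seed=3, eeg_params=syn.EEGSimParams(duration_s=5,
                                                      n_channels=16))
        a = syn.simulate_cohort(**kw)
        b = syn.simulate_cohort(**kw)
        assert a.clinical.frame.equals(b.clinical.frame)
        ra = a.eeg_recording("S01", "post")
        rb = b.eeg_recording("S01", "post")
        assert np.array_equal(ra.data, rb.data)
        assert np.array_equal(a.bold_table("S05", "pre").data,
                              b.bold_table("S05", "pre").data)

    def test_responder_occurrence_d_ratio_matches_factor(self):
        """Mean realized post/pre occurrence-D ratio in responders tracks
        the configured factor within 10% (transition boost disabled to
        isolate the factor pathway; averaged over seeds)."""
        ratios = []
        eff = syn.CohortEffects(transition_AB_to_D_boost=0.0)
        for seed in range(3):
            coh = syn.simulate_cohort(
                effects=eff, seed=seed,
                eeg_params=syn.EEGSimParams(duration_s=60, n_channels=16))
            tm = coh.true_metric_frame()
            piv = tm.pivot_table(index=["subject_id", "group"],
                                 columns="timepoint")
            r = piv[("occurrence_D", "post")] / piv[("occurrence_D", "pre")]
            ratios.append(r.xs("responder", level="group").mean())
        mean_ratio = np.mean(ratios)
        assert abs(mean_ratio - eff.occurrence_D_factor) < 0.1 * \
            eff.occurrence_D_factor

    def test_stratification_recovers_generator_labels(self):
        """The MCID rule reproduces the generator's group labels."""
        hits = []
        for seed in range(20):
            coh = syn.simulate_cohort(
                seed=seed,
                eeg_params=syn.EEGSimParams(duration_s=2, n_channels=16),
                bold_params=syn.BOLDSimParams(n_frames=30))
            labeled, _ = gs.stratify_responders(coh.clinical)
            truth = {s.subject_id: s.group for s in coh.subjects}
            got = labeled.frame.groupby("subject_id")["group"].first()
            hits.append(np.mean([truth[k] == v for k, v in got.items()]))
        assert np.mean(hits) >= 0.95

    def test_missing_fmri_subjects(self):
        coh = syn.simulate_cohort(
            seed=0, missing_fmri_subjects=1,
            eeg_params=syn.EEGSimParams(duration_s=2, n_channels=16),
            bold_params=syn.BOLDSimParams(n_frames=30))
        assert sum(s.has_fmri for s in coh.subjects) == 51
        missing = [s for s in coh.subjects if not s.has_fmri][0]
        with pytest.raises(KeyError):
            coh.bold_table(missing.subject_id, "pre")

    def test_infeasible_coupling_rejected(self):
        with pytest.raises(ValueError):
            syn.CohortEffects(coupling_rho_C=1.5)

    def test_coupling_sign_recovery(self):
        """Group-partialled Spearman between clinical reduction rate and
        the injected factors recovers the configured coupling signs."""
        import scipy.stats
        import pandas as pd
        signs = {"occ_C": [], "occ_D": [], "cap_dwell": []}
        expected = {"occ_C": 1, "occ_D": -1, "cap_dwell": -1}
        for seed in range(10):
            coh = syn.simulate_cohort(
                seed=seed,
                eeg_params=syn.EEGSimParams(duration_s=2, n_channels=16),
                bold_params=syn.BOLDSimParams(n_frames=30))
            wide = coh.clinical.pivot("mds_updrs3_total")
            red = pd.Series(gs.reduction_rate(wide["pre"].to_numpy(),
                                              wide["post"].to_numpy()),
                            index=wide.index)
            grp = pd.Series({s.subject_id: s.group for s in coh.subjects})
            for key in signs:
                f = pd.Series({s.subject_id: s.injected[key]
                               for s in coh.subjects})
                rr = red.groupby(grp).rank(pct=True)
                fr = f.groupby(grp).rank(pct=True)
                rho, _ = scipy.stats.spearmanr(rr, fr.reindex(rr.index))
                signs[key].append(np.sign(rho))
        for key, sgn in expected.items():
            assert np.mean(np.array(signs[key]) == sgn) >= 0.9, key
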