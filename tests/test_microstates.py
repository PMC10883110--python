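import itertools
import json

import numpy as np
import pytest

import microdfc as m
from microdfc.microstates import (
    _center_normalize,
    archetype_maps,
    assign_state_names,
    min_segment_samples,
    read_label_sequence,
    read_template_set,
    write_label_sequence,
    write_template_set,
)
from microdfc.montage import CHANNELS_32
from microdfc.signal_core import Recording


def _rec(data, fs=250.0):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return Recording(data=data, fs=fs,
                     channel_labels=[f"CH{i}" for i in range(data.shape[0])])


class TestSpatialCorrelation:
    def test_self_correlation(self):
        mmap = np.random.default_rng(0).standard_normal(32)
        assert m.spatial_correlation(mmap, mmap) == pytest.approx(1.0)

    def test_polarity_invariance(self):
        mmap = np.random.default_rng(1).standard_normal(32)
        assert m.spatial_correlation(mmap, -mmap, ignore_polarity=True) == pytest.approx(1.0)
        assert m.spatial_correlation(mmap, -mmap, ignore_polarity=False) == pytest.approx(-1.0)

    def test_orthogonal_maps(self):
        tset = m.generate_template_maps(2, 32, seed=2)
        assert m.spatial_correlation(tset.maps[0], tset.maps[1]) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            m.spatial_correlation(np.ones(8), np.arange(8.0))


class TestGev:
    def test_hand_case(self):
        assert m.compute_gev([2.0, 1.0], [1.0, 0.5]) == pytest.approx(0.85)

    def test_perfect_and_zero_fit(self):
        g = [1.0, 2.0, 3.0]
        assert m.compute_gev(g, [1.0, 1.0, 1.0]) == pytest.approx(1.0)
        assert m.compute_gev(g, [0.0, 0.0, 0.0]) == pytest.approx(0.0)

    def test_all_zero_gfp_rejected(self):
        with pytest.raises(ValueError):
            m.compute_gev([0.0, 0.0], [1.0, 1.0])

    def test_bounds(self):
        rng = np.random.default_rng(3)
        gev = m.compute_gev(rng.uniform(0, 5, 50), rng.uniform(-1, 1, 50))
        assert 0.0 <= gev <= 1.0


def _separable_items(k, n_ch, per_cluster, seed, noise=0.0):
    tset = m.generate_template_maps(k, n_ch, seed=seed)
    rng = np.random.default_rng(seed + 1)
    items, truth = [], []
    for j in range(k):
        for _ in range(per_cluster):
            sign = rng.choice([-1.0, 1.0])
            gfp = rng.uniform(0.5, 2.0)
            item = sign * gfp * tset.maps[j]
            if noise:
                item = item + noise * rng.standard_normal(n_ch)
            items.append(item)
            truth.append(j)
    return np.asarray(items), np.asarray(truth), tset


class TestModifiedKmeans:
    def test_noiseless_recovery(self):
        items, truth, tset = _separable_items(4, 32, 10, seed=4)
        res = m.modified_kmeans(items, 4, n_restarts=20, seed=0)
        assert res.gev == pytest.approx(1.0, abs=1e-12)
        perm = m.match_templates(tset.maps, res.templates.maps)
        for j in range(4):
            corr = m.spatial_correlation(tset.maps[j], res.templates.maps[perm[j]])
            assert corr > 0.999

    def test_degenerate_k1(self):
        items, _, _ = _separable_items(2, 16, 5, seed=5)
        res = m.modified_kmeans(items, 1, n_restarts=5, seed=0)
        assert set(res.assignments.tolist()) == {0}

    def test_restart_stability_on_separable_input(self):
        items, _, _ = _separable_items(4, 32, 10, seed=6)
        g1 = m.modified_kmeans(items, 4, n_restarts=20, seed=1).gev
        g2 = m.modified_kmeans(items, 4, n_restarts=20, seed=2).gev
        assert g1 == pytest.approx(g2, abs=1e-12)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            m.modified_kmeans(np.ones((2, 8)) * [[1.0], [2.0]], 3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_assignment_oracle(self, seed):
        """On tiny instances the clustering attains the global GEV optimum."""
        rng = np.random.default_rng(seed)
        J, k, n_ch = 8, 3, 6
        items = rng.standard_normal((J, n_ch))
        norm_items, gfp = _center_normalize(items)
        centered = norm_items * (gfp * np.sqrt(n_ch))[:, None]

        best = 0.0
        for assign in itertools.product(range(k), repeat=J):
            corr = np.empty(J)
            ok = True
            for c in range(k):
                members = centered[np.asarray(assign) == c]
                if len(members) == 0:
                    ok = False
                    break
                _, _, vt = np.linalg.svd(members, full_matrices=False)
                corr[np.asarray(assign) == c] = np.abs(norm_items[np.asarray(assign) == c] @ vt[0])
            if ok:
                best = max(best, m.compute_gev(gfp, corr))
        res = m.modified_kmeans(items, k, n_restarts=60, seed=seed)
        assert res.gev >= best - 1e-9

    def test_gev_monotone_in_k(self):
        items, _, _ = _separable_items(5, 32, 12, seed=7, noise=0.3)
        gevs = [m.modified_kmeans(items, k, n_restarts=20, seed=0).gev for k in (4, 5, 6)]
        assert gevs[0] <= gevs[1] + 1e-9 and gevs[1] <= gevs[2] + 1e-9


class TestSelectOptimalK:
    def test_singleton_range(self):
        assert m.select_optimal_k(np.zeros((1, 1)), (4, 4)) == 4

    def test_recovers_k_from_separable_items(self):
        items, _, _ = _separable_items(5, 32, 40, seed=8, noise=0.2)
        assert m.select_optimal_k(items, (4, 6), seed=0) == 5


class TestGroupTemplates:
    def test_identical_individual_sets_reproduced(self):
        tset = m.generate_template_maps(4, 32, seed=9)
        sets = [m.TemplateSet(maps=tset.maps.copy(), channel_labels=list(CHANNELS_32))
                for _ in range(6)]
        res = m.group_templates(sets, (4, 4), seed=0)
        assert res.gev == pytest.approx(1.0, abs=1e-9)
        perm = m.match_templates(tset.maps, res.templates.maps)
        for j in range(4):
            assert m.spatial_correlation(tset.maps[j], res.templates.maps[perm[j]]) > 0.999

    def test_single_subject_close_to_individual(self):
        tset = m.generate_template_maps(4, 32, seed=10)
        res = m.group_templates([tset], (4, 4), seed=0)
        perm = m.match_templates(tset.maps, res.templates.maps)
        for j in range(4):
            assert m.spatial_correlation(tset.maps[j], res.templates.maps[perm[j]]) > 0.999

    def test_channel_mismatch_rejected(self):
        a = m.generate_template_maps(4, 32, seed=0)
        b = m.generate_template_maps(4, 16, seed=0)
        with pytest.raises(ValueError):
            m.group_templates([a, b], (4, 4))


class TestBackfit:
    def test_constant_template_recording(self, truth_templates):
        data = np.outer(truth_templates.maps[2], np.ones(100))
        seq = m.backfit(_rec(data), truth_templates)
        assert (seq.labels == 2).all()
        assert np.allclose(seq.corr, 1.0)

    def test_polarity_invariance(self, noisy_recording, truth_templates):
        _, filt, _ = noisy_recording
        neg = Recording(data=-filt.data, fs=filt.fs, channel_labels=filt.channel_labels)
        a = m.backfit(filt, truth_templates)
        b = m.backfit(neg, truth_templates)
        assert np.array_equal(a.labels, b.labels)

    def test_zero_variance_samples_forward_filled(self, truth_templates):
        data = np.outer(truth_templates.maps[1], np.ones(10))
        data[:, 4] = 0.0
        seq = m.backfit(_rec(data), truth_templates)
        assert (seq.labels == 1).all()
        assert seq.corr[4] == 0.0

    def test_channel_mismatch_rejected(self, truth_templates):
        with pytest.raises(ValueError):
            m.backfit(_rec(np.ones((4, 10))), truth_templates)


class TestSmoothing:
    def test_min_segment_at_250hz_is_5_samples(self):
        assert min_segment_samples(20.0, 250.0) == 5

    def test_short_run_absorbed_by_better_flank(self):
        labels = np.array([0] * 10 + [1] * 3 + [0] * 10)
        corr_all = np.vstack([np.full(23, 0.9), np.full(23, 0.5)])
        seq = m.LabelSequence(labels=labels, corr=corr_all[labels, np.arange(23)],
                              fs=250.0, corr_all=corr_all)
        out = m.smooth_labels(seq)
        assert (out.labels == 0).all()

    def test_long_runs_are_fixed_point(self):
        labels = np.repeat([0, 1, 2], 10)
        corr_all = np.random.default_rng(0).uniform(0.2, 0.9, (3, 30))
        seq = m.LabelSequence(labels=labels, corr=corr_all[labels, np.arange(30)],
                              fs=250.0, corr_all=corr_all)
        out = m.smooth_labels(seq)
        assert np.array_equal(out.labels, labels)

    def test_all_runs_meet_minimum_after_smoothing(self, noisy_recording, truth_templates):
        _, filt, _ = noisy_recording
        out = m.smooth_labels(m.backfit(filt, truth_templates))
        runs = np.diff(np.concatenate(
            ([0], np.flatnonzero(np.diff(out.labels)) + 1, [out.labels.size])
        ))
        assert runs.min() >= 5

    def test_whole_short_sequence_collapses_to_best_state(self):
        labels = np.array([0, 1, 2])
        corr_all = np.array([[0.1, 0.1, 0.1], [0.9, 0.9, 0.9], [0.2, 0.2, 0.2]])
        seq = m.LabelSequence(labels=labels, corr=corr_all[labels, np.arange(3)],
                              fs=250.0, corr_all=corr_all)
        out = m.smooth_labels(seq)
        assert (out.labels == 1).all()

    def test_identity_on_noiseless_data(self, noiseless_recording, truth_templates):
        rec, truth = noiseless_recording
        seq = m.backfit(m.apply_average_reference(rec), truth_templates)
        out = m.smooth_labels(seq)
        assert (out.labels == truth.true_labels).mean() == 1.0


class TestExtractSegments:
    def test_full_recording_for_constant_labels(self, truth_templates):
        data = np.outer(truth_templates.maps[0], np.ones(500))
        rec = _rec(data)
        seq = m.backfit(rec, truth_templates)
        seg, seconds = m.extract_segments(rec, seq, 0)
        assert seg.shape == rec.data.shape
        assert seconds == pytest.approx(2.0)

    def test_state_totals_partition_duration(self, noisy_recording, truth_templates):
        _, filt, _ = noisy_recording
        seq = m.smooth_labels(m.backfit(filt, truth_templates))
        total = sum(m.extract_segments(filt, seq, s)[1] for s in range(5))
        assert total == pytest.approx(filt.duration)

    def test_totals_match_ground_truth_occupancy(self, noiseless_recording, truth_templates):
        rec, truth = noiseless_recording
        seq = m.backfit(m.apply_average_reference(rec), truth_templates)
        for s in range(5):
            _, seconds = m.extract_segments(rec, seq, s)
            assert seconds == pytest.approx((truth.true_labels == s).sum() / rec.fs)

    def test_absent_state_gives_empty(self, truth_templates):
        data = np.outer(truth_templates.maps[0], np.ones(100))
        rec = _rec(data)
        seq = m.backfit(rec, truth_templates)
        seg, seconds = m.extract_segments(rec, seq, 3)
        assert seg.shape[1] == 0 and seconds == 0.0


class TestStateNaming:
    def test_archetypes_name_themselves(self):
        arch = archetype_maps(list(CHANNELS_32))
        maps = np.vstack([arch[n] for n in "ABCDE"])
        tset = m.TemplateSet(maps=maps, channel_labels=list(CHANNELS_32))
        assert assign_state_names(tset) == list("ABCDE")

    def test_unknown_montage_falls_back_to_alphabet(self):
        tset = m.generate_template_maps(4, 16, seed=0)
        tset.channel_labels = [f"X{i}" for i in range(16)]
        assert assign_state_names(tset) == list("ABCD")


class TestSerialization:
    def test_template_round_trip(self, tmp_path, truth_templates):
        path = write_template_set(truth_templates, tmp_path / "templates.tsv")
        back = read_template_set(path)
        assert np.allclose(back.maps, truth_templates.maps, atol=1e-8)
        assert back.state_names == truth_templates.state_names

    def test_label_csv_per_sample(self, tmp_path):
        from microdfc.microstates import write_label_sequence_csv

        seq = m.LabelSequence(labels=np.array([0, 2]), corr=np.array([0.9, 0.5]),
                              fs=250.0)
        path = write_label_sequence_csv(seq, tmp_path / "labels.csv")
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "sample,state,state_name,corr"
        assert lines[1].startswith("0,0,A,") and lines[2].startswith("1,2,C,")

    def test_label_sequence_round_trip(self, tmp_path):
        labels = np.repeat([0, 2, 1, 2], [7, 9, 5, 11])
        seq = m.LabelSequence(labels=labels, corr=np.zeros(labels.size), fs=250.0)
        path = write_label_sequence(seq, tmp_path / "labels.json")
        back = read_label_sequence(path)
        assert np.array_equal(back.labels, labels)
        assert back.fs == 250.0
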