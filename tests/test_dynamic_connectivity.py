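import logging
import math

import numpy as np
import pytest

import microdfc as m
from microdfc.dynamic_connectivity import quantile_bin


class TestWindowing:
    # total time lengths (seconds) per microstate and the window counts
    # they must produce at a 30-s window
    TTL_CASES = [
        (857.53, 28), (1184.66, 39), (1372.45, 45), (401.95, 13), (983.41, 32),
        (1119.45, 37), (1018.68, 33), (1169.65, 38), (315.02, 10),
    ]

    @pytest.mark.parametrize("ttl,expected", TTL_CASES)
    def test_reported_window_counts(self, ttl, expected):
        fs = 250.0
        data = np.zeros((1, int(round(ttl * fs))))
        ws = m.window_signal(data, fs, 30.0)
        assert ws.n_windows == expected

    def test_inconsistent_reported_row(self):
        # one published TTL/count row is internally inconsistent: a total
        # of 1117.20 s yields floor(1117.20 / 30) = 37 windows, not the
        # printed 39 (which corresponds to a total of 1177.20 s — most
        # likely a digit transposition). The windowing stays faithful to
        # its definition rather than to the misprint.
        ws = m.window_signal(np.zeros((1, int(round(1117.20 * 250)))), 250.0, 30.0)
        assert ws.n_windows == 37
        ws = m.window_signal(np.zeros((1, int(round(1177.20 * 250)))), 250.0, 30.0)
        assert ws.n_windows == 39

    def test_below_one_window(self):
        ws = m.window_signal(np.zeros((2, int(29.9 * 250))), 250.0, 30.0)
        assert ws.n_windows == 0

    def test_partition_conserves_samples(self):
        rng = np.random.default_rng(0)
        total = 17_321
        ws = m.window_signal(rng.standard_normal((3, total)), 250.0, 4.0)
        w = ws.window_samples
        assert w == 1000
        assert all(win.shape == (3, w) for win in ws.windows)
        assert ws.n_windows * w + total % w == total
        assert total % w < w


class TestEstimateMi:
    def test_identity_equals_discrete_entropy(self):
        # with b equiprobable bins, I(x;x) is ln(b) plus the exact
        # Miller-Madow correction (b-1)/(2n)
        n, b = 30_000, 8
        x = np.random.default_rng(0).standard_normal(n)
        expected = math.log(b) + (b - 1) / (2 * n)
        assert m.estimate_mi(x, x) == pytest.approx(expected, abs=1e-9)

    def test_independence_null_small(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x, y = rng.uniform(size=30_000), rng.uniform(size=30_000)
            assert m.estimate_mi(x, y) < 0.02

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(5000), rng.standard_normal(5000)
        assert m.estimate_mi(x, y) == pytest.approx(m.estimate_mi(y, x))

    def test_monotone_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(5000)
        y = x + rng.standard_normal(5000)
        assert m.estimate_mi(2 * x + 5, y) == pytest.approx(m.estimate_mi(x, y), abs=1e-12)

    def test_constant_input_zero_with_warning(self, caplog):
        x = np.ones(500)
        y = np.random.default_rng(3).standard_normal(500)
        with caplog.at_level(logging.WARNING, logger="microdfc"):
            assert m.estimate_mi(x, y) == 0.0
        assert "constant" in caplog.text

    def test_length_contract(self):
        with pytest.raises(ValueError):
            m.estimate_mi(np.ones(50), np.ones(50))
        with pytest.raises(ValueError):
            m.estimate_mi(np.ones(200), np.ones(300))

    def test_bits_conversion(self):
        x = np.random.default_rng(4).standard_normal(10_000)
        nats = m.estimate_mi(x, x)
        bits = m.estimate_mi(x, x, m.MIEstimatorConfig(units="bits"))
        assert bits == pytest.approx(nats / math.log(2))

    def test_knn_gaussian_closed_form(self):
        rho, n = 0.9, 20_000
        rng = np.random.default_rng(5)
        xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        est = m.estimate_mi(xy[:, 0], xy[:, 1], m.MIEstimatorConfig(method="knn"))
        assert est == pytest.approx(-0.5 * math.log(1 - rho**2), abs=0.05)

    def test_shuffling_destroys_information(self):
        # data-processing sanity: the permutation null sits near zero
        rng = np.random.default_rng(6)
        x = rng.standard_normal(7500)
        y = x + 0.5 * rng.standard_normal(7500)
        coupled = m.estimate_mi(x, y)
        nulls = [
            m.estimate_mi(x, np.random.default_rng(s).permutation(y))
            for s in range(10)
        ]
        assert coupled > max(nulls)
        assert np.mean(nulls) < 0.02


class TestConnectivityMatrix:
    def test_pair_count_for_32_channels(self):
        rng = np.random.default_rng(0)
        mat = m.connectivity_matrix(rng.standard_normal((32, 600)))
        vec, pairs = m.vectorize_upper_triangle(mat)
        assert vec.size == 496 and len(pairs) == 496

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(1)
        mat = m.connectivity_matrix(rng.standard_normal((6, 500)))
        assert np.array_equal(mat, mat.T)
        assert np.all(np.diag(mat) == 0.0)

    def test_duplicate_channels_reach_entropy(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(2000)
        window = np.vstack([x, x, rng.standard_normal(2000)])
        mat = m.connectivity_matrix(window)
        expected = math.log(8) + 7 / (2 * 2000)
        assert mat[0, 1] == pytest.approx(expected, abs=1e-9)

    def test_planted_pair_exceeds_median(self, truth_templates):
        pair = tuple(sorted(np.argsort(-np.abs(truth_templates.maps[0]))[:2].tolist()))
        cfg = m.SyntheticConfig(
            duration=60.0, coupling=[m.Coupling(0, pair, "MCS", 0.8)], seed=0
        )
        rec, truth = m.generate_subject_recording(truth_templates, cfg, "MCS", seed=1)
        rec = m.bandpass_filter(m.apply_average_reference(rec), 2.0, 20.0)
        window = rec.data[:, truth.true_labels == 0][:, :2000]
        mat = m.connectivity_matrix(window)
        iu = np.triu_indices(32, 1)
        assert mat[pair] > np.median(mat[iu])


class TestGroupDifference:
    def _stack(self, seed, n=4, state=0, group="MCS"):
        mats = np.random.default_rng(seed).uniform(0, 1, (n, 5, 5))
        mats = (mats + mats.transpose(0, 2, 1)) / 2
        for mat in mats:
            np.fill_diagonal(mat, 0.0)
        return m.MIMatrixStack(matrices=mats, state=state, group=group)

    def test_identical_stacks_zero(self):
        a = self._stack(0)
        assert np.allclose(m.group_average_difference(a, a), 0.0)

    def test_antisymmetry_under_swap(self):
        a, b = self._stack(1), self._stack(2)
        assert np.allclose(
            m.group_average_difference(a, b), -m.group_average_difference(b, a)
        )

    def test_empty_stack_rejected(self):
        a = self._stack(3)
        empty = m.MIMatrixStack(matrices=np.zeros((0, 5, 5)), state=0)
        with pytest.raises(ValueError):
            m.group_average_difference(a, empty)

    def test_state_mismatch_rejected(self):
        with pytest.raises(ValueError):
            m.group_average_difference(self._stack(4, state=0), self._stack(5, state=1))


def test_quantile_bins_are_equiprobable():
    v = np.random.default_rng(0).standard_normal(8000)
    codes = quantile_bin(v, 8)
    counts = np.bincount(codes, minlength=8)
    assert counts.min() == counts.max() == 1000


def test_stack_serialization(tmp_path):
    mats = np.random.default_rng(0).uniform(0, 1, (3, 4, 4))
    mats = (mats + mats.transpose(0, 2, 1)) / 2
    stack = m.MIMatrixStack(matrices=mats, state=2, group="VS",
                            subject_ids=["a", "b", "c"])
    from microdfc.dynamic_connectivity import write_stack
    out = write_stack(stack, tmp_path / "stack")
    assert (out / "stack.json").exists()
    back = np.loadtxt(out / "window0000.csv", delimiter=",", skiprows=1)
    assert np.allclose(back, mats[0], atol=1e-8)
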