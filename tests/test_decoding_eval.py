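"""Synthetic tuned populations, error injection, preprocessing and decoding."""

import numpy as np
import pytest
from scipy import stats

from asbit.decoding_eval import (SpikeRaster, compare_conditions,
                                 corrupt_at_ser, fisher_z,
                                 generate_tuned_population, generate_velocity,
                                 preprocess, train_eval, transmit_through_asbit)


@pytest.fixture(scope="module")
def population():
    rng = np.random.default_rng(0)
    raster, velocity, pop = generate_tuned_population(
        n_neurons=120, mean_rate_hz=9.2, duration_s=20.0, rng=rng)
    return raster, velocity, pop


class TestGenerator:
    def test_population_statistics(self, population):
        raster, velocity, pop = population
        # mean rate within 5% of the 9.2 Hz motor-cortex reference
        assert abs(raster.mean_rate() - 9.2) / 9.2 < 0.05
        expect = 120 * 9.2 * 20.0
        assert abs(raster.n_spikes - expect) < 4 * np.sqrt(expect) + 0.05 * expect

    def test_deterministic_given_seed(self):
        a, va, _ = generate_tuned_population(n_neurons=10, duration_s=2.0, rng=7)
        b, vb, _ = generate_tuned_population(n_neurons=10, duration_s=2.0, rng=7)
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(va, vb)

    def test_velocity_band_limited_and_normalized(self):
        v = generate_velocity(10.0, 3)
        assert abs(v.mean()) < 1e-9
        assert v.std() == pytest.approx(1.0)
        power = np.abs(np.fft.rfft(v)) ** 2
        freqs = np.fft.rfftfreq(len(v), 1e-3)
        # finite-window leakage aside, the power concentrates below 2.5 Hz
        assert power[freqs <= 2.5].sum() > 0.95 * power.sum()

    def test_saturating_rate_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            generate_tuned_population(n_neurons=5, mean_rate_hz=1200.0,
                                      duration_s=1.0, rng=0)

    def test_untuned_population_decodes_nothing(self):
        raster, velocity, _ = generate_tuned_population(
            n_neurons=60, duration_s=12.0, modulation=0.0, rng=11)
        X, y = preprocess(raster, velocity)
        scores = train_eval(X, y)
        assert abs(np.mean([s.r for s in scores])) < 0.15


class TestCorruption:
    def test_zero_ser_identity(self, population):
        raster = population[0]
        out, realized = corrupt_at_ser(raster, 0.0, rng=1)
        np.testing.assert_array_equal(out.data, raster.data)
        assert realized == 0.0

    def test_miss_only_expectation(self, population):
        raster = population[0]
        n = raster.n_spikes
        out, realized = corrupt_at_ser(raster, 1e-3, rng=2, miss_fraction=1.0)
        deleted = n - out.n_spikes
        assert abs(deleted - 1e-3 * n) < 4 * np.sqrt(1e-3 * n) + 1
        assert realized == pytest.approx(deleted / n)

    def test_false_insertion_count(self, population):
        raster = population[0]
        out, realized = corrupt_at_ser(raster, 1e-2, rng=3, miss_fraction=0.0)
        inserted = out.n_spikes - raster.n_spikes
        lam = 1e-2 * raster.n_spikes
        assert abs(inserted - lam) < 5 * np.sqrt(lam)

    def test_invalid_ser_rejected(self, population):
        with pytest.raises(ValueError):
            corrupt_at_ser(population[0], 1.5)


class TestPreprocess:
    def test_window_binning_shape(self, population):
        raster, velocity, _ = population
        X, y = preprocess(raster, velocity)
        assert X.shape[1] == raster.n_channels * 26  # 650 ms / 25 ms bins
        assert len(X) == len(y)

    def test_count_conservation_at_zero_jitter(self, population):
        """With no jitter the binned window counts reproduce the raw spike
        counts in each window exactly."""
        raster, velocity, _ = population
        X, _ = preprocess(raster, velocity)
        raw = raster.data[:, 0:650].sum()
        assert X[0].sum() == raw

    def test_jitter_moves_only_boundary_spills(self, population):
        raster, velocity, _ = population
        X0, _ = preprocess(raster, velocity)
        Xj, _ = preprocess(raster, velocity, jitter_ms=25, rng=5)
        # totals differ only by spikes jittered across window edges
        edge_budget = raster.data[:, :25].sum() + raster.data[:, -25:].sum() \
            + 2 * 25 * raster.n_channels
        assert abs(Xj.sum() - X0.sum()) <= edge_budget

    def test_mean_subtracted_targets(self, population):
        raster, velocity, _ = population
        _, y = preprocess(raster, velocity)
        assert abs(y.mean()) < 1e-9

    def test_short_raster_rejected(self):
        r = SpikeRaster(np.zeros((3, 100), dtype=np.uint8))
        with pytest.raises(ValueError, match="shorter"):
            preprocess(r, np.zeros(100))


class TestDecoding:
    def test_linear_targets_are_realizable(self, rng):
        X = rng.standard_normal((400, 30))
        w = rng.standard_normal(30)
        y = X @ w
        scores = train_eval(X, y)
        assert np.mean([s.r for s in scores]) > 0.99

    def test_shuffled_targets_score_zero(self, rng):
        X = rng.standard_normal((400, 30))
        y = rng.permutation(X @ rng.standard_normal(30))
        scores = train_eval(X, y)
        assert abs(np.mean([s.r for s in scores])) < 0.2

    def test_strong_tuning_exceeds_r08(self, population):
        """Acceptance surface: the reference decoder reaches r > 0.8 on
        held-out folds of an uncorrupted, strongly tuned population."""
        raster, velocity, _ = population
        X, y = preprocess(raster, velocity)
        scores = train_eval(X, y)
        assert np.mean([s.r for s in scores]) > 0.8

    def test_r_non_increasing_in_ser(self, population):
        """Mean held-out r does not increase along the SER grid (paired
        corruptions of one base raster, five seeds)."""
        raster, velocity, _ = population
        grid = [0.0, 1e-4, 1e-3, 1e-2]
        means = []
        for ser in grid:
            rs = []
            for seed in range(5):
                c, _ = corrupt_at_ser(raster, ser, rng=seed)
                X, y = preprocess(c, velocity)
                rs.extend(s.r for s in train_eval(X, y))
            means.append(np.mean(rs))
        for lo, hi in zip(means[1:], means[:-1]):
            assert lo <= hi + 2e-3  # Monte-Carlo allowance

    def test_ratio_to_clean_near_one_at_tiny_ser(self, population):
        raster, velocity, _ = population
        X, y = preprocess(raster, velocity)
        clean = train_eval(X, y, condition="clean")
        c, _ = corrupt_at_ser(raster, 1e-5, rng=1)
        Xc, yc = preprocess(c, velocity)
        noisy = train_eval(Xc, yc, condition="ser")
        assert compare_conditions(clean, noisy)["ratio"] > 0.98

    def test_incompatible_folds_rejected(self, rng):
        X = rng.standard_normal((4, 3))
        with pytest.raises(ValueError, match="fold"):
            train_eval(X, np.zeros(4), n_folds=10)


class TestStatistics:
    def test_fisher_z_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.9324) == pytest.approx(np.arctanh(0.9324))
        with pytest.raises(ValueError):
            fisher_z(1.0)

    def test_identical_conditions(self):
        scores = train_eval(np.eye(10), np.arange(10.0), n_folds=5)
        out = compare_conditions(scores, scores)
        assert out["mean_dz"] == 0.0 and out["p"] == 1.0

    def test_paired_t_matches_scipy(self, rng):
        from asbit.decoding_eval import DecodeScore
        ra = np.clip(rng.uniform(0.3, 0.9, 10), None, 0.99)
        rb = np.clip(ra + rng.normal(0.05, 0.02, 10), None, 0.99)
        sa = [DecodeScore(i, r) for i, r in enumerate(ra)]
        sb = [DecodeScore(i, r) for i, r in enumerate(rb)]
        out = compare_conditions(sa, sb)
        t_ref, p_ref = stats.ttest_rel(np.arctanh(rb), np.arctanh(ra))
        assert out["t"] == pytest.approx(t_ref)
        assert out["p"] == pytest.approx(p_ref)


class TestRasterIo:
    def test_raster_roundtrip(self, tmp_path, population):
        from asbit.decoding_eval import read_raster, write_raster
        raster = population[0]
        path = tmp_path / "raster.csv"
        write_raster(path, raster)
        back = read_raster(path, n_channels=raster.n_channels,
                           n_bins=raster.n_bins)
        np.testing.assert_array_equal(back.data, raster.data)

    def test_velocity_roundtrip(self, tmp_path, population):
        from asbit.decoding_eval import read_velocity, write_velocity
        vel = population[1]
        path = tmp_path / "vel.csv"
        write_velocity(path, vel)
        np.testing.assert_allclose(read_velocity(path), vel)


class TestPhysicalTransmission:
    def test_lossless_at_high_snr(self):
        """Physical mode, strong signal, no background: realized SER 0."""
        rng = np.random.default_rng(6)
        raster, _, _ = generate_tuned_population(n_neurons=8, mean_rate_hz=9.2,
                                                 duration_s=0.8, rng=rng)
        recovered, ser = transmit_through_asbit(raster, snr_db=30.0,
                                                clock_mode="divider", seed=1)
        assert ser == 0.0
        np.testing.assert_array_equal(recovered.data, raster.data)
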