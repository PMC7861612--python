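import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vrspatial import (SimConfig, compute_profile, compute_profiles,
                       gaussian_smooth, predict_trace, reliability_all,
                       simulate_session, smi_for_session)
from vrspatial.profiles import (ReliabilityResult, profiles_from_samples,
                                position_bins, kept_mask, resolve_trials,
                                smoothed_activity)

from conftest import make_bundle, corridor_traversals, profile_oracle, \
    random_session, smooth_oracle


class TestGaussianSmooth:
    def test_constant_preserved_exactly(self):
        out = gaussian_smooth(np.full(50, 3.7), sigma=4.0)
        np.testing.assert_allclose(out, 3.7, atol=1e-12)

    def test_central_impulse_sums_to_one(self):
        x = np.zeros(101)
        x[50] = 1.0
        assert abs(gaussian_smooth(x, sigma=5.0).sum() - 1.0) < 1e-12

    def test_impulse_at_edge_matches_half_kernel_arithmetic(self):
        sigma = 3.0
        x = np.zeros(40)
        x[0] = 1.0
        out = gaussian_smooth(x, sigma)
        radius = int(np.ceil(3 * sigma))
        lags = np.arange(0, radius + 1)
        w = np.exp(-0.5 * (lags / sigma) ** 2)
        assert abs(out[0] - w[0] / w.sum()) < 1e-12

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(1.0, 80)
        np.testing.assert_allclose(gaussian_smooth(x, 2.5),
                                   smooth_oracle(x, 2.5), atol=1e-10)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.empty(0), 1.0)


class TestComputeProfile:
    def test_constant_rate_gives_flat_profile(self):
        pos, spd, tid = corridor_traversals(4)
        b = make_bundle(pos, spd, tid, [np.full(pos.size, 2.5)])
        prof = compute_profile(b, 0, "all")
        occupied = np.isfinite(prof.values)
        np.testing.assert_allclose(prof.values[occupied], 2.5, atol=1e-9)

    def test_matches_loop_oracle_on_small_session(self):
        b = random_session(np.random.default_rng(123))
        trials = resolve_trials(b, "all")
        for u in range(b.n_units):
            prof = compute_profile(b, u, "all")
            expected, _, _ = profile_oracle(b, u, set(trials.tolist()))
            np.testing.assert_allclose(prof.values, expected, atol=1e-10)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_oracle_equivalence_property(self, seed):
        """Profiles equal the brute-force oracle on random small sessions."""
        b = random_session(np.random.default_rng(seed), n_units=1)
        trials = resolve_trials(b, "all")
        prof = compute_profile(b, 0, "all")
        expected, _, _ = profile_oracle(b, 0, set(trials.tolist()))
        np.testing.assert_allclose(prof.values, expected, atol=1e-10)

    def test_pre_smoothing_maps_conserve_mass(self):
        """Unsmoothed occupancy sums to kept time; counts to activity * dt."""
        b = random_session(np.random.default_rng(7))
        trials = resolve_trials(b, "all")
        mask = kept_mask(b, trials)
        sm = smoothed_activity(b)
        bins = position_bins(b.position[mask])
        occupancy = np.bincount(bins, minlength=100) * b.dt
        counts = np.bincount(bins, weights=sm[0, mask], minlength=100) * b.dt
        assert abs(occupancy.sum() - mask.sum() * b.dt) < 1e-10
        assert abs(counts.sum() - (sm[0, mask] * b.dt).sum()) < 1e-10

    def test_half_gain_profiles_are_segment_symmetric(self):
        cfg = SimConfig(n_units=12, n_trials=120, seed=3)
        b, units = simulate_session(cfg, gain_a=0.5)
        profs = compute_profiles(b, "all")
        diffs = []
        for p in profs:
            x = np.arange(15, 45)
            diffs.append(np.nanmean(p.values[x] - p.values[x + 40]))
        # across units the signed asymmetry averages to ~0
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs)) + 0.05

    def test_speed_gate_excludes_slow_vr_timepoints(self):
        pos = np.linspace(1, 99, 20)
        spd = np.where(np.arange(20) < 10, 0.5, 10.0)  # first half too slow
        b = make_bundle(pos, spd, np.ones(20), [np.ones(20)])
        mask = kept_mask(b, resolve_trials(b, "all"))
        assert mask.sum() == 10
        assert not mask[:10].any()
        prof = compute_profile(b, 0, "all")
        # bins visited only below running speed stay unoccupied
        assert np.isnan(prof.values[: int(pos[9]) - 15]).all()

    def test_all_excluded_raises(self):
        pos = np.linspace(1, 99, 10)
        b = make_bundle(pos, np.full(10, 0.5), np.ones(10), [np.ones(10)])
        with pytest.raises(ValueError, match="no usable samples"):
            compute_profile(b, 0, "all")


class TestPredictTrace:
    def test_flat_profile_constant_prediction(self):
        pos, spd, tid = corridor_traversals(2)
        b = make_bundle(pos, spd, tid, [np.full(pos.size, 1.0)])
        prof = compute_profile(b, 0, "all")
        pred = predict_trace(prof, np.array([12.3, 55.0, 99.0]), fill_value=0.0)
        np.testing.assert_allclose(pred, 1.0, atol=1e-9)

    def test_lookup_matches_manual_table(self):
        values = np.full(100, np.nan)
        values[30] = 4.0
        values[31] = 5.0
        prof_obj = type("P", (), {"values": values})
        positions = np.array([30.2, 31.9, 30.0, 77.0])
        pred = predict_trace(prof_obj, positions, fill_value=-1.0)
        np.testing.assert_allclose(pred, [4.0, 5.0, 4.0, -1.0])

    def test_confined_trajectory_uses_single_bin(self):
        values = np.arange(100.0)
        prof_obj = type("P", (), {"values": values})
        pred = predict_trace(prof_obj, np.full(5, 30.5))
        np.testing.assert_allclose(pred, 30.0)


class TestReliability:
    def test_position_locked_unit_is_reliable(self):
        cfg = SimConfig(n_units=1, n_trials=60, seed=21)
        b, _ = simulate_session(cfg, gain_a=0.7)
        # overwrite activity with a noise-free function of position
        rate = np.where(np.isnan(b.position), 0.2,
                        1.0 + np.sin(np.nan_to_num(b.position) / 8.0))
        b.activity = rate[None, :]
        res = reliability_all(b)[0]
        assert res.responsive and res.reliability > 0.5

    def test_white_noise_units_fail_filter(self):
        cfg = SimConfig(n_units=100, n_trials=40, seed=22)
        b, _ = simulate_session(cfg)
        rng = np.random.default_rng(50)
        b.activity = rng.exponential(1.0, b.activity.shape)
        results = reliability_all(b)
        frac = np.mean([r.responsive for r in results])
        rels = [r.reliability for r in results]
        assert np.mean(rels) <= 0.01  # centered at or below zero
        assert frac <= 0.05           # near-zero false-positive rate

    def test_scale_invariance(self):
        cfg = SimConfig(n_units=2, n_trials=30, seed=23)
        b, _ = simulate_session(cfg)
        r1 = reliability_all(b)
        b.activity = b.activity * 7.3
        r2 = reliability_all(b)
        for a, c in zip(r1, r2):
            assert a.reliability == pytest.approx(c.reliability, abs=1e-10)

    def test_mean_of_folds_and_threshold_rule(self):
        cfg = SimConfig(n_units=3, n_trials=30, seed=24)
        b, _ = simulate_session(cfg, gain_a=0.6)
        for r in reliability_all(b):
            assert r.reliability == pytest.approx(r.per_fold.mean())
            assert r.responsive == (r.reliability >= 0.05)

    def test_threshold_boundary_applied_before_smi(self):
        cfg = SimConfig(n_units=2, n_trials=30, seed=25)
        b, _ = simulate_session(cfg, gain_a=0.8)
        fake = [ReliabilityResult(0.049, np.full(5, 0.049), 0.049 >= 0.05),
                ReliabilityResult(0.050, np.full(5, 0.050), 0.050 >= 0.05)]
        res = smi_for_session(b, reliabilities=fake)
        assert not res[0].included and res[0].exclusion_reason == "not_responsive"
        assert res[1].exclusion_reason != "not_responsive"
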