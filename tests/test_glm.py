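import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vrspatial import (SimConfig, build_design, fit_models, ridge_solve,
                       segment_heights, simulate_session)
from vrspatial.glm import DesignBuilder, LAMBDA_GRID

from conftest import corridor_traversals, make_bundle, ridge_oracle


@pytest.fixture(scope="module")
def glm_session():
    cfg = SimConfig(n_units=6, n_trials=30, seed=90)
    bundle, units = simulate_session(cfg, gain_a=0.75)
    return bundle


class TestDesignMatrix:
    def test_predictor_counts(self, glm_session):
        assert build_design(glm_session, "visual").shape[1] == 31
        assert build_design(glm_session, "non_spatial").shape[1] == 40
        assert build_design(glm_session, "spatial", alpha=0.3).shape[1] == 40

    def test_matched_positions_activate_same_column(self):
        # one sample at 25 cm and one at 65 cm, same segment pair
        b = make_bundle([25.0, 65.0, 25.0, 65.0, 25.0, 65.0],
                        np.full(6, 10.0), np.ones(6), [np.zeros(6)],
                        pupil=True)
        X = build_design(b, "visual")
        seg = X[:, 10:30]
        np.testing.assert_array_equal(seg[0], seg[1])
        active = np.nonzero(seg[0])[0]
        assert active.size == 1  # exactly one paired column

    def test_spatial_heights_unit_norm(self):
        h1, h2 = segment_heights(0.5)
        assert h1 == pytest.approx(1 / np.sqrt(2))
        assert h2 == pytest.approx(1 / np.sqrt(2))
        assert segment_heights(1.0) == pytest.approx((1.0, 0.0))
        assert segment_heights(0.0) == pytest.approx((0.0, 1.0))
        for a in np.arange(0, 1.01, 0.1):
            assert np.hypot(*segment_heights(a)) == pytest.approx(1.0)

    def test_spatial_heights_scale_paired_squares(self):
        b = make_bundle([25.0, 65.0], np.full(2, 10.0), np.ones(2),
                        [np.zeros(2)], pupil=True)
        X = build_design(b, "spatial", alpha=0.8)
        h1, h2 = segment_heights(0.8)
        seg = X[:, 10:30]
        col = np.nonzero(seg[0])[0][0]
        assert seg[0, col] == pytest.approx(h1)
        assert seg[1, col] == pytest.approx(h2)

    def test_nesting_at_alpha_half(self, glm_session):
        """spatial(alpha=0.5) equals non_spatial up to 1/sqrt(2) on segments."""
        Xn = build_design(glm_session, "non_spatial")
        Xs = build_design(glm_session, "spatial", alpha=0.5)
        np.testing.assert_allclose(Xs[:, 10:30] * np.sqrt(2), Xn[:, 10:30],
                                   atol=1e-12)
        np.testing.assert_allclose(Xs[:, :10], Xn[:, :10], atol=1e-12)
        np.testing.assert_allclose(Xs[:, 30:], Xn[:, 30:], atol=1e-12)

    def test_column_sums_match_bin_crossings_at_constant_speed(self):
        """On a linear trajectory each 2 cm square is hit a known number of times."""
        pos = np.arange(100) + 0.5  # exactly one sample per 1 cm bin
        b = make_bundle(pos, np.full(100, 10.0), np.ones(100),
                        [np.zeros(100)], fs=10.0)
        X = build_design(b, "visual")
        # onset/offset squares: 2 samples each; paired segment squares: 2 + 2
        np.testing.assert_allclose(X[:, :10].sum(axis=0), 2.0)
        np.testing.assert_allclose(X[:, 10:30].sum(axis=0), 4.0)

    def test_visual_model_ignores_pupil(self):
        pos, spd, tid = corridor_traversals(2)
        b = make_bundle(pos, spd, tid, [np.zeros(pos.size)])  # no pupil
        assert build_design(b, "visual").shape[1] == 31
        with pytest.raises(ValueError, match="pupil"):
            build_design(b, "non_spatial")

    def test_reward_impulse_single_sample(self, glm_session):
        X = build_design(glm_session, "non_spatial")
        reward_col = X[:, 38]
        assert set(np.unique(reward_col)) <= {0.0, 1.0}
        # one impulse per rewarded trial at most (some fall in gray periods)
        assert reward_col.sum() <= glm_session.reward_times.size


class TestRidgeSolve:
    def test_zero_target_zero_coefficients(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 4))
        beta = ridge_solve(X, np.zeros(20), 0.5)
        np.testing.assert_allclose(beta, 0.0, atol=1e-12)

    def test_lambda_zero_equals_ols(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        beta = ridge_solve(X, y, 0.0)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(beta, ols, atol=1e-8)

    def test_singular_at_lambda_zero_raises(self):
        X = np.ones((10, 3))  # rank 1
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            ridge_solve(X, np.arange(10.0), 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_explicit_inversion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        np.testing.assert_allclose(ridge_solve(X, y, 0.5),
                                   ridge_oracle(X, y, 0.5), atol=1e-8)

    def test_monotone_shrinkage(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        norms = [np.linalg.norm(ridge_solve(X, y, lam))
                 for lam in (0.01, 0.1, 1.0, 10.0)]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


class TestFitModels:
    def test_selected_hyperparameters_on_grids(self, glm_session):
        fits = fit_models(glm_session, "spatial", with_predicted_smi=False)
        for f in fits:
            assert f.lambda_selected in LAMBDA_GRID
            assert round(f.alpha_selected, 1) in np.round(np.arange(0, 1.01, 0.1), 1)

    def test_visual_model_has_no_alpha(self, glm_session):
        fits = fit_models(glm_session, "visual", with_predicted_smi=False)
        assert all(f.alpha_selected is None for f in fits)

    def test_nested_models_equal_cv_score_at_alpha_half(self, glm_session):
        """Rescaling the 20 segment columns by a constant leaves CV scores
        unchanged up to the (tiny) ridge penalty difference."""
        from vrspatial.profiles import smoothed_activity
        import scipy.linalg
        builder_n = DesignBuilder(glm_session, "non_spatial")
        builder_s = DesignBuilder(glm_session, "spatial")
        Xn = builder_n.matrix()
        Xs = builder_s.matrix(0.5)
        y = smoothed_activity(glm_session)[0, builder_n.mask]
        # the square basis tiles the corridor, so the designs are rank
        # deficient with the constant; fitted values are still unique and
        # the two designs span the same column space
        bn, *_ = np.linalg.lstsq(Xn, y, rcond=None)
        bs, *_ = np.linalg.lstsq(Xs, y, rcond=None)
        np.testing.assert_allclose(Xn @ bn, Xs @ bs, atol=1e-6)

    def test_spatial_prediction_tracks_true_modulation(self):
        cfg = SimConfig(n_units=20, n_trials=50, seed=91)
        bundle, units = simulate_session(
            cfg, gain_a=np.linspace(0.5, 1.0, 20))
        fits = fit_models(bundle, "spatial")
        alphas = np.array([f.alpha_selected for f in fits])
        true_a = np.array([u.spatial_gain_a for u in units])
        assert np.corrcoef(alphas, true_a)[0, 1] > 0.8

    def test_visual_model_prediction_is_symmetric(self):
        cfg = SimConfig(n_units=15, n_trials=50, seed=92)
        bundle, _ = simulate_session(cfg, gain_a=0.9)
        fits = fit_models(bundle, "visual")
        smis = [f.predicted_smi.smi for f in fits if f.predicted_smi.included]
        assert abs(np.median(smis)) < 0.05

    def test_spatial_model_explains_modulated_units_better(self):
        cfg = SimConfig(n_units=20, n_trials=50, seed=93)
        bundle, _ = simulate_session(cfg, gain_a=0.85)
        cv_vis = [f.cv_variance_explained
                  for f in fit_models(bundle, "visual", with_predicted_smi=False)]
        cv_spa = [f.cv_variance_explained
                  for f in fit_models(bundle, "spatial", with_predicted_smi=False)]
        assert np.median(np.array(cv_spa) - np.array(cv_vis)) > 0
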