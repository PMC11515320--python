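"""Model constructors: signatures, oracles, parameter recovery, observers."""

import numpy as np
import pytest

from chemopde.features import DelaySpec, FeatureTable
from chemopde.models import (
    MODEL_SIGNATURES,
    ModelSpec,
    SensingBounds,
    estimate_sensing_bounds,
    make_parametric_dataset,
    observer_predict,
    train_blackbox_full,
    train_blackbox_single,
    train_delay_model,
    train_graybox,
    train_observer,
    train_parametric_graybox,
    train_second_order,
)
from chemopde.simulate import (
    SimulationConfig,
    SpatioTemporalField,
    chemotactic_term_pointwise,
    simulate_ks,
)
from chemopde.surrogates import AnnConfig, predict

BC_COLS = ["b", "grad_b", "lap_b", "c", "grad_c", "lap_c"]


class TestSignatures:
    """Feature/target columns must match the published model listing."""

    def test_blackbox_full(self):
        feats, targs = MODEL_SIGNATURES["blackbox_full"]
        assert feats == BC_COLS and targs == ["b_t", "c_t"]

    def test_blackbox_single(self):
        feats, targs = MODEL_SIGNATURES["blackbox_single"]
        assert feats == BC_COLS and targs == ["b_t"]

    def test_graybox_residual_target(self):
        feats, targs = MODEL_SIGNATURES["graybox"]
        assert feats == BC_COLS and targs == ["chemo_residual"]

    def test_delay_uses_only_b_history(self):
        feats, _ = MODEL_SIGNATURES["delay_blackbox"]
        assert feats == ["b", "grad_b", "lap_b", "b_lag1", "grad_b_lag1", "lap_b_lag1"]
        assert not any("c" in f.split("_") for f in feats)

    def test_observer_has_arctan_and_raw_delayed_gradient(self):
        feats, targs = MODEL_SIGNATURES["observer"]
        assert feats[1] == "atan_gb"
        assert "grad_b_lag1" in feats and "grad_b" not in feats
        assert targs == ["c"]

    def test_second_order(self):
        feats, targs = MODEL_SIGNATURES["second_order"]
        assert feats == ["b", "grad_b", "lap_b", "b_t"] and targs == ["b_tt"]

    def test_parametric_appends_bounds(self):
        feats, _ = MODEL_SIGNATURES["parametric_graybox"]
        assert feats[-2:] == ["c_plus", "c_minus"]

    def test_graybox_requires_db(self):
        with pytest.raises(ValueError, match="D_b"):
            ModelSpec(kind="graybox")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(kind="whitebox")


class TestBlackboxFull:
    def test_ct_easier_than_bt(self, fast_sim):
        from chemopde.simulate import analytic_b_t, analytic_c_t

        b, c, config = fast_sim
        model = train_blackbox_full(b, c, seed=0)
        table = FeatureTable([b, c])
        ti, ri = table.sample_indices(((230, 290), (0, 250)), (4, 3))
        X = table.extract(BC_COLS, ti, ri)
        bt_true = analytic_b_t(X[:, 0], X[:, 1], X[:, 2], X[:, 3], X[:, 4], X[:, 5], config)
        ct_true = analytic_c_t(X[:, 0], X[:, 3], X[:, 5], config)
        pred = model.predict_targets(X)
        rel_b = np.linalg.norm(pred[:, 0] - bt_true) / np.linalg.norm(bt_true)
        rel_c = np.linalg.norm(pred[:, 1] - ct_true) / np.linalg.norm(ct_true)
        assert rel_c < rel_b  # the c equation is the easier target

    def test_pure_diffusion_recovers_diffusivity(self, diffusion_sim):
        b, c, config = diffusion_sim
        model = train_blackbox_full(b, c, window=((20.0, 60.0), (0.0, 400.0)), seed=0)
        table = FeatureTable([b, c])
        ti, ri = table.sample_indices(((20.0, 60.0), (0.0, 400.0)), (4, 4))
        X = table.extract(BC_COLS, ti, ri)
        pred = model.predict_targets(X)[:, 0]
        slope = np.linalg.lstsq(X[:, 2:3], pred, rcond=None)[0][0]
        assert slope == pytest.approx(config.D_b, rel=0.10)

    def test_constant_fields_learn_zero(self, fast_sim):
        b, c, _ = fast_sim
        grid = b.grid
        times = np.arange(0, 10.0, 0.5)
        vals_b = np.ones((times.size, grid.n)) * 0.3
        vals_c = np.ones((times.size, grid.n)) * 5.0
        bconst = SpatioTemporalField(vals_b, times, grid, name="b")
        cconst = SpatioTemporalField(vals_c, times, grid, name="c")
        model = train_blackbox_full(bconst, cconst, window=((0, 9.5), (0, 1000)), stride=(1, 5), seed=0)
        table = FeatureTable([bconst, cconst])
        ti, ri = table.sample_indices(((0, 9.5), (0, 1000)), (2, 10))
        pred = model.predict_targets(table.extract(BC_COLS, ti, ri))
        assert np.abs(pred).max() < 1e-8

    def test_window_too_small_rejected(self, fast_sim):
        b, c, _ = fast_sim
        with pytest.raises(ValueError, match="training samples"):
            train_blackbox_full(b, c, window=((200, 200.5), (0, 10)), stride=(1, 1))


class TestGraybox:
    def test_heldout_term_recovery(self, fast_sim):
        b, c, config = fast_sim
        model = train_graybox(b, c, D_b=config.D_b, seed=0, sim_config=config)
        table = FeatureTable([b, c])
        ti, ri = table.sample_indices(((230, 290), (0, 250)), (4, 3))
        X = table.extract(BC_COLS, ti, ri)
        g_true = chemotactic_term_pointwise(
            X[:, 0], X[:, 1], X[:, 3], X[:, 4], X[:, 5],
            config.chi0, config.c_minus, config.c_plus,
        )
        g_hat = model.predict_targets(X)[:, 0]
        assert np.linalg.norm(g_hat - g_true) / np.linalg.norm(g_true) <= 0.05

    def test_zero_chi_learns_zero_residual(self, diffusion_sim):
        b, c, config = diffusion_sim
        model = train_graybox(
            b, c, window=((20.0, 60.0), (0.0, 400.0)), D_b=config.D_b, seed=0, sim_config=config
        )
        table = FeatureTable([b, c])
        ti, ri = table.sample_indices(((20.0, 60.0), (0.0, 400.0)), (4, 4))
        pred = model.predict_targets(table.extract(BC_COLS, ti, ri))[:, 0]
        bt = table.extract(["b_t"], ti, ri)[:, 0]
        assert np.abs(pred).max() < 0.05 * np.abs(bt).max()


class TestParametricGraybox:
    def test_dataset_size_and_columns(self, fast_sim):
        b, c, _ = fast_sim
        X, y = make_parametric_dataset(b, c, n_samples=10_000, seed=0)
        assert X.shape == (10_000, 8)
        assert y.shape == (10_000,)
        assert np.all(X[:, 6] > X[:, 7])  # c_plus > c_minus in every row

    def test_p_sampling_spans_range(self, fast_sim):
        b, c, _ = fast_sim
        X, _ = make_parametric_dataset(b, c, n_samples=5000, seed=1)
        assert X[:, 6].min() < 20 and X[:, 6].max() > 50
        assert X[:, 7].min() < 0.7 and X[:, 7].max() > 1.7

    def test_constant_p_rejected(self, fast_sim):
        b, c, _ = fast_sim
        X, y = make_parametric_dataset(b, c, n_samples=500, seed=0)
        X[:, 6] = 30.0
        with pytest.raises(ValueError, match="span"):
            train_parametric_graybox((X, y))

    def test_surrogate_matches_analytic_on_heldout(self, fast_sim):
        """At the true bounds, the surrogate tracks the analytic term on
        held-out (unperturbed) window samples."""
        b, c, config = fast_sim
        ds = make_parametric_dataset(b, c, n_samples=10_000, seed=0, chi0=config.chi0)
        g = train_parametric_graybox(ds, seed=0)
        table = FeatureTable([b, c])
        ti, ri = table.sample_indices(((200, 230), (0, 250)), (3, 2))
        F = table.extract(BC_COLS, ti, ri)
        Xh = np.column_stack([F, np.full(len(F), 30.0), np.full(len(F), 1.0)])
        yh = chemotactic_term_pointwise(
            F[:, 0], F[:, 1], F[:, 3], F[:, 4], F[:, 5], config.chi0, 1.0, 30.0
        )
        pred = predict(g, Xh)
        assert np.linalg.norm(pred - yh) / np.linalg.norm(yh) <= 0.10

    def test_analytic_loss_minimized_at_true_p(self, fast_sim):
        """With the analytic term substituted for the surrogate, the loss is
        exactly minimized (→ 0) at the true bounds."""
        b, c, config = fast_sim
        table = FeatureTable([b, c])
        ti, ri = table.sample_indices(((200, 230), (0, 250)), (6, 5))
        X = table.extract(BC_COLS, ti, ri)
        target = chemotactic_term_pointwise(
            X[:, 0], X[:, 1], X[:, 3], X[:, 4], X[:, 5],
            config.chi0, config.c_minus, config.c_plus,
        )

        def loss(cp, cm):
            g = chemotactic_term_pointwise(
                X[:, 0], X[:, 1], X[:, 3], X[:, 4], X[:, 5], config.chi0, cm, cp
            )
            return float(np.sum((target - g) ** 2))

        l_true = loss(30.0, 1.0)
        assert l_true == pytest.approx(0.0, abs=1e-20)
        assert loss(35.0, 1.0) > 1e-10 and loss(30.0, 1.5) > 1e-10

    def test_bounds_recovered_within_20pct(self, fast_sim):
        b, c, config = fast_sim
        ds = make_parametric_dataset(b, c, n_samples=10_000, seed=0, chi0=config.chi0)
        g = train_parametric_graybox(ds, seed=0)
        bounds, details = estimate_sensing_bounds(g, b, c, D_b=config.D_b, seed=0)
        assert abs(bounds.c_plus - 30.0) / 30.0 <= 0.20
        assert abs(bounds.c_minus - 1.0) / 1.0 <= 0.20
        assert len(details) == 5

    def test_sensing_bounds_invariant(self):
        with pytest.raises(ValueError):
            SensingBounds(c_plus=1.0, c_minus=30.0)


class TestDelayModel:
    def test_discrete_step_matches_heldout_data(self, fast_sim):
        b, _, _ = fast_sim
        model = train_delay_model(b, seed=0)
        table = FeatureTable([b], delay=DelaySpec(delta_t=b.report_dt))
        ti, ri = table.sample_indices(((240, 260), (0, 250)), (5, 5))
        X = table.extract(model.spec.feature_columns, ti, ri)
        f = model.predict_targets(X)[:, 0]
        b_now = b.values[np.ix_(ti, ri)].ravel()
        b_next = b.values[np.ix_(ti + 1, ri)].ravel()
        pred_next = b_now + b.report_dt * f
        assert np.abs(pred_next - b_next).max() < 0.02 * b.values.max()

    def test_gray_variant_requires_db(self, fast_sim):
        b, _, _ = fast_sim
        with pytest.raises(ValueError, match="D_b"):
            train_delay_model(b, variant="gray")

    def test_gray_variant_target_shift(self, fast_sim):
        b, _, config = fast_sim
        mb = train_delay_model(b, seed=0, variant="black")
        mg = train_delay_model(b, seed=0, variant="gray", D_b=config.D_b)
        table = FeatureTable([b], delay=DelaySpec(delta_t=b.report_dt))
        ti, ri = table.sample_indices(((210, 215), (0, 250)), (5, 5))
        X = table.extract(mb.spec.feature_columns, ti, ri)
        lap = table.arrays["lap_b"][np.ix_(ti, ri)].ravel()
        fb = mb.predict_targets(X)[:, 0]
        fg = mg.predict_targets(X)[:, 0] + config.D_b * lap
        # both parameterizations reconstruct the same full increment
        scale = np.abs(fb).max()
        assert np.abs(fb - fg).max() < 0.15 * scale


class TestObserver:
    def test_constant_c_learned(self, fast_sim):
        b, _, _ = fast_sim
        cconst = SpatioTemporalField(
            np.full_like(b.values, 123.0), b.times, b.grid, name="c"
        )
        obs = train_observer(b, cconst, seed=0)
        c_hat, *_ = observer_predict(obs, b, window=((240, 250), (0, 250)), stride=(5, 5))
        assert np.abs(c_hat / 123.0 - 1.0).max() < 0.01

    def test_arctan_improves_flat_regions(self, fast_sim):
        """Paired training, same seed: removing the arctan observable
        degrades held-out error in near-flat regions."""
        b, c, _ = fast_sim
        with_obs = train_observer(b, c, stride=(2, 1), seed=0)
        without = train_observer(b, c, stride=(2, 1), seed=0, use_arctan=False)
        window = ((230, 290), (0, 250))
        ca, ti, ri = observer_predict(with_obs, b, window=window, stride=(4, 1))
        cb, *_ = observer_predict(without, b, window=window, stride=(4, 1))
        c_true = c.values[np.ix_(ti, ri)]
        table = FeatureTable([b])
        grad = table.arrays["grad_b"][np.ix_(ti, ri)]
        flat = np.abs(grad) < 0.01 * np.abs(grad).max()
        err_a = np.abs(ca - c_true)[flat].mean()
        err_b = np.abs(cb - c_true)[flat].mean()
        assert err_a < err_b

    def test_missing_scaling_stats_error(self, fast_sim):
        b, c, _ = fast_sim
        obs = train_observer(b, c, seed=0)
        obs.params["arctan_minmax"] = None
        with pytest.raises(ValueError, match="scaling"):
            observer_predict(obs, b, window=((240, 250), (0, 250)))


class TestSecondOrder:
    def test_insufficient_times_rejected(self, fast_sim):
        b, _, _ = fast_sim
        short = SpatioTemporalField(b.values[:3], b.times[:3], b.grid, name="b")
        with pytest.raises(ValueError, match="interpolate"):
            train_second_order(short)

    def test_trains_and_predicts(self, fast_sim):
        b, _, _ = fast_sim
        model = train_second_order(
            b, window=((210, 220), (0, 250)), stride=(2, 4),
            ann_config=AnnConfig(seed=0, epochs=256),
        )
        assert model.kind == "second_order"
        table = FeatureTable([b], with_second_time_derivative=True)
        ti, ri = table.sample_indices(((215, 218), (0, 250)), (2, 6))
        X = table.extract(model.spec.feature_columns, ti, ri)
        pred = model.predict_targets(X)[:, 0]
        assert np.all(np.isfinite(pred))


class TestSeedStability:
    def test_two_seeds_give_close_predictions(self, fast_sim):
        b, c, config = fast_sim
        table = FeatureTable([b, c])
        ti, ri = table.sample_indices(((230, 250), (0, 250)), (6, 5))
        X = table.extract(BC_COLS, ti, ri)
        bt = table.extract(["b_t"], ti, ri)[:, 0]
        preds = []
        for seed in (0, 1):
            m = train_blackbox_single(b, c, seed=seed, sim_config=config)
            preds.append(m.predict_targets(X)[:, 0])
        seed_gap = np.linalg.norm(preds[0] - preds[1])
        truth_gap = np.linalg.norm(preds[0] - bt)
        assert seed_gap < 2.0 * truth_gap
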