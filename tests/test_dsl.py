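"""Heteroscedastic loss, network construction, and training protocol."""

import numpy as np
import pandas as pd
import pytest

from dslox.dsl import (
    NetworkSpec,
    SpectralRegression,
    TrainingConfig,
    build_model,
    gaussian_nll_loss,
    predict,
)
from dslox.synthetic import (
    BAND_COLUMNS,
    NoiseModel,
    SyntheticDatasetConfig,
    generate_spectral_dataset,
)


class TestGaussianNllLoss:
    def test_unit_sigma_reduces_to_sum_of_squared_errors(self):
        rng = np.random.default_rng(0)
        m, t = rng.random(40), rng.random(40)
        got = gaussian_nll_loss(m, np.ones(40), t)
        assert got == pytest.approx(np.sum((m - t) ** 2), rel=1e-12)

    def test_sigma_stationary_point_at_absolute_residual(self):
        # per sample, x -> r^2/x + log x is minimized at x = r^2
        r = 0.13
        sig_grid = np.linspace(0.02, 0.5, 2000)
        losses = [gaussian_nll_loss(np.array([r]), np.array([s]), np.array([0.0]))
                  for s in sig_grid]
        s_best = sig_grid[int(np.argmin(losses))]
        assert s_best == pytest.approx(abs(r), rel=0.01)

    def test_hand_computed_single_sample_value(self):
        # (0.8-0.7)^2/0.05^2 + log(0.05^2) = 4 + log 0.0025
        got = gaussian_nll_loss(np.array([0.8]), np.array([0.05]), np.array([0.7]))
        assert got == pytest.approx(4.0 + np.log(0.0025), rel=1e-12)

    def test_equals_negative_log_likelihood_up_to_constant(self):
        # the loss and -2*log likelihood differ only by N*log(2*pi),
        # independently of (mean, sigma)
        rng = np.random.default_rng(1)
        diffs = []
        for _ in range(5):
            m, s, t = rng.random(20), rng.random(20) * 0.5 + 0.01, rng.random(20)
            loglik = np.sum(
                -0.5 * np.log(2 * np.pi * s**2) - (m - t) ** 2 / (2 * s**2)
            )
            diffs.append(gaussian_nll_loss(m, s, t) - (-2.0 * loglik))
        np.testing.assert_allclose(diffs, -20 * np.log(2 * np.pi), rtol=1e-9)

    def test_sigma_below_floor_clamped_not_error(self):
        got = gaussian_nll_loss(np.array([0.5]), np.array([0.0]), np.array([0.5]),
                                sigma_floor=1e-3)
        assert np.isfinite(got)
        assert got == pytest.approx(np.log(1e-6), rel=1e-9)


class TestBuildModel:
    def test_fnn_parameter_count_matches_shape_arithmetic(self):
        # 28*24+24 + 24*24+24 + 24*2+2 = 1346
        assert build_model("fnn", seed=0).param_count == 1346

    def test_outputs_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(2)
        for kind in ("fnn", "cnn"):
            model = build_model(kind, seed=3)
            pred = predict(model, rng.random((10, 28)) * 5.0)
            assert np.all(pred.mean > 0) and np.all(pred.mean < 1)
            assert np.all(pred.sigma > 0) and np.all(pred.sigma < 1)

    def test_same_seed_identical_initial_outputs(self):
        x = np.random.default_rng(4).random((5, 28))
        a = predict(build_model("cnn", seed=11), x)
        b = predict(build_model("cnn", seed=11), x)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.sigma, b.sigma)

    def test_wrong_input_length_rejected(self):
        model = build_model("fnn", seed=0)
        with pytest.raises(ValueError, match="input"):
            predict(model, np.zeros((3, 27)))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(kind="rnn")


@pytest.fixture(scope="module")
def tiny_fit():
    cfg = SyntheticDatasetConfig.small(
        seed=31, n_per_cell=4, noise=NoiseModel.off(),
        bias_coefficients={1: (0.0, 0.0), 2: (0.0, 0.0)},
    )
    df = generate_spectral_dataset(cfg)
    tcfg = TrainingConfig(epochs=400, seed=7)
    res = SpectralRegression.from_dataframe(
        df[df.split == "train"], network="fnn", config=tcfg
    ).fit()
    return df, res


class TestTrainingProtocol:
    def test_learning_rate_schedule(self):
        cfg = TrainingConfig()
        assert cfg.learning_rate(0) == pytest.approx(2.5e-3)
        assert cfg.learning_rate(100) == pytest.approx(1.25e-3)

    def test_history_records_schedule_and_losses(self, tiny_fit):
        _, res = tiny_fit
        h = res.history
        assert len(h) == 400
        assert h.lr.iloc[100] == pytest.approx(1.25e-3)
        assert np.all(np.isfinite(h.train_loss)) and np.all(np.isfinite(h.val_loss))

    def test_selection_contract_min_validation_loss(self, tiny_fit):
        _, res = tiny_fit
        assert res.val_loss == pytest.approx(res.history.val_loss.min())
        assert res.best_epoch == int(res.history.val_loss.idxmin())

    def test_noiseless_training_reaches_low_validation_mse(self, tiny_fit):
        df, res = tiny_fit
        te = df[df.split == "test"]
        mse = res.mse(te[BAND_COLUMNS].to_numpy(), te.label.to_numpy())
        assert mse < 1e-3  # labels are exactly recoverable from the input

    def test_prediction_is_deterministic(self, tiny_fit):
        df, res = tiny_fit
        x = df[BAND_COLUMNS].to_numpy()[:9]
        a, b = res.predict(x), res.predict(x)
        np.testing.assert_array_equal(a.mean, b.mean)

    def test_validation_split_holds_out_whole_animals(self, tiny_fit):
        df, res = tiny_fit
        tr = df[df.split == "train"].reset_index(drop=True)
        key = (tr.setup.astype(int) * 1000 + tr.rat.astype(int)).to_numpy()
        assert set(key[res.train_idx]).isdisjoint(set(key[res.val_idx]))

    def test_summary_mentions_architecture_and_loss(self, tiny_fit):
        _, res = tiny_fit
        text = res.summary()
        assert "FNN" in text and "val loss" in text

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            SpectralRegression(np.zeros((10, 27)), np.zeros(10))
        with pytest.raises(ValueError):
            SpectralRegression(np.zeros((10, 28)), np.zeros(9))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(val_split=0.0)
        with pytest.raises(ValueError):
            TrainingConfig(lr0=-1.0)


class TestHeteroscedasticBehaviour:
    def test_predicted_sigma_orders_noise_regimes(self):
        from dslox.synthetic import generate_two_regime_dataset

        df = generate_two_regime_dataset(n_per_regime=250, sds=(0.02, 0.08), seed=13)
        res = SpectralRegression.from_dataframe(
            df[df.split == "train"], network="fnn",
            config=TrainingConfig(epochs=250, seed=5),
        ).fit()
        te = df[df.split == "test"]
        pred = res.predict(te[BAND_COLUMNS].to_numpy())
        low = pred.sigma[te.regime.to_numpy() == 0].mean()
        high = pred.sigma[te.regime.to_numpy() == 1].mean()
        assert high > low
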