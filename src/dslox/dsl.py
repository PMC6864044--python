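"""Uncertainty-quantifying spectral regression (deep spectral learning).

Two small regressors map a 28-element normalized spectral input to a
predicted mean sO2 and a per-sample standard deviation sigma, both pushed
through a sigmoid so they live on the (0, 1) fraction scale:

* FNN  -- two hidden dense layers of 24 ReLU units (1346 parameters);
* CNN  -- two 1-D convolution layers (kernel 3, 30 filters, ReLU),
  flatten, dense output.

Training minimizes the heteroscedastic Gaussian negative log-likelihood

    L(w) = sum_i [ (mean_i(w) - label_i)^2 / sigma_i(w)^2 + log sigma_i(w)^2 ]

which is the negative log of the joint Gaussian likelihood of the labels
up to an additive constant, so each prediction carries its own error bar.
The training protocol: Adam, initial learning rate 2.5e-3 decayed as
lr0 / (1 + 0.01 * epoch), 2000 epochs, batch size 50, validation split
0.2 (grouped by animal when ids are available), and the epoch checkpoint
with minimum validation loss is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from ._net import SGD, Adam, Conv1D, Dense, Flatten, ReLU, Sequential, Sigmoid

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "Prediction",
    "gaussian_nll_loss",
    "build_model",
    "SpectralRegression",
    "SpectralRegressionResults",
    "train",
    "predict",
]

INPUT_LEN = 28
SIGMA_FLOOR = 1e-3


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description of one regressor."""

    kind: str = "fnn"  # "fnn" | "cnn"
    hidden_units: int = 24
    n_hidden: int = 2
    filters: int = 30
    kernel: int = 3
    input_len: int = INPUT_LEN

    def __post_init__(self) -> None:
        if self.kind not in ("fnn", "cnn"):
            raise ValueError("kind must be 'fnn' or 'cnn'")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization protocol for the spectral regressors."""

    lr0: float = 2.5e-3
    decay: float = 0.01  # lr(N) = lr0 / (1 + decay * N), N = epoch index
    epochs: int = 2000
    batch_size: int = 50
    val_split: float = 0.2
    optimizer: str = "adam"  # "adam" | "sgd"
    sigma_floor: float = SIGMA_FLOOR
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lr0 > 0 and self.epochs > 0 and self.batch_size > 0):
            raise ValueError("rates, epochs and batch size must be positive")
        if not 0.0 < self.val_split < 1.0:
            raise ValueError("val_split must lie in (0, 1)")

    def learning_rate(self, epoch: int) -> float:
        return self.lr0 / (1.0 + self.decay * epoch)


@dataclass(frozen=True)
class Prediction:
    """Per-sample predicted mean sO2 and standard deviation (fractions)."""

    mean: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        m = np.atleast_1d(np.asarray(self.mean, dtype=float))
        s = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "sigma", s)
        if m.shape != s.shape:
            raise ValueError("mean and sigma must have matching shapes")


def gaussian_nll_loss(
    mean,
    sigma,
    target,
    reduction: str = "sum",
    sigma_floor: float = SIGMA_FLOOR,
) -> float:
    """Heteroscedastic Gaussian loss sum_i [(m_i-t_i)^2/s_i^2 + log s_i^2].

    ``sigma`` below ``sigma_floor`` is clamped (not an error); with
    sigma = 1 everywhere the loss reduces to the (summed) squared error.
    ``reduction``: "sum" (the likelihood form) or "mean" (per-sample
    average, the form used for minibatch training).
    """
    m = np.asarray(mean, dtype=float)
    s = np.maximum(np.asarray(sigma, dtype=float), sigma_floor)
    t = np.asarray(target, dtype=float)
    per = (m - t) ** 2 / s**2 + np.log(s**2)
    if reduction == "sum":
        return float(np.sum(per))
    if reduction == "mean":
        return float(np.mean(per))
    raise ValueError("reduction must be 'sum' or 'mean'")


def _nll_grads(mean, sigma, target, sigma_floor: float) -> Tuple[np.ndarray, np.ndarray]:
    """d(mean NLL)/d(mean), d(mean NLL)/d(sigma); zero where sigma clamped."""
    n = mean.size
    s = np.maximum(sigma, sigma_floor)
    r = mean - target
    dmean = 2.0 * r / s**2 / n
    dsigma = (-2.0 * r**2 / s**3 + 2.0 / s) / n
    dsigma = np.where(sigma > sigma_floor, dsigma, 0.0)
    return dmean, dsigma


def build_model(spec: Union[NetworkSpec, str], seed: int = 0) -> Sequential:
    """Initialize a network (Glorot-uniform weights, seeded)."""
    if isinstance(spec, str):
        spec = NetworkSpec(kind=spec)
    rng = np.random.default_rng(seed)
    if spec.kind == "fnn":
        layers: List = []
        n_in = spec.input_len
        for _ in range(spec.n_hidden):
            layers += [Dense(n_in, spec.hidden_units, rng), ReLU()]
            n_in = spec.hidden_units
        layers += [Dense(n_in, 2, rng), Sigmoid()]
        return Sequential(layers, input_shape=(spec.input_len,))
    # CNN: (length, 1) input, two valid convolutions, flatten, dense head
    l_out = spec.input_len - 2 * (spec.kernel - 1)
    layers = [
        Conv1D(spec.kernel, 1, spec.filters, rng),
        ReLU(),
        Conv1D(spec.kernel, spec.filters, spec.filters, rng),
        ReLU(),
        Flatten(),
        Dense(l_out * spec.filters, 2, rng),
        Sigmoid(),
    ]
    return Sequential(layers, input_shape=(spec.input_len, 1))


def _prepare_input(model: Sequential, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[-1] != model.input_shape[0] and x.shape[1] != model.input_shape[0]:
        raise ValueError(f"expected input length {model.input_shape[0]}, got {x.shape}")
    if len(model.input_shape) == 2 and x.ndim == 2:
        x = x[:, :, None]
    return x


def predict(model: Sequential, samples: np.ndarray) -> Prediction:
    """Forward pass returning per-sample (mean sO2, sigma)."""
    out = model.forward(_prepare_input(model, samples))
    return Prediction(mean=out[:, 0], sigma=out[:, 1])


def _group_val_split(
    rng: np.random.Generator, n: int, val_split: float, groups: Optional[np.ndarray]
) -> Tuple[np.ndarray, np.ndarray]:
    """Validation split; whole groups (animals) held out when provided."""
    if groups is None:
        idx = rng.permutation(n)
        n_val = max(1, int(round(val_split * n)))
        return idx[n_val:], idx[:n_val]
    uniq = np.unique(groups)
    order = rng.permutation(uniq.size)
    val_groups: List = []
    n_val = 0
    for gi in order:
        if n_val >= val_split * n:
            break
        val_groups.append(uniq[gi])
        n_val += int(np.sum(groups == uniq[gi]))
    val_mask = np.isin(groups, val_groups)
    if val_mask.all() or not val_mask.any():  # degenerate grouping: fall back
        return _group_val_split(rng, n, val_split, None)
    return np.where(~val_mask)[0], np.where(val_mask)[0]


class SpectralRegression:
    """Heteroscedastic spectral regression model (fit -> Results).

    Parameters
    ----------
    exog : ndarray, shape (n, 28)
        Normalized spectral input vectors.
    endog : ndarray, shape (n,)
        spO2 labels, fractions in [0, 1].
    network : str or NetworkSpec
        "fnn" (default) or "cnn", or an explicit spec.
    config : TrainingConfig
    groups : ndarray, optional
        Per-sample animal identifiers; the validation split holds out
        whole animals to avoid leakage.
    """

    def __init__(
        self,
        exog: np.ndarray,
        endog: np.ndarray,
        network: Union[str, NetworkSpec] = "fnn",
        config: TrainingConfig = TrainingConfig(),
        groups: Optional[np.ndarray] = None,
    ) -> None:
        self.exog = np.asarray(exog, dtype=float)
        self.endog = np.asarray(endog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.size:
            raise ValueError("exog must be (n_samples, n_features) matching endog")
        self.spec = NetworkSpec(kind=network) if isinstance(network, str) else network
        if self.exog.shape[1] != self.spec.input_len:
            raise ValueError(f"expected {self.spec.input_len} input features")
        self.config = config
        self.groups = None if groups is None else np.asarray(groups)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        network: Union[str, NetworkSpec] = "fnn",
        config: TrainingConfig = TrainingConfig(),
    ) -> "SpectralRegression":
        """Build from a sample table (band columns + label [+ setup/rat])."""
        from .synthetic import BAND_COLUMNS

        groups = None
        if {"setup", "rat"}.issubset(df.columns):
            groups = (df["setup"].astype(int) * 1000 + df["rat"].astype(int)).to_numpy()
        return cls(
            df[BAND_COLUMNS].to_numpy(), df["label"].to_numpy(),
            network=network, config=config, groups=groups,
        )

    def fit(self, verbose: bool = False) -> "SpectralRegressionResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        model = build_model(self.spec, seed=int(rng.integers(2**31)))
        opt = (Adam if cfg.optimizer == "adam" else SGD)(model.params)

        n = self.endog.size
        train_idx, val_idx = _group_val_split(rng, n, cfg.val_split, self.groups)
        if train_idx.size < 2 or val_idx.size < 1:
            raise ValueError("need at least 2 training and 1 validation samples")
        x_tr = _prepare_input(model, self.exog[train_idx])
        y_tr = self.endog[train_idx]
        x_va = _prepare_input(model, self.exog[val_idx])
        y_va = self.endog[val_idx]

        history = []
        best = (np.inf, -1, model.get_weights())
        for epoch in range(cfg.epochs):
            lr = cfg.learning_rate(epoch)
            order = rng.permutation(train_idx.size)
            batch_losses, batch_sizes = [], []
            for start in range(0, order.size, cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                out = model.forward(x_tr[sel])
                mean, sigma = out[:, 0], out[:, 1]
                batch_losses.append(
                    gaussian_nll_loss(mean, sigma, y_tr[sel], reduction="mean",
                                      sigma_floor=cfg.sigma_floor)
                )
                batch_sizes.append(sel.size)
                dmean, dsigma = _nll_grads(mean, sigma, y_tr[sel], cfg.sigma_floor)
                model.backward(np.column_stack([dmean, dsigma]))
                opt.step(model.grads, lr)
            # running train loss over the epoch's minibatches (pre-update)
            tr_loss = float(np.average(batch_losses, weights=batch_sizes))
            out_va = model.forward(x_va)
            va_loss = gaussian_nll_loss(out_va[:, 0], out_va[:, 1], y_va,
                                        reduction="mean", sigma_floor=cfg.sigma_floor)
            if not (np.isfinite(tr_loss) and np.isfinite(va_loss)):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: "
                    f"train loss {tr_loss}, val loss {va_loss}"
                )
            history.append(dict(epoch=epoch, lr=lr, train_loss=tr_loss, val_loss=va_loss))
            if va_loss < best[0]:
                best = (va_loss, epoch, model.get_weights())
            if verbose and epoch % 100 == 0:
                print(f"epoch {epoch:5d}  lr {lr:.2e}  train {tr_loss:.4f}  val {va_loss:.4f}")

        model.set_weights(best[2])
        return SpectralRegressionResults(
            self, model, pd.DataFrame(history), best_epoch=best[1],
            train_idx=train_idx, val_idx=val_idx,
        )


class SpectralRegressionResults:
    """Trained regressor: min-validation-loss checkpoint plus history."""

    def __init__(self, model_obj, network, history, best_epoch, train_idx, val_idx):
        self.model = model_obj
        self.network = network
        self.history = history
        self.best_epoch = int(best_epoch)
        self.train_idx = train_idx
        self.val_idx = val_idx

    @property
    def val_loss(self) -> float:
        return float(self.history["val_loss"].iloc[self.best_epoch])

    def predict(self, samples: np.ndarray) -> Prediction:
        return predict(self.network, samples)

    def mse(self, exog: np.ndarray, endog: np.ndarray) -> float:
        from .lsf import evaluate_mse

        return evaluate_mse(self.predict(exog).mean, np.asarray(endog, dtype=float))

    def summary(self) -> str:
        spec, cfg = self.model.spec, self.model.config
        pred_va = self.predict(self.model.exog[self.val_idx])
        lines = [
            f"Spectral regression ({spec.kind.upper()})",
            "=" * 42,
            f"parameters:         {self.network.param_count}",
            f"train/val samples:  {self.train_idx.size}/{self.val_idx.size}",
            f"epochs:             {cfg.epochs} (best checkpoint: {self.best_epoch})",
            f"best val loss:      {self.val_loss:.4f}",
            f"val MSE:            {self.mse(self.model.exog[self.val_idx], self.model.endog[self.val_idx]):.4e}",
            f"mean predicted sigma: {pred_va.sigma.mean():.4f}",
        ]
        return "\n".join(lines)

    def save_weights(self, path) -> None:
        np.savez(path, *self.network.get_weights())

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            self.network.set_weights([data[k] for k in data.files])


def train(
    model_or_spec: Union[str, NetworkSpec],
    samples: pd.DataFrame,
    cfg: TrainingConfig = TrainingConfig(),
) -> SpectralRegressionResults:
    """Functional wrapper: train a network on a sample table."""
    return SpectralRegression.from_dataframe(samples, network=model_or_spec, config=cfg).fit()
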