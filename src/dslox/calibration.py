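"""Reliability-diagram evaluation of predicted uncertainties.

For predictions whose standard deviation falls in a bin around sigma0
(relaxed to sigma0 +/- 1% so bins hold enough samples), the empirical
probability

    P(sigma0, eta) = (1/|S|) * #{ i in S : |mean_i - label_i| < eta*sigma0 }

is compared against the theoretical Gaussian confidence erf(eta/sqrt(2)).
A well-calibrated predictor puts P on the diagonal; P below the diagonal
flags over-confidence, above flags conservativeness.  Per bin, an
ordinary least-squares line of P against the theoretical confidence
summarizes calibration by its slope (ideal 1) and constant (ideal 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import erf

from .dsl import Prediction

__all__ = [
    "ReliabilityCurve",
    "CalibrationFit",
    "EmptyBinError",
    "theoretical_confidence",
    "reliability_probability",
    "reliability_curve",
    "fit_reliability_line",
    "coverage_report",
]

DEFAULT_ETA_GRID = np.round(np.arange(0.1, 3.0 + 1e-9, 0.1), 10)
DEFAULT_TOL = 0.01  # +/- 1% bin relaxation


class EmptyBinError(ValueError):
    """No predictions fall in the sigma0 bin (distinct from P = 0)."""


def theoretical_confidence(eta) -> np.ndarray:
    """Probability mass of a standard normal within +/- eta: erf(eta/sqrt 2)."""
    eta = np.asarray(eta, dtype=float)
    if np.any(eta < 0):
        raise ValueError("eta must be non-negative")
    return erf(eta / np.sqrt(2.0))


def reliability_probability(
    preds: Prediction,
    labels: np.ndarray,
    sigma0: float,
    eta: float,
    tol: float = DEFAULT_TOL,
) -> Tuple[float, int]:
    """Empirical P(sigma0, eta) and the bin size |S|.

    S selects predictions with sigma in [sigma0 - tol, sigma0 + tol];
    the indicator uses a strict ``<`` so eta = 0 gives exactly P = 0.
    Raises :class:`EmptyBinError` when the bin is empty.
    """
    labels = np.asarray(labels, dtype=float)
    if labels.shape != preds.mean.shape:
        raise ValueError("labels must match predictions")
    in_bin = np.abs(preds.sigma - sigma0) <= tol
    n = int(in_bin.sum())
    if n == 0:
        raise EmptyBinError(f"no predictions with sigma within {sigma0} +/- {tol}")
    err = np.abs(preds.mean[in_bin] - labels[in_bin])
    return float(np.mean(err < eta * sigma0)), n


@dataclass(frozen=True)
class ReliabilityCurve:
    """Empirical vs theoretical coverage for one sigma0 bin."""

    sigma0: float
    tol: float
    eta: np.ndarray
    confidence: np.ndarray  # erf(eta/sqrt 2)
    probability: np.ndarray  # empirical P(sigma0, eta)
    n_in_bin: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(eta=self.eta, confidence=self.confidence, probability=self.probability)
        )


def reliability_curve(
    preds: Prediction,
    labels: np.ndarray,
    sigma0: float,
    tol: float = DEFAULT_TOL,
    eta_grid: np.ndarray = DEFAULT_ETA_GRID,
) -> ReliabilityCurve:
    """Evaluate P(sigma0, eta) across the eta grid for one bin."""
    probs = []
    n = 0
    for eta in eta_grid:
        p, n = reliability_probability(preds, labels, sigma0, float(eta), tol=tol)
        probs.append(p)
    return ReliabilityCurve(
        sigma0=sigma0,
        tol=tol,
        eta=np.asarray(eta_grid, dtype=float),
        confidence=theoretical_confidence(eta_grid),
        probability=np.asarray(probs),
        n_in_bin=n,
    )


@dataclass(frozen=True)
class CalibrationFit:
    """OLS line of empirical probability against theoretical confidence."""

    slope: float
    constant: float
    n: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.constant)):
            raise ValueError("calibration fit must be finite")


def fit_reliability_line(curve: ReliabilityCurve) -> CalibrationFit:
    """Least-squares P ~ slope * confidence + constant for one bin."""
    conf, prob = curve.confidence, curve.probability
    if conf.size < 2 or np.ptp(conf) < 1e-12:
        raise ValueError("confidence grid is degenerate; cannot fit a line")
    slope, constant = np.polyfit(conf, prob, 1)
    return CalibrationFit(slope=float(slope), constant=float(constant), n=curve.n_in_bin)


def coverage_report(
    preds: Prediction,
    labels: np.ndarray,
    sigma0_list: Sequence[float],
    tol: float = DEFAULT_TOL,
    eta_grid: np.ndarray = DEFAULT_ETA_GRID,
    model_name: str = "",
) -> Tuple[pd.DataFrame, float]:
    """Per-bin calibration-line table plus the covered prediction fraction.

    Empty bins appear with ``n = 0`` and NaN slope/constant and are
    excluded from any aggregate; overlapping relaxed bins may count a
    prediction more than once (coverage counts each prediction once, as
    membership in >= 1 bin).
    """
    if len(sigma0_list) == 0:
        raise ValueError("sigma0 list must be non-empty")
    rows = []
    covered = np.zeros(preds.sigma.size, dtype=bool)
    for sigma0 in sigma0_list:
        covered |= np.abs(preds.sigma - sigma0) <= tol
        try:
            curve = reliability_curve(preds, labels, sigma0, tol=tol, eta_grid=eta_grid)
            fit = fit_reliability_line(curve)
            rows.append(dict(model=model_name, sigma0=sigma0, slope=fit.slope,
                             constant=fit.constant, n=fit.n))
        except EmptyBinError:
            rows.append(dict(model=model_name, sigma0=sigma0, slope=np.nan,
                             constant=np.nan, n=0))
    return pd.DataFrame(rows), float(covered.mean())
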