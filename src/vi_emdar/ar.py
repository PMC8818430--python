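"""Autoregressive feature extraction: Burg estimation and AIC order selection.

The AR(p) model is written y(i) = sum_j phi_j y(i-j) + n(i), with positive
coefficients on past values; Burg estimation minimizes forward/backward
prediction error and always yields a stable model (all characteristic
roots inside the unit circle, asserted).  The pipeline feature vector is
the twelve Burg coefficients of an AR(6) fit on the preprocessed FP2 and
F8 epochs, named FP2_AR1..FP2_AR6, F8_AR1..F8_AR6.  AIC order selection is
retained as a per-dataset diagnostic; the pipeline order stays fixed at 6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.regression.linear_model import burg as _sm_burg

from .containers import TrialSet, FeatureMatrix

__all__ = ["ARFit", "burg_fit", "aic_order", "ar_features", "ar_feature_matrix"]

FEATURE_CHANNELS = ("FP2", "F8")


@dataclass
class ARFit:
    """Fitted AR model: y(i) = sum_j coeffs[j-1] * y(i-j) + n(i)."""

    order: int
    coeffs: np.ndarray
    resid_var: float
    method: str = "burg"

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.size != self.order:
            raise ValueError("coefficient count must equal the order")

    def roots(self) -> np.ndarray:
        """Roots of the characteristic polynomial z^p - phi_1 z^(p-1) - ..."""
        return np.roots(np.r_[1.0, -self.coeffs])

    def is_stationary(self) -> bool:
        return bool(np.all(np.abs(self.roots()) < 1.0))


def burg_fit(x: np.ndarray, p: int) -> ARFit:
    """Burg AR(p) fit (forward/backward prediction-error minimization)."""
    x = np.asarray(x, dtype=float)
    if x.size <= 3 * p:
        raise ValueError(f"need more than {3 * p} samples for order {p}")
    if np.all(x == x[0]):
        raise ValueError("constant input: AR model undefined")
    coeffs, sigma2 = _sm_burg(x, order=p, demean=True)
    fit = ARFit(order=p, coeffs=coeffs, resid_var=float(sigma2), method="burg")
    if not fit.is_stationary():  # Burg guarantees this; guard numerics
        raise AssertionError("Burg fit produced an unstable model")
    return fit


def aic_order(x: np.ndarray, p_max: int) -> int:
    """Order minimizing AIC = N ln(resid_var) + 2p over Burg fits 1..p_max.

    Ties resolve to the smallest order.
    """
    x = np.asarray(x, dtype=float)
    if p_max >= x.size / 3:
        raise ValueError(f"p_max={p_max} too large for {x.size} samples")
    n = x.size
    best_p, best_aic = None, np.inf
    for p in range(1, p_max + 1):
        fit = burg_fit(x, p)
        aic = n * np.log(fit.resid_var) + 2 * p
        if aic < best_aic - 1e-12:
            best_p, best_aic = p, aic
    return int(best_p)


def ar_features(trial: np.ndarray, channel_labels: list[str], p: int = 6,
                channels: tuple[str, ...] = FEATURE_CHANNELS):
    """Burg AR(p) coefficients per frontal channel; 12-dim for p=6.

    Returns ``(values, names)`` ordered channel-major then lag:
    FP2_AR1..FP2_AR6, F8_AR1..F8_AR6.
    """
    labels_lower = [c.lower() for c in channel_labels]
    values, names = [], []
    for ch in channels:
        if ch.lower() not in labels_lower:
            raise KeyError(f"channel {ch!r} not in {channel_labels}")
        x = np.asarray(trial, dtype=float)[labels_lower.index(ch.lower())]
        fit = burg_fit(x, p)
        values.extend(fit.coeffs.tolist())
        names.extend(f"{ch}_AR{j + 1}" for j in range(p))
    return np.asarray(values), names


def ar_feature_matrix(ts: TrialSet, p: int = 6,
                      channels: tuple[str, ...] = FEATURE_CHANNELS) -> FeatureMatrix:
    """Stack :func:`ar_features` over all trials of a set."""
    rows, names = [], None
    for i in range(ts.n_trials):
        v, names = ar_features(ts.trials[i], list(ts.channel_labels), p, channels)
        rows.append(v)
    return FeatureMatrix(np.vstack(rows), names or [], ts.labels)
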