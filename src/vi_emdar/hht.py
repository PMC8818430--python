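"""Hilbert spectral analysis of IMFs and the mean-instantaneous-energy features.

Each IMF c_j(t) is promoted to its analytic signal z_j(t) = c_j + i y_j,
with y_j the Hilbert transform of c_j, giving the instantaneous amplitude
a_j(t) = |z_j| and phase theta_j(t) = arg z_j.  The feature used for
classification is the average instantaneous energy mean(a_j^2) per IMF,
computed over the central 80% of samples to discard Hilbert end effects,
for the frontal channels FP2 and F8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .containers import TrialSet, FeatureMatrix
from .emd import SiftConfig, decompose, IMFDecomposition

__all__ = ["AnalyticIMF", "hilbert_analytic", "mean_instantaneous_energy",
           "mean_instantaneous_frequency", "hht_features", "hht_feature_matrix"]

logger = logging.getLogger(__name__)

FEATURE_CHANNELS = ("FP2", "F8")


@dataclass
class AnalyticIMF:
    """An IMF with its Hilbert transform, amplitude and phase."""

    c: np.ndarray
    y: np.ndarray
    a: np.ndarray
    theta: np.ndarray


def hilbert_analytic(c: np.ndarray) -> AnalyticIMF:
    """Analytic signal via the frequency-domain construction.

    Negative frequencies are zeroed and positive ones doubled (scipy's
    ``hilbert``), so ``z = c + i y`` and ``a^2 = c^2 + y^2`` pointwise.
    """
    c = np.asarray(c, dtype=float)
    if c.size < 8:
        raise ValueError("hilbert_analytic needs at least 8 samples")
    z = hilbert(c)
    a = np.abs(z)
    if np.all(c == 0):
        logger.info("all-zero input: instantaneous phase set to 0")
        theta = np.zeros_like(c)
    else:
        theta = np.angle(z)
    return AnalyticIMF(c=c, y=z.imag, a=a, theta=theta)


def _central(x: np.ndarray, central_fraction: float) -> np.ndarray:
    trim = int(round(x.size * (1.0 - central_fraction) / 2.0))
    return x[trim:x.size - trim] if trim > 0 else x


def mean_instantaneous_energy(a: np.ndarray, central_fraction: float = 0.8,
                              semantics: str = "energy") -> float:
    """Average instantaneous energy of an amplitude envelope.

    ``semantics='energy'`` (default) returns mean(a^2); ``'amplitude'``
    returns mean(a), the alternative reading of "average instantaneous
    energy of the amplitude".
    """
    a = np.asarray(a, dtype=float)
    if a.size == 0:
        raise ValueError("empty amplitude sequence")
    core = _central(a, central_fraction)
    if semantics == "energy":
        return float(np.mean(core ** 2))
    if semantics == "amplitude":
        return float(np.mean(core))
    raise ValueError(f"unknown semantics {semantics!r}")


def mean_instantaneous_frequency(c: np.ndarray, fs: float,
                                 central_fraction: float = 0.8) -> float:
    """Mean instantaneous frequency (Hz) from the unwrapped phase slope.

    Diagnostic used to check the high-to-low spectral ordering of IMFs.
    """
    ana = hilbert_analytic(c)
    phase = np.unwrap(ana.theta)
    dphi = _central(np.diff(phase), central_fraction)
    return float(np.mean(dphi) * fs / (2 * np.pi))


def hht_features(trial: np.ndarray, channel_labels: list[str],
                 channels: tuple[str, ...] = FEATURE_CHANNELS,
                 k_imfs: int = 4, sift_cfg: SiftConfig | None = None,
                 central_fraction: float = 0.8, semantics: str = "energy",
                 decomps: dict[str, IMFDecomposition] | None = None):
    """Mean-instantaneous-energy feature vector for one trial.

    For each requested channel the signal is EMD-decomposed, the first
    ``k_imfs`` IMFs are Hilbert-transformed, and one average energy per IMF
    is kept (zero-filled when fewer IMFs exist).  Returns
    ``(values, names)`` with names like ``FP2_E1 .. F8_Ek``.

    ``decomps`` may supply precomputed decompositions keyed by channel name
    (the pipeline shares them between feature extractors).
    """
    labels_lower = [c.lower() for c in channel_labels]
    values, names = [], []
    for ch in channels:
        if ch.lower() not in labels_lower:
            raise KeyError(f"channel {ch!r} not in {channel_labels}")
        x = np.asarray(trial, dtype=float)[labels_lower.index(ch.lower())]
        if decomps is not None and ch in decomps:
            dec = decomps[ch]
        elif np.all(x == 0):
            dec = None
        else:
            dec = decompose(x, sift_cfg, input_ref=ch)
        for j in range(k_imfs):
            if dec is not None and j < dec.n:
                a = hilbert_analytic(dec.imfs[j]).a
                e = mean_instantaneous_energy(a, central_fraction, semantics)
            else:
                e = 0.0
            values.append(e)
            names.append(f"{ch}_E{j + 1}")
    return np.asarray(values), names


def hht_feature_matrix(ts: TrialSet, channels: tuple[str, ...] = FEATURE_CHANNELS,
                       k_imfs: int = 4, sift_cfg: SiftConfig | None = None,
                       decomps_per_trial: list[dict[str, IMFDecomposition]] | None = None,
                       ) -> FeatureMatrix:
    """Stack :func:`hht_features` over all trials of a set."""
    rows, names = [], None
    for i in range(ts.n_trials):
        dec = decomps_per_trial[i] if decomps_per_trial is not None else None
        v, names = hht_features(ts.trials[i], list(ts.channel_labels), channels,
                                k_imfs, sift_cfg, decomps=dec)
        rows.append(v)
    return FeatureMatrix(np.vstack(rows), names or [], ts.labels)
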