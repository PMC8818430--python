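"""Hybrid EMD + AR feature extraction (the study's headline method).

Each frontal-channel epoch is EMD-decomposed; the IMF count is made common
across trials by zero-padding; each IMF is energy-normalized to unit L2
energy; and a least-squares AR model in the convention

    c_i(t) + sum_k h_ik c_i(t-k) = e_i(t)

is fitted to each normalized IMF.  The per-IMF eigenvector is
A_i = {h_i1..h_im, e_i^2}; class-template eigenvectors average A_i over a
class's training trials.  IMF screening ranks IMFs by variance
contribution rate and correlation with the original signal; the first four
IMFs carry the bulk of the variance, so ``k_imfs`` defaults to 4.

Note the sign convention: these ``h`` coefficients are the negatives of
the phi coefficients of :mod:`vi_emdar.ar` (y(i) = sum phi_j y(i-j) + n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import TrialSet, FeatureMatrix
from .emd import SiftConfig, decompose, IMFDecomposition

__all__ = [
    "IMFAREigenvector", "TemplateEigenvector", "IMFScreenReport",
    "energy_normalize", "pad_imf_count", "fpe_order", "ls_ar_fit",
    "screen_imfs", "emdar_features", "emdar_feature_matrix", "class_templates",
]

logger = logging.getLogger(__name__)

FEATURE_CHANNELS = ("FP2", "F8")


@dataclass
class IMFAREigenvector:
    """Least-squares AR eigenvector of one IMF: h_i1..h_im plus e_i^2."""

    imf_index: int
    h: np.ndarray
    e2: float
    m: int
    padded: bool = False

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if self.h.size != self.m:
            raise ValueError("h length must equal the order m")
        if self.e2 < 0:
            raise ValueError("residual variance must be >= 0")


@dataclass
class TemplateEigenvector:
    """Class-wise mean eigenvector of one IMF slot."""

    class_label: str
    imf_index: int
    h_bar: np.ndarray
    e2_bar: float


@dataclass
class IMFScreenReport:
    """Variance contribution rates (%) and correlations used for IMF screening."""

    contribution_pct: np.ndarray
    correlation: np.ndarray
    selected: list[int]

    def __post_init__(self) -> None:
        self.contribution_pct = np.asarray(self.contribution_pct, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)


def energy_normalize(c: np.ndarray, dt: float = 1.0, literal: bool = False) -> np.ndarray:
    """Normalize an IMF to unit discrete energy sum(c^2) dt = 1.

    Division is by the L2 norm sqrt(sum(c^2) dt); ``literal=True`` divides
    by the energy itself instead (the non-root variant, exposed for
    comparison).  An all-zero IMF (a zero-padded slot) is returned
    unchanged.
    """
    c = np.asarray(c, dtype=float)
    energy = float(np.sum(c ** 2) * dt)
    if energy == 0.0:
        logger.debug("energy_normalize: all-zero IMF left unchanged")
        return c
    return c / energy if literal else c / np.sqrt(energy)


def pad_imf_count(decomps: list[IMFDecomposition]) -> list[IMFDecomposition]:
    """Zero-pad every decomposition to the maximum IMF count of the batch."""
    if not decomps:
        raise ValueError("empty decomposition list")
    n = max(d.n for d in decomps)
    out = []
    for d in decomps:
        if d.n == n:
            out.append(d)
            continue
        zeros = [np.zeros_like(d.residual) for _ in range(n - d.n)]
        out.append(IMFDecomposition(list(d.imfs) + zeros, d.residual,
                                    list(d.sift_counts) + [0] * (n - d.n),
                                    d.input_ref))
    return out


def _lag_design(c: np.ndarray, m: int):
    """Design matrix of lagged values c(t-1..t-m) and target c(t)."""
    n = c.size
    rows = n - m
    X = np.empty((rows, m))
    for k in range(1, m + 1):
        X[:, k - 1] = c[m - k:n - k]
    return X, c[m:]


def ls_ar_fit(c: np.ndarray, m: int, imf_index: int = 0) -> IMFAREigenvector:
    """Ordinary least-squares fit of c(t) + sum_k h_k c(t-k) = e(t).

    Regresses -c(t) on the m lagged values; e2 is the mean squared
    residual.  A zero-padded (all-zero) IMF short-circuits to h = 0,
    e2 = 0 by convention.
    """
    c = np.asarray(c, dtype=float)
    if np.all(c == 0):
        return IMFAREigenvector(imf_index, np.zeros(m), 0.0, m, padded=True)
    if c.size <= 3 * m:
        raise ValueError(f"need more than {3 * m} samples for order {m}")
    X, y = _lag_design(c, m)
    # h solves min ||y + X h||^2  <=>  h = -lstsq(X, y)
    sol, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < m:
        raise ValueError("singular lag design (constant or degenerate input)")
    h = -sol
    resid = y + X @ h
    e2 = float(np.mean(resid ** 2))
    return IMFAREigenvector(imf_index, h, e2, m)


def fpe_order(c: np.ndarray, m_max: int) -> int:
    """Order minimizing the final prediction error over least-squares fits.

    FPE(m) = resid_var(m) * (N + m + 1) / (N - m - 1); ties resolve to the
    smallest order.
    """
    c = np.asarray(c, dtype=float)
    if m_max >= c.size / 3:
        raise ValueError(f"m_max={m_max} too large for {c.size} samples")
    n = c.size
    best_m, best_fpe = None, np.inf
    for m in range(1, m_max + 1):
        fit = ls_ar_fit(c, m)
        fpe = fit.e2 * (n + m + 1) / (n - m - 1)
        if fpe < best_fpe - 1e-15:
            best_m, best_fpe = m, fpe
    return int(best_m)


def screen_imfs(decomp: IMFDecomposition, x: np.ndarray,
                cum_threshold_pct: float = 95.0, min_select: int = 4) -> IMFScreenReport:
    """Rank IMFs by variance contribution rate and correlation with x.

    Contribution of IMF i is var(c_i) / sum_k var(c_k) * 100 (residual
    excluded).  The selected set is the smallest IMF prefix whose
    cumulative contribution reaches ``cum_threshold_pct``, but never fewer
    than ``min_select`` (when that many exist).
    """
    x = np.asarray(x, dtype=float)
    if decomp.n == 0:
        return IMFScreenReport(np.array([]), np.array([]), [])
    variances = np.array([np.var(c) for c in decomp.imfs])
    total = variances.sum()
    contrib = variances / total * 100.0 if total > 0 else np.zeros_like(variances)
    corr = np.array([
        np.corrcoef(c, x)[0, 1] if np.std(c) > 0 and np.std(x) > 0 else 0.0
        for c in decomp.imfs
    ])
    cum = np.cumsum(contrib)
    k = int(np.searchsorted(cum, cum_threshold_pct - 1e-12) + 1)
    k = min(max(k, min_select), decomp.n)
    return IMFScreenReport(contrib, corr, list(range(1, k + 1)))


def emdar_features(trial: np.ndarray, channel_labels: list[str],
                   channels: tuple[str, ...] = FEATURE_CHANNELS,
                   k_imfs: int = 4, m: int | str = 4,
                   sift_cfg: SiftConfig | None = None, dt: float = 1.0,
                   decomps: dict[str, IMFDecomposition] | None = None):
    """EMD+AR feature vector for one trial.

    Per channel: decompose, keep the first ``k_imfs`` IMFs (zero-padding
    missing slots), energy-normalize each, least-squares AR fit each
    (fixed order ``m``, or per-IMF FPE selection when ``m='fpe'``), and
    concatenate [h_i1..h_im, e_i^2] blocks across IMFs then channels.
    Returns ``(values, names, padded_flags)``.
    """
    labels_lower = [c.lower() for c in channel_labels]
    values, names, padded = [], [], []
    fixed_m = None if m == "fpe" else int(m)
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
        for i in range(k_imfs):
            c = dec.imfs[i] if dec is not None and i < dec.n else np.zeros_like(
                np.asarray(x))
            cbar = energy_normalize(c, dt)
            order = fixed_m
            if order is None:
                order = fpe_order(cbar, 10) if np.any(cbar) else 1
                logger.debug("FPE order for %s IMF%d: %d", ch, i + 1, order)
            ev = ls_ar_fit(cbar, order, imf_index=i + 1)
            block = np.r_[ev.h, ev.e2]
            if fixed_m is not None and ev.m != fixed_m:  # cannot happen; guard
                raise AssertionError("order mismatch")
            values.extend(block.tolist())
            names.extend([f"{ch}_IMF{i + 1}_h{k + 1}" for k in range(ev.m)]
                         + [f"{ch}_IMF{i + 1}_e2"])
            padded.append(ev.padded)
    return np.asarray(values), names, padded


def emdar_feature_matrix(ts: TrialSet, channels: tuple[str, ...] = FEATURE_CHANNELS,
                         k_imfs: int = 4, m: int | str = 4,
                         sift_cfg: SiftConfig | None = None,
                         decomps_per_trial: list[dict[str, IMFDecomposition]] | None = None,
                         ) -> FeatureMatrix:
    """Stack :func:`emdar_features` over all trials of a set."""
    dt = 1.0 / ts.fs
    rows, names = [], None
    for i in range(ts.n_trials):
        dec = decomps_per_trial[i] if decomps_per_trial is not None else None
        v, names, _ = emdar_features(ts.trials[i], list(ts.channel_labels),
                                     channels, k_imfs, m, sift_cfg, dt, decomps=dec)
        rows.append(v)
    return FeatureMatrix(np.vstack(rows), names or [], ts.labels)


def class_templates(features: FeatureMatrix) -> list[TemplateEigenvector]:
    """Class-wise mean eigenvectors per IMF slot (training data only).

    Groups feature columns by their ``<CH>_IMF<i>_`` prefix and averages
    each class's rows.  Raises on a class with zero samples.
    """
    prefixes: list[str] = []
    for name in features.names:
        pre = name.rsplit("_", 1)[0]
        if pre not in prefixes:
            prefixes.append(pre)
    from .containers import CLASSES

    out = []
    for cls in CLASSES:
        mask = features.labels == cls
        if not mask.any():
            raise ValueError(f"class {cls!r} has no samples")
        mean_row = features.X[mask].mean(axis=0)
        for pre in prefixes:
            imf_i = int(pre.rsplit("IMF", 1)[1]) if "IMF" in pre else 0
            cols_h = [j for j, n in enumerate(features.names)
                      if n.startswith(pre + "_h")]
            cols_e = [j for j, n in enumerate(features.names)
                      if n == pre + "_e2"]
            out.append(TemplateEigenvector(
                class_label=cls, imf_index=imf_i,
                h_bar=mean_row[cols_h], e2_bar=float(mean_row[cols_e[0]])))
    return out
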