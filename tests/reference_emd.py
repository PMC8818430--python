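"""Minimal reference empirical mode decomposition used as a cross-check oracle.

This is a deliberately independent, synthetic stand-in reference
implementation written for the test suite only: it shares no code with
``vi_emdar.emd`` and takes different implementation routes throughout —
extrema via ``scipy.signal.argrelextrema`` (no plateau handling),
envelopes via ``InterpolatedUnivariateSpline`` with the signal endpoints
appended as knots (no mirror extension), and sifting stopped purely by the
standard Cauchy criterion sum((h_prev-h)^2)/sum(h_prev^2) < 0.2.
Agreement between the two routes on IMF count (+/-1) and per-IMF
correlation is a correctness check for both.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import InterpolatedUnivariateSpline
from scipy.signal import argrelextrema


def _envelope(x: np.ndarray, comparator) -> np.ndarray | None:
    n = x.size
    idx = argrelextrema(x, comparator)[0]
    if idx.size < 2:
        return None
    # Clamp the spline with the signal's endpoints as extra knots.
    t = np.r_[0, idx, n - 1].astype(float)
    v = np.r_[x[0], x[idx], x[n - 1]]
    t, uniq = np.unique(t, return_index=True)
    return InterpolatedUnivariateSpline(t, v[uniq], k=3)(np.arange(n))


def reference_emd(x: np.ndarray, sd_stop: float = 0.2, max_sifts: int = 50,
                  max_imfs: int = 16) -> list[np.ndarray]:
    """Decompose ``x``; returns [imf_1, ..., imf_n, residual]."""
    x = np.asarray(x, dtype=float)
    imfs: list[np.ndarray] = []
    residual = x.copy()
    while len(imfs) < max_imfs:
        n_ext = (argrelextrema(residual, np.greater)[0].size
                 + argrelextrema(residual, np.less)[0].size)
        if n_ext < 3:
            break
        h = residual
        for _ in range(max_sifts):
            upper = _envelope(h, np.greater)
            lower = _envelope(h, np.less)
            if upper is None or lower is None:
                break
            m = 0.5 * (upper + lower)
            h_new = h - m
            sd = np.sum((h - h_new) ** 2) / np.sum(h ** 2)
            h = h_new
            if sd < sd_stop:
                break
        imfs.append(h)
        residual = residual - h
    return imfs + [residual]
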