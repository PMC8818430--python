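"""Empirical mode decomposition by cubic-spline envelope sifting.

The signal x(t) is sifted into intrinsic mode functions (IMFs): at each
sift the upper and lower envelopes are cubic splines through the local
maxima and minima, their midline m is subtracted, and the process repeats
until the candidate satisfies the IMF admissibility conditions (extrema
and zero-crossing counts equal or differing by one; envelope midline
locally symmetric about zero) or the Cauchy-type stopping criterion
SD = sum((h_prev - h)^2) / sum(h_prev^2) falls below ``sd_threshold``.
Successive IMFs c_1..c_n are peeled off the residual until it is monotone
(or has fewer than two interior extrema), leaving a residual r_n with

    x(t) = sum_j c_j(t) + r_n(t)

exact up to floating point, which :func:`decompose` asserts.

Numerical choices
-----------------
* Envelopes are natural cubic splines; the two extrema nearest each end
  are mirrored outside the support to suppress end swings.
* Flat plateaus (runs of samples equal within ``extrema_tol``) count as a
  single extremum at the plateau midpoint.
* Zero crossings are sign changes between consecutive samples; an exact
  zero sample (or a zero run) counts once.
* ``max_imfs`` (default 12) caps over-decomposition of noise; reaching the
  cap logs a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "SiftConfig",
    "IMFDecomposition",
    "EnvelopeError",
    "MonotoneSignalError",
    "find_extrema",
    "spline_envelope",
    "sift_once",
    "zero_crossings",
    "is_imf",
    "extract_imf",
    "decompose",
]

logger = logging.getLogger(__name__)


class EnvelopeError(ValueError):
    """Fewer than two usable extrema: no envelope can be fitted."""


class MonotoneSignalError(ValueError):
    """Signal is monotone; no IMF can be extracted."""


@dataclass
class SiftConfig:
    """Sifting parameters (the stopping rule is not part of the IMF definition,
    so it is configurable; defaults follow common practice)."""

    sd_threshold: float = 0.2
    max_sifts: int = 100
    max_imfs: int = 12
    boundary: str = "mirror"
    extrema_tol: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be > 0")
        if self.max_sifts < 1:
            raise ValueError("max_sifts must be >= 1")
        if self.boundary != "mirror":
            raise ValueError("only 'mirror' boundary extension is implemented")


@dataclass
class IMFDecomposition:
    """Ordered IMFs plus residual for one signal."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    sift_counts: list[int] = field(default_factory=list)
    input_ref: str = ""

    @property
    def n(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for c in self.imfs:
            out += c
        return out


def find_extrema(x: np.ndarray, extrema_tol: float = 0.0):
    """Locate strict interior maxima and minima.

    Runs of consecutive samples equal within ``extrema_tol`` are collapsed
    to their midpoint so a flat plateau yields one extremum.  Returns
    ``(max_idx, max_val, min_idx, min_val)`` with strictly increasing
    indices.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("find_extrema needs at least 3 samples")
    d = np.diff(x)
    same = np.abs(d) <= extrema_tol if extrema_tol > 0 else d == 0
    # Run-length compress near-equal neighbours; keep the run start value.
    starts = np.flatnonzero(np.r_[True, ~same])
    ends = np.r_[starts[1:] - 1, x.size - 1]
    mids = (starts + ends) // 2
    y = x[starts]
    if y.size < 3:
        empty = np.array([], dtype=int), np.array([])
        return (*empty, *empty)
    dy = np.diff(y)
    rising = dy > 0
    is_max = rising[:-1] & ~rising[1:]
    is_min = ~rising[:-1] & rising[1:]
    max_pos = np.flatnonzero(is_max) + 1
    min_pos = np.flatnonzero(is_min) + 1
    return mids[max_pos], y[max_pos], mids[min_pos], y[min_pos]


def _mirror_extend(idx: np.ndarray, val: np.ndarray, length: int):
    """Reflect up to two extrema about each end of the support."""
    left_t = 2 * 0 - idx[:2][::-1]
    left_v = val[:2][::-1]
    right_t = 2 * (length - 1) - idx[-2:][::-1]
    right_v = val[-2:][::-1]
    t = np.r_[left_t, idx, right_t].astype(float)
    v = np.r_[left_v, val, right_v]
    # Drop any non-increasing knots introduced by extrema at the ends.
    keep = np.r_[True, np.diff(t) > 0]
    return t[keep], v[keep]


def spline_envelope(idx: np.ndarray, val: np.ndarray, length: int,
                    boundary: str = "mirror") -> np.ndarray:
    """Natural cubic spline through the (mirror-extended) extrema.

    Evaluated at every sample ``0..length-1``; passes through each interior
    extremum exactly.
    """
    idx = np.asarray(idx, dtype=int)
    val = np.asarray(val, dtype=float)
    if idx.size < 1 or (idx.size == 1 and not 0 < idx[0] < length - 1):
        raise EnvelopeError(f"need >= 2 extrema after extension, got {idx.size}")
    if boundary != "mirror":
        raise ValueError("only 'mirror' boundary extension is implemented")
    t, v = _mirror_extend(idx, val, length)
    if t.size < 2:
        raise EnvelopeError("fewer than 2 usable knots after extension")
    if t.size == 2:
        # A natural spline through two knots is the straight line.
        slope = (v[1] - v[0]) / (t[1] - t[0])
        return v[0] + slope * (np.arange(length) - t[0])
    return CubicSpline(t, v, bc_type="natural")(np.arange(length))


def sift_once(h: np.ndarray, cfg: SiftConfig | None = None):
    """One sifting step: subtract the mean of the upper and lower envelopes.

    Returns ``(h_next, m)`` with ``h_next = h - m`` exactly.
    """
    cfg = cfg or SiftConfig()
    mx_i, mx_v, mn_i, mn_v = find_extrema(h, cfg.extrema_tol)
    if mx_i.size < 1 or mn_i.size < 1 or mx_i.size + mn_i.size < 2:
        raise EnvelopeError(
            f"too few extrema to sift (maxima {mx_i.size}, minima {mn_i.size})")
    upper = spline_envelope(mx_i, mx_v, len(h), cfg.boundary)
    lower = spline_envelope(mn_i, mn_v, len(h), cfg.boundary)
    m = 0.5 * (upper + lower)
    return h - m, m


def zero_crossings(x: np.ndarray) -> int:
    """Count sign changes; an exact zero sample (or zero run) counts once."""
    s = np.sign(np.asarray(x, dtype=float))
    nz = s[s != 0]
    if nz.size < 2:
        return 0
    crossings = int(np.count_nonzero(nz[1:] * nz[:-1] < 0))
    # Zero runs flanked by equal signs touch the axis: count each once.
    zero = s == 0
    if zero.any():
        starts = np.flatnonzero(zero & np.r_[True, ~zero[:-1]])
        for st in starts:
            en = st
            while en + 1 < s.size and s[en + 1] == 0:
                en += 1
            if st > 0 and en < s.size - 1 and s[st - 1] == s[en + 1]:
                crossings += 1
    return crossings


def is_imf(c: np.ndarray, extrema_tol: float = 0.0,
           midline_ratio_max: float = 0.05):
    """IMF admissibility test.

    True iff (1) the numbers of extrema and zero crossings differ by at most
    one and (2) the mean absolute envelope midline over the central 80% of
    samples is below ``midline_ratio_max`` times RMS(c) (local symmetry
    about the time axis).  Returns ``(ok, diagnostics)``.
    """
    c = np.asarray(c, dtype=float)
    diag: dict = {}
    if c.size < 3:
        return False, {"reason": "too short"}
    mx_i, mx_v, mn_i, mn_v = find_extrema(c, extrema_tol)
    n_ext = mx_i.size + mn_i.size
    n_zc = zero_crossings(c)
    diag["n_extrema"] = n_ext
    diag["n_zero_crossings"] = n_zc
    if abs(n_ext - n_zc) > 1:
        diag["reason"] = "extrema/zero-crossing counts differ by more than 1"
        return False, diag
    if mx_i.size < 2 or mn_i.size < 2:
        diag["reason"] = "too few extrema for envelopes"
        return False, diag
    upper = spline_envelope(mx_i, mx_v, c.size)
    lower = spline_envelope(mn_i, mn_v, c.size)
    m = 0.5 * (upper + lower)
    lo, hi = c.size // 10, c.size - c.size // 10
    rms = np.sqrt(np.mean(c ** 2))
    midline = float(np.mean(np.abs(m[lo:hi])))
    diag["midline_ratio"] = midline / rms if rms > 0 else np.inf
    ok = rms > 0 and midline < midline_ratio_max * rms
    if not ok:
        diag["reason"] = "envelope midline not symmetric about zero"
    return ok, diag


def _n_interior_extrema(x: np.ndarray, tol: float = 0.0) -> int:
    try:
        mx_i, _, mn_i, _ = find_extrema(x, tol)
    except ValueError:
        return 0
    return mx_i.size + mn_i.size


def extract_imf(x: np.ndarray, cfg: SiftConfig | None = None):
    """Sift one IMF out of ``x``; returns ``(c, sift_count)``.

    Stops at the first of: IMF admissibility, Cauchy criterion
    SD < ``sd_threshold``, or ``max_sifts`` iterations.
    """
    cfg = cfg or SiftConfig()
    x = np.asarray(x, dtype=float)
    if _n_interior_extrema(x, cfg.extrema_tol) == 0:
        raise MonotoneSignalError("input has no interior extrema (monotone)")
    h = x
    count = 0
    for _ in range(cfg.max_sifts):
        try:
            h_next, m = sift_once(h, cfg)
        except EnvelopeError:
            if count == 0:
                raise  # nothing could be sifted: leave content in the residual
            break  # cannot refine further; current h is the component
        count += 1
        denom = float(np.sum(h ** 2))
        sd = float(np.sum((h - h_next) ** 2)) / denom if denom > 0 else 0.0
        h = h_next
        if sd < cfg.sd_threshold:
            break
        ok, _ = is_imf(h, cfg.extrema_tol)
        if ok:
            break
    return h, count


def decompose(x: np.ndarray, cfg: SiftConfig | None = None,
              input_ref: str = "") -> IMFDecomposition:
    """Full EMD of ``x`` into IMFs plus a monotone (or near-extremum-free)
    residual.  The additive reconstruction is exact by construction and is
    asserted to 1e-9 relative tolerance."""
    cfg = cfg or SiftConfig()
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ValueError("decompose needs at least 16 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")

    imfs: list[np.ndarray] = []
    counts: list[int] = []
    residual = x.copy()
    energy_floor = 1e-12 * float(np.sum(x ** 2))
    while len(imfs) < cfg.max_imfs:
        if _n_interior_extrema(residual, cfg.extrema_tol) < 2:
            break
        try:
            c, k = extract_imf(residual, cfg)
        except (MonotoneSignalError, EnvelopeError):
            break
        if float(np.sum(c ** 2)) <= energy_floor:
            # machine-noise residue, not a mode: fold back and stop
            break
        if zero_crossings(c) < 2:
            # trend-like component, not an oscillatory mode: keep in residual
            break
        imfs.append(c)
        counts.append(k)
        residual = residual - c
    else:
        logger.warning("max_imfs=%d reached; residual may still be oscillatory",
                       cfg.max_imfs)

    dec = IMFDecomposition(imfs, residual, counts, input_ref)
    scale = np.max(np.abs(x)) or 1.0
    err = np.max(np.abs(x - dec.reconstruct()))
    if err > 1e-9 * scale:
        raise AssertionError(f"reconstruction error {err:.3e} exceeds tolerance")
    return dec
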