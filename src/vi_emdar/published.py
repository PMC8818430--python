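"""Published summary tables of the original visual-imagery EEG study.

The raw recordings behind these numbers are not publicly deposited, so the
printed tables act as fixed reference inputs: the IMF screening table
(variance contribution rates and correlations of the eight IMFs), the
per-method accuracy summary, and the accuracies of earlier visual-imagery
BCI studies used for cross-study comparison.  Functions here perform only
arithmetic on those published values.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "IMF_VARIANCE_CONTRIBUTION_PCT", "IMF_CORRELATION",
    "METHOD_SUMMARY", "PRIOR_STUDY_ACCURACY",
    "first_k_contribution_sum", "method_mean_differences",
    "cross_study_differences",
]

# IMF screening table: one value per IMF component 1..8.
IMF_VARIANCE_CONTRIBUTION_PCT = np.array(
    [57.1652, 17.5349, 14.1053, 7.3225, 1.4372, 1.0732, 0.7628, 0.5989])
IMF_CORRELATION = np.array(
    [0.7526, 0.4932, 0.4021, 0.2136, 0.0034, 0.0023, 0.0013, 0.0006])

# Per-method accuracy summary over the 18 subjects (percent).
METHOD_SUMMARY = {
    "hht": {"mean": 68.14, "se": 3.06, "max": 78.33, "min": 53.33},
    "ar": {"mean": 56.29, "se": 2.73, "max": 71.67, "min": 30.0},
    "emdar": {"mean": 78.40, "se": 2.07, "max": 87.0, "min": 48.33},
}

# Mean accuracies of earlier visual-imagery BCI studies (percent).
PRIOR_STUDY_ACCURACY = {
    "kosmyna": 52.0,
    "neuper": 56.0,
    "koizumi": 84.6,
    "sousa": 87.64,
}


def first_k_contribution_sum(k: int = 4) -> float:
    """Summed variance contribution of the first k IMFs (percent)."""
    return float(IMF_VARIANCE_CONTRIBUTION_PCT[:k].sum())


def method_mean_differences() -> dict[str, float]:
    """Pairwise differences among the three methods' mean accuracies."""
    m = {k: v["mean"] for k, v in METHOD_SUMMARY.items()}
    return {
        "hht_minus_ar": m["hht"] - m["ar"],
        "emdar_minus_hht": m["emdar"] - m["hht"],
        "emdar_minus_ar": m["emdar"] - m["ar"],
    }


def cross_study_differences() -> dict[str, float]:
    """EMD+AR mean accuracy minus each earlier study's accuracy (percent).

    Positive values mean the hybrid outperformed that study's reported
    accuracy; negative values mean it fell short.
    """
    ours = METHOD_SUMMARY["emdar"]["mean"]
    return {f"vs_{name}": ours - acc for name, acc in PRIOR_STUDY_ACCURACY.items()}
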