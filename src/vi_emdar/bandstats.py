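"""Per-band, per-channel class statistics between the two imagery tasks.

Band power is estimated from a Hann-tapered periodogram of each epoch and
integrated over the band's frequency bins.  For every (channel, band) cell
a two-sided Welch t-test compares the two imagery classes; per channel, a
balanced two-way fixed-effects ANOVA (task x band) on band power reports
the task-effect p-value and its degrees of freedom.  These statistics run
on the broadband (notch-only) signal path: applying the 8-13 Hz band-pass
first would annihilate every non-alpha band.

Band edges are conventional and configurable: delta 0.5-4, theta 4-8,
alpha 8-13, beta 13-30, gamma 30-80 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .containers import TrialSet, CLASSES

__all__ = ["BandDefinition", "DEFAULT_BANDS", "band_power", "band_power_table",
           "class_ttest", "band_anova", "band_stats_table"]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"invalid band {self.name}: [{self.low_hz}, {self.high_hz}]")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 80.0),
)


def band_power(x: np.ndarray, fs: float, band: BandDefinition) -> float:
    """Power (µV²) of one epoch in one band, by Hann-tapered periodogram.

    The power spectral density is integrated over the band's bins, so a
    unit-amplitude in-band sinusoid yields ~0.5 µV².
    """
    if band.high_hz >= fs / 2:
        raise ValueError(f"band {band.name} upper edge {band.high_hz} >= Nyquist {fs / 2}")
    f, pxx = signal.periodogram(np.asarray(x, dtype=float), fs=fs, window="hann",
                                detrend="constant")
    mask = (f >= band.low_hz) & (f < band.high_hz)
    df = f[1] - f[0]
    return float(np.sum(pxx[mask]) * df)


def band_power_table(ts: TrialSet, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                     ) -> pd.DataFrame:
    """Long-format table of band power per (trial, channel, band)."""
    rows = []
    for i in range(ts.n_trials):
        for ci, ch in enumerate(ts.channel_labels):
            for band in bands:
                rows.append({
                    "trial": i, "class": ts.labels[i], "channel": ch,
                    "band": band.name,
                    "power": band_power(ts.trials[i, ci], ts.fs, band),
                })
    return pd.DataFrame(rows)


def class_ttest(powers_a: np.ndarray, powers_b: np.ndarray) -> float:
    """Two-sided Welch t-test p-value between the two classes' band powers."""
    a = np.asarray(powers_a, dtype=float)
    b = np.asarray(powers_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per group")
    if a.std() == 0 and b.std() == 0:
        if np.mean(a) == np.mean(b):
            return 1.0
        raise ValueError("degenerate (zero-variance) groups with different means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def band_anova(table: pd.DataFrame, channel: str):
    """Balanced two-way fixed-effects ANOVA (task x band) for one channel.

    Direct sum-of-squares decomposition on the long-format band-power table;
    returns ``(p_task, df_task)`` with df_task = (number of classes) - 1.
    """
    sub = table[table["channel"] == channel]
    classes = sorted(sub["class"].unique())
    bands = sorted(sub["band"].unique())
    counts = sub.groupby(["class", "band"])["power"].count()
    if counts.nunique() != 1 or len(counts) != len(classes) * len(bands):
        missing = [(c, b) for c in classes for b in bands if (c, b) not in counts.index]
        raise ValueError(f"unbalanced design; missing or uneven cells: {missing or dict(counts)}")
    y = sub["power"].to_numpy()
    grand = y.mean()
    n_rep = int(counts.iloc[0])
    a, b = len(classes), len(bands)
    ss_task = sum((sub[sub["class"] == c]["power"].mean() - grand) ** 2
                  for c in classes) * b * n_rep
    ss_band = sum((sub[sub["band"] == bb]["power"].mean() - grand) ** 2
                  for bb in bands) * a * n_rep
    ss_cells = sum(
        (sub[(sub["class"] == c) & (sub["band"] == bb)]["power"].mean() - grand) ** 2
        for c in classes for bb in bands) * n_rep
    ss_inter = ss_cells - ss_task - ss_band
    ss_total = float(np.sum((y - grand) ** 2))
    ss_err = ss_total - ss_cells
    df_task = a - 1
    df_err = a * b * (n_rep - 1)
    ms_task = ss_task / df_task
    ms_err = ss_err / df_err
    f_stat = ms_task / ms_err if ms_err > 0 else np.inf
    p = float(stats.f.sf(f_stat, df_task, df_err))
    return p, df_task


def band_stats_table(ts: TrialSet, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                     fdr: bool = False) -> pd.DataFrame:
    """Channels x bands table of Welch p-values plus per-channel ANOVA columns.

    ``fdr=True`` applies Benjamini-Hochberg across the t-test cells (off by
    default: the original analysis reports uncorrected p-values).
    """
    powers = band_power_table(ts, bands)
    rows = []
    for ch in ts.channel_labels:
        row: dict = {"channel": ch}
        for band in bands:
            cell = powers[(powers["channel"] == ch) & (powers["band"] == band.name)]
            grp = [cell[cell["class"] == c]["power"].to_numpy() for c in CLASSES]
            row[band.name] = class_ttest(grp[0], grp[1])
        p_task, df_task = band_anova(powers, ch)
        row["anova_df"] = df_task
        row["anova_p"] = p_task
        rows.append(row)
    out = pd.DataFrame(rows).set_index("channel")
    if fdr:
        band_cols = [b.name for b in bands]
        flat = out[band_cols].to_numpy().ravel()
        adj = stats.false_discovery_control(flat, method="bh")
        out[band_cols] = adj.reshape(out[band_cols].shape)
    return out
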