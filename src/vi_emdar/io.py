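"""Reading and writing datasets, features and reports.

Datasets are stored as one delimited numeric matrix per trial (sample rows
x channel columns, header row of channel labels), a ``labels.csv`` file
(trial_id, class) and a JSON sidecar with the generator configuration and
sampling metadata.  EDF recordings are read through MNE when available.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EEGRecording, TrialSet, FeatureMatrix

__all__ = ["write_dataset", "read_dataset", "read_edf",
           "write_features", "read_features"]


def write_dataset(ts: TrialSet, out_dir: str | Path) -> Path:
    """Write a trial set: trial_XXXX.csv per trial + labels.csv + meta.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i in range(ts.n_trials):
        df = pd.DataFrame(ts.trials[i].T, columns=list(ts.channel_labels))
        df.to_csv(out / f"trial_{i:04d}.csv", index=False, float_format="%.6g")
    pd.DataFrame({"trial_id": np.arange(ts.n_trials), "class": ts.labels}
                 ).to_csv(out / "labels.csv", index=False)
    meta = {"fs": ts.fs, "channel_labels": list(ts.channel_labels),
            "window": list(ts.window), **ts.meta}
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return out


def read_dataset(in_dir: str | Path) -> TrialSet:
    """Read a trial set written by :func:`write_dataset`."""
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    labels_df = pd.read_csv(src / "labels.csv")
    trials = []
    for tid in labels_df["trial_id"]:
        df = pd.read_csv(src / f"trial_{tid:04d}.csv")
        trials.append(df.to_numpy().T)
    ts = TrialSet(np.stack(trials), labels_df["class"].to_numpy(),
                  fs=meta["fs"], channel_labels=meta["channel_labels"],
                  window=tuple(meta["window"]))
    ts.meta = {k: v for k, v in meta.items()
               if k not in ("fs", "channel_labels", "window")}
    return ts


def read_edf(path: str | Path, expected_channels: list[str] | None = None) -> EEGRecording:
    """Read an EDF recording (requires ``mne``).

    Channel labels are matched case-insensitively against
    ``expected_channels`` when given; matching channels are returned in the
    expected order.
    """
    import mne  # deferred: EDF support is optional

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads volts; convert to µV
    labels = list(raw.ch_names)
    if expected_channels is not None:
        lower = [c.lower() for c in labels]
        rows, kept = [], []
        for want in expected_channels:
            if want.lower() in lower:
                rows.append(lower.index(want.lower()))
                kept.append(want)
        if not rows:
            raise ValueError(f"none of {expected_channels} found in {labels}")
        data, labels = data[rows], kept
    return EEGRecording(data, raw.info["sfreq"], labels)


def write_features(fm: FeatureMatrix, path: str | Path) -> Path:
    """Write a feature matrix: header = names, one row per trial, final
    column = class label."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(fm.X, columns=fm.names)
    df["label"] = fm.labels
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_features(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    labels = df.pop("label").to_numpy()
    return FeatureMatrix(df.to_numpy(), list(df.columns), labels)
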