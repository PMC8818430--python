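"""Synthetic two-class visual-imagery EEG generator.

The study's recordings (two imagery tasks, 100 trials each, 8 channels at
1 kHz, 4 s epochs) are not publicly deposited, so this module generates
surrogate trial sets carrying the statistical structure the downstream
analysis assumes: the class difference is confined to the alpha band
(8-13 Hz) of the frontal channels FP2 and F8, riding on 1/f background
noise, 50 Hz line interference and slow drift common to all channels.

Generative model per trial
--------------------------
Every channel receives

* 1/f-shaped Gaussian background noise with standard deviation ``noise_sd``,
* a 50 Hz sinusoid of amplitude ``line_amp`` with a random phase shared
  across channels (line pickup is common-mode),
* a linear drift with per-channel random slope bounded by ``drift_amp``.

FP2 and F8 additionally receive a coherent alpha oscillation at a per-trial
centre frequency drawn from ``alpha_freq_range``, with phase diffusion
giving the rhythm a realistic Lorentzian linewidth (``alpha_linewidth_hz``)
rather than a deterministic sinusoid's zero bandwidth.  Its base amplitude
``A`` is log-normal across trials (alpha power varies strongly trial to
trial in real EEG).  For the *static* class the oscillation's envelope is
constant at ``A``.  For the *moving* class the envelope is
``A (1 + alpha_contrast * s(t))`` where ``s(t)`` is a periodic 0.5 Hz
ramp-and-hold: it ramps linearly 0 -> 1 over the first half of each
modulation period and holds at 1 for the second half — a recurring
nonstationarity meant to mimic imagery of motion engaging frontal alpha.

With ``alpha_contrast = 0`` the two classes are drawn from identical
distributions, which is the null used for calibration tests.

Reproducibility: each trial's random stream is derived from
``(seed, class, trial index)``, so trial ``k`` of a class is unchanged when
``n_trials_per_class`` grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import CHANNELS, CLASSES, TrialSet

__all__ = ["SynthConfig", "generate_trial", "generate_dataset", "inject_artifacts"]


@dataclass
class SynthConfig:
    """Parameters of the synthetic EEG generator (amplitudes in µV)."""

    n_trials_per_class: int = 100
    n_channels: int = 8
    fs: float = 1000.0
    epoch_s: float = 4.0
    alpha_contrast: float = 1.0
    alpha_amp: float = 2.5
    alpha_amp_sigma: float = 0.3
    alpha_freq_range: tuple[float, float] = (9.0, 11.0)
    alpha_linewidth_hz: float = 2.0  # phase-diffusion linewidth of the alpha rhythm
    mod_freq: float = 0.5
    noise_sd: float = 3.0
    noise_exponent: float = 1.0
    acquisition_high_hz: float = 100.0  # amplifier anti-alias low-pass
    line_amp: float = 1.0
    line_freq: float = 50.0
    drift_amp: float = 2.0
    seed: int = 0
    channel_labels: tuple[str, ...] = field(default=CHANNELS)

    def __post_init__(self) -> None:
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if self.n_channels < 1 or self.n_channels > len(self.channel_labels):
            raise ValueError("n_channels out of range for channel_labels")
        n = self.fs * self.epoch_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * epoch_s must be an integer number of samples")
        if self.alpha_contrast < 0:
            raise ValueError("alpha_contrast must be >= 0")

    @property
    def n_samples(self) -> int:
        return round(self.fs * self.epoch_s)

    @property
    def labels(self) -> list[str]:
        return list(self.channel_labels[: self.n_channels])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_labels"] = list(d["channel_labels"])
        d["alpha_freq_range"] = list(d["alpha_freq_range"])
        return d


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                      sd: float, exponent: float,
                      high_hz: float | None = None) -> np.ndarray:
    """Gaussian noise whose amplitude spectrum falls as 1/f^(exponent/2)."""
    white = rng.standard_normal(n)
    if sd == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    if high_hz is not None and high_hz < fs / 2:
        # emulate the amplifier's acquisition band limit (4th-order rolloff)
        shape *= 1.0 / np.sqrt(1.0 + (f / high_hz) ** 8)
    x = np.fft.irfft(spec * shape, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _ramp_hold(t: np.ndarray, mod_freq: float) -> np.ndarray:
    """Periodic ramp-and-hold: ramp 0 -> 1 over the first half of each
    modulation period, hold at 1 for the second half."""
    phase = (mod_freq * t) % 1.0
    return np.clip(2.0 * phase, 0.0, 1.0)


def generate_trial(cfg: SynthConfig, class_label: str,
                   rng: np.random.Generator) -> np.ndarray:
    """Generate one trial as a (channel x sample) matrix in µV.

    ``rng`` is consumed; pass a freshly derived substream for reproducible
    per-trial generation (see :func:`generate_dataset`).
    """
    if class_label not in CLASSES:
        raise ValueError(f"class_label must be one of {CLASSES}, got {class_label!r}")
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    labels = cfg.labels
    data = np.empty((cfg.n_channels, n))

    line_phase = rng.uniform(0, 2 * np.pi)
    line = cfg.line_amp * np.sin(2 * np.pi * cfg.line_freq * t + line_phase)

    for ch in range(cfg.n_channels):
        noise = _one_over_f_noise(rng, n, cfg.fs, cfg.noise_sd, cfg.noise_exponent,
                                  cfg.acquisition_high_hz)
        slope = rng.uniform(-1, 1)
        drift = cfg.drift_amp * slope * (t / cfg.epoch_s - 0.5)
        data[ch] = noise + line + drift

    # Class-dependent alpha oscillation, coherent on FP2 and F8 only.
    f_lo, f_hi = cfg.alpha_freq_range
    f0 = rng.uniform(f_lo, f_hi)
    phi = rng.uniform(0, 2 * np.pi)
    amp = cfg.alpha_amp * np.exp(cfg.alpha_amp_sigma * rng.standard_normal())
    if cfg.alpha_linewidth_hz > 0:
        # Phase diffusion giving the rhythm a Lorentzian linewidth: the
        # per-sample phase increments are N(0, 2*pi*linewidth/fs).
        dphi = rng.standard_normal(n) * np.sqrt(2 * np.pi * cfg.alpha_linewidth_hz / cfg.fs)
        dphi[0] = 0.0
        phase_noise = np.cumsum(dphi)
    else:
        phase_noise = 0.0
    carrier = np.sin(2 * np.pi * f0 * t + phi + phase_noise)
    if class_label == "moving":
        envelope = amp * (1.0 + cfg.alpha_contrast * _ramp_hold(t, cfg.mod_freq))
    else:
        envelope = np.full(n, amp)
    alpha = envelope * carrier
    for name in ("FP2", "F8"):
        if name in labels:
            data[labels.index(name)] += alpha
    return data


def _trial_rng(cfg: SynthConfig, class_label: str, index: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, CLASSES.index(class_label), index])


def generate_dataset(cfg: SynthConfig) -> TrialSet:
    """Generate the full two-class trial set in randomized trial order."""
    trials, labels = [], []
    for class_label in CLASSES:
        for k in range(cfg.n_trials_per_class):
            trials.append(generate_trial(cfg, class_label, _trial_rng(cfg, class_label, k)))
            labels.append(class_label)
    order = np.random.default_rng([cfg.seed, 2, 0]).permutation(len(trials))
    trials = np.stack(trials)[order]
    labels = np.asarray(labels)[order]
    return TrialSet(
        trials=trials,
        labels=labels,
        fs=cfg.fs,
        channel_labels=cfg.labels,
        window=(0.0, cfg.epoch_s),
        meta={"synth_config": cfg.to_dict()},
    )


def inject_artifacts(trials: np.ndarray, channel_labels: list[str],
                     fs: float, rng: np.random.Generator,
                     amp: float = 80.0, rate_hz: float = 0.5) -> np.ndarray:
    """Add large, low-frequency blink-like transients to frontal channels.

    A crude exerciser for the artifact-rejection stage, not a physiological
    blink model: half-cosine bumps of ~300 ms and amplitude ``amp`` µV placed
    at Poisson times on FP2 and F8.
    """
    out = np.array(trials, dtype=float, copy=True)
    n = out.shape[-1]
    width = int(0.3 * fs)
    bump = amp * np.hanning(width)
    frontal = [i for i, c in enumerate(channel_labels) if c.upper() in ("FP2", "F8")]
    for tr in range(out.shape[0]):
        n_events = rng.poisson(rate_hz * n / fs)
        for _ in range(n_events):
            start = rng.integers(0, max(1, n - width))
            for ch in frontal:
                out[tr, ch, start:start + width] += bump
    return out
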