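"""Synthetic motor-imagery EEG with lateralized ERD.

Emulates the structure of a cued left/right hand imagery session: 140
balanced trials of 9 s at 128 Hz over C3, Cz and C4.  Each channel is a
1/f^alpha background plus white measurement noise plus mu (~10 Hz) and
beta (~20 Hz) sinusoids with a random phase per trial and channel.  From
imagery onset (t = 3 s) to the end of the trial, the rhythm amplitude on
the channel contralateral to the imagined hand (C4 for left, C3 for
right) is scaled by (1 - erd_depth) - the event-related desynchronization
that the classifier must detect.  The attenuation ramps in over 250 ms
with a raised cosine so the switch itself does not create broadband
artifacts.  Cz carries the rhythms with no class dependence.

Everything is driven by one seed: the same configuration always produces
bit-identical trial sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trial_io import Trial, TrialSet


@dataclass(frozen=True)
class SimConfig:
    n_trials: int = 140
    fs: float = 128.0
    duration: float = 9.0
    imagery_onset: float = 3.0
    mu_freq: float = 10.0
    beta_freq: float = 20.0
    rhythm_amp: float = 3.5       # uV, mu amplitude; beta uses half
    erd_depth: float = 0.3        # fractional amplitude drop during imagery
    noise_sigma: float = 2.0      # uV, white sensor noise
    pink_sigma: float = 6.0       # uV RMS of the 1/f^alpha background
    noise_exponent: float = 1.0   # alpha of the 1/f^alpha slope
    ramp_s: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.erd_depth <= 1:
            raise ValueError("erd_depth must lie in [0, 1]")
        if not self.imagery_onset < self.duration:
            raise ValueError("imagery onset must precede trial end")
        for f in (self.mu_freq, self.beta_freq):
            if not 0.5 < f < 30.0:
                raise ValueError("rhythm frequencies must lie in (0.5, 30) Hz")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def _pink_noise(n: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha amplitude spectrum, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-alpha / 2.0)
    scale[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _erd_envelope(cfg: SimConfig) -> np.ndarray:
    """Amplitude envelope: 1 before onset, (1 - erd_depth) after, cosine ramp."""
    t = np.arange(cfg.n_samples) / cfg.fs
    env = np.ones(cfg.n_samples)
    lo = 1.0 - cfg.erd_depth
    in_ramp = (t >= cfg.imagery_onset) & (t < cfg.imagery_onset + cfg.ramp_s)
    frac = (t[in_ramp] - cfg.imagery_onset) / cfg.ramp_s
    env[in_ramp] = 1.0 - cfg.erd_depth * 0.5 * (1 - np.cos(np.pi * frac))
    env[t >= cfg.imagery_onset + cfg.ramp_s] = lo
    return env


def generate_planted_features(
    n_samples: int = 400,
    n_features: int = 200,
    n_informative: int = 10,
    effect: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feature matrix with class signal confined to known columns.

    Returns ``(X, labels, informative_columns)``: X is iid standard normal
    except that the ``n_informative`` randomly placed columns have their
    class-conditional mean shifted by +/- ``effect`` (left positive).
    Labels alternate left/right, so classes are balanced.  This is the
    ground-truth benchmark for feature-selection recovery: a selector
    should concentrate on the informative columns and ignore the rest.
    """
    rng = np.random.default_rng(seed)
    labels = np.array(["left", "right"] * (n_samples // 2)
                      + ["left"] * (n_samples % 2))
    X = rng.standard_normal((n_samples, n_features))
    informative = np.sort(rng.permutation(n_features)[:n_informative])
    X[:, informative] += np.where(labels[:, None] == "left", effect, -effect)
    return X, labels, informative


def generate_trialset(cfg: SimConfig = SimConfig()) -> TrialSet:
    """Simulate a labeled trial set under ``cfg``; balanced to within one trial.

    Labels alternate left/right and the trial order is then shuffled, so
    counts differ by at most one for odd ``n_trials``.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(cfg.n_samples) / cfg.fs
    erd_env = _erd_envelope(cfg)
    flat_env = np.ones(cfg.n_samples)

    labels = ["left" if i % 2 == 0 else "right" for i in range(cfg.n_trials)]
    order = rng.permutation(cfg.n_trials)
    labels = [labels[i] for i in order]

    channels = ("C3", "Cz", "C4")
    trials: list[Trial] = []
    for label in labels:
        # contralateral channel desynchronizes during imagery
        erd_channel = "C4" if label == "left" else "C3"
        data = np.empty((cfg.n_samples, len(channels)))
        for ci, ch in enumerate(channels):
            env = erd_env if ch == erd_channel else flat_env
            mu_phase, beta_phase = rng.uniform(0, 2 * np.pi, size=2)
            rhythm = (cfg.rhythm_amp * env * np.sin(2 * np.pi * cfg.mu_freq * t + mu_phase)
                      + 0.5 * cfg.rhythm_amp * env
                      * np.sin(2 * np.pi * cfg.beta_freq * t + beta_phase))
            background = cfg.pink_sigma * _pink_noise(
                cfg.n_samples, cfg.noise_exponent, rng)
            sensor = cfg.noise_sigma * rng.standard_normal(cfg.n_samples)
            data[:, ci] = rhythm + background + sensor
        trials.append(Trial(data, channels))
    return TrialSet(trials, labels, cfg.fs)
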