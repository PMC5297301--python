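"""Sliding-window AR + wavelet feature extraction.

A 3-s window (384 samples at 128 Hz) slides sample-by-sample over each
trial, starting at sample 255 (t ~ 2 s, when the cue appears).  On a
9-s / 1152-sample trial this yields 514 window positions.  Within each
window, 24 features are computed from the C3 and C4 channels:

=====  =========================================  =======
index  feature                                    channel
=====  =========================================  =======
1-6    AR(6) coefficients                         C3
7-12   AR(6) coefficients                         C4
13-16  mean |detail coeff|, level 2 then 3        C3, C4
17-20  std of detail coefficients, level 2/3      C3, C4
21-24  mean squared detail coefficient, level 2/3 C3, C4
=====  =========================================  =======

The wavelet is Daubechies-5 with a 3-level dyadic decomposition, so at
128 Hz the level-2 details span 16-32 Hz (beta band) and level-3 details
span 8-16 Hz (mu band).  AR coefficients follow the prediction convention
x[n] ~ sum_k a_k x[n-k] (Burg estimator by default).

Feature columns are window-major: column w*24 + j (0-based w, 1-based j)
holds within-window index j of window w, and an index map decodes every
column back to (window, family, channel, level, statistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from statsmodels.regression.linear_model import burg, yule_walker

from .trial_io import TrialSet

FEATURES_PER_WINDOW = 24


class DegenerateWindowWarning(UserWarning):
    """A window had zero variance; its AR coefficients were set to 0."""


@dataclass(frozen=True)
class WindowingSpec:
    """Sliding-window geometry, all in samples (0-based start_offset)."""

    window_len: int = 384
    start_offset: int = 255
    stride: int = 1

    def __post_init__(self) -> None:
        if self.window_len < 2:
            raise ValueError("window_len must be >= 2")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.start_offset < 0:
            raise ValueError("start_offset must be >= 0")


@dataclass(frozen=True)
class FeatureSpec:
    """Per-window feature configuration.

    ar_method is "burg" (default) or "yule_walker"; dwt_mode is the
    PyWavelets signal-extension mode at the boundaries.
    """

    ar_order: int = 6
    wavelet_name: str = "db5"
    dwt_levels: int = 3
    detail_levels_used: tuple[int, ...] = (2, 3)
    channels_used: tuple[str, ...] = ("C3", "C4")
    ar_method: str = "burg"
    dwt_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.ar_order < 1:
            raise ValueError("ar_order must be >= 1")
        if not set(self.detail_levels_used) <= set(range(1, self.dwt_levels + 1)):
            raise ValueError("detail_levels_used must lie within 1..dwt_levels")
        if self.ar_method not in ("burg", "yule_walker"):
            raise ValueError(f"unknown ar_method {self.ar_method!r}")


def dwt_band_edges(level: int, fs: float) -> tuple[float, float]:
    """Frequency band (Hz) of level-k detail coefficients: (fs/2^(k+1), fs/2^k)."""
    return fs / 2 ** (level + 1), fs / 2**level


def enumerate_windows(n_samples: int, spec: WindowingSpec = WindowingSpec()) -> np.ndarray:
    """0-based start indices of every window position, in order.

    Starts run from ``start_offset`` in steps of ``stride`` while the full
    window fits: count = floor((n_samples - window_len - start_offset)/stride) + 1.
    """
    last_start = n_samples - spec.window_len
    if last_start < spec.start_offset:
        raise ValueError(
            f"trial of {n_samples} samples cannot fit a {spec.window_len}-sample "
            f"window starting at {spec.start_offset}"
        )
    return np.arange(spec.start_offset, last_start + 1, spec.stride)


def ar_coefficients(window_signal: np.ndarray, order: int,
                    method: str = "burg") -> np.ndarray:
    """AR coefficients of one window, prediction form x[n] ~ sum a_k x[n-k].

    A zero-variance window cannot be fit; it yields all-zero coefficients
    and a :class:`DegenerateWindowWarning`.
    """
    x = np.asarray(window_signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("window must be 1-D")
    if x.size <= 2 * order:
        raise ValueError(f"window of {x.size} samples too short for AR({order})")
    if np.ptp(x) == 0.0:
        warnings.warn("zero-variance window, AR coefficients set to 0",
                      DegenerateWindowWarning, stacklevel=2)
        return np.zeros(order)
    if method == "burg":
        rho, _ = burg(x, order=order, demean=True)
    elif method == "yule_walker":
        rho, _ = yule_walker(x, order=order, method="mle")
    else:
        raise ValueError(f"unknown AR method {method!r}")
    return np.asarray(rho, dtype=float)


def dwt_detail_stats(window_signal: np.ndarray,
                     spec: FeatureSpec = FeatureSpec()) -> dict[int, tuple[float, float, float]]:
    """Per-level (mean_amplitude, std_dev, avg_power) of the detail coefficients.

    mean_amplitude = mean(|d|), std_dev = sample std (n-1 denominator),
    avg_power = mean(d^2), for each level in ``spec.detail_levels_used``.
    """
    x = np.asarray(window_signal, dtype=float)
    wav = pywt.Wavelet(spec.wavelet_name)
    max_lev = pywt.dwt_max_level(x.size, wav.dec_len)
    if max_lev < spec.dwt_levels:
        raise ValueError(
            f"window of {x.size} samples supports {max_lev} levels of "
            f"{spec.wavelet_name}, need {spec.dwt_levels}"
        )
    coeffs = pywt.wavedec(x, wav, mode=spec.dwt_mode, level=spec.dwt_levels)
    # wavedec returns [cA_n, cD_n, ..., cD_1]; detail level k sits at index -k
    out: dict[int, tuple[float, float, float]] = {}
    for level in spec.detail_levels_used:
        d = coeffs[-level]
        out[level] = (
            float(np.mean(np.abs(d))),
            float(np.std(d, ddof=1)),
            float(np.mean(d**2)),
        )
    return out


def _window_features(win: np.ndarray, channels: tuple[str, ...],
                     fspec: FeatureSpec) -> np.ndarray:
    """The 24-element feature vector of one window; ``win`` is (len, n_ch)."""
    ar = [ar_coefficients(win[:, c], fspec.ar_order, fspec.ar_method)
          for c in range(win.shape[1])]
    stats = [dwt_detail_stats(win[:, c], fspec) for c in range(win.shape[1])]
    vec = np.concatenate(ar)
    # statistic-major, then channel, then level: matches the index map below
    for stat_idx in range(3):  # mean_amplitude, std_dev, avg_power
        for ch in range(win.shape[1]):
            for level in fspec.detail_levels_used:
                vec = np.append(vec, stats[ch][level][stat_idx])
    return vec


_STAT_NAMES = ("mean_amplitude", "std_dev", "avg_power")


def build_index_map(window_starts: np.ndarray,
                    fspec: FeatureSpec = FeatureSpec()) -> pd.DataFrame:
    """One row per feature column, decoding it to its provenance.

    Columns: window_index, window_start, within_window_index (1-based),
    family ("AR"|"DWT"), channel, dwt_level (NaN for AR), statistic
    (``ar_coef_k`` or one of mean_amplitude/std_dev/avg_power).
    """
    rows = []
    chans = fspec.channels_used
    for w, start in enumerate(window_starts):
        j = 1
        for ch in chans:
            for k in range(1, fspec.ar_order + 1):
                rows.append((w, int(start), j, "AR", ch, np.nan, f"ar_coef_{k}"))
                j += 1
        for stat in _STAT_NAMES:
            for ch in chans:
                for level in fspec.detail_levels_used:
                    rows.append((w, int(start), j, "DWT", ch, float(level), stat))
                    j += 1
    return pd.DataFrame(
        rows,
        columns=["window_index", "window_start", "within_window_index",
                 "family", "channel", "dwt_level", "statistic"],
    )


@dataclass
class FeatureMatrix:
    """Trials-by-features matrix with a column provenance map."""

    values: np.ndarray
    index_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[1] != len(self.index_map):
            raise ValueError(
                f"{self.values.shape[1]} feature columns but index map has "
                f"{len(self.index_map)} rows"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def L(self) -> int:
        return self.values.shape[1]

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return int(self.index_map["window_index"].max()) + 1


def extract_feature_matrix(ts: TrialSet,
                           wspec: WindowingSpec = WindowingSpec(),
                           fspec: FeatureSpec = FeatureSpec()) -> FeatureMatrix:
    """Extract the full window-major feature matrix from a trial set.

    Row i concatenates, window by window, the 24 per-window features of
    trial i.  With the defaults on 1152-sample trials this is
    514 windows x 24 = 12,336 columns.
    """
    missing = set(fspec.channels_used) - set(ts.channel_names)
    if missing:
        raise ValueError(f"trial set lacks channels {sorted(missing)}")
    starts = enumerate_windows(ts.n_samples, wspec)
    index_map = build_index_map(starts, fspec)
    ch_idx = [ts.channel_names.index(c) for c in fspec.channels_used]
    rows = np.empty((len(ts), len(starts) * FEATURES_PER_WINDOW))
    for i, trial in enumerate(ts.trials):
        data = trial.samples[:, ch_idx]
        feats = [
            _window_features(data[s:s + wspec.window_len], fspec.channels_used, fspec)
            for s in starts
        ]
        rows[i] = np.concatenate(feats)
    return FeatureMatrix(rows, index_map)


def save_feature_matrix(fm: FeatureMatrix, values_path, index_map_path,
                        labels=None, labels_path=None) -> None:
    """Write features as TSV with a CSV index-map sidecar (and labels file)."""
    np.savetxt(values_path, fm.values, fmt="%.9e", delimiter="\t")
    fm.index_map.to_csv(index_map_path, index=False)
    if labels is not None and labels_path is not None:
        from pathlib import Path

        Path(labels_path).write_text("\n".join(labels) + "\n")


def load_feature_matrix(values_path, index_map_path) -> FeatureMatrix:
    """Inverse of :func:`save_feature_matrix` (values + index map)."""
    values = np.loadtxt(values_path, delimiter="\t", ndmin=2)
    index_map = pd.read_csv(index_map_path)
    return FeatureMatrix(values, index_map)
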