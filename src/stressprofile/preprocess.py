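"""Signal cleaning and normalization for stress-profile recordings.

Three steps, applied in order:

1. **Offset trim** — biofeedback amplifiers settle during the first
   instants of acquisition, so the first 0.5 s of every channel is
   discarded by default.
2. **Median filter** — removes impulse artifacts (electrode pops, motion
   spikes) without smearing step changes.  The window length scales with
   the recording: w = length / (4 * fs), rounded to the nearest odd
   integer with a floor of 3.  At the default session length this is
   269 samples, about one second of signal at 256 Hz.
3. **Standard scaling** — z = (x - a) / s per channel, so that channels
   measured in percent and in micro-Siemens contribute comparably to the
   Euclidean geometry downstream.  The transform is linear and reversible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .protocol import ProtocolDefinition, Recording, StageSegments, segment_stages

__all__ = [
    "PreprocessConfig",
    "StandardizationParams",
    "trim_offset",
    "kernel_size",
    "median_filter",
    "standardize",
    "inverse_standardize",
    "preprocess_session",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable preprocessing options.

    kernel_fraction is the coefficient c in w = c * length / fs; the
    default 1/4 gives the standard window rule.  ddof selects the
    standard-deviation convention for scaling (0 = population, the common
    standard-scaler choice).
    """

    trim_seconds: float = 0.5
    kernel_fraction: float = 0.25
    apply_median_filter: bool = True
    standardize: bool = True
    ddof: int = 0

    def __post_init__(self) -> None:
        if self.trim_seconds < 0:
            raise ValueError("trim_seconds must be >= 0")
        if not self.kernel_fraction > 0:
            raise ValueError("kernel_fraction must be positive")


@dataclass(frozen=True)
class StandardizationParams:
    """Per-channel location/scale (the a and s of the scaler), kept so the
    transform can be inverted."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        if not (np.asarray(self.std) > 0).all():
            raise ValueError("standardization requires positive per-channel SD")


def trim_offset(recording: Recording, trim_seconds: float = 0.5) -> Recording:
    """Drop the first round(trim_seconds * fs) rows (sensor settling offset).

    The number of removed rows is recorded in the recording metadata so
    that stage segmentation can charge the deficit to the baseline stage.
    """
    n_trim = int(round(trim_seconds * recording.sampling_rate))
    if n_trim == 0:
        return recording
    if n_trim > recording.n_samples:
        raise ValueError(
            f"trim of {n_trim} samples exceeds recording length {recording.n_samples}"
        )
    return recording.replace(
        recording.samples[n_trim:],
        trimmed_samples=recording.trimmed_samples + n_trim,
    )


def kernel_size(sampling_rate: float, n_samples: int, fraction: float = 0.25) -> int:
    """Median-filter window length: w = fraction * n / fs, as an odd integer.

    The raw value is rounded to the nearest integer; an even result is
    adjusted to the nearest odd integer with ties broken downward.  The
    result is floored at 3 so the filter is always non-trivial.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    raw = fraction * n_samples / sampling_rate
    w = int(np.floor(raw + 0.5))
    if w % 2 == 0:
        w -= 1  # nearest odd, ties downward
    return max(w, 3)


def median_filter(signal: np.ndarray, w: int) -> np.ndarray:
    """Running median with window w centered on each sample.

    Edge windows are truncated symmetrically: at position i the effective
    half-width is min((w-1)/2, i, n-1-i), so the window always stays odd
    and centered and no data is fabricated beyond the recording ends.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("median_filter expects a 1-D signal")
    n = x.size
    if w % 2 == 0:
        raise ValueError("median filter window must be odd")
    if not 3 <= w <= n:
        raise ValueError(f"window must satisfy 3 <= w <= {n}, got {w}")
    k = (w - 1) // 2
    # Interior samples are unaffected by the boundary convention; use the
    # O(n log w) C implementation there and redo the edge bands explicitly.
    out = ndimage.median_filter(x, size=w, mode="nearest")
    for i in range(min(k, n)):
        r = min(k, i, n - 1 - i)
        out[i] = np.median(x[i - r : i + r + 1])
    for i in range(max(n - k, 0), n):
        r = min(k, i, n - 1 - i)
        out[i] = np.median(x[i - r : i + r + 1])
    return out


def standardize(matrix: np.ndarray, ddof: int = 0) -> tuple[np.ndarray, StandardizationParams]:
    """Scale each column to zero mean and unit SD (divisor N by default).

    Raises if any column is constant, naming the offending channel index.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("standardize expects a 2-D (rows x channels) matrix")
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(std <= 0)
    if bad.size:
        raise ValueError(f"constant channel(s) at column index {bad.tolist()}: cannot standardize")
    params = StandardizationParams(mean=mean, std=std)
    return (X - mean) / std, params


def inverse_standardize(matrix: np.ndarray, params: StandardizationParams) -> np.ndarray:
    return np.asarray(matrix, dtype=float) * params.std + params.mean


def preprocess_session(
    recording: Recording,
    protocol: ProtocolDefinition,
    config: PreprocessConfig | None = None,
) -> tuple[Recording, StageSegments, StandardizationParams | None]:
    """Full cleaning pipeline: trim, median-filter each channel, standardize.

    The filter kernel is derived from the post-trim session length, and
    segmentation is computed on the trimmed recording (baseline stage
    absorbs the trimmed samples).  Channel count and order are preserved.
    """
    cfg = config or PreprocessConfig()
    rec = trim_offset(recording, cfg.trim_seconds)
    X = rec.samples
    if cfg.apply_median_filter:
        w = kernel_size(rec.sampling_rate, X.shape[0], cfg.kernel_fraction)
        X = np.column_stack([median_filter(X[:, j], w) for j in range(X.shape[1])])
    params: StandardizationParams | None = None
    if cfg.standardize:
        X, params = standardize(X, ddof=cfg.ddof)
    out = rec.replace(X, preprocessed=True)
    segments = segment_stages(out, protocol)
    return out, segments, params
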