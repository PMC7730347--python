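"""The activity-count quantification pipeline.

Raw tri-axial acceleration is converted to per-second activity counts in
eight stages, applied independently to each axis:

1. sample at a fixed rate (>= 30 Hz),
2. band-pass filter (fixed or modifiable variant, see :mod:`.filters`),
3. rectify (absolute value),
4. saturate at 2.13 g,
5. zero out samples below the 0.068 g deadband,
6. scale to counts (1 count = 0.001664 g),
7. multiply by a variant-specific gain (0.93 fixed / 0.96 modifiable),
8. aggregate into 1-s epochs (sum over the epoch divided by the sampling
   rate, i.e. the mean count per second), then combine the three axis
   epochs into the tri-axial vector magnitude VM3 = sqrt(sx² + sy² + sz²).

Rectification is not always listed with the thresholds, but the deadband and
saturation operate on signal magnitude and the epoch sums must be
nonnegative, so the absolute value is taken between filtering and
saturation; it can be disabled via ``PipelineConfig.rectify`` for
experimentation.

All thresholds are expressed in g.  The printed m/s² equivalents of the
constants (20.874, 0.6664, 0.0163072) correspond exactly to a conversion
factor of 9.8 m/s² per g, which is therefore the default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .filters import (
    AnalogBandpass,
    DigitalBandpass,
    apply_filter,
    default_fixed_filter,
    design_butterworth_bandpass,
    discretize,
    DEFAULT_LOW_HZ,
    DEFAULT_HIGH_HZ,
    DEFAULT_MODIFIABLE_ORDER,
)

__all__ = [
    "RawAcceleration",
    "PipelineConfig",
    "CountSeries",
    "to_g",
    "rectify",
    "saturate",
    "deadband",
    "scale_to_counts",
    "epoch_aggregate",
    "vm3",
    "compute_counts",
    "SATURATION_G",
    "DEADBAND_G",
    "COUNT_SCALE_G",
    "GAIN_FIXED",
    "GAIN_MODIFIABLE",
    "G_TO_MS2",
    "MIN_FS_HZ",
]

SATURATION_G = 2.13      # = 20.874 m/s²
DEADBAND_G = 0.068       # = 0.6664 m/s²
COUNT_SCALE_G = 0.001664  # 1 count, = 0.0163072 m/s²
GAIN_FIXED = 0.93
GAIN_MODIFIABLE = 0.96
G_TO_MS2 = 9.8
MIN_FS_HZ = 30.0

_UNITS = ("g", "m/s2")


@dataclass
class RawAcceleration:
    """Tri-axial acceleration samples at a fixed sampling rate."""

    fs: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    units: str = "g"
    start_time: str | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.units not in _UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {_UNITS}")
        ax = np.asarray(self.ax, dtype=float)
        ay = np.asarray(self.ay, dtype=float)
        az = np.asarray(self.az, dtype=float)
        if not (ax.shape == ay.shape == az.shape) or ax.ndim != 1:
            raise ValueError("the three axes must be equal-length 1-D arrays")
        for name, arr in (("ax", ax), ("ay", ay), ("az", az)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite samples in {name}")
        self.ax, self.ay, self.az = ax, ay, az
        self.fs = float(self.fs)

    @property
    def n_samples(self) -> int:
        return self.ax.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class PipelineConfig:
    """All tunable constants of the quantification pipeline.

    ``gain`` defaults to ``None``, meaning "resolve from the filter
    variant": 0.93 for the fixed-bandwidth filter, 0.96 for the modifiable
    one (values that calibrate the open pipeline against commercial count
    output).  ``quantize`` floors the scaled counts to integers before the
    gain step, mimicking integer-count devices; it is off by default to
    preserve the continuous mean-count-per-second epochs.
    """

    filter_variant: str = "modifiable"   # "fixed" | "modifiable" | "custom"
    saturation_g: float = SATURATION_G
    deadband_g: float = DEADBAND_G
    count_scale_g: float = COUNT_SCALE_G
    gain: float | None = None
    epoch_s: float = 1.0
    quantize: bool = False
    g_to_ms2: float = G_TO_MS2
    rectify: bool = True
    low_hz: float = DEFAULT_LOW_HZ
    high_hz: float = DEFAULT_HIGH_HZ
    filter_order: int = DEFAULT_MODIFIABLE_ORDER
    custom_filter: AnalogBandpass | DigitalBandpass | None = None

    def __post_init__(self) -> None:
        if self.filter_variant not in ("fixed", "modifiable", "custom"):
            raise ValueError(
                f"unknown filter variant {self.filter_variant!r}; "
                "expected 'fixed', 'modifiable' or 'custom'"
            )
        if self.filter_variant == "custom" and self.custom_filter is None:
            raise ValueError("filter_variant 'custom' requires custom_filter")
        if self.saturation_g <= 0 or self.count_scale_g <= 0 or self.epoch_s <= 0:
            raise ValueError("saturation, count scale and epoch length must be positive")
        if self.deadband_g < 0 or self.deadband_g >= self.saturation_g:
            raise ValueError("deadband must satisfy 0 <= deadband < saturation")
        if self.g_to_ms2 <= 0:
            raise ValueError("g_to_ms2 must be positive")

    def resolved_gain(self) -> float:
        if self.gain is not None:
            return self.gain
        return GAIN_FIXED if self.filter_variant == "fixed" else GAIN_MODIFIABLE


@dataclass
class CountSeries:
    """Per-axis and VM3 activity counts on a fixed epoch grid."""

    epoch_s: float
    sx: np.ndarray
    sy: np.ndarray
    sz: np.ndarray
    vm3: np.ndarray
    fs_source: float

    def __post_init__(self) -> None:
        sx = np.asarray(self.sx, dtype=float)
        sy = np.asarray(self.sy, dtype=float)
        sz = np.asarray(self.sz, dtype=float)
        v = np.asarray(self.vm3, dtype=float)
        if not (sx.shape == sy.shape == sz.shape == v.shape) or sx.ndim != 1:
            raise ValueError("sx, sy, sz and vm3 must be equal-length 1-D arrays")
        for name, arr in (("sx", sx), ("sy", sy), ("sz", sz), ("vm3", v)):
            if arr.size and arr.min() < 0:
                raise ValueError(f"negative counts in {name}")
        expect = np.sqrt(sx**2 + sy**2 + sz**2)
        if v.size and np.max(np.abs(v - expect)) > 1e-9:
            raise ValueError("vm3 does not satisfy the vector-magnitude identity")
        self.sx, self.sy, self.sz, self.vm3 = sx, sy, sz, v

    @classmethod
    def from_axes(
        cls, epoch_s: float, sx: Sequence[float], sy: Sequence[float],
        sz: Sequence[float], fs_source: float,
    ) -> "CountSeries":
        sx = np.asarray(sx, dtype=float)
        sy = np.asarray(sy, dtype=float)
        sz = np.asarray(sz, dtype=float)
        return cls(epoch_s, sx, sy, sz, vm3(sx, sy, sz), fs_source)

    @property
    def n_epochs(self) -> int:
        return self.vm3.size

    def to_dataframe(self) -> pd.DataFrame:
        idx = np.arange(self.n_epochs)
        return pd.DataFrame(
            {
                "epoch_index": idx,
                "epoch_start_s": idx * self.epoch_s,
                "sx": self.sx,
                "sy": self.sy,
                "sz": self.sz,
                "vm3": self.vm3,
            }
        )


def to_g(raw: RawAcceleration, g_to_ms2: float = G_TO_MS2) -> RawAcceleration:
    """Return an equivalent signal expressed in g; identity on g input."""
    if raw.units == "g":
        return raw
    return RawAcceleration(
        fs=raw.fs,
        ax=raw.ax / g_to_ms2,
        ay=raw.ay / g_to_ms2,
        az=raw.az / g_to_ms2,
        units="g",
        start_time=raw.start_time,
    )


def rectify(x: Sequence[float]) -> np.ndarray:
    """Element-wise absolute value (full-wave rectification)."""
    return np.abs(np.asarray(x, dtype=float))


def saturate(x: Sequence[float], limit: float = SATURATION_G) -> np.ndarray:
    """Clip values above ``limit`` (g) to ``limit``."""
    if limit <= 0:
        raise ValueError("saturation limit must be positive")
    return np.minimum(np.asarray(x, dtype=float), limit)


def deadband(x: Sequence[float], threshold: float = DEADBAND_G) -> np.ndarray:
    """Zero out values strictly below ``threshold`` (g); values at the
    threshold are kept."""
    if threshold < 0:
        raise ValueError("deadband threshold must be nonnegative")
    x = np.asarray(x, dtype=float)
    return np.where(x < threshold, 0.0, x)


def scale_to_counts(
    x: Sequence[float], count_scale_g: float = COUNT_SCALE_G, quantize: bool = False
) -> np.ndarray:
    """Convert g to counts (1 count = ``count_scale_g`` g); optionally floor
    to whole counts."""
    if count_scale_g <= 0:
        raise ValueError("count scale must be positive")
    c = np.asarray(x, dtype=float) / count_scale_g
    return np.floor(c) if quantize else c


def epoch_aggregate(x: Sequence[float], fs: float, epoch_s: float = 1.0) -> np.ndarray:
    """Aggregate per-sample counts into epochs of ``epoch_s`` seconds.

    Each epoch value is the sum of its samples divided by the sampling rate
    — the mean count per second times the epoch length in seconds.  A
    trailing window that does not fill a complete epoch is dropped.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    n_per = fs * epoch_s
    if abs(n_per - round(n_per)) > 1e-9 or round(n_per) < 1:
        raise ValueError(f"epoch of {epoch_s} s must span an integer number of samples at {fs} Hz")
    n_per = int(round(n_per))
    x = np.asarray(x, dtype=float)
    n_full = x.size // n_per
    if n_full == 0:
        return np.empty(0)
    return x[: n_full * n_per].reshape(n_full, n_per).sum(axis=1) / fs


def vm3(sx, sy, sz):
    """Tri-axial vector-magnitude count: Euclidean norm of the axis counts."""
    sx = np.asarray(sx, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sz = np.asarray(sz, dtype=float)
    return np.sqrt(sx**2 + sy**2 + sz**2)


def _resolve_digital(config: PipelineConfig, fs: float) -> DigitalBandpass:
    if config.filter_variant == "custom":
        filt = config.custom_filter
        if isinstance(filt, DigitalBandpass):
            if not np.isclose(filt.fs, fs, rtol=1e-9, atol=0):
                raise ValueError(
                    f"custom digital filter is bound to {filt.fs} Hz but signal is at {fs} Hz"
                )
            return filt
        return discretize(filt, fs)
    if config.filter_variant == "fixed":
        return discretize(default_fixed_filter(), fs)
    analog = design_butterworth_bandpass(config.low_hz, config.high_hz, config.filter_order)
    return discretize(analog, fs)


def compute_counts(raw: RawAcceleration, config: PipelineConfig | None = None) -> CountSeries:
    """Run the full quantification pipeline on a tri-axial recording.

    The gain (step 7) is applied to the per-sample counts before epoch
    aggregation; since aggregation is a scaled sum, this is equivalent to
    scaling the epoch values.  The signal must be sampled at >= 30 Hz — the
    pipeline operates at the native recording rate and does not resample.
    """
    if config is None:
        config = PipelineConfig()
    raw = to_g(raw, config.g_to_ms2)
    if raw.fs < MIN_FS_HZ:
        raise ValueError(
            f"sampling rate {raw.fs} Hz is below the supported minimum of {MIN_FS_HZ} Hz"
        )
    filt = _resolve_digital(config, raw.fs)
    gain = config.resolved_gain()

    def axis_pipeline(x: np.ndarray) -> np.ndarray:
        y = apply_filter(x, filt, fs=raw.fs)
        if config.rectify:
            y = rectify(y)
        y = saturate(y, config.saturation_g)
        y = deadband(y, config.deadband_g)
        y = scale_to_counts(y, config.count_scale_g, config.quantize)
        y = gain * y
        return epoch_aggregate(y, raw.fs, config.epoch_s)

    sx = axis_pipeline(raw.ax)
    sy = axis_pipeline(raw.ay)
    sz = axis_pipeline(raw.az)
    return CountSeries.from_axes(config.epoch_s, sx, sy, sz, fs_source=raw.fs)
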