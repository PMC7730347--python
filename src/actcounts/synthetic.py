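"""Synthetic tri-axial accelerometer signals for testing and demonstration.

Real wrist-worn recordings mix a gravity component (~1 g DC on whichever
axis points down), voluntary movement in roughly the 0.3–1.6 Hz band,
wide-band sensor noise, and sometimes pathological out-of-band content such
as 4–6 Hz tremor.  The generators here emulate those ingredients with
sinusoidal carriers, white Gaussian noise and piecewise-constant activity
profiles, clipped to the ±8 g range of typical research accelerometers.
Gravity is placed on the z axis; the band-pass stage removes DC, so the
placement is arbitrary and fixed only for reproducibility.

These signals are deliberately simple: they contain no biomechanical
structure, no orientation changes and no non-wear periods, so they exercise
the numerical pipeline rather than emulate human movement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .counts import RawAcceleration

__all__ = [
    "ActivitySegment",
    "gen_sinusoid",
    "gen_profile",
    "gen_tremor_overlay",
    "SENSOR_RANGE_G",
    "GRAVITY_G",
]

SENSOR_RANGE_G = 8.0
GRAVITY_G = 1.0


@dataclass(frozen=True)
class ActivitySegment:
    """One constant-intensity stretch of a piecewise activity profile."""

    duration_s: float
    carrier_hz: float = 1.0
    amplitude_g: float = 0.0
    noise_sd_g: float = 0.0
    axis_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("segment duration must be positive")
        if self.amplitude_g < 0 or self.noise_sd_g < 0:
            raise ValueError("amplitude and noise SD must be nonnegative")
        w = tuple(float(x) for x in self.axis_weights)
        if len(w) != 3 or any(x < 0 for x in w):
            raise ValueError("axis_weights must be three nonnegative numbers")
        object.__setattr__(self, "axis_weights", w)


def _check_band(freq_hz: float, fs: float) -> None:
    if freq_hz >= fs / 2:
        raise ValueError(
            f"carrier at {freq_hz} Hz would alias at fs = {fs} Hz (Nyquist {fs / 2} Hz)"
        )


def gen_sinusoid(
    freq_hz: float,
    amplitude_g: float,
    fs: float,
    duration_s: float,
    phase_rad: float = 0.0,
) -> RawAcceleration:
    """A deterministic test tone: the same sinusoid on all three axes plus
    1 g of gravity on z."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    _check_band(freq_hz, fs)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    s = amplitude_g * np.sin(2 * np.pi * freq_hz * t + phase_rad)
    return RawAcceleration(fs=fs, ax=s.copy(), ay=s.copy(), az=s + GRAVITY_G, units="g")


def gen_profile(
    segments: Sequence[ActivitySegment], fs: float, seed: int = 0
) -> RawAcceleration:
    """Concatenate constant-intensity segments into one noisy recording.

    Each segment contributes a sinusoidal carrier scaled per axis by its
    ``axis_weights`` plus white Gaussian noise (one seeded generator for the
    whole profile, so output is bit-reproducible).  Gravity (1 g) is added
    on z and the result is clipped to the ±8 g sensor range.
    """
    if not segments:
        raise ValueError("at least one segment is required")
    for seg in segments:
        _check_band(seg.carrier_hz, fs)
    rng = np.random.default_rng(seed)
    axes = [[], [], []]
    for seg in segments:
        n = int(round(seg.duration_s * fs))
        t = np.arange(n) / fs
        carrier = seg.amplitude_g * np.sin(2 * np.pi * seg.carrier_hz * t)
        for k in range(3):
            x = seg.axis_weights[k] * carrier
            if seg.noise_sd_g > 0:
                x = x + rng.normal(0.0, seg.noise_sd_g, size=n)
            axes[k].append(x)
    ax, ay, az = (np.concatenate(a) for a in axes)
    az = az + GRAVITY_G
    clip = lambda x: np.clip(x, -SENSOR_RANGE_G, SENSOR_RANGE_G)
    return RawAcceleration(fs=fs, ax=clip(ax), ay=clip(ay), az=clip(az), units="g")


def gen_tremor_overlay(
    base: RawAcceleration, tremor_hz: float, amplitude_g: float
) -> RawAcceleration:
    """Superimpose a tremor-like sinusoid (e.g., 4–6 Hz) on all three axes.

    Used to demonstrate that narrowing the modifiable filter's upper cutoff
    attenuates tremor-attributable counts.  Zero amplitude returns an
    identical copy of the base signal.
    """
    if amplitude_g < 0:
        raise ValueError("tremor amplitude must be nonnegative")
    _check_band(tremor_hz, base.fs)
    t = np.arange(base.n_samples) / base.fs
    s = amplitude_g * np.sin(2 * np.pi * tremor_hz * t)
    clip = lambda x: np.clip(x, -SENSOR_RANGE_G, SENSOR_RANGE_G)
    return RawAcceleration(
        fs=base.fs,
        ax=clip(base.ax + s),
        ay=clip(base.ay + s),
        az=clip(base.az + s),
        units=base.units,
        start_time=base.start_time,
    )
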