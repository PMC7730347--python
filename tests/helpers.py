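"""Shared independent oracles for the test suite.

These deliberately re-derive results with plain Python loops and direct
formula evaluation so they stay independent of the vectorized library code
they check.
"""

from __future__ import annotations

import math

import numpy as np

from actcounts.counts import PipelineConfig, RawAcceleration, to_g
from actcounts.counts import _resolve_digital  # type: ignore[attr-defined]


def direct_form_filter(b, a, x):
    """Difference-equation loop: y[n] = sum b x - sum a y, zero ICs."""
    b = list(b)
    a = list(a)
    y = [0.0] * len(x)
    for n in range(len(x)):
        acc = 0.0
        for k in range(len(b)):
            if n - k >= 0:
                acc += b[k] * x[n - k]
        for k in range(1, len(a)):
            if n - k >= 0:
                acc -= a[k] * y[n - k]
        y[n] = acc
    return np.array(y)


def naive_pipeline(raw: RawAcceleration, config: PipelineConfig) -> dict:
    """Straight-line per-sample reimplementation of the count pipeline.

    Shares only the digital filter coefficients with the library; every
    other step (filtering loop, rectify, saturate, deadband, scale, gain,
    epoch sums, VM3) is an explicit Python loop.
    """
    raw = to_g(raw, config.g_to_ms2)
    filt = _resolve_digital(config, raw.fs)
    gain = config.resolved_gain()
    n_per = int(round(raw.fs * config.epoch_s))
    axes_out = []
    for x in (raw.ax, raw.ay, raw.az):
        y = direct_form_filter(filt.b, filt.a, x)
        samples = []
        for v in y:
            if config.rectify:
                v = abs(v)
            if v > config.saturation_g:
                v = config.saturation_g
            if v < config.deadband_g:
                v = 0.0
            v = v / config.count_scale_g
            if config.quantize:
                v = math.floor(v)
            samples.append(gain * v)
        epochs = []
        for i in range(len(samples) // n_per):
            epochs.append(sum(samples[i * n_per : (i + 1) * n_per]) / raw.fs)
        axes_out.append(epochs)
    sx, sy, sz = axes_out
    vm = [math.sqrt(a * a + b * b + c * c) for a, b, c in zip(sx, sy, sz)]
    return {"sx": np.array(sx), "sy": np.array(sy), "sz": np.array(sz), "vm3": np.array(vm)}


def average_ranks(values):
    """Average ranks with tie handling, by explicit grouping."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return np.array(ranks)


def pearson_formula(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
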