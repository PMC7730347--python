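"""Activity-intensity classification from 1-s VM3 count series.

Two classifiers map counts-per-minute (cpm) values onto ordered intensity
categories (by default the Freedson Adult VM3 scale: Light < 2960,
Moderate 2960–6166, Vigorous 6167–9642, Very vigorous > 9642 cpm):

* the *discrete* method sums 1-s counts into back-to-back 60-s epochs
  starting at the first sample and classifies each epoch — the convention
  of commercial count software; its output depends on how activity bouts
  align with the epoch grid;
* the *continuous* method builds one overlapping 60-s window per second
  (the 30 preceding and 30 following seconds), so a 180-s recording yields
  180 classified windows and the result is insensitive to when activity
  starts relative to recording onset.

Windows at the series boundaries are clipped to the recorded span and their
sums rescaled by 60/length so every window stays on the cpm scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .counts import CountSeries

__all__ = [
    "CutpointScale",
    "IntensityProfile",
    "classify_epoch",
    "discrete_classification",
    "continuous_classification",
    "freedson_adult_vm3",
    "scale_from_json",
    "scale_to_json",
    "EPOCH_PER_MINUTE_S",
]

EPOCH_PER_MINUTE_S = 60
_HALF_WINDOW_S = 30


@dataclass(frozen=True)
class CutpointScale:
    """Ordered intensity categories with counts-per-minute lower bounds.

    ``categories`` is a sequence of ``(name, lower_bound_cpm)`` pairs; the
    k-th category covers the half-open interval from its lower bound up to
    (but excluding) the next category's lower bound, the last category
    extending to infinity.  The first lower bound must be 0 so every
    nonnegative cpm value is classifiable.
    """

    name: str
    categories: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        cats = tuple((str(n), float(lo)) for n, lo in self.categories)
        if len(cats) < 1:
            raise ValueError("a cut-point scale needs at least one category")
        lowers = [lo for _, lo in cats]
        names = [n for n, _ in cats]
        if lowers[0] != 0:
            raise ValueError("the first category's lower bound must be 0")
        if any(b <= a for a, b in zip(lowers, lowers[1:])):
            raise ValueError("lower bounds must be strictly increasing")
        if len(set(names)) != len(names):
            raise ValueError("category names must be unique")
        object.__setattr__(self, "categories", cats)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.categories)

    @property
    def lower_bounds(self) -> np.ndarray:
        return np.array([lo for _, lo in self.categories])


def freedson_adult_vm3() -> CutpointScale:
    """The default scale: Freedson Adult VM3 cut-points (counts/min)."""
    text = resources.files("actcounts.data").joinpath("freedson_adult_vm3.json").read_text()
    return scale_from_json(json.loads(text))


def scale_from_json(doc: dict) -> CutpointScale:
    return CutpointScale(
        name=doc["name"],
        categories=tuple((c["name"], c["lower"]) for c in doc["categories"]),
    )


def scale_to_json(scale: CutpointScale) -> dict:
    return {
        "name": scale.name,
        "categories": [{"name": n, "lower": lo} for n, lo in scale.categories],
    }


@dataclass(frozen=True)
class IntensityProfile:
    """Per-category epoch tallies and percentages for one classification run."""

    scale_name: str
    method: str                      # "discrete" | "continuous"
    category_names: tuple[str, ...]
    epoch_counts: np.ndarray         # per category
    percentages: np.ndarray          # per category, sums to 100 (or 0 if empty)
    epoch_total: int
    detail_cpm: np.ndarray           # one value per classified epoch/window
    detail_category: tuple[str, ...]
    warning: str | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.epoch_counts, dtype=int)
        pct = np.asarray(self.percentages, dtype=float)
        if counts.shape != (len(self.category_names),) or pct.shape != counts.shape:
            raise ValueError("per-category arrays must match the category list")
        if counts.sum() != self.epoch_total:
            raise ValueError("epoch counts must sum to epoch_total")
        if self.epoch_total > 0 and abs(pct.sum() - 100.0) > 1e-9:
            raise ValueError("percentages must sum to 100")
        object.__setattr__(self, "epoch_counts", counts)
        object.__setattr__(self, "percentages", pct)

    def summary_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(self.category_names),
                "epochs": self.epoch_counts,
                "percent": self.percentages,
            }
        )

    def detail_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(len(self.detail_cpm)),
                "cpm": self.detail_cpm,
                "category": list(self.detail_category),
            }
        )


def classify_epoch(cpm: float, scale: CutpointScale) -> str:
    """Name of the category whose [lower, next-lower) interval contains ``cpm``."""
    if cpm < 0:
        raise ValueError(f"counts per minute must be nonnegative, got {cpm}")
    idx = int(np.searchsorted(scale.lower_bounds, cpm, side="right")) - 1
    return scale.names[idx]


def _vm3_1s(counts: Union[CountSeries, Sequence[float]]) -> np.ndarray:
    if isinstance(counts, CountSeries):
        if counts.epoch_s != 1.0:
            raise ValueError("classification requires 1-s epochs")
        return counts.vm3
    v = np.asarray(counts, dtype=float)
    if v.ndim != 1:
        raise ValueError("count series must be 1-D")
    if v.size and v.min() < 0:
        raise ValueError("counts must be nonnegative")
    return v


def _profile(
    cpm: np.ndarray, scale: CutpointScale, method: str, epoch_total: int,
    warning: str | None = None,
) -> IntensityProfile:
    lowers = scale.lower_bounds
    idx = np.searchsorted(lowers, cpm, side="right") - 1
    tallies = np.bincount(idx, minlength=len(lowers)) if cpm.size else np.zeros(len(lowers), int)
    pct = 100.0 * tallies / epoch_total if epoch_total else np.zeros(len(lowers))
    names = scale.names
    return IntensityProfile(
        scale_name=scale.name,
        method=method,
        category_names=names,
        epoch_counts=tallies,
        percentages=pct,
        epoch_total=epoch_total,
        detail_cpm=cpm,
        detail_category=tuple(names[i] for i in idx),
        warning=warning,
    )


def discrete_classification(
    counts: Union[CountSeries, Sequence[float]], scale: CutpointScale | None = None
) -> IntensityProfile:
    """Classify back-to-back 60-s epochs of a 1-s VM3 count series.

    The series is partitioned into consecutive 60-s blocks starting at the
    first second; each block's cpm is the sum of its 60 one-second counts.
    A trailing partial minute is dropped.  A series shorter than one minute
    yields an empty profile carrying a warning.
    """
    if scale is None:
        scale = freedson_adult_vm3()
    v = _vm3_1s(counts)
    n_blocks = v.size // EPOCH_PER_MINUTE_S
    if n_blocks == 0:
        return _profile(
            np.empty(0), scale, "discrete", 0,
            warning=f"series of {v.size} s is shorter than one minute; nothing classified",
        )
    cpm = v[: n_blocks * EPOCH_PER_MINUTE_S].reshape(n_blocks, EPOCH_PER_MINUTE_S).sum(axis=1)
    return _profile(cpm, scale, "discrete", n_blocks)


def continuous_classification(
    counts: Union[CountSeries, Sequence[float]], scale: CutpointScale | None = None
) -> IntensityProfile:
    """Classify one sliding 60-s window per second of a 1-s VM3 series.

    Window i covers seconds [i-30, i+30), clipped to the recorded span;
    clipped windows are rescaled by 60/length so every window is expressed
    in counts per minute.  The number of classified windows equals the
    series duration in seconds.
    """
    if scale is None:
        scale = freedson_adult_vm3()
    v = _vm3_1s(counts)
    n = v.size
    if n == 0:
        return _profile(np.empty(0), scale, "continuous", 0, warning="empty series")
    csum = np.concatenate(([0.0], np.cumsum(v)))
    i = np.arange(n)
    lo = np.maximum(i - _HALF_WINDOW_S, 0)
    hi = np.minimum(i + _HALF_WINDOW_S, n)
    sums = csum[hi] - csum[lo]
    cpm = sums * (EPOCH_PER_MINUTE_S / (hi - lo))
    return _profile(cpm, scale, "continuous", n)
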