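"""Agreement statistics between two activity-count series.

Validating a count algorithm against another implementation (or a
commercial export) uses a standard battery: Pearson and Spearman
correlation, the relative difference of totals, Bland–Altman limits of
agreement (mean difference ± 1.96 SD of the paired differences, with the
count and percentage of points falling outside), and an ordinary
least-squares regression of the absolute error on the mean intensity to
detect error that grows with activity level.

Sign convention: differences are comparator minus reference (``b - a``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CountSeries

__all__ = ["AgreementReport", "agreement", "reaggregate", "bland_altman_plot"]


@dataclass(frozen=True)
class AgreementReport:
    """All agreement statistics for one pair of epoch series.

    ``flags`` records degeneracies (zero-variance inputs, zero reference
    total) that make individual statistics undefined; the affected fields
    are NaN rather than raising.
    """

    n: int
    epoch_s: float
    pearson_r: float
    spearman_rho: float
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    n_outside: int
    pct_outside: float
    relative_difference_pct: float
    regression_slope: float
    regression_intercept: float
    regression_r: float
    flags: tuple[str, ...] = ()

    def to_dataframe(self) -> pd.DataFrame:
        rows = {
            "n": self.n,
            "epoch_s": self.epoch_s,
            "pearson_r": self.pearson_r,
            "spearman_rho": self.spearman_rho,
            "mean_difference": self.mean_difference,
            "sd_difference": self.sd_difference,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n_outside": self.n_outside,
            "pct_outside": self.pct_outside,
            "relative_difference_pct": self.relative_difference_pct,
            "regression_slope": self.regression_slope,
            "regression_intercept": self.regression_intercept,
            "regression_r": self.regression_r,
            "flags": ";".join(self.flags),
        }
        return pd.DataFrame({"statistic": list(rows), "value": list(rows.values())})


def reaggregate(counts: Union[CountSeries, Sequence[float]], epoch_s: int) -> np.ndarray:
    """Sum a 1-s VM3 count series into epochs of ``epoch_s`` seconds.

    A trailing block shorter than ``epoch_s`` is dropped, so totals are
    conserved up to that truncation.
    """
    if isinstance(counts, CountSeries):
        if counts.epoch_s != 1.0:
            raise ValueError("re-aggregation starts from 1-s epochs")
        v = counts.vm3
    else:
        v = np.asarray(counts, dtype=float)
    k = int(epoch_s)
    if k != epoch_s or k < 1:
        raise ValueError("epoch_s must be a positive whole number of seconds")
    n_blocks = v.size // k
    if n_blocks == 0:
        return np.empty(0)
    return v[: n_blocks * k].reshape(n_blocks, k).sum(axis=1)


def _as_epochs(x: Union[CountSeries, Sequence[float]], epoch_s: int) -> np.ndarray:
    if isinstance(x, CountSeries):
        return reaggregate(x, epoch_s)
    return np.asarray(x, dtype=float)


def agreement(
    a: Union[CountSeries, Sequence[float]],
    b: Union[CountSeries, Sequence[float]],
    epoch_s: int = 1,
) -> AgreementReport:
    """Full agreement battery between reference ``a`` and comparator ``b``.

    ``CountSeries`` inputs are re-aggregated from 1-s epochs to ``epoch_s``;
    plain arrays are taken as already being on the requested epoch grid.
    """
    av = _as_epochs(a, epoch_s)
    bv = _as_epochs(b, epoch_s)
    if av.shape != bv.shape or av.ndim != 1:
        raise ValueError("the two series must be equal-length 1-D epoch series")
    n = av.size
    if n < 3:
        raise ValueError(f"need at least 3 paired epochs, got {n}")
    flags: list[str] = []

    diff = bv - av
    mean_ab = (av + bv) / 2.0
    md = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    loa_low, loa_high = md - 1.96 * sd, md + 1.96 * sd
    outside = (diff < loa_low) | (diff > loa_high)
    n_outside = int(np.count_nonzero(outside))

    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        pearson = spearman = float("nan")
        flags.append("zero-variance-series: correlations undefined")
    else:
        pearson = float(stats.pearsonr(av, bv).statistic)
        spearman = float(stats.spearmanr(av, bv).statistic)

    total_a = float(np.sum(av))
    if total_a == 0:
        rel = float("nan")
        flags.append("zero-reference-total: relative difference undefined")
    else:
        rel = 100.0 * (float(np.sum(bv)) - total_a) / total_a

    abs_err = np.abs(diff)
    if np.ptp(mean_ab) == 0:
        slope = intercept = reg_r = float("nan")
        flags.append("constant-mean-intensity: regression undefined")
    else:
        fit = stats.linregress(mean_ab, abs_err)
        slope, intercept = float(fit.slope), float(fit.intercept)
        reg_r = float(fit.rvalue) if np.ptp(abs_err) > 0 else float("nan")

    return AgreementReport(
        n=n,
        epoch_s=float(epoch_s),
        pearson_r=pearson,
        spearman_rho=spearman,
        mean_difference=md,
        sd_difference=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        n_outside=n_outside,
        pct_outside=100.0 * n_outside / n,
        relative_difference_pct=rel,
        regression_slope=slope,
        regression_intercept=intercept,
        regression_r=reg_r,
        flags=tuple(flags),
    )


def bland_altman_plot(
    a: Sequence[float], b: Sequence[float], path: str, title: str = "Bland–Altman"
) -> None:
    """Write a Bland–Altman scatter (mean vs. difference) with limit lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    diff = bv - av
    mean_ab = (av + bv) / 2.0
    md = diff.mean()
    sd = diff.std(ddof=1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean_ab, diff, s=8, alpha=0.5)
    for y, style in ((md, "-"), (md + 1.96 * sd, "--"), (md - 1.96 * sd, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of the two methods (counts)")
    ax.set_ylabel("difference, comparator − reference (counts)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
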