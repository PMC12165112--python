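"""Spike-in calibration: curve fitting, limit of detection, unit conversion.

A calibration series spikes tumor-cell-derived EVs into a constant
healthy-donor EV matrix over several concentrations (particles/mL) and
measures replicate TFIs, plus blank replicates of the matrix alone.  The
response is log–log linear within the diagnostic range, so the fit is
ordinary least squares of log10(TFI) — optionally blank-subtracted — on
log10(concentration) over the concentrations at or above the limit of
detection (LOD).

LOD rule: the lowest tested concentration whose replicate-mean TFI exceeds
``blank mean + 3 × blank sd``; :data:`ABOVE_RANGE` (``inf``) is returned
when no tested concentration qualifies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ABOVE_RANGE",
    "CalibrationSeries",
    "CalibrationFit",
    "Equivalents",
    "estimate_lod",
    "fit_calibration",
    "tfi_to_equivalents",
    "plot_calibration",
]

#: Sentinel LOD when every tested concentration stays within the blank band.
ABOVE_RANGE = math.inf


@dataclass(frozen=True)
class CalibrationSeries:
    """Replicate TFIs per spiked concentration plus blank replicates."""

    concentrations: tuple[float, ...]
    responses: tuple[tuple[float, ...], ...]
    blank: tuple[float, ...]

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size < 2:
            raise ValueError("need at least 2 concentrations")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly ascending (hence distinct)")
        if len(self.responses) != conc.size:
            raise ValueError("one replicate tuple required per concentration")
        if any(len(r) == 0 for r in self.responses):
            raise ValueError("every concentration needs at least one replicate")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CalibrationSeries":
        """Build from a tidy frame with columns concentration, replicate, tfi;
        rows with concentration 0 are the blank."""
        required = {"concentration", "tfi"}
        if not required.issubset(df.columns):
            raise ValueError(f"frame must have columns {sorted(required)}")
        blank = tuple(float(v) for v in df.loc[df["concentration"] == 0, "tfi"])
        spiked = df[df["concentration"] > 0]
        concs = sorted(spiked["concentration"].unique())
        responses = tuple(
            tuple(float(v) for v in spiked.loc[spiked["concentration"] == c, "tfi"])
            for c in concs
        )
        return cls(tuple(float(c) for c in concs), responses, blank)

    @classmethod
    def from_csv(cls, path) -> "CalibrationSeries":
        return cls.from_frame(pd.read_csv(path))

    def mean_responses(self) -> np.ndarray:
        return np.array([float(np.mean(r)) for r in self.responses])

    @property
    def blank_mean(self) -> float:
        return float(np.mean(self.blank)) if self.blank else 0.0

    @property
    def blank_sd(self) -> float:
        return float(np.std(self.blank, ddof=1)) if len(self.blank) >= 2 else 0.0


@dataclass(frozen=True)
class CalibrationFit:
    """OLS fit of log10(TFI) vs log10(concentration) with LOD and blanks."""

    slope: float
    intercept: float
    r_squared: float
    lod: float
    fit_range: tuple[float, ...]
    blank_mean: float
    blank_sd: float
    subtract_baseline: bool


class Equivalents(NamedTuple):
    """A TFI converted to tumor-EV-equivalents per mL via the inverse fit."""

    concentration: float
    extrapolated: bool


def estimate_lod(series: CalibrationSeries) -> float:
    """Limit of detection: lowest tested concentration whose replicate-mean
    TFI exceeds blank mean + 3 × blank sd; :data:`ABOVE_RANGE` if none."""
    if len(series.blank) < 2:
        raise ValueError("need at least 2 blank replicates for LOD")
    threshold = series.blank_mean + 3.0 * series.blank_sd
    means = series.mean_responses()
    for c, m in zip(series.concentrations, means):
        if m > threshold:
            return float(c)
    return ABOVE_RANGE


def fit_calibration(
    series: CalibrationSeries,
    subtract_baseline: bool = True,
    fit_range: tuple[float, float] | None = None,
    lod: float | None = None,
) -> CalibrationFit:
    """Fit the log–log calibration line on replicate means.

    Points used are the concentrations at or above the LOD (estimated from
    the series unless given), further restricted to ``fit_range = (lo, hi)``
    when provided (e.g. to exclude a saturated top concentration).  With
    ``subtract_baseline`` the blank mean is removed from each response
    before the log transform; non-positive adjusted responses are dropped
    with a logged warning.
    """
    if lod is None:
        lod = estimate_lod(series) if len(series.blank) >= 2 else 0.0
    lo, hi = fit_range if fit_range is not None else (0.0, math.inf)
    concs = np.asarray(series.concentrations)
    means = series.mean_responses()
    keep = (concs >= lod) & (concs >= lo) & (concs <= hi)
    xs: list[float] = []
    ys: list[float] = []
    used: list[float] = []
    for c, m in zip(concs[keep], means[keep]):
        resp = m - series.blank_mean if subtract_baseline else m
        if resp <= 0:
            logger.warning(
                "dropping concentration %.3g: non-positive baseline-subtracted TFI", c
            )
            continue
        xs.append(math.log10(c))
        ys.append(math.log10(resp))
        used.append(float(c))
    if len(xs) < 2:
        raise ValueError("fewer than 2 usable calibration points")
    res = stats.linregress(xs, ys)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        lod=float(lod),
        fit_range=tuple(used),
        blank_mean=series.blank_mean,
        blank_sd=series.blank_sd,
        subtract_baseline=subtract_baseline,
    )


def tfi_to_equivalents(fit: CalibrationFit, tfi: float) -> Equivalents:
    """Invert the fitted line: TFI → tumor-EV-equivalents per mL.

    The result is flagged ``extrapolated`` when it falls outside the fitted
    concentration range.
    """
    if fit.slope == 0:
        raise ValueError("cannot invert a zero-slope calibration")
    adjusted = tfi - fit.blank_mean if fit.subtract_baseline else tfi
    if adjusted <= 0:
        raise ValueError("TFI must exceed the blank mean for conversion")
    conc = 10.0 ** ((math.log10(adjusted) - fit.intercept) / fit.slope)
    lo, hi = min(fit.fit_range), max(fit.fit_range)
    return Equivalents(concentration=float(conc), extrapolated=not (lo <= conc <= hi))


def plot_calibration(series: CalibrationSeries, fit: CalibrationFit, path) -> None:
    """Write a log–log plot of the series, fitted line and LOD marker."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for c, reps in zip(series.concentrations, series.responses):
        ax.plot([c] * len(reps), reps, "o", color="tab:blue", alpha=0.6, ms=4)
    grid = np.logspace(
        math.log10(min(fit.fit_range)), math.log10(max(fit.fit_range)), 50
    )
    line = 10.0 ** (fit.intercept + fit.slope * np.log10(grid))
    if fit.subtract_baseline:
        line = line + fit.blank_mean
    ax.plot(grid, line, "-", color="tab:red", label=f"slope={fit.slope:.3f}, r²={fit.r_squared:.4f}")
    if math.isfinite(fit.lod):
        ax.axvline(fit.lod, ls="--", color="gray", label=f"LOD={fit.lod:.2g}")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("spiked EVs (particles/mL)")
    ax.set_ylabel("TFI")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
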