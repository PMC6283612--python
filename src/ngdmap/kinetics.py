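"""Time-series quantifications: half-lives, growth lag, polysome ratio.

Reporter half-lives come from log-linear regression of a
transcriptional-shutoff course (standard for Northern-blot shutoff
data and exact on noiseless exponentials); growth lag is the time
separation between the maxima of the first derivative of two OD600
curves; ribosome engagement is summarised as the polysome-to-monosome
peak-height ratio of an A254 sucrose-gradient trace.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


@dataclass
class DecayCourse:
    """A shutoff time course: tidy frame (replicate, time_min, abundance).

    Abundance is the reporter signal normalised to a loading control
    (SCR1 in the canonical assay) and to the pre-shutoff level.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"replicate", "time_min", "abundance"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"decay course missing columns: {sorted(missing)}")
        for rep, grp in self.data.groupby("replicate"):
            t = grp["time_min"].to_numpy(dtype=float)
            if t.size < 2:
                raise ValueError(f"replicate {rep!r} has fewer than 2 timepoints")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"replicate {rep!r} times are not strictly increasing")

    @property
    def replicates(self) -> list:
        return list(dict.fromkeys(self.data["replicate"]))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class HalfLifeEstimate:
    """Per-replicate half-lives (minutes) with their mean ± SD.

    ``sd`` is ``None`` with fewer than two usable replicates;
    ``excluded`` lists replicates flagged non-decaying.
    """

    half_lives: dict
    mean: float
    sd: Optional[float]
    excluded: list


class HalfLifeEstimator(BaseEstimator):
    """Half-life by per-replicate log-linear regression.

    For each replicate a least-squares line is fitted through
    ``(t, ln abundance)``; the half-life is ``ln 2 / |slope|``.
    Replicates with a non-decaying (zero or positive) slope are flagged
    and excluded from the mean with a warning.  Fitted attributes:
    ``half_lives_`` (per replicate), ``mean_``, ``sd_`` (sample SD,
    ``None`` with <2 replicates), ``excluded_``.
    """

    def fit(self, course: DecayCourse, y=None) -> "HalfLifeEstimator":
        half_lives: dict = {}
        excluded: list = []
        for rep, grp in course.data.groupby("replicate", sort=False):
            t = grp["time_min"].to_numpy(dtype=float)
            ab = grp["abundance"].to_numpy(dtype=float)
            if np.any(ab <= 0):
                raise ValueError(f"replicate {rep!r} has non-positive abundance; cannot fit")
            slope = np.polyfit(t, np.log(ab), 1)[0]
            if slope >= 0:
                logger.warning("replicate %r is non-decaying (slope %.3g); excluded", rep, slope)
                excluded.append(rep)
                continue
            half_lives[rep] = math.log(2) / abs(slope)
        if not half_lives:
            raise ValueError("all replicates are non-decaying; no half-life to report")
        values = np.asarray(list(half_lives.values()))
        self.half_lives_ = half_lives
        self.excluded_ = excluded
        self.mean_ = float(values.mean())
        self.sd_ = float(values.std(ddof=1)) if values.size >= 2 else None
        return self


def fit_half_life(course: DecayCourse) -> HalfLifeEstimate:
    """Functional wrapper over :class:`HalfLifeEstimator`."""
    est = HalfLifeEstimator().fit(course)
    return HalfLifeEstimate(
        half_lives=est.half_lives_, mean=est.mean_, sd=est.sd_, excluded=est.excluded_
    )


@dataclass
class GrowthCurve:
    """A microplate OD600 curve under one condition."""

    times: np.ndarray
    od: np.ndarray
    condition: Optional[str] = None
    replicate: Optional[str] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("od must be non-negative")


@dataclass
class RateSeries:
    """Instantaneous growth rate at interior timepoints."""

    times: np.ndarray
    rate: np.ndarray

    @property
    def argmax_time(self) -> float:
        """Time of maximal growth rate; ties resolve to the earliest."""
        return float(self.times[int(np.argmax(self.rate))])

    @property
    def max_rate(self) -> float:
        return float(self.rate.max())


def instantaneous_rate(curve: GrowthCurve, smooth_k: int = 5) -> RateSeries:
    """First derivative of the growth curve (dOD/dt, per hour).

    The OD series is pre-smoothed with a centred ``smooth_k``-point
    moving average (≈50 min at 10-min sampling with the default k=5 —
    raw central differences would be dominated by plate-reader noise),
    then differentiated by central differences; the derivative is
    reported at interior timepoints only.
    """
    if smooth_k % 2 != 1 or smooth_k < 1:
        raise ValueError("smooth_k must be a positive odd integer")
    n = curve.times.size
    if n < smooth_k + 2:
        raise ValueError(f"need at least smooth_k + 2 = {smooth_k + 2} timepoints, got {n}")
    half = smooth_k // 2
    if smooth_k > 1:
        od_s = np.convolve(curve.od, np.ones(smooth_k) / smooth_k, mode="valid")
        t_s = curve.times[half : n - half]
    else:
        od_s, t_s = curve.od, curve.times
    grad = np.gradient(od_s, t_s)
    return RateSeries(times=t_s[1:-1], rate=grad[1:-1])


def lag_time(reference: GrowthCurve, test: GrowthCurve, smooth_k: int = 5) -> float:
    """Lag of ``test`` behind ``reference`` (hours).

    Defined as the difference between the times of maximal
    instantaneous growth rate: positive means the test condition lags.
    Flat derivative plateaus resolve to the earliest time (flagged by a
    warning when the maximum is not unique).
    """
    lags = []
    for curve in (reference, test):
        series = instantaneous_rate(curve, smooth_k)
        if np.sum(series.rate == series.rate.max()) > 1:
            logger.warning(
                "growth curve %r: derivative maximum is not unique; using earliest time",
                curve.condition,
            )
        lags.append(series.argmax_time)
    return lags[1] - lags[0]


@dataclass
class PolysomeTrace:
    """An A254 absorbance trace along a sucrose gradient (light→heavy)."""

    position: np.ndarray
    a254: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.a254 = np.asarray(self.a254, dtype=float)
        if self.position.shape != self.a254.shape:
            raise ValueError("position and a254 must have equal length")
        if np.any(np.diff(self.position) <= 0):
            raise ValueError("positions must be strictly increasing")


def polysome_monosome_ratio(
    trace: PolysomeTrace,
    monosome_region: tuple[float, float],
    polysome_region: tuple[float, float],
) -> float:
    """Polysome-to-monosome peak-height ratio of an A254 trace.

    Regions are (lo, hi) position intervals drawn to include the
    flanking troughs of each peak; the baseline for a region is the
    minimum absorbance inside it, and the peak height is the maximum
    above that baseline.  Peak height (not area) is used.
    """
    (m_lo, m_hi), (p_lo, p_hi) = monosome_region, polysome_region
    if m_lo >= m_hi or p_lo >= p_hi:
        raise ValueError("regions must be non-empty intervals (lo < hi)")
    if max(m_lo, p_lo) < min(m_hi, p_hi):
        raise ValueError("monosome and polysome regions overlap")
    lo, hi = trace.position[0], trace.position[-1]
    if m_lo < lo or p_lo < lo or m_hi > hi or p_hi > hi:
        raise ValueError("regions must lie within the trace")

    def height(lo_: float, hi_: float) -> float:
        mask = (trace.position >= lo_) & (trace.position <= hi_)
        values = trace.a254[mask]
        if values.size == 0:
            raise ValueError("region contains no trace points")
        return float(values.max() - values.min())

    mono = height(m_lo, m_hi)
    if mono <= 0:
        raise ValueError("monosome peak height is zero; ratio undefined")
    return height(p_lo, p_hi) / mono
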