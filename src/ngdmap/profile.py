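"""Stall-relative cleavage profiles: histogram, smoothing, peak calling.

The profile is the per-nucleotide count of fragment 3' ends as a
function of distance upstream of the stall, smoothed with a 5-point
quadratic Savitzky–Golay filter.  Peaks — strict local maxima of the
smoothed track — are labelled when their height reaches the 75th
percentile of all smoothed values in the analysis window, and the
spacing between labelled peaks summarises the periodicity of the
cleavage pattern (≈30 nt for a standing ribosome queue, ≈45 nt for
cleavage–runoff cycles).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator


@dataclass
class CleavageProfile:
    """Fragment 3'-end counts over ``[1, upstream_window]`` nt upstream.

    ``counts[i]`` holds the reads whose 3' end lies ``i + 1`` nt
    upstream of the stall.  ``smoothed`` carries NaN wherever a full
    smoothing window does not fit; ``labelled`` flags labelled-peak
    positions once peaks have been called.  ``overflow`` counts
    fragments beyond the window, ``n_downstream`` fragments at or past
    the stall; together with ``n_fragments`` these conserve the number
    of accepted fragments.
    """

    reporter_name: str
    counts: np.ndarray
    smoothed: Optional[np.ndarray] = None
    labelled: Optional[np.ndarray] = None
    overflow: int = 0
    n_downstream: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.smoothed is not None:
            self.smoothed = np.asarray(self.smoothed, dtype=float)
            if self.smoothed.shape != self.counts.shape:
                raise ValueError("smoothed track must match counts length")

    @property
    def distances(self) -> np.ndarray:
        """Upstream distances (nt), 1..window."""
        return np.arange(1, len(self.counts) + 1)

    @property
    def n_fragments(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class Peak:
    distance: int
    height: float
    labelled: bool


@dataclass
class PeakSet:
    """Candidate peaks (sorted by distance) and the threshold used."""

    peaks: list[Peak]
    threshold: float

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.distance)

    @property
    def labelled_distances(self) -> np.ndarray:
        return np.asarray([p.distance for p in self.peaks if p.labelled], dtype=int)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class SpacingStats:
    """Spacing summary over labelled peaks.

    ``modal_spacing``/``median_spacing`` are ``None`` with fewer than
    two labelled peaks; ``span`` is ``None`` with none.
    """

    n_labelled: int
    modal_spacing: Optional[int] = None
    median_spacing: Optional[float] = None
    span: Optional[int] = None


def build_histogram(
    distances: Sequence[int], upstream_window: int = 600, reporter_name: str = ""
) -> CleavageProfile:
    """Tally upstream distances into a per-nucleotide histogram.

    Distances must be positive; those beyond the window are counted in
    the overflow tally rather than dropped silently.
    """
    d = np.asarray(distances, dtype=int)
    if d.size and d.min() < 1:
        raise ValueError("upstream distances must be positive")
    in_window = d[d <= upstream_window]
    counts = np.bincount(in_window, minlength=upstream_window + 1)[1:]
    return CleavageProfile(
        reporter_name=reporter_name,
        counts=counts,
        overflow=int((d > upstream_window).sum()),
    )


def savgol_track(values: np.ndarray, window: int = 5, order: int = 2) -> np.ndarray:
    """Savitzky–Golay smoothing with undefined (NaN) edges.

    Each interior value is the centred least-squares polynomial fit of
    the given order evaluated at the window centre; positions within
    ``window // 2`` of either edge carry NaN rather than an
    extrapolated fit.
    """
    values = np.asarray(values, dtype=float)
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("order must be < window")
    if values.size < window:
        raise ValueError(f"profile of length {values.size} is shorter than window {window}")
    out = savgol_filter(values, window_length=window, polyorder=order, mode="interp")
    half = window // 2
    out[:half] = np.nan
    out[-half:] = np.nan
    return out


def smooth_profile(
    profile: CleavageProfile, window: int = 5, order: int = 2
) -> CleavageProfile:
    """Return a copy of the profile carrying the smoothed track."""
    return CleavageProfile(
        reporter_name=profile.reporter_name,
        counts=profile.counts.copy(),
        smoothed=savgol_track(profile.counts, window, order),
        labelled=None if profile.labelled is None else profile.labelled.copy(),
        overflow=profile.overflow,
        n_downstream=profile.n_downstream,
    )


def _candidate_peaks(smoothed: np.ndarray) -> list[int]:
    """Indices of strict local maxima; plateaus reduced to their
    most-upstream (largest-distance) position."""
    idx: list[int] = []
    n = smoothed.size
    i = 0
    while i < n:
        if np.isnan(smoothed[i]):
            i += 1
            continue
        j = i
        while j + 1 < n and smoothed[j + 1] == smoothed[i]:
            j += 1
        left_ok = i - 1 >= 0 and not np.isnan(smoothed[i - 1]) and smoothed[i - 1] < smoothed[i]
        right_ok = j + 1 < n and not np.isnan(smoothed[j + 1]) and smoothed[j + 1] < smoothed[i]
        if left_ok and right_ok:
            idx.append(j)  # most-upstream position of the run
        i = j + 1
    return idx


def call_peaks(
    profile: CleavageProfile,
    peak_quantile: float = 0.75,
    quantile_on: str = "window",
) -> PeakSet:
    """Label local maxima of the smoothed track against a quantile cut.

    Candidates are strict local maxima (plateaus reduced to their
    most-upstream position) of positive smoothed height — a peak must
    represent actual fragment accumulation, and the smoothing filter's
    negative ringing around isolated spikes would otherwise promote
    flat zero stretches to maxima.  The threshold is the ``peak_quantile``
    quantile — linear interpolation between order statistics — of all
    smoothed values in the window (``quantile_on="window"``, the
    default) or of candidate peak heights only (``"peaks"``).  A peak is
    labelled iff its height >= threshold.
    """
    if profile.smoothed is None:
        raise ValueError("profile has no smoothed track; run smooth_profile first")
    if quantile_on not in ("window", "peaks"):
        raise ValueError("quantile_on must be 'window' or 'peaks'")
    smoothed = profile.smoothed
    finite = smoothed[~np.isnan(smoothed)]
    candidates = [i for i in _candidate_peaks(smoothed) if smoothed[i] > 0]
    if finite.size == 0 or not np.any(finite != 0):
        return PeakSet(peaks=[], threshold=0.0)
    if quantile_on == "window":
        threshold = float(np.quantile(finite, peak_quantile))
    else:
        if not candidates:
            return PeakSet(peaks=[], threshold=0.0)
        heights = smoothed[candidates]
        threshold = float(np.quantile(heights, peak_quantile))
    peaks = [
        Peak(distance=i + 1, height=float(smoothed[i]), labelled=bool(smoothed[i] >= threshold))
        for i in candidates
    ]
    return PeakSet(peaks=peaks, threshold=threshold)


def peak_spacing_stats(peak_set: PeakSet) -> SpacingStats:
    """Spacing statistics over labelled peaks.

    Spacings are differences between consecutive labelled peak
    distances; the modal spacing is the most frequent value after
    rounding to the nearest nt, ties resolved toward the smaller value.
    """
    dists = peak_set.labelled_distances
    n = dists.size
    if n == 0:
        return SpacingStats(n_labelled=0)
    if n == 1:
        return SpacingStats(n_labelled=1, span=0)
    spacings = np.diff(np.sort(dists))
    rounded = np.rint(spacings).astype(int)
    freq = Counter(rounded.tolist())
    top = max(freq.values())
    modal = min(k for k, v in freq.items() if v == top)
    return SpacingStats(
        n_labelled=int(n),
        modal_spacing=int(modal),
        median_spacing=float(np.median(spacings)),
        span=int(dists.max() - dists.min()),
    )


class CleavageProfiler(BaseEstimator):
    """Histogram → smooth → peak-call → spacing, as one estimator.

    Follows the sklearn estimator protocol: hyper-parameters are set at
    construction, :meth:`fit` consumes the upstream distances of mapped
    fragments, and fitted results live in trailing-underscore
    attributes (``profile_``, ``peaks_``, ``threshold_``,
    ``spacing_``).

    Parameters
    ----------
    upstream_window : int
        Analysis window, nt upstream of the stall (default 600).
    smoothing_window, smoothing_order : int
        Savitzky–Golay settings (default 5-point quadratic).
    peak_quantile : float
        Labelling quantile (default 0.75).
    quantile_on : str
        ``"window"`` (default) or ``"peaks"`` — what population the
        quantile threshold is computed over.
    """

    def __init__(
        self,
        upstream_window: int = 600,
        smoothing_window: int = 5,
        smoothing_order: int = 2,
        peak_quantile: float = 0.75,
        quantile_on: str = "window",
        reporter_name: str = "",
    ) -> None:
        self.upstream_window = upstream_window
        self.smoothing_window = smoothing_window
        self.smoothing_order = smoothing_order
        self.peak_quantile = peak_quantile
        self.quantile_on = quantile_on
        self.reporter_name = reporter_name

    def fit(self, X, y=None, n_downstream: int = 0) -> "CleavageProfiler":
        """Fit on a 1-d sequence of positive upstream distances (nt)."""
        profile = build_histogram(
            np.asarray(X, dtype=int).ravel(),
            upstream_window=self.upstream_window,
            reporter_name=self.reporter_name,
        )
        profile.n_downstream = n_downstream
        profile = smooth_profile(profile, self.smoothing_window, self.smoothing_order)
        peaks = call_peaks(profile, self.peak_quantile, self.quantile_on)
        labelled = np.zeros(len(profile.counts), dtype=bool)
        for p in peaks.peaks:
            if p.labelled:
                labelled[p.distance - 1] = True
        profile.labelled = labelled
        self.profile_ = profile
        self.counts_ = profile.counts
        self.smoothed_ = profile.smoothed
        self.peaks_ = peaks
        self.threshold_ = peaks.threshold
        self.spacing_ = peak_spacing_stats(peaks)
        self.n_fragments_ = profile.n_fragments
        self.overflow_ = profile.overflow
        return self
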