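"""Histogram, Savitzky–Golay smoothing, quantile peak calling, spacing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ngdmap import (
    CleavageProfile,
    CleavageProfiler,
    Peak,
    PeakSet,
    build_histogram,
    call_peaks,
    peak_spacing_stats,
    savgol_track,
    smooth_profile,
)


def oracle_window_fit(values, window, order):
    """Independent per-window least-squares polynomial fit, centre value."""
    half = window // 2
    out = np.full(len(values), np.nan)
    x = np.arange(-half, half + 1)
    for i in range(half, len(values) - half):
        coeffs = np.polyfit(x, values[i - half : i + half + 1], order)
        out[i] = np.polyval(coeffs, 0.0)
    return out


def oracle_call_peaks(smoothed, q):
    """Position-by-position local-maximum scan + direct quantile threshold."""
    finite = smoothed[~np.isnan(smoothed)]
    if finite.size == 0 or not np.any(finite != 0):
        return [], 0.0
    threshold = float(np.quantile(finite, q))
    candidates = []
    n = len(smoothed)
    for i in range(n):
        v = smoothed[i]
        if np.isnan(v) or v <= 0:
            continue
        j = i  # walk the plateau
        while j + 1 < n and smoothed[j + 1] == v:
            j += 1
        if i > 0 and smoothed[i - 1] == v:
            continue  # interior of a plateau already handled
        left = smoothed[i - 1] if i > 0 else np.nan
        right = smoothed[j + 1] if j + 1 < n else np.nan
        if not np.isnan(left) and not np.isnan(right) and left < v and right < v:
            candidates.append((j + 1, v, v >= threshold))
    return candidates, threshold


class TestHistogram:
    def test_empty_input(self):
        prof = build_histogram([], upstream_window=10)
        assert prof.n_fragments == 0 and np.all(prof.counts == 0)

    def test_conservation_at_one_position(self):
        prof = build_histogram([150, 150, 150], upstream_window=600)
        assert prof.counts[149] == 3 and prof.n_fragments == 3

    def test_overflow_tally(self):
        prof = build_histogram([5, 700], upstream_window=600)
        assert prof.overflow == 1 and prof.n_fragments == 1

    def test_non_positive_distance_rejected(self):
        with pytest.raises(ValueError):
            build_histogram([0, 5])

    def test_matches_counting_oracle(self, rng):
        distances = rng.integers(1, 200, size=500)
        prof = build_histogram(distances, upstream_window=250)
        for d in range(1, 251):
            assert prof.counts[d - 1] == int((distances == d).sum())


class TestSmoothing:
    def test_constant_counts_reproduced(self):
        track = savgol_track(np.full(20, 7.0))
        np.testing.assert_allclose(track[2:-2], 7.0)
        assert np.isnan(track[:2]).all() and np.isnan(track[-2:]).all()

    def test_linear_ramp_reproduced(self):
        track = savgol_track(np.arange(30, dtype=float))
        np.testing.assert_allclose(track[2:-2], np.arange(30)[2:-2], atol=1e-12)

    def test_unit_impulse_centre_is_17_over_35(self):
        track = savgol_track(np.array([0.0, 0, 1, 0, 0]))
        assert track[2] == pytest.approx(17 / 35, abs=1e-12)

    def test_profile_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            savgol_track(np.ones(3), window=5)

    def test_smooth_profile_preserves_counts_and_metadata(self):
        prof = CleavageProfile(reporter_name="r", counts=np.arange(10), overflow=3)
        out = smooth_profile(prof)
        np.testing.assert_array_equal(out.counts, prof.counts)
        assert out.overflow == 3 and out.smoothed is not None

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_linearity_on_random_vectors(self, seed):
        """smoothing(a x + b y) == a smoothing(x) + b smoothing(y)."""
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 25))
        a, b = rng.normal(size=2)
        np.testing.assert_allclose(
            savgol_track(a * x + b * y),
            a * savgol_track(x) + b * savgol_track(y),
            atol=1e-9,
        )


def _smoothed_profile(values):
    values = np.asarray(values, dtype=float)
    return CleavageProfile(reporter_name="t", counts=np.zeros(len(values), dtype=int),
                           smoothed=values)


class TestPeakCalling:
    def test_monotone_track_has_no_peaks(self):
        prof = _smoothed_profile(np.linspace(0.1, 5, 20))
        assert len(call_peaks(prof)) == 0

    def test_single_interior_maximum_labelled(self):
        track = np.array([np.nan, 0.1, 0.2, 3.0, 0.2, 0.1, np.nan])
        peaks = call_peaks(_smoothed_profile(track))
        labelled = [p for p in peaks.peaks if p.labelled]
        assert len(labelled) == 1 and labelled[0].distance == 4

    def test_sub_threshold_bump_unlabelled(self):
        # two bumps; the smaller one falls below the 75% window quantile
        track = np.array([0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 8.0, 9.0, 8.0, 7.5, 7.0, 6.0, 0.0])
        peaks = call_peaks(_smoothed_profile(track), peak_quantile=0.75)
        by_distance = {p.distance: p.labelled for p in peaks.peaks}
        assert by_distance == {2: False, 8: True}
        cand, threshold = oracle_call_peaks(track, 0.75)
        assert [(p.distance, p.height, p.labelled) for p in peaks.peaks] == cand
        assert peaks.threshold == threshold

    def test_plateau_reduced_to_most_upstream_position(self):
        track = np.array([0.0, 2.0, 2.0, 2.0, 0.0, 0.0])
        peaks = call_peaks(_smoothed_profile(track))
        assert [p.distance for p in peaks.peaks] == [4]

    def test_all_zero_track_empty_with_zero_threshold(self):
        peaks = call_peaks(_smoothed_profile(np.zeros(10)))
        assert len(peaks) == 0 and peaks.threshold == 0.0

    def test_missing_smoothed_track_rejected(self):
        prof = CleavageProfile(reporter_name="t", counts=np.zeros(5, dtype=int))
        with pytest.raises(ValueError, match="smoothed"):
            call_peaks(prof)

    def test_matches_oracle_on_random_profiles(self, rng):
        for _ in range(300):
            values = np.round(rng.gamma(1.0, 2.0, size=40), 2)
            values[rng.random(40) < 0.3] = 0.0
            track = savgol_track(values)
            q = float(rng.uniform(0.3, 0.95))
            peaks = call_peaks(_smoothed_profile(track), peak_quantile=q)
            cand, threshold = oracle_call_peaks(track, q)
            assert [(p.distance, p.height, p.labelled) for p in peaks.peaks] == cand
            assert peaks.threshold == pytest.approx(threshold)

    def test_raising_quantile_never_adds_labels(self, rng):
        values = rng.poisson(3.0, size=60).astype(float)
        prof = _smoothed_profile(savgol_track(values))
        counts = [
            sum(p.labelled for p in call_peaks(prof, peak_quantile=q).peaks)
            for q in np.linspace(0, 1, 21)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_quantile_on_peaks_switch(self, rng):
        values = rng.poisson(5.0, size=60).astype(float)
        prof = _smoothed_profile(savgol_track(values))
        over_peaks = call_peaks(prof, peak_quantile=0.75, quantile_on="peaks")
        heights = [p.height for p in over_peaks.peaks]
        assert over_peaks.threshold == pytest.approx(np.quantile(heights, 0.75))


class TestSpacingStats:
    def test_thirty_nt_ladder(self):
        ps = PeakSet([Peak(d, 1.0, True) for d in (15, 45, 75)], threshold=0.5)
        stats = peak_spacing_stats(ps)
        assert (stats.modal_spacing, stats.span, stats.n_labelled) == (30, 60, 3)

    def test_modal_spacing_by_frequency(self):
        ps = PeakSet([Peak(d, 1.0, True) for d in (45, 90, 135, 150)], threshold=0.5)
        stats = peak_spacing_stats(ps)
        assert stats.modal_spacing == 45  # spacings {45, 45, 15}
        assert stats.median_spacing == 45

    def test_tie_goes_to_smaller_spacing(self):
        ps = PeakSet([Peak(d, 1.0, True) for d in (10, 40, 85)], threshold=0.0)
        assert peak_spacing_stats(ps).modal_spacing == 30  # {30, 45} tie

    def test_degenerate_counts(self):
        one = peak_spacing_stats(PeakSet([Peak(50, 1.0, True)], threshold=0.0))
        assert one.n_labelled == 1 and one.modal_spacing is None and one.span == 0
        none = peak_spacing_stats(PeakSet([Peak(50, 1.0, False)], threshold=2.0))
        assert none.n_labelled == 0 and none.span is None

    def test_unlabelled_peaks_ignored(self):
        ps = PeakSet(
            [Peak(15, 1.0, True), Peak(30, 0.1, False), Peak(45, 1.0, True)], threshold=0.5
        )
        assert peak_spacing_stats(ps).modal_spacing == 30


class TestProfilerEstimator:
    def test_fit_populates_fitted_attributes(self, rng):
        distances = rng.integers(1, 300, size=400)
        est = CleavageProfiler(upstream_window=300).fit(distances)
        assert est.n_fragments_ == 400
        assert est.profile_.smoothed is not None
        assert est.spacing_.n_labelled == sum(p.labelled for p in est.peaks_.peaks)

    def test_get_set_params_roundtrip(self):
        est = CleavageProfiler(peak_quantile=0.9)
        params = est.get_params()
        assert params["peak_quantile"] == 0.9
        est.set_params(smoothing_window=7)
        assert est.smoothing_window == 7

    def test_conservation_across_bins(self, rng):
        distances = np.concatenate([rng.integers(1, 100, 50), [650, 700]])
        est = CleavageProfiler(upstream_window=600).fit(distances, n_downstream=3)
        assert est.n_fragments_ + est.overflow_ + est.profile_.n_downstream == 55
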