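"""Flanked-acuity landscape: calibration, slices, contours, size windows."""

import math

import numpy as np
import pytest

import crowdkit as ck
from crowdkit.geometry import UNFLANKED, CriterionSpec
from crowdkit.landscape import (
    FlankedAcuityLandscape,
    HingeSpec,
    LandscapeParams,
    SpacingSizeOverlapError,
)


@pytest.fixture
def scape(landscape_params):
    return FlankedAcuityLandscape(landscape_params)


class TestForwardModel:
    def test_unflanked_threshold_size_calibration_point(self, scape):
        p = scape.predict_pcorrect(0.3, UNFLANKED)
        assert p == pytest.approx(0.75, abs=1e-12)

    def test_tiny_letters_approach_guess_rate(self, scape):
        assert scape.predict_pcorrect(0.003, 10.0) == pytest.approx(0.25, abs=1e-3)

    def test_huge_letters_approach_asymptote(self, scape):
        assert scape.predict_pcorrect(30.0, 300.0) == pytest.approx(0.99, abs=1e-3)

    def test_monotone_in_size_and_spacing_flattening_beyond_hinge(self, scape):
        spacings = np.logspace(math.log10(0.45), math.log10(20.0), 60)
        ps = [scape.predict_pcorrect(0.45, s) for s in spacings]
        assert np.all(np.diff(ps) >= -1e-12)
        # flat beyond the hinge: nominal 4 x 0.45 deg
        beyond = [scape.predict_pcorrect(0.45, s) for s in (2.0, 5.0, 50.0)]
        assert beyond[0] == pytest.approx(beyond[1], abs=1e-12)
        sizes = np.logspace(-1.5, 0.5, 40)
        ps_size = [scape.predict_pcorrect(sz, UNFLANKED) for sz in sizes]
        assert np.all(np.diff(ps_size) > 0)

    def test_overlap_geometry_rejected(self, scape):
        with pytest.raises(SpacingSizeOverlapError):
            scape.predict_pcorrect(0.5, 0.4)

    def test_no_crowding_limit_reduces_to_single_acuity_function(self):
        # hinge at nominal 1 (log10 -> 0): flankers never matter in the
        # non-overlap domain, so every spacing gives the unflanked curve
        params = LandscapeParams(
            eccentricity=5.0, unflanked_threshold_size=0.3, beta_shared=6.0,
            guess=0.25, hinge=HingeSpec(hinge_location=0.0), asymptote=0.99,
        )
        s = FlankedAcuityLandscape(params)
        for size in (0.2, 0.3, 0.5):
            p_unf = s.predict_pcorrect(size, UNFLANKED)
            for spacing in (size, 2 * size, 10 * size):
                assert s.predict_pcorrect(size, spacing) == pytest.approx(p_unf, abs=1e-12)


class TestThresholdSize:
    def test_wide_nominal_equals_unflanked_threshold(self, scape):
        t_wide = scape.threshold_size(50.0, 0.75)
        assert t_wide == pytest.approx(0.3, rel=1e-5)

    def test_deep_crowding_raises_thresholds(self, scape):
        assert scape.threshold_size(1.2, 0.75) > 1.5 * scape.threshold_size(50.0, 0.75)

    def test_threshold_vs_nominal_curve_continuous_with_kink_at_hinge(self, scape):
        ms = np.linspace(1.1, 8.0, 120)
        ts = np.array([scape.threshold_size(m, 0.75) for m in ms])
        # continuity: no jumps anywhere
        rel_steps = np.abs(np.diff(np.log10(ts)))
        assert rel_steps.max() < 0.05
        # kink: crowded branch falls, flat branch is exactly constant
        flat = ts[ms > 4.2]
        assert np.allclose(flat, flat[0], rtol=1e-5)
        crowded = ts[ms < 3.5]
        assert np.all(np.diff(crowded) < 0)

    def test_level_outside_range_flagged(self, scape):
        with pytest.raises(ck.CriterionUnattainableError):
            scape.threshold_size(2.0, 0.995)


class TestContours:
    def test_contour_points_reproduce_their_level(self, scape):
        sizes = np.logspace(-0.8, 0.2, 25)
        for level in (0.5, 0.75, 0.9):
            for size, spacing in scape.iso_performance_contour(level, sizes):
                if math.isnan(spacing):
                    continue
                assert scape.predict_pcorrect(size, spacing) == pytest.approx(level, abs=1e-6)

    def test_higher_level_contour_dominates(self, scape):
        sizes = np.logspace(-0.6, 0.1, 20)
        c1 = dict(scape.iso_performance_contour(0.5, sizes))
        c2 = dict(scape.iso_performance_contour(0.8, sizes))
        for size in sizes:
            s1, s2 = c1[size], c2[size]
            if math.isnan(s1) or math.isnan(s2):
                continue
            assert s2 >= s1 - 1e-9

    def test_contour_monotone_larger_sizes_need_smaller_spacings(self, scape):
        sizes = np.logspace(-0.5, 0.0, 15)
        pts = [sp for _, sp in scape.iso_performance_contour(0.75, sizes) if not math.isnan(sp)]
        assert all(a >= b - 1e-9 for a, b in zip(pts, pts[1:]))


class TestSliceCriticalSpacing:
    crit = CriterionSpec("absolute", 0.8)

    def test_too_small_letters_floor(self, scape):
        est = scape.critical_spacing_at_size(0.1, self.crit)
        assert est.status == "floor" and not est.measurable

    def test_too_large_letters_ceiling(self, scape):
        est = scape.critical_spacing_at_size(5.0, self.crit)
        assert est.status == "ceiling"

    def test_measurable_sizes_give_finite_crossing(self, scape):
        est = scape.critical_spacing_at_size(0.5, self.crit)
        assert est.measurable
        assert scape.predict_pcorrect(0.5, est.value) == pytest.approx(0.8, abs=1e-9)

    def test_flat_across_conventional_size_multiples(self, scape):
        values = [
            scape.critical_spacing_at_size(k * 0.3, self.crit).value
            for k in np.linspace(1.5, 3.0, 7)
        ]
        assert all(np.isfinite(values))
        assert max(values) / min(values) < 1.2

    def test_results_invariant_to_nominal_vs_absolute_input_expression(self, scape):
        # the same physical geometry expressed through a nominal multiple
        size = 0.5
        m = 3.0
        s_abs = ck.nominal_to_absolute(m, size)
        assert scape.predict_pcorrect(size, s_abs) == scape.predict_pcorrect(size, m * size)


class TestValidSizeWindow:
    def test_window_brackets_floor_and_ceiling(self, scape):
        crit = CriterionSpec("absolute", 0.8)
        lo, hi = scape.valid_size_window(crit)
        assert lo < hi
        eps = 1.05
        assert scape.critical_spacing_at_size(lo * eps, crit).measurable
        assert scape.critical_spacing_at_size(hi / eps, crit).measurable
        assert scape.critical_spacing_at_size(lo / eps, crit).status == "floor"
        assert scape.critical_spacing_at_size(hi * eps, crit).status == "ceiling"

    def test_stricter_criterion_narrower_or_equal_window(self, scape):
        win_lax = scape.valid_size_window(CriterionSpec("absolute", 0.7))
        win_strict = scape.valid_size_window(CriterionSpec("absolute", 0.9))
        assert win_lax is not None and win_strict is not None
        assert win_strict[0] >= win_lax[0] - 1e-9

    def test_criterion_at_global_asymptote_empty_window(self, scape):
        assert scape.valid_size_window(CriterionSpec("absolute", 0.99)) is None

    def test_window_contains_midway_size(self, scape):
        # the size whose unflanked performance is midway between the level and
        # the asymptote must be measurable
        crit = CriterionSpec("absolute", 0.8)
        target = (0.8 + 0.99) / 2
        lo, hi = 0.01, 10.0
        for _ in range(100):
            mid = math.sqrt(lo * hi)
            if scape.slice_asymptote(mid) < target:
                lo = mid
            else:
                hi = mid
        size_mid = math.sqrt(lo * hi)
        win = scape.valid_size_window(crit)
        assert win[0] <= size_mid <= win[1]


class TestAlternativeHingeTransform:
    def test_absolute_spacing_transform_is_selectable(self):
        params = LandscapeParams(
            eccentricity=5.0, unflanked_threshold_size=0.3, beta_shared=6.0,
            guess=0.25, asymptote=0.99,
            hinge=HingeSpec(hinge_location=math.log10(2.0), crowded_slope=-1.0,
                            transform="log_c2c"),
        )
        s = FlankedAcuityLandscape(params)
        # beyond 2 deg the location is unflanked regardless of size
        assert s.predict_pcorrect(0.3, 2.5) == pytest.approx(s.predict_pcorrect(0.3, UNFLANKED))
        assert s.predict_pcorrect(0.3, 1.0) < s.predict_pcorrect(0.3, 2.5)
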