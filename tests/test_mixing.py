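"""Dual-isotope mixing model: distances, groundwater fraction, depths, CI."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootwater import (
    EndMemberSet,
    IsotopeComposition,
    SlopePosition,
    TreeRecord,
    effective_rooting_depth,
    grand_mean_ci,
    groundwater_fraction,
    isotopic_distance,
    run_mixing,
)
from conftest import GROUNDWATER, SURFACE, TREE_MEAN


def _tree(comp, tree_id="T001", pos=SlopePosition.MIDSLOPE, day=1):
    return TreeRecord(
        tree_id=tree_id,
        genus="Quercus",
        species="prinus",
        dbh_cm=35.0,
        elevation_m=280.0,
        slope_position=pos,
        xylem=comp,
        date=dt.date(2009, 7, day),
    )


class TestIsotopicDistance:
    def test_zero_at_identity(self):
        assert isotopic_distance(SURFACE, SURFACE) == 0.0

    def test_surface_to_groundwater(self):
        # hand oracle: sqrt(2.4^2 + 9.0^2)
        assert isotopic_distance(SURFACE, GROUNDWATER) == pytest.approx(
            9.3145, abs=1e-4
        )

    def test_surface_to_tree_mean(self):
        # hand oracle: sqrt(0.8^2 + 2.9^2)
        assert isotopic_distance(SURFACE, TREE_MEAN) == pytest.approx(3.0083, abs=1e-4)

    @given(st.floats(0.1, 5.0))
    @settings(max_examples=25, derandomize=True)
    def test_scale_equivariance(self, k):
        a, b = SURFACE, TREE_MEAN
        scaled = isotopic_distance(
            IsotopeComposition(a.d18O * k, a.d2H * k),
            IsotopeComposition(b.d18O * k, b.d2H * k),
        )
        assert scaled == pytest.approx(k * isotopic_distance(a, b))


class TestGroundwaterFraction:
    def test_tree_at_surface(self, catchment_end_members):
        p, clamped = groundwater_fraction(catchment_end_members, SURFACE)
        assert p == 0.0 and not clamped

    def test_tree_at_groundwater(self, catchment_end_members):
        p, clamped = groundwater_fraction(catchment_end_members, GROUNDWATER)
        assert p == pytest.approx(1.0) and not clamped

    def test_catchment_mean_worked_example(self, catchment_end_members):
        p, clamped = groundwater_fraction(catchment_end_members, TREE_MEAN)
        assert p == pytest.approx(0.3230, abs=1e-4)
        assert not clamped

    def test_beyond_groundwater_clamps_to_one(self, catchment_end_members):
        far = IsotopeComposition(-11.0, -64.0)
        p, clamped = groundwater_fraction(catchment_end_members, far)
        assert p == 1.0 and clamped

    def test_translation_invariance(self, catchment_end_members):
        for dx, dy in [(1.3, -4.0), (-2.0, 7.5)]:
            em = EndMemberSet(
                "catchment",
                IsotopeComposition(SURFACE.d18O + dx, SURFACE.d2H + dy),
                IsotopeComposition(GROUNDWATER.d18O + dx, GROUNDWATER.d2H + dy),
            )
            tree = IsotopeComposition(TREE_MEAN.d18O + dx, TREE_MEAN.d2H + dy)
            p0, _ = groundwater_fraction(catchment_end_members, TREE_MEAN)
            p1, _ = groundwater_fraction(em, tree)
            assert p1 == pytest.approx(p0)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=50, derandomize=True)
    def test_on_segment_equals_interpolation_parameter(self, f):
        # oracle: the 1-D linear interpolation parameter along the segment
        em = EndMemberSet("catchment", SURFACE, GROUNDWATER)
        s, g = SURFACE.as_array(), GROUNDWATER.as_array()
        point = s + f * (g - s)
        p, clamped = groundwater_fraction(
            em, IsotopeComposition(point[0], point[1])
        )
        assert p == pytest.approx(f, abs=1e-12)
        assert not clamped

    def test_monotone_along_segment(self, catchment_end_members):
        s, g = SURFACE.as_array(), GROUNDWATER.as_array()
        fracs = np.linspace(0, 1, 25)
        ps = [
            groundwater_fraction(
                catchment_end_members,
                IsotopeComposition(*(s + f * (g - s))),
            )[0]
            for f in fracs
        ]
        assert all(b >= a for a, b in zip(ps, ps[1:]))


class TestEffectiveRootingDepth:
    @pytest.mark.parametrize(
        "p, depth, expected", [(0.0, 120, 0.0), (1.0, 120, 120.0),
                               (0.3230, 120, 38.76), (0.5, 30, 15.0)]
    )
    def test_proportionality(self, p, depth, expected):
        assert effective_rooting_depth(p, depth) == pytest.approx(expected, abs=0.01)

    def test_rejects_unclamped_fraction(self):
        with pytest.raises(ValueError):
            effective_rooting_depth(1.2, 120)


class TestRunMixing:
    def test_tree_at_surface_gives_zero_depth(self, catchment_end_members):
        [r] = run_mixing([_tree(SURFACE)], catchment_end_members)
        assert r.dw_cm == 0.0 and not r.clamped

    def test_midpoint_tree(self, catchment_end_members):
        s, g = SURFACE.as_array(), GROUNDWATER.as_array()
        mid = IsotopeComposition(*((s + g) / 2))
        [r] = run_mixing([_tree(mid)], catchment_end_members)
        assert r.p_g == pytest.approx(0.5)
        assert r.dw_cm == pytest.approx(60.0)

    def test_restricted_variant_is_quarter_of_full(self, catchment_end_members):
        trees = [
            _tree(TREE_MEAN, "T001"),
            _tree(IsotopeComposition(-7.0, -48.0), "T002"),
        ]
        full = run_mixing(trees, catchment_end_members, max_depth_cm=120.0)
        restricted = run_mixing(trees, catchment_end_members, max_depth_cm=30.0)
        for a, b in zip(full, restricted):
            assert b.dw_cm == pytest.approx(a.dw_cm / 4.0)

    def test_per_position_matching_and_missing_set(self):
        ems = {
            SlopePosition.MIDSLOPE: EndMemberSet(
                SlopePosition.MIDSLOPE, SURFACE, GROUNDWATER
            )
        }
        [r] = run_mixing([_tree(TREE_MEAN)], ems)
        assert r.end_members_used == SlopePosition.MIDSLOPE
        with pytest.raises(ValueError, match="slope position"):
            run_mixing([_tree(TREE_MEAN, pos=SlopePosition.RIDGE)], ems)


class TestGrandMeanCI:
    def _results(self, depths, em):
        trees = [
            _tree(IsotopeComposition(
                SURFACE.d18O + (GROUNDWATER.d18O - SURFACE.d18O) * d / 120.0,
                SURFACE.d2H + (GROUNDWATER.d2H - SURFACE.d2H) * d / 120.0,
            ), tree_id=f"T{i:03d}")
            for i, d in enumerate(depths)
        ]
        return run_mixing(trees, em)

    def test_identical_depths_zero_width(self, catchment_end_members):
        res = self._results([40.0, 40.0, 40.0], catchment_end_members)
        mean, lo, hi = grand_mean_ci(res)
        assert mean == pytest.approx(40.0)
        assert lo == pytest.approx(40.0) and hi == pytest.approx(40.0)

    def test_symmetric_about_mean(self, catchment_end_members):
        res = self._results([20.0, 40.0], catchment_end_members)
        # at a level where the t-interval stays inside [0, 120] the interval
        # is symmetric about the mean ...
        mean, lo, hi = grand_mean_ci(res, level=0.5)
        assert mean == pytest.approx(30.0)
        assert (mean - lo) == pytest.approx(hi - mean)
        # ... while at 95% with n = 2 it is truncated to the physical range
        _, lo95, hi95 = grand_mean_ci(res)
        assert lo95 == 0.0 and hi95 == 120.0

    def test_matches_scipy_t_interval(self, catchment_end_members):
        from scipy import stats

        depths = [10.0, 25.0, 40.0, 55.0, 70.0, 31.0]
        res = self._results(depths, catchment_end_members)
        mean, lo, hi = grand_mean_ci(res)
        ref_lo, ref_hi = stats.t.interval(
            0.95, len(depths) - 1, loc=np.mean(depths),
            scale=stats.sem(depths),
        )
        assert lo == pytest.approx(ref_lo)
        assert hi == pytest.approx(ref_hi)

    def test_dates_averaged_per_tree_first(self, catchment_end_members):
        s, g = SURFACE.as_array(), GROUNDWATER.as_array()

        def at(d):
            return IsotopeComposition(*(s + (g - s) * d / 120.0))

        trees = [
            _tree(at(20.0), "T001", day=1),
            _tree(at(60.0), "T001", day=20),  # same tree, second date
            _tree(at(40.0), "T002", day=1),
        ]
        res = run_mixing(trees, catchment_end_members)
        mean, *_ = grand_mean_ci(res)
        assert mean == pytest.approx(40.0)  # (mean(20,60) + 40) / 2

    def test_bootstrap_is_seeded_and_reasonable(self, catchment_end_members):
        res = self._results([10.0, 30.0, 42.0, 55.0, 70.0, 25.0, 38.0],
                            catchment_end_members)
        a = grand_mean_ci(res, method="bootstrap", seed=11)
        b = grand_mean_ci(res, method="bootstrap", seed=11)
        assert a == b
        mean, lo, hi = a
        assert lo < mean < hi

    def test_truncation_to_physical_range(self, catchment_end_members):
        res = self._results([1.0, 2.0], catchment_end_members)
        _, lo, _ = grand_mean_ci(res)
        assert lo >= 0.0

    def test_fewer_than_two_trees_rejected(self, catchment_end_members):
        res = self._results([40.0], catchment_end_members)
        with pytest.raises(ValueError):
            grand_mean_ci(res)
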