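"""Ellipse geometry, 100 m sampling and the inside-outside landscape tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from firestops.grids import RasterGrid
from firestops.landscape import (
    LandscapeStack,
    OrientedEllipse,
    attribute_landscape,
    build_ellipse,
    combine_fuel_load,
    sample_ellipse,
)
from firestops.landscape import test_categorical as categorical_test
from firestops.landscape import test_continuous as continuous_test
from firestops.landscape import test_downslope as downslope_test
from firestops.perimeter import extract_fire_stops

from conftest import make_scene


def straight_edge_scene(n=11, burn_cols=5, pixel=300.0):
    """Vertical fire edge: columns [0, burn_cols) burned on day 150."""
    dob = np.zeros((n, n), dtype=int)
    dob[:, :burn_cols] = 150
    return make_scene(dob, pixel_size=pixel)


def homogeneous_stack(scene, **overrides) -> LandscapeStack:
    nr, nc = scene.day_of_burn.shape
    ps = scene.pixel_size
    ext_r, ext_c = nr * ps, nc * ps

    def grid(res, value):
        shape = (int(np.ceil(ext_r / res)), int(np.ceil(ext_c / res)))
        return RasterGrid(np.full(shape, value, dtype=float), pixel_size=res, origin=(0.0, 0.0))

    layers = {
        "tree_cover": grid(30.0, 45.0),
        "agb": grid(100.0, 48.0),
        "land_cover": grid(345.0, 1),
        "burn_history": grid(300.0, 9999.0),
        "elevation": grid(30.0, 200.0),
        "road_presence": grid(30.0, 0),
        "water_presence": grid(30.0, 0),
    }
    layers.update(overrides)
    return LandscapeStack(**layers)


def mid_stop(scene):
    stops = extract_fire_stops(scene)
    mid = len(scene.day_of_burn.data) // 2
    return stops[(stops["row"] == mid) & (stops["direction_defined"])].iloc[0]


class TestBuildEllipse:
    def test_default_axes_are_900_by_450_m(self):
        scene = straight_edge_scene()
        ell = build_ellipse(mid_stop(scene), scene)
        assert 2 * ell.semi_major == pytest.approx(3 * 300.0)
        assert 2 * ell.semi_minor == pytest.approx(1.5 * 300.0)

    def test_center_is_midpoint_of_stop_and_nearest_burned(self):
        scene = straight_edge_scene()
        stop = mid_stop(scene)
        ell = build_ellipse(stop, scene)
        sx, sy = scene.day_of_burn.cell_center(stop["row"], stop["col"])
        bx, by = scene.day_of_burn.cell_center(stop["nb_row"], stop["nb_col"])
        assert ell.center == pytest.approx(((sx + bx) / 2, (sy + by) / 2))
        assert ell.orientation == pytest.approx((1.0, 0.0))

    def test_midpoint_worked_example(self):
        # stop center (450, 150), nearest burned (150, 150) -> center (300, 150)
        dob = np.zeros((1, 2), dtype=int)
        dob[0, 0] = 150
        scene = make_scene(dob)
        stop = extract_fire_stops(scene).iloc[0]
        ell = build_ellipse(stop, scene)
        assert (stop["x"], stop["y"]) == pytest.approx((450.0, -150.0))
        assert ell.center == pytest.approx((300.0, -150.0))
        assert ell.orientation == pytest.approx((1.0, 0.0))

    def test_undefined_direction_gives_no_ellipse(self):
        scene = straight_edge_scene()
        stop = mid_stop(scene).copy()
        stop["direction_defined"] = False
        assert build_ellipse(stop, scene) is None

    def test_degenerate_axes_rejected(self):
        with pytest.raises(ValueError):
            OrientedEllipse(center=(0, 0), semi_major=100, semi_minor=200, orientation=(1, 0))


class TestSampleEllipse:
    def test_point_count_and_coverage_for_default_geometry(self):
        scene = straight_edge_scene()
        ell = build_ellipse(mid_stop(scene), scene)
        s = sample_ellipse(ell, scene, homogeneous_stack(scene))
        assert 29 <= len(s) <= 35
        coverage = len(s) * 100.0**2 / ell.area
        assert 0.85 <= coverage <= 1.1

    def test_all_samples_inside_ellipse_by_shapely_oracle(self):
        shapely = pytest.importorskip("shapely")
        from shapely import affinity
        from shapely.geometry import Point

        scene = straight_edge_scene()
        ell = build_ellipse(mid_stop(scene), scene)
        s = sample_ellipse(ell, scene, homogeneous_stack(scene))
        circle = Point(ell.center).buffer(1.0, quad_segs=256)
        poly = affinity.scale(circle, ell.semi_major, ell.semi_minor, origin=ell.center)
        ang = np.degrees(np.arctan2(ell.orientation[1], ell.orientation[0]))
        poly = affinity.rotate(poly, ang, origin=ell.center)
        assert all(poly.contains(Point(x, y)) for x, y in zip(s["x"], s["y"]))

    def test_straight_perimeter_burned_fraction_near_half(self):
        scene = straight_edge_scene()
        ell = build_ellipse(mid_stop(scene), scene)
        s = sample_ellipse(ell, scene, homogeneous_stack(scene))
        assert 0.4 <= s["burned"].mean() <= 0.6

    def test_homogeneous_layer_groups_have_equal_means(self):
        scene = straight_edge_scene()
        ell = build_ellipse(mid_stop(scene), scene)
        s = sample_ellipse(ell, scene, homogeneous_stack(scene))
        assert s.groupby("burned")["tree_cover"].mean().nunique() == 1

    def test_water_band_outside_raises_unburned_fraction(self):
        scene = straight_edge_scene()
        water = homogeneous_stack(scene).water_presence
        # river: everything east of the fire edge (x > 1500 m)
        cols = np.arange(water.shape[1])
        water.data[:, (cols + 0.5) * 30.0 > 1500.0] = 1
        stack = homogeneous_stack(scene, water_presence=water)
        ell = build_ellipse(mid_stop(scene), scene)
        s = sample_ellipse(ell, scene, stack)
        frac = s.groupby("burned")["water"].mean()
        assert frac[False] > frac[True]

    def test_burn_history_years_mapped_to_fuel_reduction(self):
        scene = straight_edge_scene()
        hist = homogeneous_stack(scene).burn_history
        hist.data[:] = 5.0  # 5 years since fire, R = 25 -> reduction 0.8
        stack = homogeneous_stack(scene, burn_history=hist)
        ell = build_ellipse(mid_stop(scene), scene)
        s = sample_ellipse(ell, scene, stack)
        assert s["burn_history"].unique() == pytest.approx([0.8])


class TestContinuous:
    def sample(self, inside, outside, rng, sd=5.0, n=16):
        return pd.DataFrame(
            {
                "burned": [True] * n + [False] * n,
                "tree_cover": np.concatenate(
                    [rng.normal(inside, sd, n), rng.normal(outside, sd, n)]
                ),
            }
        )

    def test_realistic_tree_cover_drop_passes(self, rng):
        # inside 45%, outside 26%: the magnitude typical of fuel-load stops
        t, p, ok = continuous_test(self.sample(45.0, 26.0, rng), "tree_cover")
        assert ok and p < 0.01 and t > 0

    def test_identical_groups_do_not_pass(self, rng):
        s = self.sample(45.0, 45.0, rng, sd=0.0)
        t, p, ok = continuous_test(s, "tree_cover")
        assert not ok and p == 1.0

    def test_direction_gate_blocks_higher_cover_outside(self, rng):
        t, p, ok = continuous_test(self.sample(26.0, 45.0, rng), "tree_cover")
        assert p < 0.01 and not ok

    def test_p_matches_independent_welch_oracle(self, rng):
        s = self.sample(45.0, 40.0, rng)
        t, p, _ = continuous_test(s, "tree_cover")
        a = s.loc[s.burned, "tree_cover"].to_numpy()
        b = s.loc[~s.burned, "tree_cover"].to_numpy()
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t0 = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        assert t == pytest.approx(t0, abs=1e-10)
        assert p == pytest.approx(2 * special.stdtr(df, -abs(t0)), abs=1e-10)

    def test_tiny_group_is_untestable(self, rng):
        s = self.sample(45.0, 26.0, rng)
        s = pd.concat([s[s.burned], s[~s.burned].head(2)])
        t, p, ok = continuous_test(s, "tree_cover")
        assert not ok and np.isnan(p)


class TestCategorical:
    def presence_sample(self, layer, inside_pos, inside_n, outside_pos, outside_n):
        vals = (
            [1.0] * inside_pos + [0.0] * (inside_n - inside_pos)
            + [1.0] * outside_pos + [0.0] * (outside_n - outside_pos)
        )
        return pd.DataFrame(
            {"burned": [True] * inside_n + [False] * outside_n, layer: vals}
        )

    def test_water_contrast_matches_contingency_oracle(self):
        # burned 0/15 water, unburned 12/17 water
        s = self.presence_sample("water", 0, 15, 12, 17)
        chi2, p, ok, direction_ok = categorical_test(s, "water")
        table = np.array([[15.0, 0.0], [5.0, 12.0]])
        exp = stats.contingency.expected_freq(table)
        chi2_0 = float((((np.abs(table - exp) - 0.5) ** 2) / exp).sum())  # Yates
        p0 = float(special.chdtrc(1, chi2_0))
        assert chi2 == pytest.approx(chi2_0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)
        assert ok and direction_ok

    def test_identical_distributions_give_p_one(self):
        s = self.presence_sample("water", 5, 10, 5, 10)
        chi2, p, ok, _ = categorical_test(s, "water")
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert not ok

    def test_water_higher_inside_fails_direction_gate(self):
        s = self.presence_sample("water", 12, 17, 0, 15)
        chi2, p, ok, direction_ok = categorical_test(s, "water")
        assert p < 0.01 and not ok and not direction_ok

    def test_single_class_is_untestable(self):
        s = self.presence_sample("road", 0, 10, 0, 10)
        chi2, p, ok, _ = categorical_test(s, "road")
        assert p == 1.0 and not ok

    def test_2x2_with_tiny_expected_count_skipped(self):
        s = self.presence_sample("water", 0, 3, 1, 3)
        chi2, p, ok, _ = categorical_test(s, "water")
        assert not ok and np.isnan(p)

    def test_land_cover_gate_needs_new_dominant_class_outside(self):
        # inside all class 1; outside mostly class 2: gaining class differs
        s = pd.DataFrame(
            {
                "burned": [True] * 15 + [False] * 15,
                "land_cover": [1.0] * 15 + [2.0] * 13 + [1.0] * 2,
            }
        )
        chi2, p, ok, direction_ok = categorical_test(s, "land_cover")
        assert ok and direction_ok
        # outside still dominated by the inside's modal class: gate closes
        s2 = pd.DataFrame(
            {
                "burned": [True] * 15 + [False] * 15,
                "land_cover": [1.0] * 14 + [2.0] * 1 + [1.0] * 15,
            }
        )
        _, _, ok2, dir2 = categorical_test(s2, "land_cover")
        assert not dir2 and not ok2


class TestDownslope:
    def ramp_sample(self, slope_deg, rng, noise=0.3, n=16):
        along = np.concatenate([rng.uniform(-400, -50, n), rng.uniform(50, 400, n)])
        elev = 200.0 + np.tan(np.radians(slope_deg)) * along + rng.normal(0, noise, 2 * n)
        return pd.DataFrame(
            {"burned": along < 0, "along": along, "elevation": elev}
        )

    def test_flat_terrain_not_flagged(self, rng):
        s = self.ramp_sample(0.0, rng, noise=0.0)
        slope, p, ok = downslope_test(s)
        assert not ok

    def test_minus_ten_degree_ramp_flagged(self, rng):
        s = self.ramp_sample(-10.0, rng)
        slope, p, ok = downslope_test(s)
        assert ok and slope <= -5.0
        # slope oracle: linear fit of elevation on the along-axis position
        fit = np.polyfit(s["along"], s["elevation"], 1)
        assert slope == pytest.approx(np.degrees(np.arctan(fit[0])), abs=1.0)

    def test_minus_three_degree_ramp_significant_but_below_threshold(self, rng):
        s = self.ramp_sample(-3.0, rng, noise=0.1)
        slope, p, ok = downslope_test(s)
        assert p < 0.01 and -5.0 < slope < 0.0 and not ok

    def test_uphill_not_flagged(self, rng):
        s = self.ramp_sample(10.0, rng)
        _, _, ok = downslope_test(s)
        assert not ok


class TestFuelLoadAndDriver:
    @pytest.mark.parametrize(
        "tree,agb,expected",
        [(True, False, True), (False, True, True), (True, True, True), (False, False, False)],
    )
    def test_fuel_load_is_disjunction(self, tree, agb, expected):
        assert combine_fuel_load(tree, agb) is expected

    def test_attribute_landscape_flags_planted_water(self):
        scene = straight_edge_scene()
        water = homogeneous_stack(scene).water_presence
        cols = np.arange(water.shape[1])
        water.data[:, (cols + 0.5) * 30.0 > 1500.0] = 1
        stack = homogeneous_stack(scene, water_presence=water)
        rec = attribute_landscape(mid_stop(scene), scene, stack)
        assert rec["landscape_testable"]
        assert rec["water"] and not rec["road"] and not rec["fuel_load"]

    def test_homogeneous_world_flags_nothing(self):
        scene = straight_edge_scene()
        rec = attribute_landscape(mid_stop(scene), scene, homogeneous_stack(scene))
        assert rec["landscape_testable"]
        assert not any(
            rec[k] for k in ("water", "road", "burn_history", "fuel_load", "land_cover", "downslope")
        )


class TestRotationEquivariance:
    def outcomes(self, scene, stack):
        stops = extract_fire_stops(scene)
        flags = []
        for _, stop in stops[stops["direction_defined"]].iterrows():
            rec = attribute_landscape(stop, scene, stack)
            flags.append(
                tuple(
                    rec[k]
                    for k in ("water", "road", "burn_history", "fuel_load", "land_cover", "downslope")
                )
            )
        return sorted(flags)

    def test_quarter_turn_preserves_all_test_outcomes(self, rng):
        scene = straight_edge_scene(n=9, burn_cols=4)
        stack = homogeneous_stack(scene)
        stack.tree_cover.data += rng.normal(0, 3, stack.tree_cover.shape)
        cols = np.arange(stack.water_presence.shape[1])
        stack.water_presence.data[:, (cols + 0.5) * 30.0 > 1200.0] = 1

        # rotate every grid a quarter turn counterclockwise
        rot_scene = make_scene(np.rot90(scene.day_of_burn.data))
        rot_layers = {
            name: grid.like(np.rot90(grid.data))
            for name, grid in {
                "tree_cover": stack.tree_cover,
                "agb": stack.agb,
                "land_cover": stack.land_cover,
                "burn_history": stack.burn_history,
                "elevation": stack.elevation,
                "road_presence": stack.road_presence,
                "water_presence": stack.water_presence,
            }.items()
        }
        rot_stack = LandscapeStack(**rot_layers)
        assert self.outcomes(scene, stack) == self.outcomes(rot_scene, rot_stack)
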