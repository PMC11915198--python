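"""VPD/WFSI computation, window extraction and the two-stage weather test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from firestops.fire_weather import (
    SPLIT_INDEX,
    WINDOW_HOURS,
    attribute_weather,
    compute_vpd,
    compute_wfsi,
    dewpoint_for_vpd,
    extract_window,
    make_weather_cube,
    saturation_vapor_pressure,
    split_ttest,
)


class TestVpd:
    def test_saturated_air_has_zero_vpd(self):
        assert compute_vpd(15.0, 15.0) == pytest.approx(0.0)

    def test_magnus_expression_evaluated_independently(self):
        # independent evaluation of e_s(30) - e_s(15)
        es = lambda t: 0.6112 * np.exp(17.62 * t / (243.12 + t))
        assert compute_vpd(30.0, 15.0) == pytest.approx(es(30.0) - es(15.0), rel=1e-12)

    def test_against_saturation_pressure_table(self):
        # standard table values (kPa): e_s(20 degC) = 2.339, e_s(10 degC) = 1.228
        assert saturation_vapor_pressure(20.0) == pytest.approx(2.339, rel=0.01)
        assert saturation_vapor_pressure(10.0) == pytest.approx(1.228, rel=0.01)
        assert compute_vpd(20.0, 10.0) == pytest.approx(2.339 - 1.228, rel=0.02)

    def test_slight_supersaturation_clamps_to_zero(self):
        assert compute_vpd(15.0, 15.3) == pytest.approx(0.0)

    def test_gross_supersaturation_propagates_nan(self):
        assert np.isnan(compute_vpd(15.0, 16.0))

    def test_nonfinite_input_propagates(self):
        assert np.isnan(compute_vpd(np.nan, 10.0))

    @given(
        t=st.floats(min_value=-20, max_value=40),
        vpd=st.floats(min_value=0.01, max_value=2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_dewpoint_inversion_roundtrip(self, t, vpd):
        vpd = min(vpd, saturation_vapor_pressure(t) * 0.95)
        d = dewpoint_for_vpd(t, vpd)
        assert compute_vpd(t, d) == pytest.approx(vpd, abs=1e-9)


class TestWfsi:
    def test_wind_along_outward_direction_is_positive_speed(self):
        assert compute_wfsi(5.0, 0.0, (1.0, 0.0)) == pytest.approx(5.0)

    def test_wind_opposing_is_negative_speed(self):
        assert compute_wfsi(-5.0, 0.0, (1.0, 0.0)) == pytest.approx(-5.0)

    def test_perpendicular_wind_is_zero(self):
        assert compute_wfsi(0.0, 5.0, (1.0, 0.0)) == pytest.approx(0.0)

    def test_nonunit_direction_rejected(self):
        with pytest.raises(ValueError):
            compute_wfsi(1.0, 1.0, (1.0, 1.0))

    @given(
        angle=st.floats(min_value=0, max_value=2 * np.pi),
        rot=st.floats(min_value=0, max_value=2 * np.pi),
        speed=st.floats(min_value=0, max_value=30),
    )
    @settings(max_examples=100, deadline=None)
    def test_rotation_invariance(self, angle, rot, speed):
        """Rotating wind and outward direction together leaves WFSI unchanged."""
        u, v = speed * np.cos(angle), speed * np.sin(angle)
        n = (1.0, 0.0)
        base = compute_wfsi(u, v, n)
        c, s = np.cos(rot), np.sin(rot)
        u2, v2 = c * u - s * v, s * u + c * v
        n2 = (c * n[0] - s * n[1], s * n[0] + c * n[1])
        n2 = (n2[0] / np.hypot(*n2), n2[1] / np.hypot(*n2))
        assert compute_wfsi(u2, v2, n2) == pytest.approx(base, abs=1e-9)


def welch_oracle(a, b):
    """Closed-form Welch t and p via the independent distribution functions."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2 * special.stdtr(df, -abs(t))
    return t, p


class TestSplitTtest:
    def test_identical_halves_p_one_no_pass(self):
        v = np.tile(np.sin(np.arange(24) / 24 * 2 * np.pi), 10)
        t, p, ok = split_ttest(v, direction="decline")
        assert p == pytest.approx(1.0)
        assert not ok

    def test_matches_closed_form_welch_oracle(self, rng):
        before = rng.normal(1.5, 0.2, 120)
        after = rng.normal(0.5, 0.2, 120)
        t, p, ok = split_ttest(np.concatenate([before, after]), direction="decline")
        t0, p0 = welch_oracle(before, after)
        assert t == pytest.approx(t0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)
        assert ok  # a 5-sigma decline at n=120 is overwhelming

    def test_direction_gate_blocks_wrong_sign(self, rng):
        before = rng.normal(0.5, 0.2, 120)
        after = rng.normal(1.5, 0.2, 120)
        _, p, ok = split_ttest(np.concatenate([before, after]), direction="decline")
        assert p < 1e-10 and not ok
        _, _, ok_inc = split_ttest(np.concatenate([before, after]), direction="increase")
        assert ok_inc

    def test_zero_variance_equal_means(self):
        t, p, ok = split_ttest(np.ones(240), direction="decline")
        assert (t, p, ok) == (0.0, 1.0, False)

    def test_zero_variance_unequal_means_passes(self):
        v = np.concatenate([np.ones(120), np.zeros(120)])
        t, p, ok = split_ttest(v, direction="decline")
        assert p == 0.0 and ok
        _, _, ok_inc = split_ttest(v, direction="increase")
        assert not ok_inc

    def test_pooled_variant_differs_only_in_df(self, rng):
        v = np.concatenate([rng.normal(1, 0.3, 120), rng.normal(0.8, 0.1, 120)])
        _, p_w, _ = split_ttest(v, direction="decline", equal_var=False)
        _, p_s, _ = split_ttest(v, direction="decline", equal_var=True)
        assert p_w != p_s  # both forms available; Welch is the default


def make_cube(n_days=20, start_doy=170, vpd=1.5, step_hour=None, step=0.0, ncell=2):
    hours = np.arange(n_days * 24)
    vpd_series = np.full(hours.size, vpd)
    if step_hour is not None:
        vpd_series[step_hour:] += step
    t2m = np.full(hours.size, 20.0)
    d2m = dewpoint_for_vpd(t2m, vpd_series)
    shape = (hours.size, ncell, ncell)
    zeros = np.zeros(shape)
    cell = 3000.0
    x = (np.arange(ncell) + 0.5) * cell
    y = (ncell - np.arange(ncell) - 0.5) * cell
    return make_weather_cube(
        np.broadcast_to(t2m[:, None, None], shape),
        np.broadcast_to(d2m[:, None, None], shape),
        zeros + 2.0,
        zeros,
        zeros + 0.25,
        x=x,
        y=y,
        start_doy=start_doy,
    )


def stop_row(x=1000.0, y=1000.0, doy=180, direction=(1.0, 0.0)):
    return pd.Series(
        {
            "x": x, "y": y, "last_burn_date": doy,
            "dir_x": direction[0], "dir_y": direction[1], "direction_defined": True,
        }
    )


class TestExtractWindow:
    def test_window_shape_and_split(self):
        w = extract_window(make_cube(), stop_row())
        assert len(w) == WINDOW_HOURS == 240
        assert SPLIT_INDEX == 120

    def test_planted_step_lands_at_index_120(self):
        # step at the end of the last burn day (doy 180, cube starts 170)
        cube = make_cube(step_hour=(181 - 170) * 24, step=-1.0)
        w = extract_window(cube, stop_row(doy=180))
        assert w["vpd"][:120].std() == pytest.approx(0.0, abs=1e-12)
        assert w["vpd"][119] - w["vpd"][120] == pytest.approx(1.0, abs=1e-9)

    def test_stop_too_close_to_cube_edge_is_excluded(self):
        assert extract_window(make_cube(), stop_row(doy=172)) is None
        assert extract_window(make_cube(), stop_row(doy=188)) is None

    def test_cell_boundary_ties_break_to_lower_index(self):
        cube = make_cube()
        cube["sm"].values[:, :, 0] = 0.30  # mark column x-index 0
        w = extract_window(cube, stop_row(x=3000.0))  # exactly between the two columns
        assert (w["sm"] == 0.30).all()

    def test_wfsi_uses_outward_direction(self):
        w_east = extract_window(make_cube(), stop_row(direction=(1.0, 0.0)))
        w_west = extract_window(make_cube(), stop_row(direction=(-1.0, 0.0)))
        assert (w_east["wfsi"] == 2.0).all()
        assert (w_west["wfsi"] == -2.0).all()


class TestAttributeWeather:
    def window(self, vpd=None, sm=None, wfsi=None, rng=None):
        n = WINDOW_HOURS
        base = lambda level: np.full(n, float(level))
        df = pd.DataFrame(
            {
                "hour": np.arange(n),
                "vpd": base(1.5) if vpd is None else vpd,
                "sm": base(0.25) if sm is None else sm,
                "wfsi": base(2.0) if wfsi is None else wfsi,
            }
        )
        if rng is not None:
            df["vpd"] += rng.normal(0, 0.1, n)
            df["sm"] += rng.normal(0, 0.01, n)
            df["wfsi"] += rng.normal(0, 0.3, n)
        return df

    def step(self, level, delta, at=120):
        v = np.full(WINDOW_HOURS, float(level))
        v[at:] += delta
        return v

    def test_planted_vpd_step_flags_vpd_and_fuel_moisture(self, rng):
        out = attribute_weather(self.window(vpd=self.step(1.5, -1.0), rng=rng))
        assert out["vpd_decline"] and out["fuel_moisture"]
        assert not out["sm_increase"]

    def test_sm_rise_alone_flags_fuel_moisture_via_sm(self, rng):
        out = attribute_weather(self.window(sm=self.step(0.25, 0.08), rng=rng))
        assert out["sm_increase"] and not out["vpd_decline"]
        assert out["fuel_moisture"]

    def test_wfsi_reversal_flags_wfsi_only(self, rng):
        out = attribute_weather(self.window(wfsi=self.step(4.0, -8.0), rng=rng))
        assert out["wfsi_decline"]
        assert not out["fuel_moisture"]

    def test_step_four_days_late_fails_timing_window(self, rng):
        # t-test sees a big after-mean change, but the break is at day +4
        out = attribute_weather(self.window(vpd=self.step(1.5, -1.5, at=120 + 96), rng=rng))
        assert not out["vpd_decline"]

    def test_flat_series_flags_nothing(self, rng):
        out = attribute_weather(self.window(rng=rng))
        assert not (out["vpd_decline"] or out["sm_increase"] or out["wfsi_decline"])

    def test_fuel_moisture_is_disjunction(self, rng):
        out = attribute_weather(
            self.window(vpd=self.step(1.5, -1.0), sm=self.step(0.25, 0.08), rng=rng)
        )
        assert out["vpd_decline"] and out["sm_increase"] and out["fuel_moisture"]

    def test_nan_wfsi_excluded_not_flagged(self, rng):
        w = self.window(rng=rng)
        w["wfsi"] = np.nan
        out = attribute_weather(w)
        assert not out["wfsi_decline"] and np.isnan(out["wfsi_t"])
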