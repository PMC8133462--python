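import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mobimeter as mm
from conftest import toy_records

H = 3600


def towers_df(coords):
    return pd.DataFrame([(f"T{i}", 0, x, y) for i, (x, y) in enumerate(coords)],
                        columns=["tower_id", "city", "x", "y"])


class TestFilterUsers:
    @pytest.mark.parametrize("n_records,span_hours,kept", [
        (25, 100, True),     # both thresholds met
        (19, 120, False),    # one record short of 20
        (30, 95, False),     # one hour short of 96
        (20, 96, True),      # exactly at both thresholds
    ])
    def test_selection_rules(self, n_records, span_hours, kept):
        ts = np.linspace(0, span_hours * H, n_records)
        recs = toy_records([("a", "T0", t, "connect") for t in ts])
        out = mm.filter_users(recs)
        assert ("a" in out) == kept

    def test_empty_input_empty_output(self):
        assert len(mm.filter_users(toy_records([]))) == 0

    def test_thresholds_configurable(self):
        recs = toy_records([("a", "T0", t, "connect")
                            for t in np.linspace(0, 10 * H, 5)])
        rules = mm.SelectionRules(min_records=5, min_span_hours=10)
        assert "a" in mm.filter_users(recs, rules)


class TestDwellTimes:
    def test_hour_split_between_two_towers(self):
        recs = toy_records([
            ("a", "A", 0, "connect"), ("a", "A", 1800, "disconnect"),
            ("a", "B", 1800, "connect")])
        d = mm.dwell_times(recs, (0, H))
        assert d["A"] == 1800 and d["B"] == 1800

    def test_single_connect_fills_window(self):
        recs = toy_records([("a", "A", 0, "connect")])
        d = mm.dwell_times(recs, (0, H))
        assert d["A"] == H

    def test_disconnect_opens_a_gap(self):
        recs = toy_records([
            ("a", "A", 0, "connect"), ("a", "A", 600, "disconnect"),
            ("a", "B", 3000, "connect")])
        d = mm.dwell_times(recs, (0, H))
        assert d["A"] == 600 and d["B"] == 600

    def test_service_event_renews_tower(self):
        recs = toy_records([
            ("a", "A", 0, "connect"), ("a", "A", 1200, "service"),
            ("a", "B", 2400, "connect")])
        d = mm.dwell_times(recs, (0, H))
        assert d["A"] == 2400 and d["B"] == 1200

    def test_reconnects_to_same_tower_merge(self):
        """Interval-union oracle: dwell to one tower equals the union length
        of its intervals regardless of how often the phone reconnects."""
        rng = np.random.default_rng(0)
        cuts = np.sort(rng.uniform(0, H, 9))
        bounds = np.concatenate([[0.0], cuts, [H]])
        towers = rng.choice(["A", "B"], size=len(bounds) - 1)
        recs = toy_records([("a", t, b, "connect")
                            for t, b in zip(towers, bounds[:-1])])
        d = mm.dwell_times(recs, (0, H))
        expect = {t: float(np.sum((bounds[1:] - bounds[:-1])[towers == t]))
                  for t in "AB"}
        for t in "AB":
            assert d.get(t, 0.0) == pytest.approx(expect[t])
        assert d.sum() == pytest.approx(H)

    def test_unknown_tower_is_hard_error(self):
        recs = toy_records([("a", "GHOST", 0, "connect")])
        with pytest.raises(KeyError, match="GHOST"):
            mm.dwell_times(recs, (0, H), towers_df([(0, 0)]))

    def test_no_double_counting_across_hour_windows(self):
        """A connection spanning several hours contributes each second to
        exactly one half-open hour window."""
        recs = toy_records([("a", "T0", 500, "connect"),
                            ("a", "T0", 3 * H + 100, "disconnect")])
        tw = towers_df([(0, 0)])
        total = sum(mm.dwell_times(recs, (k * H, (k + 1) * H)).sum()
                    for k in range(4))
        assert total == pytest.approx(3 * H + 100 - 500)
        hd = mm.hourly_dwell(recs, tw, end_time=4 * H)
        assert hd["seconds"].sum() == pytest.approx(3 * H + 100 - 500)


class TestWeightedPosition:
    def test_single_tower(self):
        tw = towers_df([(0, 0)])
        assert mm.weighted_position(pd.Series({"T0": 100.0}), tw) == (0.0, 0.0)

    def test_equal_dwell_midpoint(self):
        tw = towers_df([(0, 0), (100, 0)])
        d = pd.Series({"T0": 5.0, "T1": 5.0})
        assert mm.weighted_position(d, tw) == (50.0, 0.0)

    def test_three_tower_weighted_sum(self):
        """Direct arithmetic: dwell 10/20/30 min over (0,0),(100,0),(0,100)
        gives (100*2/6, 100*3/6) = (33.33, 50)."""
        tw = towers_df([(0, 0), (100, 0), (0, 100)])
        d = pd.Series({"T0": 600.0, "T1": 1200.0, "T2": 1800.0})
        x, y = mm.weighted_position(d, tw)
        assert x == pytest.approx(33.3333, abs=1e-3)
        assert y == pytest.approx(50.0)

    def test_zero_dwell_is_no_fix(self):
        with pytest.raises(ValueError, match="no position fix"):
            mm.weighted_position(pd.Series({"T0": 0.0}), towers_df([(0, 0)]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4),
                              st.floats(1.0, 1e5)),
                    min_size=1, max_size=6),
           st.floats(0.01, 100.0))
    def test_convex_hull_and_rescale_invariance(self, towers, scale):
        """The position lies in the towers' bounding box (hence convex hull
        for axis extremes) and is invariant to rescaling all dwell times."""
        tw = towers_df([(x, y) for x, y, _ in towers])
        d = pd.Series({f"T{i}": w for i, (_, _, w) in enumerate(towers)})
        x, y = mm.weighted_position(d, tw)
        assert min(t[0] for t in towers) - 1e-6 <= x <= max(t[0] for t in towers) + 1e-6
        assert min(t[1] for t in towers) - 1e-6 <= y <= max(t[1] for t in towers) + 1e-6
        x2, y2 = mm.weighted_position(d * scale, tw)
        assert x2 == pytest.approx(x, rel=1e-9, abs=1e-9)
        assert y2 == pytest.approx(y, rel=1e-9, abs=1e-9)


class TestInferHomes:
    def test_all_nights_one_tower(self):
        tw = towers_df([(500, 700)])
        recs = toy_records([("a", "T0", 0, "connect"),
                            ("a", "T0", 6 * H, "disconnect")])
        dwell = mm.hourly_dwell(recs, tw, end_time=6 * H)
        homes = mm.infer_homes(dwell, tw)
        assert homes.loc[0, "x"] == 500 and homes.loc[0, "y"] == 700
        assert homes.loc[0, "total_night_seconds"] == pytest.approx(6 * H)

    def test_equal_night_dwell_midpoint_pooled_across_days(self):
        tw = towers_df([(0, 0), (1000, 0)])
        recs = toy_records([
            ("a", "T0", 0, "connect"), ("a", "T0", 6 * H, "disconnect"),
            ("a", "T1", 24 * H, "connect"), ("a", "T1", 30 * H, "disconnect")])
        dwell = mm.hourly_dwell(recs, tw, end_time=40 * H)
        homes = mm.infer_homes(dwell, tw)
        assert homes.loc[0, "x"] == pytest.approx(500.0)

    def test_daytime_only_phone_has_no_home(self):
        tw = towers_df([(0, 0)])
        recs = toy_records([("a", "T0", 10 * H, "connect"),
                            ("a", "T0", 12 * H, "disconnect")])
        dwell = mm.hourly_dwell(recs, tw, end_time=12 * H)
        assert mm.infer_homes(dwell, tw).empty

    def test_noiseless_world_home_recovery(self, world_small, geo_small):
        """With noiseless logs the median home error is at most half the
        tower spacing (generator ground truth comparison)."""
        est = geo_small["homes"].merge(world_small.homes, on="phone_id",
                                       suffixes=("_est", "_true"))
        err = np.hypot(est["x_est"] - est["x_true"],
                       est["y_est"] - est["y_true"])
        assert err.median() <= world_small.config.tower_spacing / 2


class TestBinDistance:
    @pytest.mark.parametrize("d,mid,censored", [
        (0.0, 50.0, False),
        (150.0, 150.0, False),       # interval (100, 200]
        (100.0, 50.0, False),        # boundary belongs to the lower interval
        (200.0, 150.0, False),
        (49_951.0, 49_950.0, False),
        (50_000.0, 49_950.0, False),
        (60_000.0, 50_000.0, True),  # censored at 50 km
    ])
    def test_binning(self, d, mid, censored):
        got_mid, got_c = mm.bin_distance(d)
        assert got_mid == mid and got_c == censored

    def test_negative_distance_is_upstream_bug(self):
        with pytest.raises(ValueError):
            mm.bin_distance(-1.0)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 2e5))
    def test_idempotent_and_censor_flag_consistent(self, d):
        mid, c = mm.bin_distance(d)
        assert c == (mid == 50_000.0)
        if not c:
            # uncensored midpoints are fixed points of the binning
            mid2, c2 = mm.bin_distance(mid)
            assert mid2 == mid and not c2
        assert mid in set(np.arange(50.0, 50_000.0, 100.0)) | {50_000.0}


class TestPipelineConsistency:
    def test_hourly_position_error_bounded(self, world_small, noiseless_run,
                                           geo_small):
        """Noiseless one-tower hours place the phone at the nearest tower, so
        position error is at most half the cell diagonal for >= 95% of
        phone-hours."""
        pos = noiseless_run["positions"]
        got = geo_small["placements"].merge(
            pos, on=["phone_id", "day", "hour"], suffixes=("_est", "_true"))
        err = np.hypot(got["x_est"] - got["x_true"],
                       got["y_est"] - got["y_true"])
        bound = world_small.config.tower_spacing * np.sqrt(2) / 2
        assert (err <= bound + 1e-9).mean() >= 0.95

    def test_distance_binning_matches_raw_distance(self, geo_small):
        pl = geo_small["placements"]
        mid, cens = mm.bin_distance(pl["distance"].to_numpy())
        assert np.array_equal(mid, pl["distance_mid"].to_numpy())
        assert np.array_equal(cens, pl["censored_upper"].to_numpy())
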