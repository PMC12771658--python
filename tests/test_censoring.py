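import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divebudget.censoring import (
    CensorResult, apply_censor, censor_all, censor_bird, daily_displacement,
    detect_changepoints, haversine_km,
)

coord = st.tuples(st.floats(-89, 89), st.floats(-179, 179))


def _fixes(times, lats, lons, bird="b1"):
    return pd.DataFrame({
        "bird_id": bird, "timestamp_utc": pd.to_datetime(times),
        "lat": lats, "lon": lons,
    })


class TestHaversine:
    def test_zero_distance(self):
        assert haversine_km(39.0, -76.2, 39.0, -76.2) == 0.0

    def test_one_degree_longitude_at_equator(self):
        # 2*pi*6371/360 = 111.195 km
        assert haversine_km(0, 0, 0, 1) == pytest.approx(111.195, abs=0.001)

    @settings(deadline=None, max_examples=100)
    @given(coord, coord)
    def test_symmetry(self, p1, p2):
        assert haversine_km(*p1, *p2) == pytest.approx(haversine_km(*p2, *p1))

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            haversine_km(91, 0, 0, 0)


class TestDailyDisplacement:
    def test_two_fixes_one_degree_apart(self):
        f = _fixes(["2023-01-03T06:00", "2023-01-03T07:00"], [0.0, 0.0], [0.0, 1.0])
        d = daily_displacement(f, release_date="2023-01-02")
        assert d.loc[d["day"] == 1, "km"].iloc[0] == pytest.approx(111.195, abs=0.001)

    def test_stationary_bird_travels_zero(self):
        times = pd.date_range("2023-01-02", periods=48, freq="h")
        d = daily_displacement(_fixes(times, 39.0, -76.2))
        assert (d["km"] == 0).all()

    def test_gap_over_3h_contributes_no_segment(self):
        f = _fixes(["2023-01-02T00:00", "2023-01-02T04:00"], [0.0, 1.0], [0.0, 0.0])
        d = daily_displacement(f)
        assert (d["km"] == 0).all()

    def test_single_fix_warns_and_returns_empty(self):
        f = _fixes(["2023-01-02T00:00"], [0.0], [0.0])
        with pytest.warns(UserWarning):
            d = daily_displacement(f)
        assert d.empty


class TestDetectChangepoints:
    def test_constant_series_has_none(self):
        assert detect_changepoints(np.full(20, 7.0)) == []

    def test_single_shift_recovered_near_day_2(self):
        """Means 230 (days 1-2) then 7 (days 3-20), sd 5: cp at day 2 +-1."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = np.r_[rng.normal(230, 5, 2), rng.normal(7, 5, 18)]
            cps = detect_changepoints(x)
            days = [k for k, _ in cps]  # split index == last left day (1-based)
            hits += any(abs(day - 2) <= 1 for day in days)
            if cps:
                assert max(d for _, d in cps) > 2
        assert hits >= 45

    def test_two_shift_structure_recovered(self):
        """Shifts after day 2 and day 4 (high/mid/settled) both found +-1 day."""
        both = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            x = np.r_[rng.normal(229.3, 3, 2), rng.normal(14.0, 3, 2),
                      rng.normal(7.5, 3, 16)]
            days = [k for k, _ in detect_changepoints(x)]
            ok1 = any(abs(d - 2) <= 1 for d in days)
            ok2 = any(abs(d - 4) <= 1 for d in days)
            both += ok1 and ok2
        assert both >= 45

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_changepoints([1.0, 2.0, 3.0])


class TestApplyCensor:
    def _acc(self, bird, n_days, start="2023-01-02"):
        ts = pd.date_range(start, periods=n_days * 4, freq="6h")
        return pd.DataFrame({
            "bird_id": bird, "burst_id": [f"{bird}_{i}" for i in range(len(ts))],
            "timestamp_utc": ts,
        })

    def test_censored_through_4_removes_first_4_days(self):
        acc = self._acc("b1", 10)
        res = {"b1": CensorResult("b1", (2, 4), (0.9, 0.6), 4, True, n_days=20)}
        out = apply_censor(res, acc)
        day = (out["timestamp_utc"].dt.normalize()
               - acc["timestamp_utc"].min().normalize()).dt.days
        assert (day > 4).all()
        assert len(out) == len(acc) - 5 * 4  # days 0-4 dropped

    def test_short_lived_bird_fully_excluded(self):
        acc = self._acc("b1", 10)
        res = {"b1": CensorResult("b1", (), (), 0, included=False, n_days=10)}
        assert apply_censor(res, acc).empty

    def test_no_changepoints_keeps_everything(self):
        acc = self._acc("b1", 30)
        res = {"b1": CensorResult("b1", (), (), 0, True, n_days=30)}
        pd.testing.assert_frame_equal(apply_censor(res, acc), acc)

    def test_unknown_bird_rejected(self):
        acc = self._acc("mystery", 5)
        with pytest.raises(ValueError, match="mystery"):
            apply_censor({}, acc)

    def test_censoring_is_monotone(self):
        """A later censored-through day never keeps more bursts."""
        acc = self._acc("b1", 15)
        sizes = []
        for through in (0, 2, 4, 8):
            res = {"b1": CensorResult("b1", (through,) if through else (), (1.0,),
                                      through, True, n_days=20)}
            sizes.append(len(apply_censor(res, acc)))
        assert sizes == sorted(sizes, reverse=True)


class TestCensorBird:
    def test_synthetic_two_shift_track_censors_through_last_shift(self):
        rng = np.random.default_rng(8)
        km = np.r_[rng.normal(229.3, 3, 2), rng.normal(14.0, 3, 2), rng.normal(7.5, 3, 16)]
        rows, lat = [], 39.0
        t0 = pd.Timestamp("2023-01-01T23:00")
        rows.append((t0, lat))
        for day, target in enumerate(km, start=1):
            hop = np.degrees((target / 23) / 6371.0)
            for h in range(24):
                if h > 0:
                    lat += hop if h % 2 else -hop
                rows.append((pd.Timestamp("2023-01-02") + pd.Timedelta(days=day - 1, hours=h), lat))
        fixes = _fixes([r[0] for r in rows], [r[1] for r in rows], -76.2)
        res = censor_bird("b1", fixes)
        assert res.included
        assert res.censored_through == pytest.approx(4, abs=1)
        assert len(res.changepoints) >= 2

    def test_bird_leaving_bbox_excluded(self):
        times = pd.date_range("2023-01-02", periods=16 * 24, freq="h")
        lats = np.full(len(times), 45.0)  # far north of the bay
        res = censor_bird("b1", _fixes(times, lats, -76.2))
        assert not res.included
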