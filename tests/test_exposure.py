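import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aerequity import exposure as ex


def _conc_frame(values: dict, n_hours: int) -> pd.DataFrame:
    """Concentration frame: one row per community, columns 0..n_hours-1."""
    return pd.DataFrame(
        {h: {cid: v for cid, v in values.items()} for h in range(n_hours)}
    )


class TestExposureIntensity:
    def test_hand_sum_no_threshold(self):
        r = ex.exposure_intensity([50.0, 100.0], [10.0, 20.0])
        assert r.E == pytest.approx(2500.0)
        assert r.NT == 2

    def test_threshold_counts_only_polluted_hours(self):
        r = ex.exposure_intensity([50.0, 100.0], [10.0, 20.0], threshold=75.0)
        assert r.E == pytest.approx(2000.0)
        assert r.NT == 1

    def test_zero_density_zero_intensity(self):
        r = ex.exposure_intensity([80.0, 90.0, 70.0], [0.0, 0.0, 0.0])
        assert r.E == 0.0
        assert r.NT == 3

    def test_negative_density_raises(self):
        with pytest.raises(ValueError, match="negative"):
            ex.exposure_intensity([50.0], [-1.0])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            ex.exposure_intensity([50.0, 60.0], [10.0])

    @given(
        conc=st.lists(st.floats(0, 500), min_size=1, max_size=24),
        scale=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_density(self, conc, scale):
        dens = np.linspace(1, 10, len(conc))
        base = ex.exposure_intensity(conc, dens).E
        scaled = ex.exposure_intensity(conc, dens * scale).E
        assert scaled == pytest.approx(scale * base, rel=1e-9, abs=1e-9)


class TestWeightedConcentration:
    def test_uniform_concentration_invariant_to_schedules(self):
        od = pd.DataFrame(
            {
                "home_id": ["a", "a", "a"],
                "work_id": ["a", "b", "b"],
                "group": ["elderly_65p", "worker_19_59", "child_0_6"],
                "count": [100, 200, 50],
            }
        )
        conc = _conc_frame({"a": 64.0, "b": 64.0}, 48)
        r = ex.weighted_concentration(od, conc)
        assert r.pod == pytest.approx(64.0)

    def test_worker_weekday_hand_computation(self):
        od = pd.DataFrame(
            {"home_id": ["h"], "work_id": ["w"], "group": ["worker_19_59"], "count": [10]}
        )
        conc = _conc_frame({"h": 80.0, "w": 100.0}, 24)  # day 0 = Monday
        r = ex.weighted_concentration(od, conc)
        assert r.pod == pytest.approx((80 * 14 + 100 * 10) / 24)
        assert round(r.pod, 2) == 88.33

    def test_elderly_pod_is_home_mean(self, rng):
        hourly = rng.uniform(40, 120, 24)
        conc = pd.DataFrame([hourly], index=["h"], columns=range(24))
        od = pd.DataFrame(
            {"home_id": ["h"], "work_id": ["h"], "group": ["elderly_65p"], "count": [5]}
        )
        r = ex.weighted_concentration(od, conc)
        assert r.pod == pytest.approx(hourly.mean())

    def test_pod_bounded_by_experienced_concentrations(self, rng):
        conc = pd.DataFrame(
            rng.uniform(30, 150, (3, 48)), index=["a", "b", "c"], columns=range(48)
        )
        od = pd.DataFrame(
            {
                "home_id": ["a", "a"],
                "work_id": ["a", "c"],
                "group": ["elderly_65p", "worker_19_59"],
                "count": [30, 70],
            }
        )
        r = ex.weighted_concentration(od, conc)
        lo = min(conc.loc["a"].min(), conc.loc["c"].min())
        hi = max(conc.loc["a"].max(), conc.loc["c"].max())
        assert lo <= r.pod <= hi

    def test_workplace_outside_region_falls_back_to_home(self):
        od = pd.DataFrame(
            {"home_id": ["h"], "work_id": ["missing"], "group": ["worker_19_59"], "count": [10]}
        )
        conc = _conc_frame({"h": 90.0}, 24)
        r = ex.weighted_concentration(od, conc)
        assert r.pod == pytest.approx(90.0)

    def test_zero_population_community_raises(self):
        od = pd.DataFrame(
            {"home_id": ["h"], "work_id": ["h"], "group": ["elderly_65p"], "count": [0]}
        )
        with pytest.raises(ValueError, match="zero resident population"):
            ex.weighted_concentration(od, _conc_frame({"h": 90.0}, 24))


class TestStaticVsDynamic:
    def _city(self, center_boost):
        # 'center' is 10 ug/m3 dirtier; workers commute from 'edge' to 'center'
        conc = _conc_frame({"center": 90.0 + center_boost, "edge": 80.0}, 24 * 7)
        od = pd.DataFrame(
            {
                "home_id": ["center", "edge", "edge"],
                "work_id": ["center", "center", "edge"],
                "group": ["elderly_65p", "worker_19_59", "elderly_65p"],
                "count": [100, 300, 100],
            }
        )
        return od, conc

    def test_zero_commuting_dynamic_equals_static(self):
        conc = _conc_frame({"a": 85.0, "b": 75.0}, 24 * 7)
        od = pd.DataFrame(
            {
                "home_id": ["a", "b"],
                "work_id": ["a", "b"],
                "group": ["worker_19_59", "worker_19_59"],
                "count": [100, 200],
            }
        )
        pods = ex.weighted_concentration_all(od, conc)
        static = ex.static_exposure(conc)
        dyn, sta = ex.regional_means(pods["pod"], static, pods["population"])
        assert dyn == pytest.approx(sta)

    def test_centerward_commuting_raises_dynamic_mean(self):
        od, conc = self._city(center_boost=0.0)
        pods = ex.weighted_concentration_all(od, conc)
        static = ex.static_exposure(conc)
        dyn, sta = ex.regional_means(pods["pod"], static, pods["population"])
        assert dyn > sta

    def test_single_community_equal_regardless_of_flows(self):
        conc = _conc_frame({"only": 77.0}, 24 * 7)
        od = pd.DataFrame(
            {"home_id": ["only"], "work_id": ["only"], "group": ["worker_19_59"], "count": [50]}
        )
        pods = ex.weighted_concentration_all(od, conc)
        static = ex.static_exposure(conc)
        dyn, sta = ex.regional_means(pods["pod"], static, pods["population"])
        assert dyn == pytest.approx(sta)


class TestDecileExposure:
    def _frame(self, n, pods, props):
        return pd.DataFrame(
            {"pod": pods, "prop": props, "count": np.full(n, 100.0)}
        )

    def test_constant_pod_equal_deciles(self):
        df = self._frame(20, np.full(20, 88.0), np.linspace(0, 1, 20))
        out = ex.decile_exposure(df, "prop", weight_col="count")
        np.testing.assert_allclose(out["mean_pod"], 88.0)

    def test_monotone_fixture_gives_increasing_deciles(self):
        props = np.linspace(0.05, 0.4, 30)
        pods = 80 + 20 * props  # pod strictly increasing with proportion
        out = ex.decile_exposure(self._frame(30, pods, props), "prop")
        assert (np.diff(out["mean_pod"]) > 0).all()

    def test_twenty_communities_two_per_decile(self):
        df = self._frame(20, np.arange(20.0), np.arange(20.0))
        out = ex.decile_exposure(df, "prop")
        assert (out["n"] == 2).all()

    def test_remainder_goes_to_low_deciles(self):
        df = self._frame(13, np.arange(13.0), np.arange(13.0))
        out = ex.decile_exposure(df, "prop")
        assert out["n"].tolist() == [2, 2, 2, 1, 1, 1, 1, 1, 1, 1]

    def test_fewer_than_ten_raises(self):
        df = self._frame(9, np.arange(9.0), np.arange(9.0))
        with pytest.raises(ValueError, match=">= 10"):
            ex.decile_exposure(df, "prop")


def test_worker_schedule_is_weekday_daytime():
    s = ex.default_schedules()
    assert not s["elderly_65p"].at_work_hours and not s["child_0_6"].at_work_hours
    # Monday 09:00 at work; Monday 07:00 and Saturday 09:00 at home
    assert ex.is_work_hour(9)
    assert not ex.is_work_hour(7)
    assert not ex.is_work_hour(5 * 24 + 9)
    # 50 work-hour bins per week
    assert sum(ex.is_work_hour(h) for h in range(168)) == 50
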