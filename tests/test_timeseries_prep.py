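"""Case classification, weather imputation and weekly aggregation."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from dlagheat.timeseries_prep import (
    ImputationError,
    ValidationError,
    build_weekly,
    classify_case,
    flags_from_text,
    impute_weather,
)


class TestClassifyCase:
    @pytest.mark.parametrize(
        "icd, outcome, dehyd, comorb, expect",
        [
            ("A09", "admission", True, False, "severe"),
            ("A00", "admission", False, True, "severe"),
            ("A05", "admission", True, True, "severe"),
            ("A02", "admission", False, False, "non_severe"),
            ("A04", "death", False, False, "severe"),
            ("J18", "admission", True, False, "excluded"),
            ("B99", "death", False, False, "excluded"),
            ("A09.9", "admission", True, False, "severe"),
            ("A10", "admission", True, False, "excluded"),
        ],
    )
    def test_classification_rules(self, icd, outcome, dehyd, comorb, expect):
        rec = {"icd10": icd, "outcome": outcome, "dehydration": dehyd, "comorbidity": comorb}
        assert classify_case(rec) == expect

    def test_malformed_icd_rejected_with_record(self):
        with pytest.raises(ValidationError, match="A9X"):
            classify_case({"icd10": "A9X", "outcome": "admission",
                           "dehydration": False, "comorbidity": False})

    def test_text_front_end(self):
        assert flags_from_text("AGE with some Dehydration") == (True, False)
        assert flags_from_text("gastroenteritis; severe malnutrition") == (False, True)
        assert flags_from_text("acute gastroenteritis") == (False, False)


def _weather_frame(n_days=400, stations=("s1", "s2", "s3"), seed=0):
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2016-01-01", periods=n_days)
    doy = dates.dayofyear.to_numpy(dtype=float)
    rows = []
    for i, st in enumerate(stations):
        base = 28.0 + i * 0.5 + 2.0 * np.cos(2 * np.pi * (doy - 130) / 365.25)
        rows.append(pd.DataFrame({
            "date": dates, "station": st,
            "tmean": base + rng.normal(0, 0.7, n_days),
            "dewp": base - 4.5 + rng.normal(0, 1.0, n_days),
            "rain": np.nan,
        }))
    return pd.concat(rows, ignore_index=True)


class TestImputeWeather:
    def test_complete_input_unchanged(self):
        wx = _weather_frame()
        out = impute_weather(wx)
        merged = wx.merge(out, on=["date", "station"], suffixes=("", "_out"))
        assert np.array_equal(merged["tmean"].to_numpy(), merged["tmean_out"].to_numpy())
        assert np.array_equal(merged["dewp"].to_numpy(), merged["dewp_out"].to_numpy())

    def test_exact_linear_relation_recovered(self):
        wx = _weather_frame(stations=("s1", "s2"))
        # force target == predictor + 1 exactly, then punch one gap
        t = wx[wx.station == "s2"].set_index("date")["tmean"]
        wx.loc[wx.station == "s1", "tmean"] = (t + 1.0).to_numpy()
        gap_date = wx["date"].iloc[50]
        wx.loc[(wx.station == "s1") & (wx.date == gap_date), "tmean"] = np.nan
        out = impute_weather(wx)
        got = out[(out.station == "s1") & (out.date == gap_date)]["tmean"].iloc[0]
        assert got == pytest.approx(float(t.loc[gap_date]) + 1.0, abs=1e-8)

    def test_gaps_match_normal_equations_oracle(self):
        """Synthetic gaps punched into a complete series are filled with the
        fitted values of an explicit (X'X)^-1 X'y solve."""
        wx = _weather_frame(seed=5)
        complete = wx.copy()
        rng = np.random.default_rng(6)
        gap_idx = rng.choice(np.where(wx.station == "s1")[0], 8, replace=False)
        wx.loc[gap_idx, "tmean"] = np.nan
        out = impute_weather(wx)

        wide = complete.pivot(index="date", columns="station", values="tmean")
        doy = wide.index.dayofyear.to_numpy(dtype=float)
        ang = 2 * np.pi * doy / 365.25
        X = np.column_stack([
            np.ones(len(wide)), wide["s2"], wide["s3"], np.sin(ang), np.cos(ang),
        ])
        y = wide["s1"].to_numpy()
        gap_dates = complete.loc[gap_idx, "date"]
        mask = ~wide.index.isin(gap_dates)
        beta = np.linalg.solve(X[mask].T @ X[mask], X[mask].T @ y[mask])
        expect = X[wide.index.isin(gap_dates)] @ beta
        got = (
            out[(out.station == "s1") & out.date.isin(gap_dates)]
            .sort_values("date")["tmean"].to_numpy()
        )
        assert np.max(np.abs(np.sort(got) - np.sort(expect))) < 1e-8

    def test_observed_values_untouched_bit_identical(self):
        wx = _weather_frame(seed=7)
        wx.loc[10, "tmean"] = np.nan
        out = impute_weather(wx)
        merged = wx.merge(out, on=["date", "station"], suffixes=("", "_out"))
        obs = merged["tmean"].notna()
        assert np.array_equal(
            merged.loc[obs, "tmean"].to_numpy(), merged.loc[obs, "tmean_out"].to_numpy()
        )

    def test_cap_exceeded_refused(self):
        wx = _weather_frame(n_days=200)
        idx = wx[wx.station == "s1"].index[:50]
        wx.loc[idx, "tmean"] = np.nan
        with pytest.raises(ImputationError, match="cap"):
            impute_weather(wx)

    def test_all_stations_missing_day_listed(self):
        wx = _weather_frame(n_days=200)
        bad_date = wx["date"].iloc[30]
        wx.loc[wx.date == bad_date, "tmean"] = np.nan
        with pytest.raises(ImputationError, match="all stations missing"):
            impute_weather(wx)


class TestBuildWeekly:
    WINDOW = (date(2016, 1, 4), date(2016, 3, 27))  # 12 full weeks
    STATION_MAP = {"capital": "s1", "eastern": "s2"}

    def _weather(self):
        wx = _weather_frame(n_days=120, stations=("s1", "s2"), seed=3)
        wx["date"] = pd.date_range("2016-01-01", periods=120).repeat(1).tolist() * 0 or wx["date"]
        return wx

    def test_zero_records_weather_populated(self):
        weekly = build_weekly(
            pd.DataFrame(columns=["event_date", "district", "icd10", "outcome",
                                  "dehydration", "comorbidity"]),
            self._weather(), [], self.WINDOW, self.STATION_MAP,
        )
        assert len(weekly) == 12 * 2
        assert (weekly[["deaths", "severe_admissions", "all_admissions"]] == 0).all().all()
        assert weekly["tmean_wk"].notna().all()

    def test_counts_land_in_their_week(self):
        recs = pd.DataFrame([
            {"event_date": date(2016, 1, 5) + timedelta(days=d), "district": "capital",
             "icd10": "A09", "outcome": "admission", "dehydration": True,
             "comorbidity": False}
            for d in (0, 1, 2)
        ])
        weekly = build_weekly(recs, self._weather(), [], self.WINDOW, self.STATION_MAP)
        wk0 = weekly[(weekly.district == "capital") & (weekly.t == 0)].iloc[0]
        assert wk0["severe_admissions"] == 3
        assert wk0["all_admissions"] == 3
        assert weekly["severe_admissions"].sum() == 3

    def test_conservation_and_exclusions(self):
        rng = np.random.default_rng(11)
        days = rng.integers(0, 84, 60)
        icds = rng.choice(["A02", "A09", "J18"], 60, p=[0.4, 0.4, 0.2])
        recs = pd.DataFrame({
            "event_date": [self.WINDOW[0] + timedelta(days=int(d)) for d in days],
            "district": rng.choice(["capital", "eastern"], 60),
            "icd10": icds,
            "outcome": "admission",
            "dehydration": rng.random(60) < 0.5,
            "comorbidity": False,
        })
        weekly = build_weekly(recs, self._weather(), [], self.WINDOW, self.STATION_MAP)
        n_in_scope = int((icds != "J18").sum())
        assert weekly["all_admissions"].sum() == n_in_scope

    def test_constant_temperature_passthrough(self):
        wx = self._weather()
        wx["tmean"] = 28.0
        weekly = build_weekly(
            pd.DataFrame(columns=["event_date", "district", "icd10", "outcome",
                                  "dehydration", "comorbidity"]),
            wx, [], self.WINDOW, self.STATION_MAP,
        )
        assert np.allclose(weekly["tmean_wk"], 28.0)

    def test_holiday_counts_per_block(self):
        hols = [date(2016, 1, 4), date(2016, 1, 6), date(2016, 2, 10)]
        weekly = build_weekly(
            pd.DataFrame(columns=["event_date", "district", "icd10", "outcome",
                                  "dehydration", "comorbidity"]),
            self._weather(), hols, self.WINDOW, self.STATION_MAP,
        )
        cap = weekly[weekly.district == "capital"].set_index("t")
        assert cap.loc[0, "holidays"] == 2
        assert cap.loc[5, "holidays"] == 1
        assert cap["holidays"].sum() == 3

    def test_unmapped_district_rejected(self):
        recs = pd.DataFrame([{
            "event_date": date(2016, 1, 5), "district": "northern", "icd10": "A09",
            "outcome": "admission", "dehydration": True, "comorbidity": False,
        }])
        with pytest.raises(ValidationError, match="northern"):
            build_weekly(recs, self._weather(), [], self.WINDOW, self.STATION_MAP)

    def test_idempotent_byte_identical(self):
        recs = pd.DataFrame([{
            "event_date": date(2016, 2, 1), "district": "capital", "icd10": "A03",
            "outcome": "death", "dehydration": False, "comorbidity": False,
        }])
        a = build_weekly(recs, self._weather(), [], self.WINDOW, self.STATION_MAP)
        b = build_weekly(recs, self._weather(), [], self.WINDOW, self.STATION_MAP)
        assert a.to_csv(index=False) == b.to_csv(index=False)
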