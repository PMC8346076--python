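"""Line-list and station-weather preparation into district weekly series.

Severe diarrhoea is defined from intestinal-infectious ICD-10 codes
(A00-A09): deaths are severe by definition; admissions are severe when the
record carries a dehydration and/or co-morbidity flag, and non-severe when
the final diagnosis is plain infectious diarrhoea/gastroenteritis with
neither flag.  Weeks are consecutive 7-day blocks anchored at the study
window start; a partial terminal week is dropped.  Missing station
temperatures are imputed by ordinary least squares on the other stations'
same-day values plus annual harmonics.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_ICD_RE = re.compile(r"^[A-Z]\d{2}(\.\d+)?$")
_SEVERE_ICD_PREFIXES = tuple(f"A0{i}" for i in range(10))  # A00..A09

LINELIST_COLUMNS = ["event_date", "district", "icd10", "outcome", "dehydration", "comorbidity"]
WEATHER_COLUMNS = ["date", "station", "tmean", "dewp", "rain"]


class ValidationError(ValueError):
    pass


class ImputationError(RuntimeError):
    pass


@dataclass(frozen=True)
class LineListRecord:
    event_date: date
    district: str
    icd10: str
    outcome: str  # "death" | "admission"
    dehydration: bool
    comorbidity: bool


def classify_case(record) -> str:
    """Classify one line-list record as ``severe``, ``non_severe`` or ``excluded``.

    Records outside ICD-10 A00-A09 are excluded.  Deaths within A00-A09 are
    severe; admissions are severe with a dehydration and/or co-morbidity
    flag and non-severe otherwise.
    """
    icd = str(getattr(record, "icd10", record["icd10"] if isinstance(record, dict) else "")).strip().upper()
    if not _ICD_RE.match(icd):
        raise ValidationError(f"malformed ICD-10 code {icd!r} in record {record!r}")
    if not icd.startswith(_SEVERE_ICD_PREFIXES):
        return "excluded"
    get = record.get if isinstance(record, dict) else lambda k: getattr(record, k)
    outcome = str(get("outcome")).lower()
    if outcome not in ("death", "admission"):
        raise ValidationError(f"unknown outcome {outcome!r} in record {record!r}")
    if outcome == "death":
        return "severe"
    if bool(get("dehydration")) or bool(get("comorbidity")):
        return "severe"
    return "non_severe"


_DEFAULT_COMORBIDITY_KEYWORDS = (
    "comorbidity", "co-morbidity", "malnutrition", "sepsis", "pneumonia",
    "renal failure", "electrolyte imbalance",
)


def flags_from_text(diagnosis: str,
                    comorbidity_keywords=_DEFAULT_COMORBIDITY_KEYWORDS) -> tuple[bool, bool]:
    """Optional free-text front end: derive (dehydration, comorbidity) flags
    from a diagnosis string by case-insensitive keyword match."""
    text = diagnosis.lower()
    dehyd = "dehydration" in text
    comorb = any(k in text for k in comorbidity_keywords)
    return dehyd, comorb


def _harmonics(dates: pd.Series) -> np.ndarray:
    doy = dates.dt.dayofyear.to_numpy(dtype=float)
    ang = 2.0 * np.pi * doy / 365.25
    return np.column_stack([np.sin(ang), np.cos(ang)])


def impute_weather(weather: pd.DataFrame, missing_cap: float = 0.05,
                   variables: tuple[str, ...] = ("tmean", "dewp")) -> pd.DataFrame:
    """Fill missing station temperatures by cross-station regression.

    For each station and variable with gaps, fits OLS of the target on the
    other stations' same-day values plus annual sin/cos harmonics, using
    days where everything is observed, and replaces only the missing values
    with fitted ones.  Refuses when a station's missing fraction exceeds
    ``missing_cap`` (heavily gapped variables should be dropped instead) or
    when a gap day has no complete predictor station.
    """
    weather = weather.copy()
    weather["date"] = pd.to_datetime(weather["date"])
    out = weather.sort_values(["station", "date"]).reset_index(drop=True)
    for station, grp in out.groupby("station"):
        if grp["date"].duplicated().any():
            raise ValidationError(f"duplicate dates for station {station}")

    for var in variables:
        wide = out.pivot(index="date", columns="station", values=var)
        frac = wide.isna().mean()
        over = frac[frac > missing_cap]
        if not over.empty:
            raise ImputationError(
                f"missing fraction for {var} exceeds cap {missing_cap:.0%} at "
                f"stations {dict(over.round(3))}; drop the variable instead"
            )
        all_missing = wide.index[wide.isna().all(axis=1)]
        if len(all_missing):
            raise ImputationError(
                f"all stations missing {var} on: {[d.date() for d in all_missing]}"
            )
        harm = _harmonics(wide.index.to_series())
        for station in wide.columns:
            gaps = wide[station].isna()
            if not gaps.any():
                continue
            others = wide.drop(columns=[station])
            complete = ~gaps & others.notna().all(axis=1)
            pred_ok = others.notna().all(axis=1)
            if not (gaps & ~pred_ok).sum() == 0:
                bad = wide.index[gaps & ~pred_ok]
                raise ImputationError(
                    f"no complete predictor stations for {var} at {station} on "
                    f"{[d.date() for d in bad]}"
                )
            X = np.column_stack([
                np.ones(len(wide)), others.to_numpy(dtype=float), harm,
            ])
            beta, *_ = np.linalg.lstsq(
                X[complete.to_numpy()], wide.loc[complete, station].to_numpy(dtype=float),
                rcond=None,
            )
            fitted = X[gaps.to_numpy()] @ beta
            wide.loc[gaps, station] = fitted
        filled = wide.stack().rename(var).reset_index()
        out = out.drop(columns=[var]).merge(filled, on=["date", "station"], how="left")

    for var in ("tmean", "dewp"):
        if var in variables and out[var].isna().any():
            raise ImputationError(f"{var} still missing after imputation")
    if "tmean" in variables:
        bad = out[(out["tmean"] < 10) | (out["tmean"] > 45)]
        if not bad.empty:
            raise ValidationError(
                f"imputed/observed tmean outside plausible [10, 45] C range on "
                f"{bad['date'].dt.date.tolist()[:5]}"
            )
    return out[["date", "station", "tmean", "dewp", "rain"]]


def build_weekly(
    records: pd.DataFrame,
    weather: pd.DataFrame,
    holidays,
    window: tuple[date, date],
    station_map: dict[str, str],
) -> pd.DataFrame:
    """Aggregate classified events and daily weather into district-weeks.

    Weeks are consecutive 7-day blocks from the window start; a partial
    terminal week is dropped.  Weekly temperature/dew point are means of the
    district's station values; rain is the weekly total.  Records outside
    the window are dropped (count logged).
    """
    start, end = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
    n_weeks = int((end - start).days + 1) // 7
    if n_weeks < 1:
        raise ValidationError("window shorter than one week")
    week_starts = start + pd.to_timedelta(7 * np.arange(n_weeks), unit="D")
    last_day = week_starts[-1] + timedelta(days=6)

    records = records.copy()
    records["event_date"] = pd.to_datetime(records["event_date"])
    in_window = (records["event_date"] >= start) & (records["event_date"] <= last_day)
    n_dropped = int((~in_window).sum())
    if n_dropped:
        logger.info("dropped %d records outside the study window", n_dropped)
    records = records[in_window]

    districts = sorted(station_map)
    for d in records["district"].unique():
        if d not in station_map:
            raise ValidationError(
                f"district {d!r} has no station mapping; exclude it or extend the map"
            )

    cls = records.apply(classify_case, axis=1) if len(records) else pd.Series(dtype=object)
    records = records.assign(_class=cls)
    records = records[records["_class"] != "excluded"]
    records["_week"] = ((records["event_date"] - start).dt.days // 7).astype(int)

    weather = weather.copy()
    weather["date"] = pd.to_datetime(weather["date"])
    weather = weather[(weather["date"] >= start) & (weather["date"] <= last_day)]
    weather["_week"] = ((weather["date"] - start).dt.days // 7).astype(int)

    holidays = pd.to_datetime(pd.Series(list(holidays))) if len(list(holidays)) else pd.Series(dtype="datetime64[ns]")
    hol_weeks = ((holidays - start).dt.days // 7)
    hol_weeks = hol_weeks[(hol_weeks >= 0) & (hol_weeks < n_weeks)]
    hol_counts = hol_weeks.value_counts()

    rows = []
    for district in districts:
        station = station_map[district]
        wsta = weather[weather["station"] == station]
        grp = wsta.groupby("_week")
        n_days = grp["date"].count()
        missing_weeks = [w for w in range(n_weeks) if n_days.get(w, 0) != 7]
        if missing_weeks:
            raise ValidationError(
                f"station {station} lacks complete daily weather for weeks {missing_weeks[:5]}"
            )
        tmean_wk = grp["tmean"].mean()
        dewp_wk = grp["dewp"].mean()
        rain_wk = grp["rain"].sum(min_count=7)

        rec = records[records["district"] == district]
        deaths = rec[rec["outcome"] == "death"].groupby("_week").size()
        adm = rec[rec["outcome"] == "admission"]
        severe = adm[adm["_class"] == "severe"].groupby("_week").size()
        allo = adm.groupby("_week").size()

        for w in range(n_weeks):
            rows.append({
                "district": district,
                "t": w,
                "week_start": (start + timedelta(days=7 * w)).date(),
                "deaths": int(deaths.get(w, 0)),
                "severe_admissions": int(severe.get(w, 0)),
                "all_admissions": int(allo.get(w, 0)),
                "tmean_wk": float(tmean_wk[w]),
                "dewp_wk": float(dewp_wk[w]),
                "rain_wk": float(rain_wk[w]) if w in rain_wk.index and pd.notna(rain_wk[w]) else np.nan,
                "holidays": int(hol_counts.get(w, 0)),
            })
    return pd.DataFrame(rows)
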