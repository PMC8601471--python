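"""Seasonal weather covariates for the maize yield regression.

Turns daily county weather (tmax, tmin, precipitation, rhmax, rhmin) into
the six growing-season regressors of the yield model:

* **GDD** — growing degree days, daily heat accumulation with both
  temperatures clamped into the 10-29 °C growing range, summed over the
  season;
* **EDD** — extreme degree days, accumulation above 29 °C, summed;
* **Tmax, Tmin** — season means of daily maximum / minimum temperature;
* **Pr** — season total precipitation;
* **VPD** — season mean vapor pressure deficit from a Magnus-type
  saturation pressure at the daily mean temperature.

The growing season of a county-year is the 183-day (six-month) interval
beginning on the first day whose trailing 21-day moving average of daily
mean temperature reaches 10 °C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GDD_BASE = 10.0   # °C, lower growing threshold
GDD_CAP = 29.0    # °C, upper growing threshold / EDD base
SEASON_THRESHOLD = 10.0  # °C on the 21-day moving average
SEASON_MA_DAYS = 21
SEASON_DAYS = 183

#: Expected columns of a daily weather table.
WEATHER_COLUMNS = (
    "county_id", "date", "tmax_c", "tmin_c", "precip_mm", "rhmax_pct", "rhmin_pct",
)

COVARIATE_COLUMNS = (
    "county_id", "year", "gdd", "edd", "tmax_mean", "tmin_mean",
    "pr_total", "vpd_mean", "season_start_doy",
)


class NoGrowingSeasonError(ValueError):
    """The 21-day moving average never reached the detection threshold."""

    def __init__(self, year, max_moving_average: float):
        self.year = year
        self.max_moving_average = float(max_moving_average)
        super().__init__(
            f"no growing season in year {year}: maximum 21-day moving average "
            f"{self.max_moving_average:.2f} °C never reached threshold"
        )


class WeatherGapError(ValueError):
    """Days missing inside a growing-season window."""

    def __init__(self, missing_dates):
        self.missing_dates = list(missing_dates)
        preview = ", ".join(str(d) for d in self.missing_dates[:5])
        super().__init__(
            f"{len(self.missing_dates)} missing day(s) inside the season window: {preview}"
        )


@dataclass(frozen=True)
class GrowingSeasonWindow:
    """A county-year growing season: ``length_days`` days from ``start_day``."""

    year: int
    start_day: int
    length_days: int = SEASON_DAYS

    @property
    def end_day(self) -> int:
        return self.start_day + self.length_days - 1


@dataclass(frozen=True)
class SeasonalCovariates:
    """The six seasonal regressors for one county-year."""

    county_id: object
    year: int
    gdd: float
    edd: float
    tmax_mean: float
    tmin_mean: float
    pr_total: float
    vpd_mean: float
    season_start_doy: int


def daily_gdd(tmax, tmin):
    """Daily growing degree days with both temperatures clamped to [10, 29] °C.

    Accepts scalars or arrays; result lies in [0, 19].
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax must be >= tmin")
    hi = np.clip(tmax, GDD_BASE, GDD_CAP)
    lo = np.clip(tmin, GDD_BASE, GDD_CAP)
    out = (hi + lo) / 2.0 - GDD_BASE
    return float(out) if out.ndim == 0 else out


def daily_edd(tmax, tmin):
    """Daily extreme degree days: accumulation above 29 °C (floor at 29)."""
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax must be >= tmin")
    out = (np.maximum(tmax, GDD_CAP) + np.maximum(tmin, GDD_CAP)) / 2.0 - GDD_CAP
    return float(out) if out.ndim == 0 else out


def saturation_vapor_pressure(t_c, as_printed: bool = False):
    """Magnus-type saturation vapor pressure (hPa) at temperature ``t_c`` (°C).

    The conventional form has ``t + 237.3`` in the exponent denominator;
    ``as_printed=True`` flips the sign to ``t - 237.3`` (an escape hatch for
    reproducing a published misprint; physically wrong).
    """
    t = np.asarray(t_c, dtype=float)
    denom = (t - 237.3) if as_printed else (t + 237.3)
    return 6.112 * np.exp(17.269 * t / denom)


def daily_vpd(tmax, tmin, rhmax, rhmin, as_printed: bool = False):
    """Daily vapor pressure deficit (hPa).

    Uses the daily mean temperature ``(tmax+tmin)/2`` and mean relative
    humidity ``(rhmax+rhmin)/2`` (inputs in percent, converted to a
    fraction): ``VPD = e_s(Tmean) * (1 - RHmean)``.
    """
    rhmax = np.asarray(rhmax, dtype=float)
    rhmin = np.asarray(rhmin, dtype=float)
    if np.any((rhmax < 0) | (rhmax > 100)) or np.any((rhmin < 0) | (rhmin > 100)):
        raise ValueError("relative humidity must lie in [0, 100] percent")
    tmean = (np.asarray(tmax, dtype=float) + np.asarray(tmin, dtype=float)) / 2.0
    rhmean = (rhmax + rhmin) / 200.0
    out = saturation_vapor_pressure(tmean, as_printed=as_printed) * (1.0 - rhmean)
    return float(out) if np.ndim(out) == 0 else out


def growing_season(
    daily_mean_temps,
    year: int = 0,
    threshold: float = SEASON_THRESHOLD,
    ma_days: int = SEASON_MA_DAYS,
    length_days: int = SEASON_DAYS,
) -> GrowingSeasonWindow:
    """Detect the growing season from one year of daily mean temperatures.

    ``daily_mean_temps`` is an ordered series starting on day-of-year 1.
    The start day is the first day on which the *trailing* ``ma_days``-day
    moving average is at or above ``threshold``; the earliest candidate is
    day ``ma_days`` (the first day with a complete trailing window).

    Raises :class:`NoGrowingSeasonError` if the threshold is never reached
    and ``ValueError`` if the season would extend past the record.
    """
    t = np.asarray(daily_mean_temps, dtype=float)
    if t.size < ma_days:
        raise ValueError(f"need at least {ma_days} days of temperature data")
    ma = np.convolve(t, np.ones(ma_days) / ma_days, mode="valid")  # ma[i] ends at day i+ma_days
    hits = np.nonzero(ma >= threshold)[0]
    if hits.size == 0:
        raise NoGrowingSeasonError(year, ma.max())
    start_day = int(hits[0]) + ma_days  # 1-based day-of-year
    if start_day + length_days - 1 > t.size:
        raise ValueError(
            f"growing season starting day {start_day} of year {year} extends past "
            f"the {t.size}-day record"
        )
    return GrowingSeasonWindow(year=year, start_day=start_day, length_days=length_days)


def seasonal_covariates(
    records: pd.DataFrame,
    window: GrowingSeasonWindow,
    as_printed: bool = False,
) -> SeasonalCovariates:
    """Aggregate one county-year of daily records over a season window.

    ``records`` must carry the daily weather columns plus ``date``; the
    window is interpreted as day-of-year positions in ``window.year``.
    Degree days and precipitation are summed; temperatures and VPD are
    averaged. Missing days inside the window raise :class:`WeatherGapError`.
    """
    df = records.copy()
    df["date"] = pd.to_datetime(df["date"])
    start = pd.Timestamp(year=window.year, month=1, day=1) + pd.Timedelta(days=window.start_day - 1)
    wanted = pd.date_range(start, periods=window.length_days, freq="D")
    sub = df.set_index("date").reindex(wanted)
    missing = wanted[sub["tmax_c"].isna().to_numpy()]
    if len(missing):
        raise WeatherGapError(missing.date)
    county = df["county_id"].iloc[0] if "county_id" in df else None
    gdd = daily_gdd(sub["tmax_c"].to_numpy(), sub["tmin_c"].to_numpy())
    edd = daily_edd(sub["tmax_c"].to_numpy(), sub["tmin_c"].to_numpy())
    vpd = daily_vpd(
        sub["tmax_c"].to_numpy(), sub["tmin_c"].to_numpy(),
        sub["rhmax_pct"].to_numpy(), sub["rhmin_pct"].to_numpy(),
        as_printed=as_printed,
    )
    return SeasonalCovariates(
        county_id=county,
        year=window.year,
        gdd=float(np.sum(gdd)),
        edd=float(np.sum(edd)),
        tmax_mean=float(sub["tmax_c"].mean()),
        tmin_mean=float(sub["tmin_c"].mean()),
        pr_total=float(sub["precip_mm"].sum()),
        vpd_mean=float(np.mean(vpd)),
        season_start_doy=window.start_day,
    )


def validate_weather(weather: pd.DataFrame) -> None:
    """Check the physical invariants of a daily weather table."""
    missing = [c for c in WEATHER_COLUMNS if c not in weather.columns]
    if missing:
        raise ValueError(f"weather table missing columns: {missing}")
    if (weather["tmax_c"] < weather["tmin_c"]).any():
        raise ValueError("tmax_c < tmin_c for some rows")
    if (weather["precip_mm"] < 0).any():
        raise ValueError("negative precipitation")
    rh_bad = (
        (weather["rhmin_pct"] < 0) | (weather["rhmax_pct"] > 100)
        | (weather["rhmin_pct"] > weather["rhmax_pct"])
    )
    if rh_bad.any():
        raise ValueError("relative humidity outside [0, 100] or rhmin > rhmax")


def compute_covariates(
    weather: pd.DataFrame,
    threshold: float = SEASON_THRESHOLD,
    ma_days: int = SEASON_MA_DAYS,
    length_days: int = SEASON_DAYS,
    missing_season: str = "error",
    as_printed: bool = False,
    validate: bool = True,
) -> pd.DataFrame:
    """Compute seasonal covariates for every county-year of a weather table.

    Vectorized over county-years via a day-of-year pivot. ``missing_season``
    controls county-years where no season is detected (or where the season
    would run past the year end): ``"error"`` raises, ``"skip"`` drops them.

    Returns a frame with :data:`COVARIATE_COLUMNS`.
    """
    if validate:
        validate_weather(weather)
    if missing_season not in ("error", "skip"):
        raise ValueError("missing_season must be 'error' or 'skip'")

    df = weather[list(WEATHER_COLUMNS)].copy()
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    df["doy"] = df["date"].dt.dayofyear

    tmax = df["tmax_c"].to_numpy()
    tmin = df["tmin_c"].to_numpy()
    df["tmean"] = (tmax + tmin) / 2.0
    df["gdd_d"] = daily_gdd(tmax, tmin)
    df["edd_d"] = daily_edd(tmax, tmin)
    df["vpd_d"] = daily_vpd(
        tmax, tmin, df["rhmax_pct"].to_numpy(), df["rhmin_pct"].to_numpy(),
        as_printed=as_printed,
    )

    max_doy = int(df["doy"].max())
    mats = {}
    for col in ("tmean", "gdd_d", "edd_d", "vpd_d", "precip_mm", "tmax_c", "tmin_c"):
        mats[col] = df.pivot_table(
            index=["county_id", "year"], columns="doy", values=col, aggfunc="first",
        ).reindex(columns=range(1, max_doy + 1))
    index = mats["tmean"].index
    ndays_present = mats["tmean"].notna().sum(axis=1).to_numpy()
    days_in_year = np.array(
        [366 if pd.Timestamp(year=y, month=12, day=31).dayofyear == 366 else 365
         for _, y in index]
    )

    tm = mats["tmean"].to_numpy()  # rows: county-year, cols: doy 1..max
    n_rows, n_cols = tm.shape
    # trailing moving average; windows containing missing days are invalid
    filled = np.nan_to_num(tm, nan=0.0)
    counts = (~np.isnan(tm)).astype(float)
    csum = np.cumsum(filled, axis=1)
    ccnt = np.cumsum(counts, axis=1)
    w = ma_days
    win_sum = csum[:, w - 1:] - np.concatenate(
        [np.zeros((n_rows, 1)), csum[:, :-w]], axis=1)
    win_cnt = ccnt[:, w - 1:] - np.concatenate(
        [np.zeros((n_rows, 1)), ccnt[:, :-w]], axis=1)
    with np.errstate(invalid="ignore"):
        ma = np.where(win_cnt == w, win_sum / w, -np.inf)
    hit = ma >= threshold
    has_hit = hit.any(axis=1)
    start_doy = np.where(has_hit, hit.argmax(axis=1) + w, -1)  # 1-based
    fits = has_hit & (start_doy + length_days - 1 <= np.minimum(n_cols, days_in_year))

    bad = ~fits
    if bad.any() and missing_season == "error":
        county, year = index[np.nonzero(bad)[0][0]]
        if not has_hit[np.nonzero(bad)[0][0]]:
            raise NoGrowingSeasonError(
                year, ma[np.nonzero(bad)[0][0]][np.isfinite(ma[np.nonzero(bad)[0][0]])].max()
            )
        raise ValueError(
            f"growing season for county {county}, year {year} extends past the record"
        )

    rows = np.nonzero(fits)[0]
    s = start_doy[rows] - 1  # 0-based start column
    out = {}
    for col, how in (
        ("gdd_d", "sum"), ("edd_d", "sum"), ("precip_mm", "sum"),
        ("tmax_c", "mean"), ("tmin_c", "mean"), ("vpd_d", "mean"),
    ):
        m = mats[col].to_numpy()[rows]
        f = np.nan_to_num(m, nan=0.0)
        c = (~np.isnan(m)).astype(float)
        cs = np.concatenate([np.zeros((len(rows), 1)), np.cumsum(f, axis=1)], axis=1)
        cc = np.concatenate([np.zeros((len(rows), 1)), np.cumsum(c, axis=1)], axis=1)
        ar = np.arange(len(rows))
        tot = cs[ar, s + length_days] - cs[ar, s]
        cnt = cc[ar, s + length_days] - cc[ar, s]
        if np.any(cnt != length_days):
            i = int(np.nonzero(cnt != length_days)[0][0])
            county, year = index[rows[i]]
            raise WeatherGapError(
                [f"county {county}, year {year}: {int(length_days - cnt[i])} day(s) missing"]
            )
        out[col] = tot / length_days if how == "mean" else tot

    result = pd.DataFrame({
        "county_id": [index[i][0] for i in rows],
        "year": [index[i][1] for i in rows],
        "gdd": out["gdd_d"],
        "edd": out["edd_d"],
        "tmax_mean": out["tmax_c"],
        "tmin_mean": out["tmin_c"],
        "pr_total": out["precip_mm"],
        "vpd_mean": out["vpd_d"],
        "season_start_doy": start_doy[rows],
    })
    return result.sort_values(["county_id", "year"], ignore_index=True)


def area_weighted_mean(values, weights) -> float:
    """Area-weighted mean of per-county values: sum(w*v) / sum(w).

    ``values`` and ``weights`` are mappings or Series keyed by county.
    Every county in ``values`` must have a weight; a zero total weight is
    an error.
    """
    values = pd.Series(values, dtype=float)
    weights = pd.Series(weights, dtype=float)
    missing = values.index.difference(weights.index)
    if len(missing):
        raise KeyError(f"counties without weights: {list(missing)}")
    w = weights.reindex(values.index)
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    return float((w * values).sum() / total)
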