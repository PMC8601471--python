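"""Future climate forcings: projection ensemble members and the delta method.

Two kinds of forcing feed the yield projections:

* *ensemble members* — daily downscaled projections, treated as equally
  likely samples of climate-forcing uncertainty;
* the *delta-shifted* climate — the classical simplification that shifts
  an observed 30-year record (1981-2010 by convention) by the difference
  (temperatures, additive) or ratio (precipitation and relative humidity,
  multiplicative) between the ensemble-mean projection-window mean and the
  hindcast-window mean of each variable. It keeps the observed variance
  and so underestimates future temperature extremes; the pipeline carries
  it as the no-climate-uncertainty reference.

Delta means are computed per county, so each county keeps its own
climatology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Variables shifted additively / scaled multiplicatively by the delta method.
ADDITIVE_VARS = ("tmax_c", "tmin_c")
MULTIPLICATIVE_VARS = ("precip_mm", "rhmax_pct", "rhmin_pct")
WEATHER_VARS = ADDITIVE_VARS + MULTIPLICATIVE_VARS

#: Conventional hindcast window for delta construction.
HINDCAST_WINDOW = (1981, 2010)


@dataclass(frozen=True)
class WindowSpec:
    """An inclusive projection window of calendar years."""

    start_year: int
    end_year: int
    label: str = "custom"

    def __post_init__(self):
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)


NEAR_FUTURE = WindowSpec(2020, 2049, "near")
FAR_FUTURE = WindowSpec(2070, 2099, "far")


@dataclass
class ClimateForcing:
    """One daily county weather table standing for one climate future."""

    label: str
    kind: str                      # "ensemble_member" | "delta_shifted" | "observed"
    weather: pd.DataFrame


@dataclass
class DeltaSpec:
    """Per-county window means defining a delta shift.

    ``projection`` and ``hindcast`` are (county x variable) frames;
    temperatures shift by the difference, the rest scale by the ratio.
    """

    projection: pd.DataFrame
    hindcast: pd.DataFrame

    def __post_init__(self):
        for v in MULTIPLICATIVE_VARS:
            if (self.hindcast[v] <= 0).any():
                raise ValueError(f"hindcast mean of {v} must be positive for a ratio shift")


def window_variable_means(
    daily: pd.DataFrame,
    window: WindowSpec,
    weights: pd.Series | None = None,
    by_county: bool = False,
) -> pd.Series | pd.DataFrame:
    """Mean of each weather variable over all days of a year window.

    ``by_county=True`` returns a (county x variable) frame; otherwise
    counties are aggregated to the region, area-weighted when ``weights``
    is given and unweighted otherwise. Raises on incomplete coverage.
    """
    years = pd.to_datetime(daily["date"]).dt.year
    sub = daily[(years >= window.start_year) & (years <= window.end_year)]
    got = set(pd.to_datetime(sub["date"]).dt.year.unique())
    missing = set(window.years) - got
    if missing:
        raise ValueError(f"window {window.label} missing years: {sorted(missing)[:5]}")
    per_county = sub.groupby("county_id")[list(WEATHER_VARS)].mean()
    if by_county:
        return per_county
    if weights is None:
        return per_county.mean()
    w = weights.loc[per_county.index].to_numpy(dtype=float)
    return pd.Series(
        (per_county.to_numpy() * w[:, None]).sum(axis=0) / w.sum(),
        index=per_county.columns,
    )


def ensemble_mean(member_means: list[pd.DataFrame | pd.Series]):
    """Unweighted multi-member mean of per-variable (or per-county) means."""
    if not member_means:
        raise ValueError("need at least one ensemble member")
    return sum(member_means) / len(member_means)


def build_delta_spec(
    hindcast_daily: pd.DataFrame,
    member_dailies: list[pd.DataFrame],
    projection_window: WindowSpec,
    hindcast_window: WindowSpec | None = None,
) -> DeltaSpec:
    """Delta spec from a hindcast record and projection ensemble members.

    The projection side is the ensemble mean of each member's per-county
    projection-window means; the hindcast side is the per-county mean over
    the (by default 1981-2010) hindcast window.
    """
    if hindcast_window is None:
        hindcast_window = WindowSpec(*HINDCAST_WINDOW, "hindcast")
    proj = ensemble_mean([
        window_variable_means(m, projection_window, by_county=True) for m in member_dailies
    ])
    hind = window_variable_means(hindcast_daily, hindcast_window, by_county=True)
    return DeltaSpec(projection=proj, hindcast=hind)


def delta_shift(obs: pd.DataFrame, spec: DeltaSpec, label: str = "delta") -> ClimateForcing:
    """Shift an observed record into a delta climate.

    Temperatures move by (projection - hindcast) per county; precipitation
    and humidity scale by (projection / hindcast). Humidity is clamped to
    [0, 100] afterwards, and the tmax >= tmin ordering is restored where
    unequal temperature deltas would flip it.
    """
    out = obs.copy()
    counties = out["county_id"]
    for v in ADDITIVE_VARS:
        delta = (spec.projection[v] - spec.hindcast[v]).loc[counties].to_numpy()
        out[v] = out[v].to_numpy() + delta
    for v in MULTIPLICATIVE_VARS:
        ratio = (spec.projection[v] / spec.hindcast[v]).loc[counties].to_numpy()
        if not np.all(np.isfinite(ratio)):
            raise ValueError(f"non-finite delta ratio for {v}")
        out[v] = out[v].to_numpy() * ratio
    out["rhmax_pct"] = out["rhmax_pct"].clip(0.0, 100.0)
    out["rhmin_pct"] = np.minimum(out["rhmin_pct"].clip(0.0, 100.0), out["rhmax_pct"])
    flip = out["tmin_c"] > out["tmax_c"]
    if flip.any():
        mid = (out.loc[flip, "tmin_c"] + out.loc[flip, "tmax_c"]) / 2.0
        out.loc[flip, "tmin_c"] = mid
        out.loc[flip, "tmax_c"] = mid
    return ClimateForcing(label=label, kind="delta_shifted", weather=out)


def scenario_set(members: list[ClimateForcing], delta: ClimateForcing) -> list[ClimateForcing]:
    """The ordered forcing collection: ensemble members plus the delta climate.

    The delta member doubles as the no-climate-uncertainty reference.
    """
    forcings = list(members) + [delta]
    labels = [f.label for f in forcings]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate forcing labels: {labels}")
    return forcings
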