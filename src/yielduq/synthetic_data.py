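"""Synthetic county weather, climate-projection ensembles and maize yields.

Every stage of the pipeline is testable without external archives: this
module emulates, from known ground truth,

* a historical daily weather record per county — a sinusoidal seasonal
  temperature cycle with county offsets, regional and county-level
  interannual anomalies, white daily noise and a linear warming trend;
  intermittent exponential precipitation; Gaussian relative-humidity
  levels;
* an ensemble of future projection members sharing the historical
  climatology but differing in warming trend (right-skewed spread across
  members, mimicking the right-skewed climate-sensitivity distribution of
  multi-model ensembles) and in variance inflation;
* county yields generated from the yield polynomial at the *computed*
  seasonal covariates, plus a linear technology (year-effect) trend,
  time-constant county effects and Gaussian noise.

Everything is deterministic given (config, seed); county climatologies,
areas and member characteristics are drawn once and shared across roles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimates
from .weather_features import compute_covariates
from .yield_model import (
    FULL_STRUCTURE, REFERENCE_STRUCTURE, ModelStructure, term_matrix,
)


@dataclass
class ClimateConfig:
    """Daily-weather process parameters (temperatures °C, precip mm/day, RH %)."""

    base_temp_c: float = 12.0            # annual-mean daily mean temperature
    seasonal_amplitude_c: float = 14.0   # half peak-to-trough of the seasonal cycle
    county_offset_sd_c: float = 1.5      # spatial spread of county climatologies
    interannual_sd_c: float = 0.8        # regional year-to-year anomaly
    county_year_sd_c: float = 0.4        # county-specific year anomaly
    daily_sd_c: float = 3.5              # white daily noise
    diurnal_range_c: float = 13.0        # mean tmax - tmin
    diurnal_county_sd_c: float = 1.5     # county spread of mean diurnal range
    diurnal_year_sd_c: float = 0.8       # county-year anomaly of diurnal range
    diurnal_daily_sd_c: float = 1.0      # day-to-day diurnal-range noise
    warming_trend_c_per_decade: float = 0.25   # historical-era trend
    wet_day_prob: float = 0.35
    wet_day_mean_mm: float = 6.0
    wetness_year_log_sd: float = 0.3     # county-year wet/dry multiplier (lognormal)
    rhmax_mean_pct: float = 85.0
    rhmax_sd_pct: float = 8.0
    rh_year_sd_pct: float = 4.0          # county-year humidity anomaly (dry years)
    rh_range_mean_pct: float = 30.0
    rh_range_sd_pct: float = 5.0


@dataclass
class EnsembleConfig:
    """Projection-member spread parameters."""

    n_members: int = 18
    trend_c_per_decade: float = 0.55         # mean future (high-forcing) trend
    trend_spread_c_per_decade: float = 0.15  # scale of right-skewed member spread
    variance_inflation: tuple[float, float] = (1.0, 1.35)


@dataclass
class YieldConfig:
    """Ground-truth yield process: polynomial coefficients plus trends."""

    structure: ModelStructure = REFERENCE_STRUCTURE
    beta: np.ndarray = field(
        default_factory=lambda: estimates.REFERENCE_MODEL_BEST.copy())
    base_yield_bu_ac: float = 150.0          # folded into the effective intercept
    year_trend_bu_per_yr: float = 1.8        # technology trend via year effects
    county_effect_sd_bu: float = 8.0
    residual_sd_bu: float = 15.0             # total county-year residual SD
    #: Fraction of the residual SD carried by shared spatial factors
    #: (year shocks with county-specific loadings). County yield residuals
    #: are strongly spatially correlated in real data (drought and pest
    #: patterns span counties); without this component the regional
    #: observation band degenerates to the estimation-error scale.
    spatial_residual_frac: float = 0.75
    n_spatial_factors: int = 3
    area_acres_range: tuple[float, float] = (5.0e3, 5.0e5)


@dataclass
class SyntheticConfig:
    """Full study configuration for one synthetic world."""

    n_counties: int = 30
    start_year: int = 1979
    n_years_hist: int = 40
    climate: ClimateConfig = field(default_factory=ClimateConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    yields: YieldConfig = field(default_factory=YieldConfig)

    def __post_init__(self):
        beta = np.asarray(self.yields.beta, dtype=float)
        mask = self.yields.structure.coef_mask
        if np.any(beta[~mask] != 0.0):
            raise ValueError("true coefficients must be zero outside the chosen structure")

    @property
    def last_hist_year(self) -> int:
        return self.start_year + self.n_years_hist - 1


@dataclass
class GroundTruth:
    """The generating process, serializable next to the outputs."""

    beta: np.ndarray                    # effective 13-vector (base yield folded in)
    structure: ModelStructure
    year_effects: pd.Series             # zero in the first year
    county_effects: pd.Series           # zero for the first county
    areas: pd.Series
    seed: int

    def to_json(self) -> str:
        return json.dumps({
            "beta": {n: v for n, v in zip(estimates.COEF_NAMES, self.beta)},
            "structure": str(self.structure),
            "year_effects": {int(y): v for y, v in self.year_effects.items()},
            "county_effects": {str(c): v for c, v in self.county_effects.items()},
            "areas": {str(c): v for c, v in self.areas.items()},
            "seed": self.seed,
        }, indent=1)


class SyntheticStudy:
    """One synthetic world: county attributes and member characteristics are
    drawn once at construction and shared by every generated table."""

    def __init__(self, config: SyntheticConfig, seed: int):
        self.config = config
        self.seed = int(seed)
        c = config.climate
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 101]))
        n = config.n_counties
        self.county_ids = [f"C{i:03d}" for i in range(n)]
        self.county_offset = rng.normal(0.0, c.county_offset_sd_c, n)
        self.county_diurnal = rng.normal(0.0, c.diurnal_county_sd_c, n)
        self.county_wet_mean = c.wet_day_mean_mm * np.exp(rng.normal(0.0, 0.15, n))
        self.county_rhmax = np.clip(
            rng.normal(c.rhmax_mean_pct, 3.0, n), 55.0, 97.0)
        lo, hi = config.yields.area_acres_range
        self.areas = pd.Series(
            np.exp(rng.uniform(np.log(lo), np.log(hi), n)),
            index=pd.Index(self.county_ids, name="county_id"), name="area_acres",
        )
        e = config.ensemble
        erng = np.random.default_rng(np.random.SeedSequence([self.seed, 202]))
        # right-skewed member trend spread: standardized exponential offsets
        z = erng.exponential(1.0, e.n_members) - 1.0
        self.member_trends = e.trend_c_per_decade + e.trend_spread_c_per_decade * z
        self.member_inflation = erng.uniform(*e.variance_inflation, e.n_members)

    # ---- weather ---------------------------------------------------------

    def _daily_frame(self, start_year: int, end_year: int, rng,
                     trend_fn, inflation: float = 1.0) -> pd.DataFrame:
        """Shared daily generator; ``trend_fn(year)`` gives the mean shift (°C)."""
        c = self.config.climate
        dates = pd.date_range(f"{start_year}-01-01", f"{end_year}-12-31", freq="D")
        nd = len(dates)
        years = dates.year.to_numpy()
        doy = dates.dayofyear.to_numpy()
        seasonal = -c.seasonal_amplitude_c * np.cos(2 * np.pi * (doy - 15) / 365.25)
        trend = np.array([trend_fn(y) for y in range(start_year, end_year + 1)])
        year_pos = years - start_year
        n_years = end_year - start_year + 1
        nco = self.config.n_counties

        reg_anom = rng.normal(0.0, c.interannual_sd_c * inflation, n_years)
        cty_anom = rng.normal(0.0, c.county_year_sd_c * inflation, (nco, n_years))
        daily = rng.normal(0.0, c.daily_sd_c * inflation, (nco, nd))
        spread_mean = (
            c.diurnal_range_c
            + self.county_diurnal[:, None]
            + rng.normal(0.0, c.diurnal_year_sd_c, (nco, n_years))[:, year_pos]
        )
        spread = np.clip(
            spread_mean + rng.normal(0.0, c.diurnal_daily_sd_c, (nco, nd)), 2.0, None)
        wet = rng.random((nco, nd)) < c.wet_day_prob
        wetness = np.exp(rng.normal(0.0, c.wetness_year_log_sd, (nco, n_years)))
        amount = rng.exponential(1.0, (nco, nd)) * wetness[:, year_pos]
        rh_year = rng.normal(0.0, c.rh_year_sd_pct, (nco, n_years))[:, year_pos]
        rhmax = np.clip(
            rng.normal(self.county_rhmax[:, None] + rh_year, c.rhmax_sd_pct), 0, 100)
        rhrange = np.clip(rng.normal(c.rh_range_mean_pct, c.rh_range_sd_pct, (nco, nd)), 5.0, None)
        rhmin = np.clip(rhmax - rhrange, 0.0, 100.0)

        tmean = (
            c.base_temp_c
            + self.county_offset[:, None]
            + seasonal[None, :]
            + trend[year_pos][None, :]
            + reg_anom[year_pos][None, :]
            + cty_anom[:, year_pos]
            + daily
        )
        tmax = tmean + spread / 2.0
        tmin = tmean - spread / 2.0
        precip = wet * amount * self.county_wet_mean[:, None]

        return pd.DataFrame({
            "county_id": np.repeat(self.county_ids, nd),
            "date": np.tile(dates.to_numpy(), nco),
            "tmax_c": tmax.ravel(),
            "tmin_c": tmin.ravel(),
            "precip_mm": precip.ravel(),
            "rhmax_pct": rhmax.ravel(),
            "rhmin_pct": rhmin.ravel(),
        })

    def weather_historical(self) -> pd.DataFrame:
        """Observed record: ``n_years_hist`` years from ``start_year``."""
        cfg = self.config
        c = cfg.climate
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 303]))
        ref = cfg.start_year
        return self._daily_frame(
            cfg.start_year, cfg.last_hist_year, rng,
            trend_fn=lambda y: c.warming_trend_c_per_decade * (y - ref) / 10.0,
        )

    def _future_trend(self, member: int):
        cfg = self.config
        c = cfg.climate
        pivot = cfg.last_hist_year
        base_at_pivot = c.warming_trend_c_per_decade * (pivot - cfg.start_year) / 10.0
        mtrend = self.member_trends[member]
        return lambda y: base_at_pivot + mtrend * (y - pivot) / 10.0

    def weather_member(self, member: int, start_year: int, end_year: int) -> pd.DataFrame:
        """Projection member ``member`` over [start_year, end_year]."""
        if not 0 <= member < self.config.ensemble.n_members:
            raise IndexError(f"member {member} outside ensemble")
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, 404, member, start_year]))
        return self._daily_frame(
            start_year, end_year, rng,
            trend_fn=self._future_trend(member),
            inflation=self.member_inflation[member],
        )

    def member_labels(self) -> list[str]:
        return [f"member_{i:02d}" for i in range(self.config.ensemble.n_members)]

    # ---- yields ----------------------------------------------------------

    def generate_yields(self, covariates: pd.DataFrame) -> tuple[pd.DataFrame, GroundTruth]:
        """Yields from the ground-truth polynomial at the given covariates.

        yield = beta-polynomial + base level + year-effect trend (zero in
        the first year) + county effect (zero for the first county) +
        Gaussian noise. The base level is folded into the effective
        intercept recorded in the returned :class:`GroundTruth`, so a
        noiseless fit recovers ``truth.beta`` exactly.
        """
        cfg = self.config
        yc = cfg.yields
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 505]))
        beta_eff = np.asarray(yc.beta, dtype=float).copy()
        beta_eff[-1] += yc.base_yield_bu_ac
        years = np.sort(covariates["year"].unique())
        year_effects = pd.Series(
            yc.year_trend_bu_per_yr * (years - years[0]), index=years, name="year_effect")
        county_ids = self.county_ids
        ce = rng.normal(0.0, yc.county_effect_sd_bu, len(county_ids))
        ce[0] = 0.0
        county_effects = pd.Series(ce, index=pd.Index(county_ids, name="county_id"),
                                   name="county_effect")
        poly = term_matrix(covariates) @ beta_eff
        sd_spatial = yc.residual_sd_bu * yc.spatial_residual_frac
        sd_idio = yc.residual_sd_bu * np.sqrt(1.0 - yc.spatial_residual_frac ** 2)
        K = max(int(yc.n_spatial_factors), 1)
        loadings = rng.normal(0.0, 1.0, (K, len(county_ids)))       # county patterns
        factors = rng.normal(0.0, sd_spatial / np.sqrt(K), (K, len(years)))
        cidx = pd.Index(county_ids).get_indexer(covariates["county_id"])
        yidx = pd.Index(years).get_indexer(covariates["year"])
        spatial = np.einsum("kc,ky->cy", loadings, factors)[cidx, yidx]
        noise = rng.normal(0.0, sd_idio, len(covariates)) + spatial
        y = (
            poly
            + year_effects.loc[covariates["year"]].to_numpy()
            + county_effects.loc[covariates["county_id"]].to_numpy()
            + noise
        )
        out = pd.DataFrame({
            "county_id": covariates["county_id"],
            "year": covariates["year"],
            "yield_bu_ac": y,
            "area_acres": self.areas.loc[covariates["county_id"]].to_numpy(),
        })
        truth = GroundTruth(
            beta=beta_eff, structure=yc.structure, year_effects=year_effects,
            county_effects=county_effects, areas=self.areas, seed=self.seed,
        )
        return out, truth


# ---- presets -------------------------------------------------------------

#: A configuration whose winters and springs are too cold for the 21-day
#: moving average ever to reach 10 °C; exercises the no-growing-season path.
def cold_config(**kw) -> SyntheticConfig:
    clim = ClimateConfig(base_temp_c=-2.0, seasonal_amplitude_c=8.0)
    return SyntheticConfig(n_counties=3, n_years_hist=3, climate=clim, **kw)


def preset_config(preset: str) -> SyntheticConfig:
    """Named study configurations.

    ``tiny``: 5 counties x 15 years x 3 members — seconds, for unit tests.
    ``default``: 30 counties x 40 years x 18 members — matches the shape of
    a four-decade county record with an 18-member projection ensemble.
    ``realistic``: default sizes with the published full-model coefficients
    as ground truth.
    ``cold``: no growing season anywhere (error-path preset).
    """
    if preset == "tiny":
        return SyntheticConfig(
            n_counties=5, n_years_hist=15,
            ensemble=EnsembleConfig(n_members=3),
        )
    if preset == "default":
        return SyntheticConfig()
    if preset == "realistic":
        return SyntheticConfig(
            yields=YieldConfig(
                structure=FULL_STRUCTURE,
                beta=estimates.FULL_MODEL_BEST.copy(),
            ),
        )
    if preset == "cold":
        return cold_config()
    raise ValueError(f"unknown preset {preset!r}")


@dataclass
class Fixture:
    """A generated input bundle: historical weather, covariates, yields."""

    config: SyntheticConfig
    study: SyntheticStudy
    weather: pd.DataFrame
    covariates: pd.DataFrame
    yields: pd.DataFrame
    truth: GroundTruth


def make_fixture(preset: str = "default", seed: int = 0,
                 config: SyntheticConfig | None = None) -> Fixture:
    """Generate a full historical input bundle for one preset (or config).

    Covariates are computed from the generated weather through the regular
    feature pipeline, and yields from those covariates — so the bundle
    exercises the same code paths as external data would.
    """
    if config is None:
        config = preset_config(preset)
    study = SyntheticStudy(config, seed)
    weather = study.weather_historical()
    covariates = compute_covariates(weather)
    yields, truth = study.generate_yields(covariates)
    return Fixture(config=config, study=study, weather=weather,
                   covariates=covariates, yields=yields, truth=truth)
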