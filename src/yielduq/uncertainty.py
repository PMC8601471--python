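"""Projection distributions and cumulative (staged) uncertainty decomposition.

Each accepted parameter vector crossed with each climate forcing yields a
30-year-mean regional yield anomaly; the spread of those projections is
attributed to its sources by the *cumulative uncertainty* method:

* stage "parameters" — vary parameters under each fixed forcing; the
  conditional SD per forcing is averaged into the stage's marginal SD;
* stage "forcing" — vary forcings under each fixed parameter sample,
  averaged likewise;
* stage "both" — the SD of the full Cartesian distribution (100% by
  definition).

Percentages are ratios of standard deviations, not variances, so single-
source stages need not sum to 100% and the attribution depends on the
order sources are added; both orderings' increments are reported. All
standard deviations are population (ddof=0) statistics, which makes the
law-of-total-variance identity on the Cartesian grid exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimates import COEF_NAMES
from .weather_features import compute_covariates
from .yield_model import county_weights, regional_term_matrix

STAGE_PARAMETERS = "parameters"
STAGE_FORCING = "forcing"
STAGE_BOTH = "both"


@dataclass
class ProjectionDistribution:
    """Samples of 30-year-mean regional yield anomaly for one stage.

    ``frame`` carries provenance: which parameter sample and forcing
    produced each value.
    """

    stage: str
    frame: pd.DataFrame            # param_id, forcing_label, value

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy()

    def grid(self) -> pd.DataFrame:
        """Pivot to a (param_id x forcing_label) matrix of projections."""
        return self.frame.pivot(index="param_id", columns="forcing_label", values="value")


@dataclass
class UncertaintyStage:
    """One stage of the cumulative decomposition."""

    stage: str
    conditional_sds: pd.Series     # one SD per fixed choice of the other factor
    marginal_sd: float             # mean of the conditional SDs
    percent_of_total: float        # marginal SD / SD(both) * 100


def forcing_projection_vector(
    forcing_weather: pd.DataFrame,
    weights: pd.Series,
    years=None,
    missing_season: str = "error",
) -> np.ndarray:
    """Window-mean regional regressor vector for one climate forcing.

    Computes seasonal covariates for every county-year of the forcing,
    averages the area-weighted regional polynomial regressors over the
    window years, and returns the 13-vector ``g`` such that a coefficient
    vector ``beta`` projects to ``g @ beta``. Years defaults to all years
    present (the convention for delta climates, whose observed record
    stands for the projection window).
    """
    cov = compute_covariates(forcing_weather, missing_season=missing_season)
    R = regional_term_matrix(cov, weights)
    if years is not None:
        wanted = [y for y in years]
        missing = set(wanted) - set(R.index)
        if missing:
            raise ValueError(f"forcing does not cover years: {sorted(missing)[:5]}")
        R = R.loc[wanted]
    return R.to_numpy().mean(axis=0)


def project_window(
    beta: np.ndarray,
    forcing_weather: pd.DataFrame,
    weights: pd.Series,
    years=None,
    center: float = 0.0,
    missing_season: str = "error",
) -> float:
    """30-year-mean regional yield anomaly for one parameter vector.

    Per year: seasonal covariates per county -> yield polynomial ->
    area-weighted regional anomaly; then the mean over the window years,
    minus the historical ``center`` (the reference-parameter historical
    mean, so a stationary climate with reference parameters projects ~0).
    """
    g = forcing_projection_vector(forcing_weather, weights, years, missing_season)
    return float(g @ np.asarray(beta, dtype=float) - center)


def historical_center(covariates: pd.DataFrame, weights: pd.Series, beta: np.ndarray) -> float:
    """Area-weighted historical mean of the reference regional hindcast.

    Subtracting this constant puts hindcasts and projections in the same
    normalized anomaly space as the observed yield anomalies.
    """
    R = regional_term_matrix(covariates, weights)
    series = R.to_numpy() @ np.asarray(beta, dtype=float)
    wyear = weights.loc[covariates["county_id"]].groupby(covariates["year"].to_numpy()).sum()
    w = wyear.loc[R.index].to_numpy(dtype=float)
    return float(np.sum(w * series) / w.sum())


def stage_distribution(
    param_samples: np.ndarray,
    forcing_vectors: dict[str, np.ndarray],
    center: float = 0.0,
    stage: str | None = None,
) -> ProjectionDistribution:
    """Cartesian projection of parameter samples across forcing vectors.

    ``param_samples`` is an (m, 13) matrix (a single vector is treated as
    m=1); ``forcing_vectors`` maps forcing labels to 13-vectors from
    :func:`forcing_projection_vector`. Produces m*k provenance-tagged
    samples.
    """
    P = np.atleast_2d(np.asarray(param_samples, dtype=float))
    if not forcing_vectors:
        raise ValueError("need at least one forcing")
    m = P.shape[0]
    frames = []
    for label, g in forcing_vectors.items():
        vals = P @ np.asarray(g, dtype=float) - center
        frames.append(pd.DataFrame({
            "param_id": np.arange(m), "forcing_label": label, "value": vals,
        }))
    if stage is None:
        stage = (
            STAGE_BOTH if m > 1 and len(forcing_vectors) > 1
            else STAGE_PARAMETERS if m > 1
            else STAGE_FORCING if len(forcing_vectors) > 1
            else "reference"
        )
    return ProjectionDistribution(stage=stage, frame=pd.concat(frames, ignore_index=True))


def cumulative_decomposition(full_stage: ProjectionDistribution) -> list[UncertaintyStage]:
    """Staged SD decomposition of the full Cartesian projection grid.

    Requires the "both" stage (every parameter sample crossed with every
    forcing); the single-source stages are its conditional slices, which
    guarantees all three stages describe the same ensemble and forcing
    set.
    """
    grid = full_stage.grid()
    if grid.isna().any().any():
        raise ValueError("full stage must be a complete Cartesian grid")
    if grid.shape[0] < 2 or grid.shape[1] < 2:
        raise ValueError("decomposition needs >= 2 parameter samples and >= 2 forcings")
    g = grid.to_numpy()
    total_sd = float(g.std(ddof=0))
    if total_sd == 0.0:
        raise ValueError("degenerate projection grid: all samples identical")
    per_forcing = pd.Series(g.std(axis=0, ddof=0), index=grid.columns)
    per_param = pd.Series(g.std(axis=1, ddof=0), index=grid.index)
    stages = [
        UncertaintyStage(STAGE_PARAMETERS, per_forcing,
                         float(per_forcing.mean()), 100.0 * per_forcing.mean() / total_sd),
        UncertaintyStage(STAGE_FORCING, per_param,
                         float(per_param.mean()), 100.0 * per_param.mean() / total_sd),
        UncertaintyStage(STAGE_BOTH, pd.Series({"all": total_sd}), total_sd, 100.0),
    ]
    return stages


def incremental_attribution(stages: list[UncertaintyStage]) -> pd.DataFrame:
    """Both orderings of the order-dependent incremental attribution.

    Starting from one source, the other source's increment is
    100% - (first stage's percent); the two orderings generally disagree —
    that disagreement is a property of the method and is reported, not
    hidden.
    """
    by = {s.stage: s for s in stages}
    rows = []
    for first, second in ((STAGE_PARAMETERS, STAGE_FORCING), (STAGE_FORCING, STAGE_PARAMETERS)):
        p1 = by[first].percent_of_total
        rows.append({
            "order": f"{first} then {second}",
            f"{first}_pct": p1,
            f"{second}_pct": 100.0 - p1,
        })
    return pd.DataFrame(rows)


def distribution_summary(values: np.ndarray | ProjectionDistribution) -> dict:
    """Summary record: moments, quantiles and adjusted Fisher-Pearson skewness.

    Quantiles use linear interpolation of order statistics.
    """
    v = values.values if isinstance(values, ProjectionDistribution) else np.asarray(values, float)
    if v.size < 2:
        raise ValueError("need at least 2 samples to summarize")
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=0)),
        "median": float(np.median(v)),
        "q2.5": float(np.quantile(v, 0.025)),
        "q97.5": float(np.quantile(v, 0.975)),
        "skewness": float(stats.skew(v, bias=False)),
        "min": float(v.min()),
        "max": float(v.max()),
        "quantile_method": "linear interpolation of order statistics",
    }
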