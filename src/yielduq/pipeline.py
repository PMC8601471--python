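"""End-to-end orchestration of the yield-projection uncertainty analysis.

Glue over the stage modules: fit the reference and full models, transform
yields to normalized anomalies, fit the plausible band, run the
pre-calibration screen, build climate forcings, and produce staged
projection distributions with their cumulative decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import climate_scenarios as cs
from . import precalibration as pc
from . import uncertainty as uq
from .yield_model import (
    FULL_STRUCTURE, REFERENCE_STRUCTURE, AnomalySeries, ModelParameters,
    ModelStructure, county_weights, fit_model, join_panel, make_anomalies,
    regional_term_matrix, select_structure,
)


@dataclass
class Calibration:
    """Everything the projection stages need from the historical record."""

    panel: pd.DataFrame
    weights: pd.Series
    params_ref: ModelParameters          # cross-validation selected model
    params_full: ModelParameters         # full model (pre-calibration center)
    anomalies: AnomalySeries
    regional_terms: pd.DataFrame         # year x 13 regressor means
    center: float                        # historical mean of reference hindcast
    reference_hindcast: pd.Series        # year -> best-estimate hindcast anomaly
    band: pc.PlausibleBand
    ranges: pc.SamplingRanges
    ensemble: pc.AcceptedEnsemble | None = None
    cv_table: pd.DataFrame | None = None


def calibrate(
    covariates: pd.DataFrame,
    yields: pd.DataFrame,
    structure: ModelStructure | None = None,
    select: bool = False,
    cv_folds: int = 10,
    cv_seed: int = 0,
    weighted: bool = False,
    coverage: float = 0.95,
    k_default: float = 10.0,
    k_edd: float = 50.0,
) -> Calibration:
    """Fit models, build anomalies, the plausible band and sampling ranges.

    ``structure`` fixes the reference model; ``select=True`` instead runs
    the exhaustive 729-structure cross-validation search. The band is
    centered on the *full* model's hindcast, whose coefficients and
    standard errors also seed the sampling ranges.
    """
    panel = join_panel(covariates, yields)
    weights = county_weights(yields)
    cv_table = None
    if select:
        structure, cv_table = select_structure(panel, k=cv_folds, seed=cv_seed,
                                               weighted=weighted)
    elif structure is None:
        structure = REFERENCE_STRUCTURE
    params_ref = fit_model(panel, structure, weighted=weighted)
    anomalies = make_anomalies(panel, params_ref, weights)
    params_full = fit_model(panel, FULL_STRUCTURE, weighted=weighted)
    R = regional_term_matrix(panel, weights)
    center = uq.historical_center(panel, weights, params_full.beta)
    reference_hindcast = pd.Series(
        R.to_numpy() @ params_full.beta - center, index=R.index, name="reference_hindcast")
    band = pc.fit_band(reference_hindcast, anomalies.regional, coverage=coverage)
    ranges = pc.build_ranges(params_full.beta, params_full.se,
                             k_default=k_default, k_edd=k_edd)
    return Calibration(
        panel=panel, weights=weights, params_ref=params_ref, params_full=params_full,
        anomalies=anomalies, regional_terms=R, center=center,
        reference_hindcast=reference_hindcast, band=band, ranges=ranges,
        cv_table=cv_table,
    )


def precalibrate(
    calib: Calibration,
    n: int = 1_000_000,
    seed: int = 0,
    chunk: int = 100_000,
    coverage_accept: float | None = None,
    proposal: str = "lhs",
    inflation: float = 3.0,
) -> pc.AcceptedEnsemble:
    """Run the pre-calibration screen and attach the ensemble to ``calib``.

    ``proposal="lhs"`` is the blind Latin hypercube screen over the full
    sampling box; ``proposal="gaussian"`` applies the same acceptance test
    to fit-informed Gaussian proposals (the desk-scale route — see
    :func:`yielduq.precalibration.run_precalibration_gaussian`).
    """
    if proposal == "lhs":
        ensemble = pc.run_precalibration(
            calib.ranges, calib.regional_terms, calib.band,
            n=n, seed=seed, chunk=chunk, center=calib.center,
            coverage_accept=coverage_accept,
        )
    elif proposal == "gaussian":
        ensemble = pc.run_precalibration_gaussian(
            calib.ranges, calib.regional_terms, calib.band,
            best=calib.params_full.beta, cov=calib.params_full.cov,
            n=n, seed=seed, chunk=chunk, center=calib.center,
            inflation=inflation, coverage_accept=coverage_accept,
        )
    else:
        raise ValueError("proposal must be 'lhs' or 'gaussian'")
    calib.ensemble = ensemble
    return ensemble


@dataclass
class WindowProjections:
    """Projection distributions and decomposition for one 30-year window."""

    window: cs.WindowSpec
    forcing_vectors: dict[str, np.ndarray]   # member label -> 13-vector
    delta_vector: np.ndarray
    reference_point: float                   # best params x delta climate
    dist_parameters: uq.ProjectionDistribution
    dist_forcing: uq.ProjectionDistribution
    dist_both: uq.ProjectionDistribution
    stages: list[uq.UncertaintyStage]
    attribution: pd.DataFrame
    summaries: dict[str, dict] = field(default_factory=dict)


def project_windows(
    calib: Calibration,
    member_vectors: dict[str, np.ndarray],
    delta_vector: np.ndarray,
    window: cs.WindowSpec,
    include_delta_in_variation: bool = False,
    max_samples: int | None = None,
) -> WindowProjections:
    """Staged projection distributions for one window.

    Stage "parameters": accepted ensemble x the fixed delta reference.
    Stage "forcing": best-estimate parameters x the ensemble members
    (the delta climate is excluded from the varied forcings unless
    ``include_delta_in_variation``). Stage "both": full Cartesian grid;
    its conditional slices feed the cumulative decomposition.
    """
    if calib.ensemble is None or calib.ensemble.n_accepted == 0:
        raise ValueError("run precalibrate() first; the accepted ensemble is empty")
    samples = calib.ensemble.samples
    if max_samples is not None:
        samples = samples[:max_samples]
    varied = dict(member_vectors)
    if include_delta_in_variation:
        varied["delta"] = delta_vector
    best = calib.params_full.beta
    c = calib.center
    reference_point = float(delta_vector @ best - c)
    dist_params = uq.stage_distribution(samples, {"delta": delta_vector}, center=c,
                                        stage=uq.STAGE_PARAMETERS)
    dist_forcing = uq.stage_distribution(best, varied, center=c, stage=uq.STAGE_FORCING)
    dist_both = uq.stage_distribution(samples, varied, center=c, stage=uq.STAGE_BOTH)
    stages = uq.cumulative_decomposition(dist_both)
    attribution = uq.incremental_attribution(stages)
    summaries = {
        d.stage: uq.distribution_summary(d)
        for d in (dist_params, dist_forcing, dist_both)
    }
    return WindowProjections(
        window=window, forcing_vectors=member_vectors, delta_vector=delta_vector,
        reference_point=reference_point, dist_parameters=dist_params,
        dist_forcing=dist_forcing, dist_both=dist_both,
        stages=stages, attribution=attribution, summaries=summaries,
    )


def synthetic_forcing_vectors(
    study,
    calib: Calibration,
    window: cs.WindowSpec,
    margin_years: int = 1,
) -> tuple[dict[str, np.ndarray], np.ndarray, cs.DeltaSpec]:
    """Member and delta projection vectors for one window of a synthetic study.

    Members are generated over the window (with a margin year before, so
    season detection never touches the window edge); the delta climate
    shifts the observed 1981-2010 record by per-county ensemble-mean
    deltas. The observed record doubles as the delta hindcast baseline.
    """
    start = window.start_year - margin_years
    members = {}
    member_dailies = []
    for i, label in enumerate(study.member_labels()):
        wx = study.weather_member(i, start, window.end_year)
        member_dailies.append(wx)
        members[label] = uq.forcing_projection_vector(
            wx, calib.weights, years=window.years)
    obs = study.weather_historical()
    years = pd.to_datetime(obs["date"]).dt.year
    h0, h1 = cs.HINDCAST_WINDOW
    h0, h1 = max(h0, int(years.min())), min(h1, int(years.max()))
    if h1 < h0:  # record does not reach the conventional baseline window
        h0, h1 = int(years.min()), int(years.max())
    obs_hind = obs[(years >= h0) & (years <= h1)]
    spec = cs.build_delta_spec(obs_hind, member_dailies, window,
                               hindcast_window=cs.WindowSpec(h0, h1, "hindcast"))
    delta = cs.delta_shift(obs_hind, spec, label="delta")
    delta_vector = uq.forcing_projection_vector(delta.weather, calib.weights)
    return members, delta_vector, spec
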