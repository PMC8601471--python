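"""Weather-yield panel regression with exhaustive structure selection.

The yield of county *i* in year *t* is modelled as a polynomial in six
seasonal weather covariates plus year and county fixed effects::

    yield_it = f(GDD, EDD, Tmax, Tmin, Pr, VPD; beta) + u_t + v_i + eps_it

where ``f`` includes, per variable, nothing, a linear term, or linear plus
quadratic terms, and an intercept — a family of 3^6 = 729 model
*structures*. Year effects ``u_t`` absorb technology, price and CO2
trends; county effects ``v_i`` absorb time-constant site quality. The
best structure is the one minimizing 10-fold cross-validated RMSE.

Fixed effects are estimated jointly with the weather terms in one
(optionally area-weighted) least-squares fit. The cross-validation loop
residualizes the response and the twelve weather columns against the
fixed-effect space once per fold, so each of the 729 candidate fits
reduces to a small least-squares problem.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .estimates import COEF_NAMES, VARIABLES, VARIABLE_COLUMNS
from .weather_features import area_weighted_mean

logger = logging.getLogger(__name__)

LEVEL_ABSENT, LEVEL_LINEAR, LEVEL_QUADRATIC = 0, 1, 2


class CollinearityError(ValueError):
    """The regression design is rank deficient."""

    def __init__(self, terms):
        self.terms = list(terms)
        super().__init__(f"rank-deficient design; offending terms: {self.terms}")


@dataclass(frozen=True, order=True)
class ModelStructure:
    """Inclusion levels (0 absent, 1 linear, 2 linear+quadratic) per variable.

    Levels follow the canonical variable order (gdd, edd, tmax, tmin, pr,
    vpd). Quadratic inclusion implies linear inclusion by construction.
    """

    levels: tuple[int, ...]

    def __post_init__(self):
        if len(self.levels) != len(VARIABLES) or any(l not in (0, 1, 2) for l in self.levels):
            raise ValueError("levels must be six values in {0, 1, 2}")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "ModelStructure":
        return cls(tuple(int(d.get(v, 0)) for v in VARIABLES))

    @property
    def coef_mask(self) -> np.ndarray:
        """Boolean mask over the 13 canonical coefficients (intercept always on)."""
        mask = np.zeros(len(COEF_NAMES), dtype=bool)
        for j, lev in enumerate(self.levels):
            if lev >= 1:
                mask[2 * j] = True
            if lev == 2:
                mask[2 * j + 1] = True
        mask[-1] = True
        return mask

    @property
    def n_terms(self) -> int:
        """Number of included weather terms (intercept not counted)."""
        return int(sum(self.levels))

    def label(self) -> str:
        parts = []
        for v, lev in zip(VARIABLES, self.levels):
            if lev == 1:
                parts.append(v)
            elif lev == 2:
                parts.append(f"{v}+{v}2")
        return "+".join(parts) if parts else "intercept-only"

    def __str__(self):
        return "".join(str(l) for l in self.levels)


FULL_STRUCTURE = ModelStructure((2, 2, 2, 2, 2, 2))
INTERCEPT_ONLY = ModelStructure((0, 0, 0, 0, 0, 0))
#: Cross-validation selected reference structure: quadratic GDD, Tmin, Pr,
#: VPD, linear EDD, no Tmax terms.
REFERENCE_STRUCTURE = ModelStructure((2, 1, 0, 2, 2, 2))


def enumerate_structures() -> list[ModelStructure]:
    """All 729 up-to-quadratic model structures over the six variables."""
    return [ModelStructure(lv) for lv in itertools.product((0, 1, 2), repeat=len(VARIABLES))]


@dataclass
class ModelParameters:
    """Fitted coefficients of one model structure on a county-year panel.

    ``beta`` and ``se`` are 13-vectors in canonical coefficient order with
    exact zeros for excluded terms. ``year_effects`` are the estimated
    temporal fixed effects *including* the intercept (subtracting them
    removes the full year level); ``county_effects`` are relative to the
    reference (first) county.
    """

    structure: ModelStructure
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray                  # 13x13 sampling covariance (zeros for excluded)
    year_effects: pd.Series
    county_effects: pd.Series
    n_obs: int
    sigma2: float
    weighted: bool


@dataclass
class AnomalySeries:
    """Yield anomalies after removing year effects and the historical mean."""

    regional: pd.Series              # year -> area-weighted regional anomaly
    county: pd.DataFrame             # county_id, year, anomaly
    normalization: float             # constant subtracted so the mean is zero


def term_matrix(covariates) -> np.ndarray:
    """(n, 13) matrix of polynomial regressors in canonical coefficient order.

    Accepts a covariate DataFrame (gdd, edd, tmax_mean, tmin_mean,
    pr_total, vpd_mean) or anything with those attributes.
    """
    if isinstance(covariates, pd.DataFrame):
        cols = {v: covariates[VARIABLE_COLUMNS[v]].to_numpy(dtype=float) for v in VARIABLES}
        n = len(covariates)
    else:
        cols = {v: np.atleast_1d(np.asarray(getattr(covariates, VARIABLE_COLUMNS[v]), dtype=float))
                for v in VARIABLES}
        n = cols["gdd"].size
    out = np.empty((n, len(COEF_NAMES)))
    for j, v in enumerate(VARIABLES):
        out[:, 2 * j] = cols[v]
        out[:, 2 * j + 1] = cols[v] ** 2
    out[:, -1] = 1.0
    return out


def predict_anomaly(beta, covariates):
    """Evaluate the yield polynomial at the given covariates.

    ``beta`` is a 13-vector in canonical order (excluded terms zero).
    Returns a scalar for a single covariate record, else an array.
    """
    beta = np.asarray(beta, dtype=float)
    t = term_matrix(covariates)
    out = t @ beta
    return float(out[0]) if out.size == 1 and not isinstance(covariates, pd.DataFrame) else out


def join_panel(covariates: pd.DataFrame, yields: pd.DataFrame) -> pd.DataFrame:
    """Inner-join seasonal covariates with yield observations on county-year."""
    panel = covariates.merge(yields, on=["county_id", "year"], how="inner")
    if panel.empty:
        raise ValueError("covariates and yields share no county-years")
    return panel.sort_values(["county_id", "year"], ignore_index=True)


class _PanelDesign:
    """Precomputed design pieces for one panel: weather terms and dummies."""

    def __init__(self, panel: pd.DataFrame, weighted: bool = False):
        self.panel = panel
        self.n = len(panel)
        self.y = panel["yield_bu_ac"].to_numpy(dtype=float)
        self.terms = term_matrix(panel)          # (n, 13); last col is 1
        self.W = self.terms[:, :-1]              # 12 weather columns
        self.years = np.sort(panel["year"].unique())
        self.counties = pd.unique(panel["county_id"].sort_values())
        self.year_idx = pd.Categorical(panel["year"], categories=self.years).codes
        self.county_idx = pd.Categorical(panel["county_id"], categories=self.counties).codes
        ny, nc = len(self.years), len(self.counties)
        D = np.zeros((self.n, 1 + (ny - 1) + (nc - 1)))
        D[:, 0] = 1.0
        r = np.arange(self.n)
        m = self.year_idx > 0
        D[r[m], self.year_idx[m]] = 1.0
        m = self.county_idx > 0
        D[r[m], ny - 1 + self.county_idx[m]] = 1.0
        self.D = D
        if weighted:
            w = panel["area_acres"].to_numpy(dtype=float)
            if np.any(w <= 0):
                raise ValueError("areas must be positive for weighted fitting")
            self.sqrtw = np.sqrt(w / w.mean())
        else:
            self.sqrtw = np.ones(self.n)
        self.weighted = weighted

    def dummy_names(self):
        names = ["intercept"]
        names += [f"year_{y}" for y in self.years[1:]]
        names += [f"county_{c}" for c in self.counties[1:]]
        return names


class _FoldWorkspace:
    """QR of the (weighted) dummy block on a row subset, plus residualized
    weather columns, enabling cheap per-structure fits (Frisch-Waugh)."""

    def __init__(self, design: _PanelDesign, rows: np.ndarray):
        self.design = design
        self.rows = rows
        sw = design.sqrtw[rows][:, None]
        Dw = design.D[rows] * sw
        norms = np.linalg.norm(Dw, axis=0)
        self.kept = norms > 1e-10 * max(1.0, norms.max())
        if not self.kept.all():
            logger.warning(
                "fold lost %d fixed-effect level(s); absorbed into the reference level",
                int((~self.kept).sum()),
            )
        Q, R = np.linalg.qr(Dw[:, self.kept])
        self.Q, self.R = Q, R
        Ww = design.W[rows] * sw
        yw = design.y[rows] * sw[:, 0]
        self.QtW = Q.T @ Ww
        self.Qty = Q.T @ yw
        self.Wres = Ww - Q @ self.QtW
        self.yres = yw - Q @ self.Qty
        self.Ww = Ww
        self.yw = yw

    def fit(self, structure: ModelStructure):
        """Return (beta13, dummy_coefs_kept) for one structure."""
        sel = structure.coef_mask[:-1]
        beta = np.zeros(len(COEF_NAMES))
        if sel.any():
            X = self.Wres[:, sel]
            sol, *_ = np.linalg.lstsq(X, self.yres, rcond=None)
            beta[:-1][sel] = sol
        a = solve_triangular(self.R, self.Qty - self.QtW @ beta[:-1])
        return beta, a

    def predict(self, beta, a, rows):
        """Unweighted-space predictions for arbitrary panel rows."""
        d = self.design
        full_a = np.zeros(d.D.shape[1])
        full_a[self.kept] = a
        return d.W[rows] @ beta[:-1] + d.D[rows] @ full_a


def fit_model(
    panel: pd.DataFrame,
    structure: ModelStructure = FULL_STRUCTURE,
    weighted: bool = False,
) -> ModelParameters:
    """Fit one model structure on the county-year panel by (weighted) OLS.

    Year and county fixed effects are estimated jointly with the weather
    terms; the first year and county are folded into the intercept.
    Returns coefficients and standard errors in canonical order.
    """
    if panel["year"].nunique() < 2 or panel["county_id"].nunique() < 2:
        raise ValueError("panel needs at least 2 years and 2 counties")
    design = _PanelDesign(panel, weighted=weighted)
    sel = structure.coef_mask[:-1]
    sw = design.sqrtw[:, None]
    X = np.concatenate([design.W[:, sel] * sw, design.D * sw], axis=1)
    yw = design.y * design.sqrtw
    p = X.shape[1]
    sol, res, rank, sv = np.linalg.lstsq(X, yw, rcond=None)
    if rank < p:
        # name offenders via pivoted-QR style diagnostics on the normal matrix
        names = [c for c, s in zip(COEF_NAMES[:-1], sel) if s] + design.dummy_names()
        G = X.T @ X
        diag = np.sqrt(np.maximum(np.diag(G), 1e-300))
        C = G / np.outer(diag, diag)
        eigval, eigvec = np.linalg.eigh(C)
        bad = np.abs(eigvec[:, 0]) > 0.3
        raise CollinearityError([n for n, b in zip(names, bad) if b])
    fitted = X @ sol
    resid = yw - fitted
    dof = max(design.n - p, 1)
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se_all = np.sqrt(sigma2 * np.diag(XtX_inv))

    k = int(sel.sum())
    beta = np.zeros(len(COEF_NAMES))
    se = np.zeros(len(COEF_NAMES))
    beta[:-1][sel] = sol[:k]
    se[:-1][sel] = se_all[:k]
    beta[-1] = sol[k]          # intercept (first dummy column)
    se[-1] = se_all[k]
    cov = np.zeros((len(COEF_NAMES), len(COEF_NAMES)))
    idx13 = list(np.nonzero(sel)[0]) + [len(COEF_NAMES) - 1]
    idx_design = list(range(k)) + [k]
    cov[np.ix_(idx13, idx13)] = sigma2 * XtX_inv[np.ix_(idx_design, idx_design)]
    ny = len(design.years)
    year_coef = np.concatenate([[0.0], sol[k + 1:k + ny]])
    county_coef = np.concatenate([[0.0], sol[k + ny:]])
    year_effects = pd.Series(beta[-1] + year_coef, index=design.years, name="year_effect")
    county_effects = pd.Series(county_coef, index=pd.Index(design.counties), name="county_effect")
    return ModelParameters(
        structure=structure, beta=beta, se=se, cov=cov,
        year_effects=year_effects, county_effects=county_effects,
        n_obs=design.n, sigma2=sigma2, weighted=weighted,
    )


def _fold_assignments(n: int, k: int, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    folds = np.arange(n) % k
    return folds[rng.permutation(n)]


def cv_rmse(
    panel: pd.DataFrame,
    structure: ModelStructure,
    k: int = 10,
    seed: int = 0,
    weighted: bool = False,
) -> float:
    """Mean over k folds of held-out RMSE for one structure.

    Observations are randomly partitioned into k near-equal folds (seeded).
    """
    table = cv_table(panel, [structure], k=k, seed=seed, weighted=weighted)
    return float(table["cv_rmse"].iloc[0])


def cv_table(
    panel: pd.DataFrame,
    structures: Sequence[ModelStructure],
    k: int = 10,
    seed: int = 0,
    weighted: bool = False,
) -> pd.DataFrame:
    """Cross-validated RMSE for many structures sharing the same folds."""
    design = _PanelDesign(panel, weighted=weighted)
    n = design.n
    if n < k:
        raise ValueError(f"need at least k={k} observations, got {n}")
    assign = _fold_assignments(n, k, seed)
    workspaces = []
    tests = []
    for f in range(k):
        test = np.nonzero(assign == f)[0]
        train = np.nonzero(assign != f)[0]
        workspaces.append(_FoldWorkspace(design, train))
        tests.append(test)
    y = design.y
    rows = []
    for s in structures:
        fold_rmse = np.empty(k)
        ok = True
        for f in range(k):
            try:
                beta, a = workspaces[f].fit(s)
            except np.linalg.LinAlgError:
                logger.warning("structure %s failed on fold %d; skipped", s, f)
                ok = False
                break
            pred = workspaces[f].predict(beta, a, tests[f])
            err = y[tests[f]] - pred
            fold_rmse[f] = np.sqrt(np.mean(err ** 2))
        rows.append({
            "structure": str(s),
            "label": s.label(),
            "n_terms": s.n_terms,
            "cv_rmse": float(fold_rmse.mean()) if ok else np.nan,
        })
    return pd.DataFrame(rows)


def select_structure(
    panel: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    weighted: bool = False,
    structures: Sequence[ModelStructure] | None = None,
    tie_atol: float = 1e-8,
) -> tuple[ModelStructure, pd.DataFrame]:
    """Exhaustive structure search by 10-fold cross-validation.

    Returns the argmin structure over all 729 candidates and the full
    ranked table. RMSEs within ``tie_atol`` (bushel/acre; the numerical-
    noise scale of the solver) are treated as tied; ties are broken by
    fewer included terms, then by the lexicographic order of the level
    tuple, so a noiseless fit selects the minimal adequate structure.
    """
    if structures is None:
        structures = enumerate_structures()
    table = cv_table(panel, structures, k=k, seed=seed, weighted=weighted)

    def key(i):
        r = table["cv_rmse"].iloc[i]
        q = np.round(r / tie_atol) * tie_atol if np.isfinite(r) else np.inf
        return (q, structures[i].n_terms, structures[i].levels)

    order = sorted(range(len(structures)), key=key)
    table = table.iloc[order].reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return structures[order[0]], table


def county_weights(yields: pd.DataFrame) -> pd.Series:
    """Per-county growing area (first reported value per county)."""
    w = yields.groupby("county_id")["area_acres"].first()
    if (w <= 0).any():
        raise ValueError("county areas must be positive")
    return w


def make_anomalies(
    panel: pd.DataFrame,
    params: ModelParameters,
    weights: pd.Series | None = None,
) -> AnomalySeries:
    """Detrend yields by year effects and normalize to zero historical mean.

    Per-observation anomaly = yield - year_effect(year). The regional
    annual series is the area-weighted county mean; the (single) area-
    weighted historical mean is then subtracted from everything so the
    weighted mean of the historical regional series is exactly zero.
    County (spatial) effects are deliberately not removed.
    """
    if weights is None:
        weights = county_weights(panel)
    missing_years = set(panel["year"].unique()) - set(params.year_effects.index)
    if missing_years:
        raise KeyError(f"no year effect for years: {sorted(missing_years)}")
    df = panel[["county_id", "year", "yield_bu_ac"]].copy()
    df["anomaly"] = df["yield_bu_ac"] - params.year_effects.loc[df["year"]].to_numpy()
    w = weights.loc[df["county_id"]].to_numpy(dtype=float)
    c0 = float(np.sum(w * df["anomaly"].to_numpy()) / np.sum(w))
    df["anomaly"] -= c0
    regional = df.groupby("year").apply(
        lambda g: area_weighted_mean(
            g.set_index("county_id")["anomaly"], weights),
        include_groups=False,
    )
    regional.name = "regional_anomaly"
    return AnomalySeries(
        regional=regional,
        county=df[["county_id", "year", "anomaly"]],
        normalization=c0,
    )


def regional_term_matrix(covariates: pd.DataFrame, weights: pd.Series) -> pd.DataFrame:
    """Area-weighted regional mean of the 13 polynomial regressors per year.

    The regional annual hindcast of any coefficient vector ``beta`` is then
    the matrix-vector product ``R @ beta`` — linear in the coefficients,
    which makes screening millions of parameter samples cheap.
    """
    t = term_matrix(covariates)
    df = pd.DataFrame(t, columns=list(COEF_NAMES))
    df["year"] = covariates["year"].to_numpy()
    w = weights.loc[covariates["county_id"]].to_numpy(dtype=float)
    df[list(COEF_NAMES)] = df[list(COEF_NAMES)].mul(w, axis=0)
    sums = df.groupby("year")[list(COEF_NAMES)].sum()
    wsum = pd.Series(w, index=df.index).groupby(df["year"]).sum()
    return sums.div(wsum, axis=0)
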