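"""Mixed-model machinery: AR(1) fits, VIF, lag CV, batteries, ANOVA, Tukey."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from duetsense.stats import (
    ALPHA_BATTERY,
    anova_mean_ratings,
    compare_body_parts,
    compute_vif,
    fit_lmm_ar1,
    lag_crossvalidation,
    participant_folds,
    run_sync_models,
    run_togetherness_models,
)


def _simulate_ar1_dataset(
    seed=7, n_participants=5, n_stimuli=3, n_steps=60,
    beta0=5.0, beta1=2.0, rho=0.6, sd=2.0, tau=3.0,
):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        b = rng.normal(0, tau)
        for s in range(n_stimuli):
            x = rng.normal(0, 1, n_steps)
            noise = np.empty(n_steps)
            noise[0] = rng.normal(0, sd)
            for i in range(1, n_steps):
                noise[i] = rho * noise[i - 1] + rng.normal(
                    0, sd * np.sqrt(1 - rho**2)
                )
            y = beta0 + b + beta1 * x + noise
            for i in range(n_steps):
                rows.append((f"p{p}", f"s{s}", i, x[i], y[i]))
    df = pd.DataFrame(rows, columns=["participant", "stimulus", "t", "x",
                                     "response"])
    df["modality"] = "AO"
    return df


def _nlme_dataset():
    """The exact dataset behind the frozen R nlme reference values."""
    return _simulate_ar1_dataset(seed=7)


SERIES = ["participant", "stimulus", "modality"]


class TestFitLmmAr1:
    def test_matches_nlme_reference(self):
        """ML estimates agree with R nlme::lme + corAR1 on the same data
        (reference values frozen from tests/oracles/lmm_ar1_oracle.R)."""
        fit = fit_lmm_ar1(_nlme_dataset(), "response", ["x"], series=SERIES)
        beta = fit.params.set_index("term")
        assert beta.loc["Intercept", "beta"] == pytest.approx(3.870733, abs=1e-4)
        assert beta.loc["x", "beta"] == pytest.approx(2.039702, abs=1e-4)
        assert fit.rho == pytest.approx(0.6285705, abs=1e-4)
        assert fit.var_group == pytest.approx(18.37979, rel=1e-3)
        assert fit.var_resid == pytest.approx(4.078325, rel=1e-3)
        assert fit.loglik == pytest.approx(-1700.363, abs=0.01)
        # Wald SEs agree to the small-sample correction nlme applies
        assert beta.loc["Intercept", "se"] == pytest.approx(1.924319, rel=5e-3)
        assert beta.loc["x", "se"] == pytest.approx(0.0455648, rel=5e-3)

    def test_reduces_to_ols_without_variance_components(self):
        import statsmodels.api as sm

        df = _simulate_ar1_dataset(seed=3)
        fit = fit_lmm_ar1(df, "response", ["x"], group=None, series=None)
        ols = sm.OLS(df["response"], sm.add_constant(df["x"])).fit()
        assert np.max(np.abs(fit.params["beta"].to_numpy()
                             - ols.params.to_numpy())) < 1e-6
        assert fit.rho == 0.0 and fit.var_group == 0.0

    def test_parameter_recovery(self):
        """beta, rho and the variance components are recovered on data
        generated from the model itself."""
        df = _simulate_ar1_dataset(seed=21, n_participants=10, n_stimuli=4,
                                   n_steps=150)
        fit = fit_lmm_ar1(df, "response", ["x"], series=SERIES)
        row = fit.params.set_index("term").loc["x"]
        assert row["beta"] == pytest.approx(2.0, abs=4 * row["se"])
        assert fit.rho == pytest.approx(0.6, abs=0.06)
        assert fit.var_resid == pytest.approx(4.0, rel=0.25)
        assert fit.converged

    def test_rho_zero_data_estimates_near_zero(self):
        df = _simulate_ar1_dataset(seed=5, rho=0.0, n_participants=10,
                                   n_stimuli=4, n_steps=150)
        fit = fit_lmm_ar1(df, "response", ["x"], series=SERIES)
        assert abs(fit.rho) < 0.05

    def test_constant_predictor_raises_singular(self):
        df = _simulate_ar1_dataset(seed=2)
        df["c"] = 1.5
        with pytest.raises(ValueError, match="singular"):
            fit_lmm_ar1(df, "response", ["x", "c"], series=SERIES)

    def test_fixed_rho_respected(self):
        df = _simulate_ar1_dataset(seed=4)
        fit = fit_lmm_ar1(df, "response", ["x"], series=SERIES, rho=0.25)
        assert fit.rho == 0.25

    def test_prediction_uses_fixed_effects_only(self):
        df = _simulate_ar1_dataset(seed=6)
        fit = fit_lmm_ar1(df, "response", ["x"], series=SERIES)
        new = pd.DataFrame({"x": [0.0, 1.0]})
        pred = fit.predict(new)
        beta = fit.params.set_index("term")["beta"]
        np.testing.assert_allclose(
            pred, [beta["Intercept"], beta["Intercept"] + beta["x"]], rtol=1e-12
        )


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        n = 400
        t = np.arange(n)
        df = pd.DataFrame({"a": np.sin(2 * np.pi * t / 16),
                           "b": np.cos(2 * np.pi * t / 16)})
        vif = compute_vif(df, ["a", "b"])
        np.testing.assert_allclose(vif, 1.0, atol=1e-10)

    def test_known_correlation_closed_form(self):
        """r = 0.8 between two predictors gives VIF = 1/(1-0.64) = 2.78."""
        rng = np.random.default_rng(0)
        n = 200000
        a = rng.normal(size=n)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.normal(size=n)
        vif = compute_vif(pd.DataFrame({"a": a, "b": b}), ["a", "b"])
        np.testing.assert_allclose(vif, 1 / (1 - 0.64), rtol=0.02)

    def test_matches_statsmodels(self):
        from statsmodels.stats.outliers_influence import (
            variance_inflation_factor,
        )
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 3))
        X[:, 2] += 0.5 * X[:, 0] - 0.3 * X[:, 1]
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        mine = compute_vif(df, ["a", "b", "c"])
        Xc = sm.add_constant(X)
        theirs = [variance_inflation_factor(Xc, i + 1) for i in range(3)]
        np.testing.assert_allclose(mine.to_numpy(), theirs, rtol=1e-8)

    def test_perfect_collinearity_infinite(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0)})
        vif = compute_vif(df, ["a", "b"])
        assert np.isinf(vif).all()


def _cv_tables(true_lag=2.0, seed=0, n_participants=10, n_stimuli=3,
               n_steps=200, beta=3.0, noise_sd=2.0, rho=0.5):
    """Model tables per candidate lag from a latent process driven by a slow
    predictor at a known lag."""
    rng = np.random.default_rng(seed)
    stim_x = {
        f"s{s}": np.cumsum(rng.normal(0, 1, n_steps)) / np.sqrt(n_steps)
        for s in range(n_stimuli)
    }
    shift_true = int(true_lag * 10)
    tables = {}
    responses = {}
    for p in range(n_participants):
        b = rng.normal(0, 2)
        for s, x in stim_x.items():
            lagged = np.empty(n_steps)
            lagged[shift_true:] = x[:n_steps - shift_true]
            lagged[:shift_true] = x[0]
            noise = np.empty(n_steps)
            noise[0] = rng.normal(0, noise_sd)
            for i in range(1, n_steps):
                noise[i] = rho * noise[i - 1] + rng.normal(
                    0, noise_sd * np.sqrt(1 - rho**2)
                )
            responses[(p, s)] = 50 + b + beta * lagged + noise
    for lag in (1.0, 2.0, 3.0):
        shift = int(lag * 10)
        rows = []
        for (p, s), resp in responses.items():
            n = n_steps - shift
            rows.append(pd.DataFrame({
                "participant": f"p{p}", "stimulus": s, "modality": "AO",
                "t": np.arange(n) / 10.0,
                "x": stim_x[s][:n],
                "response": resp[shift:shift + n],
            }))
        tables[lag] = pd.concat(rows, ignore_index=True)
    return tables


class TestLagCrossvalidation:
    def test_fold_partition_properties(self):
        folds = participant_folds([f"p{i}" for i in range(23)], 10, seed=1)
        flat = [p for f in folds for p in f]
        assert sorted(flat) == sorted(f"p{i}" for i in range(23))
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_recovers_true_lag_and_mae_below_rmse(self):
        tables = _cv_tables(true_lag=2.0, seed=8)
        res = lag_crossvalidation(tables, ["x"], k=5, seed=0)
        assert res.selected_lag == 2.0
        assert (res.fold_errors["mae"] <= res.fold_errors["rmse"] + 1e-9).all()

    def test_leave_one_participant_out_boundary(self):
        tables = _cv_tables(true_lag=1.0, seed=9, n_participants=5,
                            n_steps=80)
        res = lag_crossvalidation(tables, ["x"], k=5, seed=0)
        assert res.k == 5
        assert len(res.fold_errors) == 3 * 5

    def test_too_few_participants_rejected(self):
        tables = _cv_tables(seed=1, n_participants=3, n_steps=60)
        with pytest.raises(ValueError, match="at least"):
            lag_crossvalidation(tables, ["x"], k=10, seed=0)


def _battery_table(seed=0, n_per_group=3, n_stimuli=2, n_steps=150,
                   betas=None, noise_sd=3.0, rho=0.4):
    """Minimal togetherness model table with controllable group effects."""
    rng = np.random.default_rng(seed)
    betas = betas or {}
    predictors = ["intensity", "qom_total", "cwt_head", "cwt_chest",
                  "cwt_l_shoulder", "cwt_r_shoulder", "cwt_l_arm", "cwt_r_arm"]
    stim_x = {
        f"s{s}": {
            p: np.cumsum(rng.normal(0, 1, n_steps)) / np.sqrt(n_steps)
            for p in predictors
        }
        for s in range(n_stimuli)
    }
    groups = [("novice", "none"), ("semi-pro", "pianist"),
              ("semi-pro", "clarinetist")]
    rows = []
    for background, instrument in groups:
        key = instrument if instrument != "none" else "novice"
        group_betas = betas.get(key, {})
        for i in range(n_per_group):
            pid = f"{key}{i}"
            b = rng.normal(0, 2)
            for s, feats in stim_x.items():
                for modality in ("AO", "VO", "AV"):
                    noise = np.empty(n_steps)
                    noise[0] = rng.normal(0, noise_sd)
                    for j in range(1, n_steps):
                        noise[j] = rho * noise[j - 1] + rng.normal(
                            0, noise_sd * np.sqrt(1 - rho**2)
                        )
                    latent = 50 + b + noise
                    for name, bta in group_betas.items():
                        latent = latent + bta * feats[name]
                    frame = {
                        "participant": pid, "background": background,
                        "instrument": instrument, "stimulus": s,
                        "stimulus_group": "piano", "modality": modality,
                        "t": np.arange(n_steps) / 10.0,
                        "response": latent,
                    }
                    frame.update({p: feats[p] for p in predictors})
                    rows.append(pd.DataFrame(frame))
    return pd.concat(rows, ignore_index=True)


class TestTogethernessBattery:
    def test_group_specific_intensity_effect(self):
        """Novices generated with a positive intensity effect and semi-pros
        with none: model 1b significant at 0.0125, 1a not."""
        table = _battery_table(seed=12, betas={"novice": {"intensity": 4.0}})
        fits, tidy = run_togetherness_models(table, models=("1",))
        by = tidy.set_index(["model", "term"])
        assert by.loc[("1b", "intensity"), "significant"]
        assert not by.loc[("1a", "intensity"), "significant"]
        assert by.loc[("1b", "intensity"), "beta"] == pytest.approx(4.0, abs=1.0)

    def test_battery_shape(self):
        table = _battery_table(seed=13)
        fits, tidy = run_togetherness_models(table)
        assert set(fits) == {f"{m}{g}" for m in "123" for g in "abcd"}
        # model 1: 1 predictor; model 2: 7; model 3: 8 -> per group
        assert len(tidy) == 4 * (1 + 7 + 8)
        assert (tidy["significant"] == (tidy["p"] < ALPHA_BATTERY)).all()

    def test_single_model_single_group(self):
        table = _battery_table(seed=14)
        fits, tidy = run_togetherness_models(table, models=("1",), groups=("b",))
        assert list(fits) == ["1b"]
        assert len(tidy) == 1


def _sync_table(seed=0, slope=-0.006, n_per_group=4, n_stimuli=3, n_sync=16,
                noise_sd=4.0):
    rng = np.random.default_rng(seed)
    asyncs = {
        (f"s{i}", k): abs(rng.normal(0, 130.0))
        for i in range(n_stimuli) for k in range(1, n_sync + 1)
    }
    rows = []
    for background, instrument in (("novice", "none"), ("semi-pro", "pianist"),
                                   ("semi-pro", "clarinetist")):
        key = instrument if instrument != "none" else "novice"
        for i in range(n_per_group):
            pid = f"{key}{i}"
            b = rng.normal(0, 3)
            for (sid, k), a in asyncs.items():
                for modality in ("AO", "AV"):
                    rows.append({
                        "participant": pid, "background": background,
                        "instrument": instrument, "stimulus": sid,
                        "modality": modality, "sync_index": k,
                        "abs_asynchrony": a,
                        "asynchrony": a,
                        "response": 60 + b + slope * a
                        + rng.normal(0, noise_sd),
                    })
    return pd.DataFrame(rows)


class TestSyncModels:
    def test_negative_slope_recovered(self):
        table = _sync_table(seed=3, slope=-0.02)
        fits, tidy = run_sync_models(table)
        est = tidy.set_index("model")["beta"]
        assert (est < 0).all()
        assert est["5a"] == pytest.approx(-0.02, abs=0.01)

    def test_constant_asynchrony_flagged_inestimable(self):
        table = _sync_table(seed=4)
        table["abs_asynchrony"] = 100.0
        fits, tidy = run_sync_models(table)
        assert tidy["note"].str.contains("inestimable").all()
        assert not tidy["significant"].any()

    def test_too_few_sync_points_rejected(self):
        table = _sync_table(seed=5)
        table = table[table["sync_index"] == 1]
        with pytest.raises(ValueError, match="sync points"):
            run_sync_models(table)


def _means_table(seed=0, effects=None):
    rng = np.random.default_rng(seed)
    effects = effects or {}
    rows = []
    for background in ("novice", "semi-pro"):
        for p in range(8):
            pid = f"{background}{p}"
            for sg in ("piano", "clarinet"):
                for s in range(3):
                    for modality in ("AO", "VO", "AV"):
                        mu = 50 + effects.get(background, 0.0)
                        rows.append({
                            "participant": pid, "background": background,
                            "instrument": "none", "stimulus": f"{sg}_{s}",
                            "stimulus_group": sg, "modality": modality,
                            "mean_rating": mu + rng.normal(0, 5),
                        })
    return pd.DataFrame(rows)


class TestAnova:
    def test_balanced_two_by_three_sums_of_squares_oracle(self):
        """F statistics on a balanced 2x3 design equal the hand-computed
        between/within sums-of-squares ratio."""
        rng = np.random.default_rng(10)
        cells = {("a", "x"): 50, ("a", "y"): 55, ("a", "z"): 53,
                 ("b", "x"): 60, ("b", "y"): 65, ("b", "z"): 63}
        rows = []
        n_cell = 20
        for (f1, f2), mu in cells.items():
            for _ in range(n_cell):
                rows.append({"background": f1, "modality": f2,
                             "stimulus_group": "piano",
                             "mean_rating": mu + rng.normal(0, 4)})
        df = pd.DataFrame(rows)
        res = anova_mean_ratings(df, factors=("background", "modality"),
                                 tukey_factors=("background",))
        y = df["mean_rating"].to_numpy()
        # brute-force type-II SS on this balanced design
        grand = y.mean()
        ss_a = sum(
            len(g) * (g["mean_rating"].mean() - grand) ** 2
            for _, g in df.groupby("background")
        )
        cell_means = df.groupby(["background", "modality"])["mean_rating"].mean()
        ss_resid = sum(
            (row["mean_rating"] - cell_means[(row["background"],
                                              row["modality"])]) ** 2
            for _, row in df.iterrows()
        )
        df_resid = len(df) - 6
        f_a = (ss_a / 1) / (ss_resid / df_resid)
        got = res.anova_table.loc["C(background)", "F"]
        assert got == pytest.approx(f_a, rel=1e-6)

    def test_two_level_tukey_matches_t_test(self):
        from scipy import stats as sps

        rng = np.random.default_rng(11)
        df = pd.DataFrame({
            "background": ["a"] * 30 + ["b"] * 30,
            "modality": ["AO"] * 60,
            "stimulus_group": ["piano"] * 60,
            "mean_rating": np.r_[rng.normal(50, 5, 30), rng.normal(54, 5, 30)],
        })
        res = anova_mean_ratings(df, factors=("background",),
                                 tukey_factors=("background",))
        tukey_p = float(res.tukey["background"]["p-adj"].iloc[0])
        t_p = sps.ttest_ind(
            df[df.background == "a"]["mean_rating"],
            df[df.background == "b"]["mean_rating"],
        ).pvalue
        assert tukey_p == pytest.approx(t_p, abs=2e-3)

    def test_group_effect_detected(self):
        df = _means_table(seed=1, effects={"novice": 8.0})
        res = anova_mean_ratings(
            df, factors=("background", "modality", "stimulus_group")
        )
        assert res.anova_table.loc["C(background)", "PR(>F)"] < 0.001

    def test_empty_cells_reported(self):
        df = _means_table(seed=2)
        df = df[~((df.background == "novice") & (df.modality == "AO"))]
        with pytest.warns(UserWarning, match="empty"):
            res = anova_mean_ratings(df, factors=("background", "modality"))
        assert ("novice", "AO") in res.empty_cells


def _body_part_table(seed=0, head_scale=1.0, n_stimuli=4, n_steps=120):
    rng = np.random.default_rng(seed)
    parts = ["head", "chest", "l_shoulder", "r_shoulder", "l_arm", "r_arm"]
    rows = []
    for s in range(n_stimuli):
        stim_level = rng.normal(0, 1)
        for part in parts:
            mu = 10.0 * (head_scale if part == "head" else 1.0)
            noise = np.empty(n_steps)
            noise[0] = rng.normal(0, 1.5)
            for i in range(1, n_steps):
                noise[i] = 0.5 * noise[i - 1] + rng.normal(0, 1.5 * np.sqrt(0.75))
            rows.append(pd.DataFrame({
                "stimulus": f"s{s}", "body_part": part,
                "t": np.arange(n_steps) / 10.0,
                "value": mu + stim_level + noise,
            }))
    return pd.concat(rows, ignore_index=True)


class TestCompareBodyParts:
    def test_head_dominance_detected(self):
        table = _body_part_table(seed=6, head_scale=2.0)
        fit, contrasts = compare_body_parts(table)
        head = contrasts[(contrasts.part_a == "head")
                         | (contrasts.part_b == "head")]
        assert head["significant"].all()
        # head mean exceeds every other part's mean
        for _, row in head.iterrows():
            head_mean = row.mean_a if row.part_a == "head" else row.mean_b
            other = row.mean_b if row.part_a == "head" else row.mean_a
            assert head_mean > other

    def test_identical_parts_nominal_false_positive_rate(self):
        table = _body_part_table(seed=7, head_scale=1.0)
        _, contrasts = compare_body_parts(table)
        # Tukey controls the familywise rate: expect no (or at most one)
        # significant contrast among 15 under the null
        assert contrasts["significant"].sum() <= 1

    def test_two_parts_reduce_to_paired_comparison(self):
        table = _body_part_table(seed=8)
        table = table[table.body_part.isin(["head", "chest"])]
        fit, contrasts = compare_body_parts(table)
        assert len(contrasts) == 1
        # Tukey with k=2 equals the |t| test on the model coefficient
        term = fit.params.set_index("term")
        coef_p = term.loc["C(body_part)[T.head]", "p"]
        assert contrasts["p_tukey"].iloc[0] == pytest.approx(coef_p, rel=0.05)

    def test_single_part_rejected(self):
        table = _body_part_table(seed=9)
        with pytest.raises(ValueError, match="two body parts"):
            compare_body_parts(table[table.body_part == "head"])
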