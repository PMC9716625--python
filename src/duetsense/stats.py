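"""Mixed models with AR(1) residuals, lag cross-validation, model batteries.

The workhorse is a Gaussian linear mixed model

    y = X b + Z u + e,   u ~ N(0, tau^2 I),   e ~ N(0, sigma^2 R(rho))

with a random intercept per grouping unit (participants, or stimuli for the
body-part models) and first-order autoregressive residual correlation
``R(rho)`` within each within-stimulus time series.  Estimation is maximum
likelihood (REML available): each series is whitened by the exact AR(1)
square-root transform, after which the marginal covariance is
``sigma^2 (I + gamma Z Z')`` with ``gamma = tau^2 / sigma^2`` and the
likelihood, GLS coefficients and profile of ``sigma^2`` all have closed
forms via the Woodbury identity; the remaining 2-D problem over
``(atanh rho, log gamma)`` is solved numerically.

Out-of-sample prediction uses the fixed effects only (random intercepts of
unseen participants are set to their zero mean), which is how the k-fold
lag cross-validation scores held-out participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats as sps
from scipy.stats import studentized_range

__all__ = [
    "LmmFit",
    "CvResult",
    "AnovaResult",
    "fit_lmm_ar1",
    "compute_vif",
    "lag_crossvalidation",
    "run_togetherness_models",
    "run_sync_models",
    "anova_mean_ratings",
    "compare_body_parts",
    "MODEL_BATTERY",
    "PARTICIPANT_GROUPS",
    "ALPHA_BATTERY",
]

#: Bonferroni-corrected alpha for the model battery (four models per modality).
ALPHA_BATTERY = 0.0125

CWT_COLUMNS = [
    "cwt_head",
    "cwt_chest",
    "cwt_l_shoulder",
    "cwt_r_shoulder",
    "cwt_l_arm",
    "cwt_r_arm",
]

#: Modality-specific fixed-effect sets of the togetherness model battery:
#: model 1 = sound intensity (AO), 2 = motion (VO), 3 = motion + intensity (AV).
MODEL_BATTERY = {
    "1": ("AO", ["intensity"]),
    "2": ("VO", ["qom_total"] + CWT_COLUMNS),
    "3": ("AV", ["intensity", "qom_total"] + CWT_COLUMNS),
}

#: Participant subsets: a = semi-professionals, b = novices, c = pianists,
#: d = clarinetists.
PARTICIPANT_GROUPS = {
    "a": ("background", "semi-pro"),
    "b": ("background", "novice"),
    "c": ("instrument", "pianist"),
    "d": ("instrument", "clarinetist"),
}


@dataclass
class LmmFit:
    """A fitted Gaussian mixed model with AR(1) residual correlation."""

    params: pd.DataFrame  # term, beta, se, ci_low, ci_high, t, df, p
    rho: float
    var_group: float  # random-intercept variance tau^2
    var_resid: float  # marginal residual variance sigma^2
    loglik: float
    n_obs: int
    n_groups: int
    method: str  # "ML" | "REML"
    converged: bool
    singular: bool
    cov_params: np.ndarray = field(repr=False, default=None)
    design_info: object = field(repr=False, default=None)

    @property
    def beta(self) -> pd.Series:
        return self.params.set_index("term")["beta"]

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Fixed-effects (population-level) prediction on new data."""
        X = np.asarray(patsy.dmatrix(self.design_info, data))
        return X @ self.params["beta"].to_numpy()

    def summary(self) -> pd.DataFrame:
        out = self.params.copy()
        out["rho"] = self.rho
        out["var_group"] = self.var_group
        out["var_resid"] = self.var_resid
        return out


@dataclass
class CvResult:
    """Per-lag k-fold cross-validation errors and the selected lag."""

    table: pd.DataFrame  # lag, mae, rmse (fold averages)
    fold_errors: pd.DataFrame  # lag, fold, mae, rmse
    selected_lag: float
    k: int

    def __post_init__(self) -> None:
        bad = self.fold_errors[
            self.fold_errors["mae"] > self.fold_errors["rmse"] + 1e-9
        ]
        if len(bad):
            raise AssertionError("MAE exceeded RMSE in a fold (impossible)")


@dataclass
class AnovaResult:
    """Factorial ANOVA terms plus Tukey HSD pairwise contrasts."""

    anova_table: pd.DataFrame
    tukey: dict[str, pd.DataFrame]
    empty_cells: list[tuple]


# ---------------------------------------------------------------------------
# Core AR(1) mixed model
# ---------------------------------------------------------------------------


def _series_starts(sid: np.ndarray) -> np.ndarray:
    """Start indices of each contiguous series block (sid must be sorted)."""
    return np.flatnonzero(np.r_[True, sid[1:] != sid[:-1]])


def _whiten(x: np.ndarray, rho: float, starts: np.ndarray) -> np.ndarray:
    """Exact AR(1) whitening per series: S R(rho) S' = I."""
    if rho == 0.0:
        return np.asarray(x, dtype=float).copy()
    x = np.asarray(x, dtype=float)
    c = 1.0 / np.sqrt(1.0 - rho * rho)
    z = np.empty_like(x)
    z[1:] = (x[1:] - rho * x[:-1]) * c
    z[starts] = x[starts]
    return z


class _Ar1MixedProblem:
    """Profiled likelihood of the AR(1) random-intercept model."""

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        gid: np.ndarray,
        starts: np.ndarray,
        reml: bool,
    ):
        self.y, self.X = y, X
        self.gid = gid
        self.n_groups = int(gid.max()) + 1 if len(gid) else 0
        self.starts = starts
        self.n, self.k = X.shape
        self.reml = reml
        self.n_series = len(starts)

    def _profile(self, rho: float, gamma: float):
        yt = _whiten(self.y, rho, self.starts)
        Xt = _whiten(self.X, rho, self.starts)
        zt = _whiten(np.ones(self.n), rho, self.starts)
        d = np.bincount(self.gid, weights=zt * zt, minlength=self.n_groups)
        u = np.bincount(self.gid, weights=zt * yt, minlength=self.n_groups)
        G = np.empty((self.n_groups, self.k))
        for j in range(self.k):
            G[:, j] = np.bincount(
                self.gid, weights=zt * Xt[:, j], minlength=self.n_groups
            )
        w = gamma / (1.0 + gamma * d)
        A = Xt.T @ Xt - G.T @ (w[:, None] * G)
        b = Xt.T @ yt - G.T @ (w * u)
        beta = np.linalg.solve(A, b)
        yMy = yt @ yt - w @ (u * u)
        qf = max(yMy - beta @ b, 1e-300)
        dof = self.n - self.k if self.reml else self.n
        sigma2 = qf / dof
        logdet_R = (self.n - self.n_series) * np.log1p(-rho * rho)
        logdet_W = float(np.sum(np.log1p(gamma * d)))
        m2ll = dof * np.log(2.0 * np.pi * sigma2) + dof + logdet_R + logdet_W
        if self.reml:
            sign, logdet_A = np.linalg.slogdet(A)
            if sign <= 0:
                m2ll = np.inf
            else:
                m2ll += logdet_A - self.k * np.log(sigma2)
        return m2ll, beta, sigma2, A

    def neg2ll(self, theta: np.ndarray, est_rho: bool, est_gamma: bool) -> float:
        i = 0
        rho = np.tanh(theta[i]) if est_rho else self.rho_fixed
        i += est_rho
        gamma = float(np.exp(np.clip(theta[i], -30, 30))) if est_gamma else 0.0
        try:
            m2ll = self._profile(rho, gamma)[0]
        except np.linalg.LinAlgError:
            return np.inf
        return m2ll if np.isfinite(m2ll) else np.inf


def fit_lmm_ar1(
    table: pd.DataFrame,
    response: str,
    fixed: list[str] | str,
    group: str | None = "participant",
    series: list[str] | None = None,
    time: str = "t",
    rho: float | None = None,
    reml: bool = False,
    ci_level: float = 0.95,
) -> LmmFit:
    """Fit the AR(1) random-intercept Gaussian mixed model by (RE)ML.

    Parameters
    ----------
    fixed
        List of predictor column names, or a patsy right-hand-side formula
        (an intercept is always included).
    group
        Column giving the random-intercept unit (``None`` drops the random
        effect entirely).
    series
        Columns whose combination identifies one within-stimulus time series;
        AR(1) correlation applies between consecutive rows of a series
        ordered by ``time``.  ``None`` treats all rows as independent
        (equivalent to ``rho=0``).
    rho
        Fix the AR(1) coefficient instead of estimating it.

    Raises ``ValueError`` on a rank-deficient (singular) design; boundary or
    non-converged variance estimates are flagged on the returned fit rather
    than silently dropped.
    """
    formula = fixed if isinstance(fixed, str) else " + ".join(fixed) or "1"
    df = table.reset_index(drop=True)
    # stable ordering: series blocks contiguous, time ascending within
    if series:
        key = df[series].astype(str).agg("\x1f".join, axis=1)
        order = np.lexsort((df[time].to_numpy(), key.to_numpy()))
        df = df.iloc[order].reset_index(drop=True)
        sid = pd.factorize(key.iloc[order])[0]
    else:
        sid = np.arange(len(df))
    X = patsy.dmatrix(formula, df, return_type="dataframe")
    design_info = X.design_info
    names = list(X.columns)
    Xm = X.to_numpy(float)
    y = df[response].to_numpy(float)
    if not np.all(np.isfinite(Xm)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in response or predictors")
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError(
            "singular design: collinear or constant fixed effects "
            f"in {names}"
        )
    if group is not None:
        gid = pd.factorize(df[group])[0]
    else:
        gid = np.zeros(len(df), dtype=int)
    starts = _series_starts(sid)

    prob = _Ar1MixedProblem(y, Xm, gid, starts, reml)
    est_rho = rho is None and series is not None
    prob.rho_fixed = 0.0 if rho is None else float(rho)
    est_gamma = group is not None
    converged = True
    if est_rho or est_gamma:
        theta0 = []
        if est_rho:
            theta0.append(np.arctanh(0.3))
        if est_gamma:
            theta0.append(np.log(0.1))
        res = optimize.minimize(
            prob.neg2ll,
            np.array(theta0),
            args=(est_rho, est_gamma),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 500},
        )
        converged = bool(res.success)
        i = 0
        rho_hat = float(np.tanh(res.x[i])) if est_rho else prob.rho_fixed
        i += est_rho
        gamma_hat = float(np.exp(np.clip(res.x[i], -30, 30))) if est_gamma else 0.0
    else:
        rho_hat, gamma_hat = prob.rho_fixed, 0.0
    m2ll, beta, sigma2, A = prob._profile(rho_hat, gamma_hat)
    cov = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    dof = len(y) - Xm.shape[1]
    tcrit = sps.t.ppf(0.5 + ci_level / 2.0, dof)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * sps.t.sf(np.abs(tvals), dof)
    params = pd.DataFrame(
        {
            "term": names,
            "beta": beta,
            "se": se,
            "ci_low": beta - tcrit * se,
            "ci_high": beta + tcrit * se,
            "t": tvals,
            "df": dof,
            "p": pvals,
        }
    )
    singular = bool(np.any(~np.isfinite(se)) or np.any(se == 0))
    if not converged:
        warnings.warn(
            "variance optimisation did not converge; estimates are the best "
            "point reached",
            stacklevel=2,
        )
    return LmmFit(
        params=params,
        rho=rho_hat,
        var_group=gamma_hat * sigma2,
        var_resid=sigma2,
        loglik=-0.5 * m2ll,
        n_obs=len(y),
        n_groups=prob.n_groups if group is not None else 0,
        method="REML" if reml else "ML",
        converged=converged,
        singular=singular,
        cov_params=cov,
        design_info=design_info,
    )


# ---------------------------------------------------------------------------
# Collinearity
# ---------------------------------------------------------------------------


def compute_vif(table: pd.DataFrame, predictors: list[str]) -> pd.Series:
    """Variance inflation factor per predictor: ``1 / (1 - R^2_j)`` from
    regressing predictor j on the remaining predictors (with intercept).

    Perfect collinearity yields ``inf``.
    """
    if len(predictors) < 2:
        raise ValueError("VIF needs at least two predictors")
    X = table[predictors].to_numpy(float)
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant predictor")
    out = {}
    n = X.shape[0]
    for j, name in enumerate(predictors):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = resid @ resid
        ss_tot = ((yj - yj.mean()) ** 2).sum()
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# Lag selection by participant-folded k-fold CV
# ---------------------------------------------------------------------------


def participant_folds(
    participants: list, k: int, seed: int | np.random.Generator = 0
) -> list[list]:
    """Seeded partition of participants into k folds differing in size by <= 1."""
    if len(participants) < k:
        raise ValueError(f"need at least {k} participants for {k} folds")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    order = list(np.array(sorted(participants), dtype=object)[
        rng.permutation(len(participants))
    ])
    return [list(fold) for fold in np.array_split(order, k)]


def lag_crossvalidation(
    tables: dict[float, pd.DataFrame],
    fixed: list[str] | str,
    response: str = "response",
    participant: str = "participant",
    series: list[str] | None = None,
    k: int = 10,
    seed: int | np.random.Generator = 0,
    rho: float | None = None,
) -> CvResult:
    """Select the perceptual lag by participant-folded k-fold cross-validation.

    ``tables`` maps each candidate lag (s) to its aligned model table.  For
    each lag, the model is fitted on k-1 participant folds and scores the
    held-out participants' responses from the fixed effects alone; fold-wise
    MAE and RMSE are averaged and the lag with the lowest MAE wins (RMSE then
    shorter lag break ties).
    """
    if series is None:
        series = [participant, "stimulus", "modality"]
    all_participants = sorted(
        set().union(*(set(t[participant].unique()) for t in tables.values()))
    )
    folds = participant_folds(all_participants, k, seed)
    rows = []
    for lag in sorted(tables):
        table = tables[lag]
        for fold_idx, fold in enumerate(folds):
            test_mask = table[participant].isin(fold)
            train, test = table[~test_mask], table[test_mask]
            if len(test) == 0 or len(train) == 0:
                raise ValueError(f"fold {fold_idx} has no rows for lag {lag}")
            fit = fit_lmm_ar1(
                train, response, fixed, group=participant, series=series, rho=rho
            )
            pred = fit.predict(test)
            err = test[response].to_numpy(float) - pred
            rows.append(
                {
                    "lag": lag,
                    "fold": fold_idx,
                    "mae": float(np.mean(np.abs(err))),
                    "rmse": float(np.sqrt(np.mean(err**2))),
                }
            )
    fold_errors = pd.DataFrame(rows)
    table = (
        fold_errors.groupby("lag", as_index=False)[["mae", "rmse"]].mean()
    )
    best = table.sort_values(["mae", "rmse", "lag"]).iloc[0]
    return CvResult(
        table=table, fold_errors=fold_errors, selected_lag=float(best["lag"]), k=k
    )


# ---------------------------------------------------------------------------
# Model batteries
# ---------------------------------------------------------------------------


def _group_subset(table: pd.DataFrame, group_code: str) -> pd.DataFrame:
    col, value = PARTICIPANT_GROUPS[group_code]
    return table[table[col] == value]


def run_togetherness_models(
    table: pd.DataFrame,
    alpha: float = ALPHA_BATTERY,
    models: tuple[str, ...] = ("1", "2", "3"),
    groups: tuple[str, ...] = ("a", "b", "c", "d"),
    series: list[str] | None = None,
) -> tuple[dict[str, LmmFit], pd.DataFrame]:
    """Fit the modality x expertise togetherness battery (models 1a-3d).

    ``table`` is a lag-aligned model table with log-transformed predictor
    columns.  Each model is fitted on its modality x participant-group subset
    with a participant random intercept and AR(1) errors within each
    within-stimulus rating series.  Effects are flagged significant at the
    Bonferroni-corrected ``alpha`` (0.0125 for four models per modality).
    """
    fits: dict[str, LmmFit] = {}
    rows = []
    for model_n in models:
        modality, predictors = MODEL_BATTERY[model_n]
        for group_code in groups:
            label = f"{model_n}{group_code}"
            subset = _group_subset(table[table["modality"] == modality], group_code)
            if len(subset) == 0:
                raise ValueError(f"empty subset for model {label}")
            fit = fit_lmm_ar1(
                subset,
                "response",
                predictors,
                group="participant",
                series=series or ["participant", "stimulus", "modality"],
            )
            fits[label] = fit
            for rec in fit.params.to_dict("records"):
                if rec["term"] == "Intercept":
                    continue
                rows.append(
                    {
                        "model": label,
                        "modality": modality,
                        "group": PARTICIPANT_GROUPS[group_code][1],
                        "term": rec["term"],
                        "beta": rec["beta"],
                        "se": rec["se"],
                        "ci_low": rec["ci_low"],
                        "ci_high": rec["ci_high"],
                        "t": rec["t"],
                        "df": rec["df"],
                        "p": rec["p"],
                        "significant": bool(rec["p"] < alpha),
                    }
                )
    return fits, pd.DataFrame(rows)


def run_sync_models(
    sync_table: pd.DataFrame,
    predictor: str = "abs_asynchrony",
    alpha: float = ALPHA_BATTERY,
    groups: tuple[str, ...] = ("a", "b", "c", "d"),
) -> tuple[dict[str, LmmFit], pd.DataFrame]:
    """Fit the synchronization models (4a-d on AO, 5a-d on AV).

    Response: togetherness rating read at each sync point's reference time
    plus the selected lag.  Predictor: the asynchrony magnitude in ms (signed
    asynchrony available by passing ``predictor="asynchrony"``).  Participant
    random intercept; sync points are treated as exchangeable (no AR term).
    An inestimable slope (e.g. all asynchronies identical) is flagged rather
    than raising.
    """
    fits: dict[str, LmmFit] = {}
    rows = []
    for model_n, modality in (("4", "AO"), ("5", "AV")):
        for group_code in groups:
            label = f"{model_n}{group_code}"
            subset = _group_subset(
                sync_table[sync_table["modality"] == modality], group_code
            )
            if subset["sync_index"].nunique() < 2:
                raise ValueError(f"model {label}: fewer than 2 sync points")
            try:
                fit = fit_lmm_ar1(
                    subset, "response", [predictor], group="participant", series=None
                )
            except ValueError as exc:
                rows.append(
                    {
                        "model": label,
                        "modality": modality,
                        "group": PARTICIPANT_GROUPS[group_code][1],
                        "term": predictor,
                        "beta": np.nan,
                        "p": np.nan,
                        "significant": False,
                        "note": f"inestimable: {exc}",
                    }
                )
                continue
            fits[label] = fit
            rec = fit.params.set_index("term").loc[predictor]
            rows.append(
                {
                    "model": label,
                    "modality": modality,
                    "group": PARTICIPANT_GROUPS[group_code][1],
                    "term": predictor,
                    "beta": rec["beta"],
                    "se": rec["se"],
                    "ci_low": rec["ci_low"],
                    "ci_high": rec["ci_high"],
                    "t": rec["t"],
                    "df": rec["df"],
                    "p": rec["p"],
                    "significant": bool(rec["p"] < alpha),
                    "note": "",
                }
            )
    return fits, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA on per-trial mean ratings
# ---------------------------------------------------------------------------


def anova_mean_ratings(
    means: pd.DataFrame,
    factors: tuple[str, ...],
    response: str = "mean_rating",
    tukey_factors: tuple[str, ...] | None = None,
) -> AnovaResult:
    """Factorial fixed-effects ANOVA (type-II SS) on per-trial mean ratings.

    ``means`` holds one mean rating per participant x stimulus x modality.
    ``tukey_factors`` selects the factor (or factor combination, whose cells
    are crossed into one label) receiving Tukey HSD pairwise contrasts.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    counts = means.groupby(list(factors), observed=True).size()
    full = np.prod([means[f].nunique() for f in factors])
    empty = []
    if len(counts) < full:
        seen = set(counts.index)
        levels = [means[f].unique() for f in factors]
        from itertools import product

        empty = [cell for cell in product(*levels) if cell not in seen]
        warnings.warn(f"{len(empty)} empty design cells", stacklevel=2)
    formula = f"{response} ~ " + " * ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=means).fit()
    anova_table = sm.stats.anova_lm(fit, typ=2)
    tukey_out: dict[str, pd.DataFrame] = {}
    for tf in tukey_factors or factors:
        cols = (tf,) if isinstance(tf, str) else tuple(tf)
        label = ":".join(cols)
        cells = means[list(cols)].astype(str).agg("/".join, axis=1)
        res = pairwise_tukeyhsd(means[response].to_numpy(float), cells.to_numpy())
        frame = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
        tukey_out[label] = frame
    return AnovaResult(anova_table=anova_table, tukey=tukey_out, empty_cells=empty)


# ---------------------------------------------------------------------------
# Body-part comparison
# ---------------------------------------------------------------------------


def compare_body_parts(
    long_table: pd.DataFrame,
    response: str = "value",
    part_col: str = "body_part",
    stimulus_col: str = "stimulus",
    time_col: str = "t",
) -> tuple[LmmFit, pd.DataFrame]:
    """Model a per-body-part feature series (local QoM or CWT power) as a
    function of body part, with a stimulus random intercept and AR(1) errors
    within each stimulus x body-part time series; Tukey-adjusted pairwise
    contrasts between body parts follow from the fitted covariance.
    """
    parts = sorted(long_table[part_col].unique())
    if len(parts) < 2:
        raise ValueError("need at least two body parts")
    fit = fit_lmm_ar1(
        long_table,
        response,
        f"C({part_col})",
        group=stimulus_col,
        series=[stimulus_col, part_col],
        time=time_col,
    )
    # cell means: treatment coding relative to the first (alphabetical) part
    names = list(fit.params["term"])
    beta = fit.params["beta"].to_numpy()
    k = len(parts)
    L = np.zeros((k, len(names)))
    L[:, 0] = 1.0
    for i, part in enumerate(parts):
        term = f"C({part_col})[T.{part}]"
        if term in names:
            L[i, names.index(term)] = 1.0
    means = L @ beta
    cov = L @ fit.cov_params @ L.T
    dof = fit.params["df"].iloc[0]
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j])
            q = abs(diff) / (se / np.sqrt(2.0))
            p = float(studentized_range.sf(q, k, dof))
            rows.append(
                {
                    "part_a": parts[i],
                    "part_b": parts[j],
                    "mean_a": means[i],
                    "mean_b": means[j],
                    "diff": diff,
                    "se": se,
                    "p_tukey": p,
                    "significant": p < 0.05,
                }
            )
    return fit, pd.DataFrame(rows)
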