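"""Spatiotemporal Gaussian process regression (ST-GPR).

Three stages estimate a surface per (location, year, age group, sex):

1. an ensemble of mixed-effects linear regressions on candidate covariates,
   with nested random intercepts at the super-region / region / location
   levels; candidate models whose coefficients are not significant (Wald
   P < 0.05) or not in the a-priori expected direction are dropped, the
   survivors are ranked by out-of-sample RMSE and blended;
2. a deterministic spatiotemporal smoother that borrows observed residuals
   from the same country, region and super region (space weight 1, zeta,
   zeta^2), proximate years (tricube-style window with exponent lambda) and
   neighboring age groups (omega^-rank) to correct the stage-1 prior;
3. a per-location-series Gaussian process (Matern-5/2 kernel in year) whose
   mean is the stage-2 surface and whose observation noise is the data
   variance, sampled to produce posterior draws.

Prevalence indicators are modeled in logit space; the mean z-score in
identity space.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special

import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .synthetic import LocationHierarchy, SurveySource

logger = logging.getLogger(__name__)

__all__ = [
    "CELL_KEYS",
    "StgprHyperparams",
    "Stage1Prior",
    "StgprFit",
    "prepare_observations",
    "fit_stage1",
    "smooth_spatiotemporal",
    "gpr_stage",
    "select_hyperparams",
    "run_stgpr",
    "transform_forward",
    "transform_back",
]

CELL_KEYS = ["location", "year", "age_group", "sex"]

_LOGIT_EPS = 1e-6


def transform_forward(x, transform: str):
    """Map natural-space values into modeling space (logit or identity)."""
    x = np.asarray(x, dtype=float)
    if transform == "identity":
        return x
    if transform == "logit":
        return special.logit(np.clip(x, _LOGIT_EPS, 1.0 - _LOGIT_EPS))
    raise ValueError(f"unknown transform {transform!r}")


def transform_back(x, transform: str):
    x = np.asarray(x, dtype=float)
    if transform == "identity":
        return x
    if transform == "logit":
        return special.expit(x)
    raise ValueError(f"unknown transform {transform!r}")


def _transform_variance(var, value, transform: str):
    """Delta-method variance in modeling space."""
    if transform == "identity":
        return np.asarray(var, dtype=float)
    p = np.clip(np.asarray(value, dtype=float), _LOGIT_EPS, 1.0 - _LOGIT_EPS)
    return np.asarray(var, dtype=float) / (p * (1.0 - p)) ** 2


def prepare_observations(sources, indicator: str) -> pd.DataFrame:
    """Collapse survey sources into per-cell observations with variances.

    indicator: ``mean`` (mean z-score; microdata only), ``prev2`` or
    ``prev3`` (prevalence below -2/-3 SD; microdata and tabulated).
    Variances are sampling variances in natural space: s^2/n for means,
    p(1-p)/n (floored) for proportions.
    """
    if indicator not in ("mean", "prev2", "prev3"):
        raise ValueError(f"unknown indicator {indicator!r}")
    rows = []
    for src in sources:
        if src.kind == "microdata":
            g = src.records.groupby(["age_group", "sex"])["z"]
            for (a, s), z in g:
                z = z.to_numpy()
                n = len(z)
                if n < 2:
                    continue
                if indicator == "mean":
                    val = float(np.mean(z))
                    var = float(np.var(z, ddof=1)) / n
                else:
                    t = -2.0 if indicator == "prev2" else -3.0
                    val = float(np.mean(z < t))
                    pv = min(max(val, 1.0 / (n + 1)), 1 - 1.0 / (n + 1))
                    var = pv * (1 - pv) / n
                rows.append((src.location_id, src.year, a, s, val, max(var, 1e-12), n))
        elif src.kind == "tabulated" and indicator != "mean":
            col = indicator
            for r in src.table.itertuples():
                if r.age_group == "under5" or r.sex == "both":
                    continue  # aggregates must be split upstream
                val = float(getattr(r, col))
                n = int(r.n)
                pv = min(max(val, 1.0 / (n + 1)), 1 - 1.0 / (n + 1))
                rows.append(
                    (src.location_id, src.year, r.age_group, r.sex, val,
                     max(pv * (1 - pv) / n, 1e-12), n)
                )
    return pd.DataFrame(
        rows, columns=CELL_KEYS + ["value", "variance", "sample_size"]
    )


# ---------------------------------------------------------------------------
# stage 1: covariate-ensemble mixed-effects prior
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StgprHyperparams:
    """Smoothing hyperparameters: zeta (space), lam (time), omega (age)."""

    zeta: float
    lam: float
    omega: float

    def __post_init__(self):
        if not (0 < self.zeta <= 1):
            raise ValueError("zeta must be in (0, 1]")
        if self.lam <= 0 or self.omega <= 0:
            raise ValueError("lam and omega must be positive")


@dataclass
class CandidateModel:
    covariates: tuple[str, ...]
    params: pd.Series | None = None
    pvalues: pd.Series | None = None
    oos_rmse: float = np.inf
    retained: bool = False
    reason: str = ""


@dataclass
class Stage1Prior:
    """Weighted covariate-model ensemble prior, in modeling space."""

    models: list[CandidateModel]
    weights: np.ndarray  # over retained models
    prediction: pd.Series  # modeling-space prior on the full grid
    transform: str
    fallback: bool = False

    @property
    def retained(self):
        return [m for m in self.models if m.retained]


def _attach_hierarchy(df: pd.DataFrame, hierarchy: LocationHierarchy) -> pd.DataFrame:
    return df.merge(hierarchy.frame(), on="location", how="left")


def _fit_mixed(df, covs):
    """Nested random-intercept model; returns (params, pvalues, predict_fn)."""
    import warnings

    rhs = " + ".join(covs) if covs else "1"
    formula = f"value_t ~ {rhs}"
    vc = {"region": "0 + C(region)", "location": "0 + C(location)"}
    try:
        model = smf.mixedlm(
            formula, df, groups="super_region", re_formula="1", vc_formula=vc
        )
        with warnings.catch_warnings():
            # boundary-variance warnings are routine on small synthetic worlds
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            fit = model.fit(reml=True, method="lbfgs", maxiter=200)
    except Exception as exc:  # singular fits on tiny toy data
        logger.debug("mixedlm failed (%s); falling back to OLS", exc)
        fit = smf.ols(formula, df).fit()
        params = fit.params
        pvals = fit.pvalues

        def predict_ols(newdata):
            return fit.predict(newdata)

        return params, pvals, predict_ols

    params = fit.params
    pvals = fit.pvalues

    # random-effect lookups: per super region intercept plus vc offsets
    re_super, re_region, re_loc = {}, {}, {}
    for grp, eff in fit.random_effects.items():
        for name, val in eff.items():
            if name in ("Group", "groups", "Intercept", "Group Var"):
                re_super[grp] = re_super.get(grp, 0.0) + float(val)
            elif name.startswith("region["):
                key = name.split("[")[-1].rstrip("]")
                key = key.split("[")[-1].rstrip("]")
                re_region[key] = float(val)
            elif name.startswith("location["):
                key = name.split("[")[-1].rstrip("]")
                key = key.split("[")[-1].rstrip("]")
                re_loc[key] = float(val)

    fe_names = [p for p in params.index if p in covs or p == "Intercept"]

    def predict(newdata: pd.DataFrame) -> pd.Series:
        pred = np.full(len(newdata), float(params.get("Intercept", 0.0)))
        for c in covs:
            if c in params.index:
                pred = pred + params[c] * newdata[c].to_numpy(dtype=float)
        pred = pred + newdata["super_region"].map(re_super).fillna(0.0).to_numpy()
        pred = pred + newdata["region"].map(re_region).fillna(0.0).to_numpy()
        pred = pred + newdata["location"].map(re_loc).fillna(0.0).to_numpy()
        return pd.Series(pred, index=newdata.index)

    _ = fe_names
    return params, pvals, predict


def fit_stage1(
    data: pd.DataFrame,
    covariates: pd.DataFrame,
    hierarchy: LocationHierarchy,
    expected_signs: dict,
    holdout_cfg: dict | None = None,
    seed: int = 0,
    transform: str = "identity",
    max_subset_size: int = 3,
) -> Stage1Prior:
    """Covariate-ensemble mixed-effects prior.

    Enumerates covariate subsets (size <= ``max_subset_size``) of the keys of
    ``expected_signs``, fits each as a nested random-intercept regression in
    modeling space, drops models with wrong-signed or insignificant
    coefficients, ranks survivors by holdout RMSE and blends them with
    weights proportional to exp(-RMSE / min RMSE).  Falls back to the
    intercept-plus-random-effects model when every candidate is dropped.
    """
    holdout_cfg = holdout_cfg or {"prop": 0.2}
    rng = np.random.default_rng(seed)

    obs = data.copy()
    obs["value_t"] = transform_forward(obs["value"].to_numpy(), transform)
    obs = _attach_hierarchy(obs, hierarchy)
    obs = obs.merge(covariates, on=CELL_KEYS, how="left")

    grid = _attach_hierarchy(covariates.copy(), hierarchy)

    cov_names = list(expected_signs)
    subsets = [
        combo
        for r in range(1, min(max_subset_size, len(cov_names)) + 1)
        for combo in itertools.combinations(cov_names, r)
    ]

    n = len(obs)
    holdout_mask = rng.random(n) < holdout_cfg.get("prop", 0.2)
    if holdout_mask.all() or not holdout_mask.any():
        holdout_mask = np.zeros(n, dtype=bool)
        holdout_mask[: max(1, n // 5)] = True
    train, test = obs[~holdout_mask], obs[holdout_mask]

    models: list[CandidateModel] = []
    for covs in subsets:
        cand = CandidateModel(covariates=covs)
        try:
            params, pvals, _ = _fit_mixed(obs, list(covs))
        except Exception as exc:
            cand.reason = f"fit failed: {exc}"
            models.append(cand)
            continue
        cand.params, cand.pvalues = params, pvals
        bad = []
        for c in covs:
            coef = float(params.get(c, 0.0))
            pv = float(pvals.get(c, 1.0))
            if np.sign(coef) != np.sign(expected_signs[c]):
                bad.append(f"{c}: wrong sign")
            elif not np.isfinite(pv) or pv >= 0.05:
                bad.append(f"{c}: p={pv:.3g}")
        if bad:
            cand.reason = "; ".join(bad)
            models.append(cand)
            continue
        try:
            _, _, predict_tr = _fit_mixed(train, list(covs))
            resid = test["value_t"].to_numpy() - predict_tr(test).to_numpy()
            cand.oos_rmse = float(np.sqrt(np.mean(resid**2)))
        except Exception as exc:
            cand.reason = f"holdout failed: {exc}"
            models.append(cand)
            continue
        cand.retained = True
        models.append(cand)

    retained = [m for m in models if m.retained]
    fallback = not retained
    if fallback:
        logger.warning("stage 1: all candidate models dropped; "
                       "falling back to intercept + random effects")
        _, _, predict = _fit_mixed(obs, [])
        prediction = pd.Series(
            predict(grid).to_numpy(),
            index=pd.MultiIndex.from_frame(grid[CELL_KEYS]),
        )
        return Stage1Prior(models, np.array([]), prediction, transform, True)

    rmses = np.array([m.oos_rmse for m in retained])
    scale = max(rmses.min(), 1e-12)
    w = np.exp(-rmses / scale)
    w = w / w.sum()

    preds = []
    for m in retained:
        _, _, predict = _fit_mixed(obs, list(m.covariates))
        preds.append(predict(grid).to_numpy())
    blend = np.einsum("m,mc->c", w, np.array(preds))
    prediction = pd.Series(blend, index=pd.MultiIndex.from_frame(grid[CELL_KEYS]))
    return Stage1Prior(models, w, prediction, transform)


# ---------------------------------------------------------------------------
# stage 2: spatiotemporal residual smoothing
# ---------------------------------------------------------------------------


def _space_weights(grid_df, obs_df, hierarchy, zeta):
    hf = hierarchy.frame().set_index("location")
    g_reg = hf["region"].reindex(grid_df["location"]).to_numpy()
    g_sup = hf["super_region"].reindex(grid_df["location"]).to_numpy()
    o_reg = hf["region"].reindex(obs_df["location"]).to_numpy()
    o_sup = hf["super_region"].reindex(obs_df["location"]).to_numpy()
    same_loc = grid_df["location"].to_numpy()[:, None] == obs_df["location"].to_numpy()[None, :]
    same_reg = g_reg[:, None] == o_reg[None, :]
    same_sup = g_sup[:, None] == o_sup[None, :]
    w = np.where(same_loc, 1.0, np.where(same_reg, zeta, np.where(same_sup, zeta**2, 0.0)))
    return w


def smooth_spatiotemporal(
    residuals: pd.DataFrame,
    prior: pd.Series,
    hierarchy: LocationHierarchy,
    hp: StgprHyperparams,
    age_order=None,
) -> pd.Series:
    """Stage-2 surface: prior plus weighted average of observed residuals.

    Weight between a target cell and an observed residual is the product of
    a space weight (1 same country, zeta same region, zeta^2 same super
    region, 0 otherwise), a tricube-style time weight
    ``(1 - (|dt| / (1 + max dt))**lam)**3`` and an age-rank weight
    ``omega**(-|da|)``; residuals from the opposite sex carry zero weight.
    Cells with no in-scope residuals fall back to the prior.

    ``residuals`` has the cell keys plus a ``residual`` column (modeling
    space); ``prior`` is indexed by cell.
    """
    grid_df = prior.index.to_frame(index=False)
    if residuals.empty:
        return prior.copy()
    obs = residuals.groupby(CELL_KEYS, as_index=False)["residual"].mean()

    if age_order is None:
        age_order = list(dict.fromkeys(grid_df["age_group"]))
    age_rank = {a: i for i, a in enumerate(age_order)}

    w = _space_weights(grid_df, obs, hierarchy, hp.zeta)

    dt = np.abs(
        grid_df["year"].to_numpy(dtype=float)[:, None]
        - obs["year"].to_numpy(dtype=float)[None, :]
    )
    max_dt = dt.max() if dt.size else 0.0
    w_time = (1.0 - (dt / (1.0 + max_dt)) ** hp.lam) ** 3
    da = np.abs(
        np.array([age_rank[a] for a in grid_df["age_group"]])[:, None]
        - np.array([age_rank[a] for a in obs["age_group"]])[None, :]
    )
    w_age = hp.omega ** (-da.astype(float))
    same_sex = (
        grid_df["sex"].to_numpy()[:, None] == obs["sex"].to_numpy()[None, :]
    )
    w = w * w_time * w_age * same_sex

    denom = w.sum(axis=1)
    num = w @ obs["residual"].to_numpy()
    corr = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
    return pd.Series(prior.to_numpy() + corr, index=prior.index)


# ---------------------------------------------------------------------------
# stage 3: Gaussian process over time, per location series
# ---------------------------------------------------------------------------


def _matern52(t1, t2, length_scale):
    r = np.abs(t1[:, None] - t2[None, :]) / length_scale
    s5 = np.sqrt(5.0) * r
    return (1.0 + s5 + 5.0 * r**2 / 3.0) * np.exp(-s5)


@dataclass
class StgprFit:
    """Full three-stage fit with posterior draws (natural space)."""

    stage1: Stage1Prior | None
    stage2: pd.Series  # modeling space
    draws: pd.DataFrame  # index: cells, columns draw_0..draw_{n-1}
    hyperparams: StgprHyperparams | None
    transform: str
    posterior_mean: pd.Series | None = None  # modeling space

    def summary(self) -> pd.DataFrame:
        d = self.draws.to_numpy()
        return pd.DataFrame(
            {
                "mean": d.mean(axis=1),
                "lower": np.percentile(d, 2.5, axis=1),
                "upper": np.percentile(d, 97.5, axis=1),
            },
            index=self.draws.index,
        )


def _gp_series(years, mean_fn_vals, obs_years, obs_vals, obs_vars,
               amplitude, length_scale, n_draws, rng):
    """Posterior draws of one time series.

    Returns ``(draws, post_mean)`` with shapes (n_years, n_draws) and
    (n_years,)."""
    K_gg = amplitude**2 * _matern52(years, years, length_scale)
    if len(obs_years) == 0:
        post_mean = mean_fn_vals.copy()
        post_cov = K_gg
    else:
        K_oo = amplitude**2 * _matern52(obs_years, obs_years, length_scale)
        K_go = amplitude**2 * _matern52(years, obs_years, length_scale)
        resid = obs_vals - np.interp(obs_years, years, mean_fn_vals)
        for jitter in (0.0, 1e-10, 1e-8, 1e-6):
            try:
                A = K_oo + np.diag(obs_vars + jitter)
                cf = linalg.cho_factor(A, lower=True)
                break
            except linalg.LinAlgError:
                continue
        else:
            raise linalg.LinAlgError("GP covariance not positive definite")
        alpha = linalg.cho_solve(cf, resid)
        post_mean = mean_fn_vals + K_go @ alpha
        post_cov = K_gg - K_go @ linalg.cho_solve(cf, K_go.T)
    for jitter in (1e-12, 1e-10, 1e-8, 1e-6):
        try:
            L = np.linalg.cholesky(post_cov + jitter * np.eye(len(years)))
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise np.linalg.LinAlgError("posterior covariance not positive definite")
    eps = rng.standard_normal((len(years), n_draws))
    return post_mean[:, None] + L @ eps, post_mean


def gpr_stage(
    stage2: pd.Series,
    data: pd.DataFrame,
    kernel_cfg: dict | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    transform: str = "identity",
    stage1: Stage1Prior | None = None,
    hyperparams: StgprHyperparams | None = None,
) -> StgprFit:
    """Gaussian-process smoothing and draw generation.

    Each (location, age group, sex) time series gets an independent GP whose
    mean function is the stage-2 surface, with a Matern-5/2 kernel in year.
    The kernel amplitude defaults to 1.4826 x the median absolute deviation
    of the data-minus-stage2 residuals (a robust residual scale), and the
    observation noise is the (modeling-space) data variance, so the final
    uncertainty reflects both the data noise and the disagreement between
    the data and the first two stages.
    """
    kernel_cfg = kernel_cfg or {}
    rng = np.random.default_rng(seed)

    obs = data.copy()
    if (obs["variance"] <= 0).any():
        raise ValueError("data variances must be positive")
    obs["value_t"] = transform_forward(obs["value"].to_numpy(), transform)
    obs["var_t"] = _transform_variance(
        obs["variance"].to_numpy(), obs["value"].to_numpy(), transform
    )

    s2_frame = stage2.rename("stage2").reset_index()
    s2_frame.columns = CELL_KEYS + ["stage2"]
    merged = obs.merge(s2_frame, on=CELL_KEYS, how="inner")
    # The MAD is taken over residuals the stage-2 smoother has already
    # shrunk toward the data, so it understates the surface uncertainty at
    # unobserved cells; the inflation factor compensates.
    inflation = float(kernel_cfg.get("amplitude_inflation", 1.5))
    if len(merged):
        resid = merged["value_t"] - merged["stage2"]
        mad = float(np.median(np.abs(resid - np.median(resid))))
        amp_default = max(inflation * 1.4826 * mad, 1e-3)
    else:
        amp_default = 0.1
    amplitude = float(kernel_cfg.get("amplitude", amp_default))
    length_scale = float(kernel_cfg.get("length_scale", 3.0))

    out = {}
    pmeans = {}
    cols = [f"draw_{i}" for i in range(n_draws)]
    for (loc, a, s), sub in s2_frame.groupby(["location", "age_group", "sex"], sort=True):
        sub = sub.sort_values("year")
        years = sub["year"].to_numpy(dtype=float)
        mvals = sub["stage2"].to_numpy()
        o = merged[
            (merged["location"] == loc)
            & (merged["age_group"] == a)
            & (merged["sex"] == s)
        ]
        draws_t, pmean_t = _gp_series(
            years,
            mvals,
            o["year"].to_numpy(dtype=float),
            o["value_t"].to_numpy(),
            o["var_t"].to_numpy(),
            amplitude,
            length_scale,
            n_draws,
            rng,
        )
        nat = transform_back(draws_t, transform)
        for iy, y in enumerate(sub["year"]):
            out[(loc, int(y), a, s)] = nat[iy]
            pmeans[(loc, int(y), a, s)] = pmean_t[iy]
    index = pd.MultiIndex.from_tuples(out.keys(), names=CELL_KEYS)
    draws = pd.DataFrame(list(out.values()), index=index, columns=cols).sort_index()
    pmean = pd.Series(pmeans)
    pmean.index = pd.MultiIndex.from_tuples(pmeans.keys(), names=CELL_KEYS)
    return StgprFit(stage1, stage2, draws, hyperparams, transform,
                    posterior_mean=pmean.sort_index())


def select_hyperparams(
    grid,
    data: pd.DataFrame,
    prior: pd.Series,
    hierarchy: LocationHierarchy,
    holdout_cfg: dict | None = None,
    seed: int = 0,
    transform: str = "identity",
) -> StgprHyperparams:
    """Pick the grid point minimizing holdout RMSE of the stage-2 surface.

    A random fraction of observations (default 20%) is withheld; stage 2 is
    computed from the remainder under each hyperparameter set and scored on
    the held-out points in modeling space.  Ties break toward smoother fits
    (larger lambda, then larger zeta).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    holdout_cfg = holdout_cfg or {"prop": 0.2}
    rng = np.random.default_rng(seed)
    obs = data.copy()
    obs["value_t"] = transform_forward(obs["value"].to_numpy(), transform)

    mask = rng.random(len(obs)) < holdout_cfg.get("prop", 0.2)
    if mask.all() or not mask.any():
        mask = np.zeros(len(obs), dtype=bool)
        mask[: max(1, len(obs) // 5)] = True
    train, test = obs[~mask], obs[mask]

    prior_lookup = prior.rename("prior").reset_index()
    prior_lookup.columns = CELL_KEYS + ["prior"]
    tr = train.merge(prior_lookup, on=CELL_KEYS, how="inner")
    tr["residual"] = tr["value_t"] - tr["prior"]
    te = test.merge(prior_lookup, on=CELL_KEYS, how="inner")

    best, best_key = None, None
    results = []
    for hp in grid:
        s2 = smooth_spatiotemporal(tr[CELL_KEYS + ["residual"]], prior, hierarchy, hp)
        s2_lookup = s2.rename("s2").reset_index()
        s2_lookup.columns = CELL_KEYS + ["s2"]
        m = te.merge(s2_lookup, on=CELL_KEYS, how="inner")
        rmse = float(np.sqrt(np.mean((m["value_t"] - m["s2"]) ** 2)))
        results.append((hp, rmse))
        key = (round(rmse, 12), -hp.lam, -hp.zeta)
        if best_key is None or key < best_key:
            best, best_key = hp, key
    logger.info("hyperparameter search: %s", [(h, round(r, 5)) for h, r in results])
    return best


def run_stgpr(
    sources,
    indicator: str,
    covariates: pd.DataFrame,
    hierarchy: LocationHierarchy,
    expected_signs: dict,
    hp_grid=None,
    n_draws: int = 1000,
    seed: int = 0,
    kernel_cfg: dict | None = None,
    max_subset_size: int = 3,
) -> StgprFit:
    """Convenience wrapper: observations -> stage 1 -> 2 -> 3 for one indicator."""
    transform = "identity" if indicator == "mean" else "logit"
    data = prepare_observations(sources, indicator)
    if data.empty:
        raise ValueError(f"no observations for indicator {indicator!r}")
    prior = fit_stage1(
        data, covariates, hierarchy, expected_signs,
        seed=seed, transform=transform, max_subset_size=max_subset_size,
    )
    if hp_grid is None:
        hp_grid = [
            StgprHyperparams(z, l, o)
            for z in (0.6, 0.9)
            for l in (0.5, 2.0)
            for o in (1.5,)
        ]
    hp = select_hyperparams(
        hp_grid, data, prior.prediction, hierarchy, seed=seed + 1, transform=transform
    )
    obs = data.copy()
    obs["value_t"] = transform_forward(obs["value"].to_numpy(), transform)
    lookup = prior.prediction.rename("prior").reset_index()
    lookup.columns = CELL_KEYS + ["prior"]
    obs = obs.merge(lookup, on=CELL_KEYS, how="inner")
    obs["residual"] = obs["value_t"] - obs["prior"]
    stage2 = smooth_spatiotemporal(
        obs[CELL_KEYS + ["residual"]], prior.prediction, hierarchy, hp
    )
    return gpr_stage(
        stage2, data, kernel_cfg, n_draws, seed + 2, transform, prior, hp
    )
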