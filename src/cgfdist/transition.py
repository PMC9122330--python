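"""Monotone quadratic-spline ensembles of prevalence against the UHC index.

Expected prevalence as a function of health-system strength (the universal
health coverage index, 0-100) is modeled in logit space as a weighted
ensemble of 20 spline submodels.  Each submodel is a quadratic spline over
five segments (four randomized interior knots), fit by constrained least
squares under a hard non-increasing constraint: because a quadratic spline's
derivative is piecewise linear, enforcing non-positive derivative at every
knot guarantees monotonicity on the whole domain.  Submodels are weighted by
predictive validity (location-grouped cross-validation RMSE), the lowest and
highest 0.5% of points by signed residual are trimmed once and the ensemble
refit, and an optional linear SDI covariate can be added.  Age-sex-specific
ensembles are aggregated with population weights, and curves for different
severities can be scaled to a common anchor at the lowest observed UHC value
to compare decline trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

__all__ = [
    "SplineConfig",
    "SplineSubmodel",
    "SplineEnsembleFit",
    "ScaledTrajectory",
    "fit_spline_ensemble",
    "fit_with_sdi",
    "predict_at_sdi",
    "aggregate_splines",
    "scale_trajectories",
]

_DEGREE = 2
_PREV_FLOOR = 1e-7


@dataclass(frozen=True)
class SplineConfig:
    """Tunables of the spline ensemble."""

    n_submodels: int = 20
    n_interior_knots: int = 4  # five quadratic segments
    knot_quantile_range: tuple[float, float] = (0.05, 0.95)
    min_knot_spacing: float = 5.0  # UHC index points
    n_folds: int = 5
    trim_fraction: float = 0.005  # per tail, by signed residual


@dataclass
class SplineSubmodel:
    """One constrained quadratic spline in logit-prevalence space."""

    knots: np.ndarray  # full knot vector (with boundary repeats)
    coef: np.ndarray  # basis coefficients; last entry is the SDI slope if present
    oos_rmse: float
    has_sdi: bool = False

    @property
    def n_basis(self) -> int:
        return len(self.knots) - _DEGREE - 1

    def predict_logit(self, uhc, sdi=None) -> np.ndarray:
        x = np.clip(np.asarray(uhc, dtype=float), self.knots[0], self.knots[-1])
        X = BSpline.design_matrix(x, self.knots, _DEGREE).toarray()
        out = X @ self.coef[: self.n_basis]
        if self.has_sdi:
            if sdi is None:
                raise ValueError("submodel has an SDI term; pass sdi")
            out = out + self.coef[self.n_basis] * np.asarray(sdi, dtype=float)
        return out

    def derivative_bound(self) -> float:
        """Exact maximum of the spline derivative over the domain."""
        spl = BSpline(self.knots, self.coef[: self.n_basis], _DEGREE)
        pts = np.unique(self.knots)
        return float(np.max(spl.derivative()(pts)))


@dataclass
class SplineEnsembleFit:
    """Weighted collection of monotone spline submodels."""

    submodels: list[SplineSubmodel]
    weights: np.ndarray
    trimmed_ids: np.ndarray  # positional indices of trimmed input points
    domain: tuple[float, float]
    has_sdi: bool = False
    transform: str = "logit"

    def predict_logit(self, uhc, sdi=None) -> np.ndarray:
        preds = np.stack(
            [m.predict_logit(uhc, sdi=sdi) for m in self.submodels]
        )
        return np.einsum("m,mx->x", self.weights, preds)

    def predict(self, uhc, sdi=None) -> np.ndarray:
        """Prevalence (natural space) at the given UHC values."""
        return special.expit(self.predict_logit(uhc, sdi=sdi))


def _draw_knots(rng, lo, hi, n_interior, min_spacing):
    for _ in range(500):
        cand = np.sort(rng.uniform(lo, hi, n_interior))
        if np.all(np.diff(np.concatenate([[lo], cand, [hi]])) >= min_spacing):
            return cand
    # fall back to evenly spaced interior knots if spacing can't be met
    return np.linspace(lo, hi, n_interior + 2)[1:-1]


def _full_knots(lo, hi, interior):
    return np.concatenate([[lo] * (_DEGREE + 1), interior, [hi] * (_DEGREE + 1)])


def _design(x, knots, sdi=None):
    X = BSpline.design_matrix(
        np.clip(x, knots[0], knots[-1]), knots, _DEGREE
    ).toarray()
    if sdi is not None:
        X = np.hstack([X, np.asarray(sdi, dtype=float)[:, None]])
    return X


def _derivative_matrix(knots, n_extra_cols=0):
    """Rows: d/du of each basis function at every knot (and thus everywhere,
    since the derivative of a quadratic spline is piecewise linear)."""
    n_basis = len(knots) - _DEGREE - 1
    pts = np.unique(knots)
    D = np.zeros((len(pts), n_basis + n_extra_cols))
    for j in range(n_basis):
        c = np.zeros(n_basis)
        c[j] = 1.0
        D[:, j] = BSpline(knots, c, _DEGREE).derivative()(pts)
    return D


def _greville(knots):
    n_basis = len(knots) - _DEGREE - 1
    return np.array(
        [knots[j + 1 : j + _DEGREE + 1].mean() for j in range(n_basis)]
    )


def _fit_constrained(X, y, D, n_basis):
    """Least squares subject to D c <= 0 (non-increasing spline)."""
    c0 = np.zeros(X.shape[1])
    # initialize from a decreasing straight line through the data
    c0[:n_basis] = np.linspace(y.max(), y.min(), n_basis)

    def fun(c):
        r = X @ c - y
        return 0.5 * float(r @ r)

    def jac(c):
        return X.T @ (X @ c - y)

    cons = [{"type": "ineq", "fun": lambda c: -(D @ c), "jac": lambda c: -D}]
    res = optimize.minimize(
        fun, c0, jac=jac, method="SLSQP", constraints=cons,
        options={"maxiter": 500, "ftol": 1e-12},
    )
    c = res.x
    if not res.success:
        logger.debug("SLSQP: %s", res.message)
    return c


def _fit_submodel(x, y, knots, sdi=None) -> np.ndarray:
    n_basis = len(knots) - _DEGREE - 1
    X = _design(x, knots, sdi)
    D = _derivative_matrix(knots, n_extra_cols=0 if sdi is None else 1)
    c = _fit_constrained(X, y, D, n_basis)
    # exact monotonicity repair: subtract a line with the residual positive
    # slope (a linear function is inside the quadratic spline space)
    vmax = float(np.max(D[:, :n_basis] @ c[:n_basis]))
    if vmax > 0:
        logger.debug("repairing +%.2g derivative overshoot", vmax)
        c = c.copy()
        c[:n_basis] -= vmax * _greville(knots)
    return c


def _location_folds(locations, n_folds, rng):
    locs = np.array(sorted(set(locations)))
    rng.shuffle(locs)
    fold_of = {l: i % n_folds for i, l in enumerate(locs)}
    return np.array([fold_of[l] for l in locations])


def _fit_pass(x, y, locs, sdi, knot_sets, cfg, rng):
    submodels = []
    folds = _location_folds(locs, cfg.n_folds, rng)
    n_folds_eff = folds.max() + 1
    for interior in knot_sets:
        knots = _full_knots(x.min(), x.max(), interior)
        errs = []
        for f in range(n_folds_eff):
            tr, te = folds != f, folds == f
            if not tr.any() or not te.any():
                continue
            c = _fit_submodel(
                x[tr], y[tr], knots, None if sdi is None else sdi[tr]
            )
            sub = SplineSubmodel(knots, c, np.nan, has_sdi=sdi is not None)
            pred = sub.predict_logit(x[te], None if sdi is None else sdi[te])
            errs.append(np.sqrt(np.mean((pred - y[te]) ** 2)))
        rmse = float(np.mean(errs)) if errs else np.inf
        c = _fit_submodel(x, y, knots, sdi)
        submodels.append(
            SplineSubmodel(knots, c, rmse, has_sdi=sdi is not None)
        )
    rmses = np.array([m.oos_rmse for m in submodels])
    rmses = np.where(np.isfinite(rmses), rmses, np.nanmax(rmses[np.isfinite(rmses)]))
    w = np.exp(-(rmses - rmses.min()) / max(rmses.min(), 1e-12))
    w = w / w.sum()
    return submodels, w


def fit_spline_ensemble(
    points: pd.DataFrame,
    cfg: SplineConfig | None = None,
    seed: int = 0,
    use_sdi: bool = False,
) -> SplineEnsembleFit:
    """Fit the 20-submodel monotone spline ensemble in logit space.

    ``points`` needs columns ``uhc``, ``prevalence`` and ``location`` (for
    grouped cross-validation); ``sdi`` as well when ``use_sdi``.  All
    locations are weighted evenly (each point enters the least squares once).
    After a first fit, the lowest and highest ``trim_fraction`` of points by
    signed residual against the ensemble are trimmed and the ensemble refit
    once.
    """
    cfg = cfg or SplineConfig()
    if len(points) < 50:
        raise ValueError("need at least 50 points")
    rng = np.random.default_rng(seed)

    x = points["uhc"].to_numpy(dtype=float)
    p = points["prevalence"].to_numpy(dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        logger.warning("flooring prevalences at 0 or 1 into (%g, 1-%g)",
                       _PREV_FLOOR, _PREV_FLOOR)
    p = np.clip(p, _PREV_FLOOR, 1 - _PREV_FLOOR)
    y = special.logit(p)
    locs = points["location"].to_numpy()
    sdi = points["sdi"].to_numpy(dtype=float) if use_sdi else None

    qlo, qhi = np.quantile(x, cfg.knot_quantile_range)
    knot_sets = [
        _draw_knots(rng, qlo, qhi, cfg.n_interior_knots, cfg.min_knot_spacing)
        for _ in range(cfg.n_submodels)
    ]

    submodels, w = _fit_pass(x, y, locs, sdi, knot_sets, cfg, rng)
    ens = np.einsum(
        "m,mx->x",
        w,
        np.stack([m.predict_logit(x, sdi) for m in submodels]),
    )
    resid = y - ens
    k = int(np.ceil(cfg.trim_fraction * len(points)))
    order = np.argsort(resid, kind="stable")
    trimmed = np.concatenate([order[:k], order[-k:]]) if k else np.array([], int)
    keep = np.setdiff1d(np.arange(len(points)), trimmed)

    submodels, w = _fit_pass(
        x[keep], y[keep], locs[keep],
        None if sdi is None else sdi[keep], knot_sets, cfg, rng,
    )
    return SplineEnsembleFit(
        submodels=submodels,
        weights=w,
        trimmed_ids=trimmed,
        domain=(float(x.min()), float(x.max())),
        has_sdi=use_sdi,
    )


def fit_with_sdi(points: pd.DataFrame, cfg=None, seed: int = 0) -> SplineEnsembleFit:
    """Spline ensemble with an additional linear SDI covariate (logit space)."""
    return fit_spline_ensemble(points, cfg=cfg, seed=seed, use_sdi=True)


def predict_at_sdi(fit: SplineEnsembleFit, sdi_values=(20, 40, 60, 80), grid=None):
    """Expected-prevalence curves over the UHC domain at fixed SDI levels."""
    if not fit.has_sdi:
        raise ValueError("fit has no SDI covariate")
    if grid is None:
        grid = np.linspace(fit.domain[0], fit.domain[1], 201)
    grid = np.asarray(grid, dtype=float)
    out = {}
    for s in sdi_values:
        out[s] = fit.predict(grid, sdi=np.full(len(grid), float(s)))
    return pd.DataFrame(out, index=pd.Index(grid, name="uhc"))


def aggregate_splines(
    fits: dict,
    populations: pd.DataFrame,
    grid=None,
    sdi=None,
) -> pd.Series:
    """Population-weighted aggregate of age-sex-specific ensemble curves.

    ``fits`` maps (age_group, sex) -> :class:`SplineEnsembleFit`; weights are
    total population per age-sex cell.  Predictions are averaged in natural
    (prevalence) space.
    """
    cells = list(fits)
    pop = populations.groupby(["age_group", "sex"])["population"].sum()
    missing = [c for c in cells if c not in pop.index]
    if missing:
        raise KeyError(f"populations missing for cells {missing}")
    if grid is None:
        lo = min(f.domain[0] for f in fits.values())
        hi = max(f.domain[1] for f in fits.values())
        grid = np.linspace(lo, hi, 201)
    grid = np.asarray(grid, dtype=float)
    w = np.array([pop.loc[c] for c in cells], dtype=float)
    w = w / w.sum()
    preds = np.stack(
        [
            fits[c].predict(
                grid, sdi=None if sdi is None else np.full(len(grid), float(sdi))
            )
            for c in cells
        ]
    )
    return pd.Series(
        np.einsum("c,cx->x", w, preds), index=pd.Index(grid, name="uhc")
    )


@dataclass
class ScaledTrajectory:
    """Per-severity curves rescaled to coincide at the lowest UHC value."""

    curves: pd.DataFrame  # index: uhc grid; columns: severities
    anchor_uhc: float
    scalars: dict


def scale_trajectories(
    curves: pd.DataFrame, uhc_min: float | None = None, reference: str = "overall"
) -> ScaledTrajectory:
    """Anchor severity curves to a common value at the minimum UHC index.

    Each severity curve is multiplied by reference(uhc_min)/severity(uhc_min)
    so all scaled curves coincide at the anchor; steeper proportional
    declines with rising UHC then read directly as lower scaled curves.
    """
    grid = curves.index.to_numpy(dtype=float)
    if uhc_min is None:
        uhc_min = float(grid.min())
    i0 = int(np.argmin(np.abs(grid - uhc_min)))
    ref_val = float(curves[reference].iloc[i0])
    scalars = {}
    scaled = {}
    for sev in curves.columns:
        v0 = float(curves[sev].iloc[i0])
        if v0 <= 0:
            raise ValueError(f"{sev}: zero curve value at the anchor")
        scalars[sev] = ref_val / v0
        scaled[sev] = curves[sev].to_numpy() * scalars[sev]
    return ScaledTrajectory(
        curves=pd.DataFrame(scaled, index=curves.index),
        anchor_uhc=float(grid[i0]),
        scalars=scalars,
    )
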