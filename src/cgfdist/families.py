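"""Method-of-moments parameterizations for the ensemble component families.

Each of the ten candidate families is parameterized from the target mean and
variance of the z-score distribution ("method of moments").  Families with
positive support are fit to the shifted variable ``x = z + shift``; mirrored
families are fit to the reflected variable ``x = anchor - z``.  The module
exposes vectorized CDF/PDF evaluation on the z-score scale plus sampling, and
reports infeasibility (e.g. a shifted mean that is not positive) through NaN
masks rather than exceptions so that an ensemble can renormalize around an
infeasible component.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES",
    "REAL_FAMILIES",
    "POSITIVE_FAMILIES",
    "MIRRORED_FAMILIES",
    "FamilyInfeasibleError",
    "mom_params",
    "family_cdf",
    "family_pdf",
    "family_rvs",
]

EULER_GAMMA = float(np.euler_gamma)

#: families fit directly on the z-score axis (support = R)
REAL_FAMILIES = ("normal", "gumbel")
#: families fit on the shifted axis x = z + shift (support = R+)
POSITIVE_FAMILIES = (
    "lognormal",
    "loglogistic",
    "exponential",
    "gamma",
    "inverse_gamma",
    "weibull",
)
#: families fit on the reflected axis x = anchor - z
MIRRORED_FAMILIES = ("mirrored_gamma", "mirrored_gumbel")

FAMILIES = (
    "normal",
    "lognormal",
    "loglogistic",
    "exponential",
    "gamma",
    "mirrored_gamma",
    "inverse_gamma",
    "gumbel",
    "mirrored_gumbel",
    "weibull",
)


class FamilyInfeasibleError(ValueError):
    """Raised when a family cannot match the requested moments."""


# ---------------------------------------------------------------------------
# shape-parameter solves
#
# For the log-logistic, with c = pi / shape the squared coefficient of
# variation has the closed form CV^2 = tan(c)/c - 1, monotone increasing in
# c on (0, pi/2); for the Weibull, CV^2 = G(1+2/k)/G(1+1/k)^2 - 1 is
# monotone decreasing in k.  Both are inverted once on a dense log-CV grid
# and evaluated by interpolation thereafter, which keeps the ensemble CDF
# closed-form and fast when called on large draw arrays.
# ---------------------------------------------------------------------------

_LOGCV_GRID = np.linspace(np.log(1e-5), np.log(1e3), 4097)
_shape_tables: dict[str, np.ndarray] = {}


def _loglogistic_c_exact(cv2: float) -> float:
    # solve tan(c)/c = 1 + cv2 on (0, pi/2)
    def f(c):
        return np.tan(c) / c - 1.0 - cv2

    return optimize.brentq(f, 1e-9, np.pi / 2 - 1e-12, xtol=1e-15, rtol=1e-14)


def _weibull_k_exact(cv2: float) -> float:
    def f(logk):
        k = np.exp(logk)
        g1 = special.gammaln(1.0 + 1.0 / k)
        g2 = special.gammaln(1.0 + 2.0 / k)
        return np.log(np.expm1(np.clip(g2 - 2.0 * g1, 1e-300, None))) - np.log(cv2)

    lo, hi = np.log(1e-2), np.log(1e6)
    return float(np.exp(optimize.brentq(f, lo, hi, xtol=1e-13, rtol=1e-14)))


def _get_shape_table(kind: str) -> np.ndarray:
    tab = _shape_tables.get(kind)
    if tab is None:
        cv2 = np.exp(_LOGCV_GRID) ** 2
        if kind == "loglogistic":
            tab = np.array([_loglogistic_c_exact(v) for v in cv2])
        elif kind == "weibull":
            tab = np.log([_weibull_k_exact(v) for v in cv2])
        else:  # pragma: no cover
            raise KeyError(kind)
        _shape_tables[kind] = tab
    return tab


def _loglogistic_c(cv: np.ndarray) -> np.ndarray:
    logcv = np.clip(np.log(cv), _LOGCV_GRID[0], _LOGCV_GRID[-1])
    return np.interp(logcv, _LOGCV_GRID, _get_shape_table("loglogistic"))


def _weibull_k(cv: np.ndarray) -> np.ndarray:
    logcv = np.clip(np.log(cv), _LOGCV_GRID[0], _LOGCV_GRID[-1])
    return np.exp(np.interp(logcv, _LOGCV_GRID, _get_shape_table("weibull")))


# ---------------------------------------------------------------------------
# native-scale parameter sets (mean m, variance v on the *native* axis)
# ---------------------------------------------------------------------------


def _native_params(family: str, m, v):
    """Parameters of ``family`` matching native mean ``m`` and variance ``v``.

    Returns a dict of arrays; entries are NaN where the moments are
    infeasible for the family.
    """
    m = np.asarray(m, dtype=float)
    v = np.asarray(v, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        if family == "normal":
            return {"loc": m, "scale": np.sqrt(v)}
        if family == "gumbel":
            scale = np.sqrt(6.0 * v) / np.pi
            return {"loc": m - EULER_GAMMA * scale, "scale": scale}
        ok = m > 0
        mm = np.where(ok, m, np.nan)
        if family == "lognormal":
            s2 = np.log1p(v / mm**2)
            return {"s": np.sqrt(s2), "scale": np.exp(np.log(mm) - s2 / 2.0)}
        if family == "exponential":
            # single parameter: matches the mean only
            return {"scale": mm}
        if family == "gamma":
            return {"a": mm**2 / v, "scale": v / mm}
        if family == "inverse_gamma":
            a = mm**2 / v + 2.0
            return {"a": a, "scale": mm * (a - 1.0)}
        if family == "weibull":
            k = _weibull_k(np.sqrt(v) / mm)
            lam = mm / np.exp(special.gammaln(1.0 + 1.0 / k))
            return {"c": k, "scale": lam}
        if family == "loglogistic":
            c = _loglogistic_c(np.sqrt(v) / mm)
            return {"c": np.pi / c, "scale": mm * np.sin(c) / c}
    raise KeyError(f"unknown family {family!r}")


_NATIVE_DIST = {
    "normal": stats.norm,
    "gumbel": stats.gumbel_r,
    "lognormal": stats.lognorm,
    "loglogistic": stats.fisk,
    "exponential": stats.expon,
    "gamma": stats.gamma,
    "inverse_gamma": stats.invgamma,
    "weibull": stats.weibull_min,
    "mirrored_gamma": stats.gamma,
    "mirrored_gumbel": stats.gumbel_r,
}


def _native_moments(family: str, mean, var, shift: float, anchor: float):
    """Map z-scale moments to the family's native axis; NaN if infeasible."""
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    var = np.where(var > 0, var, np.nan)
    if family in REAL_FAMILIES:
        return mean + 0.0 * var, var
    if family in MIRRORED_FAMILIES:
        m = anchor - mean
    else:
        m = mean + shift
    return np.where(m > 0, m, np.nan) + 0.0 * var, var


def mom_params(family: str, mean, var, *, shift: float = 10.0, anchor: float = 10.0):
    """Method-of-moments parameters for one family on its native axis.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    mean, var : float
        Target mean and variance on the z-score scale.
    shift : float
        Offset applied to z for positive-support families (``x = z + shift``).
    anchor : float
        Upper anchor for mirrored families (``x = anchor - z``).

    Returns
    -------
    dict
        scipy-style keyword parameters for the family's native distribution.

    Raises
    ------
    FamilyInfeasibleError
        If the moments cannot be matched (non-positive variance, or a
        non-positive mean on the native axis).
    """
    if family not in FAMILIES:
        raise KeyError(f"unknown family {family!r}")
    base = family.removeprefix("mirrored_")
    m, v = _native_moments(family, mean, var, shift, anchor)
    if not np.all(np.isfinite(m)):
        raise FamilyInfeasibleError(
            f"{family}: moments (mean={mean}, var={var}) infeasible "
            f"with shift={shift}, anchor={anchor}"
        )
    params = _native_params(base if family in MIRRORED_FAMILIES else family, m, v)
    if not all(np.all(np.isfinite(p)) for p in params.values()):
        raise FamilyInfeasibleError(f"{family}: no parameters match the moments")
    return params


def _native_params_masked(family: str, mean, var, shift, anchor):
    m, v = _native_moments(family, mean, var, shift, anchor)
    base = family.removeprefix("mirrored_")
    return _native_params(base, m, v)


def family_cdf(family: str, x, mean, var, *, shift: float = 10.0, anchor: float = 10.0):
    """P(Z <= x) on the z-score scale; NaN where moments are infeasible."""
    params = _native_params_masked(family, mean, var, shift, anchor)
    dist = _NATIVE_DIST[family]
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        if family in MIRRORED_FAMILIES:
            # P(z <= x) = P(native >= anchor - x)
            return dist.sf(anchor - x, **params)
        if family in POSITIVE_FAMILIES:
            return dist.cdf(x + shift, **params)
        return dist.cdf(x, **params)


def family_pdf(family: str, x, mean, var, *, shift: float = 10.0, anchor: float = 10.0):
    """Density at x on the z-score scale; NaN where moments are infeasible."""
    params = _native_params_masked(family, mean, var, shift, anchor)
    dist = _NATIVE_DIST[family]
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        if family in MIRRORED_FAMILIES:
            return dist.pdf(anchor - x, **params)
        if family in POSITIVE_FAMILIES:
            return dist.pdf(x + shift, **params)
        return dist.pdf(x, **params)


def family_rvs(
    family: str,
    mean: float,
    var: float,
    size: int,
    rng: np.random.Generator,
    *,
    shift: float = 10.0,
    anchor: float = 10.0,
):
    """Sample z-scores from one moment-parameterized family."""
    params = mom_params(family, mean, var, shift=shift, anchor=anchor)
    dist = _NATIVE_DIST[family]
    x = dist.rvs(**params, size=size, random_state=rng)
    if family in MIRRORED_FAMILIES:
        return anchor - x
    if family in POSITIVE_FAMILIES:
        return x - shift
    return x
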