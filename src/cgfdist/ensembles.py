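"""Ensemble densities of child-growth z-scores and global weight fitting.

A characteristic z-score curve shape is represented as a convex mixture of up
to ten parametric families (normal, log-normal, log-logistic, exponential,
gamma, mirrored gamma, inverse gamma, Gumbel, mirrored Gumbel, Weibull), every
component parameterized by the same mean and variance via the method of
moments.  The mixture weights are global: one weight set per indicator,
fitted by minimizing the squared error in predicting the empirical prevalence
below -1, -2 and -3 SD across all individual-level survey sources
simultaneously, each source weighted evenly, using a simplex (Nelder-Mead
family) optimizer restarted from many random initial weight sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import families as fam
from .families import FAMILIES

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleSpec",
    "MomentPair",
    "WeightFitResult",
    "ensemble_pdf",
    "ensemble_cdf",
    "prevalence_below",
    "ensemble_rvs",
    "fit_ensemble_weights",
    "weights_to_csv",
    "weights_from_csv",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (-1.0, -2.0, -3.0)


@dataclass(frozen=True)
class MomentPair:
    """Mean and variance of a z-score distribution."""

    mean: float
    variance: float

    def __post_init__(self):
        if not np.isfinite(self.mean) or not np.isfinite(self.variance):
            raise ValueError("moments must be finite")
        if self.variance <= 0:
            raise ValueError(f"variance must be positive, got {self.variance}")


@dataclass(frozen=True)
class EnsembleSpec:
    """Weights over the candidate families plus shift/mirror conventions.

    Parameters
    ----------
    weights : dict
        Mapping family name -> non-negative weight.  Families omitted from
        the mapping carry weight zero.  Weights must sum to 1 (tol 1e-9).
    shift : float
        Positive-support families are fit to ``z + shift``; the default 10
        maps every plausible z-score onto positive support.
    mirror_anchor : float
        Mirrored families are fit to ``mirror_anchor - z``.
    """

    weights: dict[str, float]
    shift: float = 10.0
    mirror_anchor: float = 10.0

    def __post_init__(self):
        unknown = set(self.weights) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")
        w = np.array(list(self.weights.values()), dtype=float)
        if len(w) == 0:
            raise ValueError("at least one family required")
        if np.any(w < -1e-12):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
        if not (np.isfinite(self.shift) and np.isfinite(self.mirror_anchor)):
            raise ValueError("shift and mirror_anchor must be finite")

    @classmethod
    def single(cls, family: str, **kw) -> "EnsembleSpec":
        return cls(weights={family: 1.0}, **kw)

    @classmethod
    def uniform(cls, families=FAMILIES, **kw) -> "EnsembleSpec":
        n = len(families)
        return cls(weights={f: 1.0 / n for f in families}, **kw)

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(f for f in FAMILIES if self.weights.get(f, 0.0) > 0)

    def weight_vector(self, names=FAMILIES) -> np.ndarray:
        return np.array([self.weights.get(f, 0.0) for f in names])


def _moments_arrays(moments):
    if isinstance(moments, MomentPair):
        return np.asarray(moments.mean, float), np.asarray(moments.variance, float)
    mean, var = moments
    return np.asarray(mean, dtype=float), np.asarray(var, dtype=float)


def _stack_eval(kind: str, spec: EnsembleSpec, moments, x):
    """Weighted family cdf/pdf with per-point renormalization over the
    feasible components.  Broadcasts over arrays of x, mean and variance."""
    mean, var = _moments_arrays(moments)
    x = np.asarray(x, dtype=float)
    shape = np.broadcast_shapes(x.shape, mean.shape, var.shape)
    total = np.zeros(shape)
    wsum = np.zeros(shape)
    f_eval = fam.family_cdf if kind == "cdf" else fam.family_pdf
    for name in spec.families:
        w = spec.weights[name]
        vals = np.broadcast_to(
            f_eval(name, x, mean, var, shift=spec.shift, anchor=spec.mirror_anchor),
            shape,
        )
        feas = np.isfinite(vals)
        total = np.where(feas, total + w * vals, total)
        wsum = np.where(feas, wsum + w, wsum)
    if np.any(wsum <= 0):
        raise fam.FamilyInfeasibleError(
            "all ensemble components infeasible for the given moments"
        )
    out = total / wsum
    if kind == "cdf":
        out = np.clip(out, 0.0, 1.0)
    return out if out.shape else float(out)


def ensemble_pdf(spec: EnsembleSpec, moments, x):
    """Mixture density at ``x`` (z-score scale).

    Components whose moments are infeasible contribute zero density and the
    remaining weights are renormalized.
    """
    return _stack_eval("pdf", spec, moments, x)


def ensemble_cdf(spec: EnsembleSpec, moments, x):
    """Mixture CDF at ``x``: the weighted sum of closed-form family CDFs."""
    return _stack_eval("cdf", spec, moments, x)


def prevalence_below(spec: EnsembleSpec, moments, threshold):
    """Proportion of the z-score distribution below ``threshold``.

    This is the quantity integrated under the ensemble curve to the left of a
    severity cutoff (-2 SD for overall, -3 severe, -4 extreme); because every
    component CDF is closed-form, no numerical quadrature is involved.
    """
    return ensemble_cdf(spec, moments, threshold)


def ensemble_rvs(spec, moments, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` z-scores from the mixture (component chosen per draw)."""
    mean, var = _moments_arrays(moments)
    mean, var = float(mean), float(var)
    names = [f for f in spec.families]
    w = np.array([spec.weights[f] for f in names])
    counts = rng.multinomial(size, w / w.sum())
    parts = [
        fam.family_rvs(
            name, mean, var, int(n), rng, shift=spec.shift, anchor=spec.mirror_anchor
        )
        for name, n in zip(names, counts)
        if n > 0
    ]
    out = np.concatenate(parts) if parts else np.empty(0)
    rng.shuffle(out)
    return out


# ---------------------------------------------------------------------------
# global weight fitting
# ---------------------------------------------------------------------------


@dataclass
class WeightFitResult:
    """Best ensemble weights over the optimizer restarts."""

    spec: EnsembleSpec
    objective: float
    n_restarts: int
    restart_objectives: list[float] = field(default_factory=list)


def _source_summaries(sources, thresholds):
    """Per-source (mean, var, empirical prevalences); drops degenerate ones."""
    out = []
    for src in sources:
        z = np.asarray(
            src.records["z"] if hasattr(src, "records") else src, dtype=float
        )
        if z.size < 2:
            logger.warning("dropping source with fewer than 2 records")
            continue
        v = float(np.var(z, ddof=1))
        if v <= 0:
            logger.warning("dropping degenerate (zero-variance) source")
            continue
        m = float(np.mean(z))
        prev = [float(np.mean(z < t)) for t in thresholds]
        out.append((m, v, prev))
    if not out:
        raise ValueError("no usable microdata sources (all degenerate or empty)")
    # canonical order makes the fit exactly invariant to source ordering
    out.sort(key=lambda t: (t[0], t[1], t[2]))
    return out


def _prediction_tensor(summaries, thresholds, names, shift, anchor):
    """C[s, f, t] = family CDF at threshold t under source s's moments."""
    n_s, n_f, n_t = len(summaries), len(names), len(thresholds)
    C = np.full((n_s, n_f, n_t), np.nan)
    means = np.array([m for m, _, _ in summaries])
    varis = np.array([v for _, v, _ in summaries])
    for j, name in enumerate(names):
        for k, t in enumerate(thresholds):
            C[:, j, k] = fam.family_cdf(
                name, t, means, varis, shift=shift, anchor=anchor
            )
    return C


def _objective_factory(C, emp):
    feas = np.isfinite(C[:, :, 0])  # feasibility does not depend on threshold
    C0 = np.nan_to_num(C)

    def objective(w):
        w = np.abs(w)
        tot = w.sum()
        if tot <= 0:
            w = np.full_like(w, 1.0 / len(w))
        else:
            w = w / tot
        wmask = feas * w[None, :]
        denom = wmask.sum(axis=1)
        if np.any(denom <= 0):
            return 1e6
        pred = np.einsum("sf,sft->st", wmask, C0) / denom[:, None]
        return float(np.sum((pred - emp) ** 2))

    return objective


def fit_ensemble_weights(
    sources,
    thresholds=DEFAULT_THRESHOLDS,
    n_restarts: int = 100,
    seed: int = 0,
    *,
    candidate_families=FAMILIES,
    shift: float = 10.0,
    mirror_anchor: float = 10.0,
    maxiter: int = 400,
) -> WeightFitResult:
    """Fit global ensemble weights to microdata sources.

    For each source the empirical mean, variance (n-1 normalization) and
    empirical prevalences below each threshold are computed.  The objective is
    the unweighted sum over sources of the squared difference between the
    ensemble-predicted and empirical prevalences at the three thresholds.  It
    is minimized over the weight simplex with Nelder-Mead, restarted from
    ``n_restarts`` Dirichlet(1) initial weight sets; the best restart wins.

    Parameters
    ----------
    sources : sequence
        Microdata sources; each either an object with a ``records`` frame
        containing a ``z`` column, or directly an array of z-scores.
    thresholds : sequence of float
        Cutoffs whose prevalences enter the objective (default -1, -2, -3).
    n_restarts : int
        Number of random initial weight sets.
    seed : int
        Seeds the Dirichlet restarts.
    candidate_families : sequence of str
        Restrict the mixture to a subset of the ten families.
    """
    names = tuple(candidate_families)
    if not names:
        raise ValueError("need at least one candidate family")
    summaries = _source_summaries(sources, thresholds)
    emp = np.array([p for _, _, p in summaries])
    C = _prediction_tensor(summaries, thresholds, names, shift, mirror_anchor)
    objective = _objective_factory(C, emp)

    rng = np.random.default_rng(seed)
    if len(names) == 1:
        w = np.ones(1)
        obj = objective(w)
        spec = EnsembleSpec({names[0]: 1.0}, shift=shift, mirror_anchor=mirror_anchor)
        return WeightFitResult(spec, obj, n_restarts, [obj])

    best_w, best_obj, per_restart = None, np.inf, []
    for _ in range(n_restarts):
        w0 = rng.dirichlet(np.ones(len(names)))
        res = optimize.minimize(
            objective,
            w0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-12},
        )
        per_restart.append(float(res.fun))
        if res.fun < best_obj:
            best_obj, best_w = float(res.fun), np.abs(res.x)
    best_w = best_w / best_w.sum()
    best_w[best_w < 1e-12] = 0.0
    best_w = best_w / best_w.sum()
    spec = EnsembleSpec(
        dict(zip(names, best_w)), shift=shift, mirror_anchor=mirror_anchor
    )
    return WeightFitResult(spec, best_obj, n_restarts, per_restart)


def weights_to_csv(result_or_spec, path) -> None:
    """Write fitted weights as a two-column (family, weight) CSV."""
    spec = getattr(result_or_spec, "spec", result_or_spec)
    rows = [(f, spec.weights.get(f, 0.0)) for f in FAMILIES]
    pd.DataFrame(rows, columns=["family", "weight"]).to_csv(path, index=False)


def weights_from_csv(path, **kw) -> EnsembleSpec:
    df = pd.read_csv(path, comment="#")
    w = {r.family: float(r.weight) for r in df.itertuples() if r.weight > 0}
    total = sum(w.values())
    return EnsembleSpec({k: v / total for k, v in w.items()}, **kw)
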