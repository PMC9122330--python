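"""Reusable simulation studies validating the pipeline against known truth.

These are desk-scale experiments with fixed designs: a Gaussian-process
calibration study (does the 95% interval cover the truth at the advertised
rate?), a full-pipeline truth-recovery study on a ten-country world, and a
differential-decline world in which severe and extreme prevalence improve
faster than overall prevalence, used to confirm that severity-stratified
change metrics and scaled transition curves preserve that ordering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import change as change_mod
from . import integration, stgpr, synthetic, transition
from .ensembles import EnsembleSpec, fit_ensemble_weights

__all__ = [
    "gp_coverage_study",
    "end_to_end_study",
    "severity_ordering_study",
]


def gp_coverage_study(
    seed: int,
    n_locations: int = 200,
    years=range(1990, 2021),
    obs_every: int = 4,
    obs_sd: float = 0.05,
    bias_sd: float = 0.04,
    n_draws: int = 100,
) -> dict:
    """Empirical coverage of the stage-3 GP's 95% intervals.

    Each location carries an independent smooth truth curve; the stage-2
    surface handed to the GP is the truth plus a smooth location-specific
    bias (intercept and slope of scale ``bias_sd``, emulating residual
    stage-2 error), and noisy observations of the truth are available every
    ``obs_every`` years.  Returns the fraction of location-year cells whose
    truth falls inside the 2.5th-97.5th percentile band of the draws.
    """
    rng = np.random.default_rng(seed)
    years = np.array(sorted(years))
    ny = len(years)
    tmid = years.mean()
    tspan = (years[-1] - years[0]) / 2

    cells, s2_vals, truth_vals = [], [], []
    data_rows = []
    for i in range(n_locations):
        loc = f"L{i:03d}"
        level = rng.normal(-1.5, 0.3)
        slope = rng.normal(0.008, 0.004)
        amp = rng.normal(0.0, 0.03)
        phase = rng.uniform(0, 2 * np.pi)
        truth = level + slope * (years - tmid) + amp * np.sin(
            2 * np.pi * (years - tmid) / 20 + phase
        )
        bias = rng.normal(0, bias_sd) + rng.normal(0, bias_sd) * (
            (years - tmid) / tspan
        )
        for iy, y in enumerate(years):
            cells.append((loc, int(y), "2-4y", "female"))
            s2_vals.append(truth[iy] + bias[iy])
            truth_vals.append(truth[iy])
        for iy in range(i % obs_every, ny, obs_every):
            data_rows.append(
                (
                    loc,
                    int(years[iy]),
                    "2-4y",
                    "female",
                    truth[iy] + rng.normal(0, obs_sd),
                    obs_sd**2,
                    1,
                )
            )

    index = pd.MultiIndex.from_tuples(cells, names=stgpr.CELL_KEYS)
    stage2 = pd.Series(s2_vals, index=index)
    truth_s = pd.Series(truth_vals, index=index)
    data = pd.DataFrame(
        data_rows, columns=stgpr.CELL_KEYS + ["value", "variance", "sample_size"]
    )
    fit = stgpr.gpr_stage(stage2, data, n_draws=n_draws, seed=seed + 1)
    summ = fit.summary()
    covered = (summ["lower"] <= truth_s) & (truth_s <= summ["upper"])
    return {
        "coverage": float(covered.mean()),
        "n_cells": int(len(covered)),
        "mean_width": float((summ["upper"] - summ["lower"]).mean()),
    }


def _survey_world(seed: int, trend_cfg=None, age_groups=("12-23m", "2-4y"),
                  micro_n: int = 4000, tab_n: int = 10000, cadence: int = 2):
    """Ten-country world with dense, low-noise surveys: every country-year
    carries either a microdata survey or a large tabulated report."""
    hierarchy = synthetic.make_hierarchy(1, 2, 5, seed=0)
    truth = synthetic.simulate_truth(
        hierarchy, range(1990, 2021), trend_cfg=trend_cfg, seed=seed,
        age_groups=age_groups,
    )
    covs = synthetic.simulate_covariates(truth, hierarchy, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    sources = []
    for i, c in enumerate(hierarchy.countries):
        for y in range(1990, 2021):
            cells = [(c, y, a, s) for a in age_groups for s in synthetic.SEXES]
            if (y + i) % cadence == 0:
                sources.append(
                    synthetic.simulate_microdata(
                        truth, cells, micro_n, seed=int(rng.integers(2**31))
                    )
                )
            if (y + i) % cadence == 1:
                sources.append(
                    synthetic.simulate_tabulated(
                        truth, cells, tab_n, seed=int(rng.integers(2**31))
                    )
                )
    return hierarchy, truth, covs, sources


def end_to_end_study(seed: int, n_draws: int = 100, n_restarts: int = 20) -> dict:
    """Truth recovery of the full estimation chain on a 10-country world.

    Ensemble weights are fit to the simulated microdata, the three ST-GPR
    models are run, the SD is recovered per draw, and the final mean
    prevalence estimates are compared to the closed-form true prevalences.
    Returns the mean absolute error (percentage points) per severity.
    """
    hierarchy, truth, covs, sources = _survey_world(seed)
    micro = [s.records["z"].to_numpy() for s in sources if s.kind == "microdata"]
    wres = fit_ensemble_weights(micro, n_restarts=n_restarts, seed=seed + 3)

    signs = synthetic.expected_covariate_signs()
    fits = {}
    for ind in ("mean", "prev2", "prev3"):
        sg = signs if ind == "mean" else {k: -v for k, v in signs.items()}
        fits[ind] = stgpr.run_stgpr(
            sources, ind, covs, hierarchy, sg, n_draws=n_draws,
            seed=seed + 4, max_subset_size=2,
        )
    surface = integration.integrate_surface(
        wres.spec, fits["mean"].draws, fits["prev2"].draws, fits["prev3"].draws
    )
    summ = integration.summarize(surface)
    out = {"surface": surface, "truth": truth, "covariates": covs}
    for sev, t in [("overall", -2.0), ("severe", -3.0), ("extreme", -4.0)]:
        tp = truth.prevalence_below(t).rename("truth")
        est = summ.xs(sev, level="severity")["mean"].rename("est")
        joined = est.to_frame().join(tp)
        out[f"mae_{sev}_pp"] = float(
            (joined["est"] - joined["truth"]).abs().mean() * 100
        )
    out["mae_pp"] = float(
        np.mean([out["mae_overall_pp"], out["mae_severe_pp"], out["mae_extreme_pp"]])
    )
    return out


def _decline_world(seed: int, years=range(1990, 2021)):
    """World whose mean rises and SD narrows: severe/extreme prevalence
    decline proportionally faster than overall prevalence."""
    cfg = synthetic.TrendConfig(
        mean_start=-1.9,
        mean_end=-1.4,
        sd_start=1.25,
        sd_end=0.95,
        rw_sd_mean=0.004,
        rw_sd_logsd=0.002,
        ensemble=EnsembleSpec.single("normal"),
    )
    hierarchy = synthetic.make_hierarchy(1, 2, 5, seed=0)
    truth = synthetic.simulate_truth(
        hierarchy, years, trend_cfg=cfg, seed=seed, age_groups=("12-23m", "2-4y")
    )
    covs = synthetic.simulate_covariates(truth, hierarchy, seed=seed + 1)
    return hierarchy, truth, covs


def _truth_surface_draws(truth, covs, n_draws: int = 2, jitter=0.0, seed=0):
    """GrowthSurface built directly from the truth (degenerate draws)."""
    f = truth.frame
    rng = np.random.default_rng(seed)
    cols = [f"draw_{i}" for i in range(n_draws)]
    mean = pd.DataFrame(
        np.repeat(f["mean_z"].to_numpy()[:, None], n_draws, axis=1)
        + jitter * rng.standard_normal((len(f), n_draws)),
        index=f.index, columns=cols,
    )
    sd = pd.DataFrame(
        np.repeat(f["sd_z"].to_numpy()[:, None], n_draws, axis=1),
        index=f.index, columns=cols,
    )
    prev = {}
    thresholds = integration.SeverityThresholds()
    from .ensembles import prevalence_below

    for name, t in thresholds.named().items():
        prev[name] = pd.DataFrame(
            prevalence_below(
                truth.ensemble, (mean.to_numpy(), sd.to_numpy() ** 2), t
            ),
            index=f.index, columns=cols,
        )
    return integration.GrowthSurface(mean, sd, prev, thresholds, truth.ensemble)


def severity_ordering_study(seed: int, n_draws: int = 20) -> dict:
    """Relative-change medians and scaled transition curves under faster
    decline of the deeper severities.

    The truth world narrows its z-score spread while the mean rises, so the
    true relative declines order extreme > severe > overall.  Returns the
    severity-stratified median relative changes (1990-2020, both sexes,
    under 5, averaged over locations) and the scaled transition curves at
    the top of the observed UHC range.
    """
    hierarchy, truth, covs = _decline_world(seed)
    surface = _truth_surface_draws(truth, covs, n_draws=n_draws,
                                   jitter=0.01, seed=seed + 5)

    from .pipeline import _year_slice

    cur = _year_slice(surface, 2020)
    ref = _year_slice(surface, 1990)
    medians = {}
    for sev in ("overall", "severe", "extreme"):
        ch = change_mod.relative_change(cur, ref, covs, severity=sev)
        medians[sev] = float(change_mod.summarize_change(ch)["median"].mean())

    summ = integration.summarize(surface).reset_index()
    uhc_ly = covs.groupby(["location", "year"], as_index=False)["uhc"].mean()
    pts = summ.merge(uhc_ly, on=["location", "year"])
    cfg = transition.SplineConfig(n_submodels=8, n_folds=4)
    curves = {}
    for sev in ("overall", "severe", "extreme"):
        sub = pts[pts.severity == sev].rename(columns={"mean": "prevalence"})
        fit = transition.fit_spline_ensemble(
            sub[["uhc", "prevalence", "location"]], cfg, seed=seed + 6
        )
        grid = np.linspace(fit.domain[0], fit.domain[1], 201)
        curves[sev] = pd.Series(fit.predict(grid), index=grid)
    curve_df = pd.DataFrame(curves)
    scaled = transition.scale_trajectories(curve_df)
    top = scaled.curves.iloc[-1]
    return {
        "change_medians": medians,
        "scaled_top": {k: float(v) for k, v in top.items()},
        "scaled": scaled,
    }
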