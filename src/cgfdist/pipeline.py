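"""End-to-end orchestration: simulate -> fit-weights -> ST-GPR -> integrate
-> change / disruption / transition, driven by one config with one seed.

Every stage reads and writes plain CSV intermediates (schema/seed header
comments, draw matrices stored wide as draw_0..draw_{n-1}) and the run
emits a manifest recording per-stage outputs, SHA-256 digests, timings and
warning counts, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import change as change_mod
from . import ensembles, integration, stgpr, synthetic, tables, transition

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]

STAGES = (
    "simulate",
    "fit_weights",
    "stgpr",
    "integrate",
    "change",
    "disruption",
    "transition",
)


@dataclass
class RunConfig:
    """Single structured configuration for a full pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    years: tuple[int, int] = (1990, 2020)
    age_groups: tuple[str, ...] = synthetic.AGE_GROUPS
    n_draws: int = 100
    n_super: int = 1
    n_regions_per: int = 2
    n_countries_per: int = 2
    microdata_every: int = 5  # survey cadence in years
    microdata_n: int = 1000  # records per cell
    tabulated_every: int = 3
    tabulated_n: int = 2000
    weight_restarts: int = 20
    stages: tuple[str, ...] = STAGES
    transition_submodels: int = 20
    transition_folds: int = 5
    stage1_max_subset: int = 2
    reference_year: int = 1990

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)
    completed: bool = False

    def record(self, stage, outputs, seconds, n_warnings=0):
        self.stages[stage] = {
            "outputs": {str(p): _digest(p) for p in outputs},
            "seconds": round(seconds, 3),
            "warnings": n_warnings,
        }

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(
                {"config": self.config, "stages": self.stages,
                 "completed": self.completed},
                fh, indent=2, default=str,
            )


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class _WarningCounter(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record):
        self.count += 1


def _simulate(cfg: RunConfig, out: Path, seed: int):
    hierarchy = synthetic.make_hierarchy(
        cfg.n_super, cfg.n_regions_per, cfg.n_countries_per, seed=seed
    )
    years = range(cfg.years[0], cfg.years[1] + 1)
    truth = synthetic.simulate_truth(
        hierarchy, years=years, seed=seed, age_groups=cfg.age_groups
    )
    covs = synthetic.simulate_covariates(truth, hierarchy, seed=seed + 1)

    sources = []
    countries = hierarchy.countries
    rng = np.random.default_rng(seed + 2)
    for i, c in enumerate(countries):
        for y in years:
            cells = [(c, y, a, s) for a in cfg.age_groups for s in synthetic.SEXES]
            if (y - cfg.years[0] + i) % cfg.microdata_every == 0:
                sources.append(
                    synthetic.simulate_microdata(
                        truth, cells, cfg.microdata_n,
                        seed=int(rng.integers(2**31)),
                    )
                )
            if (y - cfg.years[0] + i) % cfg.tabulated_every == 1:
                sources.append(
                    synthetic.simulate_tabulated(
                        truth, cells, cfg.tabulated_n,
                        seed=int(rng.integers(2**31)),
                    )
                )

    out.mkdir(parents=True, exist_ok=True)
    tables.write_table(hierarchy.frame(), out / "hierarchy.csv", "hierarchy", seed)
    tables.write_table(
        truth.frame.reset_index(), out / "truth.csv", "truth_surface", seed
    )
    tables.write_table(covs, out / "covariates.csv", "covariates", seed)
    micro = pd.concat(
        [
            s.records.assign(location=s.location_id, year=s.year, source_id=s.source_id)
            for s in sources
            if s.kind == "microdata"
        ],
        ignore_index=True,
    )
    tab = pd.concat(
        [
            s.table.assign(location=s.location_id, year=s.year, source_id=s.source_id)
            for s in sources
            if s.kind == "tabulated"
        ],
        ignore_index=True,
    )
    tables.write_table(micro, out / "microdata.csv", "microdata", seed)
    tables.write_table(tab, out / "tabulated.csv", "tabulated", seed)
    return hierarchy, truth, covs, sources


def _load_sources(out: Path):
    micro = tables.read_table(out / "microdata.csv")
    tab = tables.read_table(out / "tabulated.csv")
    sources = []
    for sid, g in micro.groupby("source_id"):
        sources.append(
            synthetic.SurveySource(
                sid, g["location"].iloc[0], int(g["year"].iloc[0]), "microdata",
                records=g[["age_group", "sex", "z"]].reset_index(drop=True),
            )
        )
    for sid, g in tab.groupby("source_id"):
        sources.append(
            synthetic.SurveySource(
                sid, g["location"].iloc[0], int(g["year"].iloc[0]), "tabulated",
                table=g[["age_group", "sex", "prev2", "prev3", "n"]].reset_index(
                    drop=True
                ),
            )
        )
    return sources


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute the enabled stages in dependency order.

    Any stage failure halts the run; the manifest records the stages that
    completed.  Rerunning with the same config reproduces identical output
    digests.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(cfg))
    counter = _WarningCounter()
    logging.getLogger().addHandler(counter)

    hierarchy = truth = covs = sources = None
    spec = None
    fits = {}
    surface = None

    try:
        for stage in STAGES:
            if stage not in cfg.stages:
                continue
            t0 = time.perf_counter()
            w0 = counter.count
            outputs = []

            if stage == "simulate":
                hierarchy, truth, covs, sources = _simulate(cfg, out, cfg.seed)
                outputs = [
                    out / f for f in (
                        "hierarchy.csv", "truth.csv", "covariates.csv",
                        "microdata.csv", "tabulated.csv",
                    )
                ]

            elif stage == "fit_weights":
                micro = [s.records["z"].to_numpy() for s in sources
                         if s.kind == "microdata"]
                res = ensembles.fit_ensemble_weights(
                    micro, n_restarts=cfg.weight_restarts, seed=cfg.seed + 10
                )
                spec = res.spec
                from .families import FAMILIES

                tables.write_table(
                    pd.DataFrame(
                        [(f, spec.weights.get(f, 0.0)) for f in FAMILIES],
                        columns=["family", "weight"],
                    ),
                    out / "weights.csv", "ensemble_weights", cfg.seed,
                )
                outputs = [out / "weights.csv"]

            elif stage == "stgpr":
                signs_mean = synthetic.expected_covariate_signs()
                for indicator in ("mean", "prev2", "prev3"):
                    signs = (
                        signs_mean
                        if indicator == "mean"
                        else {k: -v for k, v in signs_mean.items()}
                    )
                    fit = stgpr.run_stgpr(
                        sources, indicator, covs, hierarchy, signs,
                        n_draws=cfg.n_draws, seed=cfg.seed + 20,
                        max_subset_size=cfg.stage1_max_subset,
                    )
                    fits[indicator] = fit
                    tables.write_table(
                        fit.draws.reset_index(),
                        out / f"stgpr_{indicator}_draws.csv",
                        f"stgpr_draws_{indicator}", cfg.seed,
                    )
                    tables.write_table(
                        fit.summary().reset_index(),
                        out / f"stgpr_{indicator}_summary.csv",
                        f"stgpr_summary_{indicator}", cfg.seed,
                    )
                    outputs += [
                        out / f"stgpr_{indicator}_draws.csv",
                        out / f"stgpr_{indicator}_summary.csv",
                    ]

            elif stage == "integrate":
                if spec is None:
                    spec = ensembles.weights_from_csv(out / "weights.csv")
                surface = integration.integrate_surface(
                    spec,
                    fits["mean"].draws,
                    fits["prev2"].draws,
                    fits["prev3"].draws,
                )
                summ = integration.summarize(surface).reset_index()
                tables.write_table(summ, out / "estimates.csv", "estimates", cfg.seed)
                outputs = [out / "estimates.csv"]

            elif stage == "change":
                years = surface.mean_z.reset_index()["year"]
                last = int(years.max())
                cur = _year_slice(surface, last)
                ref = _year_slice(surface, cfg.reference_year)
                rows = []
                for sev in ("overall", "severe", "extreme"):
                    ch = change_mod.relative_change(cur, ref, covs, severity=sev)
                    s = change_mod.summarize_change(ch)
                    s["severity"] = sev
                    s["year_range"] = f"{cfg.reference_year}-{last}"
                    rows.append(s.reset_index())
                tables.write_table(
                    pd.concat(rows, ignore_index=True),
                    out / "change.csv", "relative_change", cfg.seed,
                )
                outputs = [out / "change.csv"]

            elif stage == "disruption":
                rec = change_mod.annual_changes(
                    surface, covs, covs,
                    change_mod.ChangeFilters(min_population=0.0),
                )
                tables.write_table(
                    rec, out / "annual_changes.csv", "annual_changes", cfg.seed
                )
                ks_rows = []
                for sev, g in rec.groupby("severity"):
                    a = g.loc[g.uhc_direction == "improved", "annual_change"]
                    b = g.loc[g.uhc_direction == "worsened", "annual_change"]
                    if len(a) >= 2 and len(b) >= 2:
                        d, p = change_mod.ks_two_sample(a, b)
                        ks_rows.append((sev, d, p, len(a), len(b)))
                tables.write_table(
                    pd.DataFrame(
                        ks_rows,
                        columns=["severity", "ks_D", "ks_p", "n_improved",
                                 "n_worsened"],
                    ),
                    out / "ks.csv", "ks_statistics", cfg.seed,
                )
                outputs = [out / "annual_changes.csv", out / "ks.csv"]

            elif stage == "transition":
                curves = _transition_stage(cfg, surface, covs)
                tables.write_table(
                    curves.reset_index(), out / "transition.csv",
                    "transition_curves", cfg.seed,
                )
                scaled = transition.scale_trajectories(curves)
                tables.write_table(
                    scaled.curves.reset_index(), out / "transition_scaled.csv",
                    "transition_scaled", cfg.seed,
                )
                outputs = [out / "transition.csv", out / "transition_scaled.csv"]

            manifest.record(
                stage, outputs, time.perf_counter() - t0, counter.count - w0
            )
        manifest.completed = True
    finally:
        logging.getLogger().removeHandler(counter)
        manifest.write(out / "manifest.json")
    return manifest


def _year_slice(surface: integration.GrowthSurface, year: int):
    """Sub-surface restricted to one year (cells keep their year key)."""
    def take(df):
        f = df.reset_index()
        f = f[f["year"] == year]
        return f.set_index(stgpr.CELL_KEYS)

    return integration.GrowthSurface(
        mean_z=take(surface.mean_z),
        sd_z=take(surface.sd_z),
        prevalence={k: take(v) for k, v in surface.prevalence.items()},
        thresholds=surface.thresholds,
        spec=surface.spec,
    )


def _transition_stage(cfg: RunConfig, surface, covs) -> pd.DataFrame:
    summ = integration.summarize(surface).reset_index()
    uhc_ly = covs.groupby(["location", "year"], as_index=False)[["uhc", "sdi"]].mean()
    pts = summ.merge(uhc_ly, on=["location", "year"])
    spline_cfg = transition.SplineConfig(
        n_submodels=cfg.transition_submodels, n_folds=cfg.transition_folds
    )
    curves = {}
    for sev in ("overall", "severe", "extreme"):
        fits = {}
        for (a, s), g in pts[pts.severity == sev].groupby(["age_group", "sex"]):
            g = g.rename(columns={"mean": "prevalence"})
            fits[(a, s)] = transition.fit_spline_ensemble(
                g[["uhc", "prevalence", "location"]], spline_cfg,
                seed=cfg.seed + 30,
            )
        curves[sev] = transition.aggregate_splines(fits, covs)
    return pd.DataFrame(curves)
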