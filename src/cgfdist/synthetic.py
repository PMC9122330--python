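"""Synthetic worlds with known truth for exercising the estimation pipeline.

Real inputs to this kind of analysis are survey microdata, tabulated
prevalence reports, covariate databases and population tables, none of which
can be bundled.  This module generates all of them from a configurable
ground-truth surface: a location hierarchy (super region / region / country),
smoothly drifting mean z-scores with optionally narrowing spread, hierarchical
random offsets, survey noise, and covariates that are monotone transforms of
the truth so that the covariate-selection stage has signal to find.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensembles import EnsembleSpec, ensemble_cdf, ensemble_rvs

__all__ = [
    "AGE_GROUPS",
    "SEXES",
    "LocationNode",
    "LocationHierarchy",
    "TrendConfig",
    "TrueSurface",
    "SurveySource",
    "make_hierarchy",
    "simulate_truth",
    "simulate_microdata",
    "simulate_tabulated",
    "simulate_covariates",
    "split_aggregated",
]

#: the six under-5 age bins used throughout
AGE_GROUPS = ("0-6d", "7-27d", "1-5m", "6-11m", "12-23m", "2-4y")
SEXES = ("male", "female")

#: approximate share of person-time under 5 spent in each age bin
_AGE_SHARES = {
    "0-6d": 0.004,
    "7-27d": 0.012,
    "1-5m": 0.084,
    "6-11m": 0.10,
    "12-23m": 0.20,
    "2-4y": 0.60,
}

LEVELS = ("global", "super_region", "region", "country")


@dataclass(frozen=True)
class LocationNode:
    location_id: str
    level: str
    parent_id: str | None


@dataclass(frozen=True)
class LocationHierarchy:
    """Three administrative levels beneath a single global root."""

    nodes: tuple[LocationNode, ...]

    def __post_init__(self):
        ids = [n.location_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate location_ids")
        roots = [n for n in self.nodes if n.level == "global"]
        if len(roots) != 1:
            raise ValueError("exactly one global root required")
        by_id = {n.location_id: n for n in self.nodes}
        for n in self.nodes:
            if n.level == "global":
                continue
            parent = by_id.get(n.parent_id)
            if parent is None or LEVELS.index(parent.level) != LEVELS.index(n.level) - 1:
                raise ValueError(f"{n.location_id}: parent must be one level up")

    def _by_level(self, level):
        return [n for n in self.nodes if n.level == level]

    @property
    def countries(self):
        return [n.location_id for n in self._by_level("country")]

    def parents(self, location_id: str) -> tuple[str, str]:
        """(region_id, super_region_id) of a country."""
        by_id = {n.location_id: n for n in self.nodes}
        region = by_id[location_id].parent_id
        super_region = by_id[region].parent_id
        return region, super_region

    def frame(self) -> pd.DataFrame:
        rows = []
        for c in self.countries:
            r, s = self.parents(c)
            rows.append((c, r, s))
        return pd.DataFrame(rows, columns=["location", "region", "super_region"])


def make_hierarchy(
    n_super: int, n_regions_per: int, n_countries_per: int, seed: int = 0
) -> LocationHierarchy:
    """Complete three-level location tree beneath a global root.

    ``seed`` is accepted for interface symmetry with the other generators;
    the tree itself is a deterministic function of the counts.
    """
    for name, v in [
        ("n_super", n_super),
        ("n_regions_per", n_regions_per),
        ("n_countries_per", n_countries_per),
    ]:
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    nodes = [LocationNode("G", "global", None)]
    for i in range(1, n_super + 1):
        sid = f"S{i}"
        nodes.append(LocationNode(sid, "super_region", "G"))
        for j in range(1, n_regions_per + 1):
            rid = f"{sid}R{j}"
            nodes.append(LocationNode(rid, "region", sid))
            for k in range(1, n_countries_per + 1):
                nodes.append(LocationNode(f"{rid}C{k}", "country", rid))
    return LocationHierarchy(tuple(nodes))


@dataclass(frozen=True)
class TrendConfig:
    """Ground-truth trend: linear-plus-random-walk on mean_z and log(sd_z).

    Defaults emulate a high-burden stunting setting whose distribution mean
    drifts from -1.88 to -1.65 over the study period while the spread
    narrows, with nested zero-mean random offsets at the super-region,
    region and country levels.
    """

    mean_start: float = -1.88
    mean_end: float = -1.65
    sd_start: float = 1.15
    sd_end: float = 1.00
    level_sd_mean: tuple[float, float, float] = (0.15, 0.10, 0.08)
    level_sd_logsd: tuple[float, float, float] = (0.04, 0.03, 0.03)
    rw_sd_mean: float = 0.01
    rw_sd_logsd: float = 0.004
    age_offsets: dict = field(
        default_factory=lambda: {
            "0-6d": 0.40,
            "7-27d": 0.35,
            "1-5m": 0.20,
            "6-11m": 0.00,
            "12-23m": -0.15,
            "2-4y": -0.10,
        }
    )
    sex_offsets: dict = field(
        default_factory=lambda: {"male": -0.05, "female": 0.05}
    )
    sd_floor: float = 0.05
    ensemble: EnsembleSpec = field(
        default_factory=lambda: EnsembleSpec(
            {"normal": 0.6, "weibull": 0.25, "gumbel": 0.15}
        )
    )

    def __post_init__(self):
        if self.sd_floor <= 0:
            raise ValueError("sd_floor must be positive")
        if min(self.sd_start, self.sd_end) <= self.sd_floor:
            raise ValueError("trend sd endpoints must stay above sd_floor")


@dataclass
class TrueSurface:
    """Known ground truth per (location, year, age_group, sex).

    ``frame`` is indexed by the four cell keys with columns ``mean_z`` and
    ``sd_z``; ``global_trend`` carries the shared year path of the mean so
    that tests can separate the common trend from location offsets.
    """

    frame: pd.DataFrame
    ensemble: EnsembleSpec
    global_trend: pd.Series
    location_offsets: pd.Series
    age_groups: tuple[str, ...]

    def cell(self, location, year, age_group, sex):
        return self.frame.loc[(location, year, age_group, sex)]

    def prevalence_below(self, threshold) -> pd.Series:
        """Closed-form true prevalence below ``threshold`` for every cell."""
        f = self.frame
        return pd.Series(
            ensemble_cdf(
                self.ensemble,
                (f["mean_z"].to_numpy(), f["sd_z"].to_numpy() ** 2),
                threshold,
            ),
            index=f.index,
            name=f"prev{abs(threshold):g}",
        )


def simulate_truth(
    hierarchy: LocationHierarchy,
    years=range(1990, 2021),
    trend_cfg: TrendConfig | None = None,
    seed: int = 0,
    age_groups=AGE_GROUPS,
) -> TrueSurface:
    """Simulate a smooth ground-truth surface over the full estimation grid.

    mean_z(l, y, a, s) = linear trend(y) + random walk_l(y)
                       + super/region/country offsets + age + sex offsets,
    and analogously for log sd_z (floored at ``sd_floor``).
    """
    cfg = trend_cfg if trend_cfg is not None else TrendConfig()
    years = np.array(sorted(years))
    frac = (years - years[0]) / max(years[-1] - years[0], 1)
    trend_mean = cfg.mean_start + frac * (cfg.mean_end - cfg.mean_start)
    trend_logsd = np.log(cfg.sd_start) + frac * (np.log(cfg.sd_end) - np.log(cfg.sd_start))

    rng = np.random.default_rng(seed)
    sup_ids = sorted({h.location_id for h in hierarchy.nodes if h.level == "super_region"})
    reg_ids = sorted({h.location_id for h in hierarchy.nodes if h.level == "region"})
    countries = hierarchy.countries
    off_m = {
        lid: rng.normal(0, sd)
        for sd, ids in zip(cfg.level_sd_mean, (sup_ids, reg_ids, countries))
        for lid in ids
    }
    off_s = {
        lid: rng.normal(0, sd)
        for sd, ids in zip(cfg.level_sd_logsd, (sup_ids, reg_ids, countries))
        for lid in ids
    }

    rows = []
    loc_offsets = {}
    for c in countries:
        region, sup = hierarchy.parents(c)
        base_m = off_m[sup] + off_m[region] + off_m[c]
        base_s = off_s[sup] + off_s[region] + off_s[c]
        loc_offsets[c] = base_m
        rw_m = np.cumsum(rng.normal(0, cfg.rw_sd_mean, len(years)))
        rw_s = np.cumsum(rng.normal(0, cfg.rw_sd_logsd, len(years)))
        for iy, y in enumerate(years):
            m_ly = trend_mean[iy] + base_m + rw_m[iy]
            s_ly = trend_logsd[iy] + base_s + rw_s[iy]
            for a in age_groups:
                for sx in SEXES:
                    rows.append(
                        (
                            c,
                            int(y),
                            a,
                            sx,
                            m_ly + cfg.age_offsets.get(a, 0.0) + cfg.sex_offsets.get(sx, 0.0),
                            max(np.exp(s_ly), cfg.sd_floor),
                        )
                    )
    frame = pd.DataFrame(
        rows, columns=["location", "year", "age_group", "sex", "mean_z", "sd_z"]
    ).set_index(["location", "year", "age_group", "sex"])
    return TrueSurface(
        frame=frame,
        ensemble=cfg.ensemble,
        global_trend=pd.Series(trend_mean, index=years, name="mean_z_trend"),
        location_offsets=pd.Series(loc_offsets, name="mean_offset"),
        age_groups=tuple(age_groups),
    )


@dataclass
class SurveySource:
    """One evidence source: either individual z-scores or tabulated prevalences."""

    source_id: str
    location_id: str
    year: int
    kind: str  # "microdata" | "tabulated"
    records: pd.DataFrame | None = None  # microdata: age_group, sex, z
    table: pd.DataFrame | None = None  # tabulated: age_group, sex, prev2, prev3, n

    def __post_init__(self):
        if self.kind not in ("microdata", "tabulated"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.kind == "tabulated" and self.table is not None and len(self.table):
            t = self.table
            if ((t.prev3 > t.prev2 + 1e-12) | (t.prev2 > 1) | (t.prev3 < 0)).any():
                raise ValueError("need 0 <= prev3 <= prev2 <= 1")
            if (t.n < 1).any():
                raise ValueError("sample sizes must be >= 1")


def _check_cells(truth: TrueSurface, cells):
    for cell in cells:
        if tuple(cell) not in truth.frame.index:
            raise KeyError(f"cell {cell!r} not in the truth surface")
    locs = {c[0] for c in cells}
    yrs = {c[1] for c in cells}
    if len(locs) != 1 or len(yrs) != 1:
        raise ValueError("a survey source covers a single location-year")
    return next(iter(locs)), next(iter(yrs))


def simulate_microdata(
    truth: TrueSurface, cells, n_per_cell: int, seed: int = 0, source_id=None
) -> SurveySource:
    """I.i.d. z-score draws from each cell's ensemble distribution."""
    loc, year = _check_cells(truth, cells)
    rng = np.random.default_rng(seed)
    frames = []
    for cell in cells:
        row = truth.frame.loc[tuple(cell)]
        z = ensemble_rvs(
            truth.ensemble, (row.mean_z, row.sd_z**2), int(n_per_cell), rng
        )
        frames.append(pd.DataFrame({"age_group": cell[2], "sex": cell[3], "z": z}))
    records = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["age_group", "sex", "z"])
    )
    return SurveySource(
        source_id=source_id or f"micro_{loc}_{year}_{seed}",
        location_id=loc,
        year=int(year),
        kind="microdata",
        records=records,
    )


def simulate_tabulated(
    truth: TrueSurface, cells, n: int, seed: int = 0, source_id=None
) -> SurveySource:
    """Binomial-style tabulated prevalences below -2 and -3 SD.

    A single trinomial draw over {below -3, between -3 and -2, above -2}
    guarantees prev3 <= prev2 on every draw without clipping.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    loc, year = _check_cells(truth, cells)
    rng = np.random.default_rng(seed)
    rows = []
    for cell in cells:
        row = truth.frame.loc[tuple(cell)]
        mom = (row.mean_z, row.sd_z**2)
        p3 = float(ensemble_cdf(truth.ensemble, mom, -3.0))
        p2 = float(ensemble_cdf(truth.ensemble, mom, -2.0))
        counts = rng.multinomial(n, [p3, p2 - p3, 1.0 - p2])
        rows.append(
            (cell[2], cell[3], (counts[0] + counts[1]) / n, counts[0] / n, n)
        )
    table = pd.DataFrame(rows, columns=["age_group", "sex", "prev2", "prev3", "n"])
    return SurveySource(
        source_id=source_id or f"tab_{loc}_{year}_{seed}",
        location_id=loc,
        year=int(year),
        kind="tabulated",
        table=table,
    )


def aggregate_tabulated(
    truth: TrueSurface, location, year, n: int, populations: pd.DataFrame, seed: int = 0
) -> SurveySource:
    """A both-sex, under-5 aggregated tabulated report for one location-year."""
    cells = [
        (location, year, a, s) for a in truth.age_groups for s in SEXES
    ]
    pops = populations.set_index(["location", "year", "age_group", "sex"])["population"]
    w = np.array([pops.loc[c] for c in cells], dtype=float)
    p2 = np.array(
        [
            float(
                ensemble_cdf(
                    truth.ensemble,
                    (truth.frame.loc[c].mean_z, truth.frame.loc[c].sd_z ** 2),
                    -2.0,
                )
            )
            for c in cells
        ]
    )
    p3 = np.array(
        [
            float(
                ensemble_cdf(
                    truth.ensemble,
                    (truth.frame.loc[c].mean_z, truth.frame.loc[c].sd_z ** 2),
                    -3.0,
                )
            )
            for c in cells
        ]
    )
    P2 = float(np.average(p2, weights=w))
    P3 = float(np.average(p3, weights=w))
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, [P3, P2 - P3, 1.0 - P2])
    table = pd.DataFrame(
        [
            (
                "under5",
                "both",
                (counts[0] + counts[1]) / n,
                counts[0] / n,
                n,
            )
        ],
        columns=["age_group", "sex", "prev2", "prev3", "n"],
    )
    return SurveySource(
        source_id=f"agg_{location}_{year}_{seed}",
        location_id=location,
        year=int(year),
        kind="tabulated",
        table=table,
    )


# ---------------------------------------------------------------------------
# covariates, UHC/SDI, populations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateConfig:
    """Covariates as monotone transforms of the truth mean plus noise.

    ``covariates`` maps name -> (direction, noise_sd): direction +1 means the
    covariate increases as growth outcomes improve (mean z rises).  A pure
    noise column can be added to give the selection step something to drop.
    """

    covariates: dict = field(
        default_factory=lambda: {
            "health_access": (1.0, 0.05),
            "sanitation": (1.0, 0.08),
            "noise_cov": (0.0, 1.0),
        }
    )
    uhc_noise_sd: float = 1.5
    sdi_noise_sd: float = 2.0
    pop_log_mean: float = np.log(2.0e6)
    pop_log_sd: float = 0.6


def simulate_covariates(
    truth: TrueSurface,
    hierarchy: LocationHierarchy,
    cfg: CovariateConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Covariate / UHC / SDI / population table on the full estimation grid.

    UHC and SDI are smooth monotone transforms of the country-year mean
    z-score (better growth <-> stronger health system), jittered and clipped
    to [0, 100]; populations are constant over time within a location with a
    fixed under-5 age composition and even sex split.
    """
    cfg = cfg if cfg is not None else CovariateConfig()
    rng = np.random.default_rng(seed)
    f = truth.frame.reset_index()
    loc_year = (
        f.groupby(["location", "year"])["mean_z"].mean().rename("m_ly").reset_index()
    )
    m = loc_year["m_ly"].to_numpy()
    lo, hi = m.min(), m.max()
    span = max(hi - lo, 1e-9)
    base01 = (m - lo) / span

    uhc = np.clip(
        15 + 70 * base01 + rng.normal(0, cfg.uhc_noise_sd, len(m)), 0.0, 100.0
    )
    sdi = np.clip(
        20 + 60 * base01 + rng.normal(0, cfg.sdi_noise_sd, len(m)), 0.0, 100.0
    )
    loc_year["uhc"] = uhc
    loc_year["sdi"] = sdi

    pops = {
        c: float(np.exp(rng.normal(cfg.pop_log_mean, cfg.pop_log_sd)))
        for c in hierarchy.countries
    }

    out = f[["location", "year", "age_group", "sex", "mean_z"]].merge(
        loc_year, on=["location", "year"]
    )
    for name, (direction, noise_sd) in cfg.covariates.items():
        out[name] = direction * out["mean_z"] + rng.normal(0, noise_sd, len(out))
    out["population"] = [
        pops[l] * _AGE_SHARES.get(a, 1.0 / 6) * 0.5
        for l, a in zip(out["location"], out["age_group"])
    ]
    return out.drop(columns=["mean_z", "m_ly"])


def expected_covariate_signs(cfg: CovariateConfig | None = None) -> dict:
    """A priori expected coefficient signs (on the mean-z scale) per covariate."""
    cfg = cfg if cfg is not None else CovariateConfig()
    return {
        name: (1.0 if direction > 0 else -1.0)
        for name, (direction, _) in cfg.covariates.items()
        if direction != 0.0
    }


# ---------------------------------------------------------------------------
# age-sex splitting of aggregated reports
# ---------------------------------------------------------------------------


def split_aggregated(
    aggregate: SurveySource, pattern, populations: pd.DataFrame
) -> SurveySource:
    """Split a both-sex under-5 prevalence into age-sex-specific values.

    The split follows the age-sex pattern's prevalence ratios, rescaled so
    the population-weighted mean of the split values reproduces the
    aggregate exactly.  ``pattern`` is a :class:`TrueSurface` (prevalence
    evaluated from its ensemble) or a frame indexed by cell with ``prev2``
    and ``prev3`` columns.
    """
    if aggregate.kind != "tabulated" or len(aggregate.table) != 1:
        raise ValueError("aggregate must be a single-row tabulated source")
    agg = aggregate.table.iloc[0]
    if agg.age_group != "under5" or agg.sex != "both":
        raise ValueError("aggregate must be a both-sex under-5 record")
    loc, year = aggregate.location_id, aggregate.year

    if isinstance(pattern, TrueSurface):
        cells = [(loc, year, a, s) for a in pattern.age_groups for s in SEXES]
        pat = pd.DataFrame(
            {
                "prev2": pattern.prevalence_below(-2.0).loc[cells].to_numpy(),
                "prev3": pattern.prevalence_below(-3.0).loc[cells].to_numpy(),
            },
            index=pd.MultiIndex.from_tuples(
                cells, names=["location", "year", "age_group", "sex"]
            ),
        )
    else:
        pat = pattern
        cells = list(pat.index)

    pops = populations.set_index(["location", "year", "age_group", "sex"])["population"]
    w = np.array([pops.loc[c] for c in cells], dtype=float)
    if w.sum() <= 0:
        raise ValueError("zero total population")

    rows = []
    split = {}
    for col, target in [("prev2", agg.prev2), ("prev3", agg.prev3)]:
        p = pat[col].to_numpy(dtype=float)
        wmean = float(np.average(p, weights=w))
        if wmean <= 0:
            if target > 0:
                raise ValueError(
                    f"pattern has zero {col} everywhere but aggregate is positive"
                )
            split[col] = np.zeros_like(p)
        else:
            split[col] = p * (target / wmean)
    n_split = np.maximum(1, np.round(agg.n * w / w.sum())).astype(int)
    for i, cell in enumerate(cells):
        rows.append(
            (
                cell[2],
                cell[3],
                split["prev2"][i],
                min(split["prev3"][i], split["prev2"][i]),
                int(n_split[i]),
            )
        )
    table = pd.DataFrame(rows, columns=["age_group", "sex", "prev2", "prev3", "n"])
    return SurveySource(
        source_id=f"{aggregate.source_id}_split",
        location_id=loc,
        year=year,
        kind="tabulated",
        table=table,
    )
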