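"""Relative-change metrics, UHC-direction annual changes, and KS comparisons.

Relative change since a reference year is computed at the draw level from
age- and sex-specific prevalence draws and aggregated to a both-sex under-5
value with population weights.  Because draws of prevalence can approach
zero in low-burden settings -- making ratios explode and the mean
unrepresentative -- change summaries report the median with a 95%
uncertainty interval, and draws whose reference prevalence is numerically
zero are dropped (counted).

Sign convention: positive values denote decreases in prevalence
(improvement); change = (reference - current) / reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .integration import GrowthSurface

logger = logging.getLogger(__name__)

__all__ = [
    "ChangeDraws",
    "ChangeFilters",
    "relative_change",
    "summarize_change",
    "annual_changes",
    "ks_two_sample",
]

SIGN_CONVENTION = "positive=improvement (prevalence decrease)"


@dataclass
class ChangeDraws:
    """Draw-level relative change per location (both sexes, under 5)."""

    draws: pd.DataFrame  # index: location; columns: draw_*
    n_dropped: int
    sign_convention: str = SIGN_CONVENTION


def _pop_lookup(populations: pd.DataFrame) -> pd.Series:
    return populations.set_index(["location", "year", "age_group", "sex"])[
        "population"
    ]


def _cell_pops(cells: pd.MultiIndex, pops: pd.Series) -> np.ndarray:
    return np.array([pops.loc[tuple(c)] for c in cells], dtype=float)


def relative_change(
    current: GrowthSurface,
    reference: GrowthSurface,
    populations: pd.DataFrame,
    severity: str = "overall",
    ref_floor: float = 1e-9,
) -> ChangeDraws:
    """Draw-level relative change in prevalence between two surfaces.

    Per draw and age-sex cell the ratio current/reference is formed, and the
    draw-level change values ``1 - ratio`` are aggregated to a both-sex
    under-5 value per location using age- and sex-specific population
    weights.  Cell-draws whose reference prevalence is below ``ref_floor``
    are dropped from the aggregation (their count is logged and returned).
    """
    cur = current.prevalence[severity]
    ref = reference.prevalence[severity]
    if cur.shape[1] != ref.shape[1]:
        raise ValueError("surfaces must be draw-aligned")

    cur_f = cur.reset_index()
    ref_f = ref.reset_index()
    draw_cols = [c for c in cur.columns]
    merged = cur_f.merge(
        ref_f,
        on=["location", "age_group", "sex"],
        suffixes=("_cur", "_ref"),
    )
    if merged.empty:
        raise ValueError("no common (location, age_group, sex) cells")

    pops = _pop_lookup(populations)
    year_cur = merged["year_cur"] if "year_cur" in merged else merged["year"]
    w = np.array(
        [
            pops.loc[(l, int(y), a, s)]
            for l, y, a, s in zip(
                merged["location"], year_cur, merged["age_group"], merged["sex"]
            )
        ],
        dtype=float,
    )
    if w.sum() <= 0:
        raise ValueError("zero total population")

    cur_m = merged[[f"{c}_cur" for c in draw_cols]].to_numpy()
    ref_m = merged[[f"{c}_ref" for c in draw_cols]].to_numpy()
    valid = ref_m >= ref_floor
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("relative_change: dropped %d cell-draws with reference "
                    "prevalence < %g", n_dropped, ref_floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        change = np.where(valid, 1.0 - cur_m / np.where(valid, ref_m, 1.0), np.nan)

    out = {}
    for loc, idx in merged.groupby("location").indices.items():
        ch = change[idx]
        ww = w[idx][:, None] * np.isfinite(ch)
        num = np.nansum(ch * w[idx][:, None], axis=0)
        den = ww.sum(axis=0)
        out[loc] = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    draws = pd.DataFrame.from_dict(out, orient="index", columns=draw_cols)
    draws.index.name = "location"
    return ChangeDraws(draws.sort_index(), n_dropped)


def summarize_change(draws: ChangeDraws) -> pd.DataFrame:
    """Median and 2.5th/97.5th percentiles of the change draws per location.

    The median (not the mean) is the point estimate: near-zero reference
    draws produce heavy right-skew in ratios, and the median better
    represents the commonly estimated values.
    """
    d = draws.draws.to_numpy()
    if d.shape[1] < 2:
        raise ValueError("need at least 2 draws")
    return pd.DataFrame(
        {
            "median": np.nanmedian(d, axis=1),
            "lower": np.nanpercentile(d, 2.5, axis=1),
            "upper": np.nanpercentile(d, 97.5, axis=1),
        },
        index=draws.draws.index,
    )


@dataclass(frozen=True)
class ChangeFilters:
    """Inclusion filters for the annual-change analysis."""

    prev_floor: float = 1e-6  # one per million, on the both-sex under-5 mean
    min_population: float = 300_000.0
    uhc_tie_tol: float = 1e-9

    severities: tuple[str, ...] = ("overall", "severe", "extreme")


def _aggregate_prev_draws(surface, severity, populations, year):
    """Both-sex under-5 prevalence draws per location for one year."""
    prev = surface.prevalence[severity]
    f = prev.reset_index()
    f = f[f["year"] == year]
    pops = _pop_lookup(populations)
    out, pop_tot = {}, {}
    draw_cols = list(prev.columns)
    for loc, sub in f.groupby("location"):
        w = np.array(
            [
                pops.loc[(loc, year, a, s)]
                for a, s in zip(sub["age_group"], sub["sex"])
            ],
            dtype=float,
        )
        d = sub[draw_cols].to_numpy()
        out[loc] = np.average(d, axis=0, weights=w)
        pop_tot[loc] = float(w.sum())
    return out, pop_tot


def annual_changes(
    surface: GrowthSurface,
    uhc: pd.DataFrame,
    populations: pd.DataFrame,
    filters: ChangeFilters | None = None,
) -> pd.DataFrame:
    """Annual relative changes labeled by the direction of UHC change.

    For every location-year from 1991 to 2019 with a prior-year estimate,
    the draw-level relative change versus the prior year is computed (both
    sexes, under 5) and its median recorded, labeled ``improved`` when the
    location's UHC index rose versus the previous year and ``worsened`` when
    it fell; exact ties are excluded.  Location-years are retained only when
    the severity's mean prevalence exceeds ``prev_floor`` (one per million by
    default) and the under-5 population exceeds ``min_population``.
    """
    filters = filters or ChangeFilters()
    years = sorted(surface.mean_z.reset_index()["year"].unique())
    uhc_ly = uhc.groupby(["location", "year"])["uhc"].mean()

    records = []
    cache: dict[tuple[str, int], tuple[dict, dict]] = {}

    def agg(severity, year):
        key = (severity, year)
        if key not in cache:
            cache[key] = _aggregate_prev_draws(surface, severity, populations, year)
        return cache[key]

    for year in years:
        if not (1991 <= year <= 2019):
            continue
        if year - 1 not in years:
            logger.info("annual_changes: no prior-year estimate for %d", year)
            continue
        for severity in filters.severities:
            cur, pop_tot = agg(severity, year)
            ref, _ = agg(severity, year - 1)
            for loc, cur_draws in cur.items():
                if loc not in ref:
                    continue
                if pop_tot.get(loc, 0.0) <= filters.min_population:
                    continue
                if float(np.mean(cur_draws)) <= filters.prev_floor:
                    continue
                try:
                    duhc = float(uhc_ly.loc[(loc, year)] - uhc_ly.loc[(loc, year - 1)])
                except KeyError:
                    continue
                if abs(duhc) < filters.uhc_tie_tol:
                    continue
                ref_draws = ref[loc]
                valid = ref_draws >= 1e-9
                if not valid.any():
                    continue
                change = 1.0 - cur_draws[valid] / ref_draws[valid]
                records.append(
                    (
                        loc,
                        int(year),
                        severity,
                        float(np.median(change)),
                        "improved" if duhc > 0 else "worsened",
                    )
                )
    return pd.DataFrame(
        records,
        columns=["location", "year", "severity", "annual_change", "uhc_direction"],
    )


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value.

    D is the supremum absolute difference between the two empirical CDFs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
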