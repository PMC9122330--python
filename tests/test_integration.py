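"""SD recovery and multi-severity prevalence integration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cgfdist.ensembles import EnsembleSpec, prevalence_below
from cgfdist.integration import (
    GrowthSurface,
    SeverityThresholds,
    integrate_surface,
    optimize_sd,
    optimize_sd_batch,
    severity_share,
    summarize,
)


def _draw_frame(values, n_draws=None, cells=None):
    values = np.atleast_2d(values)
    if cells is None:
        cells = pd.MultiIndex.from_tuples(
            [("C1", 2000, "2-4y", "male")][: values.shape[0]]
            if values.shape[0] == 1
            else [("C1", 2000 + i, "2-4y", "male") for i in range(values.shape[0])],
            names=["location", "year", "age_group", "sex"],
        )
    cols = [f"draw_{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=cells, columns=cols)


class TestThresholds:
    def test_defaults_strictly_decreasing(self):
        t = SeverityThresholds()
        assert t.auxiliary > t.overall > t.severe > t.extreme

    def test_rejects_misordered(self):
        with pytest.raises(ValueError):
            SeverityThresholds(overall=-3.0, severe=-2.0)


class TestOptimizeSd:
    def test_normal_analytic_case(self):
        spec = EnsembleSpec.single("normal")
        sd = optimize_sd(spec, -2.0, 0.5, 0.15866)
        assert sd == pytest.approx(1.0, abs=1e-4)

    def test_round_trip_recovery(self):
        spec = EnsembleSpec({"normal": 0.5, "gamma": 0.3, "gumbel": 0.2})
        true_sd, mean = 1.2, -1.7
        t2 = float(prevalence_below(spec, (mean, true_sd**2), -2.0))
        t3 = float(prevalence_below(spec, (mean, true_sd**2), -3.0))
        assert optimize_sd(spec, mean, t2, t3) == pytest.approx(true_sd, abs=1e-3)

    def test_inconsistent_targets_rejected(self):
        spec = EnsembleSpec.single("normal")
        with pytest.raises(ValueError):
            optimize_sd(spec, -2.0, 0.1, 0.2)

    def test_misspecified_family_beats_single_family_grid(self):
        """Targets from a Gumbel curve, fit with a normal-heavy ensemble:
        residual error exists but stays below the best single-family-at-
        fixed-sd grid search error at each threshold."""
        truth_spec = EnsembleSpec.single("gumbel")
        mean, sd = -1.5, 1.0
        t2 = float(prevalence_below(truth_spec, (mean, sd**2), -2.0))
        t3 = float(prevalence_below(truth_spec, (mean, sd**2), -3.0))
        fit_spec = EnsembleSpec({"normal": 0.9, "lognormal": 0.1})
        sd_hat = optimize_sd(fit_spec, mean, t2, t3)
        e2 = abs(float(prevalence_below(fit_spec, (mean, sd_hat**2), -2.0)) - t2)
        e3 = abs(float(prevalence_below(fit_spec, (mean, sd_hat**2), -3.0)) - t3)
        # grid-search the worst single candidate family at its own best sd
        worst = []
        for fam_name in ("normal", "lognormal"):
            single = EnsembleSpec.single(fam_name)
            grid = np.linspace(0.05, 5, 400)
            errs = [
                abs(float(prevalence_below(single, (mean, s**2), -2.0)) - t2)
                + abs(float(prevalence_below(single, (mean, s**2), -3.0)) - t3)
                for s in grid
            ]
            worst.append(min(errs))
        assert e2 + e3 <= max(worst) + 1e-9
        assert e2 + e3 > 0

    def test_batch_agrees_with_scalar(self):
        spec = EnsembleSpec(
            {"normal": 0.4, "weibull": 0.3, "mirrored_gamma": 0.3}
        )
        rng = np.random.default_rng(0)
        means = rng.uniform(-2.5, -0.5, 30)
        sds = rng.uniform(0.3, 2.5, 30)
        t2 = prevalence_below(spec, (means, sds**2), -2.0)
        t3 = prevalence_below(spec, (means, sds**2), -3.0)
        batch = optimize_sd_batch(spec, means, t2, t3)
        for i in range(0, 30, 7):
            scalar = optimize_sd(spec, means[i], float(t2[i]), float(t3[i]))
            assert batch[i] == pytest.approx(scalar, abs=1e-3)


class TestIntegrateSurface:
    def test_identical_draws_identical_outputs(self):
        spec = EnsembleSpec.single("normal")
        m = _draw_frame(np.full((1, 8), -1.8))
        p2 = _draw_frame(np.full((1, 8), 0.42))
        p3 = _draw_frame(np.full((1, 8), 0.13))
        surf = integrate_surface(spec, m, p2, p3)
        for name, draws in surf.prevalence.items():
            assert draws.to_numpy().std() == pytest.approx(0.0, abs=1e-12)

    def test_severity_ordering_every_draw(self):
        spec = EnsembleSpec({"normal": 0.5, "weibull": 0.5})
        rng = np.random.default_rng(1)
        m = _draw_frame(rng.uniform(-2.5, -1, (5, 20)))
        sd_true = rng.uniform(0.8, 1.5, (5, 20))
        p2 = _draw_frame(prevalence_below(spec, (m.to_numpy(), sd_true**2), -2.0),
                         cells=m.index)
        p3 = _draw_frame(prevalence_below(spec, (m.to_numpy(), sd_true**2), -3.0),
                         cells=m.index)
        surf = integrate_surface(spec, m, p2, p3)
        assert (
            surf.prevalence["extreme"].to_numpy()
            <= surf.prevalence["severe"].to_numpy() + 1e-12
        ).all()
        assert (
            surf.prevalence["severe"].to_numpy()
            <= surf.prevalence["overall"].to_numpy() + 1e-12
        ).all()

    def test_normal_closed_form_at_minus_four(self):
        spec = EnsembleSpec.single("normal")
        mean, sd = -1.9, 1.1
        p2 = float(stats.norm.cdf(-2, mean, sd))
        p3 = float(stats.norm.cdf(-3, mean, sd))
        m = _draw_frame(np.full((1, 4), mean))
        surf = integrate_surface(
            spec, m, _draw_frame(np.full((1, 4), p2)),
            _draw_frame(np.full((1, 4), p3)),
        )
        expected = stats.norm.cdf(-4, mean, sd)
        got = surf.prevalence["extreme"].to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_prevalence_equals_weighted_cdf_sum(self):
        """Threshold prevalence is the closed-form weighted CDF (no
        quadrature residual)."""
        spec = EnsembleSpec({"normal": 0.6, "gamma": 0.4})
        m = _draw_frame(np.full((1, 3), -1.5))
        p2 = _draw_frame(np.full((1, 3), 0.3))
        p3 = _draw_frame(np.full((1, 3), 0.08))
        surf = integrate_surface(spec, m, p2, p3)
        sd = surf.sd_z.to_numpy()
        for name, t in surf.thresholds.named().items():
            direct = prevalence_below(spec, (m.to_numpy(), sd**2), t)
            np.testing.assert_allclose(
                surf.prevalence[name].to_numpy(), direct, atol=1e-9
            )

    def test_mismatched_indexes_rejected(self):
        spec = EnsembleSpec.single("normal")
        m = _draw_frame(np.full((1, 3), -1.5))
        other = m.copy()
        other.index = pd.MultiIndex.from_tuples(
            [("C2", 2000, "2-4y", "male")], names=m.index.names
        )
        with pytest.raises(ValueError):
            integrate_surface(spec, m, other, other)


class TestSummarize:
    def _surface(self, draws):
        spec = EnsembleSpec.single("normal")
        d = _draw_frame(draws)
        return GrowthSurface(d, d * 0 + 1, {"overall": d}, SeverityThresholds(), spec)

    def test_constant_draws(self):
        s = summarize(self._surface(np.full((1, 10), 0.3)))
        row = s.iloc[0]
        assert row["mean"] == pytest.approx(0.3)
        assert row["lower"] == pytest.approx(0.3)
        assert row["upper"] == pytest.approx(0.3)

    def test_percentiles_match_order_statistics(self):
        vals = (np.arange(1, 1001) / 1000.0)[None, :]
        s = summarize(self._surface(vals))
        row = s.iloc[0]
        assert row["lower"] == pytest.approx(np.percentile(np.sort(vals[0]), 2.5))
        assert row["upper"] == pytest.approx(np.percentile(np.sort(vals[0]), 97.5))
        assert row["mean"] == pytest.approx(vals.mean())

    def test_permutation_invariant(self):
        rng = np.random.default_rng(2)
        vals = rng.random((1, 200))
        a = summarize(self._surface(vals))
        b = summarize(self._surface(vals[:, rng.permutation(200)]))
        pd.testing.assert_frame_equal(a, b)

    def test_requires_two_draws(self):
        with pytest.raises(ValueError):
            summarize(self._surface(np.full((1, 1), 0.5)))


def test_interval_width_shrinks_with_data_noise():
    """Lower survey noise propagates into narrower final prevalence
    intervals (two noise levels through the GP + integration chain)."""
    from cgfdist.stgpr import CELL_KEYS, gpr_stage

    cells = [("C1", y, "2-4y", "male") for y in range(2000, 2011)]
    index = pd.MultiIndex.from_tuples(cells, names=CELL_KEYS)
    spec = EnsembleSpec.single("normal")
    widths = {}
    for noise in (0.02, 0.4):
        fits = {}
        for ind, level in [("mean", -1.8), ("prev2", 0.42), ("prev3", 0.13)]:
            transform = "identity" if ind == "mean" else "logit"
            stage2 = pd.Series(
                level if ind == "mean" else np.log(level / (1 - level)),
                index=index,
            )
            data = pd.DataFrame(
                [("C1", y, "2-4y", "male", level, noise**2, 100)
                 for y in range(2000, 2011, 3)],
                columns=CELL_KEYS + ["value", "variance", "sample_size"],
            )
            fits[ind] = gpr_stage(
                stage2, data, {"amplitude": 0.1}, n_draws=300, seed=1,
                transform=transform,
            )
        surf = integrate_surface(
            spec, fits["mean"].draws, fits["prev2"].draws, fits["prev3"].draws
        )
        s = summarize(surf).xs("overall", level="severity")
        widths[noise] = float((s["upper"] - s["lower"]).mean())
    assert widths[0.02] < widths[0.4]


class TestSeverityShare:
    def test_identity(self):
        assert severity_share(0.3, 0.3) == pytest.approx(1.0)

    def test_zero_overall_rejected(self):
        with pytest.raises(ValueError):
            severity_share(0.0, 0.0)

    def test_subset_cannot_exceed_overall(self):
        with pytest.raises(ValueError):
            severity_share(0.2, 0.3)

    def test_draw_level(self):
        overall = np.array([0.4, 0.5])
        subset = np.array([0.1, 0.2])
        np.testing.assert_allclose(
            severity_share(overall, subset), [0.25, 0.4]
        )
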