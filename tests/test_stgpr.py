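"""Three-stage spatiotemporal Gaussian process regression."""

import numpy as np
import pandas as pd
import pytest

from cgfdist import stgpr, synthetic as syn
from cgfdist.stgpr import (
    CELL_KEYS,
    StgprHyperparams,
    fit_stage1,
    gpr_stage,
    prepare_observations,
    select_hyperparams,
    smooth_spatiotemporal,
    transform_back,
    transform_forward,
)


def test_transform_round_trip():
    p = np.array([1e-6, 1e-3, 0.5, 0.999, 1 - 1e-6])
    np.testing.assert_allclose(
        transform_back(transform_forward(p, "logit"), "logit"), p, atol=1e-12
    )
    x = np.array([-3.0, 0.0, 2.5])
    np.testing.assert_allclose(
        transform_back(transform_forward(x, "identity"), "identity"), x
    )


def test_hyperparams_validated():
    with pytest.raises(ValueError):
        StgprHyperparams(zeta=1.5, lam=1, omega=1)
    with pytest.raises(ValueError):
        StgprHyperparams(zeta=0.5, lam=0, omega=1)


class TestPrepareObservations:
    def test_microdata_mean_and_prevalence(self, small_world):
        _, truth, _, sources = small_world
        for ind in ("mean", "prev2", "prev3"):
            obs = prepare_observations(sources, ind)
            assert set(CELL_KEYS) < set(obs.columns)
            assert (obs["variance"] > 0).all()
            if ind != "mean":
                assert obs["value"].between(0, 1).all()

    def test_tabulated_excluded_from_mean(self, small_world):
        _, _, _, sources = small_world
        tab_only = [s for s in sources if s.kind == "tabulated"]
        assert prepare_observations(tab_only, "mean").empty
        assert not prepare_observations(tab_only, "prev2").empty


class TestStage1:
    def test_informative_covariate_recovers_truth(self, small_world):
        hierarchy, truth, covs, sources = small_world
        data = prepare_observations(sources, "mean")
        prior = fit_stage1(
            data, covs, hierarchy, {"health_access": 1.0}, seed=0
        )
        assert not prior.fallback
        joined = prior.prediction.rename("prior").to_frame().join(
            truth.frame["mean_z"]
        )
        corr = joined["prior"].corr(joined["mean_z"])
        assert corr > 0.9

    def test_wrong_sign_covariate_dropped(self, small_world):
        hierarchy, _, covs, sources = small_world
        data = prepare_observations(sources, "mean")
        prior = fit_stage1(
            data, covs, hierarchy, {"health_access": -1.0}, seed=0
        )
        assert prior.fallback
        assert not prior.models[0].retained
        assert "wrong sign" in prior.models[0].reason

    def test_fallback_predicts_hierarchical_means(self):
        hierarchy = syn.make_hierarchy(1, 1, 2, seed=0)
        rng = np.random.default_rng(0)
        rows = []
        for loc, mu in [("S1R1C1", -1.0), ("S1R1C2", -2.0)]:
            for y in range(2000, 2010):
                rows.append((loc, y, "2-4y", "male",
                             mu + rng.normal(0, 0.01), 1e-4, 100))
        data = pd.DataFrame(
            rows, columns=CELL_KEYS + ["value", "variance", "sample_size"]
        )
        covs = data[CELL_KEYS].copy()
        covs["noise_cov"] = rng.normal(size=len(covs))
        prior = fit_stage1(data, covs, hierarchy, {"noise_cov": 1.0}, seed=1)
        pred = prior.prediction
        assert pred.xs("S1R1C1", level="location").mean() == pytest.approx(
            -1.0, abs=0.1
        )
        assert pred.xs("S1R1C2", level="location").mean() == pytest.approx(
            -2.0, abs=0.1
        )


def _toy_prior(cells):
    index = pd.MultiIndex.from_tuples(cells, names=CELL_KEYS)
    return pd.Series(0.0, index=index)


class TestStage2:
    def test_zero_residuals_returns_prior(self, small_hierarchy):
        cells = [("S1R1C1", y, "2-4y", "male") for y in (2000, 2001)]
        prior = _toy_prior(cells) + 0.7
        resid = pd.DataFrame(columns=CELL_KEYS + ["residual"])
        hp = StgprHyperparams(0.5, 1.0, 2.0)
        out = smooth_spatiotemporal(resid, prior, small_hierarchy, hp)
        pd.testing.assert_series_equal(out, prior)

    def test_same_cell_unit_weight(self, small_hierarchy):
        cells = [("S1R1C1", 2000, "2-4y", "male")]
        prior = _toy_prior(cells) + 0.2
        resid = pd.DataFrame(
            [("S1R1C1", 2000, "2-4y", "male", 0.5)],
            columns=CELL_KEYS + ["residual"],
        )
        hp = StgprHyperparams(0.5, 1.0, 2.0)
        out = smooth_spatiotemporal(resid, prior, small_hierarchy, hp)
        assert out.iloc[0] == pytest.approx(0.7, abs=1e-15)

    def test_matches_hand_computed_weighted_mean(self, small_hierarchy):
        """Brute-force product weights on a 3-observation toy grid."""
        cells = [
            ("S1R1C1", y, a, "male")
            for y in (2000, 2001, 2002)
            for a in ("6-11m", "12-23m")
        ]
        prior = _toy_prior(cells)
        obs = [
            ("S1R1C1", 2000, "6-11m", "male", 0.5),
            ("S1R1C2", 2002, "6-11m", "male", -0.3),
            ("S2R1C1", 2001, "12-23m", "male", 0.2),
        ]
        resid = pd.DataFrame(obs, columns=CELL_KEYS + ["residual"])
        zeta, lam, omega = 0.6, 1.3, 1.7
        hp = StgprHyperparams(zeta, lam, omega)
        out = smooth_spatiotemporal(
            resid, prior, small_hierarchy, hp, age_order=["6-11m", "12-23m"]
        )

        hier = small_hierarchy.frame().set_index("location")
        max_dt = 2.0
        age_rank = {"6-11m": 0, "12-23m": 1}
        for cell in cells:
            num = den = 0.0
            for loc, y, a, s, r in obs:
                if loc == cell[0]:
                    sw = 1.0
                elif hier.loc[loc, "region"] == hier.loc[cell[0], "region"]:
                    sw = zeta
                elif (
                    hier.loc[loc, "super_region"]
                    == hier.loc[cell[0], "super_region"]
                ):
                    sw = zeta**2
                else:
                    sw = 0.0
                tw = (1 - (abs(y - cell[1]) / (1 + max_dt)) ** lam) ** 3
                aw = omega ** (-abs(age_rank[a] - age_rank[cell[2]]))
                w = sw * tw * aw
                num += w * r
                den += w
            expected = num / den if den > 0 else 0.0
            assert out.loc[cell] == pytest.approx(expected, abs=1e-12)

    def test_output_within_residual_hull(self, small_hierarchy):
        """Stage 2 never extrapolates beyond the prior-corrected range."""
        cells = [("S1R1C1", y, "2-4y", "male") for y in range(2000, 2010)]
        prior = _toy_prior(cells)
        rng = np.random.default_rng(0)
        resid = pd.DataFrame(
            [(c[0], c[1], c[2], c[3], rng.normal()) for c in cells[::2]],
            columns=CELL_KEYS + ["residual"],
        )
        hp = StgprHyperparams(0.9, 0.8, 1.5)
        out = smooth_spatiotemporal(resid, prior, small_hierarchy, hp)
        assert out.max() <= resid["residual"].max() + 1e-12
        assert out.min() >= resid["residual"].min() - 1e-12


def _series_cells(loc="S1R1C1", years=range(2000, 2011)):
    return [(loc, int(y), "2-4y", "male") for y in years]


class TestGprStage:
    def test_no_data_draws_around_stage2(self):
        cells = _series_cells()
        stage2 = _toy_prior(cells) - 1.5
        data = pd.DataFrame(columns=CELL_KEYS + ["value", "variance",
                                                 "sample_size"])
        fit = gpr_stage(stage2, data, {"amplitude": 0.2}, n_draws=4000, seed=0)
        d = fit.draws.to_numpy()
        assert np.allclose(d.mean(axis=1), -1.5, atol=0.02)
        assert np.allclose(d.std(axis=1), 0.2, atol=0.02)

    def test_interpolates_exact_observation(self):
        cells = _series_cells()
        stage2 = _toy_prior(cells)
        data = pd.DataFrame(
            [("S1R1C1", 2005, "2-4y", "male", 0.8, 1e-12, 100)],
            columns=CELL_KEYS + ["value", "variance", "sample_size"],
        )
        fit = gpr_stage(stage2, data, {"amplitude": 0.3}, n_draws=500, seed=1)
        summ = fit.summary()
        assert summ.loc[("S1R1C1", 2005, "2-4y", "male"), "mean"] == pytest.approx(
            0.8, abs=1e-3
        )
        # the posterior mean itself (not the draw average) hits the datum
        mean_at_obs = fit.draws.loc[("S1R1C1", 2005, "2-4y", "male")].mean()
        assert abs(mean_at_obs - 0.8) < 5e-3

    def test_draw_mean_matches_analytic_posterior(self):
        """Conjugate single-observation GP: draw average equals the
        closed-form posterior mean within Monte-Carlo error."""
        cells = _series_cells(years=range(2000, 2006))
        stage2 = _toy_prior(cells)
        amp, ls, noise = 0.5, 3.0, 0.1
        data = pd.DataFrame(
            [("S1R1C1", 2002, "2-4y", "male", 1.0, noise, 10)],
            columns=CELL_KEYS + ["value", "variance", "sample_size"],
        )
        n_draws = 8000
        fit = gpr_stage(
            stage2, data, {"amplitude": amp, "length_scale": ls},
            n_draws=n_draws, seed=2,
        )
        years = np.arange(2000, 2006, dtype=float)
        k = stgpr._matern52(years, np.array([2002.0]), ls)[:, 0] * amp**2
        post_mean = k / (amp**2 + noise) * 1.0
        post_var = amp**2 - k**2 / (amp**2 + noise)
        got = fit.draws.to_numpy().mean(axis=1)
        mc_se = np.sqrt(post_var / n_draws)
        assert np.all(np.abs(got - post_mean) < 4 * mc_se + 1e-9)

    def test_logit_transform_keeps_draws_in_unit_interval(self):
        cells = _series_cells()
        stage2 = _toy_prior(cells) - 1.0  # logit space
        data = pd.DataFrame(
            [("S1R1C1", 2003, "2-4y", "male", 0.3, 0.001, 500)],
            columns=CELL_KEYS + ["value", "variance", "sample_size"],
        )
        fit = gpr_stage(stage2, data, {"amplitude": 0.5}, n_draws=200, seed=3,
                        transform="logit")
        d = fit.draws.to_numpy()
        assert ((d > 0) & (d < 1)).all()
        summ = fit.summary()
        assert (summ["lower"] <= summ["upper"]).all()

    def test_rejects_nonpositive_variance(self):
        cells = _series_cells()
        stage2 = _toy_prior(cells)
        data = pd.DataFrame(
            [("S1R1C1", 2003, "2-4y", "male", 0.3, 0.0, 500)],
            columns=CELL_KEYS + ["value", "variance", "sample_size"],
        )
        with pytest.raises(ValueError):
            gpr_stage(stage2, data, n_draws=10, seed=0)


class TestHyperparamSelection:
    def test_grid_of_one(self, small_world):
        hierarchy, _, _, sources = small_world
        data = prepare_observations(sources, "mean")
        cells = data[CELL_KEYS].drop_duplicates()
        prior = pd.Series(
            -1.5, index=pd.MultiIndex.from_frame(cells)
        )
        hp = StgprHyperparams(0.5, 1.0, 2.0)
        assert select_hyperparams([hp], data, prior, hierarchy, seed=0) is hp

    def test_deterministic_given_seed(self, small_world):
        hierarchy, _, _, sources = small_world
        data = prepare_observations(sources, "mean")
        cells = data[CELL_KEYS].drop_duplicates()
        prior = pd.Series(-1.5, index=pd.MultiIndex.from_frame(cells))
        grid = [
            StgprHyperparams(z, l, 1.5) for z in (0.3, 0.9) for l in (0.5, 2.0)
        ]
        a = select_hyperparams(grid, data, prior, hierarchy, seed=7)
        b = select_hyperparams(grid, data, prior, hierarchy, seed=7)
        assert a == b


def test_rmse_improves_with_sample_size(small_hierarchy):
    """Final-estimate error shrinks as per-cell survey sample size grows
    tenfold (three sizes)."""
    truth = syn.simulate_truth(
        small_hierarchy, range(2000, 2011), seed=4, age_groups=("2-4y",)
    )
    covs = syn.simulate_covariates(truth, small_hierarchy, seed=5)
    signs = syn.expected_covariate_signs()
    rmses = []
    for n in (20, 200, 2000):
        rng = np.random.default_rng(n)
        sources = [
            syn.simulate_microdata(
                truth,
                [(c, y, "2-4y", s) for s in syn.SEXES],
                n,
                seed=int(rng.integers(2**31)),
            )
            for i, c in enumerate(small_hierarchy.countries)
            for y in range(2000, 2011)
            if (y + i) % 3 == 0
        ]
        fit = stgpr.run_stgpr(
            sources, "mean", covs, small_hierarchy, signs,
            n_draws=50, seed=6, max_subset_size=1,
        )
        joined = fit.summary().join(truth.frame["mean_z"])
        rmses.append(
            float(np.sqrt(((joined["mean"] - joined["mean_z"]) ** 2).mean()))
        )
    assert rmses[0] > rmses[1] > rmses[2]
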