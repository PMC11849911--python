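import numpy as np
import pandas as pd
import pytest

from dielwl.growth import (
    GompertzParams,
    VarianceParams,
    PriorSpec,
    PosteriorDraws,
    gompertz_mean,
    variance_profile,
    fit_growth_model,
    test_hypothesis as hypothesis_test,
    diagnostics,
    posterior_predictive,
    hypothesis_table,
)
from dielwl.synthetic import GrowthSimDesign, gen_growth_data


class TestCurves:
    def test_gompertz_inflection_value(self):
        p = GompertzParams(130.0, 15.0, 0.25)
        assert gompertz_mean(15.0, p) == pytest.approx(130.0 / np.e)

    def test_gompertz_asymptote(self):
        p = GompertzParams(130.0, 15.0, 0.25)
        assert gompertz_mean(1e6, p) == pytest.approx(130.0)

    def test_gompertz_near_zero_at_origin(self):
        p = GompertzParams(130.0, 15.0, 0.25)
        assert gompertz_mean(0.0, p) == pytest.approx(130.0 * np.exp(-np.exp(3.75)))
        assert gompertz_mean(0.0, p) < 1e-15

    def test_gompertz_strictly_increasing(self):
        p = GompertzParams(80.0, 12.0, 0.3)
        t = np.linspace(0, 40, 200)
        assert np.all(np.diff(gompertz_mean(t, p)) > 0)

    def test_variance_midpoint_and_asymptote(self):
        v = VarianceParams(20.0, 10.0, 3.0)
        assert variance_profile(10.0, v) == pytest.approx(10.0)
        assert variance_profile(1e3, v) == pytest.approx(20.0)
        assert variance_profile(0.0, v) == pytest.approx(20.0 / (1 + np.exp(30.0)))

    @pytest.mark.parametrize("bad", [(-1, 15, 0.25), (130, 0, 0.25), (130, 15, -2)])
    def test_positivity_enforced(self, bad):
        with pytest.raises(ValueError):
            GompertzParams(*bad)


class TestPriors:
    def test_prior_sample_medians(self):
        rng = np.random.default_rng(0)
        s = PriorSpec().sample(20000, rng)
        assert np.median(s["A"]) == pytest.approx(130.0, rel=0.02)
        assert np.median(s["B"]) == pytest.approx(15.0, rel=0.02)
        assert np.median(s["C"]) == pytest.approx(0.25, rel=0.02)
        assert np.median(s["subA"]) == pytest.approx(20.0, rel=0.02)
        assert np.min(s["nu"]) >= 1.0
        # Gamma(2, 0.1) has mean 20
        assert np.mean(s["nu"]) == pytest.approx(20.0, rel=0.1)

    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(sigma=-0.1)


@pytest.fixture(scope="module")
def lownoise_fit():
    """One cheap fit on low-noise synthetic data from known parameters."""
    design = GrowthSimDesign(
        n_plants_per_group=6,
        variance={"WW": VarianceParams(0.5, 10.0, 3.0),
                  "WL": VarianceParams(0.5, 10.0, 3.0)},
        seed=4,
    )
    table, _ = gen_growth_data(design)
    post = fit_growth_model(table, chains=2, warmup=400, draws=400, seed=9)
    return design, post


class TestFit:
    def test_parameter_recovery_low_noise(self, lownoise_fit):
        design, post = lownoise_fit
        for g in ("WW", "WL"):
            truth = design.params[g]
            assert post.median(f"{g}:A") == pytest.approx(truth.A, rel=0.05)
            assert post.median(f"{g}:B") == pytest.approx(truth.B, rel=0.05)
            assert post.median(f"{g}:C") == pytest.approx(truth.C, rel=0.05)

    def test_draw_positivity(self, lownoise_fit):
        _, post = lownoise_fit
        assert np.all(post.draws > 0)

    def test_determinism(self):
        table, _ = gen_growth_data(GrowthSimDesign(n_plants_per_group=4, seed=1))
        a = fit_growth_model(table, warmup=100, draws=100, seed=5,
                             rhat_threshold=np.inf)
        b = fit_growth_model(table, warmup=100, draws=100, seed=5,
                             rhat_threshold=np.inf)
        assert np.array_equal(a.draws, b.draws)

    def test_prior_only_matches_prior_centers(self):
        table, _ = gen_growth_data(GrowthSimDesign(n_plants_per_group=4, seed=1))
        post = fit_growth_model(table, prior_only=True, draws=5000, seed=2)
        assert post.median("WW:A") == pytest.approx(130.0, rel=0.02)
        assert post.median("WL:subC") == pytest.approx(3.0, rel=0.03)

    def test_input_validation(self):
        table, _ = gen_growth_data(GrowthSimDesign(n_plants_per_group=4, seed=1))
        with pytest.raises(ValueError):
            fit_growth_model(table[table["treatment"] == "WW"].iloc[:3])
        few_days = table[table["day"] < 4]
        with pytest.raises(ValueError):
            fit_growth_model(few_days)


def _draws_from_arrays(**arrays):
    names = list(arrays)
    n = len(next(iter(arrays.values())))
    d = np.stack([np.asarray(arrays[k], float) for k in names], axis=-1)
    return PosteriorDraws(d.reshape(2, n // 2, len(names)), names, ["WW", "WL"])


class TestHypotheses:
    def test_exact_doubling_gives_certainty(self):
        a_wl = np.full(100, 65.0)
        post = _draws_from_arrays(**{"WW:A": 2 * a_wl, "WL:A": a_wl})
        r = hypothesis_test(post, "asymptote_50")
        assert r.probability == 1.0
        assert r.effect_size == pytest.approx(100.0)
        assert r.supported

    def test_equal_parameters_never_supported(self):
        a = np.full(100, 65.0)
        post = _draws_from_arrays(**{"WW:A": a, "WL:A": a})
        r = hypothesis_test(post, "asymptote_50")
        assert r.probability == 0.0
        assert not r.supported

    def test_margin_zero_probabilities_partition(self):
        rng = np.random.default_rng(3)
        ww, wl = rng.normal(10, 1, 200), rng.normal(10, 1, 200)
        p_fwd = np.mean((ww - wl) / wl > 0)
        p_rev = np.mean((wl - ww) / ww >= 0)
        assert p_fwd + p_rev == pytest.approx(1.0)

    def test_unknown_hypothesis_rejected(self):
        post = _draws_from_arrays(**{"WW:A": np.ones(4), "WL:A": np.ones(4)})
        with pytest.raises(KeyError):
            hypothesis_test(post, "no_such_test")

    def test_hypothesis_table_shape(self, lownoise_fit):
        _, post = lownoise_fit
        tab = hypothesis_table(post)
        assert set(tab["hypothesis"]) == {"asymptote_50", "inflection_5", "rate_5"}


class TestDiagnostics:
    def test_single_chain_undefined(self):
        d = np.random.default_rng(0).normal(size=(1, 100, 1))
        post = PosteriorDraws(d, ["WW:A"], ["WW"])
        with pytest.raises(ValueError):
            diagnostics(post)

    def test_stationary_chains_near_one(self):
        rng = np.random.default_rng(1)
        d = rng.normal(10, 1, size=(2, 4000, 1))
        post = PosteriorDraws(d, ["WW:A"], ["WW"])
        rhat, ess = post.rhat, post.ess
        rhat, ess = diagnostics(post)
        assert rhat.iloc[0] < 1.01
        assert ess.iloc[0] > 1000

    def test_offset_chains_flagged(self):
        rng = np.random.default_rng(2)
        d = np.stack([rng.normal(0, 1, (500, 1)), rng.normal(50, 1, (500, 1))])
        post = PosteriorDraws(d, ["WW:A"], ["WW"])
        rhat, _ = diagnostics(post)
        assert rhat.iloc[0] > 1.05

    def test_constant_chains_not_reported_converged(self):
        d = np.ones((2, 100, 1))
        post = PosteriorDraws(d, ["WW:A"], ["WW"])
        rhat, _ = diagnostics(post)
        assert not (rhat.iloc[0] <= 1.05)  # NaN or large, never "converged"


class TestPosteriorPredictive:
    def test_ribbon_collapses_without_noise(self):
        n = 200
        const = {
            "WW:A": np.full(n, 130.0), "WW:B": np.full(n, 15.0), "WW:C": np.full(n, 0.25),
            "WW:subA": np.full(n, 1e-9), "WW:subB": np.full(n, 10.0), "WW:subC": np.full(n, 3.0),
            "nu": np.full(n, 20.0),
        }
        names = list(const)
        d = np.stack([const[k] for k in names], axis=-1).reshape(2, n // 2, len(names))
        post = PosteriorDraws(d, names, ["WW"])
        rib = posterior_predictive(post, [5, 15, 25], seed=0)
        mu = gompertz_mean(rib["day"].to_numpy(), GompertzParams(130.0, 15.0, 0.25))
        assert np.allclose(rib["q2.5"], mu, atol=1e-6)
        assert np.allclose(rib["q97.5"], mu, atol=1e-6)

    def test_ribbon_widens_monotonically(self):
        rng = np.random.default_rng(7)
        n = 400
        draws = {
            "WW:A": rng.lognormal(np.log(130), 0.05, n),
            "WW:B": rng.lognormal(np.log(15), 0.05, n),
            "WW:C": rng.lognormal(np.log(0.25), 0.05, n),
            "WW:subA": rng.lognormal(np.log(20), 0.1, n),
            "WW:subB": rng.lognormal(np.log(10), 0.1, n),
            "WW:subC": rng.lognormal(np.log(3), 0.1, n),  # subC > 0 throughout
            "nu": np.full(n, 30.0),
        }
        names = list(draws)
        d = np.stack([draws[k] for k in names], axis=-1).reshape(2, n // 2, len(names))
        post = PosteriorDraws(d, names, ["WW"])
        rib = posterior_predictive(post, np.arange(0, 27, 2), n_draws=n, seed=1)
        width = (rib["q97.5"] - rib["q2.5"]).to_numpy()
        # non-decreasing up to Monte-Carlo jitter in the quantile estimates
        assert np.all(np.diff(width) > -0.15 * width.max())

    def test_coverage_of_heldout_observations(self):
        design = GrowthSimDesign(n_plants_per_group=10, seed=21)
        table, _ = gen_growth_data(design)
        fit_half = table[table["plant_id"].str.endswith(("1", "3", "5", "7", "9"))]
        post = fit_growth_model(fit_half, warmup=400, draws=400, seed=3,
                                rhat_threshold=np.inf)
        rib = posterior_predictive(post, sorted(table["day"].unique()), seed=4)
        held = table[~table.index.isin(fit_half.index)]
        merged = held.merge(rib, left_on=["treatment", "day"], right_on=["group", "day"])
        inside = (merged["area_cm2"] >= merged["q2.5"]) & (
            merged["area_cm2"] <= merged["q97.5"]
        )
        # binomial tolerance around 95%
        assert inside.mean() > 0.88
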