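"""Penalized thin-plate basis, family selection and the Bayesian GAMM."""

import numpy as np
import pandas as pd
import pytest

from nutflex.bayes.engine import SamplerSettings
from nutflex.gam import (
    BayesGAMM,
    build_spline_basis,
    penalized_least_squares,
    posterior_smooth,
    select_family,
)


class TestSplineBasis:
    def test_linear_function_lives_in_null_space(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 200)
        b = build_spline_basis(x, k=10)
        w = penalized_least_squares(b, 2.0 * x, lam=1e8)  # only unpenalized terms survive
        assert np.abs(b.design @ w - 2.0 * x).max() < 1e-8
        assert w[2:] @ b.penalty[2:, 2:] @ w[2:] < 1e-12

    def test_penalty_zero_for_constant(self):
        b = build_spline_basis(np.linspace(0, 1, 50), k=6)
        const = np.zeros(6)
        const[0] = 3.0
        assert const @ b.penalty @ const == 0.0
        assert np.all(np.linalg.eigvalsh(b.penalty) > -1e-10)

    def test_sin_recovery_against_dense_oracle(self):
        x = np.linspace(0, 2 * np.pi, 150)
        b = build_spline_basis(x, k=10)
        w = penalized_least_squares(b, np.sin(x), lam=1e-6)
        grid = np.linspace(0, 2 * np.pi, 500)
        assert np.abs(b.evaluate(grid) @ w - np.sin(grid)).max() < 0.05

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError, match="smaller basis"):
            build_spline_basis(np.array([1.0, 2.0, 3.0, 1.0, 2.0]), k=6)
        with pytest.raises(ValueError, match=">= 4"):
            build_spline_basis(np.linspace(0, 1, 30), k=3)


class TestSelectFamily:
    def test_recovers_generating_family(self):
        rng = np.random.default_rng(5)
        gamma = select_family(rng.gamma(4.0, 2.0, 2000))
        assert gamma.family == "gamma"
        assert gamma.params["shape"] == pytest.approx(4.0, rel=0.15)
        assert select_family(rng.lognormal(0.0, 0.5, 2000)).family == "lognormal"
        assert select_family(rng.normal(10.0, 1.0, 2000)).family == "gaussian"

    def test_nonpositive_with_positive_candidates_rejected(self):
        y = np.array([1.0, -0.5, 2.0])
        with pytest.raises(ValueError, match="positive-support"):
            select_family(y, candidates=("lognormal", "gamma"))
        assert select_family(y).family == "gaussian"


@pytest.fixture(scope="module")
def simple_gaussian_fit():
    rng = np.random.default_rng(4)
    x = rng.uniform(0, 10, 300)
    y = 1.0 + 0.3 * x + rng.normal(0, 0.5, 300)
    df = pd.DataFrame({"y": y, "x": x})
    return BayesGAMM(df, "y", "x", "gaussian", k=6, group=None).fit(profile="test", seed=4)


class TestGAMMFits:
    def test_gamma_smooth_recovery(self, gamma_gamm_fit):
        """Posterior smooth tracks the generating sinusoid over the central range."""
        res = gamma_gamm_fit["results"]
        grid = np.linspace(1.0, 9.0, 60)  # central ~80% of x in [0, 10]
        sm = res.smooth(grid)
        truth = gamma_gamm_fit["truth_fn"](grid)
        est = sm - sm.mean(axis=1, keepdims=True)
        lo, hi = np.quantile(est, [0.025, 0.975], axis=0)
        tr = truth - truth.mean()
        inside = (lo - 0.1 <= tr) & (tr <= hi + 0.1)
        assert inside.mean() > 0.95
        assert np.abs(est.mean(axis=0) - tr).max() < 0.2
        # dispersion recovered on the natural scale
        assert res.draws.get("shape").mean() == pytest.approx(5.0, rel=0.3)

    def test_family_link_coherence(self, gamma_gamm_fit, bernoulli_gamm_fit):
        rep = gamma_gamm_fit["results"].posterior_predictive(50, seed=1)
        assert np.all(rep > 0)
        pb = bernoulli_gamm_fit["results"].fitted_mean()
        assert np.all((pb > 0) & (pb < 1))

    def test_posterior_predictive_matches_moments(self, gamma_gamm_fit):
        """PPC: replicate mean and SD bracket the observed response."""
        y = gamma_gamm_fit["model"].y
        rep = gamma_gamm_fit["results"].posterior_predictive(400, seed=3)
        mean_q = np.mean(rep.mean(axis=1) < y.mean())
        sd_q = np.mean(rep.std(axis=1) < y.std())
        assert 0.01 < mean_q < 0.99
        assert 0.01 < sd_q < 0.99

    def test_bernoulli_decreasing_trend_detected(self, bernoulli_gamm_fit):
        res = bernoulli_gamm_fit["results"]
        slopes = res.slopes(np.linspace(1.5, 8.5, 50))
        assert np.all(slopes.slopes.mean(axis=0) < 0)

    def test_gaussian_flat_truth_covered(self):
        rng = np.random.default_rng(3)
        n, J = 400, 8
        x = rng.uniform(0, 10, n)
        ids = rng.integers(0, J, n)
        y = 3.0 + rng.normal(0, 0.3, J)[ids] + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "x": x, "individual_id": ids})
        res = BayesGAMM(df, "y", "x", "gaussian", k=8).fit(profile="test", seed=3)
        sm = res.smooth(np.linspace(0.5, 9.5, 40))
        lo, hi = np.quantile(sm, [0.025, 0.975], axis=0)
        assert np.all((lo <= 0.0) & (0.0 <= hi))

    def test_wellspecified_simple_fit_passes_rhat_gate(self, simple_gaussian_fit):
        """A low-dimensional, well-specified fit converges below Rhat 1.01."""
        d = simple_gaussian_fit.draws.diagnostics()
        assert d.max_rhat < 1.01
        assert d.divergences == 0

    def test_underfit_run_flags_nonconvergence(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"y": rng.normal(0, 1, 200), "x": rng.uniform(0, 1, 200)})
        res = BayesGAMM(df, "y", "x", "gaussian", k=6, group=None).fit(
            profile=SamplerSettings(steps=12, warmup=2), seed=5
        )
        assert not res.converged

    def test_clean_gaussian_fit_pareto_k_below_threshold(self, simple_gaussian_fit):
        d = simple_gaussian_fit.diagnostics()
        assert d["pareto_k_gt_0.7"] == 0

    def test_hierarchical_fit_pareto_k_mostly_clean(self, gamma_gamm_fit):
        # per-individual slopes make the odd point influential; no more than
        # a fraction of a percent of observations may exceed 0.7
        d = gamma_gamm_fit["results"].diagnostics()
        assert d["pareto_k_gt_0.7"] <= 3

    def test_family_support_validation(self):
        df = pd.DataFrame({"y": [-1.0, 2.0, 3.0, 4.0, 5.0, 6.0], "x": np.arange(6.0)})
        with pytest.raises(ValueError, match="positive"):
            BayesGAMM(df, "y", "x", "gamma", k=4, group=None)
        with pytest.raises(ValueError, match="bernoulli"):
            BayesGAMM(df.assign(y=[0.0, 1.0, 2.0, 0.0, 1.0, 0.0]), "y", "x", "bernoulli",
                      k=4, group=None)


class TestPosteriorSmooth:
    def test_shape_and_duplicate_columns(self, gamma_gamm_fit):
        res = gamma_gamm_fit["results"]
        grid = np.array([2.0, 2.0, 5.0])
        sm = posterior_smooth(res, grid)
        ndraws = res.draws.chain.shape[0] * res.draws.chain.shape[1]
        assert sm.shape == (ndraws, 3)
        np.testing.assert_array_equal(sm[:, 0], sm[:, 1])

    def test_coarse_grid_subset_of_fine(self, gamma_gamm_fit):
        res = gamma_gamm_fit["results"]
        fine = posterior_smooth(res, np.linspace(1, 9, 17))
        coarse = posterior_smooth(res, np.linspace(1, 9, 5))
        np.testing.assert_allclose(coarse, fine[:, ::4], rtol=1e-10)

    def test_extrapolation_rejected(self, gamma_gamm_fit):
        res = gamma_gamm_fit["results"]
        with pytest.raises(ValueError, match="extrapolat"):
            res.smooth(np.array([-5.0, 5.0]))


def test_model_from_declarative_spec():
    from nutflex.gam import GAMMSpec

    rng = np.random.default_rng(9)
    df = pd.DataFrame({
        "resp": rng.gamma(3, 1, 120), "pred": rng.uniform(0, 1, 120),
        "individual_id": rng.integers(0, 5, 120),
    })
    spec = GAMMSpec(response="resp", predictor="pred", family="gamma", k=5,
                    random_slopes=())
    m = BayesGAMM.from_spec(spec, df)
    assert m.family == "gamma" and m.basis.k == 5
    assert m.random_slope_cols == ()


def test_reproducibility_fixed_seed():
    rng = np.random.default_rng(6)
    df = pd.DataFrame({"y": rng.normal(0, 1, 150), "x": rng.uniform(0, 1, 150)})
    kwargs = dict(profile=SamplerSettings(steps=400, warmup=200), seed=42)
    a = BayesGAMM(df, "y", "x", "gaussian", k=5, group=None).fit(**kwargs)
    b = BayesGAMM(df, "y", "x", "gaussian", k=5, group=None).fit(**kwargs)
    np.testing.assert_array_equal(a.draws.chain, b.draws.chain)
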