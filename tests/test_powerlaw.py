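"""Protein-prioritization power-law model."""

import numpy as np
import pandas as pd
import pytest

from nutflex.powerlaw import PowerLawPriors, ProteinLeverageModel
from nutflex.simulate import SimConfig, make_truth, simulate_follows, simulate_phenology


def constant_protein_frame(n=600, J=12, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    e = np.exp(rng.uniform(np.log(1000), np.log(4000), n))
    pct = 100.0 * 250.0 / e * np.exp(rng.normal(0, noise, n)) if noise else 100.0 * 250.0 / e
    return pd.DataFrame(
        {
            "individual_id": np.repeat([f"I{j}" for j in range(J)], n // J),
            "kcal_total": e,
            "pct_protein_energy": pct,
        }
    )


class TestFit:
    def test_noiseless_constant_protein_concentrates_at_minus_one(self):
        df = constant_protein_frame(noise=1e-4, seed=1)
        res = ProteinLeverageModel(df).fit(profile="test", seed=1)
        assert res.L.mean() == pytest.approx(-1.0, abs=0.005)
        assert res.L.std() < 0.01
        assert res.interpret()["label"] == "complete prioritization"

    def test_noiseless_constant_percent_concentrates_at_zero(self):
        rng = np.random.default_rng(2)
        df = constant_protein_frame(seed=2)
        df["pct_protein_energy"] = 10.0 * np.exp(rng.normal(0, 1e-4, len(df)))
        res = ProteinLeverageModel(df).fit(profile="test", seed=2)
        assert res.L.mean() == pytest.approx(0.0, abs=0.005)
        assert res.interpret()["label"] == "no proportional regulation"

    def test_recovers_partial_truth(self, truth_partial, small_tables):
        follows = small_tables["follows"]
        res = ProteinLeverageModel(follows[follows["full_day"]]).fit(profile="test", seed=3)
        lo, hi = np.quantile(res.L, [0.025, 0.975])
        assert lo < truth_partial.L_true < hi

    def test_input_validation(self):
        df = constant_protein_frame(seed=3)
        bad = df.copy()
        bad.loc[0, "kcal_total"] = 0.0
        with pytest.raises(ValueError, match="energy"):
            ProteinLeverageModel(bad)
        bad2 = df.copy()
        bad2.loc[0, "pct_protein_energy"] = 100.0
        with pytest.raises(ValueError, match="percent"):
            ProteinLeverageModel(bad2)
        with pytest.raises(ValueError, match="individuals"):
            ProteinLeverageModel(df.assign(individual_id="same"))


class TestInvariantsAndOracles:
    def test_ols_oracle_equivalence(self):
        """Pooled fit with near-flat priors matches ordinary least squares."""
        rng = np.random.default_rng(5)
        n = 400
        e = np.exp(rng.uniform(np.log(900), np.log(5000), n))
        pct = np.exp(2.3 - 0.6 * (np.log(e) - 7.8) + rng.normal(0, 0.2, n))
        df = pd.DataFrame(
            {"individual_id": "X", "kcal_total": e, "pct_protein_energy": pct}
        )
        ols_slope = np.polyfit(np.log(e), np.log(pct), 1)[0]
        flat = PowerLawPriors(c_sd=100.0, L_sd=100.0, sigma_eps_sd=100.0)
        res = ProteinLeverageModel(df, random_intercepts=False, priors=flat).fit(
            profile="test", seed=5
        )
        mcse = res.L.std() / np.sqrt(max(res.diagnostics().min_ess_bulk, 1.0))
        # posterior mean within 2 Monte-Carlo SE (plus tiny prior shrinkage slack)
        assert abs(res.L.mean() - ols_slope) < 2 * mcse + 0.002

    def test_scale_equivariance(self):
        """Multiplying energies by a constant shifts c but not L."""
        df = constant_protein_frame(noise=0.1, seed=6)
        res1 = ProteinLeverageModel(df).fit(profile="test", seed=6)
        df2 = df.assign(kcal_total=df["kcal_total"] * 1000.0)
        res2 = ProteinLeverageModel(df2).fit(profile="test", seed=6)
        assert res1.L.mean() == pytest.approx(res2.L.mean(), abs=0.01)

    def test_convergence_diagnostics_attached(self):
        df = constant_protein_frame(noise=0.1, seed=8)
        res = ProteinLeverageModel(df).fit(profile="test", seed=8)
        d = res.diagnostics()
        assert d.divergences == 0
        assert set(d.rhat) >= {"c", "L", "sigma_eps"}
        assert res.summary().attrs["max_rhat"] == pytest.approx(d.max_rhat)


class TestBayesR2:
    def test_zero_noise_r2_near_one(self):
        df = constant_protein_frame(noise=1e-4, seed=9)
        res = ProteinLeverageModel(df).fit(profile="test", seed=9)
        assert res.bayes_r2()["mean"] > 0.99

    def test_pure_noise_r2_near_zero(self):
        rng = np.random.default_rng(10)
        df = constant_protein_frame(seed=10)
        df["pct_protein_energy"] = np.exp(rng.normal(2.3, 0.5, len(df)))
        res = ProteinLeverageModel(df).fit(profile="test", seed=10)
        assert res.bayes_r2()["mean"] < 0.05

    def test_r2_matches_analytic_variance_ratio(self):
        """Known generator variance components imply the R^2 directly."""
        rng = np.random.default_rng(11)
        n, J = 2000, 20
        ids = np.repeat(np.arange(J), n // J)
        alpha = rng.normal(0, 0.1, J)
        log_e = rng.uniform(np.log(900), np.log(5000), n)
        sig = 0.2
        log_pct = 2.3 - 0.73 * (log_e - log_e.mean()) + alpha[ids] + rng.normal(0, sig, n)
        df = pd.DataFrame(
            {
                "individual_id": ids,
                "kcal_total": np.exp(log_e),
                "pct_protein_energy": np.exp(log_pct),
            }
        )
        var_fit = (0.73**2) * np.var(log_e) + np.var(alpha[ids])
        expected = var_fit / (var_fit + sig**2)
        res = ProteinLeverageModel(df).fit(profile="test", seed=11)
        assert res.bayes_r2()["mean"] == pytest.approx(expected, abs=0.03)


class TestInterpretation:
    def test_labels_from_synthetic_draw_sets(self):
        from types import SimpleNamespace

        from nutflex.powerlaw import ProteinLeverageResults

        def interp(draws):
            obj = ProteinLeverageResults.__new__(ProteinLeverageResults)
            obj.draws = SimpleNamespace(get=lambda name: np.asarray(draws))
            return obj.interpret()

        complete = interp(np.full(1000, -1.0))
        assert complete["label"] == "complete prioritization"
        assert complete["p_L_below_-0.5"] == 1.0
        none = interp(np.zeros(1000))
        assert none["label"] == "no proportional regulation"
        rng = np.random.default_rng(0)
        strong = interp(rng.normal(-0.73, 0.02, 4000))
        assert strong["label"] == "strong but not complete"
        assert strong["p_L_below_-0.5"] > 0.999
        assert strong["p_L_in_(-1,0)"] > 0.99


def test_recovery_with_random_slopes_path():
    """The explicit (non-marginalised) path with random slopes stays sane."""
    rng = np.random.default_rng(13)
    n, J = 600, 10
    ids = np.repeat(np.arange(J), n // J)
    slopes = -0.7 + rng.normal(0, 0.05, J)
    log_e = rng.uniform(np.log(900), np.log(5000), n)
    log_pct = 2.3 + slopes[ids] * (log_e - log_e.mean()) + rng.normal(0, 0.15, n)
    df = pd.DataFrame(
        {"individual_id": ids, "kcal_total": np.exp(log_e), "pct_protein_energy": np.exp(log_pct)}
    )
    res = ProteinLeverageModel(df, random_slopes=True).fit(profile="test", seed=13)
    assert res.L.mean() == pytest.approx(-0.7, abs=0.1)
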