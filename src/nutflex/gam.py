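"""Bayesian penalized-spline regression with family-specific likelihoods.

Each response (a macronutrient intake or a urinary biomarker) is regressed
on a single predictor (FAI or an intake variable) through a penalized
low-rank thin-plate spline, with fixed covariates (e.g. sex, FAI) entering
linearly and a maximal random-effect structure: a random intercept per
individual plus random slopes on the predictor and covariates.  One
nutritional predictor per model — correlated predictors are screened
beforehand with the robust-correlation model and fitted separately to
avoid concurvity.

Families: gaussian (identity link), lognormal and gamma (log link),
bernoulli (logit link).  The smooth is reparameterised so that its penalty
is an identity prior precision: eigenvectors of the projected thin-plate
energy matrix are scaled by the inverse square root of their eigenvalues,
giving spline weights d ~ N(0, tau^2 I) with tau ~ half-Normal(0, 1) as
the smoothing prior; constants and the linear trend span the unpenalized
null space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .bayes.engine import (
    ParamBlock,
    ParamIndex,
    PosteriorDraws,
    ScaleGroup,
    half_normal_logpdf,
    run_ensemble,
    scaled_settings,
)

__all__ = [
    "SplineBasis",
    "build_spline_basis",
    "penalized_least_squares",
    "FamilyChoice",
    "select_family",
    "GAMMSpec",
    "BayesGAMM",
    "GAMMResults",
    "posterior_smooth",
]

FAMILIES = ("gaussian", "lognormal", "gamma", "bernoulli")


# ---------------------------------------------------------------------------
# low-rank thin-plate basis


class SplineBasis:
    """Low-rank penalized thin-plate-style smooth basis in one dimension.

    Built from the radial basis |x - x_k|^3 on the distinct data values
    (capped, quantile-thinned knots beyond ``max_knots``), projected
    orthogonal to the polynomial null space and eigen-truncated to the
    leading ``k - 2`` energy eigenvectors.  ``design`` is the n-by-k
    matrix [1, x_std, Z]; ``penalty`` is the k-by-k positive
    semi-definite penalty, zero on the constant/linear null space.
    """

    def __init__(self, x: np.ndarray, k: int = 10, max_knots: int = 400):
        x = np.asarray(x, float)
        distinct = np.unique(x)
        if k < 4:
            raise ValueError("basis dimension k must be >= 4")
        if distinct.size < k:
            raise ValueError(
                f"only {distinct.size} distinct predictor values; "
                f"choose a smaller basis dimension than k={k}"
            )
        self.k = int(k)
        self.x_mean = float(x.mean())
        self.x_scale = float(x.std()) or 1.0
        self.x_min = float(x.min())
        self.x_max = float(x.max())
        if distinct.size > max_knots:
            q = np.linspace(0.0, 1.0, max_knots)
            knots = np.unique(np.quantile(distinct, q))
        else:
            knots = distinct
        zk = self._std(knots)
        self._knots = zk
        E = np.abs(zk[:, None] - zk[None, :]) ** 3
        T = np.column_stack([np.ones_like(zk), zk])
        # projector orthogonal to the null space; P E P is PSD
        P = np.eye(zk.size) - T @ np.linalg.pinv(T)
        lam, U = np.linalg.eigh(P @ E @ P)
        order = np.argsort(lam)[::-1][: k - 2]
        lam = np.clip(lam[order], 0.0, None)
        self._A = P @ U[:, order]  # radial coefficients per basis function
        # strip the null-space component out of the penalized columns
        Z_raw = E @ self._A
        self._gamma = np.linalg.pinv(T) @ Z_raw
        Zk = Z_raw - T @ self._gamma
        # absorb the penalty: scale columns so d ~ N(0, tau^2 I) is the smooth prior
        with np.errstate(divide="ignore"):
            scale = 1.0 / np.sqrt(lam)
        scale[~np.isfinite(scale)] = 0.0
        col_rms = np.sqrt(np.mean((Zk * scale) ** 2, axis=0))
        col_rms[col_rms == 0] = 1.0
        self._col_scale = scale / col_rms
        self._lam = lam
        xs = self._std(x)
        self.x_std = xs
        self.Z = self._z(xs)
        self.design = np.column_stack([np.ones_like(xs), xs, self.Z])
        pen = np.zeros((self.k, self.k))
        pen[2:, 2:] = np.diag(lam * self._col_scale**2)
        self.penalty = pen

    def _std(self, x):
        return (np.asarray(x, float) - self.x_mean) / self.x_scale

    def _z(self, xs: np.ndarray) -> np.ndarray:
        E = np.abs(xs[:, None] - self._knots[None, :]) ** 3
        T = np.column_stack([np.ones_like(xs), xs])
        return (E @ self._A - T @ self._gamma) * self._col_scale

    def evaluate(self, x_new: np.ndarray) -> np.ndarray:
        """Full design [1, x_std, Z] at new predictor values."""
        xs = self._std(np.asarray(x_new, float))
        return np.column_stack([np.ones_like(xs), xs, self._z(xs)])


def build_spline_basis(x: np.ndarray, k: int = 10) -> SplineBasis:
    """Penalized low-rank thin-plate smooth basis (see :class:`SplineBasis`)."""
    return SplineBasis(x, k)


def penalized_least_squares(
    basis: SplineBasis, y: np.ndarray, lam: float = 1e-8
) -> np.ndarray:
    """Ridge solution min ||y - B w||^2 + lam w' Pen w — the frequentist oracle."""
    B = basis.design
    A = B.T @ B + lam * basis.penalty
    return np.linalg.solve(A, B.T @ np.asarray(y, float))


# ---------------------------------------------------------------------------
# family selection


@dataclass(frozen=True)
class FamilyChoice:
    family: str
    params: dict
    scores: dict  # AIC per candidate (lower is better)


def select_family(y: np.ndarray, candidates: tuple[str, ...] | None = None) -> FamilyChoice:
    """Pick the best-fitting distribution family for a response.

    Positive data compare gaussian, lognormal and gamma by AIC; data with
    non-positive values can only be gaussian.  Gamma parameters come from
    the method of moments (shape = mean^2/var, rate = mean/var); gaussian
    and lognormal use maximum likelihood.
    """
    y = np.asarray(y, float)
    y = y[np.isfinite(y)]
    if y.size == 0:
        raise ValueError("empty response")
    positive = bool(np.all(y > 0))
    if candidates is None:
        candidates = ("gaussian", "lognormal", "gamma") if positive else ("gaussian",)
    if not positive and all(c in ("lognormal", "gamma") for c in candidates):
        raise ValueError("non-positive values cannot follow a positive-support family")
    n = y.size
    scores: dict[str, float] = {}
    params: dict[str, dict] = {}
    for cand in candidates:
        if cand == "gaussian":
            mu, sd = y.mean(), y.std()
            ll = -0.5 * n * np.log(2 * np.pi * sd**2) - 0.5 * np.sum((y - mu) ** 2) / sd**2
            params[cand] = {"mean": float(mu), "sd": float(sd)}
        elif cand == "lognormal":
            ly = np.log(y)
            mu, sd = ly.mean(), ly.std()
            ll = (
                -0.5 * n * np.log(2 * np.pi * sd**2)
                - 0.5 * np.sum((ly - mu) ** 2) / sd**2
                - np.sum(ly)
            )
            params[cand] = {"log_mean": float(mu), "log_sd": float(sd)}
        elif cand == "gamma":
            m, v = y.mean(), y.var()
            shape, rate = m**2 / v, m / v
            ll = np.sum(
                shape * np.log(rate) + (shape - 1) * np.log(y) - rate * y - gammaln(shape)
            )
            params[cand] = {"shape": float(shape), "rate": float(rate)}
        else:
            raise ValueError(f"unknown candidate family {cand!r}")
        scores[cand] = float(2 * 2 - 2 * ll)
    best = min(scores, key=scores.get)
    return FamilyChoice(family=best, params=params[best], scores=scores)


# ---------------------------------------------------------------------------
# the model


@dataclass(frozen=True)
class GAMMSpec:
    """Declarative model description consumed by the pipeline."""

    response: str
    predictor: str
    family: str
    k: int = 10
    covariates: tuple[str, ...] = ()
    group: str = "individual_id"
    random_slopes: tuple[str, ...] | None = None  # None -> maximal
    model_dispersion: bool = False


class BayesGAMM:
    """Bayesian GAMM: penalized-spline smooth + linear covariates + random effects.

    ``random_slopes=None`` requests the maximal structure (slopes on the
    predictor and every covariate per individual); pass ``()`` for random
    intercepts only.  ``model_dispersion=True`` adds a linear model on the
    log dispersion in the predictor (a distributional extension; the
    default models location only).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        predictor: str,
        family: str,
        *,
        k: int = 10,
        covariates: tuple[str, ...] = (),
        group: str | None = "individual_id",
        random_slopes: tuple[str, ...] | None = None,
        model_dispersion: bool = False,
    ):
        if family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        cols = [response, predictor, *covariates] + ([group] if group else [])
        df = data[cols].dropna().reset_index(drop=True)
        if df.empty:
            raise ValueError("no complete rows for the requested variables")
        y = df[response].to_numpy()
        if family in ("lognormal", "gamma"):
            y = y.astype(float)
            if np.any(y <= 0):
                raise ValueError(f"{family} family requires a strictly positive response")
        elif family == "bernoulli":
            y = y.astype(float)
            if not set(np.unique(y)) <= {0.0, 1.0}:
                raise ValueError("bernoulli family requires a 0/1 (or boolean) response")
        else:
            y = y.astype(float)
        self.family = family
        self.response, self.predictor = response, predictor
        self.spec_covariates = tuple(covariates)
        self.model_dispersion = bool(model_dispersion)
        self.data = df
        self.basis = SplineBasis(df[predictor].to_numpy(float), k=k)
        self.n = len(df)

        # linear covariates: numeric standardized, categorical centered codes
        self._cov_cols = []
        covs = []
        for c in covariates:
            v = df[c]
            if v.dtype.kind in "OUSb" or isinstance(v.dtype, pd.CategoricalDtype):
                codes, _ = pd.factorize(v)
                col = codes - codes.mean()
            else:
                col = (v.to_numpy(float) - v.mean()) / (v.std() or 1.0)
            covs.append(np.asarray(col, float))
            self._cov_cols.append(c)
        self.X_cov = np.column_stack(covs) if covs else np.zeros((self.n, 0))

        # response scaling: gaussian fits on standardized y, log/logit links as-is
        if family == "gaussian":
            self._y_loc, self._y_scale = float(y.mean()), float(y.std() or 1.0)
        else:
            self._y_loc, self._y_scale = 0.0, 1.0
        self.y = (y - self._y_loc) / self._y_scale

        self.hierarchical = group is not None
        if self.hierarchical:
            self.group_idx, self.group_labels = pd.factorize(df[group])
            self.n_groups = len(self.group_labels)
            if random_slopes is None:
                random_slopes = (predictor, *covariates)
            self.random_slope_cols = tuple(random_slopes)
        else:
            self.random_slope_cols = ()

        kp = self.basis.k - 2  # penalized spline coefficients
        blocks = [
            ParamBlock("beta0", 1),
            ParamBlock("beta_lin", 1),
            ParamBlock("spline", kp),
            ParamBlock("tau", 1, np.abs),  # tau = |t|; prior t ~ N(0,1) => half-Normal(0,1)
        ]
        if self.X_cov.shape[1]:
            blocks.append(ParamBlock("beta_cov", self.X_cov.shape[1]))
        if self.hierarchical:
            blocks.append(ParamBlock("sd_intercept", 1, np.abs))
            blocks.append(ParamBlock("re_intercept", self.n_groups))
            for s in self.random_slope_cols:
                blocks.append(ParamBlock(f"sd_slope_{s}", 1, np.abs))
                blocks.append(ParamBlock(f"re_slope_{s}", self.n_groups))
        if family in ("gaussian", "lognormal"):
            blocks.append(ParamBlock("sigma", 1, np.exp))
        elif family == "gamma":
            blocks.append(ParamBlock("shape", 1, np.exp))
        if self.model_dispersion and family != "bernoulli":
            blocks.append(ParamBlock("disp_slope", 1))
        self.index = ParamIndex(blocks)

        self._slope_design = {}
        for s in self.random_slope_cols:
            if s == predictor:
                self._slope_design[s] = self.basis.x_std
            else:
                self._slope_design[s] = self.X_cov[:, self._cov_cols.index(s)]

    # -- linear predictor ----------------------------------------------
    @classmethod
    def from_spec(cls, spec: GAMMSpec, data: pd.DataFrame) -> "BayesGAMM":
        """Build a model from a declarative :class:`GAMMSpec`."""
        return cls(
            data,
            spec.response,
            spec.predictor,
            spec.family,
            k=spec.k,
            covariates=spec.covariates,
            group=spec.group,
            random_slopes=spec.random_slopes,
            model_dispersion=spec.model_dispersion,
        )

    def _eta(self, theta: np.ndarray) -> np.ndarray:
        ix = self.index
        b0 = ix.raw(theta, "beta0")[:, :1]
        bl = ix.raw(theta, "beta_lin")[:, :1]
        tau = np.abs(ix.raw(theta, "tau"))[:, :1]
        d = tau * ix.raw(theta, "spline")  # non-centered weights
        eta = b0 + bl * self.basis.x_std[None, :] + d @ self.basis.Z.T
        if self.X_cov.shape[1]:
            eta = eta + ix.raw(theta, "beta_cov") @ self.X_cov.T
        if self.hierarchical:
            sd0 = np.abs(ix.raw(theta, "sd_intercept"))[:, :1]
            re0 = ix.raw(theta, "re_intercept") * sd0
            eta = eta + re0[:, self.group_idx]
            for s in self.random_slope_cols:
                sds = np.abs(ix.raw(theta, f"sd_slope_{s}"))[:, :1]
                res = ix.raw(theta, f"re_slope_{s}") * sds
                eta = eta + res[:, self.group_idx] * self._slope_design[s][None, :]
        return eta

    def _log_post(self, theta: np.ndarray) -> np.ndarray:
        ix = self.index
        eta = self._eta(theta)
        b0 = ix.raw(theta, "beta0")[:, 0]
        bl = ix.raw(theta, "beta_lin")[:, 0]
        d_raw = ix.raw(theta, "spline")
        t_tau = ix.raw(theta, "tau")[:, 0]
        lp = -0.5 * ((b0 - self._b0_center) / 5.0) ** 2 - 0.5 * (bl / 5.0) ** 2
        lp += -0.5 * t_tau**2              # tau = |t_tau| ~ half-Normal(0, 1)
        lp += -0.5 * np.sum(d_raw**2, axis=1)  # non-centered spline weights
        if self.X_cov.shape[1]:
            lp += -0.5 * np.sum((ix.raw(theta, "beta_cov") / 5.0) ** 2, axis=1)
        if self.hierarchical:
            for name in ("sd_intercept", *[f"sd_slope_{s}" for s in self.random_slope_cols]):
                lp += -0.5 * ix.raw(theta, name)[:, 0] ** 2
            for name in ("re_intercept", *[f"re_slope_{s}" for s in self.random_slope_cols]):
                lp += -0.5 * np.sum(ix.raw(theta, name) ** 2, axis=1)
        lp += self._log_lik(theta, eta).sum(axis=1)
        return lp

    def _dispersion(self, theta: np.ndarray) -> np.ndarray:
        """Per-observation log dispersion (W, n) or (W, 1) when constant."""
        ix = self.index
        if self.family in ("gaussian", "lognormal"):
            base = ix.raw(theta, "sigma")
        elif self.family == "gamma":
            base = ix.raw(theta, "shape")
        else:
            return np.zeros((theta.shape[0], 1))
        if self.model_dispersion:
            slope = ix.raw(theta, "disp_slope")
            return base + slope * self.basis.x_std[None, :]
        return base

    def _log_lik(self, theta: np.ndarray, eta: np.ndarray | None = None) -> np.ndarray:
        """(W, n) pointwise log likelihood."""
        if eta is None:
            eta = self._eta(theta)
        y = self.y[None, :]
        if self.family == "gaussian":
            log_sig = self._dispersion(theta)
            return -0.5 * ((y - eta) / np.exp(log_sig)) ** 2 - log_sig - 0.5 * np.log(2 * np.pi)
        if self.family == "lognormal":
            log_sig = self._dispersion(theta)
            ly = np.log(y)
            return (
                -0.5 * ((ly - eta) / np.exp(log_sig)) ** 2
                - log_sig
                - ly
                - 0.5 * np.log(2 * np.pi)
            )
        if self.family == "gamma":
            a = np.exp(self._dispersion(theta))
            log_mean = eta
            return (
                a * (np.log(a) - log_mean)
                + (a - 1.0) * np.log(y)
                - a * y / np.exp(log_mean)
                - gammaln(a)
            )
        # bernoulli with logit link
        return y * eta - np.logaddexp(0.0, eta)

    # -- fitting --------------------------------------------------------
    @property
    def _b0_center(self) -> float:
        if self.family == "gaussian":
            return 0.0  # y standardized
        if self.family == "bernoulli":
            pbar = float(np.clip(self.y.mean(), 1e-3, 1 - 1e-3))
            return float(np.log(pbar / (1 - pbar)))
        return float(np.log(self.y.mean()))  # log link

    def _initial_ensemble(self, nw: int, rng: np.random.Generator) -> np.ndarray:
        """Overdispersed ensemble centered on crude data-driven estimates.

        An ensemble sampler needs a dispersed starting cloud (its proposals
        scale with the ensemble spread), so all families start from
        moment-based centers with moderate jitter rather than a point.
        """
        init = rng.uniform(-0.5, 0.5, size=(nw, self.index.ndim))
        ix = self.index
        init[:, ix.slices["beta0"]] += self._b0_center
        init[:, ix.slices["tau"]] = rng.uniform(-1.0, 1.0, (nw, 1))
        if self.family in ("gaussian", "lognormal"):
            resid = self.y if self.family == "gaussian" else np.log(self.y)
            init[:, ix.slices["sigma"]] = np.log(max(np.std(resid), 1e-3)) + rng.uniform(
                -0.3, 0.3, (nw, 1)
            )
        elif self.family == "gamma":
            shape0 = max(self.y.mean() ** 2 / self.y.var(), 0.5)
            init[:, ix.slices["shape"]] = np.log(shape0) + rng.uniform(-0.5, 0.5, (nw, 1))
        if self.hierarchical:
            for s in ("sd_intercept", *[f"sd_slope_{c}" for c in self.random_slope_cols]):
                init[:, ix.slices[s]] = rng.uniform(-0.6, 0.6, (nw, 1))
            for name in ("re_intercept", *[f"re_slope_{s}" for s in self.random_slope_cols]):
                sl = ix.slices[name]
                init[:, sl] = rng.standard_normal((nw, sl.stop - sl.start))
        return init

    def fit(
        self,
        *,
        profile: str = "test",
        seed: int = 0,
        moves: str = "de",
        run_scale: float = 6.0,
    ) -> "GAMMResults":
        """Sample the posterior.

        ``run_scale`` lengthens the ensemble run relative to the named
        profile; the default suits the hierarchical models' mixing (the
        many latent random-effect coordinates decorrelate slowly).
        """
        if not self.hierarchical:
            run_scale = min(run_scale, 3.0)
        settings = scaled_settings(profile, run_scale)
        rng = np.random.default_rng(seed)
        nw = settings.resolve_walkers(self.index.ndim)
        init = self._initial_ensemble(nw, rng)
        groups = [ScaleGroup(self.index.slices["tau"].start,
                             np.arange(*self.index.slices["spline"].indices(self.index.ndim)))]
        if self.hierarchical:
            pairs = [("sd_intercept", "re_intercept")]
            pairs += [(f"sd_slope_{s}", f"re_slope_{s}") for s in self.random_slope_cols]
            for sd_name, re_name in pairs:
                groups.append(ScaleGroup(
                    self.index.slices[sd_name].start,
                    np.arange(*self.index.slices[re_name].indices(self.index.ndim)),
                ))
        draws = run_ensemble(self._log_post, init, settings, self.index, seed=seed,
                             moves=moves, scale_groups=groups)
        return GAMMResults(self, draws)


class GAMMResults:
    """Posterior fit of a :class:`BayesGAMM`."""

    def __init__(self, model: BayesGAMM, draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    # -- smooth ---------------------------------------------------------
    def smooth(self, grid: np.ndarray, extrapolation_tol: float = 0.05) -> np.ndarray:
        """(ndraws, ngrid) smooth component on the link scale.

        The smooth is the spline plus its unpenalized linear trend
        (intercept excluded).  Grids beyond 5% extrapolation of the
        observed predictor range raise.
        """
        m = self.model
        grid = np.atleast_1d(np.asarray(grid, float))
        rng_x = m.basis.x_max - m.basis.x_min
        lo = m.basis.x_min - extrapolation_tol * rng_x
        hi = m.basis.x_max + extrapolation_tol * rng_x
        if grid.min() < lo or grid.max() > hi:
            raise ValueError(
                f"grid extrapolates beyond {extrapolation_tol:.0%} of the observed "
                f"predictor range [{m.basis.x_min:g}, {m.basis.x_max:g}]"
            )
        B = m.basis.evaluate(grid)  # [1, xs, Z]
        theta = self.draws.stacked_theta()
        bl = m.index.raw(theta, "beta_lin")[:, :1]
        d = np.abs(m.index.raw(theta, "tau"))[:, :1] * m.index.raw(theta, "spline")
        out = bl * B[None, :, 1] + d @ B[:, 2:].T
        return out * m._y_scale

    def slopes(self, grid: np.ndarray | None = None, eps: float | None = None):
        from .derivatives import finite_difference_slopes

        if grid is None:
            grid = np.linspace(self.model.basis.x_min, self.model.basis.x_max, 200)
        return finite_difference_slopes(self.smooth, np.asarray(grid, float), eps)

    def nonflat_regions(self, grid: np.ndarray | None = None, level: float = 0.95):
        from .derivatives import detect_nonflat_regions

        return detect_nonflat_regions(self.slopes(grid), level=level)

    # -- predictions ----------------------------------------------------
    def linear_predictor(self) -> np.ndarray:
        """(ndraws, n) eta at the training rows (link scale, standardized y units)."""
        return self.model._eta(self.draws.stacked_theta())

    def fitted_mean(self) -> np.ndarray:
        """(ndraws, n) posterior expected response on the natural scale."""
        eta = self.linear_predictor()
        m = self.model
        if m.family == "gaussian":
            return eta * m._y_scale + m._y_loc
        if m.family == "lognormal":
            sig = np.exp(m._dispersion(self.draws.stacked_theta()))
            return np.exp(eta + 0.5 * sig**2)
        if m.family == "gamma":
            return np.exp(eta)
        return expit(eta)

    def posterior_predictive(self, n_draws: int = 200, seed: int = 0) -> np.ndarray:
        """(n_draws, n) replicate responses simulated from the fitted model."""
        m = self.model
        rng = np.random.default_rng(seed)
        theta = self.draws.stacked_theta()
        pick = rng.choice(theta.shape[0], size=min(n_draws, theta.shape[0]), replace=False)
        theta = theta[pick]
        eta = m._eta(theta)
        if m.family == "gaussian":
            sig = np.exp(m._dispersion(theta))
            rep = rng.normal(eta, np.broadcast_to(sig, eta.shape))
            return rep * m._y_scale + m._y_loc
        if m.family == "lognormal":
            sig = np.exp(m._dispersion(theta))
            return np.exp(rng.normal(eta, np.broadcast_to(sig, eta.shape)))
        if m.family == "gamma":
            a = np.exp(m._dispersion(theta))
            a = np.broadcast_to(a, eta.shape)
            return rng.gamma(a, np.exp(eta) / a)
        return (rng.random(eta.shape) < expit(eta)).astype(float)

    # -- diagnostics ----------------------------------------------------
    def log_likelihood(self, max_draws: int = 500, seed: int = 0) -> np.ndarray:
        """(draws, n) pointwise log likelihood on a draw subsample."""
        theta = self.draws.stacked_theta()
        rng = np.random.default_rng(seed)
        if theta.shape[0] > max_draws:
            theta = theta[rng.choice(theta.shape[0], max_draws, replace=False)]
        return self.model._log_lik(theta)

    def loo(self, max_draws: int = 500):
        """PSIS-LOO with pointwise Pareto-k diagnostics (via arviz)."""
        import arviz as az

        ll = self.log_likelihood(max_draws=max_draws)
        # arviz wants (chain, draw, obs); use 4 pseudo-chains for stability
        n_chain = 4
        per = ll.shape[0] // n_chain
        ll4 = ll[: n_chain * per].reshape(n_chain, per, -1)
        idata = az.from_dict(
            posterior={"dummy": np.zeros((n_chain, per))},
            log_likelihood={"y": ll4},
        )
        return az.loo(idata, pointwise=True)

    def diagnostics(self) -> dict:
        """Rhat/ESS/divergences plus the PSIS Pareto-k summary."""
        d = self.draws.diagnostics().to_dict()
        try:
            loo = self.loo()
            k = np.asarray(loo.pareto_k)
            d["pareto_k_max"] = float(np.max(k))
            d["pareto_k_gt_0.7"] = int(np.sum(k > 0.7))
            d["elpd_loo"] = float(loo.elpd_loo)
        except Exception as exc:  # pragma: no cover - loo failure is reported, not fatal
            d["loo_error"] = str(exc)
        return d

    @property
    def converged(self) -> bool:
        return self.draws.converged

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in ("beta0", "beta_lin", "tau"):
            v = self.draws.get(name)
            lo, hi = np.quantile(v, [0.025, 0.975])
            rows.append({"param": name, "mean": v.mean(), "sd": v.std(),
                         "ci_low": lo, "ci_high": hi})
        if self.model.X_cov.shape[1]:
            bc = np.atleast_2d(self.draws.get("beta_cov").T).T
            for i, c in enumerate(self.model._cov_cols):
                v = bc[:, i]
                lo, hi = np.quantile(v, [0.025, 0.975])
                rows.append({"param": f"beta[{c}]", "mean": v.mean(), "sd": v.std(),
                             "ci_low": lo, "ci_high": hi})
        df = pd.DataFrame(rows).set_index("param")
        df.attrs["family"] = self.model.family
        df.attrs["converged"] = self.converged
        return df


def posterior_smooth(results: GAMMResults, grid: np.ndarray) -> np.ndarray:
    """Smooth-term evaluations per posterior draw (draws x grid, link scale)."""
    return results.smooth(grid)
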