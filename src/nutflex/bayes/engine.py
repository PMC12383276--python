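"""Ensemble-MCMC engine shared by every Bayesian model in the package.

All models expose their posterior as a vectorised log-density over an
unconstrained parameter vector; this module runs an affine-invariant /
differential-evolution ensemble sampler (emcee) over it and wraps the raw
chain in a :class:`PosteriorDraws` object that knows parameter names,
back-transforms, and convergence diagnostics.  For diagnostics each walker
is treated as a chain: rank-normalised split-Rhat and bulk/tail effective
sample sizes are computed across walkers with arviz.  There is no
Hamiltonian dynamics here, so the divergence count reported by
:class:`Diagnostics` is always zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import arviz as az
import emcee
import numpy as np

__all__ = [
    "SamplerSettings",
    "PROFILES",
    "ParamBlock",
    "ParamIndex",
    "Diagnostics",
    "PosteriorDraws",
    "run_ensemble",
]

RHAT_LIMIT = 1.01  # convergence gate used throughout the package


@dataclass(frozen=True)
class SamplerSettings:
    """Number of ensemble steps and warmup discarded, per profile.

    ``steps`` counts total ensemble moves; the first ``warmup`` are
    discarded.  ``nwalkers`` of ``None`` means ``max(2*ndim + 2, floor)``.
    """

    steps: int = 1000
    warmup: int = 500
    nwalkers: int | None = None
    walker_floor: int = 64
    thin: int = 1

    def resolve_walkers(self, ndim: int) -> int:
        if self.nwalkers is not None:
            return self.nwalkers
        n = max(2 * ndim + 2, self.walker_floor)
        return n + (n % 2)  # emcee requires an even ensemble


#: Named sampler profiles.  ``paper`` mirrors the published run length
#: (7000 iterations, 3500 warmup); ``test`` is the desk-scale profile.
PROFILES: dict[str, SamplerSettings] = {
    "test": SamplerSettings(steps=4000, warmup=2000, thin=4),
    "paper": SamplerSettings(steps=7000, warmup=3500, thin=3),
}


def resolve_profile(profile: str | SamplerSettings) -> SamplerSettings:
    if isinstance(profile, SamplerSettings):
        return profile
    try:
        return PROFILES[profile]
    except KeyError:
        raise ValueError(
            f"unknown sampler profile {profile!r}; choose from {sorted(PROFILES)}"
        ) from None


def scaled_settings(
    profile: str | SamplerSettings, scale: float = 1.0, target_draws: int = 400
) -> SamplerSettings:
    """Scale a profile's run length for slower-mixing (higher-dim) models.

    Hierarchical models with many latent coordinates need proportionally
    longer ensemble runs to pass the split-Rhat gate; ``scale`` multiplies
    steps and warmup, and thinning is set so roughly ``target_draws``
    post-warmup draws per walker are stored.
    """
    base = resolve_profile(profile)
    steps = int(round(base.steps * scale))
    warmup = int(round(base.warmup * scale))
    thin = max(1, (steps - warmup) // target_draws)
    return SamplerSettings(
        steps=steps, warmup=warmup, thin=thin,
        nwalkers=base.nwalkers, walker_floor=base.walker_floor,
    )


@dataclass(frozen=True)
class ParamBlock:
    """One named block of the packed parameter vector.

    ``transform`` maps the unconstrained coordinates to the reported scale
    (e.g. ``np.exp`` for a standard deviation sampled on the log scale).
    """

    name: str
    size: int
    transform: Callable[[np.ndarray], np.ndarray] | None = None


class ParamIndex:
    """Maps names to slices of a packed unconstrained parameter vector."""

    def __init__(self, blocks: Sequence[ParamBlock]):
        self.blocks = list(blocks)
        self.slices: dict[str, slice] = {}
        start = 0
        for b in self.blocks:
            self.slices[b.name] = slice(start, start + b.size)
            start += b.size
        self.ndim = start
        self._transforms = {b.name: b.transform for b in self.blocks}

    def extract(self, theta: np.ndarray, name: str) -> np.ndarray:
        """Slice ``name`` out of ``theta`` (last axis) and back-transform."""
        out = theta[..., self.slices[name]]
        tr = self._transforms[name]
        return tr(out) if tr is not None else out

    def raw(self, theta: np.ndarray, name: str) -> np.ndarray:
        return theta[..., self.slices[name]]


@dataclass
class Diagnostics:
    max_rhat: float
    min_ess_bulk: float
    min_ess_tail: float
    divergences: int = 0
    rhat: dict = field(default_factory=dict)
    ess_bulk: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(np.isfinite(self.max_rhat) and self.max_rhat < RHAT_LIMIT)

    def to_dict(self) -> dict:
        return {
            "max_rhat": float(self.max_rhat),
            "min_ess_bulk": float(self.min_ess_bulk),
            "min_ess_tail": float(self.min_ess_tail),
            "divergences": int(self.divergences),
            "converged": self.converged,
        }


class PosteriorDraws:
    """Post-warmup draws with named access and diagnostics.

    ``chain`` has shape ``(nwalkers, ndraws, ndim)`` on the unconstrained
    scale; walkers are treated as chains for Rhat/ESS purposes.
    """

    def __init__(self, chain: np.ndarray, index: ParamIndex, *, meta: dict | None = None):
        if chain.ndim != 3:
            raise ValueError("chain must be (walkers, draws, ndim)")
        self.chain = chain
        self.index = index
        self.meta = dict(meta or {})
        self._diag: Diagnostics | None = None

    # -- access -------------------------------------------------------
    @property
    def n_chains(self) -> int:
        return self.chain.shape[0]

    @property
    def n_draws(self) -> int:
        return self.chain.shape[1]

    def per_chain(self, name: str) -> np.ndarray:
        """(chains, draws, size) on the reported scale."""
        return self.index.extract(self.chain, name)

    def get(self, name: str) -> np.ndarray:
        """All draws pooled: (chains*draws, size), squeezed if size==1."""
        x = self.per_chain(name)
        x = x.reshape(-1, x.shape[-1])
        return x[:, 0] if x.shape[-1] == 1 else x

    def stacked_theta(self) -> np.ndarray:
        """(chains*draws, ndim) unconstrained draws."""
        return self.chain.reshape(-1, self.chain.shape[-1])

    # -- diagnostics ---------------------------------------------------
    def to_inference_data(self) -> az.InferenceData:
        data = {}
        for b in self.index.blocks:
            arr = self.per_chain(b.name)
            if b.size == 1:
                data[b.name] = arr[..., 0]
            else:
                data[b.name] = arr
        return az.from_dict(posterior=data)

    def diagnostics(self, recompute: bool = False) -> Diagnostics:
        if self._diag is not None and not recompute:
            return self._diag
        idata = self.to_inference_data()
        rhat_ds = az.rhat(idata)
        ess_b = az.ess(idata, method="bulk")
        ess_t = az.ess(idata, method="tail")
        rhat = {k: float(np.nanmax(v.values)) for k, v in rhat_ds.items()}
        essb = {k: float(np.nanmin(v.values)) for k, v in ess_b.items()}
        esst = {k: float(np.nanmin(v.values)) for k, v in ess_t.items()}
        self._diag = Diagnostics(
            max_rhat=max(rhat.values()),
            min_ess_bulk=min(essb.values()),
            min_ess_tail=min(esst.values()),
            divergences=0,
            rhat=rhat,
            ess_bulk=essb,
        )
        return self._diag

    @property
    def converged(self) -> bool:
        return self.diagnostics().converged


class ScaleGroup:
    """A non-centered block with the exact rescaling symmetry.

    For a scale coordinate t and raw coordinates r entering the likelihood
    only through |t| * r, the map (t, r) -> (g t, r / g) leaves the
    likelihood invariant.  An MH move along this family (log g Gaussian,
    with the N(0,1) priors and the Jacobian g^(1-m)) decorrelates the
    scale from the raw magnitudes — the interweaving fix for the
    non-centered funnel.
    """

    def __init__(self, scale_idx: int, raw_idx: np.ndarray):
        self.scale_idx = int(scale_idx)
        self.raw_idx = np.asarray(raw_idx, int)

    def propose(self, coords: np.ndarray, rng: np.random.RandomState) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised over walkers: returns (new_coords, log_accept_ratio)."""
        W = coords.shape[0]
        log_g = rng.normal(0.0, 0.5, W)
        g = np.exp(log_g)
        t = coords[:, self.scale_idx]
        r = coords[:, self.raw_idx]
        m = self.raw_idx.size
        dprior = -0.5 * ((g * t) ** 2 - t**2)
        dprior += -0.5 * ((r**2).sum(axis=1) * (1.0 / g**2 - 1.0))
        log_ratio = dprior + (1.0 - m) * log_g
        new = coords.copy()
        new[:, self.scale_idx] = g * t
        new[:, self.raw_idx] = r / g[:, None]
        return new, log_ratio

    def centered_propose(
        self, coords: np.ndarray, rng: np.random.RandomState
    ) -> tuple[np.ndarray, np.ndarray]:
        """Centered (ASIS) companion move: update the scale holding the
        *effective* weights d = |t| r fixed, so the likelihood is untouched
        and only p(t) * p(r = d/|t|) with the reparameterisation Jacobian
        enters the MH ratio."""
        W = coords.shape[0]
        t = coords[:, self.scale_idx]
        r = coords[:, self.raw_idx]
        m = self.raw_idx.size
        tau = np.maximum(np.abs(t), 1e-12)
        d_eff = tau[:, None] * r
        d2 = (d_eff**2).sum(axis=1)

        def logf(log_tau):
            # p(tau) p(d/tau) |J|: J of (d -> r) is tau^-m, plus d log tau
            return -0.5 * np.exp(2 * log_tau) - m * log_tau - 0.5 * d2 * np.exp(-2 * log_tau) + log_tau

        cur = np.log(tau)
        prop = cur + rng.normal(0.0, 0.4, W)
        log_ratio = logf(prop) - logf(cur)
        tau_new = np.exp(prop)
        new = coords.copy()
        new[:, self.scale_idx] = np.sign(t) * tau_new
        new[:, self.raw_idx] = d_eff / tau_new[:, None]
        return new, log_ratio


def run_ensemble(
    log_prob: Callable[[np.ndarray], np.ndarray],
    init: np.ndarray,
    settings: SamplerSettings,
    index: ParamIndex,
    *,
    seed: int,
    moves: str = "de",
    scale_groups: Sequence[ScaleGroup] = (),
    interweave_every: int = 100,
    progress: bool = False,
) -> PosteriorDraws:
    """Run emcee over a vectorised log posterior.

    ``log_prob`` must accept ``(nwalkers, ndim)`` and return ``(nwalkers,)``.
    ``init`` is the (nwalkers, ndim) starting ensemble.  ``moves='de'``
    mixes differential-evolution moves (better in high dimension);
    ``'stretch'`` is the classic affine-invariant move.  ``scale_groups``
    interleaves likelihood-invariant rescaling MH updates every
    ``interweave_every`` ensemble sweeps (see :class:`ScaleGroup`).
    """
    nwalkers, ndim = init.shape
    if ndim != index.ndim:
        raise ValueError("init width does not match parameter index")
    if moves == "de":
        mv = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    elif moves == "stretch":
        mv = [(emcee.moves.StretchMove(), 1.0)]
    else:
        raise ValueError("moves must be 'de' or 'stretch'")

    def _lp(theta: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            out = log_prob(theta)
        return np.where(np.isfinite(out), out, -np.inf)

    sampler = emcee.EnsembleSampler(
        nwalkers, ndim, _lp, vectorize=True, moves=mv,
    )
    rs = np.random.RandomState(seed % (2**32))
    sampler._random = rs
    if not scale_groups:
        sampler.run_mcmc(init, settings.steps, progress=progress, skip_initial_state_check=True)
    else:
        state = emcee.State(init, log_prob=_lp(init))
        done = 0
        while done < settings.steps:
            seg = min(interweave_every, settings.steps - done)
            state = sampler.run_mcmc(state, seg, progress=False, skip_initial_state_check=True)
            done += seg
            coords = state.coords
            for group in scale_groups:
                for proposer in (group.propose, group.centered_propose):
                    new, log_ratio = proposer(coords, rs)
                    accept = np.log(rs.uniform(size=coords.shape[0])) < log_ratio
                    coords = np.where(accept[:, None], new, coords)
            state = emcee.State(coords, log_prob=_lp(coords))
    raw = sampler.get_chain()  # (steps, nwalkers, ndim)
    post = raw[settings.warmup :: settings.thin]
    chain = np.moveaxis(post, 0, 1)  # (nwalkers, draws, ndim)
    meta = {
        "sampler": "emcee-ensemble",
        "moves": moves,
        "chains": nwalkers,
        "iterations": settings.steps,
        "warmup": settings.warmup,
        "seed": int(seed),
        "acceptance_fraction": float(np.mean(sampler.acceptance_fraction)),
    }
    return PosteriorDraws(chain, index, meta=meta)


def ball_init(
    center: np.ndarray, nwalkers: int, rng: np.random.Generator, scale: float = 1e-2
) -> np.ndarray:
    """Small Gaussian ball around ``center`` — used for zero-initialised fits."""
    center = np.asarray(center, float)
    return center[None, :] + scale * rng.standard_normal((nwalkers, center.size))


def uniform_init(
    ndim: int, nwalkers: int, rng: np.random.Generator, low: float = -2.0, high: float = 2.0
) -> np.ndarray:
    """Random starting values uniform in (low, high), the non-gamma default."""
    return rng.uniform(low, high, size=(nwalkers, ndim))


def half_normal_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    """log density of |N(0, scale)| evaluated at x >= 0 (constants dropped)."""
    return -0.5 * (x / scale) ** 2


def normal_logpdf(x: np.ndarray, mu: float | np.ndarray, sd: float) -> np.ndarray:
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd)
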