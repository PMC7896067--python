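"""SBayesRS: the four-component mixture extension of the MAF-coupled model.

Each SNP effect follows

    beta_j ~ sum_k pi_k N(0, gamma_k h_j^S sigma_b^2),

with the variance-multiplier grid ``gamma = (0, 0.01, 0.1, 1)`` representing
zero, small, medium and large effects. The mixing probabilities have a
Dirichlet(1,1,1,1) prior; polygenicity is reported as the nonnull mass
``pi = pi_2 + pi_3 + pi_4``. ``S`` and ``sigma_b^2`` are shared across the
nonnull components; their full conditionals sum ``beta_j^2 / (gamma_k h_j^S)``
over the nonnull SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import mcmc
from ._kernels import sweep_mixture
from .ldmatrix import SparseLdMatrix
from .mcmc import McmcSamples, rinvchisq
from .pointnormal import (AdaptiveStep, ArchitectureResult, RunConfig,
                          SamplerData, _summarize, prepare_inputs,
                          s_log_target)
from .sumstats import SummaryDataset

logger = logging.getLogger(__name__)


@dataclass
class MixtureSpec:
    """Fixed variance-multiplier grid and Dirichlet hyperparameters."""

    gammas: tuple = (0.0, 0.01, 0.1, 1.0)
    dirichlet_alpha: tuple = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        g = np.asarray(self.gammas, float)
        if g[0] != 0.0:
            raise ValueError("first mixture component must be the point mass "
                             "(gamma_1 = 0)")
        if not np.all(np.diff(g) > 0):
            raise ValueError("gamma grid must be strictly ascending")
        if len(self.dirichlet_alpha) != len(g):
            raise ValueError("dirichlet_alpha length must match gammas")


def sample_mixture_pis(labels: np.ndarray, rng: np.random.Generator,
                       spec: MixtureSpec | None = None) -> np.ndarray:
    """Conjugate Dirichlet(alpha_k + m_k) draw from component counts."""
    spec = spec or MixtureSpec()
    K = len(spec.gammas)
    counts = np.bincount(labels, minlength=K)[:K]
    return rng.dirichlet(np.asarray(spec.dirichlet_alpha) + counts)


@dataclass
class MixtureRunConfig(RunConfig):
    mixture: MixtureSpec = field(default_factory=MixtureSpec)


def _run_chain_mixture(data: SamplerData, cfg: MixtureRunConfig, chain_id: int,
                       seed_seq: np.random.SeedSequence) -> McmcSamples:
    rng = np.random.default_rng(seed_seq)
    m = len(data.r)
    B = data.B
    gammas = np.asarray(cfg.mixture.gammas, float)
    K = len(gammas)
    logh = np.log(data.h)

    beta = np.zeros(m)
    r_adj = data.r.copy()
    labels = np.zeros(m, np.int64)
    prior = cfg.priors
    scale_e = prior.scale_e if prior.scale_e is not None else data.vary / 2.0
    scale_b = prior.scale_b
    if scale_b is None:
        scale_b = 0.5 * data.vary / (m * float(np.mean(data.h)))

    pis = rng.dirichlet(np.asarray(cfg.mixture.dirichlet_alpha))
    S = float(rng.standard_normal()) if cfg.estimate_S else cfg.S_fixed
    sigma_b2 = rinvchisq(rng, prior.nu_b, scale_b)
    sigma_e2 = rinvchisq(rng, prior.nu_e, scale_e)
    stepper = AdaptiveStep(cfg.mh_step)

    n_store = (cfg.iterations - cfg.burnin) // cfg.thin
    names = (["h2", "pi", "S", "sigma_g2", "sigma_e2", "sigma_b2", "nnz"]
             + [f"pi{k + 1}" for k in range(K)])
    draws = {k: np.empty(n_store) for k in names}
    beta_sum = np.zeros(m)
    pip_sum = np.zeros(m)
    kept = stored = 0

    state = mcmc.McmcState(beta=beta, r=data.r, r_adj=r_adj, h=data.h,
                           n=data.n, vary=data.vary, sigma_e2=sigma_e2,
                           sigma_b2=sigma_b2, pi=pis, S=S,
                           indicators=labels, vare_mul=data.vare_mul)

    for it in range(cfg.iterations):
        logpis = np.log(np.clip(pis, 1e-12, None))
        hpow = np.exp((state.S + 1.0) * logh)
        u = rng.random(m)
        z = rng.standard_normal(m)
        sweep_mixture(B.indptr, B.indices, B.data, state.r_adj, state.beta,
                      labels, data.n, hpow, gammas, state.sigma_b2,
                      logpis, state.sigma_e2, state.vare_mul, u, z)
        if cfg.rebuild_every and (it + 1) % cfg.rebuild_every == 0:
            state.r_adj = data.r - B @ state.beta

        state.sigma_g2 = mcmc.genetic_variance(state, B)
        state.sigma_e2 = mcmc.sample_sigma_e(state, rng, prior)

        nz = labels > 0
        if cfg.estimate_S:
            if it >= cfg.burnin:
                stepper.frozen = True
            if nz.any():
                lh = logh[nz]
                bsq = (state.beta[nz] ** 2 / data.h[nz]) / gammas[labels[nz]]
                cur = s_log_target(state.S, bsq, lh, state.sigma_b2)
                prop = state.S + stepper.step * rng.standard_normal()
                new = s_log_target(prop, bsq, lh, state.sigma_b2)
                acc = np.log(rng.random()) < new - cur
                stepper.record(bool(acc))
                if acc:
                    state.S = float(prop)
            else:
                state.S = float(rng.standard_normal())

        # sigma_b2 full conditional over nonnull components
        m_nz = int(nz.sum())
        if m_nz:
            ssq = float(np.sum((state.beta[nz] ** 2 / data.h[nz])
                               * np.exp(-state.S * logh[nz])
                               / gammas[labels[nz]]))
            df = prior.nu_b + m_nz
            state.sigma_b2 = rinvchisq(rng, df,
                                       (ssq + prior.nu_b * scale_b) / df)
        else:
            state.sigma_b2 = rinvchisq(rng, prior.nu_b, scale_b)

        pis = sample_mixture_pis(labels, rng, cfg.mixture)
        state.pi = pis

        if it >= cfg.burnin:
            beta_sum += state.beta / np.sqrt(data.h)
            pip_sum += nz
            kept += 1
            if (it - cfg.burnin) % cfg.thin == 0 and stored < n_store:
                draws["h2"][stored] = state.h2
                draws["pi"][stored] = float(pis[1:].sum())
                draws["S"][stored] = state.S
                draws["sigma_g2"][stored] = state.sigma_g2
                draws["sigma_e2"][stored] = state.sigma_e2
                draws["sigma_b2"][stored] = state.sigma_b2
                draws["nnz"][stored] = int(nz.sum())
                for k in range(K):
                    draws[f"pi{k + 1}"][stored] = pis[k]
                stored += 1

    return McmcSamples(
        chain_id=chain_id,
        draws={k: v[:stored] for k, v in draws.items()},
        beta_mean=beta_sum / max(kept, 1),
        pip=pip_sum / max(kept, 1),
        config={"iterations": cfg.iterations, "burnin": cfg.burnin,
                "thin": cfg.thin, "seed": cfg.seed, "chain": chain_id},
    )


def run_sbayesrs(ds: SummaryDataset, ld: SparseLdMatrix,
                 config: MixtureRunConfig | None = None) -> ArchitectureResult:
    """Run the four-component mixture sampler.

    The result's ``pi`` is the total nonnull mass; per-component posterior
    means are reported under ``extra`` as ``pi1 .. pi4``.
    """
    cfg = config or MixtureRunConfig()
    data = prepare_inputs(ds, ld, cfg)
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    chains = [_run_chain_mixture(data, cfg, i, s) for i, s in enumerate(seeds)]
    K = len(cfg.mixture.gammas)
    extra = {
        f"pi{k + 1}": float(np.concatenate(
            [ch.draws[f"pi{k + 1}"] for ch in chains]).mean())
        for k in range(K)
    }
    return _summarize(chains, data, cfg, extra=extra)
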