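"""Shared MCMC machinery for the summary-statistics samplers.

Internal effect scale
---------------------
All samplers operate on *standardized-genotype* effects,

    beta_std_j = beta_j * sqrt(h_j),    h_j = 2 p_j q_j,

so that the genetic variance is exactly the quadratic form
``sigma_g^2 = beta_std' B beta_std`` with ``B`` the LD correlation matrix,
and (with a standardized phenotype) the per-SNP marginal statistic is
``r_j = sqrt(h_j) * b_j``. The MAF-coupled prior ``beta_j ~ N(0, h_j^S
sigma_b^2)`` on the per-allele scale becomes ``beta_std_j ~ N(0, h_j^(S+1)
sigma_b^2)``. Genotype-scale effects are recovered by back-transformation
for reporting.

Right-hand-side updating
------------------------
The state carries ``r_adj = r - B beta_std`` (the marginal statistics
adjusted for the current fit). Updating one SNP touches only the sparse
column of ``B``, and the genetic variance is the difference of two inner
products, ``beta' r - beta' r_adj = beta' B beta``. The residual sum of
squares follows from the same two products:
``e'e / n = y'y/n - beta' r - beta' r_adj``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import norm

logger = logging.getLogger(__name__)


class McmcError(RuntimeError):
    """Numerical inconsistency detected during sampling."""


# ---------------------------------------------------------------------------
# distributions

def rinvchisq(rng: np.random.Generator, df: float, scale: float) -> float:
    """Draw from a scaled inverse chi-squared distribution.

    Parametrized so the density is that of ``df * scale / X`` with
    ``X ~ chi2(df)``; the mean is ``df * scale / (df - 2)`` for ``df > 2``.
    """
    return float(df * scale / rng.chisquare(df))


# ---------------------------------------------------------------------------
# state

@dataclass
class McmcState:
    """Current values of one chain.

    ``beta`` is on the standardized-genotype scale; ``r`` holds
    ``sqrt(h_j) b_j``; ``r_adj = r - B beta``. ``h`` is the genotype
    variance 2pq used in the prior coupling, ``n`` the per-SNP sample sizes
    and ``vary = y'y / median(n)`` the phenotypic variance estimate.
    """

    beta: np.ndarray
    r: np.ndarray
    r_adj: np.ndarray
    h: np.ndarray
    n: np.ndarray
    vary: float
    sigma_e2: float
    sigma_b2: float
    pi: float | np.ndarray
    S: float
    indicators: np.ndarray = None
    sigma_g2: float = 0.0
    vare_mul: np.ndarray = None  # optional per-SNP residual inflation

    def __post_init__(self) -> None:
        m = len(self.beta)
        if self.indicators is None:
            self.indicators = np.zeros(m, np.int64)
        if self.vare_mul is None:
            self.vare_mul = np.ones(m)

    @property
    def h2(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


def rebuild_r_adj(state: McmcState, B: sp.spmatrix) -> np.ndarray:
    """Recompute ``r_adj`` from scratch (consistency oracle / guard)."""
    return state.r - B @ state.beta


def residualize_rhs(state: McmcState, B: sp.spmatrix, j: int, beta_new: float) -> McmcState:
    """Set ``beta[j] = beta_new`` and update ``r_adj`` through column j of B."""
    diff = beta_new - state.beta[j]
    if diff != 0.0:
        col = B.getcol(j).tocoo()
        state.r_adj[col.row] -= col.data * diff
        state.beta[j] = beta_new
    return state


def genetic_variance(state: McmcState, B: sp.spmatrix | None = None) -> float:
    """``sigma_g^2 = beta' r - beta' r_adj`` (equals ``beta' B beta``).

    A negative value beyond floating-point tolerance triggers a rebuild of
    ``r_adj`` when ``B`` is supplied. A value that stays negative after the
    rebuild reflects an indefinite sparsified LD matrix (possible when the
    reference sample is small relative to the sparsification threshold);
    it is clamped to zero with a warning.
    """
    tol = 1e-8 * max(1.0, state.vary)
    val = float(state.beta @ state.r - state.beta @ state.r_adj)
    if val < -tol and B is not None:
        state.r_adj = rebuild_r_adj(state, B)
        val = float(state.beta @ state.r - state.beta @ state.r_adj)
    if val < -tol:
        logger.warning("negative genetic variance %.3g clamped to 0 "
                       "(indefinite sparsified LD matrix)", val)
    return max(val, 0.0)


def residual_ss(state: McmcState) -> float:
    """``e'e / n = y'y/n - beta' r - beta' r_adj`` with a degeneracy floor."""
    ee = state.vary - float(state.beta @ state.r) - float(state.beta @ state.r_adj)
    floor = 1e-6 * state.vary
    if ee <= floor:
        logger.warning("e'e/n %.3g at or below floor; clamping (degenerate fit)", ee)
        ee = floor
    return ee


# ---------------------------------------------------------------------------
# variance-component updates

@dataclass
class PriorConfig:
    """Weakly informative scaled inverse chi-squared hyperparameters."""

    nu_e: float = 4.0
    nu_b: float = 4.0
    scale_e: float | None = None  # default: vary / 2
    scale_b: float | None = None  # default: h2=0.5 spread over all m SNPs
                                  # (a weak anchor; the conditional is data-
                                  # dominated once a few SNPs are included)


def sample_sigma_e(state: McmcState, rng: np.random.Generator,
                   prior: PriorConfig | None = None) -> float:
    """Draw the residual variance from its scaled inverse chi-squared
    full conditional, with scale driven by ``e'e``."""
    prior = prior or PriorConfig()
    n = float(np.median(state.n))
    scale_e = prior.scale_e if prior.scale_e is not None else state.vary / 2.0
    ee = residual_ss(state) * n  # back to sum-of-squares units
    df = prior.nu_e + n
    scale = (ee + prior.nu_e * scale_e) / df
    return rinvchisq(rng, df, scale)


def sample_sigma_beta(state: McmcState, rng: np.random.Generator,
                      prior: PriorConfig | None = None) -> float:
    """Draw ``sigma_b^2`` from its full conditional given the nonzero
    genotype-scale effects: sum over included j of ``beta_j^2 / h_j^S``."""
    prior = prior or PriorConfig()
    nz = state.indicators > 0
    m = len(state.beta)
    scale_b = prior.scale_b
    if scale_b is None:
        scale_b = 0.5 * state.vary / (max(m, 1) * float(np.mean(state.h)))
    m_nz = int(nz.sum())
    if m_nz == 0:
        return rinvchisq(rng, prior.nu_b, scale_b)
    beta_geno = state.beta[nz] / np.sqrt(state.h[nz])
    ssq = float(np.sum(beta_geno**2 * np.exp(-state.S * np.log(state.h[nz]))))
    df = prior.nu_b + m_nz
    return rinvchisq(rng, df, (ssq + prior.nu_b * scale_b) / df)


def sample_pi(state: McmcState, rng: np.random.Generator) -> float:
    """Conjugate Beta(1 + m_NZ, 1 + m - m_NZ) draw under the U(0,1) prior."""
    m = len(state.beta)
    m_nz = int((state.indicators > 0).sum())
    return float(rng.beta(1.0 + m_nz, 1.0 + m - m_nz))


# ---------------------------------------------------------------------------
# convergence diagnostics

@dataclass
class GelmanRubin:
    """Potential scale reduction statistic for one parameter."""

    T: int
    W: float
    B_between: float
    var_hat: float
    R_hat: float

    @property
    def flagged(self) -> bool:
        return not np.isfinite(self.R_hat)


def gelman_rubin(chains) -> GelmanRubin:
    """Gelman-Rubin statistic from >= 2 equal-length chains of draws.

    ``var_hat = (T-1)/T * W + B/T`` with W the mean within-chain variance
    and B the between-chain variance (T times the variance of chain means);
    ``R_hat = sqrt(var_hat / W)``. Degenerate chains (W = 0) give a
    non-finite, flagged R_hat.
    """
    arr = np.asarray(chains, float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length T >= 2")
    M, T = arr.shape
    W = float(np.mean(np.var(arr, axis=1, ddof=1)))
    B = float(T * np.var(np.mean(arr, axis=1), ddof=1))
    var_hat = (T - 1) / T * W + B / T
    with np.errstate(divide="ignore", invalid="ignore"):
        R = float(np.sqrt(var_hat / W)) if W > 0 else float("inf")
    return GelmanRubin(T=T, W=W, B_between=B, var_hat=var_hat, R_hat=R)


@dataclass
class ConvergenceVerdict:
    converged: bool
    failing: list = field(default_factory=list)
    r_hats: dict = field(default_factory=dict)

    def __str__(self) -> str:
        stat = "converged" if self.converged else "NOT converged"
        parts = ", ".join(f"{k}: R-hat={v:.4f}" for k, v in self.r_hats.items())
        extra = f" (failing: {', '.join(self.failing)})" if self.failing else ""
        return f"{stat} [{parts}]{extra}"


R_HAT_LIMIT = 1.2


def convergence_check(results: dict) -> ConvergenceVerdict:
    """Converged iff every parameter's R_hat is strictly below 1.2."""
    failing = [
        name for name, gr in results.items()
        if not (np.isfinite(gr.R_hat) and gr.R_hat < R_HAT_LIMIT)
    ]
    return ConvergenceVerdict(
        converged=not failing,
        failing=failing,
        r_hats={k: gr.R_hat for k, gr in results.items()},
    )


# ---------------------------------------------------------------------------
# scale conversions

def liability_transform(h2_obs: float, K: float, P: float) -> float:
    """Observed-scale to liability-scale heritability for a binary trait.

    Under the liability-threshold model with population prevalence ``K`` and
    sample case proportion ``P``,

        h2_lia = h2_obs * K^2 (1-K)^2 / (z^2 P (1-P))

    where ``z`` is the standard normal density at the threshold
    ``Phi^{-1}(1-K)``.
    """
    if not (0.0 < K < 1.0 and 0.0 < P < 1.0):
        raise ValueError("K and P must lie strictly inside (0, 1)")
    if h2_obs < 0:
        raise ValueError("h2_obs must be non-negative")
    z = norm.pdf(norm.ppf(1.0 - K))
    return h2_obs * K**2 * (1.0 - K) ** 2 / (z**2 * P * (1.0 - P))


# ---------------------------------------------------------------------------
# stored draws

@dataclass
class McmcSamples:
    """Post-burn-in draws of one chain plus running posterior summaries."""

    chain_id: int
    draws: dict                      # name -> 1-D array of stored draws
    beta_mean: np.ndarray            # posterior mean effects, genotype scale
    pip: np.ndarray                  # posterior inclusion probabilities
    config: dict

    def __len__(self) -> int:
        return len(next(iter(self.draws.values())))
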