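"""Discrete-generation Wright-Fisher forward simulation under pleiotropic
selection, with the out-of-Africa style demography used for evolutionary
calibration of the genetic-architecture parameters.

The demography is, in unscaled generations: an ancestral population of
7,310 that expands to 14,474 after a 52,080-generation neutral burn-in
(~1.3 million years at 25 years per generation), a split of 1,861
individuals at generation 55,960, a bottleneck to 1,032 at generation
57,080, and continuous exponential growth at rate 0.0038 per generation
until generation 58,000, reaching 34,039 individuals.

For desk-scale runs the standard population-genetic rescaling is applied:
population sizes and generation counts are divided by ``scale`` while
mutation, recombination, selection coefficients and the growth rate are
multiplied by it, which preserves the population-scaled parameters
(4N mu, 4N r, 4N s).

Trait mutations arise as a fraction ``pim`` of new mutations, with causal
effects from the three-normal mixture whose scale is calibrated so the
mutational heritability is ``h2m = 2 L pim mu V_beta`` (in environmental-
variance units). Selection couples to effects through ``s_j = k beta_j^2``
with ``k = sbar / V_beta``; fitness is multiplicative across loci and
semidominant (heterozygote ``1 - s/2``), a configurable reconstruction.
Optionally a fraction ``pim_b`` of trait mutations is beneficial with its
own mean coefficient ``sbar_b``. At the end of selection the trait effects
of segregating causal variants are remodelled by either the n_t-traits
pleiotropy model (``beta ~ N(0, s / (k n_t))``) or the Eyre-Walker model
(``beta = delta (4 Ne s)^tau (1 + eps)``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from numba import njit

from . import simulate as sim
from .ldmatrix import compute_sparse_ld
from .pointnormal import RunConfig, run_sbayess

logger = logging.getLogger(__name__)


@dataclass
class Epoch:
    """One demographic epoch: constant size, or exponential growth when
    ``growth`` is nonzero (continuous ``N0 * exp(growth * t)``)."""

    generations: int
    size: int
    growth: float = 0.0

    def size_at(self, t: int) -> int:
        if self.growth == 0.0:
            return self.size
        return max(2, int(round(self.size * math.exp(self.growth * t))))


def default_demography() -> list:
    """The four-epoch bottleneck-and-expansion demography (unscaled)."""
    return [
        Epoch(52_080, 7_310),
        Epoch(55_960 - 52_080, 14_474),
        Epoch(57_080 - 55_960, 1_861),
        Epoch(58_000 - 57_080, 1_032, growth=0.0038),
    ]


def final_epoch_size(n0: int = 1032, rate: float = 0.0038,
                     generations: int = 920) -> int:
    """Final size under continuous exponential growth, nearest integer."""
    return int(round(n0 * math.exp(rate * generations)))


def burnin_years(generations: int = 52_080, years_per_gen: float = 25.0) -> float:
    return generations * years_per_gen


@dataclass
class EvoSimConfig:
    """Evolutionary inputs for one forward simulation."""

    sbar: float = 1e-3            # mean selection coefficient of trait mutations
    pim: float = 0.01             # fraction of mutations affecting the trait
    h2m: float = 1e-3             # mutational heritability (env-variance units)
    mu: float = 1.65e-8           # mutation rate per bp per generation
    L: float = 1e7                # simulated genome length in bp
    recomb: float = 1e-8          # recombination rate per bp per generation
    model: str = "simons"         # "simons" or "eyre_walker"
    n_t: int = 1                  # traits sharing selection (simons model)
    tau: float = 0.5              # fitness-trait coupling (eyre_walker model)
    sigma2: float = 0.1           # eyre_walker effect noise
    pim_b: float = 0.0            # fraction of trait mutations beneficial
    sbar_b: float = 1e-3          # mean beneficial selection coefficient
    demography: list = field(default_factory=default_demography)
    scale: int = 100              # rescaling factor for desk runs
    s_max: float = 0.9            # cap on the scaled coefficient in fitness
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pim", "h2m", "mu", "L", "recomb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sbar < 0:
            raise ValueError("sbar must be non-negative (0 = neutral)")
        if not (0.0 <= self.pim_b < 1.0):
            raise ValueError("pim_b must lie in [0, 1)")
        if self.model not in ("simons", "eyre_walker"):
            raise ValueError(f"unknown pleiotropy model {self.model!r}")


@dataclass
class CausalArchitecture:
    """Causal variants surviving selection, with both the original and the
    pleiotropy-remodelled effects."""

    beta: np.ndarray        # remodelled focal-trait effects (env-SD units)
    beta_raw: np.ndarray    # effects as drawn from the mixture
    s: np.ndarray           # unscaled selection coefficients (signed;
                            # negative = beneficial)
    freqs: np.ndarray
    k: float
    Vbeta: float
    sigma_b2: float


@dataclass
class ForwardResult:
    haplotypes: np.ndarray      # final-generation haplotypes (2N x sites)
    positions: np.ndarray
    freqs: np.ndarray
    is_causal: np.ndarray
    arch: CausalArchitecture
    config: EvoSimConfig


class _Population:
    """Mutable haplotype store; columns kept sorted by position."""

    def __init__(self, n_ind: int):
        self.H = np.zeros((2 * n_ind, 0), np.uint8)
        self.pos = np.zeros(0)
        self.beta = np.zeros(0)
        self.s = np.zeros(0)       # unscaled, signed
        self.causal = np.zeros(0, bool)

    @property
    def n_ind(self) -> int:
        return self.H.shape[0] // 2

    def prune(self) -> None:
        counts = self.H.sum(axis=0, dtype=np.int64)
        seg = (counts > 0) & (counts < self.H.shape[0])
        if not seg.all():
            self.H = np.ascontiguousarray(self.H[:, seg])
            self.pos = self.pos[seg]
            self.beta = self.beta[seg]
            self.s = self.s[seg]
            self.causal = self.causal[seg]


def forward_simulate(cfg: EvoSimConfig,
                     rng: np.random.Generator | None = None) -> ForwardResult:
    """Run the scaled Wright-Fisher simulation and remodel causal effects."""
    rng = rng or np.random.default_rng(cfg.seed)
    lam = cfg.scale
    mu_s = cfg.mu * lam
    recomb_s = cfg.recomb * lam
    Vbeta = cfg.h2m / (2.0 * cfg.L * cfg.pim * cfg.mu)
    sigma_b2 = Vbeta / sim.MIXTURE_VAR_FACTOR
    k = cfg.sbar / Vbeta
    k_b = cfg.sbar_b / Vbeta if cfg.pim_b > 0 else 0.0
    map_len = recomb_s * cfg.L   # expected crossovers per meiosis

    pop = _Population(max(2, cfg.demography[0].size // lam))
    gen_total = 0
    for ep_i, ep in enumerate(cfg.demography):
        gens = max(1, ep.generations // lam)
        for t in range(gens):
            # continuous exponential growth uses unscaled time
            n_next = max(2, ep.size_at((t + 1) * lam) // lam) \
                if ep.growth else max(2, ep.size // lam)
            _advance_generation(pop, n_next, cfg, rng, mu_s, map_len,
                                k, k_b, sigma_b2, lam)
            gen_total += 1
            pop.prune()
        if pop.H.shape[1] == 0 and ep_i == len(cfg.demography) - 1:
            raise RuntimeError("no segregating variants at end of simulation")
    pop.prune()
    if pop.n_ind < 2:
        raise RuntimeError("population extinct under selection")

    order = np.argsort(pop.pos)
    H = pop.H[:, order]
    pos = pop.pos[order]
    beta_raw = pop.beta[order]
    s = pop.s[order]
    causal = pop.causal[order]
    freqs = H.mean(axis=0)

    beta = beta_raw.copy()
    cz = causal & (s != 0)
    if cz.any():
        if cfg.model == "simons":
            beta[cz] = sim.pleiotropy_simons(np.abs(s[cz]), k, cfg.n_t, rng)
        else:
            beta[cz] = sim.pleiotropy_eyre_walker(np.abs(s[cz]), cfg.tau,
                                                  cfg.sigma2, rng)
            # Eyre-Walker effects come out on the 4*Ne*s scale; rescale so
            # the effect variance matches the mixture calibration
            sd = beta[cz].std()
            if sd > 0:
                beta[cz] *= math.sqrt(Vbeta) / sd
    arch = CausalArchitecture(beta=beta[causal], beta_raw=beta_raw[causal],
                              s=s[causal], freqs=freqs[causal], k=k,
                              Vbeta=Vbeta, sigma_b2=sigma_b2)
    logger.info("forward sim: %d segregating sites, %d causal, final N=%d",
                H.shape[1], int(causal.sum()), pop.n_ind)
    return ForwardResult(haplotypes=H, positions=pos, freqs=freqs,
                         is_causal=causal, arch=arch, config=cfg)


@njit(cache=True)
def _gametes(H, pos, parents, starts, cx_flat, cx_off, out):
    """Build gametes by walking sorted positions against sorted crossover
    points; ``out[g]`` copies from the parent's two haplotypes according to
    the recombination phase."""
    n_sites = pos.shape[0]
    for g in range(out.shape[0]):
        par = parents[g]
        h0 = H[2 * par]
        h1 = H[2 * par + 1]
        a, b = cx_off[g], cx_off[g + 1]
        phase = starts[g]
        k = a
        for j in range(n_sites):
            while k < b and cx_flat[k] < pos[j]:
                phase = 1 - phase
                k += 1
            out[g, j] = h0[j] if phase == 0 else h1[j]


def _advance_generation(pop: _Population, n_next: int, cfg: EvoSimConfig,
                        rng, mu_s, map_len, k, k_b, sigma_b2, lam) -> None:
    n_prev = pop.n_ind
    # fitness: multiplicative, semidominant; signed s (negative = beneficial)
    csel = np.flatnonzero(pop.causal & (pop.s != 0))
    if csel.size:
        s_eff = np.clip(pop.s[csel] * lam, -cfg.s_max, cfg.s_max)
        G = (pop.H[0::2][:, csel] + pop.H[1::2][:, csel]).astype(float)
        logw = G @ np.log1p(-0.5 * s_eff)
        logw -= logw.max()
        w = np.exp(logw)
        wsum = w.sum()
        if wsum <= 0 or not np.isfinite(wsum):
            raise RuntimeError("population extinct under selection")
        probs = w / wsum
    else:
        probs = np.full(n_prev, 1.0 / n_prev)

    parents = rng.choice(n_prev, size=2 * n_next, p=probs)
    n_sites = pop.H.shape[1]
    children = np.empty((2 * n_next, n_sites), np.uint8)
    n_cx = rng.poisson(map_len, size=2 * n_next)
    starts = rng.integers(0, 2, size=2 * n_next).astype(np.int64)
    cx_off = np.zeros(2 * n_next + 1, np.int64)
    np.cumsum(n_cx, out=cx_off[1:])
    cx_flat = rng.uniform(0.0, cfg.L, size=int(cx_off[-1]))
    for g in range(2 * n_next):
        cx_flat[cx_off[g]:cx_off[g + 1]].sort()
    _gametes(pop.H, pop.pos, parents, starts, cx_flat, cx_off, children)
    pop.H = children

    # new mutations, merged keeping positions sorted
    n_new = rng.poisson(2 * n_next * mu_s * cfg.L)
    if n_new:
        newpos = rng.uniform(0.0, cfg.L, size=n_new)
        carriers = rng.integers(0, 2 * n_next, size=n_new)
        trait = rng.random(n_new) < cfg.pim
        beta_new = np.zeros(n_new)
        s_new = np.zeros(n_new)
        nt = int(trait.sum())
        if nt:
            b = sim.draw_causal_effects(nt, sigma_b2, rng)
            beta_new[trait] = b
            s_trait = k * b**2
            if cfg.pim_b > 0:
                beneficial = rng.random(nt) < cfg.pim_b
                s_trait = np.where(beneficial, -k_b * b**2, s_trait)
            s_new[trait] = s_trait
        cols = np.zeros((2 * n_next, n_new), np.uint8)
        cols[carriers, np.arange(n_new)] = 1
        pos = np.concatenate([pop.pos, newpos])
        order = np.argsort(pos, kind="stable")
        pop.H = np.ascontiguousarray(
            np.concatenate([pop.H, cols], axis=1)[:, order])
        pop.pos = pos[order]
        pop.beta = np.concatenate([pop.beta, beta_new])[order]
        pop.s = np.concatenate([pop.s, s_new])[order]
        pop.causal = np.concatenate([pop.causal, trait])[order]


# ---------------------------------------------------------------------------
# evolutionary replicate: forward sim -> summary stats -> architecture fit

@dataclass
class EvoReplicate:
    """True and estimated genetic-architecture parameters for one run."""

    h2_true: float
    m_causal_common: int
    S_ols: float
    h2_hat: float
    pi_hat: float
    nnz_hat: float
    S_hat: float
    m_analysed: int


def evo_replicate(cfg: EvoSimConfig, rng: np.random.Generator,
                  n_gwas: float = 350_000,
                  maf_min: float = 0.01,
                  relatedness_max: float = 1.0,
                  run_config: RunConfig | None = None,
                  use_markers: bool = False,
                  m_ref: int = 1_100_000,
                  L_ref: float = 3e9,
                  sampler: str = "mixture") -> EvoReplicate:
    """One full evolutionary replicate.

    Runs the forward simulation, takes the (optionally unrelatedness-
    filtered) final generation, computes sparse LD at the common causal
    variants (or, with ``use_markers``, a density-matched random marker
    set excluding causal variants), simulates GWAS summary statistics at
    ``alpha ~ N(B beta, vary B / N)`` and fits the point-normal model.
    """
    fwd = forward_simulate(cfg, rng)
    H = fwd.haplotypes
    X = (H[0::2] + H[1::2]).astype(float)
    if relatedness_max < 1.0:
        keep = sim.unrelated_indices(X, threshold=relatedness_max)
        X = X[keep]
    n_ind = X.shape[0]
    freqs = X.mean(axis=0) / 2.0
    maf = np.minimum(freqs, 1.0 - freqs)

    causal_idx = np.flatnonzero(fwd.is_causal)
    common_causal = causal_idx[maf[causal_idx] >= maf_min]
    if common_causal.size < 2:
        raise RuntimeError("fewer than 2 common causal variants survived")

    # true architecture
    beta_all = np.zeros(H.shape[1])
    beta_all[causal_idx] = fwd.arch.beta
    g = (X - X.mean(axis=0)) @ beta_all
    sg2 = float(np.var(g))
    vary = sg2 + 1.0
    h2_true = sg2 / vary
    slope, _, _ = sim.ols_S(beta_all[common_causal], freqs[common_causal])

    if use_markers:
        markers = sim.subsample_snps(freqs, m_ref, L_ref, cfg.L, rng,
                                     causal=causal_idx, maf_min=maf_min)
    else:
        markers = common_causal
    Xm = X[:, markers]
    snp_map = pd.DataFrame({
        "SNP": [f"v{j}" for j in markers], "chrom": "1",
        "pos": np.round(fwd.positions[markers]).astype(np.int64) + 1,
    })
    # dense within-chromosome LD: the reference is the analysed sample
    # itself and the sample correlation is positive semidefinite, which a
    # chi-squared-thresholded matrix from a small panel need not be
    ld = compute_sparse_ld(Xm, snp_map, chisq_threshold=0.0)

    # expected standardized marginal effects from the realized genotypes
    Z = (Xm - Xm.mean(axis=0)) / Xm.std(axis=0)
    alpha_mean = (Z.T @ (g - g.mean())) / n_ind
    ds = sim.simulate_summary_stats(ld, np.zeros(len(markers)), n_gwas, rng,
                                    vary=vary, alpha_mean=alpha_mean)
    cfg_run = run_config or RunConfig(iterations=3000, burnin=1000, thin=2,
                                      chains=2, seed=int(rng.integers(2**31)))
    if sampler == "mixture":
        # the mixture prior is markedly more robust than the single normal
        # when the true effect distribution is heavy-tailed, which matters
        # most for the S estimate under weak selection
        from .mixture import MixtureRunConfig, run_sbayesrs
        mix_cfg = MixtureRunConfig(**{f.name: getattr(cfg_run, f.name)
                                      for f in fields(RunConfig)})
        res = run_sbayesrs(ds, ld, mix_cfg)
    else:
        res = run_sbayess(ds, ld, cfg_run)
    nnz = float(np.mean(np.concatenate(
        [ch.draws["nnz"] for ch in res.chains])))
    return EvoReplicate(
        h2_true=h2_true, m_causal_common=int(common_causal.size),
        S_ols=slope, h2_hat=res.h2_mean, pi_hat=res.pi_mean,
        nnz_hat=nnz, S_hat=res.S_mean, m_analysed=len(markers),
    )
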