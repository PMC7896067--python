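"""Annotation-stratified model (two components) and cross-trait meta-analysis.

One focal annotation category is analysed at a time: SNPs inside the
category and the remaining SNPs each get their own ``(S, pi, sigma_b^2)``
while sharing a single residual variance, and all effects are sampled
jointly against the same LD matrix. Per iteration the category genetic
variance is the partial quadratic form ``sum_{j in c} beta_j (B beta)_j``,
so category plus complement always add up to the genome-wide genetic
variance exactly.

Enrichment of a parameter is the posterior mean of the per-iteration ratio
of the category value to the genome-wide value computed empirically from
the sampled effects (per-SNP heritability, per-nonzero-effect heritability
and polygenicity folds). Meta-analysis across traits reports the median
fold per category, with a standard error of the mean scaled by the
effective number of independent traits from the eigenvalues of the
phenotypic correlation matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mcmc
from ._kernels import sweep_spike_slab
from .ldmatrix import SparseLdMatrix
from .mcmc import rinvchisq
from .pointnormal import (AdaptiveStep, RunConfig, SamplerData,
                          prepare_inputs, s_log_target)
from .sumstats import SummaryDataset

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    pass


@dataclass
class AnnotationSet:
    """Binary category membership per SNP; overlap between categories is
    allowed. ``df`` has a ``SNP`` column plus one 0/1 column per category."""

    df: pd.DataFrame

    @property
    def categories(self) -> list:
        return [c for c in self.df.columns if c != "SNP"]

    def membership(self, name: str, ids) -> np.ndarray:
        """Boolean membership vector for ``ids`` (absent SNPs are outside)."""
        if name not in self.df.columns:
            raise AnnotationError(f"unknown category {name!r}")
        inside = set(self.df.loc[self.df[name].astype(int) == 1, "SNP"].astype(str))
        member = np.array([s in inside for s in np.asarray(ids, str)])
        if member.all() or not member.any():
            raise AnnotationError(
                f"category {name!r} is degenerate on the analysed SNPs")
        return member


def read_annot(path) -> AnnotationSet:
    """Read an LDSC-style annot table: SNP id column plus binary flags."""
    df = pd.read_csv(path, sep=r"\s+", dtype={"SNP": str})
    if "SNP" not in df.columns:
        raise AnnotationError(f"{path}: annot table needs a SNP column")
    return AnnotationSet(df=df)


def annotation_from_bed(path, snp_map: pd.DataFrame, name: str) -> AnnotationSet:
    """Map BED intervals (0-based half-open) onto a SNP map (1-based pos)."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["chrom", "start", "end"], usecols=[0, 1, 2],
                      dtype={"chrom": str})
    chroms = snp_map["chrom"].astype(str).str.lstrip("chr").to_numpy()
    pos0 = snp_map["pos"].to_numpy(float) - 1.0
    member = np.zeros(len(snp_map), bool)
    for _, row in bed.iterrows():
        c = str(row["chrom"]).lstrip("chr")
        member |= (chroms == c) & (pos0 >= row["start"]) & (pos0 < row["end"])
    return AnnotationSet(df=pd.DataFrame({
        "SNP": snp_map["SNP"].astype(str), name: member.astype(int)}))


# ---------------------------------------------------------------------------
# enrichment arithmetic

def enrichment_fold(theta_c_draws, theta_global_draws):
    """Posterior mean and standard deviation of the per-iteration ratio.

    Iterations where the genome-wide draw is zero are excluded and counted.
    """
    c = np.asarray(theta_c_draws, float)
    g = np.asarray(theta_global_draws, float)
    if c.shape != g.shape:
        raise ValueError("draw vectors must have equal length")
    ok = g != 0
    excluded = int((~ok).sum())
    if excluded:
        logger.warning("enrichment_fold: %d iterations with zero genome-wide "
                       "value excluded", excluded)
    ratio = c[ok] / g[ok]
    return float(ratio.mean()), float(ratio.std()), excluded


def effective_traits(corr: np.ndarray) -> float:
    """Effective number of independent traits from a phenotypic correlation
    matrix: ``(sum lambda_i)^2 / sum lambda_i^2``."""
    corr = np.asarray(corr, float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    lam = np.linalg.eigvalsh(corr)
    return float(lam.sum() ** 2 / np.sum(lam**2))


def meta_combine(per_trait: dict, corr: np.ndarray) -> pd.DataFrame:
    """Median fold across traits with s.e.m. = SD / sqrt(n_e).

    ``per_trait`` maps trait name -> mapping of quantity name -> posterior
    mean fold (e.g. the ``folds`` attribute of :class:`EnrichmentResult`).
    """
    if len(per_trait) < 2:
        raise ValueError("meta-analysis needs at least two traits")
    ne = effective_traits(corr)
    table = pd.DataFrame(per_trait).T  # traits x quantities
    out = pd.DataFrame({
        "median": table.median(axis=0),
        "sem": table.std(axis=0, ddof=1) / np.sqrt(ne),
    })
    out.attrs["n_e"] = ne
    return out


# ---------------------------------------------------------------------------
# the two-component sampler

@dataclass
class EnrichmentResult:
    """Posterior summaries of the focal-category parameters and folds."""

    category: str
    m_category: int
    S_c_mean: float
    S_c_pse: float
    S_rest_mean: float
    S_rest_pse: float
    pi_c_mean: float
    pi_c_pse: float
    folds: dict                 # quantity -> posterior mean fold
    folds_pse: dict
    draws: dict
    global_result: dict
    verdict: mcmc.ConvergenceVerdict | None = None


def run_strat(ds: SummaryDataset, ld: SparseLdMatrix, category: np.ndarray,
              config: RunConfig | None = None,
              name: str = "focal") -> EnrichmentResult:
    """Fit the two-component model for one focal category.

    ``category`` is a boolean membership vector over the analysed SNPs
    (map order). Chains are pooled for the fold summaries; R-hat is
    computed for the three genome-wide parameters when >= 2 chains run.
    """
    cfg = config or RunConfig()
    data = prepare_inputs(ds, ld, cfg)
    member = np.asarray(category, bool)
    if member.shape != data.ids.shape:
        raise AnnotationError("membership length does not match dataset")
    if member.all() or not member.any():
        raise AnnotationError("degenerate category")

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    chain_draws = [_run_chain_strat(data, cfg, member, i, s)
                   for i, s in enumerate(seeds)]
    pooled = {k: np.concatenate([d[k] for d in chain_draws])
              for k in chain_draws[0]}

    if cfg.chains >= 2:
        grs = {p: mcmc.gelman_rubin([d[p] for d in chain_draws])
               for p in (("h2", "pi_global", "S_c") if cfg.estimate_S
                         else ("h2", "pi_global"))}
        verdict = mcmc.convergence_check(grs)
    else:
        verdict = None

    folds, folds_pse = {}, {}
    for q in ("h2_per_snp", "h2_per_nze", "pi"):
        folds[q] = float(np.nanmean(pooled[f"fold_{q}"]))
        folds_pse[q] = float(np.nanstd(pooled[f"fold_{q}"]))
    return EnrichmentResult(
        category=name, m_category=int(member.sum()),
        S_c_mean=float(pooled["S_c"].mean()), S_c_pse=float(pooled["S_c"].std()),
        S_rest_mean=float(pooled["S_rest"].mean()),
        S_rest_pse=float(pooled["S_rest"].std()),
        pi_c_mean=float(pooled["pi_c"].mean()),
        pi_c_pse=float(pooled["pi_c"].std()),
        folds=folds, folds_pse=folds_pse, draws=pooled,
        global_result={
            "h2_mean": float(pooled["h2"].mean()),
            "pi_mean": float(pooled["pi_global"].mean()),
        },
        verdict=verdict,
    )


def _run_chain_strat(data: SamplerData, cfg: RunConfig, member: np.ndarray,
                     chain_id: int, seed_seq) -> dict:
    rng = np.random.default_rng(seed_seq)
    m = len(data.r)
    B = data.B
    logh = np.log(data.h)
    groups = [~member, member]   # 0 = rest, 1 = focal
    mg = [int(g.sum()) for g in groups]

    prior = cfg.priors
    scale_e = prior.scale_e if prior.scale_e is not None else data.vary / 2.0
    scale_b = prior.scale_b
    if scale_b is None:
        scale_b = 0.5 * data.vary / (m * float(np.mean(data.h)))

    beta = np.zeros(m)
    r_adj = data.r.copy()
    indicators = np.zeros(m, np.int64)
    pi_g = rng.uniform(size=2)
    S_g = (rng.standard_normal(2) if cfg.estimate_S
           else np.full(2, cfg.S_fixed))
    sb2_g = np.array([rinvchisq(rng, prior.nu_b, scale_b) for _ in range(2)])
    sigma_e2 = rinvchisq(rng, prior.nu_e, scale_e)
    steppers = [AdaptiveStep(cfg.mh_step) for _ in range(2)]

    state = mcmc.McmcState(beta=beta, r=data.r, r_adj=r_adj, h=data.h,
                           n=data.n, vary=data.vary, sigma_e2=sigma_e2,
                           sigma_b2=float(sb2_g[0]), pi=float(pi_g[0]),
                           S=float(S_g[0]), indicators=indicators,
                           vare_mul=data.vare_mul)

    n_store = (cfg.iterations - cfg.burnin) // cfg.thin
    names = ["h2", "pi_global", "S_c", "S_rest", "pi_c", "pi_rest", "h2_c",
             "fold_h2_per_snp", "fold_h2_per_nze", "fold_pi"]
    draws = {k: np.empty(n_store) for k in names}
    stored = 0

    logpi = np.empty(m)
    log1mpi = np.empty(m)
    vprior = np.empty(m)
    for it in range(cfg.iterations):
        for g, mask in enumerate(groups):
            pc = min(max(pi_g[g], 1e-12), 1 - 1e-12)
            logpi[mask] = np.log(pc)
            log1mpi[mask] = np.log1p(-pc)
            vprior[mask] = np.exp((S_g[g] + 1.0) * logh[mask]) * sb2_g[g]
        u = rng.random(m)
        z = rng.standard_normal(m)
        sweep_spike_slab(B.indptr, B.indices, B.data, state.r_adj, state.beta,
                         indicators, data.n, vprior, logpi, log1mpi,
                         state.sigma_e2, state.vare_mul, u, z)
        if cfg.rebuild_every and (it + 1) % cfg.rebuild_every == 0:
            state.r_adj = data.r - B @ state.beta

        state.sigma_g2 = mcmc.genetic_variance(state, B)
        state.sigma_e2 = mcmc.sample_sigma_e(state, rng, prior)

        for g, mask in enumerate(groups):
            nz = mask & (indicators > 0)
            m_nz = int(nz.sum())
            if cfg.estimate_S:
                if it >= cfg.burnin:
                    steppers[g].frozen = True
                if m_nz:
                    lh = logh[nz]
                    bsq = state.beta[nz] ** 2 / data.h[nz]
                    cur = s_log_target(S_g[g], bsq, lh, sb2_g[g])
                    prop = S_g[g] + steppers[g].step * rng.standard_normal()
                    new = s_log_target(prop, bsq, lh, sb2_g[g])
                    acc = np.log(rng.random()) < new - cur
                    steppers[g].record(bool(acc))
                    if acc:
                        S_g[g] = float(prop)
                else:
                    S_g[g] = float(rng.standard_normal())
            if m_nz:
                ssq = float(np.sum(state.beta[nz] ** 2 / data.h[nz]
                                   * np.exp(-S_g[g] * logh[nz])))
                df = prior.nu_b + m_nz
                sb2_g[g] = rinvchisq(rng, df, (ssq + prior.nu_b * scale_b) / df)
            else:
                sb2_g[g] = rinvchisq(rng, prior.nu_b, scale_b)
            pi_g[g] = rng.beta(1.0 + m_nz, 1.0 + mg[g] - m_nz)

        if it >= cfg.burnin and (it - cfg.burnin) % cfg.thin == 0 \
                and stored < n_store:
            q = data.r - state.r_adj           # B beta
            sg2 = state.sigma_g2
            tot = sg2 + state.sigma_e2
            h2 = sg2 / tot
            sg2_c = float(state.beta[member] @ q[member])
            h2_c = sg2_c / tot
            m_nz_all = int((indicators > 0).sum())
            m_nz_c = int((member & (indicators > 0)).sum())
            pi_emp = m_nz_all / m
            pi_emp_c = m_nz_c / mg[1]
            draws["h2"][stored] = h2
            draws["pi_global"][stored] = pi_emp
            draws["S_c"][stored] = S_g[1]
            draws["S_rest"][stored] = S_g[0]
            draws["pi_c"][stored] = pi_g[1]
            draws["pi_rest"][stored] = pi_g[0]
            draws["h2_c"][stored] = h2_c
            # per-iteration enrichment folds (NaN when a denominator is zero)
            draws["fold_h2_per_snp"][stored] = (
                (h2_c / mg[1]) / (h2 / m) if h2 > 0 else np.nan)
            draws["fold_h2_per_nze"][stored] = (
                (h2_c / m_nz_c) / (h2 / m_nz_all)
                if (m_nz_c > 0 and m_nz_all > 0 and h2 > 0) else np.nan)
            draws["fold_pi"][stored] = (
                pi_emp_c / pi_emp if pi_emp > 0 else np.nan)
            stored += 1

    return {k: v[:stored] for k, v in draws.items()}
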