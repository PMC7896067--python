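"""Synthetic-data generation for the summary-statistics samplers.

Covers LD-structured genotype and LD-matrix fixtures, causal effects from
the three-normal mixture calibrated by mutational heritability, the
selection-effect coupling and the two pleiotropy models, direct simulation
of GWAS summary statistics from an LD matrix, liability-threshold
case-control ascertainment, SNP subsampling / unrelated-individual
selection, and the ordinary-least-squares proxy of the S parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm

from .ldmatrix import SparseLdMatrix
from .sumstats import SummaryDataset, compute_scaling

logger = logging.getLogger(__name__)

#: Mixture of causal-effect variances: 70% small, 25% medium, 5% large.
MIXTURE_WEIGHTS = (0.70, 0.25, 0.05)
MIXTURE_VARIANCES = (0.01, 0.1, 1.0)
#: Marginal variance of the mixture in units of sigma_b^2:
#: 0.7*0.01 + 0.25*0.1 + 0.05*1 = 0.082.
MIXTURE_VAR_FACTOR = float(np.dot(MIXTURE_WEIGHTS, MIXTURE_VARIANCES))

NE_REFERENCE = 10_000  # effective size used to scale selection coefficients


# ---------------------------------------------------------------------------
# causal architectures

def draw_causal_effects(m_causal: int, sigma_b2: float,
                        rng: np.random.Generator,
                        weights=MIXTURE_WEIGHTS,
                        variances=MIXTURE_VARIANCES) -> np.ndarray:
    """Causal effects from the three-normal mixture (per-allele scale)."""
    if m_causal < 1:
        raise ValueError("need at least one causal variant")
    w = np.asarray(weights, float)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("mixture weights must sum to 1")
    comp = rng.choice(len(w), size=m_causal, p=w)
    sd = np.sqrt(np.asarray(variances, float)[comp] * sigma_b2)
    return rng.standard_normal(m_causal) * sd


def calibrate_sigma_b2(h2m: float, L: float, pim: float, mu: float) -> float:
    """Mixture scale from mutational heritability: with ``h2m = 2 L pim mu
    V_beta`` (environmental-variance units), ``sigma_b^2 = V_beta / 0.082``."""
    denom = 2.0 * L * pim * mu
    if denom <= 0:
        raise ValueError("L, pim and mu must all be positive")
    return (h2m / denom) / MIXTURE_VAR_FACTOR


def selection_from_effects(beta: np.ndarray, k: float) -> np.ndarray:
    """Deterministic effect-selection coupling ``s_j = k beta_j^2``."""
    if k <= 0:
        raise ValueError("coupling constant k must be positive")
    return k * np.asarray(beta, float) ** 2


def pleiotropy_simons(s: np.ndarray, k: float, n_t: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Redraw focal-trait effects given selection: ``beta ~ N(0, s/(k n_t))``.

    ``n_t`` is the number of traits sharing the variant's selection
    pressure; n_t = 1 preserves effect magnitude in expectation.
    """
    var = np.asarray(s, float) / (k * n_t)
    return rng.standard_normal(len(var)) * np.sqrt(var)


def pleiotropy_eyre_walker(s: np.ndarray, tau: float, sigma2: float,
                           rng: np.random.Generator,
                           ne: int = NE_REFERENCE) -> np.ndarray:
    """Eyre-Walker coupling: ``beta = delta * (4 Ne s)^tau * (1 + eps)``
    with random sign delta and ``eps ~ N(0, sigma2)``."""
    Sj = 4.0 * ne * np.asarray(s, float)
    delta = rng.choice([-1.0, 1.0], size=len(Sj))
    eps = rng.standard_normal(len(Sj)) * np.sqrt(sigma2)
    return delta * Sj**tau * (1.0 + eps)


def ols_S(beta: np.ndarray, p: np.ndarray) -> tuple[float, float, int]:
    """OLS proxy of S: slope of ``log(beta^2)`` on ``log(2pq)``.

    Zero effects are excluded (their count is the third return value).
    """
    beta = np.asarray(beta, float)
    p = np.asarray(p, float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("frequencies must lie strictly inside (0, 1)")
    ok = beta != 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("ols_S: excluded %d zero effects", n_excluded)
    x = np.log(2.0 * p[ok] * (1.0 - p[ok]))
    y = np.log(beta[ok] ** 2)
    A = np.column_stack([np.ones(x.size), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef[1]), float(coef[0]), n_excluded


# ---------------------------------------------------------------------------
# LD and genotype fixtures

def block_ld_matrix(m: int, block_size: int, rho: float, nref: float,
                    rng: np.random.Generator,
                    chisq_threshold: float = 10.0,
                    maf_range=(0.01, 0.5)) -> SparseLdMatrix:
    """Autoregressive LD blocks: corr(j, k) = rho^|j-k| within blocks of
    ``block_size`` SNPs, zero between blocks; sparsified at the chi-squared
    threshold. SNP frequencies drawn uniformly from ``maf_range``."""
    freqs = rng.uniform(*maf_range, size=m)
    offsets = np.arange(block_size)
    base = rho ** np.abs(offsets[:, None] - offsets[None, :])
    blocks = []
    done = 0
    while done < m:
        sz = min(block_size, m - done)
        A = base[:sz, :sz].copy()
        keep = nref * A**2 > chisq_threshold
        np.fill_diagonal(keep, True)
        blocks.append(sp.csr_matrix(np.where(keep, A, 0.0)))
        done += sz
    snp_map = pd.DataFrame({
        "SNP": [f"snp{i}" for i in range(m)],
        "chrom": "1", "pos": np.arange(1, m + 1) * 1000,
        "A1": "A", "A2": "C", "freq": freqs,
    })
    block = sp.block_diag(blocks, format="csr")
    return SparseLdMatrix(snp_map=snp_map, blocks={"1": block}, nref=nref,
                          chisq_threshold=chisq_threshold)


def simulate_genotypes(n: int, freqs: np.ndarray, rng: np.random.Generator,
                       block_size: int = 1, rho: float = 0.0) -> np.ndarray:
    """Dosage matrix with optional AR(1) LD within blocks.

    Two latent Gaussian haplotypes per individual are thresholded at each
    SNP's frequency quantile, giving approximately the latent correlation
    as genotypic LD.
    """
    m = len(freqs)
    thresh = norm.ppf(freqs)
    X = np.zeros((n, m))
    for hap in range(2):
        z = rng.standard_normal((n, m))
        if block_size > 1 and rho > 0:
            for start in range(0, m, block_size):
                stop = min(start + block_size, m)
                for j in range(start + 1, stop):
                    z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * z[:, j]
        X += (z < thresh).astype(float)
    return X


def architecture_dataset(ld: SparseLdMatrix, h2: float, pi: float, S: float,
                         N: int, rng: np.random.Generator,
                         vare: float | None = None):
    """Recovery fixture: draw causal effects from the MAF-coupled point-normal
    prior on the LD map, rescale to an exact heritability, and simulate
    summary statistics at sample size N.

    Returns ``(SummaryDataset, beta_std_truth)``.
    """
    m = ld.m
    p = ld.snp_map["freq"].to_numpy(float)
    h = 2.0 * p * (1.0 - p)
    m_causal = max(1, int(round(pi * m)))
    causal = rng.choice(m, size=m_causal, replace=False)
    beta_std = np.zeros(m)
    # per-allele effects ~ N(0, h^S); standardized scale multiplies by sqrt(h)
    beta_std[causal] = (rng.standard_normal(m_causal)
                        * np.exp(0.5 * (S + 1.0) * np.log(h[causal])))
    B = sp.block_diag(list(ld.blocks.values()), format="csr")
    sg2 = float(beta_std @ (B @ beta_std))
    beta_std *= np.sqrt(h2 / sg2)
    ds = simulate_summary_stats(ld, beta_std, N, rng,
                                vary=h2 + (vare if vare is not None else 1.0 - h2))
    return ds, beta_std


def simulate_summary_stats(ld, beta_std: np.ndarray, N: float,
                           rng: np.random.Generator,
                           vary: float = 1.0,
                           eig_floor: float = 1e-8,
                           jitter: float = 1e-6,
                           alpha_mean: np.ndarray | None = None) -> SummaryDataset:
    """Directly simulate marginal GWAS statistics from an LD matrix.

    One draw of the standardized marginal effects ``alpha ~ N(B beta,
    B / N)`` per chromosome block; blocks whose smallest eigenvalue is below
    ``eig_floor`` get a logged ridge ``jitter`` on the diagonal before
    factorization. Standard errors are the exact ``sqrt(vary / (N h_j))``
    of a standardized phenotype with variance ``vary``; frequencies and
    sample sizes come from the SNP map. ``alpha_mean`` overrides the
    ``B beta`` mean (used when the marginal expectations are computed from
    realized genotypes rather than through the stored LD matrix).
    """
    if N <= 0:
        raise ValueError("sample size must be positive")
    snp_map = ld.snp_map
    p = snp_map["freq"].to_numpy(float)
    h = 2.0 * p * (1.0 - p)
    alpha = np.empty(ld.m)
    off = 0
    for blk in ld.blocks.values():
        A = np.asarray(blk.todense(), float)
        sz = A.shape[0]
        b = beta_std[off:off + sz]
        try:
            L = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            w = np.linalg.eigvalsh(A)
            if w.min() < eig_floor:
                logger.info("ridge jitter %.1e added to LD block (min eig %.3g)",
                            jitter, w.min())
                A = A + np.eye(sz) * (jitter + max(0.0, -w.min()))
            L = np.linalg.cholesky(A)
        mean = alpha_mean[off:off + sz] if alpha_mean is not None else A @ b
        alpha[off:off + sz] = mean + (L @ rng.standard_normal(sz)) \
            * np.sqrt(vary / N)
        off += sz
    zstat = alpha * np.sqrt(N / vary)
    pval = np.clip(2.0 * norm.sf(np.abs(zstat)), 1e-300, 1.0)
    df = pd.DataFrame({
        "SNP": snp_map["SNP"].astype(str),
        "A1": snp_map.get("A1", pd.Series(["A"] * ld.m)),
        "A2": snp_map.get("A2", pd.Series(["C"] * ld.m)),
        "freq": p,
        "b": alpha / np.sqrt(h),
        "se": np.sqrt(vary / (N * h)),
        "p": pval,
        "N": float(N),
    })
    for col in ("chrom", "pos"):
        if col in snp_map.columns:
            df[col] = snp_map[col].to_numpy()
    return compute_scaling(SummaryDataset(df=df, provenance="simulated"))


# ---------------------------------------------------------------------------
# marginal regression / case-control

def marginal_regression(X: np.ndarray, y: np.ndarray,
                        snp_map: pd.DataFrame) -> SummaryDataset:
    """Per-SNP least-squares GWAS on a quantitative or 0/1 phenotype."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, m = X.shape
    xm = X.mean(axis=0)
    ym = y.mean()
    sxx = np.sum((X - xm) ** 2, axis=0)
    if np.any(sxx <= 0):
        raise ValueError("monomorphic SNP in genotype matrix")
    sxy = (X - xm).T @ (y - ym)
    b = sxy / sxx
    resid_ss = np.sum((y - ym) ** 2) - b * sxy
    se = np.sqrt(np.maximum(resid_ss, 1e-300) / (n - 2) / sxx)
    t = b / se
    pval = np.clip(2.0 * norm.sf(np.abs(t)), 1e-300, 1.0)
    df = pd.DataFrame({
        "SNP": snp_map["SNP"].astype(str),
        "A1": snp_map.get("A1", pd.Series(["A"] * m)),
        "A2": snp_map.get("A2", pd.Series(["C"] * m)),
        "freq": xm / 2.0, "b": b, "se": se, "p": pval, "N": float(n),
    })
    return compute_scaling(SummaryDataset(df=df, provenance="marginal GWAS"))


@dataclass
class CaseControlSim:
    ds: SummaryDataset
    genotypes: np.ndarray
    y: np.ndarray
    h2_liability: float
    h2_observed_expected: float
    K: float
    P: float


def simulate_case_control(h2: float, K: float, P: float, n: int, m: int,
                          rng: np.random.Generator,
                          pi_causal: float = 0.1,
                          maf_range=(0.05, 0.5),
                          max_draw_factor: int = 200) -> CaseControlSim:
    """Liability-threshold disease with optional case oversampling.

    A standard-normal liability ``l = g + e`` with ``Var(g) = h2`` assigns
    disease when ``l`` exceeds the ``1 - K`` quantile. Cases are then
    sampled to a fraction ``P`` of the ``n`` analysed individuals and a
    per-SNP 0/1 regression produces the summary statistics. The expected
    observed-scale heritability ``h2 * z^2 P(1-P) / (K^2 (1-K)^2)`` is
    recorded for checking the liability transform.
    """
    if not (0 < K <= P < 1):
        raise ValueError("need 0 < K <= P < 1")
    n_cases = int(round(P * n))
    n_controls = n - n_cases
    freqs = rng.uniform(*maf_range, size=m)
    m_causal = max(1, int(round(pi_causal * m)))
    causal = rng.choice(m, size=m_causal, replace=False)
    thresh_t = norm.ppf(1.0 - K)

    Xc, yc, gcase = [], [], 0
    Xn, yn = [], []
    drawn = 0
    batch = max(2000, int(2 * n_cases / K / 50))
    while (gcase < n_cases or len(yn) < n_controls):
        if drawn > max_draw_factor * n / K:
            raise RuntimeError("insufficient cases for the requested "
                               "ascertainment; increase K or reduce P")
        X = simulate_genotypes(batch, freqs, rng)
        Z = (X - 2 * freqs) / np.sqrt(2 * freqs * (1 - freqs))
        if drawn == 0:
            # effects fixed once on the first batch
            bs = rng.standard_normal(m_causal)
            bs *= np.sqrt(h2 / np.sum(bs**2))
            beta_fixed = np.zeros(m)
            beta_fixed[causal] = bs
        beta_std = beta_fixed
        g = Z @ beta_std
        lia = g + rng.standard_normal(batch) * np.sqrt(1.0 - h2)
        case = lia > thresh_t
        need_cases = n_cases - gcase
        ci = np.flatnonzero(case)[:need_cases]
        ni = np.flatnonzero(~case)[: n_controls - len(yn)]
        if ci.size:
            Xc.append(X[ci])
            yc.extend([1.0] * ci.size)
            gcase += ci.size
        if ni.size:
            Xn.append(X[ni])
            yn.extend([0.0] * ni.size)
        drawn += batch
    Xall = np.vstack([np.vstack(Xc), np.vstack(Xn)])
    yall = np.array(yc + yn)
    perm = rng.permutation(n)
    Xall, yall = Xall[perm], yall[perm]

    snp_map = pd.DataFrame({
        "SNP": [f"snp{i}" for i in range(m)], "chrom": "1",
        "pos": np.arange(1, m + 1) * 1000, "A1": "A", "A2": "C",
        "freq": freqs,
    })
    ds = marginal_regression(Xall, yall, snp_map)
    z = norm.pdf(thresh_t)
    h2_obs = h2 * z**2 * P * (1 - P) / (K**2 * (1 - K) ** 2)
    return CaseControlSim(ds=ds, genotypes=Xall, y=yall, h2_liability=h2,
                          h2_observed_expected=h2_obs, K=K, P=P)


# ---------------------------------------------------------------------------
# subsetting utilities

def subsample_snps(freqs: np.ndarray, m_ref: int, L_ref: float, L_sim: float,
                   rng: np.random.Generator,
                   causal: np.ndarray | None = None,
                   exclude_causal: bool = True,
                   maf_min: float = 0.01) -> np.ndarray:
    """Sample ``round(m_ref * L_sim / L_ref)`` common SNPs (indices).

    Mirrors matching the marker density of a reference panel on a shorter
    simulated genome; causal variants can be excluded from the marker set.
    """
    target = int(round(m_ref * L_sim / L_ref))
    maf = np.minimum(freqs, 1 - freqs)
    ok = maf >= maf_min
    if exclude_causal and causal is not None:
        mask = np.zeros(len(freqs), bool)
        mask[np.asarray(causal, int)] = True
        ok &= ~mask
    pool = np.flatnonzero(ok)
    if pool.size < target:
        raise ValueError(f"only {pool.size} common SNPs available, "
                         f"need {target}")
    return np.sort(rng.choice(pool, size=target, replace=False))


def unrelated_indices(X: np.ndarray, threshold: float = 0.05) -> np.ndarray:
    """Greedy selection of individuals with pairwise genomic relationship
    below ``threshold`` (GRM from standardized dosages)."""
    X = np.asarray(X, float)
    n, m = X.shape
    freqs = X.mean(axis=0) / 2
    ok = (freqs > 0) & (freqs < 1)
    Z = (X[:, ok] - 2 * freqs[ok]) / np.sqrt(2 * freqs[ok] * (1 - freqs[ok]))
    grm = (Z @ Z.T) / ok.sum()
    related = (np.abs(grm) >= threshold)
    np.fill_diagonal(related, False)
    keep = np.ones(n, bool)
    deg = related.sum(axis=1)
    order = np.argsort(-deg)
    for i in order:
        if keep[i] and related[i, keep].any():
            keep[i] = False
    return np.flatnonzero(keep)
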