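"""Individual-level Gibbs sampler for the MAF-coupled spike-slab model.

A deliberately plain, small-scale reference sampler on genotype-phenotype
data. It shares no sweep code with the summary-statistics samplers, so the
two can be compared as independent routes to the same posterior: when the
LD matrix is computed from the GWAS genotypes themselves (full, not
sparsified), the summary-level sampler and this one target equivalent
posteriors for (h2, pi, S). Intended for n <= a few thousand and
m <= a few hundred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class BayesSConfig:
    iterations: int = 5000
    burnin: int = 1000
    seed: int = 0
    nu: float = 4.0
    mh_step: float = 0.2
    estimate_S: bool = True


def run_bayess(y: np.ndarray, X: np.ndarray,
               config: BayesSConfig | None = None) -> dict:
    """Gibbs sampling of the point-normal model on individual-level data.

    ``y`` is the phenotype (centred internally), ``X`` the dosage matrix.
    Returns a dict of post-burn-in draw arrays for h2, pi, S plus the
    posterior mean genotype-scale effects.
    """
    cfg = config or BayesSConfig()
    rng = np.random.default_rng(cfg.seed)
    y = np.asarray(y, float)
    y = y - y.mean()
    X = np.asarray(X, float)
    freq = X.mean(axis=0) / 2.0
    X = X - X.mean(axis=0)
    n, m = X.shape
    xtx = np.sum(X**2, axis=0)
    if np.any(xtx <= 0):
        raise ValueError("monomorphic SNP in genotype matrix")
    # MAF coupling uses the HWE genotype variance 2pq from the allele
    # frequency, the same convention as the summary-statistics samplers
    h = 2.0 * freq * (1.0 - freq)
    logh = np.log(h)
    vary = float(y @ y) / n

    beta = np.zeros(m)
    resid = y.copy()
    incl = np.zeros(m, bool)
    pi = float(rng.uniform())
    S = float(rng.standard_normal()) if cfg.estimate_S else 0.0
    scale_b = 0.5 * vary / (m * float(h.mean()))
    sigma_b2 = cfg.nu * scale_b / rng.chisquare(cfg.nu)
    sigma_e2 = cfg.nu * (vary / 2) / rng.chisquare(cfg.nu)
    step = cfg.mh_step

    keep = cfg.iterations - cfg.burnin
    draws = {k: np.empty(keep) for k in ("h2", "pi", "S")}
    beta_sum = np.zeros(m)

    for it in range(cfg.iterations):
        pi_c = min(max(pi, 1e-12), 1 - 1e-12)
        for j in range(m):
            vj = np.exp(S * logh[j]) * sigma_b2
            rhs = X[:, j] @ resid + xtx[j] * beta[j]
            C = xtx[j] + sigma_e2 / vj
            mean = rhs / C
            logbf = 0.5 * (np.log(sigma_e2 / (vj * C)) + rhs**2 / (C * sigma_e2))
            a = np.log(pi_c) + logbf
            b = np.log1p(-pi_c)
            mx = max(a, b)
            pinc = np.exp(a - mx) / (np.exp(a - mx) + np.exp(b - mx))
            if rng.random() < pinc:
                bnew = mean + rng.standard_normal() * np.sqrt(sigma_e2 / C)
                incl[j] = True
            else:
                bnew = 0.0
                incl[j] = False
            if bnew != beta[j]:
                resid -= X[:, j] * (bnew - beta[j])
                beta[j] = bnew

        g = y - resid
        sigma_g2 = float(g @ g) / n
        ee = float(resid @ resid)
        df_e = cfg.nu + n
        sigma_e2 = df_e * ((ee + cfg.nu * vary / 2) / df_e) / rng.chisquare(df_e)

        if cfg.estimate_S:
            nz = np.flatnonzero(incl)
            if nz.size:
                lh = logh[nz]
                bsq = beta[nz] ** 2

                def logt(s):
                    return (-0.5 * s * lh.sum()
                            - 0.5 * np.sum(bsq * np.exp(-s * lh)) / sigma_b2
                            - 0.5 * s * s)

                prop = S + step * rng.standard_normal()
                if np.log(rng.random()) < logt(prop) - logt(S):
                    S = float(prop)
            else:
                S = float(rng.standard_normal())

        nz = np.flatnonzero(incl)
        if nz.size:
            ssq = float(np.sum(beta[nz] ** 2 * np.exp(-S * logh[nz])))
            df_b = cfg.nu + nz.size
            sigma_b2 = df_b * ((ssq + cfg.nu * scale_b) / df_b) / rng.chisquare(df_b)
        else:
            sigma_b2 = cfg.nu * scale_b / rng.chisquare(cfg.nu)
        pi = float(rng.beta(1 + nz.size, 1 + m - nz.size))

        if it >= cfg.burnin:
            k = it - cfg.burnin
            draws["h2"][k] = sigma_g2 / (sigma_g2 + sigma_e2)
            draws["pi"][k] = pi
            draws["S"][k] = S
            beta_sum += beta

    draws["beta_mean"] = beta_sum / keep
    return draws
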