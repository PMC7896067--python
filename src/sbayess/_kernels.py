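"""Numba inner loops for the per-SNP Gibbs sweeps.

The kernels mutate ``beta`` / ``r_adj`` / label arrays in place. All
randomness is passed in as pre-drawn uniform/normal arrays from a seeded
``numpy.random.Generator``, so chains are bitwise reproducible and the
kernels themselves are deterministic.

Scale conventions match :mod:`sbayess.mcmc`: ``beta`` is on the
standardized-genotype scale, ``r_adj = r - B beta``, the likelihood
precision contribution of SNP j is ``n_j / sigma_e2`` and the spike-slab
prior variance of SNP j is ``vprior[j] = h_j^(S+1) sigma_b2`` (times the
mixture multiplier gamma_k in the multi-component kernel).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sweep_spike_slab(indptr, indices, data, r_adj, beta, indicators,
                     nj, vprior, logpi, log1mpi, sigma_e2, vare_mul, u, z):
    """One full sweep of the point-normal (spike and slab) update.

    ``logpi``/``log1mpi`` are per-SNP, which lets the stratified model reuse
    this kernel with component-specific inclusion probabilities.
    """
    m = beta.shape[0]
    for j in range(m):
        se2 = sigma_e2 * vare_mul[j]
        vj = vprior[j]
        rc = r_adj[j] + beta[j]
        C = nj[j] + se2 / vj
        mean = nj[j] * rc / C
        logbf = 0.5 * (np.log(se2 / (vj * C)) + (nj[j] * rc) ** 2 / (C * se2))
        a = logpi[j] + logbf
        b = log1mpi[j]
        mx = a if a > b else b
        p1 = np.exp(a - mx)
        pinc = p1 / (p1 + np.exp(b - mx))
        if u[j] < pinc:
            bnew = mean + z[j] * np.sqrt(se2 / C)
            indicators[j] = 1
        else:
            bnew = 0.0
            indicators[j] = 0
        diff = bnew - beta[j]
        if diff != 0.0:
            beta[j] = bnew
            for k in range(indptr[j], indptr[j + 1]):
                r_adj[indices[k]] -= data[k] * diff


@njit(cache=True)
def sweep_mixture(indptr, indices, data, r_adj, beta, labels,
                  nj, hpow, gammas, sigma_b2, logpis, sigma_e2, vare_mul, u, z):
    """One sweep of the multi-component mixture update.

    ``gammas`` is the ascending variance-multiplier grid with gammas[0] = 0
    (the point mass); ``hpow[j] = h_j^(S+1)``; ``logpis`` are the log mixing
    probabilities. Component selection uses log-sum-exp normalization and a
    single uniform per SNP.
    """
    m = beta.shape[0]
    K = gammas.shape[0]
    logp = np.empty(K)
    for j in range(m):
        se2 = sigma_e2 * vare_mul[j]
        rc = r_adj[j] + beta[j]
        logp[0] = logpis[0]
        best = logp[0]
        for k in range(1, K):
            v = gammas[k] * hpow[j] * sigma_b2
            C = nj[j] + se2 / v
            lbf = 0.5 * (np.log(se2 / (v * C)) + (nj[j] * rc) ** 2 / (C * se2))
            logp[k] = logpis[k] + lbf
            if logp[k] > best:
                best = logp[k]
        tot = 0.0
        for k in range(K):
            logp[k] = np.exp(logp[k] - best)
            tot += logp[k]
        target = u[j] * tot
        acc = 0.0
        sel = K - 1
        for k in range(K):
            acc += logp[k]
            if target <= acc:
                sel = k
                break
        labels[j] = sel
        if sel == 0:
            bnew = 0.0
        else:
            v = gammas[sel] * hpow[j] * sigma_b2
            C = nj[j] + se2 / v
            bnew = nj[j] * rc / C + z[j] * np.sqrt(se2 / C)
        diff = bnew - beta[j]
        if diff != 0.0:
            beta[j] = bnew
            for k in range(indptr[j], indptr[j + 1]):
                r_adj[indices[k]] -= data[k] * diff
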