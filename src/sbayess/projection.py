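"""Projection of genetic-architecture estimates onto evolutionary parameters.

A multivariate polynomial regression (full monomial basis up to a total
degree, default 3) is trained on a simulation grid linking the true
evolutionary parameters -- mean selection coefficient ``sbar``, mutational
target proportion ``pim`` and mutational heritability ``h2m``, all on the
log10 scale -- to the estimated genetic-architecture parameters
``(h2_SNP, pi, S)`` (or the mixture-model variant with per-component
fractions). The fitted polynomials then map architecture estimates for a
new trait to point predictions and OLS predictive intervals of the
evolutionary parameters on the natural scale, with an extrapolation flag
for query points outside the convex hull of the training predictors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

logger = logging.getLogger(__name__)

TARGETS = ["log10_sbar", "log10_pim", "log10_h2m"]
PREDICTORS = ["h2", "pi", "S"]


def _monomial_powers(n_vars: int, degree: int) -> list:
    powers = []
    for d in range(degree + 1):
        for combo in itertools.combinations_with_replacement(range(n_vars), d):
            pw = np.zeros(n_vars, int)
            for v in combo:
                pw[v] += 1
            powers.append(pw)
    return powers


def polynomial_basis(X: np.ndarray, degree: int) -> np.ndarray:
    """Full multivariate monomial basis of total degree <= ``degree``,
    including all interactions (first column is the intercept)."""
    X = np.atleast_2d(np.asarray(X, float))
    powers = _monomial_powers(X.shape[1], degree)
    return np.column_stack([np.prod(X**pw, axis=1) for pw in powers])


@dataclass
class PolyProjection:
    """Fitted polynomial maps from architecture estimates to log10
    evolutionary parameters, one OLS fit per target."""

    degree: int
    predictors: list
    targets: list
    coef: dict                  # target -> coefficient vector
    sigma2: dict                # target -> residual variance
    xtx_inv: np.ndarray
    dof: int
    train_X: np.ndarray
    _hull: object = field(default=None, repr=False)

    def in_hull(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if self._hull is None:
            try:
                self._hull = Delaunay(self.train_X)
            except QhullError:
                return np.zeros(len(X), bool)
        return self._hull.find_simplex(X) >= 0


@dataclass
class EvoPrediction:
    """Natural-scale point predictions with predictive intervals."""

    point: dict                 # parameter -> value
    interval: dict              # parameter -> (low, high)
    extrapolated: bool


def fit_projection(table: pd.DataFrame, degree: int = 3,
                   predictors: list | None = None,
                   targets: list | None = None) -> PolyProjection:
    """Least-squares polynomial fit per evolutionary parameter."""
    predictors = predictors or PREDICTORS
    targets = targets or TARGETS
    X = table[predictors].to_numpy(float)
    basis = polynomial_basis(X, degree)
    n, p = basis.shape
    if n < p:
        raise ValueError(f"{n} rows cannot identify a degree-{degree} basis "
                         f"of {p} terms")
    rank = np.linalg.matrix_rank(basis)
    if rank < p:
        raise ValueError(f"rank-deficient design: rank {rank} < {p} basis terms")
    xtx_inv = np.linalg.inv(basis.T @ basis)
    coef, sigma2 = {}, {}
    for t in targets:
        y = table[t].to_numpy(float)
        beta = xtx_inv @ basis.T @ y
        resid = y - basis @ beta
        coef[t] = beta
        sigma2[t] = float(resid @ resid) / max(n - p, 1)
    return PolyProjection(degree=degree, predictors=predictors,
                          targets=targets, coef=coef, sigma2=sigma2,
                          xtx_inv=xtx_inv, dof=max(n - p, 1), train_X=X)


def predict_evo(model: PolyProjection, estimates) -> EvoPrediction:
    """Back-transformed predictions for one set of architecture estimates.

    ``estimates`` maps predictor name to value (or is an ordered sequence).
    The 95% interval is the standard OLS predictive interval on the log10
    scale, exponentiated.
    """
    from scipy.stats import t as t_dist

    if isinstance(estimates, dict):
        x = np.array([estimates[p] for p in model.predictors], float)
    else:
        x = np.asarray(estimates, float)
    phi = polynomial_basis(x[None, :], model.degree)[0]
    inside = bool(model.in_hull(x[None, :])[0])
    if not inside:
        logger.warning("architecture estimates outside the training hull; "
                       "prediction is an extrapolation")
    tq = t_dist.ppf(0.975, model.dof)
    point, interval = {}, {}
    for tname in model.targets:
        mu = float(phi @ model.coef[tname])
        se = np.sqrt(model.sigma2[tname] * (1.0 + phi @ model.xtx_inv @ phi))
        natural = tname.replace("log10_", "")
        point[natural] = 10.0**mu
        interval[natural] = (10.0 ** (mu - tq * se), 10.0 ** (mu + tq * se))
    return EvoPrediction(point=point, interval=interval,
                         extrapolated=not inside)


def cross_validate(table: pd.DataFrame, degree: int,
                   rng: np.random.Generator,
                   split: float = 0.2, repeats: int = 10,
                   predictors: list | None = None,
                   targets: list | None = None) -> pd.DataFrame:
    """Repeated random-split validation (default 80% train / 20% test).

    Returns mean held-out Pearson correlation and RMSE per target.
    """
    if not 0.0 < split < 1.0:
        raise ValueError("split must lie in (0, 1)")
    predictors = predictors or PREDICTORS
    targets = targets or TARGETS
    n = len(table)
    n_test = max(1, int(round(split * n)))
    cors = {t: [] for t in targets}
    rmses = {t: [] for t in targets}
    for _ in range(repeats):
        perm = rng.permutation(n)
        test, train = perm[:n_test], perm[n_test:]
        model = fit_projection(table.iloc[train], degree, predictors, targets)
        basis = polynomial_basis(table.iloc[test][predictors].to_numpy(float),
                                 degree)
        for t in targets:
            pred = basis @ model.coef[t]
            truth = table.iloc[test][t].to_numpy(float)
            if np.std(pred) > 0 and np.std(truth) > 0:
                cors[t].append(np.corrcoef(pred, truth)[0, 1])
            else:
                cors[t].append(0.0)
            rmses[t].append(float(np.sqrt(np.mean((pred - truth) ** 2))))
    return pd.DataFrame({
        "target": targets,
        "cor": [float(np.mean(cors[t])) for t in targets],
        "rmse": [float(np.mean(rmses[t])) for t in targets],
    })


def degree_sweep(table: pd.DataFrame, degrees, rng: np.random.Generator,
                 **kwargs) -> pd.DataFrame:
    """Cross-validated accuracy for a range of polynomial degrees."""
    rows = []
    for d in degrees:
        cv = cross_validate(table, d, rng, **kwargs)
        rows.append({"degree": d, "mean_cor": float(cv["cor"].mean())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# training tables

def table_from_replicates(reps, truths) -> pd.DataFrame:
    """Build a training table from evolutionary replicates.

    ``reps`` is a sequence of objects with ``h2_hat / pi_hat / S_hat``
    attributes; ``truths`` a matching sequence of dicts with keys
    ``sbar / pim / h2m`` on the natural scale.
    """
    rows = []
    for rep, tr in zip(reps, truths):
        rows.append({
            "h2": rep.h2_hat, "pi": rep.pi_hat, "S": rep.S_hat,
            "log10_sbar": np.log10(tr["sbar"]),
            "log10_pim": np.log10(tr["pim"]),
            "log10_h2m": np.log10(tr["h2m"]),
        })
    return pd.DataFrame(rows)


def synthetic_training_table(n: int, rng: np.random.Generator,
                             noise: float = 0.05,
                             ne: float = 10_000.0) -> pd.DataFrame:
    """Synthetic stand-in for a forward-simulation training grid.

    Emulates the qualitative response surface of the full evolutionary
    pipeline -- equilibrium genetic variance from mutation-selection-drift
    balance (variance persistence ~ 1/(s + 1/(2 Ne))), polygenicity driven
    by the mutational target and purged by selection, and a selection
    signature S that strengthens with the mean coefficient -- at a cost of
    milliseconds instead of forward-simulation hours. It is a synthetic
    surrogate: use :func:`table_from_replicates` on real forward runs for
    calibrated projections.
    """
    log_sbar = rng.uniform(-5, -2, n)
    log_pim = rng.uniform(-3, -1, n)
    log_h2m = rng.uniform(-4, -2, n)
    sbar, pim, h2m = 10.0**log_sbar, 10.0**log_pim, 10.0**log_h2m

    persist = 1.0 / (sbar + 1.0 / (2.0 * ne))
    vg = h2m * persist * np.exp(rng.normal(0, noise * 4, n))
    h2 = vg / (vg + 1.0)
    nc = pim * 4e3 * persist / (persist + 500.0)
    pi = np.clip(nc / (nc + 20.0) * np.exp(rng.normal(0, noise * 4, n)),
                 1e-5, 0.5)
    S = -(sbar**0.4 / (sbar**0.4 + 0.03)) + rng.normal(0, noise, n)
    return pd.DataFrame({
        "h2": h2, "pi": pi, "S": S,
        "log10_sbar": log_sbar, "log10_pim": log_pim, "log10_h2m": log_h2m,
    })
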