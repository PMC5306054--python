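"""Community dissimilarity vs. environmental distance.

Community composition is compared between transects with Bray-Curtis
dissimilarity; the environment with a normalized Euclidean distance in
which each variable's pairwise absolute differences are divided by
their maximum, so all variables weigh equally and the total distance
lies in [0, sqrt(3)]. The association between the two distance matrices
is tested with a one-sided Mantel permutation test (transect labels
permuted jointly in rows and columns), and summarized by the OLS slope
and R² of dissimilarity on distance. The observed slope is contrasted
against the slope for null (fully stochastic) communities by fitting
dissimilarity ~ distance x group on the stacked pair-level records; the
interaction term tests for a slope difference. Pair-level records are
not independent, which the contrast inherits from the classical
distance-decay ANCOVA; a one-pair-per-transect subsample is available
as a diagnostic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations as _permutations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform

from .data_io import Dataset
from .trait_env_stats import ENV_VARS, zscale, _fit_mixed, _wald_p

log = logging.getLogger("asmpipe")

__all__ = [
    "MantelResult",
    "bray_curtis",
    "bray_curtis_matrix",
    "env_distance_matrix",
    "mantel",
    "slope_contrast",
    "abundance_richness_regressions",
]


def bray_curtis(x_counts, y_counts) -> float:
    """Bray-Curtis dissimilarity: sum|x_i - y_i| / sum(x_i + y_i)."""
    x = np.asarray(x_counts, dtype=float)
    y = np.asarray(y_counts, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both communities are empty")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(abundance: pd.DataFrame, relative: bool = False) -> pd.DataFrame:
    """Pairwise Bray-Curtis matrix from a transect x species table."""
    mat = abundance.to_numpy(dtype=float)
    if relative:
        mat = mat / mat.sum(axis=1, keepdims=True)
    bc = squareform(pdist(mat, metric="braycurtis"))
    return pd.DataFrame(bc, index=abundance.index, columns=abundance.index)


def env_distance_matrix(environment: pd.DataFrame, variables=ENV_VARS) -> pd.DataFrame:
    """Normalized environmental distance between all transect pairs.

    Per variable, pairwise |difference| / max pairwise |difference|;
    total = sqrt(sum of squared normalized scores). Constant variables
    are dropped with a warning.
    """
    env = environment[list(variables)]
    if len(env) < 2:
        raise ValueError("need at least 2 transects")
    total_sq = np.zeros((len(env), len(env)))
    used = 0
    for v in variables:
        d = np.abs(env[v].to_numpy()[:, None] - env[v].to_numpy()[None, :])
        dmax = d.max()
        if dmax == 0:
            log.warning("environment variable %r constant across transects; dropped", v)
            continue
        total_sq += (d / dmax) ** 2
        used += 1
    if used == 0:
        raise ValueError("all environment variables are constant")
    return pd.DataFrame(np.sqrt(total_sq), index=env.index, columns=env.index)


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    slope: float
    intercept: float
    r_squared: float
    exact: bool = False


def _tri(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel(
    mat_a,
    mat_b,
    n_perm: int = 100_000,
    rng: np.random.Generator | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the off-diagonal (upper-triangle)
    entries; the null distribution permutes the labels of ``mat_b``
    jointly in rows and columns. When the exhaustive permutation set is
    no larger than ``n_perm`` the test enumerates it and the p-value is
    exact; otherwise p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    Also reports the OLS fit of tri(A) on tri(B).
    """
    A = np.asarray(mat_a, dtype=float)
    B = np.asarray(mat_b, dtype=float)
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 transects")
    for name, M in (("A", A), ("B", B)):
        if M.shape != (n, n) or not np.allclose(M, M.T) or np.any(np.diag(M) != 0):
            raise ValueError(f"matrix {name} must be square, symmetric, zero-diagonal")
    a, b = _tri(A), _tri(B)
    r_obs = float(np.corrcoef(a, b)[0, 1])
    slope, intercept, r_ols, _, _ = sps.linregress(b, a)

    # Pearson r under permutation of B depends only on sum(a * b_perm):
    # precompute the centred/scaled a-matrix once and take inner products.
    a_c = (a - a.mean()) / (a.std() * len(a))
    b_c = (b - b.mean()) / b.std()
    Ac = np.zeros((n, n))
    Ac[np.triu_indices(n, 1)] = a_c
    Ac = Ac + Ac.T
    Bc = np.zeros((n, n))
    Bc[np.triu_indices(n, 1)] = b_c
    Bc = Bc + Bc.T

    exact = math.factorial(n) <= n_perm
    if exact:
        perms = np.array(list(_permutations(range(n))))
    else:
        rng = rng if rng is not None else np.random.default_rng()
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    count = 0
    chunk = max(1, 2_000_000 // (n * n))
    for start in range(0, len(perms), chunk):
        P = perms[start : start + chunk]
        Bp = Bc[P[:, :, None], P[:, None, :]]
        r_perm = 0.5 * np.einsum("kij,ij->k", Bp, Ac)
        if alternative == "greater":
            count += int((r_perm >= r_obs - 1e-12).sum())
        elif alternative == "two-sided":
            count += int((np.abs(r_perm) >= abs(r_obs) - 1e-12).sum())
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    if exact:
        p = count / len(perms)
    else:
        p = (1 + count) / (1 + len(perms))
    return MantelResult(
        r=r_obs,
        p=float(p),
        n_permutations=len(perms),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r_ols**2),
        exact=exact,
    )


def slope_contrast(
    bc_observed,
    bc_null,
    env_dist,
    subsample_rng: np.random.Generator | None = None,
) -> dict:
    """Compare observed vs. null dissimilarity-distance slopes.

    Fits dissimilarity ~ distance * group by OLS on the stacked
    pair-level records and reports both group slopes and the
    interaction p-value. Pair records are mutually dependent (each
    transect enters n-1 pairs); the ``subsample`` entry refits on a
    one-pair-per-transect random subsample as a robustness diagnostic.
    """
    d = _tri(np.asarray(env_dist, dtype=float))
    y_obs = _tri(np.asarray(bc_observed, dtype=float))
    y_null = _tri(np.asarray(bc_null, dtype=float))
    y = np.concatenate([y_obs, y_null])
    x = np.concatenate([d, d])
    g = np.concatenate([np.zeros(len(d)), np.ones(len(d))])
    X = sm.add_constant(np.column_stack([x, g, x * g]))
    fit = sm.OLS(y, X).fit()
    out = {
        "slope_observed": float(fit.params[1]),
        "slope_null": float(fit.params[1] + fit.params[3]),
        "interaction_coef": float(fit.params[3]),
        "interaction_p": float(fit.pvalues[3]),
        "n_pairs": int(len(d)),
        "caveat": "pair-level records are not independent",
    }
    if subsample_rng is not None:
        n = np.asarray(env_dist).shape[0]
        order = subsample_rng.permutation(n)
        pairs = [(order[i], order[i + 1]) for i in range(0, n - 1, 2)]
        iu, ju = zip(*pairs)
        ds = np.asarray(env_dist)[iu, ju]
        ys = np.concatenate(
            [np.asarray(bc_observed)[iu, ju], np.asarray(bc_null)[iu, ju]]
        )
        xs = np.concatenate([ds, ds])
        gs = np.concatenate([np.zeros(len(ds)), np.ones(len(ds))])
        Xs = sm.add_constant(np.column_stack([xs, gs, xs * gs]))
        sub = sm.OLS(ys, Xs).fit()
        out["subsample"] = {
            "slope_observed": float(sub.params[1]),
            "slope_null": float(sub.params[1] + sub.params[3]),
            "interaction_p": float(sub.pvalues[3]),
            "n_pairs": int(len(ds)),
        }
    return out


def abundance_richness_regressions(dataset: Dataset, alpha: float = 0.05) -> pd.DataFrame:
    """Total abundance and species richness against each habitat variable.

    One cluster-random-intercept mixed model per (response, variable)
    pair on z-scored data; reports the standardized coefficient, its
    Wald-t p-value and the conditional R².
    """
    env = dataset.environment()
    clusters = env["cluster_id"]
    abundance = dataset.abundance_matrix()
    responses = {
        "abundance": abundance.sum(axis=1).to_numpy(float),
        "richness": (abundance > 0).sum(axis=1).to_numpy(float),
    }
    rows = []
    for rname, yraw in responses.items():
        for v in ENV_VARS:
            if env[v].nunique() < 2:
                log.warning("environment variable %r constant; regression skipped", v)
                continue
            y = zscale(yraw)
            X = pd.DataFrame({v: zscale(env[v])}, index=env.index)
            params, bse, var_u, var_e, fitted, converged, ols_fb = _fit_mixed(
                y, X, clusters
            )
            p = float(_wald_p(params, bse, len(y))[v])
            var_f = float(np.var(fitted))
            denom = var_f + var_u + var_e
            rows.append(
                {
                    "response": rname,
                    "variable": v,
                    "coefficient": float(params[v]),
                    "p": p,
                    "r2_conditional": (var_f + var_u) / denom if denom > 0 else 0.0,
                    "significant": p <= alpha,
                    "ols_fallback": ols_fb,
                }
            )
    return pd.DataFrame(rows)
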