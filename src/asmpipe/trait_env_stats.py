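"""Trait-environment mixed models.

Community trait means (CTMs) are regressed on the three habitat
variables (depth, sand cover, substrate complexity) with the sampling
cluster as a random intercept. Responses and predictors are z-scored
first so coefficients are standardized. Nonsignificant predictors are
removed backwards (largest p first) until all retained predictors are
significant at ``alpha``. Explained variance is summarized by the
conditional R² of Nakagawa & Schielzeth:

    R²_marginal    = s²_f / (s²_f + s²_u + s²_e)
    R²_conditional = (s²_f + s²_u) / (s²_f + s²_u + s²_e)

with s²_f the variance of the fixed-effect linear predictor, s²_u the
random-intercept variance, and s²_e the residual variance.

Fixed-effect p-values are Wald t-tests with n - k - 1 degrees of
freedom (k fixed effects), a small-sample correction over the normal
reference that matters with only ~36 transects.

The same machinery is applied to replicate artificial communities: the
final model formula selected on the observed data is refit, without
re-selection, to each replicate's CTMs, and coefficients/R² are averaged
across replicates — the observed-vs-simulated contrast table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .data_io import Dataset
from .null_ensembles import NullEnsemble

log = logging.getLogger("asmpipe")

__all__ = ["LmmResult", "zscale", "fit_ctm_lmm", "refit_formula", "table1_pipeline", "ctm_table"]

ENV_VARS = ["depth", "sand", "complexity"]


def zscale(x) -> np.ndarray:
    """z-score a vector (sample sd); errors on constant input."""
    arr = np.asarray(x, dtype=float)
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-scale a constant vector")
    return (arr - arr.mean()) / sd


@dataclass
class LmmResult:
    response: str
    coefficients: dict[str, float]
    pvalues: dict[str, float]
    dropped: list[str]
    r2_conditional: float
    r2_marginal: float
    var_fixed: float
    var_random: float
    var_residual: float
    n_obs: int
    converged: bool
    ols_fallback: bool = False
    notes: list[str] = field(default_factory=list)


def _fit_mixed(y: np.ndarray, X: pd.DataFrame, groups) -> tuple:
    """REML mixed fit with OLS fallback when the mixed fit fails.

    Returns (params, bse, var_random, var_residual, fitted_fixed,
    converged, ols_fallback). ``X`` excludes the constant.
    """
    exog = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MixedLM(y, exog, groups=np.asarray(groups)).fit(reml=True)
            converged = bool(res.converged)
        except Exception as exc:  # singular / non-converging fits
            log.debug("mixed model failed (%s); OLS fallback", exc)
            res = None
            converged = False
        if res is not None and converged and np.isfinite(res.scale):
            var_u = float(np.asarray(res.cov_re)[0, 0])
            var_e = float(res.scale)
            params = res.fe_params
            bse = res.bse_fe  # lazy; may warn / go NaN on boundary fits
            if np.asarray(bse).size and np.isfinite(np.asarray(bse)).all():
                fitted_fixed = np.asarray(exog) @ np.asarray(params)
                return params, bse, var_u, var_e, fitted_fixed, True, False
        ols = sm.OLS(y, exog).fit()
        fitted_fixed = np.asarray(ols.fittedvalues)
        return ols.params, ols.bse, 0.0, float(ols.mse_resid), fitted_fixed, False, True


def _wald_p(params, bse, n_obs: int) -> pd.Series:
    k = len(params) - 1  # excluding intercept
    df = max(n_obs - k - 1, 1)
    t = np.asarray(params) / np.asarray(bse)
    p = pd.Series(2 * sps.t.sf(np.abs(t), df), index=params.index)
    return p.fillna(1.0)  # degenerate SEs count as nonsignificant


def fit_ctm_lmm(
    ctm_vector,
    environment: pd.DataFrame,
    clusters,
    alpha: float = 0.05,
    response_name: str = "ctm",
) -> LmmResult:
    """Backward-eliminated mixed model of one CTM on the environment.

    ``environment`` holds the candidate fixed effects (columns); rows
    must align with ``ctm_vector`` and ``clusters``.
    """
    y = zscale(ctm_vector)
    X_full = environment.apply(zscale)
    preds = list(X_full.columns)
    dropped: list[str] = []
    n = len(y)

    while True:
        params, bse, var_u, var_e, fitted, converged, ols_fb = _fit_mixed(
            y, X_full[preds], clusters
        )
        if not preds:
            pvals = pd.Series(dtype=float)
            break
        pvals = _wald_p(params, bse, n).drop("const")
        worst_p = pvals.max()
        if worst_p <= alpha:
            break
        # drop the least significant predictor; ties break by name
        worst = sorted(pvals.index[pvals == worst_p])[0]
        preds.remove(worst)
        dropped.append(worst)
        if not preds:
            params, bse, var_u, var_e, fitted, converged, ols_fb = _fit_mixed(
                y, X_full[[]], clusters
            )
            pvals = pd.Series(dtype=float)
            break

    var_f = float(np.var(fitted))
    denom = var_f + var_u + var_e
    return LmmResult(
        response=response_name,
        coefficients={p: float(params[p]) for p in preds},
        pvalues={p: float(pvals[p]) for p in preds},
        dropped=dropped,
        r2_conditional=(var_f + var_u) / denom if denom > 0 else 0.0,
        r2_marginal=var_f / denom if denom > 0 else 0.0,
        var_fixed=var_f,
        var_random=var_u,
        var_residual=var_e,
        n_obs=n,
        converged=converged,
        ols_fallback=ols_fb,
    )


def refit_formula(
    ctm_vector,
    environment: pd.DataFrame,
    clusters,
    predictors: list[str],
    response_name: str = "ctm",
) -> LmmResult:
    """Fit a fixed formula (no selection) — used on ensemble replicates."""
    y = zscale(ctm_vector)
    X = environment[predictors].apply(zscale) if predictors else environment[[]]
    params, bse, var_u, var_e, fitted, converged, ols_fb = _fit_mixed(y, X, clusters)
    pvals = (
        _wald_p(params, bse, len(y)).drop("const") if predictors else pd.Series(dtype=float)
    )
    var_f = float(np.var(fitted))
    denom = var_f + var_u + var_e
    return LmmResult(
        response=response_name,
        coefficients={p: float(params[p]) for p in predictors},
        pvalues={p: float(pvals[p]) for p in predictors},
        dropped=[],
        r2_conditional=(var_f + var_u) / denom if denom > 0 else 0.0,
        r2_marginal=var_f / denom if denom > 0 else 0.0,
        var_fixed=var_f,
        var_random=var_u,
        var_residual=var_e,
        n_obs=len(y),
        converged=converged,
        ols_fallback=ols_fb,
    )


# ---------------------------------------------------------------------------
# CTM construction and the observed-vs-simulated contrast table
# ---------------------------------------------------------------------------


def ctm_table(dataset: Dataset, communities: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Per-transect community trait means (unweighted, presence-based).

    With ``communities`` given (transect id -> pool index array), CTMs
    are computed for those communities instead of the observed ones.
    """
    mat = dataset.pool.matrix
    rows = {}
    for t in dataset.transects:
        idx = (
            communities[t.transect_id]
            if communities is not None
            else dataset.community_indices(t.transect_id)
        )
        rows[t.transect_id] = mat[np.asarray(idx)].mean(axis=0)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=dataset.pool.traits.trait_names
    ).loc[dataset.transect_ids]


def table1_pipeline(
    dataset: Dataset,
    ensembles: dict[str, NullEnsemble],
    trait_list: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Observed vs. artificial-community CTM regressions, long format.

    For every trait: fit the backward-eliminated model on observed CTMs;
    then, for each ensemble mode, refit the *observed* final formula to
    each replicate's CTMs and average coefficients and conditional R²
    across replicates. One output row per trait x source.
    """
    traits = trait_list or dataset.pool.traits.trait_names
    env = dataset.environment()[ENV_VARS]
    clusters = dataset.environment()["cluster_id"]
    obs_ctm = ctm_table(dataset)

    rows = []
    for trait in traits:
        obs = fit_ctm_lmm(obs_ctm[trait], env, clusters, alpha=alpha, response_name=trait)
        rows.append(_row(trait, "observed", obs.coefficients, obs.r2_conditional, obs))
        for mode, ens in ensembles.items():
            coefs = []
            r2s = []
            for rep in range(ens.n_rep):
                comm = {tid: ens.replicate_indices(tid, rep) for tid in dataset.transect_ids}
                rep_ctm = ctm_table(dataset, communities=comm)[trait]
                try:
                    res = refit_formula(
                        rep_ctm, env, clusters,
                        predictors=list(obs.coefficients),
                        response_name=trait,
                    )
                except ValueError:  # constant replicate CTM: no variance to model
                    continue
                coefs.append(res.coefficients)
                r2s.append(res.r2_conditional)
            mean_coef = {
                p: float(np.mean([c[p] for c in coefs])) for p in obs.coefficients
            } if coefs else {}
            mean_r2 = float(np.mean(r2s)) if r2s else np.nan
            rows.append(_row(trait, mode, mean_coef, mean_r2, None, n_rep=len(r2s)))
    return pd.DataFrame(rows)


def _row(trait, source, coefs, r2, obs_result, n_rep=None) -> dict:
    row = {"trait": trait, "source": source, "r2_conditional": r2, "n_rep": n_rep}
    for v in ENV_VARS:
        row[v] = coefs.get(v, np.nan)
    if obs_result is not None:
        for v in ENV_VARS:
            row[f"p_{v}"] = obs_result.pvalues.get(v, np.nan)
        row["dropped"] = ",".join(obs_result.dropped)
    return row
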