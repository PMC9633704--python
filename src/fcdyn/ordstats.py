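"""Inferential layer: proportional-odds ordinal regression of per-subject
measures on ordered condition labels, a likelihood-ratio check of the
proportional-odds assumption, Spearman inter-correlations, and rank-sum
group contrasts.

The cumulative-logit model is P(Y <= j | x) = logistic(zeta_j - x'beta)
with a slope shared across levels (parallel slopes); exp(beta) is the
odds ratio per unit (by default per standard deviation) of the measure.
Reversing the condition order flips beta's sign and maps OR -> 1/OR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "OlrResult",
    "PoCheckResult",
    "fit_proportional_odds",
    "proportional_odds_check",
    "measure_correlations",
    "rank_sum_compare",
    "run_cohort_analysis",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OlrResult:
    """Proportional-odds fit for one or more predictors.

    Arrays are aligned with the predictor columns; ``odds_ratio`` =
    exp(beta) with Wald 95% confidence limits. ``standardized`` records
    whether predictors were z-scored (odds ratios are then per standard
    deviation).
    """

    beta: np.ndarray
    odds_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_value: np.ndarray
    sided: str
    intercepts: np.ndarray
    loglike: float
    converged: bool
    standardized: bool
    n_obs: int
    vif: np.ndarray | None = None


@dataclass(frozen=True)
class PoCheckResult:
    """Likelihood-ratio check of the proportional-odds assumption."""

    lr_stat: float
    df: int
    p_value: float
    converged: bool


def _prepare_y(y, order=None) -> np.ndarray:
    """Ordered labels -> contiguous integer ranks 0..J-1."""
    y = np.asarray(y)
    if order is not None:
        order = list(order)
        ranks = {lab: i for i, lab in enumerate(order)}
        missing = set(np.unique(y)) - set(order)
        if missing:
            raise ValueError(f"labels not in order: {sorted(missing)}")
        codes = np.array([ranks[v] for v in y])
    else:
        levels, codes = np.unique(y, return_inverse=True)
    if np.unique(codes).size < 2:
        raise ValueError("ordinal outcome needs >= 2 levels")
    return codes


def fit_proportional_odds(y, X, standardize: bool = True,
                          sided: str = "two", order=None) -> OlrResult:
    """Maximum-likelihood cumulative-logit model with parallel slopes.

    Parameters
    ----------
    y : array-like
        Ordered outcome labels; ranked by ``order`` if given, otherwise by
        sorted unique value.
    X : array-like, shape (n, p) or (n,)
        Continuous predictors.
    standardize : bool
        z-score predictors so odds ratios are per standard deviation.
    sided : {"two", "greater", "less"}
        "greater"/"less" halve the Wald p-value when the estimated beta
        sign matches the stated direction (otherwise 1 - p/2).
    """
    codes = _prepare_y(y, order=order)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and codes.size > 1:
        X = X.T
    if X.shape[0] != codes.size:
        raise ValueError("y and X lengths differ")
    n, p = X.shape
    if standardize:
        sd = X.std(axis=0)
        if (sd == 0).any():
            raise ValueError("constant predictor cannot be standardized")
        X = (X - X.mean(axis=0)) / sd
    endog = pd.Series(
        pd.Categorical(codes, categories=np.unique(codes), ordered=True))
    model = OrderedModel(endog, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=500, disp=False)
    converged = bool(res.mle_retvals.get("converged", True))
    if not converged:
        log.warning("proportional-odds fit did not converge")
    beta = np.asarray(res.params[:p], dtype=float)
    se = np.asarray(res.bse[:p], dtype=float)
    zcrit = stats.norm.ppf(0.975)
    zstat = beta / se
    p_two = 2 * stats.norm.sf(np.abs(zstat))
    if sided == "two":
        pv = p_two
    elif sided in ("greater", "less"):
        match = beta > 0 if sided == "greater" else beta < 0
        pv = np.where(match, p_two / 2, 1 - p_two / 2)
    else:
        raise ValueError("sided must be 'two', 'greater' or 'less'")
    thresholds = model.transform_threshold_params(res.params)[1:-1]
    vif = None
    if p >= 2:
        vif = np.array([variance_inflation_factor(X, i) for i in range(p)])
        if (vif > 5).any():
            log.warning("variance inflation factor above 5: %s", vif)
    with np.errstate(over="ignore"):  # separation gives unbounded CIs
        odds_ratio = np.exp(beta)
        ci_low = np.exp(beta - zcrit * se)
        ci_high = np.exp(beta + zcrit * se)
    return OlrResult(
        beta=beta, odds_ratio=odds_ratio, ci_low=ci_low, ci_high=ci_high,
        p_value=np.asarray(pv), sided=sided,
        intercepts=np.asarray(thresholds, dtype=float),
        loglike=float(res.llf), converged=converged,
        standardized=standardize, n_obs=n, vif=vif)


def _cumulative_nll(codes: np.ndarray, X: np.ndarray, zetas: np.ndarray,
                    betas: np.ndarray) -> float:
    """Negative log-likelihood of a cumulative-logit model with
    level-specific slopes: P(Y<=j|x) = logistic(zeta_j - x'beta_j)."""
    eta = zetas[None, :] - X @ betas.T  # (n, J-1)
    cum = 1.0 / (1.0 + np.exp(-eta))
    cum = np.hstack([np.zeros((X.shape[0], 1)), cum,
                     np.ones((X.shape[0], 1))])
    probs = np.diff(cum, axis=1)
    p_obs = probs[np.arange(codes.size), codes]
    if (p_obs <= 0).any():
        # non-monotone cumulative curves for some x: barrier
        return 1e10 + float(-(np.minimum(p_obs, 0)).sum()) * 1e10
    return float(-np.log(p_obs).sum())


def proportional_odds_check(y, X, order=None) -> PoCheckResult:
    """Likelihood-ratio test of parallel slopes.

    The constrained model shares one slope vector across cumulative
    logits; the relaxed model gives each of the J-1 logits its own slopes
    (fitted jointly on the categorical likelihood, initialised at the
    constrained solution). The statistic is referred to chi-square with
    (J - 2) * p degrees of freedom.
    """
    codes = _prepare_y(y, order=order)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and codes.size > 1:
        X = X.T
    n, p = X.shape
    n_levels = int(codes.max()) + 1
    df = (n_levels - 2) * p
    if df < 1:
        raise ValueError("relaxed model needs >= 3 outcome levels")
    constrained = fit_proportional_odds(codes, X, standardize=False)
    zeta0 = constrained.intercepts
    beta0 = constrained.beta

    def nll(theta):
        zetas = theta[:n_levels - 1]
        betas = theta[n_levels - 1:].reshape(n_levels - 1, p)
        return _cumulative_nll(codes, X, zetas, betas)

    theta0 = np.concatenate([zeta0, np.tile(beta0, n_levels - 1)])
    # derivative-free search from the constrained solution: the relaxed
    # likelihood is only piecewise-smooth where cumulative curves cross
    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-9,
                                     "maxiter": 2000 * theta0.size})
    ll_relaxed = -float(res.fun)
    lr = max(0.0, 2.0 * (ll_relaxed - constrained.loglike))
    converged = bool(res.success) and constrained.converged
    if not converged:
        log.warning("proportional-odds check inconclusive (non-convergence)")
    return PoCheckResult(lr_stat=lr, df=df,
                         p_value=float(stats.chi2.sf(lr, df)),
                         converged=converged)


def measure_correlations(table: pd.DataFrame, measures=None):
    """Pairwise Spearman correlations between per-subject measures, pooled
    across conditions. Returns (rho, p) DataFrames."""
    if measures is None:
        measures = [c for c in table.columns
                    if table[c].dtype.kind in "fi"]
    if len(table) < 5:
        raise ValueError("need at least 5 subjects")
    data = table[list(measures)].to_numpy(dtype=float)
    k = len(measures)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if np.unique(data[:, i]).size < 2 or np.unique(data[:, j]).size < 2:
                warnings.warn(f"constant measure column: correlation between "
                              f"{measures[i]} and {measures[j]} undefined",
                              UserWarning, stacklevel=2)
                rho[i, j] = rho[j, i] = np.nan
                pmat[i, j] = pmat[j, i] = np.nan
                continue
            r, pv = stats.spearmanr(data[:, i], data[:, j])
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = pv
    idx = list(measures)
    return (pd.DataFrame(rho, index=idx, columns=idx),
            pd.DataFrame(pmat, index=idx, columns=idx))


def rank_sum_compare(a, b) -> tuple[float, float]:
    """Two-sample rank-sum z test with normal approximation and tie
    correction. Returns (z, two-sided p); all-tied data give (0, 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    w = ranks[:n1].sum()
    mean_w = n1 * (n1 + n2 + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return 0.0, 1.0
    z = (w - mean_w) / np.sqrt(var_w)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def run_cohort_analysis(table: pd.DataFrame, condition_order,
                        measures=None, sided_map=None,
                        joint=None, standardize: bool = True) -> pd.DataFrame:
    """Per-measure proportional-odds regressions across a cohort.

    Parameters
    ----------
    table : DataFrame
        Tidy per-subject measures: columns subject_id, condition, measure,
        value, and optionally subset / params qualifiers that become part
        of the measure grouping.
    condition_order : sequence of str
        Condition labels from least to most aware; the fitted odds ratio
        is per unit of the measure toward *higher* awareness.
    measures : sequence of str, optional
        Restrict to these measure names.
    sided_map : dict, optional
        measure name -> "two" | "greater" | "less".
    joint : sequence of sequences, optional
        Groups of measure names entered jointly as covariates.
    """
    condition_order = list(condition_order)
    if len(condition_order) < 2:
        raise ValueError("ordinal outcome needs >= 2 levels")
    wide = table.pivot_table(index=["subject_id", "condition"],
                             columns="measure", values="value").reset_index()
    present = set(table["condition"].unique())
    if len(present & set(condition_order)) < 2:
        raise ValueError("ordinal outcome needs >= 2 levels")
    all_measures = [c for c in wide.columns
                    if c not in ("subject_id", "condition")]
    if measures is not None:
        all_measures = [m for m in all_measures if m in set(measures)]
    sided_map = sided_map or {}
    rows = []
    specs = [[m] for m in all_measures] + [list(g) for g in (joint or [])]
    for group in specs:
        sub = wide.dropna(subset=group)
        dropped = len(wide) - len(sub)
        if dropped:
            log.info("dropped %d subject(s) missing %s", dropped, group)
        sided = sided_map.get(group[0], "two") if len(group) == 1 else "two"
        res = fit_proportional_odds(
            sub["condition"].to_numpy(), sub[group].to_numpy(dtype=float),
            standardize=standardize, sided=sided, order=condition_order)
        n_per = sub["condition"].value_counts().to_dict()
        for i, name in enumerate(group):
            rows.append({
                "measure": name,
                "covariates": "+".join(group),
                "odds_ratio": res.odds_ratio[i],
                "ci_low": res.ci_low[i], "ci_high": res.ci_high[i],
                "p_value": res.p_value[i], "sided": res.sided,
                "beta": res.beta[i],
                "standardized": res.standardized,
                "converged": res.converged,
                "n_obs": res.n_obs,
                "n_per_condition": ";".join(
                    f"{c}={n_per.get(c, 0)}" for c in condition_order),
            })
    return pd.DataFrame(rows)
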