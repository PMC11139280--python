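"""Statistical battery for comparing nod functions.

Preprocessing (z-scoring, conservative IQR-fence outlier removal), two-sample
location tests, Pearson correlation with a Fisher-z confidence interval,
random-intercept logistic mixed models with likelihood-ratio model
comparison, and a bootstrap of median differences.

The mixed model is a binomial GLMM: the log-odds that a nod is affirmative
(rather than feedback) is a linear function of z-scored kinematic predictors
plus a Gaussian random intercept per signer.  The marginal likelihood
integrates the random intercept out with Gauss-Hermite quadrature and is
maximized directly; the quadrature order and optimizer are recorded in every
fit so the approximation is never silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

DEFAULT_QUARTILE_METHOD = "hazen"


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def z_score(values: np.ndarray) -> np.ndarray:
    """Standardize to sample mean 0 and sd 1 (ddof=1, as in R's scale)."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot z-score a constant variable")
    return (values - values.mean()) / sd


def remove_outliers(
    df: pd.DataFrame,
    columns: list[str],
    k: float = 5.0,
    method: str = DEFAULT_QUARTILE_METHOD,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, tuple[float, float]]]:
    """Drop rows outside Q1 - k*IQR .. Q3 + k*IQR on any of the given columns.

    Whole observations are removed: a nod that is extreme on one variable
    leaves the dataset entirely.  Fences are computed once on the input (the
    removal is not iterated).  Quartiles use the Hazen convention by default;
    the convention is returned with the fences so it is always logged.

    Returns (retained, removed, fences) where fences maps column ->
    (lower, upper).
    """
    if len(df) < 4:
        raise ValueError("need at least 4 observations to place quartile fences")
    keep = np.ones(len(df), dtype=bool)
    fences: dict[str, tuple[float, float]] = {}
    for col in columns:
        v = df[col].to_numpy(dtype=float)
        q1, q3 = np.percentile(v, [25, 75], method=method)
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        fences[col] = (lo, hi)
        keep &= (v >= lo) & (v <= hi)
    if not keep.any():
        raise ValueError("outlier fences removed every observation")
    return df.loc[keep].copy(), df.loc[~keep].copy(), fences


# ---------------------------------------------------------------------------
# two-sample comparisons
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample t and rank tests for one measure, group A minus group B.

    ``rank_sum`` is the sum of ranks of group A in the pooled ranking;
    ``u_statistic`` is the corresponding Mann-Whitney U for group A.
    """

    measure: str
    t_statistic: float
    t_p: float
    rank_sum: float
    u_statistic: float
    wilcoxon_p: float
    n_a: int
    n_b: int
    equal_var: bool

    @property
    def t_stars(self) -> str:
        return significance_stars(self.t_p)

    @property
    def wilcoxon_stars(self) -> str:
        return significance_stars(self.wilcoxon_p)


def compare_groups(
    group_a: np.ndarray,
    group_b: np.ndarray,
    measure: str = "",
    equal_var: bool = False,
) -> ComparisonResult:
    """Welch t test (by default) and Wilcoxon rank-sum test, two-sided.

    The sign convention is group A minus group B throughout.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    t_res = stats.ttest_ind(a, b, equal_var=equal_var)
    u_res = stats.mannwhitneyu(a, b, alternative="two-sided")
    ranks = stats.rankdata(np.concatenate([a, b]))
    rank_sum = float(ranks[: len(a)].sum())
    return ComparisonResult(
        measure=measure,
        t_statistic=float(t_res.statistic),
        t_p=float(t_res.pvalue),
        rank_sum=rank_sum,
        u_statistic=float(u_res.statistic),
        wilcoxon_p=float(u_res.pvalue),
        n_a=len(a),
        n_b=len(b),
        equal_var=equal_var,
    )


def pearson_with_ci(
    x: np.ndarray, y: np.ndarray, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Pearson r with a Fisher variance-stabilized confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    crit = stats.norm.ppf(0.5 + level / 2)
    return r, (float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se)))


def bootstrap_median_diff(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_boot: int = 10000,
    seed: int | None = None,
    level: float = 0.95,
) -> dict[str, object]:
    """Percentile bootstrap of median(group A) - median(group B).

    Each group is resampled with replacement independently; fully
    reproducible for a fixed seed.  ``n_boot`` below 100 is allowed (for
    smoke runs) but flagged in the result.
    """
    if seed is None:
        raise ValueError("seed is mandatory for the bootstrap")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    boot_a = np.median(a[rng.integers(0, len(a), size=(n_boot, len(a)))], axis=1)
    boot_b = np.median(b[rng.integers(0, len(b), size=(n_boot, len(b)))], axis=1)
    diffs = boot_a - boot_b
    alpha = (1 - level) / 2
    lo, hi = np.quantile(diffs, [alpha, 1 - alpha])
    return {
        "observed": float(np.median(a) - np.median(b)),
        "ci": (float(lo), float(hi)),
        "n_boot": n_boot,
        "warning": "n_boot < 100" if n_boot < 100 else None,
    }


# ---------------------------------------------------------------------------
# random-intercept logistic mixed model
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """A fitted random-intercept logistic model."""

    formula: str
    param_names: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    loglik: float
    n_params: int
    sigma_u: float
    group_effects: dict[str, float] = field(repr=False, default_factory=dict)
    converged: bool = True
    method: str = ""
    n_obs: int = 0
    n_groups: int = 0
    message: str = ""


def _mixed_loglik(
    params: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    nodes: np.ndarray,
    log_weights: np.ndarray,
) -> float:
    """Marginal log-likelihood, random intercept integrated by quadrature."""
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    eta0 = X @ beta
    u = np.sqrt(2.0) * sigma * nodes  # (q,)
    eta = eta0[:, None] + u[None, :]  # (n, q)
    # Bernoulli log-likelihood, numerically safe log(1 + e^eta)
    ll_obs = y[:, None] * eta - np.logaddexp(0.0, eta)
    S = np.zeros((n_groups, len(nodes)))
    np.add.at(S, group_idx, ll_obs)
    return float(np.sum(logsumexp(S + log_weights[None, :], axis=1)))


def _plain_logistic_loglik(beta: np.ndarray, y: np.ndarray, X: np.ndarray) -> float:
    eta = X @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            pp = x.copy(); pp[i] += eps; pp[j] += eps
            pm = x.copy(); pm[i] += eps; pm[j] -= eps
            mp = x.copy(); mp[i] -= eps; mp[j] += eps
            mm = x.copy(); mm[i] -= eps; mm[j] -= eps
            H[i, j] = H[j, i] = (f(pp) - f(pm) - f(mp) + f(mm)) / (4 * eps**2)
    return H


def fit_logistic_mixed(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    param_names: list[str] | None = None,
    n_quad: int = 25,
    formula: str = "",
) -> ModelFit:
    """Maximum-likelihood fit of a logistic model with a random intercept.

    Parameters are the fixed-effect coefficients and the log of the random-
    intercept standard deviation.  With a single group the random intercept
    is unidentifiable and the model collapses to plain logistic regression
    (sigma fixed at 0).  Non-convergence is flagged on the returned fit,
    never silently ignored.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    labels, group_idx = np.unique(groups, return_inverse=True)
    n_groups = len(labels)
    p = X.shape[1]
    names = list(param_names) if param_names else [f"x{i}" for i in range(p)]

    if n_groups == 1:
        res = optimize.minimize(
            lambda b: -_plain_logistic_loglik(b, y, X), np.zeros(p), method="BFGS"
        )
        H = _numeric_hessian(lambda b: -_plain_logistic_loglik(b, y, X), res.x)
        se = np.sqrt(np.diag(np.linalg.pinv(H)))
        return ModelFit(
            formula=formula, param_names=names,
            coef=dict(zip(names, res.x.tolist())), se=dict(zip(names, se.tolist())),
            loglik=-float(res.fun), n_params=p, sigma_u=0.0,
            group_effects={str(labels[0]): 0.0}, converged=bool(res.success),
            method="plain logistic (single group, sigma fixed at 0); BFGS",
            n_obs=len(y), n_groups=1, message=str(res.message),
        )

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_weights = np.log(weights) - 0.5 * np.log(np.pi)

    def nll(params: np.ndarray) -> float:
        return -_mixed_loglik(params, y, X, group_idx, n_groups, nodes, log_weights)

    x0 = np.concatenate([np.zeros(p), [np.log(0.5)]])
    res = optimize.minimize(nll, x0, method="L-BFGS-B")
    beta, log_sigma = res.x[:-1], res.x[-1]
    sigma = float(np.exp(log_sigma))

    H = _numeric_hessian(nll, res.x)
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))

    # posterior mean of each group's random intercept (empirical Bayes)
    u = np.sqrt(2.0) * sigma * nodes
    eta = (X @ beta)[:, None] + u[None, :]
    ll_obs = y[:, None] * eta - np.logaddexp(0.0, eta)
    S = np.zeros((n_groups, n_quad))
    np.add.at(S, group_idx, ll_obs)
    logw = S + log_weights[None, :]
    post = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
    blups = post @ u

    return ModelFit(
        formula=formula, param_names=names,
        coef=dict(zip(names, beta.tolist())), se=dict(zip(names, se.tolist())),
        loglik=-float(res.fun), n_params=p + 1, sigma_u=sigma,
        group_effects={str(lab): float(b) for lab, b in zip(labels, blups)},
        converged=bool(res.success),
        method=f"Gauss-Hermite quadrature ({n_quad} nodes); L-BFGS-B",
        n_obs=len(y), n_groups=n_groups, message=str(res.message),
    )


def fit_function_model(
    records: pd.DataFrame,
    fixed_effects: list[str],
    outcome: str = "is_affirmation",
    group: str = "signer",
    n_quad: int = 25,
) -> ModelFit:
    """Fit the affirmation-vs-feedback model on a per-nod record table.

    ``records`` must carry the binary outcome column (1 = affirmation), the
    signer label, and the (z-scored) predictor columns named in
    ``fixed_effects``.  An intercept is always included.
    """
    X = np.column_stack(
        [np.ones(len(records))] + [records[c].to_numpy(dtype=float) for c in fixed_effects]
    )
    names = ["intercept"] + list(fixed_effects)
    formula = f"{outcome} ~ 1 + {' + '.join(fixed_effects) if fixed_effects else '1'} + (1 | {group})"
    return fit_logistic_mixed(
        records[outcome].to_numpy(dtype=float), X, records[group].to_numpy(),
        param_names=names, n_quad=n_quad, formula=formula,
    )


@dataclass(frozen=True)
class LikelihoodRatioResult:
    chi2: float
    df: int
    p: float


def compare_models(fit_small: ModelFit, fit_large: ModelFit) -> LikelihoodRatioResult:
    """Likelihood-ratio test of nested fits on the same data.

    Nesting is checked on the fixed-effect names and the sample size; the
    statistic is 2 * (LL_large - LL_small) with df equal to the parameter
    difference.  Tiny negative statistics from optimizer noise are clamped
    to zero.
    """
    if fit_small.n_obs != fit_large.n_obs:
        raise ValueError("fits are not on the same data (different n)")
    if not set(fit_small.param_names) <= set(fit_large.param_names):
        raise ValueError("models are not nested")
    chi2 = 2.0 * (fit_large.loglik - fit_small.loglik)
    if chi2 < 0:
        if chi2 < -1e-4:
            raise ValueError(f"larger model has lower likelihood (chi2 = {chi2:.6f}); check convergence")
        chi2 = 0.0
    df = fit_large.n_params - fit_small.n_params
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return LikelihoodRatioResult(chi2=float(chi2), df=df, p=p)
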