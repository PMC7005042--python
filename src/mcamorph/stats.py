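"""Case-control inference: rank tests, correlation screen, logistic models, ROC.

The inference stage mirrors a standard observational case-control workflow:
nonparametric location comparisons between groups (Mann–Whitney U), paired
predicted-vs-observed contrasts (Wilcoxon signed-rank), a Pearson correlation
screen among candidate predictors, univariate logistic fits, a selection rule
(univariate p < 0.1, drop one of each strongly correlated pair), a
multivariate logistic model, and ROC analysis with Youden-optimal cut-offs.

Rank tests and the logistic maximum-likelihood fit are delegated to scipy and
statsmodels respectively; the ROC construction is implemented here because
its contract (candidate thresholds at midpoints between consecutive pooled
values, trapezoid AUC, smallest-threshold tie-break for Youden) is part of
this package's interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "pearson_correlation_matrix",
    "LogisticFit",
    "fit_logistic",
    "univariate_screen",
    "select_model_variables",
    "RocResult",
    "roc_analysis",
]

#: exact-method sample-size ceiling for the rank tests
EXACT_LIMIT = 12


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns ``(U, p)`` with U counted for x.

    ``U`` counts pairs with ``x_i > y_j`` plus half of the ties.  Method
    ``auto`` uses exact null enumeration when ``n1 + n2 <= 12`` and there are
    no ties, otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        pooled = np.concatenate([x, y])
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (x.size + y.size <= EXACT_LIMIT and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(
    paired_diffs: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped.  ``auto``: exact enumeration of the 2^n
    sign patterns for n <= 12 without tied magnitudes, else the normal
    approximation with continuity correction.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    if method == "auto":
        no_ties = np.unique(np.abs(d)).size == d.size
        method = "exact" if (d.size <= EXACT_LIMIT and no_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True, method=method)
    return float(res.statistic), float(res.pvalue)


def pearson_correlation_matrix(
    table: pd.DataFrame, columns: Optional[Sequence[str]] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson r and t-test p-value matrices.

    Cells with fewer than 3 complete pairs or a zero-variance margin are NaN.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            xy = table[[cols[i], cols[j]]].dropna()
            if len(xy) < 3:
                continue
            xi = xy.iloc[:, 0].to_numpy()
            yj = xy.iloc[:, 1].to_numpy()
            if np.ptp(xi) == 0 or np.ptp(yj) == 0:
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            rr = sps.pearsonr(xi, yj)
            r[i, j] = r[j, i] = rr.statistic
            p[i, j] = p[j, i] = rr.pvalue
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def _ridge_logit(
    y: np.ndarray, X: np.ndarray, lam: float = 1e-6, n_iter: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Newton fit of an L2-penalised logistic log-likelihood (fallback path)."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = np.clip(X @ beta, -700, 700)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-12)
        grad = X.T @ (y - p) - lam * beta
        hess = (X * w[:, None]).T @ X + lam * np.eye(X.shape[1])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    se = np.sqrt(np.diag(np.linalg.inv(hess)))
    return beta, se


@dataclass(frozen=True)
class LogisticFit:
    """One logistic model: per-term Wald summaries in raw predictor units.

    Odds ratios are per one raw unit of the predictor (per degree, per cm³/s,
    per exponent unit, ...); the 95% CI is ``exp(coef ± 1.96·SE)``.
    """

    terms: pd.DataFrame  # index: term; columns: coef, se, odds_ratio, ci_low, ci_high, p
    converged: bool
    separation: bool
    n_obs: int
    outcome: str = ""


def fit_logistic(
    y: Sequence[int],
    X: pd.DataFrame,
    outcome: str = "",
) -> LogisticFit:
    """Maximum-likelihood logistic regression with an intercept.

    Raises on a single-class outcome or a constant predictor column; flags
    (rather than hides) non-convergence and quasi-perfect separation.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    for c in X.columns:
        if np.ptp(X[c].to_numpy(dtype=float)) == 0:
            raise ValueError(f"predictor {c!r} is constant")

    design = sm.add_constant(X.astype(float), has_constant="add")
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", False))
            coef, se = fit.params, fit.bse
            fitted = np.asarray(fit.predict(design))
        except Exception:
            # unbounded likelihood (separation) breaks the Hessian inversion;
            # a faintly ridge-penalised Newton fit still yields finite,
            # flagged numbers instead of a crash
            beta, se_vec = _ridge_logit(y, design.to_numpy())
            coef = pd.Series(beta, index=design.columns)
            se = pd.Series(se_vec, index=design.columns)
            fitted = 1.0 / (1.0 + np.exp(-(design.to_numpy() @ beta)))
    # quasi-perfect prediction marks (near-)separation
    separation = bool(np.all(np.abs(fitted - y) < 1e-3))
    terms = pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "odds_ratio": np.exp(coef),
            "ci_low": np.exp(coef - 1.96 * se),
            "ci_high": np.exp(coef + 1.96 * se),
            "p": 2.0 * sps.norm.sf(np.abs(coef / se)),
        }
    )
    return LogisticFit(
        terms=terms,
        converged=converged,
        separation=separation,
        n_obs=int(len(y)),
        outcome=outcome,
    )


def univariate_screen(
    table: pd.DataFrame,
    y_col: str,
    candidate_vars: Sequence[str],
    outcome: str = "",
) -> dict[str, LogisticFit]:
    """One single-predictor logistic fit per candidate, complete-case per var."""
    out: dict[str, LogisticFit] = {}
    for var in candidate_vars:
        sub = table[[y_col, var]].dropna()
        out[var] = fit_logistic(sub[y_col], sub[[var]], outcome=outcome)
    return out


def select_model_variables(
    screen: dict[str, LogisticFit],
    corr: pd.DataFrame,
    p_enter: float = 0.1,
    r_max: float = 0.5,
) -> tuple[list[str], list[dict]]:
    """Entry rule for the multivariate model, with an audit trail.

    Keeps candidates with univariate p < ``p_enter``; within any retained pair
    with ``|r| > r_max`` drops the member with the larger univariate p (tie:
    the later one in input order).  Returns ``(retained, audit)`` where each
    audit entry records a dropped variable and why.
    """
    pvals = {v: float(f.terms.loc[v, "p"]) for v, f in screen.items()}
    audit: list[dict] = []
    retained: list[str] = []
    for v, p in pvals.items():
        if np.isfinite(p) and p < p_enter:
            retained.append(v)
        else:
            audit.append({"variable": v, "action": "excluded",
                          "reason": f"univariate p={p:.4g} >= {p_enter}"})
    order = {v: i for i, v in enumerate(pvals)}
    names = list(retained)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if a not in retained or b not in retained:
                continue
            r_ab = corr.loc[a, b] if (a in corr.index and b in corr.columns) else np.nan
            if np.isfinite(r_ab) and abs(r_ab) > r_max:
                if pvals[a] > pvals[b]:
                    drop = a
                elif pvals[a] < pvals[b]:
                    drop = b
                else:
                    drop = b if order[b] > order[a] else a
                keep = a if drop == b else b
                retained.remove(drop)
                audit.append({
                    "variable": drop, "action": "dropped",
                    "reason": f"|r|={abs(r_ab):.3f} > {r_max} with {keep}; "
                              f"larger univariate p ({pvals[drop]:.4g})",
                })
    return retained, audit


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve with a Youden-optimal cut-off.

    ``thresholds`` are midpoints between consecutive sorted unique pooled
    scores (padded with sentinels below/above the data range); a score
    strictly above the threshold is classified as a case.
    """

    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    youden_j: float


def roc_analysis(
    scores_cases: Sequence[float], scores_controls: Sequence[float]
) -> RocResult:
    """Empirical ROC; higher score means case-like.

    For a protective marker (cases score lower), callers flip the sign of the
    scores first.  The AUC (trapezoid over the empirical curve) equals the
    Mann–Whitney U statistic of cases-vs-controls divided by ``n1·n2``, ties
    counted half; the optimal cut-off maximises Youden's
    ``J = sensitivity + specificity − 1``, ties resolved toward the smallest
    threshold.
    """
    cases = np.asarray(scores_cases, dtype=float)
    controls = np.asarray(scores_controls, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both score samples must be non-empty")

    pooled = np.unique(np.concatenate([cases, controls]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    lo = pooled[0] - 1.0
    hi = pooled[-1] + 1.0
    thresholds = np.concatenate([[lo], mids, [hi]])

    cs = np.sort(cases)
    ct = np.sort(controls)
    sens = 1.0 - np.searchsorted(cs, thresholds, side="right") / cases.size
    spec = np.searchsorted(ct, thresholds, side="right") / controls.size

    # traverse the curve in descending-threshold order: (0,0) -> (1,1) with
    # FPR and sensitivity jointly nondecreasing (ties advance diagonally)
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))

    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())
    pick = best[np.argmin(thresholds[best])]
    return RocResult(
        auc=auc,
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        cutoff=float(thresholds[pick]),
        sensitivity_at_cutoff=float(sens[pick]),
        specificity_at_cutoff=float(spec[pick]),
        youden_j=float(j[pick]),
    )
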