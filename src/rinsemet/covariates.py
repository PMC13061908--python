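"""Sex/age robustness checks for a candidate marker.

Two complementary analyses: a logistic regression of group on the marker
score with sex and age group entered as categorical covariates (adjusted
odds ratio vs. the unadjusted marker-only fit), and a sex-stratified
Mann-Whitney comparison checking that the direction of the group difference
is consistent in both sexes.

With 16 participants per group and a strong marker, (quasi-)complete
separation is a real possibility; it is detected and handled by a
Firth-type (Jeffreys-prior) penalized fit, and the flag is surfaced rather
than hidden because near-separation inflates Wald intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .univariate import mann_whitney

__all__ = ["AdjustedFit", "logistic_adjust", "stratified_compare"]


@dataclass
class AdjustedFit:
    """Adjusted and unadjusted logistic fits for one marker."""

    terms: pd.DataFrame  # coef, odds_ratio, ci_lo, ci_hi, p per term
    unadjusted: pd.DataFrame  # same columns, marker-only model
    converged: bool
    separation: bool  # True when a Firth-type penalized fallback was used


def _firth_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """Jeffreys-prior penalized logistic regression (Firth's correction).

    Newton iterations on the penalized score U* = X'(y - p + h (1/2 - p))
    with h the hat-matrix diagonal; finite estimates exist even under
    complete separation.
    """
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        XtW = X.T * w
        info = XtW @ X
        cov = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, cov, X) * w
        u_star = X.T @ (y - p + h * (0.5 - p))
        step = cov @ u_star
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    cov = np.linalg.pinv((X.T * (p * (1 - p))) @ X)
    return beta, cov


def _wald_table(beta, cov, names) -> pd.DataFrame:
    se = np.sqrt(np.diag(cov))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    lo, hi = beta - 1.96 * se, beta + 1.96 * se
    return pd.DataFrame(
        {
            "coef": beta,
            "odds_ratio": np.exp(beta),
            "ci_lo": np.exp(lo),
            "ci_hi": np.exp(hi),
            "p": p,
        },
        index=names,
    )


def _design_matrix(scores, sex=None, age_group=None):
    df = pd.DataFrame({"marker": np.asarray(scores, dtype=float)})
    if sex is not None:
        levels = sorted(pd.unique(np.asarray(sex)))
        for lev in levels[1:]:
            df[f"sex[{lev}]"] = (np.asarray(sex) == lev).astype(float)
    if age_group is not None:
        levels = sorted(pd.unique(np.asarray(age_group)))
        for lev in levels[1:]:
            df[f"age[{lev}]"] = (np.asarray(age_group) == lev).astype(float)
    X = sm.add_constant(df, prepend=True, has_constant="add")
    return X.to_numpy(dtype=float), list(X.columns)


def _fit_logistic(X, names, y):
    """ML fit; fall back to the Firth penalized fit on (near-)separation.

    Constant (zero-information) non-intercept columns are dropped from the
    fit and reported with coefficient 0 (odds ratio 1).
    """
    keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
    if len(keep) < X.shape[1]:
        sub_tab, conv, sep = _fit_logistic(X[:, keep], [names[j] for j in keep], y)
        tab = pd.DataFrame(
            {"coef": 0.0, "odds_ratio": 1.0, "ci_lo": np.nan, "ci_hi": np.nan, "p": 1.0},
            index=names,
        )
        tab.loc[sub_tab.index] = sub_tab
        return tab, conv, sep
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # PerfectSeparationWarning -> raise
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
        se = np.asarray(res.bse)
        if not converged or not np.isfinite(se).all() or np.max(np.abs(res.params)) > 25:
            raise RuntimeError("unstable ML fit")
        return _wald_table(np.asarray(res.params), np.asarray(res.cov_params()), names), converged, separation
    except Exception:
        separation = True
        beta, cov = _firth_fit(X, y.astype(float))
        return _wald_table(beta, cov, names), True, separation


def logistic_adjust(scores, labels, sex, age_group) -> AdjustedFit:
    """Logistic regression of group on marker score, sex and age group.

    Returns the covariate-adjusted fit alongside the unadjusted
    (marker-only) fit, so direction retention under adjustment can be read
    off directly. One score per participant; ``labels`` is the binary
    high-stress indicator.
    """
    y = np.asarray(labels).astype(float)
    X, names = _design_matrix(scores, sex, age_group)
    terms, converged, separation = _fit_logistic(X, names, y)
    X0, names0 = _design_matrix(scores)
    unadj, conv0, sep0 = _fit_logistic(X0, names0, y)
    return AdjustedFit(
        terms=terms,
        unadjusted=unadj,
        converged=converged and conv0,
        separation=separation or sep0,
    )


def stratified_compare(scores, labels, sex) -> pd.DataFrame:
    """Per-sex Mann-Whitney comparison with a direction-consistency flag.

    Each sex stratum with both groups present contributes (U, p, direction
    of high-stress minus control medians); strata missing a group are
    skipped with a warning. The ``consistent`` column is True for all rows
    when every tested stratum agrees in sign.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    sx = np.asarray(sex)
    rows = []
    for lev in sorted(pd.unique(sx)):
        m = sx == lev
        if not (y[m].any() and (~y[m]).any()):
            warnings.warn(f"sex stratum {lev!r} lacks one group; skipped", stacklevel=2)
            continue
        u, p = mann_whitney(s[m & y], s[m & ~y])
        rows.append(
            {
                "sex": lev,
                "n": int(m.sum()),
                "U": u,
                "p": p,
                "direction": int(np.sign(np.median(s[m & y]) - np.median(s[m & ~y]))),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        nonzero = out.loc[out["direction"] != 0, "direction"]
        out["consistent"] = bool(len(nonzero)) and nonzero.nunique() == 1
    return out
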