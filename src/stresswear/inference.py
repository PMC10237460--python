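"""Statistical layer: diurnal spline fits, Dunnett-vs-Pre mixed-model
comparisons, and Tukey HSD across run-load groups.

Diurnal RFD profiles are summarized by continuous piecewise-linear
least-squares fits (truncated-power basis) with configured knots; the
per-segment slope beta has units of fractional RFD per hour and a two-sided
p-value for slope != 0.

Post-event deviations are compared against the pre-event bin with a linear
mixed model (random intercept per user) followed by Dunnett's many-to-one
adjustment.  Because the double normalization makes the Pre bin identically
zero, the Pre rows carry no information and would artificially deflate the
residual variance, so the model is fit on the post-event (and During) bins
only and each bin mean is contrasted against zero; the max-|T| adjustment uses
the estimated correlation of the fixed effects through the multivariate-t CDF.
Degrees of freedom use a containment-style residual count (observations minus
bins minus users).

Dose-response is assessed with Tukey's HSD on per-event AUCs, by default
averaged within user per group first to avoid pseudo-replication.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .errors import ConfigurationError, InferenceError
from .impact import POST_LABELS

logger = logging.getLogger(__name__)

#: default spline knots (bin-center hours) for clock-hour diurnal profiles
DEFAULT_KNOTS_HR_CLOCK = (0.5, 4.5, 13.5, 19.5, 23.5)
DEFAULT_KNOTS_HRV_CLOCK = (0.5, 6.5, 11.5, 17.5, 23.5)

BIN_ORDER = ["Pre", "During"] + POST_LABELS


@dataclass(frozen=True)
class SplineFit:
    """Continuous piecewise-linear fit: per-segment slopes and p-values."""

    knots_h: tuple[float, ...]
    segment_slopes_beta: np.ndarray
    segment_se: np.ndarray
    segment_p_values: np.ndarray
    fitted_values: np.ndarray
    residual_df: int


def fit_linear_spline(
    x: Sequence[float], y: Sequence[float], knots: Sequence[float]
) -> SplineFit:
    """Least-squares continuous piecewise-linear fit between given knots.

    ``knots`` include both endpoints; segment ``j`` spans
    ``[knots[j], knots[j+1]]`` and its slope is the sum of the base slope and
    the hinge coefficients active on that segment.  Each slope's p-value is a
    two-sided t-test of the corresponding coefficient combination.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    knots = tuple(float(k) for k in knots)
    if len(knots) < 2 or np.any(np.diff(knots) <= 0):
        raise ConfigurationError("knots must be strictly increasing, >= 2")
    if x.size != y.size or x.size == 0:
        raise ConfigurationError("x and y must be equal-length, non-empty")
    n_seg = len(knots) - 1
    for j in range(n_seg):
        hi_incl = x <= knots[j + 1] if j == n_seg - 1 else x < knots[j + 1]
        if np.sum((x >= knots[j]) & hi_incl) < 2:
            raise InferenceError(
                f"segment {j} [{knots[j]}, {knots[j + 1]}] has < 2 observations"
            )
    cols = [np.ones_like(x), x - knots[0]]
    for k in knots[1:-1]:
        cols.append(np.maximum(x - k, 0.0))
    X = np.column_stack(cols)
    res = sm.OLS(y, X).fit()
    slopes = np.empty(n_seg)
    ses = np.empty(n_seg)
    pvals = np.empty(n_seg)
    for j in range(n_seg):
        contrast = np.zeros(X.shape[1])
        contrast[1 : 2 + j] = 1.0  # base slope + hinges up to segment j
        tt = res.t_test(contrast)
        slopes[j] = float(np.squeeze(tt.effect))
        ses[j] = float(np.squeeze(tt.sd))
        pvals[j] = float(np.squeeze(tt.pvalue))
    return SplineFit(
        knots_h=knots,
        segment_slopes_beta=slopes,
        segment_se=ses,
        segment_p_values=pvals,
        fitted_values=np.asarray(res.fittedvalues),
        residual_df=int(res.df_resid),
    )


def _dunnett_adjust(
    t_stats: np.ndarray, corr: np.ndarray, df: float, random_state: int = 0
) -> np.ndarray:
    """Two-sided max-|T| adjusted p-values under a multivariate t with the
    given correlation: p_k = 1 - P(all |T_j| <= |t_k|)."""
    m = t_stats.size
    if m == 1:
        return 2.0 * stats.t.sf(np.abs(t_stats), df)
    # regularize for numerical PSD-ness
    corr = (corr + corr.T) / 2.0 + 1e-10 * np.eye(m)
    dist = stats.multivariate_t(loc=np.zeros(m), shape=corr, df=df)
    out = np.empty(m)
    for k, t_k in enumerate(np.abs(t_stats)):
        if not np.isfinite(t_k):
            out[k] = np.nan
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            inside = dist.cdf(
                np.full(m, t_k),
                lower_limit=np.full(m, -t_k),
                random_state=np.random.default_rng(random_state),
            )
        out[k] = float(np.clip(1.0 - inside, 0.0, 1.0))
    return out


def dunnett_critical_value(
    m: int,
    df: float,
    alpha: float = 0.05,
    corr: np.ndarray | None = None,
    random_state: int = 0,
) -> float:
    """Two-sided max-|T| critical value for ``m`` many-to-one comparisons:
    the c with P(any |T_j| > c) = alpha under a multivariate t."""
    from scipy.optimize import brentq

    if m == 1:
        return float(stats.t.ppf(1.0 - alpha / 2.0, df))
    corr = np.eye(m) if corr is None else corr
    dist = stats.multivariate_t(loc=np.zeros(m), shape=corr, df=df)

    def excess(c: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            inside = dist.cdf(
                np.full(m, c), lower_limit=np.full(m, -c),
                random_state=np.random.default_rng(random_state),
            )
        return (1.0 - float(inside)) - alpha

    return float(brentq(excess, 1.0, 8.0, xtol=1e-3))


def dunnett_vs_pre(
    binned: pd.DataFrame,
    metric: str = "delta_hr_bpm",
    alpha: float = 0.05,
    random_state: int = 0,
) -> pd.DataFrame:
    """Mixed-model Dunnett comparison of each post-event bin against Pre.

    ``binned`` holds one row per event x bin with columns ``user_id``,
    ``bin_label`` and the metric.  Pre deviations are identically zero by
    construction, so each bin's fixed-effect mean is tested against zero with
    a random intercept per user and max-|T| (Dunnett) correction across bins.
    """
    if metric not in binned.columns:
        raise ConfigurationError(f"metric {metric!r} not in table")
    data = binned.loc[binned["bin_label"] != "Pre"].copy()
    data = data.dropna(subset=[metric])
    if data.empty:
        raise InferenceError("no non-Pre bins to compare")
    labels = [b for b in BIN_ORDER if b in set(data["bin_label"])]
    if data["user_id"].nunique() < 2:
        raise InferenceError("dunnett_vs_pre requires >= 2 users")

    y = data[metric].to_numpy(dtype=float)
    if np.allclose(y, 0.0):
        # degenerate all-zero table: nothing deviates, nothing significant
        return pd.DataFrame({
            "bin_label": labels,
            "estimate": 0.0,
            "se": 0.0,
            "t": 0.0,
            "df": float(len(y) - len(labels)),
            "p_unadjusted": 1.0,
            "p_adjusted": 1.0,
            "significant": False,
        })
    X = pd.get_dummies(data["bin_label"], dtype=float)[labels].to_numpy()
    groups = data["user_id"].to_numpy()
    fit = None
    # Powell handles the zero random-effect-variance boundary (common under
    # the null) that gradient methods stumble on; Nelder-Mead is the fallback
    for method in ("powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, X, groups=groups)
                fit = model.fit(reml=True, method=method)
            break
        except Exception:
            continue
    if fit is None:
        raise InferenceError("mixed model failed to converge")
    k = len(labels)
    est = np.asarray(fit.fe_params, dtype=float)
    cov = np.asarray(fit.cov_params())[:k, :k]
    se = np.sqrt(np.diag(cov))
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise InferenceError("singular mixed-model fit (zero standard error)")
    t_stats = est / se
    n_users = int(pd.unique(groups).size)
    df = max(float(len(y) - k - n_users), 1.0)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    p_unadj = 2.0 * stats.t.sf(np.abs(t_stats), df)
    p_adj = _dunnett_adjust(t_stats, corr, df, random_state=random_state)
    p_adj = np.maximum(p_adj, p_unadj)  # adjustment can never help
    return pd.DataFrame({
        "bin_label": labels,
        "estimate": est,
        "se": se,
        "t": t_stats,
        "df": df,
        "p_unadjusted": p_unadj,
        "p_adjusted": p_adj,
        "significant": p_adj < alpha,
    })


def tukey_auc_groups(
    auc: pd.DataFrame,
    metric: str = "auc_hr_bpm_min",
    average_within_user: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs Tukey HSD of per-event AUC across load groups.

    By default each user contributes one value per group (the mean of their
    events' AUCs) to avoid pseudo-replication; ``average_within_user=False``
    uses raw per-event AUCs.  Groups with fewer than two observations are
    dropped with a warning.
    """
    df = auc.dropna(subset=[metric]).copy()
    if average_within_user:
        df = (
            df.groupby(["load", "user_id"], as_index=False)[metric].mean()
        )
    groups: dict[str, np.ndarray] = {}
    for load, sub in df.groupby("load"):
        vals = sub[metric].to_numpy(dtype=float)
        if vals.size < 2:
            logger.warning("load group %r dropped: < 2 observations", load)
            continue
        groups[load] = vals
    if len(groups) < 2:
        raise InferenceError("tukey_auc_groups requires >= 2 usable groups")
    names = sorted(groups)
    res = stats.tukey_hsd(*(groups[g] for g in names))
    rows = []
    for i, j in combinations(range(len(names)), 2):
        est = float(np.mean(groups[names[i]]) - np.mean(groups[names[j]]))
        p = float(res.pvalue[i, j])
        rows.append({
            "group_a": names[i],
            "group_b": names[j],
            "estimate": est,
            "p_adjusted": p,
            "significant": p < alpha,
        })
    return pd.DataFrame(rows)
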