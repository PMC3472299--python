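"""Moderated-t differential expression with empirical-Bayes shrinkage.

The model is the classical one-way layout on log2 expression: group
means per condition, a pooled residual variance s_g^2 per gene on
d_g = (arrays - conditions) degrees of freedom, and an inverse-chi-square
prior (d0, s0^2) on the gene variances estimated across genes by a
method of moments on ln s_g^2.  The moderated t for a contrast A - B is

    t_g = (mean_A - mean_B) / sqrt(s_tilde^2 (1/n_A + 1/n_B)),
    s_tilde^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g),

tested against Student t on d0 + d_g degrees of freedom (normal in the
d0 -> infinity limit).  Discoveries are controlled by Benjamini-Hochberg
FDR; no fold-change filter is applied.  Linear fold changes follow the
signed convention where a halving is reported as -2, not 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .summarize import ExpressionMatrix

__all__ = [
    "LinearFit",
    "PriorEstimate",
    "D0_INFINITE_CAP",
    "VARIANCE_FLOOR",
    "fit_group_means",
    "estimate_prior",
    "moderated_t",
    "bh_adjust",
    "classify_de",
    "signed_linear_fold_change",
    "run_de",
    "de_summary",
]

#: d0 at or above this cap is treated as an infinite prior (normal reference).
D0_INFINITE_CAP = 1e7
#: Floor applied to zero sample variances before taking logs.
VARIANCE_FLOOR = 1e-8


@dataclass
class LinearFit:
    """Group means, pooled residual variance and residual df per gene."""

    group_means: pd.DataFrame  # genes x conditions
    residual_variance: pd.Series  # s_g^2 per gene
    residual_df: int  # d_g = arrays - conditions
    n_per_condition: dict[str, int]


@dataclass
class PriorEstimate:
    """Hyperparameters of the scaled inverse-chi-square variance prior."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("prior degrees of freedom must be non-negative")
        if not (self.s0_sq > 0):
            raise ValueError("prior variance must be positive")

    @property
    def is_infinite(self) -> bool:
        return self.d0 >= D0_INFINITE_CAP or math.isinf(self.d0)


def fit_group_means(expr: ExpressionMatrix, design: pd.DataFrame) -> LinearFit:
    """One-way fit: per-condition means and pooled residual variance.

    ``design`` needs columns ``array_id`` and ``condition`` covering
    every array of ``expr``.
    """
    design = design.set_index("array_id") if "array_id" in design.columns else design
    missing = [a for a in expr.array_ids if a not in design.index]
    if missing:
        raise ValueError(f"arrays missing from design: {missing}")
    cond_of = design.loc[expr.array_ids, "condition"]
    conditions = list(dict.fromkeys(cond_of))
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    values = expr.values
    means = {}
    rss = np.zeros(len(values))
    n_per = {}
    for cond in conditions:
        arrays = cond_of.index[cond_of == cond]
        block = values[list(arrays)].to_numpy(dtype=float)
        mu = block.mean(axis=1)
        means[cond] = mu
        rss += ((block - mu[:, None]) ** 2).sum(axis=1)
        n_per[cond] = block.shape[1]
    d_g = len(expr.array_ids) - len(conditions)
    if d_g <= 0:
        raise ValueError("no residual degrees of freedom (arrays <= conditions)")
    s_sq = pd.Series(rss / d_g, index=values.index, name="s_sq")
    return LinearFit(
        group_means=pd.DataFrame(means, index=values.index),
        residual_variance=s_sq,
        residual_df=d_g,
        n_per_condition=n_per,
    )


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma(x) = y with a bisection fallback;
    # trigamma is decreasing and convex on (0, inf).
    if y <= 0:
        return math.inf
    x = 0.5 + 1.0 / y  # asymptotic start (trigamma(x) ~ 1/x for large x)
    for _ in range(100):
        f = float(polygamma(1, x)) - y
        fprime = float(polygamma(2, x))
        step = f / fprime
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2
        if abs(x_new - x) < 1e-10 * (1 + abs(x)):
            return x_new
        x = x_new
    lo, hi = 1e-8, 1e9
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if float(polygamma(1, mid)) > y:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def estimate_prior(s_sq: np.ndarray | pd.Series, d: int) -> PriorEstimate:
    """Method-of-moments fit of (d0, s0^2) from gene-wise variances.

    Works on z = ln s^2: under the hierarchical model
    var(z) = trigamma(d/2) + trigamma(d0/2), so d0 solves
    trigamma(d0/2) = var(z) - trigamma(d/2) (infinite when the right
    side is non-positive), and ln s0^2 is mean(z) recentred so the model
    mean of z matches.  Zero variances enter through a small floor.
    """
    s = np.asarray(s_sq, dtype=float)
    s = s[np.isfinite(s)]
    if s.size < 10:
        raise ValueError("need >= 10 genes to estimate the variance prior")
    if np.all(s <= 0):
        raise ValueError("all residual variances are zero; prior is degenerate")
    z = np.log(np.maximum(s, VARIANCE_FLOOR))
    var_z = float(np.var(z, ddof=1))
    rhs = var_z - float(polygamma(1, d / 2))
    if rhs <= 0:
        # no excess dispersion beyond chi-square sampling noise: the
        # variances are exchangeable and the prior mean is their average
        d0 = math.inf
        ln_s0 = math.log(float(np.mean(np.maximum(s, VARIANCE_FLOOR))))
    else:
        d0 = 2.0 * _trigamma_inverse(rhs)
        d0 = min(d0, D0_INFINITE_CAP)
        ln_s0 = (
            float(np.mean(z))
            - float(digamma(d / 2))
            + float(digamma(d0 / 2))
            - math.log(d0 / d)
        )
    return PriorEstimate(d0=d0, s0_sq=float(np.exp(ln_s0)))


def moderated_t(
    fit: LinearFit,
    prior: PriorEstimate,
    contrast: tuple[str, str],
    n_per_group: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Moderated t and two-sided p for the contrast ``A - B``.

    Returns a DataFrame with columns ``log2fc``, ``t_mod``, ``p_value``
    and a boolean ``degenerate`` flag for genes whose posterior variance
    is zero (p undefined there, reported as NaN rather than 0).
    """
    cond_a, cond_b = contrast
    for c in (cond_a, cond_b):
        if c not in fit.group_means.columns:
            raise ValueError(f"condition {c!r} not in fit")
    if n_per_group is None:
        n_a, n_b = fit.n_per_condition[cond_a], fit.n_per_condition[cond_b]
    else:
        n_a, n_b = n_per_group
    delta = fit.group_means[cond_a] - fit.group_means[cond_b]
    s_sq = fit.residual_variance.to_numpy(dtype=float)
    d_g = fit.residual_df
    if prior.is_infinite:
        post_var = np.full_like(s_sq, prior.s0_sq)
        df_total = math.inf
    else:
        post_var = (prior.d0 * prior.s0_sq + d_g * s_sq) / (prior.d0 + d_g)
        df_total = prior.d0 + d_g
    degenerate = post_var <= 0
    se = np.sqrt(np.where(degenerate, np.nan, post_var) * (1.0 / n_a + 1.0 / n_b))
    t_mod = delta.to_numpy(dtype=float) / se
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    return pd.DataFrame(
        {
            "log2fc": delta,
            "t_mod": t_mod,
            "p_value": p,
            "degenerate": degenerate,
        },
        index=fit.group_means.index,
    )


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    if isinstance(p, pd.Series):
        return pd.Series(q, index=p.index)
    return q


def signed_linear_fold_change(log2fc: float | np.ndarray) -> float | np.ndarray:
    """Linear fold change with the minus convention for down-regulation.

    2^log2fc for log2fc >= 0, else -2^(-log2fc): a 4-fold reduction is
    reported as -4, and no change maps to 1.
    """
    arr = np.asarray(log2fc, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError("log2 fold change must be finite")
    out = np.where(arr >= 0, np.exp2(arr), -np.exp2(-arr))
    return float(out) if np.isscalar(log2fc) or arr.ndim == 0 else out


def classify_de(results: pd.DataFrame, q_threshold: float = 0.005) -> pd.DataFrame:
    """Attach q-values, linear fold changes, and up/flat/down calls.

    ``direction`` is sign(log2fc) for genes with q strictly below the
    threshold and 0 otherwise; no minimal fold-change filter is applied.
    Degenerate genes (undefined p) are never called.
    """
    out = results.copy()
    testable = ~out["degenerate"] & np.isfinite(out["p_value"])
    q = np.full(len(out), np.nan)
    q[testable.to_numpy()] = bh_adjust(out.loc[testable, "p_value"].to_numpy())
    out["q_value"] = q
    out["fold_change_linear"] = signed_linear_fold_change(
        out["log2fc"].to_numpy(dtype=float)
    )
    direction = np.zeros(len(out), dtype=int)
    significant = testable.to_numpy() & (q < q_threshold)
    direction[significant] = np.sign(out.loc[significant, "log2fc"]).astype(int)
    out["direction"] = direction
    return out


def run_de(
    expr: ExpressionMatrix,
    design: pd.DataFrame,
    contrasts: list[tuple[str, str]] | None = None,
    q_threshold: float = 0.005,
) -> dict[str, pd.DataFrame]:
    """Full DE analysis: fit, prior, moderated t and calls per contrast.

    Default contrasts compare every non-reference condition against
    ``WT`` in design order.
    """
    fit = fit_group_means(expr, design)
    prior = estimate_prior(fit.residual_variance, fit.residual_df)
    if contrasts is None:
        conditions = list(fit.group_means.columns)
        if "WT" not in conditions:
            raise ValueError("default contrasts need a WT condition")
        contrasts = [(c, "WT") for c in conditions if c != "WT"]
    results = {}
    for cond_a, cond_b in contrasts:
        label = f"{cond_a}-{cond_b}"
        res = moderated_t(fit, prior, (cond_a, cond_b))
        results[label] = classify_de(res, q_threshold=q_threshold)
    return results


def de_summary(results: dict[str, pd.DataFrame]) -> dict[str, dict[str, int]]:
    """Up/down/total counts per contrast."""
    return {
        label: {
            "up": int((df["direction"] == 1).sum()),
            "down": int((df["direction"] == -1).sum()),
            "total": int((df["direction"] != 0).sum()),
        }
        for label, df in results.items()
    }
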