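"""Empirical-Bayes moderated t-statistics with local false discovery rates.

Per-gene residual variances from a two-group comparison are shrunk toward a
prior fitted by moment matching on the log variances (the scaled
inverse-chi-square hierarchy of the moderated-t model): with per-gene
variance s^2 on d degrees of freedom and prior (d0, s0^2),

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)
    t    = log2FC / (s~ * sqrt(1/n1 + 1/n2))

referenced to a t distribution on d + d0 degrees of freedom (the normal
limit when d0 is infinite).  Two-sided p-values are then converted to local
false discovery rates with a two-component mixture: the null proportion pi0
is estimated from the p-value density near 1, the mixture density f by the
Grenander (monotone nonincreasing) estimator, and lfdr = min(1, pi0 / f(p)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

# lfdr thresholds of the emulated study: per-model xenograft contrasts and
# the permissive control-vs-control check
THRESHOLD_PRESETS = {"C4-2B": 1e-5, "VCaP": 3e-5, "control": 0.2}


@dataclass
class VariancePrior:
    """Hyperparameters of the variance hierarchy: prior df d0 (may be inf),
    prior variance s0^2 (log2 units squared), residual df d per gene."""

    d0: float
    s0_sq: float
    d: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if self.s0_sq <= 0:
            raise ValueError("s0_sq must be > 0")


@dataclass
class LocalFdrModel:
    """Two-component p-value mixture: pi0 * U(0,1) + (1 - pi0) * alternative."""

    pi0: float
    # Grenander density: right-open breakpoints and the constant density on
    # each piece; f is nonincreasing and integrates to 1 on [0, 1]
    breaks: np.ndarray
    heights: np.ndarray

    def density(self, p: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(self.breaks, p, side="right") - 1, 0, len(self.heights) - 1)
        return self.heights[idx]

    def lfdr(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=np.float64)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p-values outside [0, 1]")
        f = np.maximum(self.density(p), 1e-300)
        return np.minimum(1.0, self.pi0 / f)


def _trigamma_inverse(x: np.ndarray | float) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Uses the monotone reparametrization of the standard empirical-Bayes
    hyperparameter fit: starting from y = 0.5 + 1/x, iterate
    y <- y + trigamma(y) * (1 - trigamma(y)/x) / tetragamma(y).
    """
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(-dif / y < 1e-10):
            break
    return y


def fit_variance_prior(s_sq: np.ndarray, d: float) -> VariancePrior:
    """Moment-matching fit of (d0, s0^2) from per-gene sample variances.

    Works on z = log(s^2): under the hierarchy, z - digamma(d/2) + log(d/2)
    has mean log(s0^2) + digamma(d0/2) - log(d0/2) and variance
    trigamma(d/2) + trigamma(d0/2).  If the empirical variance of z does not
    exceed trigamma(d/2), the variances are consistent with a single shared
    value and d0 = infinity is returned.
    """
    s_sq = np.asarray(s_sq, dtype=np.float64)
    if d < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    positive = s_sq > 0
    if not positive.any():
        raise ValueError("all variances are zero: degenerate input")
    if positive.sum() < 10:
        raise ValueError("need >= 10 genes with positive variance")
    z = np.log(s_sq[positive])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        # no excess dispersion beyond sampling noise: common variance, whose
        # natural estimate is the plain mean of the sample variances
        return VariancePrior(d0=np.inf, s0_sq=float(np.mean(s_sq[positive])), d=d)
    d0 = float(2.0 * _trigamma_inverse(excess)[0])
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return VariancePrior(d0=d0, s0_sq=s0_sq, d=d)


def moderated_t_test(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str],
    prior: VariancePrior | str = "fit",
) -> pd.DataFrame:
    """Two-group moderated t-test for ``contrast = (group_a, group_b)``.

    log2FC = mean(group_a) - mean(group_b); positive values are up-regulated
    in ``group_a`` (the xenograft, in the study's orientation).  Returns a
    DETable indexed like ``expr`` with means, log2FC, s_sq, s_tilde_sq,
    t_mod, p, and (after :func:`estimate_local_fdr`) lfdr.
    """
    group_a, group_b = contrast
    cols_a = design.index[design["group"] == group_a]
    cols_b = design.index[design["group"] == group_b]
    n1, n2 = len(cols_a), len(cols_b)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both groups need >= 2 samples (got {n1}, {n2})")
    a = expr[cols_a].to_numpy(dtype=np.float64)
    b = expr[cols_b].to_numpy(dtype=np.float64)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    lfc = mean_a - mean_b
    d = float(n1 + n2 - 2)
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s_sq = ss / d

    if prior == "fit":
        prior = fit_variance_prior(s_sq, d)
    elif not isinstance(prior, VariancePrior):
        raise TypeError("prior must be a VariancePrior or 'fit'")

    d0, s0_sq = prior.d0, prior.s0_sq
    if np.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (d0 * s0_sq + d * s_sq) / (d0 + d)
        df_total = d + d0

    se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = lfc / se
    undefined = se == 0  # only possible when d0 = 0 and a gene has zero variance
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p = np.where(undefined, np.nan, p)

    table = pd.DataFrame(
        {
            f"mean_{group_a}": mean_a,
            f"mean_{group_b}": mean_b,
            "log2FC": lfc,
            "s_sq": s_sq,
            "s_tilde_sq": s_tilde_sq,
            "t_mod": np.where(undefined, np.nan, t_mod),
            "p": p,
        },
        index=expr.index,
    )
    table.attrs["prior"] = prior
    table.attrs["contrast"] = (group_a, group_b)
    return table


def _grenander(p_sorted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Grenander estimator of a nonincreasing density on [0, 1].

    The density is the left derivative of the least concave majorant of the
    empirical distribution function (with fixed endpoints (0,0) and (1,1)).
    Returns (breakpoints, piecewise-constant heights).
    """
    n = p_sorted.shape[0]
    x = np.concatenate(([0.0], p_sorted, [1.0]))
    y = np.concatenate(([0.0], np.arange(1, n + 1) / n, [1.0]))
    # collapse duplicate abscissae, keeping the largest ECDF value
    keep_x: list[float] = []
    keep_y: list[float] = []
    for xi, yi in zip(x, y):
        if keep_x and xi == keep_x[-1]:
            keep_y[-1] = max(keep_y[-1], yi)
        else:
            keep_x.append(xi)
            keep_y.append(yi)
    xs = np.array(keep_x)
    ys = np.array(keep_y)
    # least concave majorant via monotone-chain upper hull
    hull: list[int] = []
    for i in range(len(xs)):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            cross = (xs[i2] - xs[i1]) * (ys[i] - ys[i1]) - (ys[i2] - ys[i1]) * (xs[i] - xs[i1])
            if cross >= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    hx = xs[hull]
    hy = ys[hull]
    heights = np.diff(hy) / np.diff(hx)
    return hx[:-1], heights


def estimate_local_fdr(
    p_values: np.ndarray, pi0_window: float = 0.75
) -> tuple[np.ndarray, LocalFdrModel]:
    """Local false discovery rates from two-sided p-values.

    pi0 is the larger of the Storey-type count estimate on
    [pi0_window, 1] and the terminal Grenander slope (the mixture density at
    p = 1); the latter guarantees lfdr(1) = 1.  lfdr is nondecreasing in p
    because the Grenander density is nonincreasing.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if np.any(np.isnan(p)):
        raise ValueError("p-values contain NaN")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]: corrupted input")
    if p.shape[0] < 100:
        raise ValueError("need >= 100 p-values for stable lfdr estimation")
    order = np.argsort(p, kind="stable")
    breaks, heights = _grenander(p[order])
    pi0_count = np.mean(p >= pi0_window) / (1.0 - pi0_window)
    pi0 = float(np.clip(max(pi0_count, heights[-1]), 1e-8, 1.0))
    model = LocalFdrModel(pi0=pi0, breaks=breaks, heights=heights)
    lfdr = model.lfdr(p)
    # isotonic enforcement in p (guards against numerical ties at breakpoints)
    iso = np.maximum.accumulate(lfdr[order])
    out = np.empty_like(lfdr)
    out[order] = iso
    return out, model


def add_lfdr(table: pd.DataFrame) -> pd.DataFrame:
    """Append an lfdr column (and attach the fitted model) to a DETable."""
    ok = ~table["p"].isna()
    lfdr = np.full(len(table), np.nan)
    values, model = estimate_local_fdr(table.loc[ok, "p"].to_numpy())
    lfdr[ok.to_numpy()] = values
    table = table.copy()
    table["lfdr"] = lfdr
    table.attrs["lfdr_model"] = model
    return table


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Tail-area FDR (step-up) for comparison with the local fdr."""
    p = np.asarray(p_values, dtype=np.float64)
    n = p.shape[0]
    order = np.argsort(p)
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def select_de(table: pd.DataFrame, threshold: float | str) -> pd.DataFrame:
    """Genes at lfdr <= threshold, annotated with direction by sign of log2FC.

    ``threshold`` may be a number or a preset name ('C4-2B', 'VCaP',
    'control'; whether the study's printed cutoffs are local-fdr or tail-area
    quantities is not fully determined, so the presets carry that caveat).
    """
    if isinstance(threshold, str):
        threshold = THRESHOLD_PRESETS[threshold]
    if "lfdr" not in table.columns:
        raise ValueError("table has no lfdr column; run add_lfdr first")
    hits = table[table["lfdr"] <= threshold].copy()
    hits["direction"] = np.where(hits["log2FC"] > 0, "up", "down")
    hits.attrs["threshold"] = threshold
    return hits.sort_values("lfdr", kind="stable")
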