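"""Negative-binomial differential expression between consecutive stages.

Counts for gene g in sample j are modeled as NB with mean ``s_j * q_g *
2**(x_j * beta_g)`` and variance ``mu + alpha_g * mu**2``, where ``s_j`` is
the sample's median-of-ratios size factor, ``x_j`` indicates the second stage
of the contrast and ``alpha_g`` is a gene-wise dispersion.  Dispersions are
estimated by method of moments on normalized counts and shrunk toward a
parametric mean-dispersion trend ``a0 + a1/mean`` (empirical-Bayes average in
log space, with genes far above the trend kept at their own estimate).  The
group coefficient is fitted by iteratively reweighted least squares and
tested with a Wald statistic against the standard normal; it is the
dispersion shrinkage that stabilizes the statistic at few replicates (a
heavier-tailed reference on top of shrunk dispersions is markedly
conservative).

Significance filtering follows the pipeline's conventions: BH adjustment
(pooled across all consecutive contrasts by default, controlling the global
FDR), a fold-change floor applied in either direction on the linear scale,
and an abundance floor requiring a mean normalized count of at least
``min_mean_count`` in one of the two groups of the contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .io import Design, PipelineConfig, ValidationError
from .normalization import compute_size_factors

_MIN_DISP, _MAX_DISP = 1e-8, 10.0


def _fit_dispersion_trend(alpha_mom: np.ndarray, base_mean: np.ndarray):
    """Parametric trend a0 + a1/mean fitted to gene-wise moment estimates.

    Iterative least squares with outlier exclusion; falls back to a constant
    (median gene-wise estimate) when too few genes are usable.  Returns a
    callable mean -> trend dispersion.
    """
    use = np.isfinite(alpha_mom) & (alpha_mom > 1e-7) & (base_mean > 1.0)
    if use.sum() < 50:
        level = float(np.median(alpha_mom[use])) if use.any() else 0.01
        level = max(level, _MIN_DISP)
        return lambda m: np.full(np.asarray(m, dtype=float).shape, level)
    a, m = alpha_mom[use], base_mean[use]
    X = np.column_stack([np.ones_like(m), 1.0 / m])
    keep = np.ones(a.size, dtype=bool)
    coef = np.array([np.median(a), 0.0])
    for _ in range(10):
        w = keep / np.maximum(X @ coef, 1e-8) ** 2
        XtW = X.T * w
        coef_new, *_ = np.linalg.lstsq(XtW @ X, XtW @ a, rcond=None)
        coef_new = np.maximum(coef_new, [1e-10, 0.0])
        pred = np.maximum(X @ coef_new, 1e-10)
        keep = (a / pred > 1e-4) & (a / pred < 15.0)
        if np.allclose(coef_new, coef, rtol=1e-6):
            coef = coef_new
            break
        coef = coef_new
    a0, a1 = coef
    return lambda mm: np.maximum(a0 + a1 / np.maximum(np.asarray(mm, dtype=float), 1e-8),
                                 _MIN_DISP)


def estimate_dispersions(
    norm: np.ndarray, group: np.ndarray, size_factors: np.ndarray
) -> np.ndarray:
    """Trend-shrunk gene-wise NB dispersions from normalized counts.

    ``norm`` is genes x samples (already divided by size factors); ``group``
    is the 0/1 stage indicator.
    """
    n = norm.shape[1]
    base_mean = norm.mean(axis=1)
    xim = float(np.mean(1.0 / size_factors))
    ss = np.zeros(norm.shape[0])
    for g in (0, 1):
        sub = norm[:, group == g]
        ss += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
    pooled_var = ss / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (pooled_var - xim * base_mean) / base_mean**2
    valid = np.isfinite(alpha_mom) & (alpha_mom > _MIN_DISP) & (base_mean > 0)
    alpha_clipped = np.clip(alpha_mom, _MIN_DISP, _MAX_DISP)
    trend_fn = _fit_dispersion_trend(np.where(valid, alpha_clipped, np.nan), base_mean)
    trend_all = trend_fn(np.maximum(base_mean, 1e-8))

    out = np.maximum(trend_all, _MIN_DISP).copy()
    if valid.any():
        # the log of a variance-type estimate at df = n - 2 is biased down by
        # digamma(df/2) - log(df/2); uncorrected, log-space shrinkage would
        # systematically understate dispersions and inflate the type-I error
        df_half = (n - 2) / 2.0
        log_bias = float(special.digamma(df_half) - np.log(df_half))
        lr = np.log(alpha_clipped[valid]) - log_bias
        lt = np.log(np.maximum(trend_all[valid], _MIN_DISP))
        # sampling variance of the log dispersion estimate at m samples, 2 coefs
        s_lr2 = float(special.polygamma(1, df_half))
        prior_var = max(float(np.var(lr - lt)) - s_lr2, 0.25)
        l_map = (lr / s_lr2 + lt / prior_var) / (1.0 / s_lr2 + 1.0 / prior_var)
        # dispersion outliers far above the trend keep their own estimate
        outlier = lr > lt + 2.0 * np.sqrt(s_lr2 + prior_var)
        l_map[outlier] = lr[outlier]
        out[valid] = np.exp(l_map)
    return np.clip(out, _MIN_DISP, _MAX_DISP)


def _nb_irls(
    y: np.ndarray,
    group: np.ndarray,
    size_factors: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
):
    """Vectorized IRLS fit of the 2-coefficient NB GLM, all genes at once.

    Returns (b0, b1, se1): natural-log intercept, group coefficient and the
    Wald standard error of the group coefficient.
    """
    offs = np.log(size_factors)[None, :]
    x = group.astype(float)[None, :]
    a = alpha[:, None]
    mean0 = np.maximum((y / size_factors)[:, group == 0].mean(axis=1), 1e-8)
    mean1 = np.maximum((y / size_factors)[:, group == 1].mean(axis=1), 1e-8)
    b0 = np.log(mean0)
    b1 = np.log(mean1) - np.log(mean0)
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x
        mu = np.exp(offs + eta)
        mu = np.clip(mu, 1e-10, 1e12)
        w = mu / (1.0 + a * mu)
        z = eta + (y - mu) / mu
        s0 = w.sum(axis=1)
        s1 = (w * x).sum(axis=1)
        s2 = (w * x * x).sum(axis=1)
        t0 = (w * z).sum(axis=1)
        t1 = (w * x * z).sum(axis=1)
        det = s0 * s2 - s1 * s1
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        nb0 = (s2 * t0 - s1 * t1) / det
        nb1 = (s0 * t1 - s1 * t0) / det
        nb0 = np.clip(nb0, -50.0, 50.0)
        nb1 = np.clip(nb1, -50.0, 50.0)
        delta = max(np.max(np.abs(nb0 - b0)), np.max(np.abs(nb1 - b1)))
        b0, b1 = nb0, nb1
        if delta < tol:
            break
    eta = b0[:, None] + b1[:, None] * x
    mu = np.clip(np.exp(offs + eta), 1e-10, 1e12)
    w = mu / (1.0 + a * mu)
    s0 = w.sum(axis=1)
    s1 = (w * x).sum(axis=1)
    s2 = (w * x * x).sum(axis=1)
    det = np.maximum(s0 * s2 - s1 * s1, 1e-300)
    se1 = np.sqrt(s0 / det)
    return b0, b1, se1


def test_contrast(
    counts: pd.DataFrame,
    design: Design,
    contrast: tuple[str, str],
    cfg: PipelineConfig | None = None,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Wald test of one consecutive-stage contrast (stage_to vs stage_from).

    Size factors default to median-of-ratios on the full matrix, so library
    scaling is shared across contrasts.  Genes with all-zero counts in both
    groups get an undefined p-value and call ``ns``.

    Returns a DataFrame indexed by gene: baseMean, mean_from, mean_to,
    log2FoldChange, pvalue (padj/call are filled by
    :func:`adjust_and_filter`).
    """
    stage_from, stage_to = contrast
    order = {s: i for i, s in enumerate(design.stages)}
    if order.get(stage_to, -99) != order.get(stage_from, 99) + 1:
        raise ValidationError(
            f"contrast ({stage_from}, {stage_to}) is not a consecutive stage pair"
        )
    ids_a, ids_b = design.samples_of(stage_from), design.samples_of(stage_to)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValidationError("each group of a contrast needs >= 2 replicates")
    if size_factors is None:
        size_factors = compute_size_factors(counts)
    sub = counts[ids_a + ids_b]
    s = size_factors.reindex(sub.columns).to_numpy(dtype=float)
    y = sub.to_numpy(dtype=float)
    group = np.array([0] * len(ids_a) + [1] * len(ids_b))
    norm = y / s

    nonzero = y.sum(axis=1) > 0
    base_mean = norm.mean(axis=1)
    res = pd.DataFrame(
        {
            "baseMean": base_mean,
            "mean_from": norm[:, group == 0].mean(axis=1),
            "mean_to": norm[:, group == 1].mean(axis=1),
            "log2FoldChange": np.nan,
            "pvalue": np.nan,
        },
        index=sub.index,
    )
    if nonzero.any():
        alpha = estimate_dispersions(norm[nonzero], group, s)
        _, b1, se1 = _nb_irls(y[nonzero], group, s, alpha)
        wald = b1 / se1
        pvals = 2.0 * stats.norm.sf(np.abs(wald))
        res.loc[nonzero, "log2FoldChange"] = b1 / np.log(2.0)
        res.loc[nonzero, "pvalue"] = pvals
    res.index.name = "gene"
    return res


def adjust_and_filter(
    results: dict[str, pd.DataFrame], cfg: PipelineConfig
) -> dict[str, pd.DataFrame]:
    """BH-adjust p-values and apply the abundance and fold-change filters.

    With ``fdr_scope="global"`` (default) BH runs once on the pooled raw
    p-values of every contrast, controlling the FDR across all comparisons;
    ``"per-contrast"`` adjusts each table separately.  A gene is called
    ``up``/``down`` when adjusted p < de_alpha, |fold change| >=
    min_fold_change and its mean normalized count reaches min_mean_count in
    at least one of the contrast's two groups; otherwise ``ns``.
    """
    if cfg.fdr_scope not in ("global", "per-contrast"):
        raise ValidationError(f"unknown fdr_scope {cfg.fdr_scope!r}")
    results = {name: df.copy() for name, df in results.items()}
    if cfg.fdr_scope == "global":
        pooled = np.concatenate(
            [df["pvalue"].to_numpy(dtype=float) for df in results.values()]
        )
        mask = np.isfinite(pooled)
        adj = np.full(pooled.size, np.nan)
        if mask.any():
            adj[mask] = stats.false_discovery_control(pooled[mask], method="bh")
        start = 0
        for df in results.values():
            df["padj"] = adj[start : start + len(df)]
            start += len(df)
    else:
        for df in results.values():
            p = df["pvalue"].to_numpy(dtype=float)
            mask = np.isfinite(p)
            adj = np.full(p.size, np.nan)
            if mask.any():
                adj[mask] = stats.false_discovery_control(p[mask], method="bh")
            df["padj"] = adj

    min_lfc = np.log2(cfg.min_fold_change)
    for df in results.values():
        df["passes_abundance"] = (df["mean_from"] >= cfg.min_mean_count) | (
            df["mean_to"] >= cfg.min_mean_count
        )
        sig = (df["padj"] < cfg.de_alpha) & df["passes_abundance"]
        call = np.where(
            sig & (df["log2FoldChange"] >= min_lfc),
            "up",
            np.where(sig & (df["log2FoldChange"] <= -min_lfc), "down", "ns"),
        )
        df["call"] = call
    return results


def de_summary(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Up/down/total counts per contrast plus the union across contrasts."""
    rows = []
    union: set = set()
    for name, df in results.items():
        up = int((df["call"] == "up").sum())
        down = int((df["call"] == "down").sum())
        union |= set(df.index[df["call"] != "ns"])
        rows.append({"contrast": name, "up": up, "down": down, "total": up + down})
    rows.append(
        {"contrast": "union", "up": np.nan, "down": np.nan, "total": len(union)}
    )
    return pd.DataFrame(rows)


class NegativeBinomialDE(BaseEstimator):
    """Consecutive-stage differential expression over a whole design.

    Runs the NB Wald test for every adjacent stage pair, then BH adjustment
    and the abundance/fold-change filters.

    Parameters mirror :class:`~stepcourse.io.PipelineConfig` (de_alpha,
    min_fold_change, min_mean_count, fdr_scope).

    Attributes
    ----------
    results_ : dict[str, pd.DataFrame]
        One filtered table per contrast, keyed ``"<from>__vs__<to>"``.
    summary_ : pd.DataFrame
        Up/down counts per contrast and the union of DE genes.
    de_genes_ : set[str]
        Union of genes called in at least one contrast.
    size_factors_ : pd.Series
    """

    def __init__(self, de_alpha: float = 0.05, min_fold_change: float = 2.0,
                 min_mean_count: float = 64.0, fdr_scope: str = "global"):
        self.de_alpha = de_alpha
        self.min_fold_change = min_fold_change
        self.min_mean_count = min_mean_count
        self.fdr_scope = fdr_scope

    def fit(self, X: pd.DataFrame, y: Design = None) -> "NegativeBinomialDE":
        if y is None:
            raise ValidationError("a Design must be passed as y")
        cfg = PipelineConfig(
            de_alpha=self.de_alpha,
            min_fold_change=self.min_fold_change,
            min_mean_count=self.min_mean_count,
            fdr_scope=self.fdr_scope,
            stage_order=y.stage_order,
        )
        self.size_factors_ = compute_size_factors(X)
        raw = {
            f"{a}__vs__{b}": test_contrast(X, y, (a, b), cfg, self.size_factors_)
            for a, b in y.consecutive_contrasts()
        }
        self.results_ = adjust_and_filter(raw, cfg)
        self.summary_ = de_summary(self.results_)
        self.de_genes_ = set().union(
            *(set(df.index[df["call"] != "ns"]) for df in self.results_.values())
        )
        return self
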