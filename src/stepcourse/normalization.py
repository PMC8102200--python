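"""Library-size correction by the median-of-ratios method.

Sequencing depth differs between libraries, so raw counts are not comparable
across samples.  The median-of-ratios estimator computes, per sample, the
median over reference genes of the ratio between that sample's count and the
gene's geometric mean across samples; dividing each column by its factor puts
all samples on a common scale.  The reference set is the genes with strictly
positive counts in every sample, the standard definition.

Log expression is always log2(normalized + 1): the pseudocount guards zeros
and is negligible at the abundances the downstream thresholds operate on
(a normalized count of 63 maps to exactly 6 on the log2 scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import Design, ValidationError


def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one positive scalar per sample.

    Parameters
    ----------
    counts
        Genes x samples matrix of non-negative counts.

    Returns
    -------
    Per-sample factors, unnormalized (exactly the ratio medians).

    Raises
    ------
    ValidationError
        If no gene has positive counts in all samples (empty reference set);
        a pseudo-reference fallback is deliberately not provided.
    """
    x = counts.to_numpy(dtype=float)
    ref = (x > 0).all(axis=1)
    if not ref.any():
        raise ValidationError(
            "no gene has positive counts in every sample; the median-of-ratios "
            "reference set is empty and a pseudo-reference fallback is disabled"
        )
    logx = np.log(x[ref])
    log_geo_mean = logx.mean(axis=1, keepdims=True)
    # midpoint convention for even-length medians (numpy default): deterministic
    log_factors = np.median(logx - log_geo_mean, axis=0)
    return pd.Series(np.exp(log_factors), index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    if set(size_factors.index) != set(counts.columns):
        raise ValidationError("size factors do not match the matrix samples")
    if (size_factors <= 0).any():
        raise ValidationError("size factors must be positive")
    return counts / size_factors.reindex(counts.columns)


class MedianOfRatiosNormalizer(BaseEstimator, TransformerMixin):
    """Transformer wrapping median-of-ratios library-size correction.

    Operates on genes x samples DataFrames (the field's orientation for bulk
    count matrices).  ``fit`` estimates one factor per sample of the fitted
    matrix; ``transform`` rescales a matrix with those same samples.

    Attributes
    ----------
    size_factors_ : pd.Series
        Estimated per-sample factors.
    n_reference_genes_ : int
        Size of the all-positive reference gene set.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "MedianOfRatiosNormalizer":
        self.size_factors_ = compute_size_factors(X)
        self.n_reference_genes_ = int((X.to_numpy() > 0).all(axis=1).sum())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return normalize(X, self.size_factors_)


@dataclass(frozen=True)
class StageProfile:
    """Stage-level expression summaries of a normalized matrix.

    Attributes
    ----------
    stage_means
        Genes x stages matrix of mean normalized counts (arithmetic mean over
        the replicates of each stage).
    log_expr
        Genes x samples matrix of log2(normalized + 1).
    design
        The design the profile was computed under.
    """

    stage_means: pd.DataFrame
    log_expr: pd.DataFrame
    design: Design

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(self.stage_means.columns)


def stage_profile(normalized: pd.DataFrame, design: Design) -> StageProfile:
    """Per-stage mean normalized expression and per-sample log2 values."""
    missing = set(design.sample_ids) - set(normalized.columns)
    if missing:
        raise ValidationError(f"design samples absent from matrix: {sorted(missing)}")
    means = {}
    for stage in design.stages:
        ids = design.samples_of(stage)
        if not ids:
            raise ValidationError(f"stage {stage!r} has no samples")
        means[stage] = normalized[ids].mean(axis=1)
    stage_means = pd.DataFrame(means, index=normalized.index)[list(design.stages)]
    log_expr = np.log2(normalized[design.sample_ids] + 1.0)
    return StageProfile(stage_means=stage_means, log_expr=log_expr, design=design)
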