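"""Piecewise-constant step-model fitting over ordered differentiation stages.

Each gene's trajectory across S ordered stages (with replicate log2 values at
every stage) is fitted by every piecewise-constant model with 0, 1 or 2
transition points: a breakpoint b means the expression level changes between
stage b and stage b+1 (stages indexed 1..S).  Levels are least-squares fits,
i.e. the mean of all replicate values in a segment.  The enumeration is
exhaustive: 1 flat model, S-1 one-step models and C(S-1, 2) two-step models.

Model selection uses BIC by default (``n*ln(sse/n) + p*ln(n)`` with
``p = (k+1)+1`` for the k+1 segment means plus a noise variance), or nested
F-tests at level 0.01; in both modes a selected transition whose level change
is smaller than ``step_min_delta`` log2 units demotes the gene to the best
model of smaller k, applied recursively.  Ties break toward smaller k, then
toward earlier breakpoints.

The selected model maps onto four temporal pattern labels: one-step-up /
one-step-down (single transition low-to-high or high-to-low between two
consecutive stages) and two-step-up-down / two-step-down-up (impulse up or
down).  A two-step fit whose level changes share a sign is not an impulse;
it collapses to the one-step label at its major transition (largest |delta|).
The transition stage is the first stage of the new regime — for a four-stage
course MBC, prePB, PB, PC, a one-step-up at breakpoint 1 reads "up-at-prePB":
low at MBC, high from prePB through PC.

Fitting operates on per-replicate values, not stage means, so within-stage
replicate variance informs selection.  The module is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import Design, PipelineConfig, ValidationError, logger
from .normalization import StageProfile

LABEL_FLAT = "flat"
LABEL_UP = "one-step-up"
LABEL_DOWN = "one-step-down"
LABEL_UP_DOWN = "two-step-up-down"
LABEL_DOWN_UP = "two-step-down-up"
ALL_LABELS = (LABEL_FLAT, LABEL_UP, LABEL_DOWN, LABEL_UP_DOWN, LABEL_DOWN_UP)

_F_ALPHA = 0.01  # nested F-test level


@dataclass(frozen=True)
class StepModel:
    """One fitted piecewise-constant candidate.

    breakpoints are 1-based: breakpoint b separates stage b from stage b+1.
    ``levels`` are the k+1 segment means on the log2 scale; ``sse`` is over
    all S x R points; ``score`` is filled by the selection criterion.
    """

    k: int
    breakpoints: tuple[int, ...]
    levels: tuple[float, ...]
    sse: float
    n_points: int
    score: float = np.nan

    @property
    def deltas(self) -> tuple[float, ...]:
        return tuple(
            self.levels[i + 1] - self.levels[i] for i in range(len(self.levels) - 1)
        )


@dataclass(frozen=True)
class PatternLabel:
    label: str
    transition_stage: str | None


def _segments(n_stages: int, breakpoints: tuple[int, ...]):
    """Stage-index slices (0-based, half-open) delimited by 1-based breakpoints."""
    edges = (0, *breakpoints, n_stages)
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def enumerate_fits(
    values_per_stage: Sequence[np.ndarray], max_k: int = 2
) -> list[StepModel]:
    """Least-squares fit of every candidate step model for one gene.

    Parameters
    ----------
    values_per_stage
        One array of replicate log2 values per stage, in stage order; every
        stage needs at least one value.
    max_k
        Transition cap; effective cap is ``min(max_k, S-1)``.
    """
    S = len(values_per_stage)
    if S < 2:
        raise ValidationError("need at least 2 stages to fit step models")
    arrs = [np.asarray(v, dtype=float) for v in values_per_stage]
    if any(a.size == 0 for a in arrs):
        raise ValidationError("every stage needs at least one replicate value")
    n = sum(a.size for a in arrs)
    sums = np.array([a.sum() for a in arrs])
    sqs = np.array([np.square(a).sum() for a in arrs])
    sizes = np.array([a.size for a in arrs])

    models = []
    for k in range(min(max_k, S - 1) + 1):
        for bps in combinations(range(1, S), k):
            levels, sse = [], 0.0
            for lo, hi in _segments(S, bps):
                cnt = sizes[lo:hi].sum()
                mean = sums[lo:hi].sum() / cnt
                levels.append(mean)
                sse += sqs[lo:hi].sum() - cnt * mean * mean
            models.append(
                StepModel(
                    k=k,
                    breakpoints=bps,
                    levels=tuple(levels),
                    sse=max(float(sse), 0.0),
                    n_points=int(n),
                )
            )
    return models


def _bic(sse: float, n: int, k: int) -> float:
    p = (k + 1) + 1
    return n * np.log(max(sse, 1e-300) / n) + p * np.log(n)


def _best_per_k(candidates: Sequence[StepModel]) -> dict[int, StepModel]:
    """Lowest-sse candidate for each k (ties toward earlier breakpoints)."""
    best: dict[int, StepModel] = {}
    for m in candidates:  # enumeration order already sorts breakpoints ascending
        cur = best.get(m.k)
        if cur is None or m.sse < cur.sse - 1e-12:
            best[m.k] = m
    return best


def _passes_delta(model: StepModel, min_delta: float) -> bool:
    return all(abs(d) >= min_delta for d in model.deltas)


def select_model(
    candidates: Sequence[StepModel],
    criterion: str = "bic",
    step_min_delta: float = 1.0,
    f_alpha: float = _F_ALPHA,
) -> StepModel:
    """Pick one model: criterion first, then magnitude demotion.

    BIC mode scores every candidate and takes the minimum (ties toward
    smaller k, then earlier breakpoints).  F-test mode grows k through nested
    F-tests on the per-k best fits, accepting an added transition only when
    significant at ``f_alpha``.  In both modes a surviving transition with
    |delta| < ``step_min_delta`` demotes to the best smaller-k model,
    recursively; the k=0 model is always admissible.
    """
    if criterion not in ("bic", "ftest"):
        raise ValidationError(f"unknown selection criterion {criterion!r}")
    n = candidates[0].n_points
    by_k = _best_per_k(candidates)
    ks = sorted(by_k)

    if criterion == "bic":
        scored = sorted(
            (StepModel(m.k, m.breakpoints, m.levels, m.sse, m.n_points,
                       score=_bic(m.sse, n, m.k)) for m in candidates),
            key=lambda m: (m.score, m.k, m.breakpoints),
        )
        chosen = scored[0]
    else:
        chosen = by_k[0]
        for k in ks[1:]:
            smaller, larger = chosen, by_k[k]
            df1 = larger.k - smaller.k
            df2 = n - (larger.k + 1)
            if df2 <= 0:
                break
            if larger.sse <= 1e-12:
                significant = smaller.sse > 1e-12
            else:
                f = ((smaller.sse - larger.sse) / df1) / (larger.sse / df2)
                significant = stats.f.sf(f, df1, df2) < f_alpha
            if not significant:
                break
            chosen = larger
        chosen = StepModel(chosen.k, chosen.breakpoints, chosen.levels, chosen.sse,
                           chosen.n_points, score=_bic(chosen.sse, n, chosen.k))

    while chosen.k > 0 and not _passes_delta(chosen, step_min_delta):
        m = by_k[chosen.k - 1]
        chosen = StepModel(m.k, m.breakpoints, m.levels, m.sse, m.n_points,
                           score=_bic(m.sse, n, m.k))
    return chosen


def classify_pattern(fit: StepModel, stage_order: Sequence[str]) -> PatternLabel:
    """Map a selected model to one of the four temporal labels (or flat).

    The transition stage names the first stage of the new regime.  Same-sign
    two-step fits collapse to the one-step label at the major transition
    (largest |delta|; ties toward the earlier breakpoint).
    """
    stage_order = list(stage_order)
    if fit.k == 0:
        return PatternLabel(LABEL_FLAT, None)
    d = fit.deltas
    if fit.k == 1:
        label = LABEL_UP if d[0] > 0 else LABEL_DOWN
        return PatternLabel(label, stage_order[fit.breakpoints[0]])
    if d[0] > 0 and d[1] < 0:
        return PatternLabel(LABEL_UP_DOWN, stage_order[fit.breakpoints[0]])
    if d[0] < 0 and d[1] > 0:
        return PatternLabel(LABEL_DOWN_UP, stage_order[fit.breakpoints[0]])
    # same-sign deltas: not an impulse; report the major transition only
    major = 0 if abs(d[0]) >= abs(d[1]) else 1
    label = LABEL_UP if d[major] > 0 else LABEL_DOWN
    return PatternLabel(label, stage_order[fit.breakpoints[major]])


def profile_genes(
    profile: StageProfile,
    gene_subset: Sequence[str] | None = None,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Fit, select and label the step model of every gene in the subset.

    ``gene_subset`` defaults to every gene in the profile; the pipeline's
    run-all command passes the intersection of active and differentially
    expressed genes.  Flat-labelled genes stay in the table, flagged by their
    label.  Breakpoints, levels and deltas are ';'-joined in the output.
    """
    cfg = cfg or PipelineConfig()
    genes = list(profile.stage_means.index if gene_subset is None else gene_subset)
    if not genes:
        logger.warning("empty gene subset: returning empty step-fit table")
    missing = set(genes) - set(profile.stage_means.index)
    if missing:
        raise ValidationError(f"genes absent from profile: {sorted(missing)[:10]}")

    stages = profile.stages
    cols_by_stage = [profile.design.samples_of(s) for s in stages]
    log_expr = profile.log_expr
    stage_mats = [log_expr[ids].to_numpy(dtype=float) for ids in cols_by_stage]
    pos = pd.Series(np.arange(len(log_expr.index)), index=log_expr.index)
    rows = []
    for gene in genes:
        i = pos[gene]
        per_stage = [mat[i] for mat in stage_mats]
        fit = select_model(
            enumerate_fits(per_stage),
            criterion=cfg.selection_criterion,
            step_min_delta=cfg.step_min_delta,
        )
        pat = classify_pattern(fit, stages)
        rows.append(
            {
                "gene": gene,
                "k": fit.k,
                "breakpoints": ";".join(map(str, fit.breakpoints)),
                "levels": ";".join(f"{v:.6g}" for v in fit.levels),
                "deltas": ";".join(f"{v:.6g}" for v in fit.deltas),
                "sse": fit.sse,
                "score": fit.score,
                "label": pat.label,
                "transition_stage": pat.transition_stage or "",
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["gene", "k", "breakpoints", "levels", "deltas", "sse", "score",
                 "label", "transition_stage"],
    )
    if len(out):
        n_flat = int((out["label"] == LABEL_FLAT).sum())
        logger.info(
            "step profiling: %d genes, %d with transitions, %d flat",
            len(out), len(out) - n_flat, n_flat,
        )
    return out


def pattern_summary(fits: pd.DataFrame) -> pd.DataFrame:
    """Gene counts per (label, transition stage) group."""
    if fits.empty:
        return pd.DataFrame(columns=["label", "transition_stage", "n_genes"])
    out = (
        fits.groupby(["label", "transition_stage"], dropna=False)
        .size()
        .reset_index(name="n_genes")
    )
    return out.sort_values(["label", "transition_stage"]).reset_index(drop=True)


class StepPatternProfiler(BaseEstimator):
    """Estimator interface over step-model fitting and labelling.

    Parameters
    ----------
    criterion : {"bic", "ftest"}
        Model-selection rule.
    step_min_delta : float
        Magnitude floor (log2 units) below which transitions are demoted.

    Attributes
    ----------
    fits_ : pd.DataFrame
        One row per profiled gene (k, breakpoints, levels, deltas, sse,
        score, label, transition stage).
    summary_ : pd.DataFrame
        Counts per (label, transition stage).
    """

    def __init__(self, criterion: str = "bic", step_min_delta: float = 1.0):
        self.criterion = criterion
        self.step_min_delta = step_min_delta

    def fit(self, X: StageProfile, y: Sequence[str] | None = None) -> "StepPatternProfiler":
        cfg = PipelineConfig(
            selection_criterion=self.criterion, step_min_delta=self.step_min_delta,
            stage_order=X.design.stage_order,
        )
        self.fits_ = profile_genes(X, gene_subset=y, cfg=cfg)
        self.summary_ = pattern_summary(self.fits_)
        return self

    def fit_predict(self, X: StageProfile, y: Sequence[str] | None = None) -> pd.Series:
        """Pattern label per gene."""
        self.fit(X, y)
        return self.fits_.set_index("gene")["label"]
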