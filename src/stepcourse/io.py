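"""Readers, writers and shared configuration for the staged-expression pipeline.

All tabular formats are plain TSV.  Gene identifiers are opaque strings; no
symbol/ID mapping is attempted.  Gene-set collections use the standard GMT
layout (name, description, then member symbols, tab-separated) and regulator
catalogs are one symbol per line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

logger = logging.getLogger("stepcourse")

#: Default stage order of the plasma-cell differentiation model system:
#: memory B cell -> preplasmablast -> plasmablast -> plasma cell.
DEFAULT_STAGE_ORDER = ("MBC", "prePB", "PB", "PC")

#: Fixed float format for all written tables (6 significant digits).
FLOAT_FORMAT = "%.6g"


class ParseError(ValueError):
    """A file's contents violate the expected format."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a semantic contract."""


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Design:
    """Sample sheet mapping samples to ordered differentiation stages.

    Parameters
    ----------
    samples
        DataFrame with columns ``sample_id``, ``stage``, ``replicate``.
    stage_order
        Declared total order of stages; never inferred from names.
    """

    samples: pd.DataFrame
    stage_order: tuple[str, ...]

    def __post_init__(self) -> None:
        required = {"sample_id", "stage", "replicate"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValidationError(f"design is missing columns: {sorted(missing)}")
        if self.samples["sample_id"].duplicated().any():
            dups = self.samples.loc[self.samples["sample_id"].duplicated(), "sample_id"]
            raise ValidationError(f"duplicated sample ids: {sorted(set(dups))}")
        unknown = set(self.samples["stage"]) - set(self.stage_order)
        if unknown:
            raise ValidationError(
                f"stages {sorted(unknown)} not in declared stage order {list(self.stage_order)}"
            )
        present = [s for s in self.stage_order if s in set(self.samples["stage"])]
        if len(present) < 2:
            raise ValidationError(
                f"need at least 2 stages for a differentiation course, got {present}"
            )
        counts = self.samples["stage"].value_counts()
        thin = sorted(s for s in present if counts[s] < 2)
        if thin:
            raise ValidationError(
                f"every stage needs >= 2 samples for variance estimation; "
                f"stages with fewer: {thin}"
            )
        if (self.samples["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate indices must be >= 1")
        object.__setattr__(self, "stage_order", tuple(self.stage_order))

    @property
    def stages(self) -> tuple[str, ...]:
        """Stages actually present, in declared order."""
        present = set(self.samples["stage"])
        return tuple(s for s in self.stage_order if s in present)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def samples_of(self, stage: str) -> list[str]:
        """Sample ids belonging to one stage, in sheet order."""
        sel = self.samples["stage"] == stage
        return list(self.samples.loc[sel, "sample_id"])

    def consecutive_contrasts(self) -> list[tuple[str, str]]:
        """(from, to) pairs of adjacent stages in declared order."""
        st = self.stages
        return [(st[i], st[i + 1]) for i in range(len(st) - 1)]


def read_design(
    path: str | Path, stage_order: Sequence[str] = DEFAULT_STAGE_ORDER
) -> Design:
    """Read a sample sheet TSV (columns sample_id, stage, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "stage": str})
    return Design(samples=df, stage_order=tuple(stage_order))


def write_design(design: Design, path: str | Path) -> None:
    design.samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a genes x samples count matrix: unique genes, non-negative integers."""
    if counts.index.duplicated().any():
        dups = sorted(set(counts.index[counts.index.duplicated()]))
        raise ValidationError(f"duplicated gene ids: {dups[:10]}")
    for col in counts.columns:
        vals = counts[col]
        if not pd.api.types.is_numeric_dtype(vals):
            bad = vals[pd.to_numeric(vals, errors="coerce").isna()]
            raise ParseError(
                f"non-numeric count in column {col!r}, row {bad.index[0]!r}: {bad.iloc[0]!r}"
            )
        if (vals < 0).any():
            row = vals.index[(vals < 0).to_numpy().nonzero()[0][0]]
            raise ParseError(f"negative count in column {col!r}, row {row!r}")
        if not (vals == vals.astype(int)).all():
            row = vals.index[(vals != vals.astype(int)).to_numpy().nonzero()[0][0]]
            raise ParseError(f"non-integer count in column {col!r}, row {row!r}")
    return counts.astype(int)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a raw count TSV (first column gene ids, header row of sample ids).

    Returns a genes x samples DataFrame of non-negative integers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return validate_counts(df)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    out = counts.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table with the pipeline's fixed float format."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Gene sets and regulator lists
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection into {name: member set}.

    Empty sets are dropped with a warning; memberships are deduplicated.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "GMT needs name, description and at least one member"
                )
            name = fields[0]
            members = {m for m in fields[2:] if m}
            if not members:
                logger.warning("gene set %r is empty; dropped", name)
                continue
            sets[name] = members
    return sets


def write_gene_sets(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text gene list, one symbol per line, upper-cased."""
    with open(path) as fh:
        return {line.strip().upper() for line in fh if line.strip()}


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Tunable thresholds shared across the pipeline stages.

    Attributes
    ----------
    active_threshold
        Normalized-count cutoff for active expression, or ``"auto"`` to derive
        it from the bimodal distribution of stage-mean log expression.
    de_alpha
        Adjusted-p significance level for differential expression.
    min_fold_change
        Linear-scale fold-change threshold (applied in either direction).
    min_mean_count
        Abundance filter: mean normalized count required in at least one of
        the two groups of a contrast (64 = 2**6).
    step_min_delta
        Minimum |level change| in log2 units for a step transition to stand.
    selection_criterion
        Step-model selection rule: ``"bic"`` or ``"ftest"``.
    fdr_scope
        ``"global"`` pools raw p-values of all contrasts before BH;
        ``"per-contrast"`` adjusts each contrast separately.
    seed
        Seed for every stochastic component (mixture restarts, simulation).
    """

    active_threshold: float | str = "auto"
    de_alpha: float = 0.05
    min_fold_change: float = 2.0
    min_mean_count: float = 64.0
    step_min_delta: float = 1.0
    selection_criterion: str = "bic"
    fdr_scope: str = "global"
    seed: int = 0
    stage_order: tuple[str, ...] = field(default_factory=lambda: DEFAULT_STAGE_ORDER)

    def __post_init__(self) -> None:
        if not (0.0 < self.de_alpha < 1.0):
            raise ValidationError(f"de_alpha must be in (0,1), got {self.de_alpha}")
        if self.min_fold_change <= 1.0:
            raise ValidationError(
                f"min_fold_change must be > 1, got {self.min_fold_change}"
            )
        if self.min_mean_count < 0 or self.step_min_delta < 0:
            raise ValidationError("thresholds must be non-negative")
        if self.selection_criterion not in ("bic", "ftest"):
            raise ValidationError(
                f"unknown selection_criterion {self.selection_criterion!r}"
            )
        if self.fdr_scope not in ("global", "per-contrast"):
            raise ValidationError(f"unknown fdr_scope {self.fdr_scope!r}")
        if self.active_threshold != "auto":
            if float(self.active_threshold) <= 0:
                raise ValidationError("fixed active_threshold must be > 0")
            self.active_threshold = float(self.active_threshold)
        self.stage_order = tuple(self.stage_order)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat key-value (YAML) config file, with flag overrides."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParseError(f"{path}: expected flat key-value mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "stage_order" in data and isinstance(data["stage_order"], str):
            data["stage_order"] = tuple(data["stage_order"].split(","))
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
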