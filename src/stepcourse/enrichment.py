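"""Regulator-repertoire annotation and gene-set over-representation.

Temporal pattern groups become interpretable once cross-referenced with
curated catalogs of transcription factors (TFs) and epigenetic enzymes (EEs)
and tested for over-representation of functional gene sets.  The ORA test is
the upper-tail hypergeometric: with a universe of N genes of which K belong
to a set, the probability of observing at least the realized overlap in a
query of size n.  The default universe is the actively expressed gene set,
so enrichment is judged against the expressed transcriptome rather than the
whole annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError


@dataclass(frozen=True)
class RegulatorCatalog:
    """Transcription-factor and epigenetic-enzyme symbol sets (upper-cased)."""

    tf_symbols: frozenset[str]
    ee_symbols: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "tf_symbols", frozenset(s.upper() for s in self.tf_symbols))
        object.__setattr__(self, "ee_symbols", frozenset(s.upper() for s in self.ee_symbols))
        if not self.tf_symbols and not self.ee_symbols:
            raise ValidationError("regulator catalog is empty")


def annotate_regulators(
    fits: pd.DataFrame, catalog: RegulatorCatalog
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag step-profiled genes found in the TF/EE catalogs.

    Returns the fits table with ``is_tf``/``is_ee`` columns plus per
    (label, transition_stage) counts of TF-or-EE genes — a gene in both
    catalogs counts once.
    """
    out = fits.copy()
    symbols = out["gene"].astype(str).str.upper()
    out["is_tf"] = symbols.isin(catalog.tf_symbols)
    out["is_ee"] = symbols.isin(catalog.ee_symbols)
    reg = out[out["is_tf"] | out["is_ee"]]
    if reg.empty:
        counts = pd.DataFrame(columns=["label", "transition_stage", "n_regulators"])
    else:
        counts = (
            reg.groupby(["label", "transition_stage"], dropna=False)
            .size()
            .reset_index(name="n_regulators")
            .sort_values(["label", "transition_stage"])
            .reset_index(drop=True)
        )
    return out, counts


def ora(
    query: set[str],
    universe: set[str],
    gene_sets: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in a query.

    Every set is intersected with the universe before testing; sets with
    zero overlap are reported (p is the survival probability at zero), never
    dropped.  BH adjustment runs across all tested sets.

    Returns a table sorted by adjusted p: set name, overlap, set size within
    the universe, query size, universe size, p, padj, significance flag and
    the overlapping symbols.
    """
    query, universe = set(query), set(universe)
    if not query <= universe:
        stray = sorted(query - universe)
        raise ValidationError(f"query genes outside the universe: {stray[:10]}")
    N, n = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        in_universe = members & universe
        K = len(in_universe)
        overlap = sorted(in_universe & query)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "gene_set": name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "pvalue": min(p, 1.0),
                "overlap_genes": ";".join(overlap),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_set", "overlap", "set_size", "query_size", "universe_size",
                 "pvalue", "overlap_genes"],
    )
    if len(out):
        out["padj"] = stats.false_discovery_control(out["pvalue"].to_numpy(), method="bh")
        out["significant"] = out["padj"] < alpha
        out = out.sort_values(["padj", "pvalue", "gene_set"]).reset_index(drop=True)
    else:
        out["padj"] = np.nan
        out["significant"] = pd.Series(dtype=bool)
    return out[["gene_set", "overlap", "set_size", "query_size", "universe_size",
                "pvalue", "padj", "significant", "overlap_genes"]]
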