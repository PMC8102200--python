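import numpy as np
import pandas as pd
import pytest

from stepcourse import Design, SimulationConfig, simulate


@pytest.fixture
def two_group_design():
    """Minimal 2-stage x 3-replicate design."""
    cols = [f"A_{i}" for i in (1, 2, 3)] + [f"B_{i}" for i in (1, 2, 3)]
    return Design(
        samples=pd.DataFrame(
            {
                "sample_id": cols,
                "stage": ["A"] * 3 + ["B"] * 3,
                "replicate": [1, 2, 3, 1, 2, 3],
            }
        ),
        stage_order=("A", "B"),
    )


@pytest.fixture
def four_stage_design():
    """The default four-stage course with 3 replicates each."""
    stages = ("MBC", "prePB", "PB", "PC")
    rows = [
        {"sample_id": f"{s}_{r}", "stage": s, "replicate": r}
        for s in stages
        for r in (1, 2, 3)
    ]
    return Design(samples=pd.DataFrame(rows), stage_order=stages)


@pytest.fixture
def small_sim():
    """A small seeded simulation shared by several tests."""
    return simulate(SimulationConfig(n_genes=400, seed=11))


def random_counts(rng, n_genes=30, n_samples=6, max_count=500):
    genes = [f"g{i}" for i in range(n_genes)]
    cols = [f"s{j}" for j in range(n_samples)]
    return pd.DataFrame(
        rng.integers(0, max_count, size=(n_genes, n_samples)),
        index=pd.Index(genes, name="gene"),
        columns=cols,
    )
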