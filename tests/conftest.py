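import numpy as np
import pandas as pd
import pytest

from alloexpr.io import CountMatrix, HomoeologPairTable, SampleSheet


def make_sheet(n_individuals: int = 1, replicates: int = 3) -> SampleSheet:
    rows = []
    for r in range(1, replicates + 1):
        rows.append({"sample_id": f"PA_r{r}", "genotype": "PARENT_A", "individual": "", "replicate": r})
    for r in range(1, replicates + 1):
        rows.append({"sample_id": f"PC_r{r}", "genotype": "PARENT_C", "individual": "", "replicate": r})
    for i in range(1, n_individuals + 1):
        for r in range(1, replicates + 1):
            rows.append({"sample_id": f"AACC{i}_r{r}", "genotype": "POLYPLOID",
                         "individual": f"AACC{i}", "replicate": r})
    return SampleSheet(pd.DataFrame(rows))


def make_counts(counts: np.ndarray, sheet: SampleSheet, n_pairs: int) -> CountMatrix:
    """Counts array ordered [A genes..., C genes...] x sheet samples."""
    return CountMatrix(
        gene_ids=[f"gA{i}" for i in range(n_pairs)] + [f"gC{i}" for i in range(n_pairs)],
        subgenome=np.array(["A"] * n_pairs + ["C"] * n_pairs, dtype=object),
        sample_ids=sheet.sample_ids,
        counts=np.asarray(counts),
    )


def make_pairs(n_pairs: int) -> HomoeologPairTable:
    return HomoeologPairTable(
        pd.DataFrame(
            {
                "pair_id": [f"p{i}" for i in range(n_pairs)],
                "gene_A": [f"gA{i}" for i in range(n_pairs)],
                "gene_C": [f"gC{i}" for i in range(n_pairs)],
                "identity_pct": 95.0,
                "evalue": 1e-30,
            }
        )
    )


@pytest.fixture
def toy_sheet() -> SampleSheet:
    return make_sheet(n_individuals=1)


@pytest.fixture
def small_sim():
    """A small planted cohort shared by recovery-flavoured unit tests."""
    from alloexpr.simulate import SimConfig, simulate

    return simulate(SimConfig(n_pairs=600, n_individuals=1, seed=7))
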