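import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from assemblyscape import CommunityTable, preset, simulate_metacommunity


@pytest.fixture
def tiny_table():
    """4 samples x 4 taxa with simple structure."""
    counts = pd.DataFrame(
        [[5, 5, 0, 0],
         [4, 6, 0, 0],
         [0, 0, 7, 3],
         [0, 1, 6, 3]],
        index=["s1", "s2", "s3", "s4"],
        columns=["A", "B", "C", "D"],
    )
    return CommunityTable(counts)


@pytest.fixture
def tiny_tree():
    return TreeNode.read(["((A:0.1,B:0.1):0.9,(C:0.2,D:0.2):0.8):0.0;"])


@pytest.fixture
def tiny_meta(tiny_table):
    return pd.DataFrame(
        {
            "season": ["S1"] * 4,
            "site": ["site1", "site1", "site2", "site2"],
            "latitude": [38.5, 38.5, 38.5, 38.5],
            "longitude": [118.0, 118.0, 118.3, 118.3],
            "distance_to_land": [5.0, 5.0, 35.0, 35.0],
            "temperature": [20.0, 20.1, 24.0, 23.9],
            "salinity": [32.0, 31.9, 29.0, 29.2],
        },
        index=tiny_table.sample_ids,
    )


@pytest.fixture(scope="session")
def het_dataset():
    """Small heterogeneous-selection metacommunity used by several suites."""
    cfg = preset("heterogeneous_selection", n_taxa=120, n_sites=3, n_reps=3,
                 depth=1000, seed=42)
    return simulate_metacommunity(cfg)


def write_dataset(tmp_path, table, tree, meta):
    """Write a dataset triple to disk, returning the three paths."""
    counts_path = tmp_path / "counts.tsv"
    tree_path = tmp_path / "tree.nwk"
    meta_path = tmp_path / "metadata.tsv"
    table.counts.to_csv(counts_path, sep="\t", index_label="sample_id")
    tree.write(str(tree_path))
    meta.to_csv(meta_path, sep="\t", index_label="sample_id")
    return counts_path, tree_path, meta_path
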