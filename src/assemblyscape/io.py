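"""Dataset container types and I/O.

The unit of analysis is a triple: a sample x taxon count table, a rooted
phylogeny whose tips are the taxa, and a per-sample metadata frame carrying
grouping factors (season, site), coordinates, distance to land and measured
environmental variables.  All on-disk formats are plain text: tab-delimited
tables and Newick trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityTable",
    "load_dataset",
    "read_counts",
    "rarefy",
    "relative_abundance",
    "write_counts",
    "write_matrix",
    "write_manifest",
]


@dataclass
class CommunityTable:
    """Sample x taxon matrix of nonnegative integer read counts.

    Wraps a pandas DataFrame (rows = samples, columns = taxa) and validates
    the invariants every downstream pairwise analysis relies on: unique
    sample and taxon identifiers and nonnegative integer counts.
    """

    counts: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise ValueError("duplicate sample IDs in count table")
        if df.columns.has_duplicates:
            raise ValueError("duplicate taxon IDs in count table")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = df.columns[np.where(~np.isclose(arr, np.round(arr)))[1][:1]]
                raise ValueError(f"non-integer counts (e.g. in taxon {bad[0]!r})")
            self.counts = df.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative counts in count table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy()

    def drop_empty_taxa(self) -> "CommunityTable":
        """Remove taxa with zero total abundance."""
        keep = self.counts.sum(axis=0) > 0
        return CommunityTable(self.counts.loc[:, keep])


def read_counts(path) -> CommunityTable:
    """Read a tab-delimited count table.

    The default dialect is samples as rows with the first column holding the
    sample ID.  A transposed dialect (taxa as rows) is auto-detected when the
    header's first token is ``#taxon_id`` and transposed on load.
    """
    with open(path) as fh:
        first = fh.readline()
    header0 = first.rstrip("\n").split("\t")[0].strip()
    df = pd.read_csv(path, sep="\t", index_col=0)
    if header0 == "#taxon_id":
        df = df.T
    df.index = pd.Index([str(i) for i in df.index], name=None)
    df.columns = pd.Index([str(c) for c in df.columns], name=None)
    return CommunityTable(df)


def write_counts(table: CommunityTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id")


def load_dataset(counts_path, tree_path, metadata_path):
    """Load and mutually align the (counts, tree, metadata) triple.

    Returns a ``(CommunityTable, TreeNode, DataFrame)`` tuple in which the
    metadata rows are reordered to the table's samples and the tree is pruned
    to the table's taxa.  Tips absent from the table are pruned silently
    (logged); table taxa missing from the tree are an error, because a taxon
    without phylogenetic placement invalidates nearest-taxon metrics.
    """
    table = read_counts(counts_path)
    tree = TreeNode.read(str(tree_path), convert_underscores=False)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    return align_dataset(table, tree, meta)


def align_dataset(table: CommunityTable, tree: TreeNode, meta: pd.DataFrame):
    """Align an in-memory triple; see :func:`load_dataset` for the policy."""
    missing_meta = [s for s in table.sample_ids if s not in meta.index]
    if missing_meta:
        raise ValueError(
            f"samples missing from metadata: {', '.join(missing_meta)}"
        )
    meta = meta.loc[table.sample_ids]

    tip_names = {t.name for t in tree.tips()}
    table_taxa = set(table.taxon_ids)
    missing_tips = sorted(table_taxa - tip_names)
    if missing_tips:
        raise ValueError(
            f"taxa missing from tree: {', '.join(missing_tips)}"
        )
    extra = tip_names - table_taxa
    if extra:
        logger.info("pruning %d tree tips absent from table", len(extra))
        tree = tree.shear(table_taxa)
        tree.prune()
    for node in tree.traverse():
        if node.length is None:
            node.length = 0.0
        elif node.length < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")
    return table, tree, meta


def rarefy(
    table: CommunityTable,
    depth: int,
    seed: int,
    drop: bool = False,
) -> CommunityTable:
    """Subsample every sample to a common depth without replacement.

    Each row is drawn from the multivariate hypergeometric distribution over
    its reads, so rarefied counts never exceed the originals and every
    retained row sums exactly to ``depth``.  Samples with fewer reads than
    ``depth`` raise an error unless ``drop=True``, in which case they are
    removed (logged).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    shallow = totals[totals < depth].index.tolist()
    if shallow and not drop:
        raise ValueError(
            f"samples below rarefaction depth {depth}: {', '.join(map(str, shallow))}"
        )
    keep = [s for s in table.sample_ids if s not in set(shallow)]
    if shallow:
        logger.warning("dropping %d samples below depth %d: %s",
                       len(shallow), depth, ", ".join(map(str, shallow)))
    out = np.empty((len(keep), table.n_taxa), dtype=np.int64)
    for i, s in enumerate(keep):
        row = table.counts.loc[s].to_numpy()
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return CommunityTable(
        pd.DataFrame(out, index=keep, columns=table.taxon_ids)
    )


def relative_abundance(table: CommunityTable) -> pd.DataFrame:
    """Per-sample relative frequencies; every row sums to 1."""
    totals = table.counts.sum(axis=1)
    empty = totals[totals == 0].index.tolist()
    if empty:
        raise ValueError(f"all-zero samples: {', '.join(map(str, empty))}")
    return table.counts.div(totals, axis=0)


def write_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="id"
    )


def write_manifest(path, **entries) -> None:
    """Write a YAML run manifest (inputs, seed, parameters, version)."""
    from assemblyscape import __version__

    doc = {"assemblyscape_version": __version__, **entries}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
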