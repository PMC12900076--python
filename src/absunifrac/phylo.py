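"""Branch enumeration and cumulative descendant-abundance aggregation.

Every UniFrac formula sums over *branches*; the operand for a sample is
the vector of its abundances accumulated over each branch's descendant
leaves.  The enumeration here fixes a postorder over all edges of a
:class:`~absunifrac.model_io.PhyloTree` once (children strictly before
parents, the root's own edge last) and caches it on the tree, so that
profiles for any number of samples and rarefaction iterations reduce to
one vectorized postorder accumulation against the cached index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import skbio

from .model_io import BranchProfile, CountTable, PhyloTree, ValidationError

__all__ = [
    "BranchEnumeration",
    "enumerate_branches",
    "align_tree_table",
    "branch_profile",
    "branch_profiles",
    "prune_to_taxa",
]


@dataclass(frozen=True)
class BranchEnumeration:
    """Fixed postorder indexing of a tree's edges.

    Branch *i* is the edge above postorder node *i*; the root edge is the
    last entry with parent index −1.  ``leaf_branch[t]`` is the branch row
    of the leaf labeled ``taxa[t]``.
    """

    lengths: np.ndarray        # (n_branches,) edge length above each node
    parent: np.ndarray         # (n_branches,) postorder index of parent, root = -1
    is_leaf: np.ndarray        # (n_branches,) bool
    taxa: tuple                # leaf labels, in postorder
    leaf_branch: np.ndarray    # (n_taxa,) branch index of each leaf

    @property
    def n_branches(self) -> int:
        return self.lengths.shape[0]


def enumerate_branches(tree: PhyloTree) -> BranchEnumeration:
    """Return the tree's cached postorder branch enumeration, building it once."""
    if tree._enum is not None:
        return tree._enum
    nodes = list(tree.skbio_tree.postorder(include_self=True))
    index = {id(n): i for i, n in enumerate(nodes)}
    lengths = np.array([n.length if n.length is not None else 0.0 for n in nodes])
    parent = np.array(
        [index[id(n.parent)] if n.parent is not None else -1 for n in nodes],
        dtype=np.intp,
    )
    is_leaf = np.array([n.is_tip() for n in nodes], dtype=bool)
    taxa = tuple(n.name for n in nodes if n.is_tip())
    leaf_branch = np.flatnonzero(is_leaf)
    enum = BranchEnumeration(lengths, parent, is_leaf, taxa, leaf_branch)
    tree._enum = enum
    return enum


def align_tree_table(tree: PhyloTree, table: CountTable):
    """Check and align a count table against a tree's leaf set.

    Every table taxon must map to exactly one leaf.  Leaves absent from
    the table are assigned abundance 0 in every sample — absent taxa do
    not contribute to nor change any branch sum, so no pruning is needed.

    Returns
    -------
    (tree, aligned_table, zero_leaves)
        ``aligned_table`` has columns in the tree's postorder leaf order;
        ``zero_leaves`` lists the leaves that received all-zero columns.
    """
    enum = enumerate_branches(tree)
    tree_taxa = list(enum.taxa)
    missing = [t for t in table.taxa if t not in set(tree_taxa)]
    if missing:
        raise ValidationError(
            f"{len(missing)} table taxa missing from the tree: {missing[:10]}"
        )
    zero_leaves = [t for t in tree_taxa if t not in set(table.taxa)]
    aligned = table.data.reindex(columns=tree_taxa, fill_value=0.0)
    return tree, CountTable(aligned, mode=table.mode), zero_leaves


def branch_profiles(tree: PhyloTree, table: CountTable) -> np.ndarray:
    """Cumulative branch abundances for every sample at once.

    One postorder pass: leaf branches are seeded with the per-taxon
    abundances, then each branch's value is added into its parent.

    Returns a (n_samples, n_branches) array aligned to the enumeration;
    column −1 (the root edge) holds the sample totals.
    """
    _, aligned, _ = align_tree_table(tree, table)
    enum = enumerate_branches(tree)
    counts = aligned.values  # samples x taxa, taxa already in postorder leaf order
    prof = np.zeros((counts.shape[0], enum.n_branches))
    prof[:, enum.leaf_branch] = counts
    for i in range(enum.n_branches - 1):  # root (last) has no parent
        prof[:, enum.parent[i]] += prof[:, i]
    return prof


def branch_profile(tree: PhyloTree, sample_counts, mode: str = "absolute") -> BranchProfile:
    """Branch profile for a single sample.

    ``sample_counts`` maps taxon label -> abundance (dict or pandas
    Series); taxa absent from the mapping get 0.
    """
    import pandas as pd

    series = pd.Series(sample_counts, dtype=float)
    table = CountTable(series.to_frame().T.set_axis(["_s"]), mode="raw_reads")
    values = branch_profiles(tree, table)[0]
    return BranchProfile(values=values, mode=mode, tree=tree)


def prune_to_taxa(tree: PhyloTree, taxa) -> PhyloTree:
    """Minimal subtree spanning ``taxa`` and the root.

    Retained branch lengths are unchanged; unbranched internal chains are
    kept rather than merged, so every leaf-to-root path length (and the
    root position) is preserved exactly.
    """
    taxa = set(taxa)
    if not taxa:
        raise ValidationError("cannot prune to an empty taxon set")
    leaf_set = set(t.name for t in tree.skbio_tree.tips())
    unknown = taxa - leaf_set
    if unknown:
        raise ValidationError(f"taxa not in tree: {sorted(unknown)[:10]}")

    def _copy(node: skbio.TreeNode):
        if node.is_tip():
            if node.name in taxa:
                return skbio.TreeNode(name=node.name, length=node.length)
            return None
        kept = [c for c in (_copy(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        new = skbio.TreeNode(name=node.name, length=node.length)
        new.extend(kept)
        return new

    pruned = _copy(tree.skbio_tree)
    return PhyloTree(pruned, provenance=f"pruned to {len(taxa)} taxa")
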