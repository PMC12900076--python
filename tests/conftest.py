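"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's vectorized postorder
path: branch terms are recomputed by explicitly enumerating each branch's
descendant leaf set via skbio tree traversal, so they can falsify the
implementation.
"""

import io

import numpy as np
import pandas as pd
import pytest
import skbio

import absunifrac as au

# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def branch_terms(phylo_tree, counts_a, counts_b):
    """(length, x_a, x_b) per branch via explicit descendant leaf sets."""
    terms = []
    for node in phylo_tree.skbio_tree.postorder(include_self=True):
        leaves = [node.name] if node.is_tip() else [t.name for t in node.tips()]
        b = node.length if node.length is not None else 0.0
        xa = sum(counts_a.get(t, 0.0) for t in leaves)
        xb = sum(counts_b.get(t, 0.0) for t in leaves)
        terms.append((b, xa, xb))
    return terms


def naive_weighted(tree, a, b):
    terms = branch_terms(tree, a, b)
    num = sum(bl * abs(xa - xb) for bl, xa, xb in terms)
    den = sum(bl * (xa + xb) for bl, xa, xb in terms)
    return num / den


def naive_generalized(tree, a, b, alpha):
    terms = [(bl, xa, xb) for bl, xa, xb in branch_terms(tree, a, b) if xa + xb > 0]
    num = sum(bl * (xa + xb) ** alpha * abs(xa - xb) / (xa + xb) for bl, xa, xb in terms)
    den = sum(bl * (xa + xb) ** alpha for bl, xa, xb in terms)
    return num / den


def naive_unweighted(tree, a, b):
    terms = branch_terms(tree, a, b)
    num = sum(bl for bl, xa, xb in terms if (xa > 0) != (xb > 0))
    den = sum(bl for bl, xa, xb in terms if xa > 0 or xb > 0)
    return num / den


def profiles_for(tree, a, b, mode="absolute"):
    return au.branch_profile(tree, a, mode=mode), au.branch_profile(tree, b, mode=mode)


def random_leveled_tree(rng, n_leaves, depth=None):
    """Random tree with unit branch lengths and all leaves at equal depth."""
    if depth is None:
        depth = int(rng.integers(1, 4))
    nodes = [skbio.TreeNode(name=f"L{i+1}", length=1.0) for i in range(n_leaves)]
    for level in range(depth - 1):
        if len(nodes) == 1:
            wrap = skbio.TreeNode(length=1.0)
            wrap.extend(nodes)
            nodes = [wrap]
            continue
        n_parents = int(rng.integers(1, len(nodes)))
        assignment = rng.integers(0, n_parents, size=len(nodes))
        assignment[rng.permutation(len(nodes))[:n_parents]] = np.arange(n_parents)
        parents = []
        for p in range(n_parents):
            kids = [nodes[i] for i in np.flatnonzero(assignment == p)]
            parent = skbio.TreeNode(length=1.0)
            parent.extend(kids)
            parents.append(parent)
        nodes = parents
    root = skbio.TreeNode(length=0.0)
    root.extend(nodes)
    return au.PhyloTree(root, provenance="random leveled unit-length tree")


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def two_leaf_tree():
    return au.read_newick(io.StringIO("(A:1,B:1):0;"))


@pytest.fixture(scope="session")
def two_leaf_tree_module():
    # session-scoped twin for hypothesis-driven tests (function-scoped
    # fixtures are off-limits inside @given)
    return au.read_newick(io.StringIO("(A:1,B:1):0;"))


@pytest.fixture
def balanced_tree():
    return au.read_newick(io.StringIO("((A:1,B:1):0.5,(C:1,D:1):0.5):0;"))


@pytest.fixture
def grid_tree():
    return au.default_grid_tree()


@pytest.fixture
def grid():
    return au.grid_communities()


@pytest.fixture
def small_fixture():
    """20-sample, 12-taxon raw-read fixture with a ~10-fold load range."""
    return au.random_fixture(
        n_taxa=12, n_samples=20, load_log10_range=(7.0, 8.2), seed=42
    )


def make_table(rows, samples, taxa, mode="raw_reads"):
    return au.CountTable(
        pd.DataFrame(rows, index=samples, columns=taxa, dtype=float), mode=mode
    )
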