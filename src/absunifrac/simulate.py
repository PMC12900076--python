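"""Synthetic fixtures: the four-taxon abundance grid, a stand-in phylogeny,
randomized tree/table/load fixtures, and the cross-metric comparison of
absolute vs relative dissimilarities over all sample pairs.
"""

from __future__ import annotations

import io
import itertools

import numpy as np
import pandas as pd

from .metrics import pairwise_distances
from .model_io import (
    CountTable,
    LoadVector,
    MetricSpec,
    PhyloTree,
    ValidationError,
    read_newick,
)

__all__ = [
    "grid_communities",
    "default_grid_tree",
    "compare_metrics",
    "random_fixture",
]

#: stand-in topology for the four-taxon grid.  The published demonstration
#: tree's branch lengths are not tabulated anywhere reproducible, so this
#: synthetic placeholder uses unit lengths; supply your own Newick tree to
#: reproduce published correlation values exactly.
DEFAULT_GRID_NEWICK = "((ASV_1:1,ASV_2:1):1,(ASV_3:1,ASV_4:1):1):0;"


def grid_communities(levels=(1, 10, 100), n_taxa: int = 4) -> CountTable:
    """Every combination of the abundance levels across ``n_taxa`` taxa.

    With the defaults this is the 3^4 grid: 81 unique communities over
    four taxa (3240 unordered pairs).  Samples are emitted in
    deterministic lexicographic order of their level tuples and named
    after them (``C_1_10_100_1`` carries abundances 1,10,100,1).
    Abundances are already absolute cell counts, so the table mode is
    ``absolute`` and the natural load of each sample is its row total.
    """
    levels = [float(v) for v in levels]
    if not levels:
        raise ValidationError("levels must be non-empty")
    if any(v <= 0 for v in levels):
        raise ValidationError("levels must be positive")
    if n_taxa < 1:
        raise ValidationError("n_taxa must be >= 1")
    taxa = [f"ASV_{i + 1}" for i in range(n_taxa)]
    rows = list(itertools.product(levels, repeat=n_taxa))
    names = ["C_" + "_".join(f"{v:g}" for v in row) for row in rows]
    df = pd.DataFrame(rows, index=names, columns=taxa, dtype=float)
    return CountTable(df, mode="absolute")


def default_grid_tree() -> PhyloTree:
    """The synthetic stand-in tree ((ASV_1,ASV_2),(ASV_3,ASV_4)), unit lengths."""
    tree = read_newick(io.StringIO(DEFAULT_GRID_NEWICK))
    tree.provenance = "synthetic unit-length stand-in for the four-taxon demonstration tree"
    return tree


def compare_metrics(
    table: CountTable,
    tree: PhyloTree,
    loads: LoadVector | None = None,
    alphas=(),
):
    """Cross-metric comparison over every unordered sample pair.

    Computes BC^R, BC^A, U^R and U^A (plus GU^A at any requested alphas)
    for all pairs and summarizes how absolute weighted UniFrac relates to
    the other metrics by Pearson correlation.

    Returns
    -------
    (records, summary)
        ``records`` is a long-format DataFrame with columns
        ``sample_a, sample_b, metric, distance``; ``summary`` maps each
        non-U^A metric name to Pearson r against U^A over all pairs (NaN
        when a metric is constant, e.g. a table of identical samples).
    """
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples to compare metrics")
    if loads is None:
        if table.mode != "absolute":
            raise ValidationError(
                "supply loads, or a table already in absolute mode (loads are "
                "then the row totals)"
            )
        loads = LoadVector(pd.Series(table.values.sum(axis=1), index=table.samples))

    specs = {
        "BC^R": MetricSpec("bray_curtis", "relative"),
        "BC^A": MetricSpec("bray_curtis", "absolute"),
        "U^R": MetricSpec("unifrac_weighted", "relative"),
        "U^A": MetricSpec("unifrac_weighted", "absolute"),
    }
    condensed = {}
    ids = table.samples
    for name, spec in specs.items():
        dm = pairwise_distances(table, tree, spec, loads)
        condensed[name] = dm.condensed_form()
    if alphas:
        gdm = pairwise_distances(
            table, tree, MetricSpec("unifrac_generalized", "absolute", tuple(alphas)), loads
        )
        for a, dm in gdm.items():
            condensed[f"GU^A(a={a:g})"] = dm.condensed_form()

    pairs = list(itertools.combinations(ids, 2))
    records = pd.DataFrame(
        [
            {"sample_a": a, "sample_b": b, "metric": m, "distance": v}
            for m, vec in condensed.items()
            for (a, b), v in zip(pairs, vec)
        ]
    )
    ua = condensed["U^A"]
    summary = {}
    for name, vec in condensed.items():
        if name == "U^A":
            continue
        if np.ptp(ua) == 0 or np.ptp(vec) == 0:
            summary[name] = float("nan")
        else:
            summary[name] = float(np.corrcoef(ua, vec)[0, 1])
    return records, summary


def _random_topology(taxa, rng: np.random.Generator, mean_length: float = 0.1):
    """Random binary tree via sequential joins; exponential branch lengths."""
    import skbio

    def edge():
        return float(rng.exponential(mean_length))

    nodes = [skbio.TreeNode(name=t, length=edge()) for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = skbio.TreeNode(length=edge())
        parent.extend([left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return PhyloTree(root, provenance="random sequential-join topology")


def random_fixture(
    n_taxa: int,
    n_samples: int,
    load_log10_range=(5.6, 12.3),
    seed: int = 0,
    concentration: float = 1.0,
    mean_reads: float = 3e4,
    read_sigma: float = 0.3,
    mean_branch_length: float = 0.1,
):
    """Seed-deterministic random (tree, raw-read table, loads) fixture.

    Emulates the shape of real quantitative-profiling datasets: a random
    binary topology with exponential branch lengths, Dirichlet sample
    compositions, lognormal read totals, and per-sample loads log-uniform
    over ``load_log10_range`` — the default spans 4e5 cells/mL to 2e12
    16S copies/g, the extremes reported across published systems.
    """
    if n_taxa < 2:
        raise ValidationError("n_taxa must be >= 2")
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    lo, hi = (float(v) for v in load_log10_range)
    if hi < lo:
        raise ValidationError("load_log10_range must be (low, high)")
    rng = np.random.default_rng(seed)
    taxa = [f"ASV_{i + 1}" for i in range(n_taxa)]
    tree = _random_topology(taxa, rng, mean_branch_length)
    comps = rng.dirichlet(np.full(n_taxa, concentration), size=n_samples)
    depths = np.maximum(
        rng.lognormal(np.log(mean_reads), read_sigma, size=n_samples), 100
    ).astype(np.int64)
    counts = np.vstack([rng.multinomial(d, p) for d, p in zip(depths, comps)])
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    table = CountTable(
        pd.DataFrame(counts, index=samples, columns=taxa), mode="raw_reads"
    )
    loads = LoadVector(
        pd.Series(10 ** rng.uniform(lo, hi, size=n_samples), index=samples)
    )
    return tree, table, loads
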