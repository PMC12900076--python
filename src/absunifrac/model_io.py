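"""Domain types and file I/O for count tables, trees, loads, and distance matrices.

The canonical on-disk formats are plain TSV (dense count tables, sample
metadata, square labeled distance matrices) and Newick for phylogenies.
Distance matrices are carried as :class:`skbio.stats.distance.DistanceMatrix`,
which already enforces symmetry, a zero diagonal, and label bookkeeping.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import skbio
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "PhyloTree",
    "CountTable",
    "LoadVector",
    "BranchProfile",
    "MetricSpec",
    "DistanceMatrix",
    "read_count_table",
    "write_count_table",
    "read_newick",
    "write_newick",
    "read_loads",
    "write_loads",
    "read_distance_matrix",
    "write_distance_matrix",
]

#: count-table modes
MODES = ("raw_reads", "relative", "absolute")

#: tolerance for "rows sum to 1" in relative mode
_REL_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------


class PhyloTree:
    """A rooted phylogeny with branch lengths, wrapping an skbio TreeNode.

    The wrapped tree is treated as immutable after construction.  Branch
    enumeration (a fixed postorder over all edges, computed by
    :mod:`absunifrac.phylo`) is cached on the instance so that repeated
    profile/metric computations — e.g. 100 rarefaction iterations — never
    re-traverse the tree.

    Parameters
    ----------
    tree
        A rooted ``skbio.TreeNode``.  A missing length on any edge
        (including the root's own edge) is treated as 0.
    provenance
        Free-text note about how the tree was obtained/rooted.
    """

    def __init__(self, tree: skbio.TreeNode, provenance: str = ""):
        lengths = []
        names = []
        for node in tree.postorder(include_self=True):
            if node.length is not None and node.length < 0:
                raise ValidationError(
                    f"negative branch length {node.length} on node {node.name!r}"
                )
            lengths.append(node.length)
            if node.is_tip():
                if node.name is None:
                    raise ValidationError("tree has an unlabeled leaf")
                names.append(node.name)
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate leaf labels: {dupes}")
        self._tree = tree
        self.provenance = provenance
        self._enum = None  # populated lazily by absunifrac.phylo

    @property
    def skbio_tree(self) -> skbio.TreeNode:
        return self._tree

    @property
    def taxa(self) -> list[str]:
        """Leaf labels in postorder."""
        return [t.name for t in self._tree.postorder() if t.is_tip()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._tree.tips())

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree with {self.n_leaves} leaves>"


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Samples x taxa abundance matrix with a mode tag.

    ``mode`` tracks what the numbers mean: ``raw_reads`` (sequencing
    counts), ``relative`` (per-sample proportions summing to 1) or
    ``absolute`` (load-scaled real-valued abundances).  Entries may be
    non-integer in any mode except where rarefaction requires integer
    reads; integrality is enforced at rarefaction time, not here.
    """

    data: pd.DataFrame  # index = samples, columns = taxa
    mode: str = "raw_reads"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample identifiers")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate taxon identifiers")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("non-finite abundance values")
        if (values < 0).any():
            s, t = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {self.data.index[s]!r}, "
                f"taxon {self.data.columns[t]!r}"
            )
        if self.mode == "relative":
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > _REL_TOL
            if bad.any():
                raise ValidationError(
                    f"relative-mode rows must sum to 1: offending samples "
                    f"{list(self.data.index[bad][:5])}"
                )

    # -- convenience views -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    # -- mode pipeline -----------------------------------------------------
    def to_relative(self) -> "CountTable":
        """Row-normalize to proportions.  All-zero samples are an error."""
        if self.mode == "relative":
            return self
        totals = self.values.sum(axis=1)
        if (totals <= 0).any():
            bad = list(self.data.index[totals <= 0][:5])
            raise ValidationError(f"cannot normalize all-zero samples: {bad}")
        rel = self.data.div(pd.Series(totals, index=self.data.index), axis=0)
        return CountTable(rel, mode="relative")

    def to_absolute(self, loads: "LoadVector") -> "CountTable":
        """Scale per-sample proportions by total microbial load N_s."""
        if self.mode == "absolute":
            return self
        rel = self.to_relative()
        n = loads.reindex(rel.samples)
        scaled = rel.data.mul(pd.Series(n, index=rel.data.index), axis=0)
        return CountTable(scaled, mode="absolute")


# ---------------------------------------------------------------------------
# LoadVector
# ---------------------------------------------------------------------------


@dataclass
class LoadVector:
    """Per-sample total absolute abundance N_s (cells/mL, 16S copies/g, ...)."""

    loads: pd.Series  # index = sample ids, strictly positive

    def __post_init__(self):
        self.loads = self.loads.astype(float)
        if self.loads.index.has_duplicates:
            raise ValidationError("duplicate sample identifiers in loads")
        bad = ~(np.isfinite(self.loads.to_numpy()) & (self.loads.to_numpy() > 0))
        if bad.any():
            raise ValidationError(
                f"loads must be finite and > 0; offending samples "
                f"{list(self.loads.index[bad][:5])}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.loads.index)

    def reindex(self, samples: Sequence[str]) -> np.ndarray:
        missing = [s for s in samples if s not in self.loads.index]
        if missing:
            raise ValidationError(f"samples without a load value: {missing[:5]}")
        return self.loads.reindex(samples).to_numpy()

    def __getitem__(self, sample: str) -> float:
        return float(self.loads[sample])


# ---------------------------------------------------------------------------
# BranchProfile
# ---------------------------------------------------------------------------


@dataclass
class BranchProfile:
    """Per-branch cumulative descendant abundance for one sample.

    ``values[i]`` is the sum of the sample's abundances over every leaf
    descending from branch *i* of the tree's fixed postorder enumeration;
    the root-edge entry equals the sample total.  This is the direct
    operand of every UniFrac kernel (p_i in relative mode, c_i in
    absolute mode).
    """

    values: np.ndarray
    mode: str  # "relative" or "absolute"
    tree: PhyloTree

    def __post_init__(self):
        if self.mode not in ("relative", "absolute"):
            raise ValidationError(f"profile mode must be relative/absolute, got {self.mode!r}")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def total(self) -> float:
        return float(self.values[-1])  # root edge is last in postorder


# ---------------------------------------------------------------------------
# MetricSpec
# ---------------------------------------------------------------------------

FAMILIES = (
    "unifrac_weighted",
    "unifrac_generalized",
    "unifrac_unweighted",
    "bray_curtis",
)


@dataclass(frozen=True)
class MetricSpec:
    """Which dissimilarity to compute and on which abundance scale.

    ``alphas`` is only meaningful (and required) for the generalized
    UniFrac family; all alphas share one branch-profile computation.
    """

    family: str
    weighting: str = "relative"  # "relative" | "absolute"
    alphas: tuple = field(default=())

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}; expected {FAMILIES}")
        if self.weighting not in ("relative", "absolute"):
            raise ValidationError(f"weighting must be relative/absolute, got {self.weighting!r}")
        object.__setattr__(self, "alphas", tuple(float(a) for a in self.alphas))
        if self.family == "unifrac_generalized":
            if not self.alphas:
                raise ValidationError("generalized UniFrac requires at least one alpha")
            if any(not (0.0 <= a <= 1.0) for a in self.alphas):
                raise ValidationError(f"alpha values must lie in [0, 1], got {self.alphas}")
        elif self.alphas:
            raise ValidationError("alphas are only valid for the generalized family")

    @property
    def needs_tree(self) -> bool:
        return self.family.startswith("unifrac")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_count_table(path, orientation: str = "samples_as_rows") -> CountTable:
    """Read a dense TSV count table.

    Parameters
    ----------
    path
        TSV with one header row and one identifier column; numeric body.
    orientation
        ``samples_as_rows`` (default) or ``taxa_as_rows``; the returned
        table is always samples x taxa.
    """
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any() and not df[col].isna().any():
            row = df.index[converted.isna()][0]
            raise ValidationError(
                f"non-numeric value at row {row!r}, column {col!r} in {path}"
            )
        df[col] = converted
    if df.isna().to_numpy().any():
        raise ValidationError(f"missing values in count table {path}")
    if orientation == "taxa_as_rows":
        df = df.T
    return CountTable(df, mode="raw_reads")


def write_count_table(table: CountTable, path) -> None:
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_newick(path) -> PhyloTree:
    """Read a Newick tree; branch lengths required on internal edges.

    An unrooted export (basal multifurcation) is adopted as-is: the basal
    node becomes the root with a zero-length root edge, which contributes
    0 to every branch sum.  The choice is recorded in ``provenance``.
    """
    src = path if hasattr(path, "read") else str(path)
    # underscores in labels are kept literal (ASV ids routinely contain them)
    tree = skbio.TreeNode.read(src, format="newick", convert_underscores=False)
    note = ""
    if tree.length is None:
        note = "root edge length absent in source; treated as 0"
    if len(tree.children) > 2:
        note = (
            "basal multifurcation (likely unrooted export) adopted as root "
            "with zero-length root edge"
        )
    return PhyloTree(tree, provenance=note)


def write_newick(tree: PhyloTree, path) -> None:
    tree.skbio_tree.write(str(path), format="newick")


def read_loads(path, column: str, sample_column: str | None = None) -> LoadVector:
    """Read per-sample loads from a metadata TSV.

    ``sample_column`` defaults to the first column.  Samples with a
    non-positive or non-finite load raise a validation error naming them.
    """
    meta = pd.read_csv(path, sep="\t", dtype={0: str})
    if sample_column is None:
        sample_column = meta.columns[0]
    if column not in meta.columns:
        raise ValidationError(
            f"column {column!r} not found; available columns: {list(meta.columns)}"
        )
    series = pd.Series(
        pd.to_numeric(meta[column], errors="coerce").to_numpy(),
        index=meta[sample_column].astype(str),
        name=column,
    )
    vals = series.to_numpy()
    bad = ~(np.isfinite(vals) & (vals > 0))
    if bad.any():
        raise ValidationError(
            f"non-positive or missing load for samples {list(series.index[bad][:5])}"
        )
    return LoadVector(series)


def write_loads(loads: LoadVector, path, column: str = "load") -> None:
    df = pd.DataFrame({"sample_id": loads.samples, column: loads.loads.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    """Write a square labeled TSV (lsmat layout: header row + label column)."""
    dm.write(str(path))


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a square labeled TSV; asymmetric or non-square input raises."""
    return DistanceMatrix.read(str(path))
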