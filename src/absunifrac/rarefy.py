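"""Rarefaction-averaged distance workflow for absolute-abundance tables.

Sequencing depth biases both richness and dissimilarity, so read-count
tables are repeatedly subsampled to a common depth before computing any
distance.  The workflow implemented here:

1. discard samples below a minimum-read threshold (logged);
2. per iteration, subsample every sample to equal depth *without*
   replacement (multivariate hypergeometric);
3. divide by the depth to obtain relative abundance — no rounding at any
   point;
4. multiply by each sample's total load N_s when the metric is absolute;
5. compute the distance matrix;
6. average the matrices elementwise across iterations (default 100).

Distances are averaged, never tables: the mean of per-iteration distance
matrices is the estimator, and the ordering matters.  Branch enumeration
is computed once and reused across all iterations.  Per-iteration seeds
derive from the master seed by iteration index, so any single iteration
is reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import pairwise_distances
from .model_io import (
    CountTable,
    DistanceMatrix,
    LoadVector,
    MetricSpec,
    PhyloTree,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = ["RarefactionConfig", "rarefy_sample", "rarefy_table", "rarefied_distance"]


@dataclass(frozen=True)
class RarefactionConfig:
    """Parameters of the rarefaction-averaging workflow.

    depth
        Target reads per sample; ``None`` means the minimum read total
        among retained samples (the recommended default).
    iterations
        Number of rarefied tables to average over (default 100).
    seed
        Master seed; iteration k uses ``SeedSequence(seed, spawn_key=(k,))``.
    min_depth
        Samples with fewer total reads are discarded before the depth is
        fixed; ``None`` disables discarding.
    """

    depth: int | None = None
    iterations: int = 100
    seed: int = 0
    min_depth: int | None = None

    def __post_init__(self):
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if self.depth is not None and self.depth < 1:
            raise ValidationError("depth must be a positive integer")


def _iteration_rng(seed: int, k: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))


def _as_int_counts(values: np.ndarray, context: str) -> np.ndarray:
    rounded = np.rint(values)
    if not np.allclose(values, rounded, atol=1e-9):
        raise ValidationError(f"{context}: rarefaction requires integer read counts")
    return rounded.astype(np.int64)


def rarefy_sample(counts, depth: int, seed_or_rng=0) -> np.ndarray:
    """Subsample one sample's reads to ``depth`` without replacement.

    Draws from the multivariate hypergeometric: the result is elementwise
    <= counts and sums exactly to depth.  Reproducible under a fixed seed.
    """
    counts = _as_int_counts(np.asarray(counts, dtype=float), "sample")
    total = int(counts.sum())
    if total < depth:
        raise ValidationError(f"sample has {total} reads, fewer than depth {depth}")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    return rng.multivariate_hypergeometric(counts, depth)


def rarefy_table(table: CountTable, depth: int, rng: np.random.Generator) -> CountTable:
    """Rarefy every sample of a raw-read table to equal depth."""
    counts = _as_int_counts(table.values, "table")
    out = np.empty_like(counts)
    for i, sample in enumerate(table.samples):
        if counts[i].sum() < depth:
            raise ValidationError(
                f"sample {sample!r} has {counts[i].sum()} reads, fewer than depth {depth}"
            )
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    return CountTable(
        pd.DataFrame(out, index=table.samples, columns=table.taxa), mode="raw_reads"
    )


def rarefied_distance(
    table: CountTable,
    tree: PhyloTree | None,
    loads: LoadVector | None,
    spec: MetricSpec,
    config: RarefactionConfig,
):
    """Rarefaction-averaged distance matrix (Monte-Carlo mean over iterations).

    Returns a :class:`DistanceMatrix`, or ``{alpha: DistanceMatrix}`` for
    the generalized family.
    """
    if table.mode != "raw_reads":
        raise ValidationError("rarefaction operates on raw read counts")
    counts = _as_int_counts(table.values, "table")
    totals = counts.sum(axis=1)

    keep = np.ones(table.n_samples, dtype=bool)
    if config.min_depth is not None:
        keep = totals >= config.min_depth
        dropped = [s for s, k in zip(table.samples, keep) if not k]
        if dropped:
            logger.warning(
                "discarding %d samples below min_depth=%d: %s",
                len(dropped), config.min_depth, dropped,
            )
    if keep.sum() < 2:
        raise ValidationError("fewer than 2 samples retained after depth filtering")
    work = CountTable(table.data.loc[keep], mode="raw_reads")
    retained_totals = totals[keep]

    depth = config.depth if config.depth is not None else int(retained_totals.min())
    if depth > retained_totals.min():
        low = work.samples[int(np.argmin(retained_totals))]
        raise ValidationError(
            f"depth {depth} exceeds the smallest retained sample total "
            f"({int(retained_totals.min())}, sample {low!r})"
        )
    if spec.weighting == "absolute" and loads is None:
        raise ValidationError("absolute weighting requires loads")

    generalized = spec.family == "unifrac_generalized"
    acc = None
    for k in range(config.iterations):
        rng = _iteration_rng(config.seed, k)
        sub = rarefy_table(work, depth, rng)
        dm = pairwise_distances(sub, tree, spec, loads)
        if generalized:
            if acc is None:
                acc = {a: m.data.copy() for a, m in dm.items()}
            else:
                for a, m in dm.items():
                    acc[a] += m.data
        else:
            acc = dm.data.copy() if acc is None else acc + dm.data
    ids = work.samples
    if generalized:
        return {a: DistanceMatrix(v / config.iterations, ids=ids) for a, v in acc.items()}
    return DistanceMatrix(acc / config.iterations, ids=ids)
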