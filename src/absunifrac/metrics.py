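"""The dissimilarity family: weighted / generalized / unweighted UniFrac and
Bray-Curtis, each in relative- or absolute-abundance mode.

All UniFrac kernels operate on branch profiles (cumulative descendant
abundance per branch, see :mod:`absunifrac.phylo`).  Writing x for either
p (relative) or c (absolute) per branch i with length b_i:

    weighted      U  = sum b_i |x_i^a - x_i^b| / sum b_i (x_i^a + x_i^b)
    generalized   GU = sum b_i s_i^alpha |x_i^a - x_i^b| / s_i
                       ------------------------------------------
                              sum b_i s_i^alpha,        s_i = x_i^a + x_i^b
    unweighted       = sum of b_i unique to one sample / sum of b_i covered

Branches with s_i = 0 are excluded from the generalized sums (the ratio
term is undefined there); at alpha = 1 the generalized form reduces to the
weighted form exactly.  Evaluated on absolute profiles the weighted and
generalized forms are U^A and GU^A: two samples with identical composition
but a k-fold load difference score (k-1)/(k+1) instead of 0.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform

from .model_io import (
    BranchProfile,
    CountTable,
    DistanceMatrix,
    LoadVector,
    MetricSpec,
    PhyloTree,
    ValidationError,
)
from .phylo import branch_profiles, enumerate_branches

__all__ = [
    "weighted_unifrac",
    "generalized_unifrac",
    "unweighted_unifrac",
    "bray_curtis",
    "pairwise_distances",
]

#: slack allowed on the [0, 1] bound for floating-point accumulation
_BOUND_TOL = 1e-12


def _check_pair(pa: BranchProfile, pb: BranchProfile) -> None:
    if pa.tree is not pb.tree:
        raise ValidationError("profiles were computed on different trees")
    if pa.mode != pb.mode:
        raise ValidationError(f"profile mode mismatch: {pa.mode!r} vs {pb.mode!r}")
    if pa.total <= 0 and pb.total <= 0:
        raise ValidationError("distance undefined: both profiles are all-zero")


def weighted_unifrac(pa: BranchProfile, pb: BranchProfile) -> float:
    """Weighted UniFrac on a profile pair: U^R (relative) or U^A (absolute)."""
    _check_pair(pa, pb)
    b = enumerate_branches(pa.tree).lengths
    num = float(b @ np.abs(pa.values - pb.values))
    den = float(b @ (pa.values + pb.values))
    if den == 0:
        raise ValidationError("distance undefined: all branch lengths weigh zero abundance")
    return num / den


def generalized_unifrac(pa: BranchProfile, pb: BranchProfile, alpha: float) -> float:
    """Generalized UniFrac GU(alpha): GU^R (relative) or GU^A (absolute).

    alpha in [0, 1] down-weights abundant lineages; alpha = 1 recovers the
    weighted form, alpha -> 0 approaches incidence-like behavior.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must lie in [0, 1], got {alpha}")
    _check_pair(pa, pb)
    b = enumerate_branches(pa.tree).lengths
    s = pa.values + pb.values
    mask = s > 0
    if not mask.any():
        raise ValidationError("distance undefined: no branch carries abundance")
    w = b[mask] * s[mask] ** alpha
    num = float(w @ (np.abs(pa.values - pb.values)[mask] / s[mask]))
    den = float(w.sum())
    if den == 0:
        raise ValidationError("distance undefined: zero denominator")
    return num / den


def unweighted_unifrac(pa: BranchProfile, pb: BranchProfile) -> float:
    """Unweighted UniFrac: incidence only, invariant to any positive rescaling."""
    _check_pair(pa, pb)
    b = enumerate_branches(pa.tree).lengths
    ina, inb = pa.values > 0, pb.values > 0
    covered = ina | inb
    unique = ina ^ inb
    den = float(b[covered].sum())
    if den == 0:
        raise ValidationError("distance undefined: no covered branch length")
    return float(b[unique].sum()) / den


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b) on per-taxon vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"vector length mismatch: {a.shape} vs {b.shape}")
    den = float((a + b).sum())
    if den == 0:
        raise ValidationError("distance undefined: both vectors are all-zero")
    return float(np.abs(a - b).sum()) / den


# ---------------------------------------------------------------------------
# all-pairs matrix builders
# ---------------------------------------------------------------------------


def _pipeline(table: CountTable, spec: MetricSpec, loads: LoadVector | None) -> CountTable:
    """raw_reads -> relative (row-normalize) -> absolute (x N_s) as demanded."""
    if spec.weighting == "relative":
        return table.to_relative()
    if table.mode == "absolute":
        return table
    if loads is None:
        raise ValidationError(
            "absolute weighting requires a load vector when the table is not "
            "already in absolute mode"
        )
    return table.to_absolute(loads)


def _finalize(condensed: np.ndarray, ids) -> DistanceMatrix:
    over = condensed.max(initial=0.0) - 1.0
    if over > _BOUND_TOL:
        raise AssertionError(f"dissimilarity exceeds 1 by {over:.3e}")
    return DistanceMatrix(squareform(np.clip(condensed, 0.0, 1.0), checks=False), ids=ids)


def pairwise_distances(
    table: CountTable,
    tree: PhyloTree | None,
    spec: MetricSpec,
    loads: LoadVector | None = None,
):
    """All-pairs dissimilarity matrix for one metric spec.

    The table is passed through the mode pipeline (normalize, then scale
    by loads if the spec is absolute), profiles are computed once against
    the tree's cached branch enumeration, and every unordered pair is
    evaluated.

    Returns a :class:`DistanceMatrix`, or for the generalized family a
    dict ``{alpha: DistanceMatrix}`` sharing one profile computation.
    """
    if spec.needs_tree and tree is None:
        raise ValidationError(f"{spec.family} requires a phylogenetic tree")
    work = _pipeline(table, spec, loads)
    ids = work.samples
    n = work.n_samples
    if n == 1:
        zero = DistanceMatrix(np.zeros((1, 1)), ids=ids)
        if spec.family == "unifrac_generalized":
            return {a: zero for a in spec.alphas}
        return zero

    if spec.family == "bray_curtis":
        x = work.values
        totals = x.sum(axis=1)
        from scipy.spatial.distance import pdist

        num = pdist(x, metric="cityblock")
        den = totals[:, None] + totals[None, :]
        return _finalize(num / squareform(den - np.diag(np.diag(den)), checks=False), ids)

    prof = branch_profiles(tree, work)  # n x branches
    b = enumerate_branches(tree).lengths

    if spec.family == "unifrac_weighted":
        from scipy.spatial.distance import pdist

        num = pdist(prof * b, metric="cityblock")
        t = prof @ b
        den = t[:, None] + t[None, :]
        return _finalize(num / squareform(den - np.diag(np.diag(den)), checks=False), ids)

    if spec.family == "unifrac_unweighted":
        inc = prof > 0
        out = np.zeros(n * (n - 1) // 2)
        k = 0
        for i in range(n - 1):
            covered = inc[i] | inc[i + 1 :]
            unique = inc[i] ^ inc[i + 1 :]
            out[k : k + n - 1 - i] = (unique @ b) / (covered @ b)
            k += n - 1 - i
        return _finalize(out, ids)

    # generalized: per-pair loop vectorized over branches, one pass per alpha
    results = {a: np.zeros(n * (n - 1) // 2) for a in spec.alphas}
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            s = prof[i] + prof[j]
            mask = s > 0
            ratio = np.abs(prof[i] - prof[j])[mask] / s[mask]
            bs = b[mask]
            sm = s[mask]
            for a in spec.alphas:
                w = bs * sm**a
                results[a][k] = (w @ ratio) / w.sum()
            k += 1
    return {a: _finalize(v, ids) for a, v in results.items()}
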