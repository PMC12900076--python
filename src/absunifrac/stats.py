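"""Evaluation statistics: Mantel correlation, one-way PERMANOVA, and the
sensitivity of absolute-mode distances to error in load quantification.

Both permutation tests use the add-one convention
p = (1 + #{permuted statistic at least as extreme}) / (1 + permutations),
so p is never exactly 0, and all randomness is driven by an explicit seed.
"""

from __future__ import annotations

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

__all__ = [
    "MantelResult",
    "PermanovaResult",
    "load_difference_matrix",
    "mantel",
    "permanova",
    "error_sensitivity",
]


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    permutations: int
    n_samples: int
    seed: int


@dataclass(frozen=True)
class PermanovaResult:
    r_squared: float
    pseudo_f: float
    p_value: float
    permutations: int
    group_sizes: dict
    ss_between: float
    ss_within: float
    ss_total: float
    seed: int


def load_difference_matrix(loads: LoadVector, log10: bool = False) -> DistanceMatrix:
    """Pairwise |N_a - N_b| of total loads (optionally on log10 loads).

    This is the comparator used to ask how strongly a dissimilarity metric
    is driven by biomass differences alone.
    """
    vals = loads.loads.to_numpy(dtype=float)
    if len(vals) < 2:
        raise ValidationError("need at least 2 samples")
    if log10:
        vals = np.log10(vals)
    diff = np.abs(vals[:, None] - vals[None, :])
    return DistanceMatrix(diff, ids=loads.samples)


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    permutations: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel test: Pearson correlation of two distance matrices.

    Matrices are matched by label (reordered, not assumed positionally
    aligned).  R is the Pearson correlation of the strictly-upper-triangle
    vectors; the permutation null simultaneously permutes rows and columns
    of the second matrix; the test is two-sided on |R|.

    With ``exhaustive=True`` all n! relabelings are enumerated (small n
    only) and p = #{|R*| >= |R|} / n! (the identity guarantees p > 0);
    otherwise p uses the Monte-Carlo add-one convention.
    """
    if set(d1.ids) != set(d2.ids):
        raise ValidationError("distance matrices have mismatched sample labels")
    d2 = d2.filter(d1.ids)
    x = _upper(d1.data)
    y = _upper(d2.data)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined: constant distance triangle")
    r = float(np.corrcoef(x, y)[0, 1])
    n = d1.shape[0]
    m2 = d2.data

    def _stat(perm):
        return abs(np.corrcoef(x, _upper(m2[np.ix_(perm, perm)]))[0, 1])

    if exhaustive:
        import itertools, math

        hits = sum(_stat(np.array(p)) >= abs(r) - 1e-12
                   for p in itertools.permutations(range(n)))
        total = math.factorial(n)
        return MantelResult(r=r, p_value=hits / total, permutations=total,
                            n_samples=n, seed=seed)
    rng = np.random.default_rng(seed)
    hits = sum(_stat(rng.permutation(n)) >= abs(r) - 1e-12 for _ in range(permutations))
    p = (1 + hits) / (1 + permutations)
    return MantelResult(r=r, p_value=p, permutations=permutations, n_samples=n, seed=seed)


def _permanova_ss(sq: np.ndarray, labels: np.ndarray, groups: np.ndarray):
    """SS decomposition on squared distances for one labeling.

    The matrix is symmetric with zero diagonal, so sum_{i<j in S} d2 equals
    half the full submatrix sum.
    """
    n = sq.shape[0]
    ss_total = sq.sum() / 2.0 / n
    ss_within = 0.0
    for g in groups:
        ix = np.flatnonzero(labels == g)
        if len(ix) > 1:
            ss_within += sq[np.ix_(ix, ix)].sum() / 2.0 / len(ix)
    return ss_total, ss_within


def permanova(
    dm: DistanceMatrix,
    groups,
    permutations: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = sum_{i<j} d2_ij / n, SS_within pools the analogous sums per
    group, pseudo-F = (SS_between/(g-1)) / (SS_within/(n-g)) and
    R^2 = SS_between / SS_total.  ``groups`` maps sample id -> label (dict
    or pandas Series).

    ``exhaustive=True`` enumerates all n! label orders (small n only) with
    p = #{F* >= F} / n!; otherwise Monte-Carlo with the add-one convention.
    """
    labels_map = pd.Series(groups)
    missing = [s for s in dm.ids if s not in labels_map.index]
    if missing:
        raise ValidationError(f"samples without a group label: {missing[:5]}")
    labels = labels_map.reindex(dm.ids).to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    n, g = dm.shape[0], len(uniq)
    if g < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    if g >= n:
        raise ValidationError("more groups than residual degrees of freedom allow")
    sq = dm.data**2
    ss_total, ss_within = _permanova_ss(sq, labels, uniq)
    ss_between = ss_total - ss_within
    f = (ss_between / (g - 1)) / (ss_within / (n - g)) if ss_within > 0 else np.inf
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    def _f_for(perm_labels):
        st, sw = _permanova_ss(sq, perm_labels, uniq)
        return ((st - sw) / (g - 1)) / (sw / (n - g)) if sw > 0 else np.inf

    if exhaustive:
        import itertools, math

        hits = sum(_f_for(labels[np.array(pm)]) >= f - 1e-12
                   for pm in itertools.permutations(range(n)))
        total = math.factorial(n)
        p = hits / total
        permutations = total
    else:
        rng = np.random.default_rng(seed)
        hits = sum(_f_for(labels[rng.permutation(n)]) >= f - 1e-12
                   for _ in range(permutations))
        p = (1 + hits) / (1 + permutations)
    return PermanovaResult(
        r_squared=float(r2),
        pseudo_f=float(f),
        p_value=p,
        permutations=permutations,
        group_sizes={str(u): int(c) for u, c in zip(uniq, counts)},
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        ss_total=float(ss_total),
        seed=seed,
    )


def _offdiag_abs_delta(a: np.ndarray, b: np.ndarray):
    d = np.abs(a - b)
    tri = d[np.triu_indices(d.shape[0], k=1)]
    return tri.mean(), tri.max()


def error_sensitivity(
    table: CountTable,
    tree: PhyloTree | None,
    loads: LoadVector,
    spec: MetricSpec,
    error_percents,
    iterations: int = 50,
    seed: int = 0,
    distribution: str = "uniform",
) -> pd.DataFrame:
    """Sensitivity of an absolute-mode metric to error in load estimates.

    Per iteration every sample's load N_s is perturbed to N_s * (1 + u)
    with u ~ Uniform(-e, +e) (the minimal reading of "random variation in
    either direction"; a normal alternative truncated to +-e is available
    via ``distribution='normal'``), the distance matrix is recomputed, and
    the mean and max |delta| over off-diagonal entries relative to the
    unperturbed matrix are recorded, then averaged over iterations.

    Returns a tidy DataFrame with one row per (error level[, alpha]):
    columns ``error_percent``, optionally ``alpha``, ``mean_abs_dev``,
    ``max_abs_dev``, ``sd_mean_abs_dev``.
    """
    if spec.weighting != "absolute":
        raise ValidationError("error sensitivity applies to absolute-mode metrics")
    errors = [float(e) for e in error_percents]
    if any(e < 0 or e >= 100 for e in errors):
        raise ValidationError("error percents must lie in [0, 100); loads must stay positive")
    generalized = spec.family == "unifrac_generalized"
    base = pairwise_distances(table, tree, spec, loads)
    base_mats = base if generalized else {None: base}

    load_vals = loads.loads.to_numpy(dtype=float)
    rows = []
    for e in errors:
        frac = e / 100.0
        per_iter = {a: [] for a in base_mats}
        for k in range(iterations):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(int(round(e * 100)), k))
            )
            if frac == 0:
                u = np.zeros_like(load_vals)
            elif distribution == "uniform":
                u = rng.uniform(-frac, frac, size=load_vals.shape)
            elif distribution == "normal":
                u = np.clip(rng.normal(0.0, frac / 2, size=load_vals.shape), -frac, frac)
            else:
                raise ValidationError(f"unknown error distribution {distribution!r}")
            pert = LoadVector(pd.Series(load_vals * (1 + u), index=loads.samples))
            dm = pairwise_distances(table, tree, spec, pert)
            mats = dm if generalized else {None: dm}
            for a, m in mats.items():
                per_iter[a].append(_offdiag_abs_delta(m.data, base_mats[a].data))
        for a, stats_list in per_iter.items():
            means = np.array([s[0] for s in stats_list])
            maxes = np.array([s[1] for s in stats_list])
            row = {
                "error_percent": e,
                "mean_abs_dev": float(means.mean()),
                "max_abs_dev": float(maxes.mean()),
                "sd_mean_abs_dev": float(means.std(ddof=1)) if iterations > 1 else 0.0,
            }
            if a is not None:
                row["alpha"] = a
            rows.append(row)
    return pd.DataFrame(rows)
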