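"""Cross-level statistics linking clonal clusters and bacterial families.

Family-level 16S read counts are normalized to relative abundances
(rare families pooled as "Other"); family and clonal-cluster
trajectories are co-clustered under the shape-based distance
SBD = 1 - max_w CC_w(x, y) / (||x|| ||y||), an amplitude- and
phase-tolerant dissimilarity; the degree of intermixing between clones
and families in the resulting tree is measured as
D_cm = 1 - sup|F(c) - F(m)|, a Kolmogorov-Smirnov-type comparison of
the cophenetic distance distributions of clone-clone vs clone-family
pairs; and the sharing of barcodes between clonal clusters is tested
with the overlap coefficient OC = |A n B| / min(|A|, |B|) against a
resampled null expressed as a z-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm as normal_dist

from .lineage import ClonalCluster, _log_with_zero_replacement, _numeric_timepoints

__all__ = [
    "CoclusterResult",
    "MixingResult",
    "OverlapResult",
    "relative_abundance",
    "znormalize",
    "sbd",
    "cocluster",
    "mixing_index",
    "overlap_significance",
]


@dataclass
class CoclusterResult:
    """UPGMA tree over the union of family and clone trajectories."""

    labels: list[str]
    sbd_matrix: pd.DataFrame
    linkage_matrix: np.ndarray
    clone_labels: list[str]
    family_labels: list[str]


@dataclass
class MixingResult:
    D_cm: float
    clone_clone_distances: np.ndarray
    clone_family_distances: np.ndarray


@dataclass
class OverlapResult:
    oc: float
    null_mean: float
    null_sd: float
    z: float | None
    p_value: float | None


def relative_abundance(
    counts: pd.DataFrame, other_threshold: float = 1e-3
) -> pd.DataFrame:
    """Column-normalize family read counts; pool rare families as "Other".

    Families whose mean fraction across timepoints falls below
    ``other_threshold`` are summed into a single "Other" row.
    All-zero columns are dropped with a warning.
    """
    totals = counts.sum(axis=0)
    zero_cols = totals.index[totals == 0].tolist()
    if zero_cols:
        warnings.warn(f"dropping all-zero timepoint columns: {zero_cols}")
        counts = counts.drop(columns=zero_cols)
        totals = totals.drop(zero_cols)
    fracs = counts.div(totals, axis=1)
    if fracs.shape[0] <= 1:
        return fracs
    rare = fracs.mean(axis=1) < other_threshold
    if not rare.any():
        return fracs
    other = fracs.loc[rare].sum(axis=0)
    out = fracs.loc[~rare]
    out.loc["Other"] = other
    return out


def znormalize(trajectory: np.ndarray) -> np.ndarray:
    """Center to mean 0, scale to SD 1; constant series map to zeros."""
    x = np.asarray(trajectory, dtype=float)
    if x.size < 2:
        raise ValueError("z-normalization needs at least 2 points")
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _cross_correlations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """CC_w(x, y) over all integer shifts w in (-L, L), zero-padded."""
    return np.correlate(x, y, mode="full")


def sbd(x: np.ndarray, y: np.ndarray) -> float:
    """Shape-based distance between two z-normalized trajectories.

    1 - max over shifts of the normalized cross-correlation; in [0, 2].
    Zero-norm input (a flagged constant series) yields the uninformative
    value 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("inputs must share a length of at least 2")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        warnings.warn("zero-norm input to sbd; distance defined as 1")
        return 1.0
    cc = _cross_correlations(x, y) / (nx * ny)
    return float(1.0 - cc.max())


def _prepare_series(values: np.ndarray) -> np.ndarray:
    return znormalize(values)


def cocluster(
    families: pd.DataFrame,
    clones: list[ClonalCluster],
    min_family_nonzero: int = 7,
) -> CoclusterResult:
    """SBD matrix + UPGMA tree over family and clonal-cluster trajectories.

    Families need at least ``min_family_nonzero`` nonzero timepoints;
    their relative abundances are log-transformed (half-minimum zero
    replacement) before z-normalization.  Clone consensus curves are
    already on a log scale.  Family series sampled on a different grid
    are linearly interpolated onto the clone grid.
    """
    if not clones:
        raise ValueError("no clonal clusters supplied")
    clone_grid = _numeric_timepoints(clones[0].timepoints)

    eligible = families[(families > 0).sum(axis=1) >= min_family_nonzero]
    series: dict[str, np.ndarray] = {}
    if eligible.shape[0] > 0:
        logged = _log_with_zero_replacement(eligible)
        fam_grid = _numeric_timepoints(list(eligible.columns))
        for fam, row in logged.iterrows():
            vals = row.to_numpy(dtype=float)
            if not np.array_equal(fam_grid, clone_grid):
                vals = np.interp(clone_grid, fam_grid, vals)
            series[str(fam)] = _prepare_series(vals)
    family_labels = sorted(series)
    clone_labels = []
    for c in clones:
        series[c.label] = _prepare_series(np.asarray(c.consensus, dtype=float))
        clone_labels.append(c.label)

    labels = family_labels + clone_labels
    if len(labels) < 2:
        raise ValueError("need at least 2 eligible trajectories to co-cluster")
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = sbd(series[labels[i]], series[labels[j]])
    Z = linkage(squareform(D, checks=False), method="average")
    return CoclusterResult(
        labels=labels,
        sbd_matrix=pd.DataFrame(D, index=labels, columns=labels),
        linkage_matrix=Z,
        clone_labels=clone_labels,
        family_labels=family_labels,
    )


def _ecdf_sup_distance(a: np.ndarray, b: np.ndarray) -> float:
    """sup |F_a - F_b| over the pooled support (two-sample KS statistic)."""
    grid = np.union1d(a, b)
    Fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
    Fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return float(np.max(np.abs(Fa - Fb)))


def mixing_index(result: CoclusterResult) -> MixingResult:
    """Clone/family intermixing in the co-clustering tree.

    F(c) is the ECDF of cophenetic distances among clone-clone pairs,
    F(m) that of clone-family pairs; D_cm = 1 - sup|F(c) - F(m)|.
    Values near 1 mean clones and families intermix in the tree.
    """
    if len(result.clone_labels) < 2 or len(result.family_labels) < 2:
        raise ValueError("mixing index needs >= 2 clones and >= 2 families")
    coph = squareform(cophenet(result.linkage_matrix))
    pos = {lab: i for i, lab in enumerate(result.labels)}
    cc = [
        coph[pos[a], pos[b]]
        for i, a in enumerate(result.clone_labels)
        for b in result.clone_labels[i + 1 :]
    ]
    cm = [
        coph[pos[a], pos[b]]
        for a in result.clone_labels
        for b in result.family_labels
    ]
    cc_arr, cm_arr = np.asarray(cc), np.asarray(cm)
    D = 1.0 - _ecdf_sup_distance(cc_arr, cm_arr)
    return MixingResult(D_cm=float(D), clone_clone_distances=cc_arr,
                        clone_family_distances=cm_arr)


def overlap_significance(
    A: set,
    B: set,
    universe: set,
    n_boot: int = 1000,
    seed: int = 0,
) -> OverlapResult:
    """Overlap coefficient of two barcode sets with a resampling null.

    OC = |A n B| / min(|A|, |B|).  The null draws subsets of sizes |A|
    and |B| uniformly without replacement from ``universe`` and records
    their OC; significance is the z-score of the observed value on that
    distribution with a two-sided normal p-value.
    """
    A, B, universe = set(A), set(B), set(universe)
    if not A or not B:
        raise ValueError("A and B must be non-empty")
    if not (A <= universe and B <= universe):
        raise ValueError("A and B must be subsets of the universe")
    oc = len(A & B) / min(len(A), len(B))
    pool = np.array(sorted(universe))
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_boot)
    for i in range(n_boot):
        a = rng.choice(pool, size=len(A), replace=False)
        b = rng.choice(pool, size=len(B), replace=False)
        nulls[i] = np.intersect1d(a, b).size / min(len(A), len(B))
    mu, sd = float(nulls.mean()), float(nulls.std(ddof=1))
    if sd == 0:
        return OverlapResult(oc=float(oc), null_mean=mu, null_sd=0.0, z=None, p_value=None)
    z = (oc - mu) / sd
    p = 2.0 * normal_dist.sf(abs(z))
    return OverlapResult(oc=float(oc), null_mean=mu, null_sd=sd, z=float(z), p_value=float(p))
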