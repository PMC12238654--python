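"""Barcode lineage analysis: frequencies, diversity, clonal clusters.

A barcode-by-time count table is normalized to frequencies; lineage
diversity is summarized by Hill numbers qD = (sum f^q)^(1/(1-q)) for
q in {0, 1, inf}; persistent lineages are clustered by the distance
dF_ij = 1 - rho(log f_i, log f_j) (Pearson correlation of log-frequency
trajectories) with UPGMA linkage; each retained cluster is summarized
by a LOESS consensus curve and ranked C1, C2, ... by average frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "DiversityProfile",
    "ClonalCluster",
    "barcode_frequencies",
    "diversity_profile",
    "persistence_filter",
    "lineage_distances",
    "cluster_lineages",
    "loess_consensus",
    "select_threshold",
]


@dataclass
class DiversityProfile:
    """Hill numbers per timepoint for q in {0, 1, inf}."""

    timepoints: list
    q0: np.ndarray  # richness
    q1: np.ndarray  # exp(Shannon entropy)
    qinf: np.ndarray  # 1 / max frequency

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"q0": self.q0, "q1": self.q1, "qinf": self.qinf}, index=self.timepoints
        )


@dataclass
class ClonalCluster:
    """A group of correlated barcode lineages and its consensus trajectory."""

    label: str
    members: list[str]
    consensus: np.ndarray  # log10-frequency consensus over timepoints
    mean_frequency: float
    timepoints: list = field(default_factory=list)


def barcode_frequencies(table: pd.DataFrame) -> pd.DataFrame:
    """Column-normalize read counts to frequencies; drop all-zero columns."""
    totals = table.sum(axis=0)
    zero_cols = totals.index[totals == 0].tolist()
    if zero_cols:
        warnings.warn(f"dropping all-zero timepoint columns: {zero_cols}")
        table = table.drop(columns=zero_cols)
        totals = totals.drop(zero_cols)
    return table.div(totals, axis=1)


def diversity_profile(freqs: pd.DataFrame) -> DiversityProfile:
    """Hill diversity of each timepoint column.

    q0 counts nonzero lineages; q1 is the exponential of the Shannon
    entropy over nonzero frequencies; qinf is the reciprocal of the
    dominant lineage's frequency.
    """
    f = freqs.to_numpy(dtype=float)
    q0 = (f > 0).sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log(f), 0.0)
    q1 = np.exp(-plogp.sum(axis=0))
    fmax = f.max(axis=0)
    qinf = np.where(fmax > 0, 1.0 / np.where(fmax > 0, fmax, 1.0), np.nan)
    q1 = np.where(q0 > 0, q1, np.nan)
    q0 = np.where(q0 > 0, q0, np.nan)
    return DiversityProfile(list(freqs.columns), q0, q1, qinf)


def persistence_filter(
    freqs: pd.DataFrame, min_timepoints: int = 12, min_mean_freq: float = 5e-5
) -> pd.DataFrame:
    """Keep lineages seen at >= min_timepoints timepoints with mean
    frequency >= min_mean_freq (both boundaries inclusive)."""
    if min_timepoints <= 0 or min_mean_freq <= 0:
        raise ValueError("thresholds must be positive")
    nonzero = (freqs > 0).sum(axis=1)
    meanf = freqs.mean(axis=1)
    keep = (nonzero >= min_timepoints) & (meanf >= min_mean_freq)
    return freqs.loc[keep]


def _log_with_zero_replacement(freqs: pd.DataFrame) -> pd.DataFrame:
    """log10 frequencies; zeros replaced by half the smallest positive value."""
    vals = freqs.to_numpy(dtype=float)
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ValueError("frequency table has no positive entries")
    repl = pos.min() / 2.0
    return pd.DataFrame(
        np.log10(np.where(vals > 0, vals, repl)), index=freqs.index, columns=freqs.columns
    )


def lineage_distances(freqs: pd.DataFrame, min_overlap: int = 4) -> pd.DataFrame:
    """Pairwise trajectory distance dF = 1 - Pearson(log f_i, log f_j).

    Correlation is computed over timepoints where both lineages are
    nonzero (pairwise-complete); when fewer than ``min_overlap`` such
    points exist, the zero-replaced log values over all timepoints are
    used instead.  Lineages with zero-variance log-trajectories are
    excluded with a warning.
    """
    if freqs.shape[0] < 2:
        raise ValueError("need at least 2 lineages")
    logged = _log_with_zero_replacement(freqs).to_numpy()
    raw = freqs.to_numpy(dtype=float)
    ids = list(freqs.index)

    variable = [i for i in range(len(ids)) if np.std(logged[i]) > 0]
    dropped = [ids[i] for i in range(len(ids)) if i not in variable]
    if dropped:
        warnings.warn(f"excluding zero-variance trajectories: {dropped}")
    n = len(variable)
    if n < 2:
        raise ValueError("fewer than 2 lineages with variable trajectories")
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            i, j = variable[a], variable[b]
            both = (raw[i] > 0) & (raw[j] > 0)
            if both.sum() >= min_overlap:
                xi, xj = np.log10(raw[i][both]), np.log10(raw[j][both])
            else:
                xi, xj = logged[i], logged[j]
            si, sj = np.std(xi), np.std(xj)
            rho = float(np.corrcoef(xi, xj)[0, 1]) if si > 0 and sj > 0 else 0.0
            D[a, b] = D[b, a] = 1.0 - rho
    D = np.clip(D, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    kept = [ids[i] for i in variable]
    return pd.DataFrame(D, index=kept, columns=kept)


def cluster_lineages(
    distances: pd.DataFrame,
    freqs: pd.DataFrame,
    threshold: float,
    min_cluster_size: int = 8,
    span: float = 0.3,
) -> list[ClonalCluster]:
    """UPGMA clustering of the lineage distance matrix, cut at ``threshold``.

    Clusters below ``min_cluster_size`` are discarded; survivors are
    summarized by a LOESS consensus of their members' log-frequencies
    and ranked C1, C2, ... by descending average member frequency.
    """
    if not 0 < threshold < 2:
        raise ValueError("threshold must be in (0, 2)")
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")
    ids = list(distances.index)
    Z = linkage(squareform(distances.to_numpy(), checks=False), method="average")
    labels = fcluster(Z, t=threshold, criterion="distance")

    timepoints = list(freqs.columns)
    tvals = _numeric_timepoints(timepoints)
    clusters = []
    for lab in np.unique(labels):
        members = [ids[i] for i in np.flatnonzero(labels == lab)]
        if len(members) < min_cluster_size:
            continue
        sub = freqs.loc[members]
        consensus = loess_consensus(sub, span=span)
        mean_freq = float(sub.mean(axis=1).mean())
        clusters.append(
            ClonalCluster(
                label="",
                members=sorted(members),
                consensus=consensus,
                mean_frequency=mean_freq,
                timepoints=timepoints,
            )
        )
    clusters.sort(key=lambda c: (-c.mean_frequency, c.members[0]))
    for rank, c in enumerate(clusters, start=1):
        c.label = f"C{rank}"
    return clusters


def _numeric_timepoints(cols: list) -> np.ndarray:
    try:
        return np.asarray([float(c) for c in cols])
    except (TypeError, ValueError):
        return np.arange(len(cols), dtype=float)


def loess_consensus(member_freqs: pd.DataFrame, span: float = 0.3) -> np.ndarray:
    """LOESS consensus (tricube weights, locally linear) of pooled
    member log10-frequencies, evaluated at the observed timepoints."""
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if member_freqs.shape[0] < 1:
        raise ValueError("need at least one member")
    logged = _log_with_zero_replacement(member_freqs).to_numpy()
    t = _numeric_timepoints(list(member_freqs.columns))
    x = np.tile(t, logged.shape[0])
    y = logged.ravel()
    # local linear fits need >= 3 points in the window; widen the span on
    # very short series rather than returning NaN
    frac = max(span, min(1.0, 3.0 / t.size))
    # statsmodels lowess: locally weighted linear regression with tricube weights
    fitted = lowess(y, x, frac=frac, return_sorted=False, xvals=t)
    return np.asarray(fitted, dtype=float)


def select_threshold(
    distances: pd.DataFrame,
    freqs: pd.DataFrame,
    candidate_thresholds: np.ndarray,
    min_cluster_size: int = 8,
    span: float = 0.3,
) -> float:
    """Pick the cut height where cluster count and cluster separation cross.

    For each candidate threshold, compute the number of retained
    clusters and the minimum pairwise distance between cluster consensus
    curves; min-max normalize both over the candidates and return the
    first candidate where normalized separation >= normalized count.
    Falls back to the largest candidate (with a warning) when the curves
    never cross or clustering is degenerate everywhere.
    """
    cands = np.asarray(sorted(candidate_thresholds), dtype=float)
    if cands.size < 3:
        raise ValueError("need at least 3 candidate thresholds")
    n_clusters = np.zeros(cands.size)
    min_sep = np.full(cands.size, np.nan)
    for k, thr in enumerate(cands):
        clusters = cluster_lineages(distances, freqs, thr, min_cluster_size, span)
        n_clusters[k] = len(clusters)
        if len(clusters) >= 2:
            curves = np.array([c.consensus for c in clusters])
            d = [
                np.linalg.norm(curves[a] - curves[b])
                for a in range(len(curves))
                for b in range(a + 1, len(curves))
            ]
            min_sep[k] = min(d)
    valid = n_clusters >= 2
    if not valid.any():
        warnings.warn("clustering degenerate at every threshold; returning largest")
        return float(cands[-1])

    def norm(v: np.ndarray) -> np.ndarray:
        lo, hi = np.nanmin(v), np.nanmax(v)
        return (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)

    ns, nc = norm(min_sep), norm(n_clusters)
    crossing = np.flatnonzero(valid & (ns >= nc))
    if crossing.size == 0:
        warnings.warn("separation and cluster-count curves never cross; returning largest")
        return float(cands[-1])
    return float(cands[crossing[0]])
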