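"""Phase detection on eigenvalue trajectories.

The windows-by-2N eigenvalue matrix is reduced with kernel PCA; the
(PC1, PC2) plane is mapped to two univariate summaries (distance from
the origin and planar angle, mirroring the geometric-mapping approach
to multivariate changepoint analysis); changepoints are detected on
both series under an ensemble of penalties and quantile settings; and
boundaries recurring across the ensemble are merged into consensus
phase boundaries graded ***, ** or *.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import KernelPCA

from .changepoint import PENALTIES, ChangepointRun, detect_changepoints
from .spectral import EigenTrajectoryMatrix

__all__ = [
    "PCSeries",
    "PhaseBoundary",
    "PhaseSegmentation",
    "kernel_pca",
    "geometric_map",
    "changepoint_ensemble",
    "consensus_phases",
    "detect_phases",
]

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX"]


@dataclass
class PCSeries:
    window_indices: list[int]
    pc1: np.ndarray
    pc2: np.ndarray
    explained_variance_fraction: np.ndarray

    def __len__(self) -> int:
        return self.pc1.size


@dataclass
class PhaseBoundary:
    index: int  # 1-based first window of the new phase
    grade: str  # "***", "**" or "*"
    support: float  # fraction of runs containing the boundary


@dataclass
class PhaseSegmentation:
    boundaries: list[PhaseBoundary]
    n_windows: int
    phases: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.phases:
            edges = [1, *[b.index for b in self.boundaries], self.n_windows + 1]
            self.phases = [
                (_ROMAN[i], a, b - 1) for i, (a, b) in enumerate(zip(edges, edges[1:]))
            ]


def _median_heuristic_gamma(X: np.ndarray) -> float:
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    return 1.0 / med if med > 0 else 1.0


def kernel_pca(
    matrix: EigenTrajectoryMatrix,
    kernel: str = "linear",
    n_components: int = 2,
) -> PCSeries:
    """Kernel PCA of the eigenvalue trajectory.

    The linear kernel reproduces classical PCA; 'rbf' uses a
    median-heuristic bandwidth.  Scores are deterministic up to sign,
    fixed so the largest-magnitude score of each component is positive.
    Explained-variance fractions are eigenvalues of the centered kernel
    matrix relative to its trace.
    """
    X = matrix.values
    s = X.shape[0]
    if s < 2:
        raise ValueError("kernel PCA needs at least 2 windows")
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    if kernel not in ("linear", "rbf"):
        raise ValueError("kernel must be 'linear' or 'rbf'")

    if np.allclose(X, X[0], atol=1e-300) or np.ptp(X, axis=0).max() == 0:
        zeros = np.zeros(s)
        return PCSeries(matrix.window_indices, zeros, zeros.copy(), np.zeros(n_components))

    kwargs = {}
    if kernel == "rbf":
        kwargs["gamma"] = _median_heuristic_gamma(X)
    kp = KernelPCA(n_components=n_components, kernel=kernel, **kwargs)
    scores = kp.fit_transform(X)
    # pad in case degenerate input yields fewer components
    if scores.shape[1] < n_components:
        pad = np.zeros((s, n_components - scores.shape[1]))
        scores = np.hstack([scores, pad])
    eigvals = np.zeros(n_components)
    eigvals[: kp.eigenvalues_.size] = np.maximum(kp.eigenvalues_, 0.0)

    # total variance = trace of the doubly centered kernel matrix
    from sklearn.metrics.pairwise import pairwise_kernels

    K = pairwise_kernels(X, metric=kernel, **kwargs)
    one = np.full((s, s), 1.0 / s)
    Kc = K - one @ K - K @ one + one @ K @ one
    total = float(np.trace(Kc))
    frac = eigvals / total if total > 0 else np.zeros(n_components)

    for j in range(scores.shape[1]):
        col = scores[:, j]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            scores[:, j] = -col
    return PCSeries(matrix.window_indices, scores[:, 0], scores[:, 1], frac)


def geometric_map(pcs: PCSeries) -> tuple[np.ndarray, np.ndarray]:
    """Map (PC1, PC2) points to distance-from-origin and angle series.

    Angle is in [0, 2*pi); the origin's angle is defined as 0.
    """
    if len(pcs) < 4:
        raise ValueError("geometric mapping needs at least 4 windows")
    dist = np.hypot(pcs.pc1, pcs.pc2)
    ang = np.mod(np.arctan2(pcs.pc2, pcs.pc1), 2 * np.pi)
    ang[dist == 0] = 0.0
    return dist, ang


def changepoint_ensemble(
    pcs: PCSeries,
    penalties: tuple[str, ...] = PENALTIES,
    quantile_settings: tuple[int, ...] = (10, 20),
) -> list[ChangepointRun]:
    """Detection runs over both mapped series x penalties x quantile settings."""
    dist, ang = geometric_map(pcs)
    runs = []
    for label, series in (("distance", dist), ("angle", ang)):
        for pen in penalties:
            for nq in quantile_settings:
                runs.append(
                    detect_changepoints(series, penalty=pen, n_quantiles=nq,
                                        series_label=label)
                )
    return runs


def consensus_phases(
    runs: list[ChangepointRun],
    n_windows: int,
    tolerance_windows: int = 1,
) -> PhaseSegmentation:
    """Merge boundaries recurring across runs and grade the consensus.

    Boundaries within ±tolerance_windows are merged (medoid index kept).
    Grades: *** when the merged boundary appears in runs of all four
    penalty criteria, ** when in >= 90% of runs, * when in >= 70%;
    otherwise the boundary is discarded.
    """
    if not runs:
        raise ValueError("empty run list")
    events = []  # (boundary index, run id, penalty)
    for rid, run in enumerate(runs):
        for b in run.boundaries:
            events.append((b, rid, run.penalty))
    if not events:
        return PhaseSegmentation(boundaries=[], n_windows=n_windows)
    events.sort()
    groups: list[list[tuple[int, int, str]]] = [[events[0]]]
    for ev in events[1:]:
        if ev[0] - groups[-1][-1][0] <= tolerance_windows:
            groups[-1].append(ev)
        else:
            groups.append([ev])

    n_runs = len(runs)
    out = []
    for grp in groups:
        idxs = np.array([g[0] for g in grp])
        support_runs = {g[1] for g in grp}
        pens = {g[2] for g in grp}
        support = len(support_runs) / n_runs
        if pens >= set(PENALTIES):
            grade = "***"
        elif support >= 0.9:
            grade = "**"
        elif support >= 0.7:
            grade = "*"
        else:
            continue
        # medoid: member minimizing total absolute deviation (lower on ties)
        medoid = int(idxs[np.argmin([np.abs(idxs - i).sum() for i in idxs])])
        out.append(PhaseBoundary(index=medoid, grade=grade, support=support))
    out.sort(key=lambda b: b.index)
    return PhaseSegmentation(boundaries=out, n_windows=n_windows)


def detect_phases(
    matrix: EigenTrajectoryMatrix,
    kernel: str = "linear",
    tolerance_windows: int = 1,
    quantile_settings: tuple[int, ...] = (10, 20),
) -> PhaseSegmentation:
    """Full chain: kernel PCA -> geometric map -> ensemble -> consensus."""
    pcs = kernel_pca(matrix, kernel=kernel)
    runs = changepoint_ensemble(pcs, quantile_settings=quantile_settings)
    return consensus_phases(runs, n_windows=matrix.n_windows,
                            tolerance_windows=tolerance_windows)
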