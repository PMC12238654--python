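"""Covariance estimation of the community interaction matrix.

Given a member-by-time abundance matrix z_i(t), the overall interaction
strength of member j on member i near a reference time is estimated as
J_ij = Cov(f_i, z_j), where f_i = dz_i/dt is the population growth rate;
the per-capita interaction strength is a_ij = Cov(phi_i, z_j) with
phi_i = f_i / z_i.  The two matrices are related by J = diag(z) A when z
is near-constant in the window.  Estimates are computed over a sequence
of expanding time windows, all anchored at the first sample, yielding a
time-resolved ("dynamic") map of the interaction network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AbundanceSeries",
    "GrowthRateSeries",
    "WindowSpec",
    "InteractionEstimate",
    "estimate_growth_rates",
    "expanding_windows",
    "estimate_interactions",
    "jacobian_trajectory",
]


@dataclass
class AbundanceSeries:
    """Member-by-timepoint abundance matrix with explicit timestamps.

    ``kind`` distinguishes relative abundances (columns sum to <= 1) from
    absolute counts/densities; the estimator itself is agnostic.
    """

    member_ids: list[str]
    timestamps: np.ndarray
    abundances: np.ndarray
    kind: str = "absolute"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.abundances = np.atleast_2d(np.asarray(self.abundances, dtype=float))
        self.member_ids = list(self.member_ids)
        if len(self.member_ids) != len(set(self.member_ids)):
            dupes = {m for m in self.member_ids if self.member_ids.count(m) > 1}
            raise ValueError(f"duplicate member ids: {sorted(dupes)}")
        if self.abundances.shape != (len(self.member_ids), self.timestamps.size):
            raise ValueError("abundances must be members x timestamps")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be non-negative")
        if self.kind not in ("relative", "absolute"):
            raise ValueError("kind must be 'relative' or 'absolute'")
        if self.kind == "relative" and np.any(self.abundances.sum(axis=0) > 1 + 1e-6):
            raise ValueError("relative abundance columns must sum to <= 1")

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    @property
    def n_times(self) -> int:
        return self.timestamps.size

    def select(self, members: list[str]) -> "AbundanceSeries":
        idx = [self.member_ids.index(m) for m in members]
        return AbundanceSeries(members, self.timestamps, self.abundances[idx], self.kind)


@dataclass
class GrowthRateSeries:
    """Overall (f_i) and per-capita (phi_i) growth rates on the same grid."""

    overall_rates: np.ndarray
    per_capita_rates: np.ndarray
    timestamps: np.ndarray


@dataclass
class WindowSpec:
    """An inclusive index window [start_index, end_index] into the timestamps."""

    start_index: int
    end_index: int
    center: float
    width: float

    def __post_init__(self) -> None:
        if self.end_index - self.start_index < 2:
            raise ValueError("a window needs at least 3 samples")

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index + 1

    def slice(self) -> slice:
        return slice(self.start_index, self.end_index + 1)


@dataclass
class InteractionEstimate:
    """Per-window covariance estimates: overall J and per-capita A."""

    window: WindowSpec
    J: np.ndarray
    A: np.ndarray


def estimate_growth_rates(
    series: AbundanceSeries, floor_fraction: float = 1e-9
) -> GrowthRateSeries:
    """Growth rates by three-point finite differences on the irregular grid.

    Interior points use the second-order three-point Lagrange stencil;
    the two endpoints use the one-sided three-point stencil.  Per-capita
    rates divide by max(z, floor) where floor = ``floor_fraction`` times
    the series maximum, which avoids blow-ups at (near-)zero abundance
    while preserving the sign of f.
    """
    if series.n_times < 3:
        raise ValueError("growth-rate estimation needs at least 3 timepoints")
    z = series.abundances
    f = np.gradient(z, series.timestamps, axis=1, edge_order=2)
    floor = floor_fraction * max(z.max(), np.finfo(float).tiny)
    phi = f / np.maximum(z, floor)
    return GrowthRateSeries(overall_rates=f, per_capita_rates=phi, timestamps=series.timestamps)


def expanding_windows(series: AbundanceSeries, min_points: int = 3) -> list[WindowSpec]:
    """Windows anchored at the first timestamp, growing one sample at a time.

    A series of T timepoints yields T - min_points + 1 windows; the first
    holds ``min_points`` samples and the last spans the whole series.
    """
    if min_points < 3:
        raise ValueError("min_points must be >= 3")
    T = series.n_times
    if T < min_points:
        raise ValueError(f"series has {T} timepoints, fewer than min_points={min_points}")
    t = series.timestamps
    out = []
    for end in range(min_points - 1, T):
        out.append(
            WindowSpec(
                start_index=0,
                end_index=end,
                center=(t[0] + t[end]) / 2.0,
                width=float(t[end] - t[0]),
            )
        )
    return out


def _cross_cov(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sample cross-covariance (k-1 denominator) between rows of x and rows of y."""
    k = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    return xc @ yc.T / (k - 1)


def estimate_interactions(
    series: AbundanceSeries, rates: GrowthRateSeries, window: WindowSpec
) -> InteractionEstimate:
    """Covariance interaction estimate restricted to one window.

    J_ij = Cov(f_i, z_j) and a_ij = Cov(phi_i, z_j) with the unbiased
    k-1 denominator.  Zero-variance abundance rows yield zero covariance.
    """
    if window.end_index >= series.n_times:
        raise ValueError("window exceeds series length")
    sl = window.slice()
    z = series.abundances[:, sl]
    J = _cross_cov(rates.overall_rates[:, sl], z)
    A = _cross_cov(rates.per_capita_rates[:, sl], z)
    return InteractionEstimate(window=window, J=J, A=A)


def jacobian_trajectory(
    series: AbundanceSeries, min_points: int = 3
) -> list[InteractionEstimate]:
    """Interaction estimates over the full expanding-window schedule."""
    rates = estimate_growth_rates(series)
    return [
        estimate_interactions(series, rates, w)
        for w in expanding_windows(series, min_points)
    ]
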