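"""Nonparametric multiple-changepoint detection.

The cost of a candidate segment is the empirical-distribution cost of
Haynes, Fearnhead & Eckley: the series' distribution is summarized at K
quantile levels (tail-weighted), and each segment is scored by the
binomial log-likelihood of its points falling below each quantile.  The
optimal segmentation under a linear penalty on the number of
changepoints is found by exact dynamic programming (optimal
partitioning); series here are short (one value per analysis window), so
no pruning is needed.

Penalties (p = parameters per changepoint, T = series length):
  BIC = SIC : p * log T
  HQ        : p * log log T
  MBIC      : p * log T plus 3/2 * log(segment length) per segment
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChangepointRun", "detect_changepoints", "PENALTIES"]

PENALTIES = ("MBIC", "BIC", "SIC", "HQ")

#: parameters per changepoint entering the penalty
PARAMS_PER_CHANGEPOINT = 2


@dataclass
class ChangepointRun:
    """Result of one detection run: penalty, quantile count, boundaries.

    ``boundaries`` are 1-based indices of the first point of each new
    segment, strictly increasing and interior (in 2..T).
    """

    penalty: str
    n_quantiles: int
    boundaries: list[int]
    series_label: str = ""

    def __post_init__(self) -> None:
        if any(b >= c for b, c in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("boundaries must be strictly increasing")


def _quantile_levels(T: int, K: int) -> np.ndarray:
    """Tail-weighted probability levels at which the ECDF is summarized."""
    k = np.arange(1, K + 1)
    w = (2 * T - 1) ** (1 - (2 * k - 1) / K)
    return 1.0 / (1.0 + w)


def segment_cost_factory(series: np.ndarray, n_quantiles: int):
    """Return cost(s, e) for the inclusive 0-based segment [s, e].

    Cost is -(2 log(2T-1) / K) * sum over quantiles of the segment's
    binomial log-likelihood; ties at a quantile count one half.
    Precomputes cumulative indicator counts so each evaluation is O(K).
    """
    x = np.asarray(series, dtype=float)
    T = x.size
    K = n_quantiles
    probs = _quantile_levels(T, K)
    qs = np.quantile(x, probs)
    # cum_below[k, i] = #{x_j < q_k : j < i} + 0.5 #{x_j == q_k : j < i}
    below = (x[None, :] < qs[:, None]).astype(float) + 0.5 * (x[None, :] == qs[:, None])
    cum = np.concatenate([np.zeros((K, 1)), np.cumsum(below, axis=1)], axis=1)
    scale = 2.0 * np.log(2 * T - 1) / K

    def cost(s: int, e: int) -> float:
        n = e - s + 1
        f = (cum[:, e + 1] - cum[:, s]) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            inner = f * np.log(f) + (1 - f) * np.log(1 - f)
        inner = np.where((f > 0) & (f < 1), inner, 0.0)
        return -scale * n * float(inner.sum())

    return cost


def _penalty_value(penalty: str, T: int) -> float:
    p = PARAMS_PER_CHANGEPOINT
    if penalty in ("BIC", "SIC"):
        return p * np.log(T)
    if penalty == "HQ":
        return p * np.log(np.log(T))
    if penalty == "MBIC":
        return p * np.log(T)
    raise ValueError(f"unknown penalty {penalty!r}; choose from {PENALTIES}")


def detect_changepoints(
    series: np.ndarray,
    penalty: str = "MBIC",
    n_quantiles: int = 10,
    min_segment: int = 2,
    series_label: str = "",
) -> ChangepointRun:
    """Exact optimal segmentation of a univariate series.

    Returns the changepoint set minimizing total segment cost plus
    penalty per changepoint (MBIC additionally charges 3/2 log of each
    segment length).  ``min_segment`` is the smallest allowed segment.
    """
    x = np.asarray(series, dtype=float).ravel()
    T = x.size
    if T < 6:
        raise ValueError("changepoint detection needs at least 6 points")
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    cost = segment_cost_factory(x, n_quantiles)
    beta = _penalty_value(penalty, T)
    mbic = penalty == "MBIC"

    def seg(s: int, e: int) -> float:
        c = cost(s, e)
        if mbic:
            c += 1.5 * np.log(e - s + 1)
        return c

    # F[t] = optimal cost of x[0:t]; last segment starts at s (0-based)
    F = np.full(T + 1, np.inf)
    F[0] = -beta
    back = np.zeros(T + 1, dtype=int)
    for t in range(min_segment, T + 1):
        for s in range(0, t - min_segment + 1):
            if F[s] == np.inf:
                continue
            val = F[s] + seg(s, t - 1) + beta
            if val < F[t] - 1e-12:
                F[t] = val
                back[t] = s
    cps = []
    t = T
    while t > 0:
        s = back[t]
        if s > 0:
            cps.append(s + 1)  # 1-based first index of the new segment
        t = s
    return ChangepointRun(
        penalty=penalty,
        n_quantiles=n_quantiles,
        boundaries=sorted(cps),
        series_label=series_label,
    )
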