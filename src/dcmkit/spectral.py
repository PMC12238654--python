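"""Eigenvalue stability analysis of interaction-matrix trajectories.

The local dynamics around a reference state follow dz/dt = J z, whose
solution is a linear combination of modes exp(lambda_k t): a positive
real part Re(lambda) signals instability (exponentially growing
amplitude) and a nonzero imaginary part Im(lambda) signals oscillation
at that angular frequency.  Per window we therefore record the full
complex spectrum, and across windows we assemble a windows-by-2N matrix
of (Re, Im) pairs of the magnitude-ranked eigenvalues, the input to the
phase-detection stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dcm import InteractionEstimate

__all__ = [
    "EigenSpectrum",
    "StabilityLabel",
    "EigenTrajectoryMatrix",
    "eigen_decompose",
    "classify_stability",
    "assemble_eigen_matrix",
]


@dataclass
class EigenSpectrum:
    eigenvalues: np.ndarray  # complex, unordered
    eigenvectors: np.ndarray  # columns correspond to eigenvalues
    window_index: int | None = None


@dataclass
class StabilityLabel:
    is_unstable: bool
    is_oscillatory: bool
    leading_eigenvalue: complex


@dataclass
class EigenTrajectoryMatrix:
    """s windows x 2N columns of (Re, Im) of magnitude-ranked eigenvalues."""

    values: np.ndarray
    window_indices: list[int]

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_eigenvalues(self) -> int:
        return self.values.shape[1] // 2


def eigen_decompose(estimate: InteractionEstimate, which: str = "J") -> EigenSpectrum:
    """Full complex spectrum of a window's J (overall) or A (per-capita) matrix."""
    if which not in ("J", "A"):
        raise ValueError("which must be 'J' or 'A'")
    M = estimate.J if which == "J" else estimate.A
    if not np.all(np.isfinite(M)):
        raise ValueError("interaction matrix contains non-finite entries")
    vals, vecs = np.linalg.eig(M)
    return EigenSpectrum(eigenvalues=vals, eigenvectors=vecs)


def classify_stability(spectrum: EigenSpectrum, tol: float | None = None) -> StabilityLabel:
    """Stable/unstable and oscillatory flags at a scale-aware tolerance.

    Default tol is 1e-9 times the Frobenius-like scale of the spectrum,
    so that numerically-zero parts do not flip the labels.
    """
    lam = spectrum.eigenvalues
    if tol is None:
        scale = float(np.sqrt(np.sum(np.abs(lam) ** 2)))
        tol = 1e-9 * max(scale, np.finfo(float).tiny)
    if tol <= 0:
        raise ValueError("tol must be positive")
    leading = lam[int(np.argmax(lam.real))]
    return StabilityLabel(
        is_unstable=bool(np.max(lam.real) > tol),
        is_oscillatory=bool(np.max(np.abs(lam.imag)) > tol),
        leading_eigenvalue=complex(leading),
    )


def _rank_eigenvalues(lam: np.ndarray) -> np.ndarray:
    """Sort by descending |lambda|; ties by descending Re, then descending Im.

    The Im tie-break puts the +Im member of a conjugate pair first.
    """
    order = np.lexsort((-lam.imag, -lam.real, -np.abs(lam)))
    return lam[order]


def assemble_eigen_matrix(trajectory: list[EigenSpectrum]) -> EigenTrajectoryMatrix:
    """Stack magnitude-ranked (Re, Im) eigenvalue components across windows."""
    if not trajectory:
        raise ValueError("empty trajectory")
    N = trajectory[0].eigenvalues.size
    rows = []
    for spec in trajectory:
        if spec.eigenvalues.size != N:
            raise ValueError("all spectra must have the same dimension")
        lam = _rank_eigenvalues(np.asarray(spec.eigenvalues, dtype=complex))
        rows.append(np.column_stack([lam.real, lam.imag]).ravel())
    idx = [
        spec.window_index if spec.window_index is not None else i
        for i, spec in enumerate(trajectory)
    ]
    return EigenTrajectoryMatrix(values=np.array(rows), window_indices=idx)
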