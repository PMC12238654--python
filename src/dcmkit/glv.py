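"""Generalized Lotka-Volterra simulation and synthetic read generation.

The community model is the standard gLV system

    dz_i/dt = z_i * (r_i + sum_j a_ij z_j)

with an interaction matrix that may switch between regimes at scheduled
times (a piecewise-constant vector field).  The module also provides a
sequencing-read simulator for barcode lineage tracking: multinomial
template sampling, Galton-Watson PCR amplification (the source of
"jackpot" heavy tails), multinomial read sampling, and per-base
substitution/indel corruption of the barcode sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dcm import AbundanceSeries

__all__ = [
    "GLVModel",
    "TimeGrid",
    "ReadSimConfig",
    "simulate_glv",
    "make_switch_scenario",
    "simulate_barcode_reads",
    "planted_lineage_groups",
]

#: abundance below which a species is considered extinct and clamped to 0
EXTINCTION_FLOOR = 1e-12

_BASES = np.array(list("ACGT"))


@dataclass
class GLVModel:
    """A gLV community: growth rates plus a schedule of interaction matrices.

    ``interaction_schedule`` is an ordered list of ``(start_time, A)``
    pairs; matrix ``A[i]`` governs the dynamics from its start time until
    the next segment begins.
    """

    n_species: int
    growth_rates: np.ndarray
    interaction_schedule: list[tuple[float, np.ndarray]]
    initial_abundance: np.ndarray

    def __post_init__(self) -> None:
        self.growth_rates = np.asarray(self.growth_rates, dtype=float)
        self.initial_abundance = np.asarray(self.initial_abundance, dtype=float)
        n = self.n_species
        if n < 1:
            raise ValueError("n_species must be positive")
        if self.growth_rates.shape != (n,):
            raise ValueError("growth_rates must have length n_species")
        if self.initial_abundance.shape != (n,):
            raise ValueError("initial_abundance must have length n_species")
        if np.any(self.initial_abundance <= 0):
            raise ValueError("initial abundances must be strictly positive")
        if not self.interaction_schedule:
            raise ValueError("interaction_schedule must be non-empty")
        starts = [t for t, _ in self.interaction_schedule]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("schedule start times must be strictly increasing")
        self.interaction_schedule = [
            (float(t), np.asarray(A, dtype=float)) for t, A in self.interaction_schedule
        ]
        for _, A in self.interaction_schedule:
            if A.shape != (n, n):
                raise ValueError("every schedule matrix must be n_species x n_species")

    def matrix_at(self, t: float) -> np.ndarray:
        """Interaction matrix governing the dynamics at time ``t``."""
        A = self.interaction_schedule[0][1]
        for start, mat in self.interaction_schedule:
            if t >= start:
                A = mat
            else:
                break
        return A


@dataclass
class TimeGrid:
    """Strictly increasing sampling times (same unit as growth rates)."""

    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.ndim != 1 or self.timestamps.size < 2:
            raise ValueError("need at least 2 timestamps")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @classmethod
    def regular(cls, start: float, stop: float, step: float) -> "TimeGrid":
        n = int(round((stop - start) / step)) + 1
        return cls(np.linspace(start, stop, n))


@dataclass
class ReadSimConfig:
    """Parameters of the barcode read simulator.

    ``genomes_sampled`` is the effective number of template molecules
    going into PCR; ``per_cycle_efficiency`` is the probability that a
    molecule is duplicated in one cycle.
    """

    depth: int = 100_000
    pcr_cycles: int = 0
    per_cycle_efficiency: float = 1.0
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    genomes_sampled: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.pcr_cycles < 0:
            raise ValueError("pcr_cycles must be >= 0")
        for name in ("per_cycle_efficiency", "substitution_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _glv_rhs(t: float, z: np.ndarray, r: np.ndarray, A: np.ndarray) -> np.ndarray:
    z = np.maximum(z, 0.0)
    return z * (r + A @ z)


def simulate_glv(
    model: GLVModel,
    grid: TimeGrid,
    integrator_step: float = 1e-3,
    member_ids: list[str] | None = None,
) -> AbundanceSeries:
    """Integrate the gLV system and sample it on ``grid``.

    Integration is segment-wise between schedule boundaries (the matrix
    switch is a discontinuity of the vector field, so the adaptive
    Runge-Kutta integrator is re-initialized at each boundary).  Species
    falling below the extinction floor are clamped to zero.
    """
    if integrator_step <= 0:
        raise ValueError("integrator_step must be positive")
    min_spacing = float(np.min(np.diff(grid.timestamps)))
    if integrator_step > min_spacing:
        raise ValueError("integrator_step must not exceed the smallest grid spacing")

    times = grid.timestamps
    t0 = float(times[0])
    t_end = float(times[-1])
    # segment boundaries interior to the simulated interval
    boundaries = [s for s, _ in model.interaction_schedule if t0 < s < t_end]
    seg_edges = [t0, *boundaries, t_end]

    z = model.initial_abundance.copy()
    out = np.empty((model.n_species, times.size))
    filled = 0
    if times[0] == t0:
        out[:, 0] = z
        filled = 1

    for a, b in zip(seg_edges, seg_edges[1:]):
        A = model.matrix_at(a)
        t_sample = times[(times > a) & (times <= b)]
        t_eval = np.union1d(t_sample, [b])
        sol = solve_ivp(
            _glv_rhs,
            (a, b),
            z,
            t_eval=t_eval,
            args=(model.growth_rates, A),
            method="RK45",
            max_step=integrator_step * 100,
            rtol=1e-8,
            atol=1e-10,
        )
        if not sol.success:
            raise RuntimeError(f"gLV integration failed near t={sol.t[-1]:.4g}: {sol.message}")
        if not np.all(np.isfinite(sol.y)):
            bad = sol.t[np.argmin(np.isfinite(sol.y).all(axis=0))]
            raise RuntimeError(f"gLV trajectory diverged to non-finite values near t={bad:.4g}")
        if t_sample.size:
            keep = np.isin(sol.t, t_sample)
            y = sol.y[:, keep].copy()
            y[y < EXTINCTION_FLOOR] = 0.0
            out[:, filled : filled + t_sample.size] = y
            filled += t_sample.size
        # restart from the segment endpoint; extinct species stay at 0
        z = np.where(sol.y[:, -1] < EXTINCTION_FLOOR, 0.0, sol.y[:, -1])

    if member_ids is None:
        member_ids = [f"sp{i + 1}" for i in range(model.n_species)]
    return AbundanceSeries(member_ids=member_ids, timestamps=times, abundances=out, kind="absolute")


def make_switch_scenario(
    n_species: int,
    switch_time: float,
    seed: int,
    scale: float = 1.0,
) -> GLVModel:
    """A two-regime gLV model whose interaction matrix changes sign structure.

    Off-diagonals are drawn uniformly in ``[-1, 1] * scale``, diagonals in
    ``[-1.5, -0.5] * scale``, and growth rates in ``[0.5, 1.5]``.  Each
    matrix is re-drawn until its symmetric part is negative definite
    (dissipativity: z'Az <= -c|z|^2, which bounds total abundance for any
    growth rates — a negative diagonal alone does not rule out divergent
    mutualistic pairs).  The second matrix is additionally re-drawn until
    at least one off-diagonal entry flips sign relative to the first.
    Deterministic given ``seed``.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = np.random.default_rng(seed)

    def draw() -> np.ndarray:
        while True:
            A = rng.uniform(-1.0, 1.0, size=(n_species, n_species)) * scale
            np.fill_diagonal(A, rng.uniform(-1.5, -0.5, size=n_species) * scale)
            if np.max(np.linalg.eigvalsh((A + A.T) / 2)) < 0:
                return A

    A1 = draw()
    off = ~np.eye(n_species, dtype=bool)
    while True:
        A2 = draw()
        if np.any(np.sign(A1[off]) != np.sign(A2[off])):
            break
    r = rng.uniform(0.5, 1.5, size=n_species)
    z0 = rng.uniform(0.1, 1.0, size=n_species)
    return GLVModel(
        n_species=n_species,
        growth_rates=r,
        interaction_schedule=[(0.0, A1), (float(switch_time), A2)],
        initial_abundance=z0,
    )


def planted_lineage_groups(
    n_groups: int = 3,
    members_per_group: int = 10,
    n_times: int = 18,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Lineage frequency trajectories with known group structure.

    Each group follows a distinct smooth log10-frequency template
    (rising, falling, humped, dipping, ...); members add iid Gaussian
    noise of ``noise_sd`` (log10 units) and columns are normalized to
    frequencies.  Returns (frequency table, true group label per row).
    """
    if n_groups > 4:
        raise ValueError("at most 4 distinct template shapes are defined")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_times)
    shapes = [2 * t, -2 * t, 2 * np.sin(np.pi * t), -2 * np.sin(np.pi * t)]
    templates = np.array(shapes[:n_groups]) - 4.0
    logf = (
        np.repeat(templates, members_per_group, axis=0)
        + rng.normal(0.0, noise_sd, (n_groups * members_per_group, n_times))
    )
    f = 10.0 ** logf
    f = f / f.sum(axis=0)
    labels = np.repeat(np.arange(n_groups), members_per_group)
    table = pd.DataFrame(
        f,
        index=[f"bc{i}" for i in range(n_groups * members_per_group)],
        columns=np.arange(n_times, dtype=float),
    )
    return table, labels


def _random_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    seqs: set[str] = set()
    while len(seqs) < n:
        seqs.add("".join(rng.choice(_BASES, size=length)))
    return sorted(seqs)


def _substitute(seq: str, sub_rate: float, rng: np.random.Generator) -> str:
    mask = rng.random(len(seq)) < sub_rate
    if not mask.any():
        return seq
    chars = list(seq)
    for i in np.flatnonzero(mask):
        chars[i] = "ACGT".replace(chars[i], "")[rng.integers(3)]
    return "".join(chars)


def _corrupt(seq: str, sub_rate: float, indel_rate: float, rng: np.random.Generator) -> str:
    out = []
    for base in seq:
        u = rng.random()
        if u < indel_rate / 2:
            continue  # deletion
        if u < indel_rate:
            out.append(str(rng.choice(_BASES)))  # insertion before base
        if rng.random() < sub_rate:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[rng.integers(3)])
        else:
            out.append(base)
    return "".join(out)


def simulate_barcode_reads(
    lineage_frequencies: pd.DataFrame,
    barcodes_per_lineage: int = 1,
    cfg: ReadSimConfig | None = None,
    barcode_length: int = 15,
) -> pd.DataFrame:
    """Simulate barcode read-count tables from true lineage frequencies.

    ``lineage_frequencies`` is a lineage-by-timepoint frame whose columns
    each sum to 1.  Per timepoint the simulator (i) draws
    ``genomes_sampled`` template molecules multinomially, (ii) amplifies
    each template through ``pcr_cycles`` rounds of stochastic doubling
    (a Galton-Watson process, reproducing PCR jackpotting), (iii) draws
    ``depth`` reads multinomially from the amplified pool, and (iv)
    corrupts each read's barcode with substitution/indel errors.

    Returns a barcode-by-timepoint integer count table; the index holds
    the (possibly corrupted) barcode sequences.  The attribute
    ``attrs["true_barcodes"]`` maps lineage id -> list of true barcodes.
    """
    if cfg is None:
        cfg = ReadSimConfig()
    freqs = lineage_frequencies.to_numpy(dtype=float)
    colsums = freqs.sum(axis=0)
    if np.any(np.abs(colsums - 1.0) > 1e-9):
        raise ValueError("frequency columns must each sum to 1")

    rng = np.random.default_rng(cfg.seed)
    n_lineages, n_times = freqs.shape
    n_bc = n_lineages * barcodes_per_lineage
    barcodes = _random_barcodes(n_bc, barcode_length, rng)
    true_map = {
        lid: barcodes[i * barcodes_per_lineage : (i + 1) * barcodes_per_lineage]
        for i, lid in enumerate(lineage_frequencies.index)
    }
    # barcodes split a lineage's frequency evenly
    bc_freqs = np.repeat(freqs / barcodes_per_lineage, barcodes_per_lineage, axis=0)

    counts: dict[str, np.ndarray] = {}
    for tcol in range(n_times):
        if cfg.depth == 0:
            continue
        templates = rng.multinomial(cfg.genomes_sampled, bc_freqs[:, tcol])
        present = np.flatnonzero(templates)
        if present.size == 0:
            continue
        # Galton-Watson amplification, one integer count per template molecule
        mol_owner = np.repeat(present, templates[present])
        copies = np.ones(mol_owner.size, dtype=np.int64)
        for _ in range(cfg.pcr_cycles):
            copies += rng.binomial(copies, cfg.per_cycle_efficiency)
        pool = np.bincount(mol_owner, weights=copies, minlength=n_bc)
        reads = rng.multinomial(cfg.depth, pool / pool.sum())
        for bc_idx in np.flatnonzero(reads):
            n_reads = int(reads[bc_idx])
            seq = barcodes[bc_idx]
            if cfg.substitution_rate == 0.0 and cfg.indel_rate == 0.0:
                counts.setdefault(seq, np.zeros(n_times, dtype=np.int64))[tcol] += n_reads
                continue
            if cfg.indel_rate == 0.0:
                # substitutions only: count error-free reads in bulk and
                # mutate only the erroneous ones individually
                p_clean = (1.0 - cfg.substitution_rate) ** len(seq)
                n_err = rng.binomial(n_reads, 1.0 - p_clean)
                if n_reads - n_err:
                    counts.setdefault(seq, np.zeros(n_times, dtype=np.int64))[
                        tcol
                    ] += n_reads - n_err
                for _ in range(n_err):
                    obs = seq
                    while obs == seq:
                        obs = _substitute(seq, cfg.substitution_rate, rng)
                    counts.setdefault(obs, np.zeros(n_times, dtype=np.int64))[tcol] += 1
            else:
                for _ in range(n_reads):
                    obs = _corrupt(seq, cfg.substitution_rate, cfg.indel_rate, rng)
                    counts.setdefault(obs, np.zeros(n_times, dtype=np.int64))[tcol] += 1

    table = pd.DataFrame(
        counts.values(), index=list(counts.keys()), columns=lineage_frequencies.columns
    )
    table = table.sort_index()
    table.attrs["true_barcodes"] = true_map
    return table
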