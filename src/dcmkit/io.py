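"""Delimited-table readers/writers, Newick export, and run configuration.

All matrices travel as delimited text (TSV by default; commas are
auto-detected), with member or barcode ids in the first column and
timestamps in the header.  Dendrograms are exported as Newick strings.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import to_tree

from .dcm import AbundanceSeries, InteractionEstimate

__all__ = [
    "RunConfig",
    "read_abundance",
    "write_abundance",
    "read_table",
    "write_table",
    "write_interactions",
    "write_eigen_matrix",
    "write_phases",
    "linkage_to_newick",
]


def _sniff_delimiter(path: str | Path) -> str:
    first = Path(path).read_text().splitlines()[0]
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited id-by-column table (delimiter auto-detected)."""
    return pd.read_csv(
        path, sep=_sniff_delimiter(path), index_col=0, float_precision="round_trip"
    )


def write_table(frame: pd.DataFrame, path: str | Path, float_format: str = "%.12g") -> None:
    frame.to_csv(path, sep="\t", float_format=float_format)


def read_abundance(
    path: str | Path, orientation: str | None = None, kind: str = "absolute"
) -> AbundanceSeries:
    """Load an AbundanceSeries from delimited text.

    Orientation is auto-detected: the axis whose labels parse as numbers
    is taken to be time.  Pass orientation="rows" (members in rows,
    default interpretation) or "columns" to override.
    """
    df = read_table(path)

    def numeric(labels) -> bool:
        try:
            [float(x) for x in labels]
            return True
        except (TypeError, ValueError):
            return False

    if orientation is None:
        if numeric(df.columns):
            orientation = "rows"
        elif numeric(df.index):
            orientation = "columns"
        else:
            raise ValueError(f"{path}: neither axis has a numeric time header")
    if orientation == "columns":
        df = df.T
    elif orientation != "rows":
        raise ValueError("orientation must be 'rows' or 'columns'")

    timestamps = np.array([float(c) for c in df.columns])
    if np.any(np.diff(timestamps) <= 0):
        raise ValueError(f"{path}: timestamps must be strictly increasing")
    members = [str(m) for m in df.index]
    dupes = {m for m in members if members.count(m) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate member ids: {sorted(dupes)}")
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError(f"{path}: negative abundance entries")
    return AbundanceSeries(members, timestamps, values, kind=kind)


def write_abundance(series: AbundanceSeries, path: str | Path) -> None:
    frame = pd.DataFrame(
        series.abundances,
        index=pd.Index(series.member_ids, name="member"),
        columns=[repr(float(t)) for t in series.timestamps],
    )
    write_table(frame, path, float_format="%.17g")


def write_interactions(
    estimates: list[InteractionEstimate], member_ids: list[str], path: str | Path
) -> None:
    """Long-format per-window table: window_end, i, j, J, A."""
    rows = []
    for est in estimates:
        for a, mi in enumerate(member_ids):
            for b, mj in enumerate(member_ids):
                rows.append(
                    {
                        "window_end": est.window.end_index,
                        "i": mi,
                        "j": mj,
                        "J": est.J[a, b],
                        "A": est.A[a, b],
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_eigen_matrix(matrix, path: str | Path) -> None:
    n = matrix.n_eigenvalues
    cols = [f"{part}{k + 1}" for k in range(n) for part in ("re", "im")]
    frame = pd.DataFrame(matrix.values, columns=cols,
                         index=pd.Index(matrix.window_indices, name="window"))
    write_table(frame, path)


def write_phases(segmentation, window_times: np.ndarray | None, path: str | Path) -> None:
    rows = []
    for b in segmentation.boundaries:
        t = float(window_times[b.index - 1]) if window_times is not None else float("nan")
        rows.append({"boundary_window": b.index, "time": t, "grade": b.grade,
                     "support": b.support})
    pd.DataFrame(rows, columns=["boundary_window", "time", "grade", "support"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return render(tree, tree.dist).rsplit(":", 1)[0] + ";"


_CONFIG_DOC = "flat key-value run configuration; unknown keys are rejected"


@dataclass
class RunConfig:
    """All pipeline defaults as one flat, schema-validated document."""

    seed: int = 0
    # barcode correction
    min_barcode_len: int = 13
    max_barcode_len: int = 17
    max_edits: int = 3
    min_counts_for_centroid: int = 2
    poisson_error_rate: float = 0.1
    # lineage clustering
    min_timepoints: int = 12
    min_mean_freq: float = 5e-5
    min_cluster_size: int = 8
    loess_span: float = 0.3
    cluster_threshold: float | None = None  # None -> select automatically
    # interaction estimation / phases
    min_points: int = 3
    kernel: str = "linear"
    quantile_settings: tuple[int, ...] = (10, 20)
    tolerance_windows: int = 1
    # comparison
    other_threshold: float = 1e-3
    min_family_nonzero: int = 7
    n_boot: int = 1000

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")
        if self.min_points < 3:
            raise ValueError("min_points must be >= 3")
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must be in (0, 1]")
        self.quantile_settings = tuple(int(q) for q in self.quantile_settings)

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset also parses JSON
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a key-value mapping")
        return cls.from_mapping(data)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)
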