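"""End-to-end orchestration: counts -> clusters -> interactions -> phases.

Mirrors the analysis flow applied to gut-colonization data: barcode
correction, lineage clustering, optional merge with family-level 16S
relative abundances, expanding-window covariance Jacobians, eigenvalue
assembly, kernel-PCA phase detection, and clone/family co-clustering.
Every stage's output is written as delimited text together with a
machine-readable JSON log (stage, parameters, wall time); all
randomness flows from the config seed, so reruns are byte-identical.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import barcode_qc, compare, lineage
from .dcm import AbundanceSeries, expanding_windows, jacobian_trajectory
from .io import (
    RunConfig,
    linkage_to_newick,
    read_table,
    write_abundance,
    write_eigen_matrix,
    write_interactions,
    write_phases,
    write_table,
)
from .phases import detect_phases
from .spectral import assemble_eigen_matrix, eigen_decompose

__all__ = ["run_pipeline"]


def _clusters_to_series(clusters, timestamps: np.ndarray) -> AbundanceSeries:
    values = np.array([10.0 ** c.consensus for c in clusters])
    return AbundanceSeries(
        member_ids=[c.label for c in clusters],
        timestamps=timestamps,
        abundances=values,
        kind="absolute",
    )


def run_pipeline(
    config: RunConfig,
    barcode_counts: str | Path | pd.DataFrame,
    taxon_counts: str | Path | pd.DataFrame | None = None,
    out_dir: str | Path = "dcm_out",
) -> Path:
    """Run the full analysis; returns the artifact directory.

    ``barcode_counts`` is a barcode-by-timepoint read-count table (path
    or frame, numeric time header); ``taxon_counts`` an optional
    family-by-timepoint 16S count table on the same time grid.  Any
    stage failure aborts with the stage name; partial outputs are kept.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    stage = "setup"

    def record(name: str, t0: float, **params) -> None:
        log.append({"stage": name, "wall_seconds": round(time.perf_counter() - t0, 4),
                    "seed": config.seed, **params})

    try:
        if not isinstance(barcode_counts, pd.DataFrame):
            barcode_counts = read_table(barcode_counts)
        if taxon_counts is not None and not isinstance(taxon_counts, pd.DataFrame):
            taxon_counts = read_table(taxon_counts)

        stage = "correct"
        t0 = time.perf_counter()
        counts = barcode_qc.length_filter(
            barcode_counts, config.min_barcode_len, config.max_barcode_len
        )
        counts = barcode_qc.deletion_correct(
            counts, config.max_edits, config.min_counts_for_centroid,
            config.poisson_error_rate,
        )
        write_table(counts, out / "corrected_counts.tsv")
        record(stage, t0, n_barcodes=int(counts.shape[0]),
               n_merged=len(counts.attrs.get("correction_report", {})))

        stage = "lineage"
        t0 = time.perf_counter()
        freqs = lineage.barcode_frequencies(counts)
        diversity = lineage.diversity_profile(freqs)
        write_table(diversity.as_frame(), out / "diversity.tsv")
        persistent = lineage.persistence_filter(
            freqs, config.min_timepoints, config.min_mean_freq
        )
        distances = lineage.lineage_distances(persistent)
        threshold = config.cluster_threshold
        if threshold is None:
            threshold = lineage.select_threshold(
                distances, persistent.loc[distances.index],
                np.linspace(0.1, 1.5, 15), config.min_cluster_size, config.loess_span,
            )
        clusters = lineage.cluster_lineages(
            distances, persistent.loc[distances.index], threshold,
            config.min_cluster_size, config.loess_span,
        )
        if not clusters:
            raise RuntimeError("no clonal clusters retained; relax the thresholds")
        membership = pd.DataFrame(
            [(bc, c.label) for c in clusters for bc in c.members],
            columns=["barcode", "cluster"],
        ).set_index("barcode")
        write_table(membership, out / "cluster_membership.tsv")
        consensus = pd.DataFrame(
            {c.label: c.consensus for c in clusters},
            index=persistent.columns,
        ).T
        write_table(consensus, out / "cluster_consensus_log10.tsv")
        record(stage, t0, threshold=float(threshold), n_clusters=len(clusters))

        stage = "merge"
        t0 = time.perf_counter()
        timestamps = lineage._numeric_timepoints(list(persistent.columns))
        series = _clusters_to_series(clusters, timestamps)
        families = None
        if taxon_counts is not None:
            families = compare.relative_abundance(taxon_counts, config.other_threshold)
            fam_series = AbundanceSeries(
                member_ids=[str(i) for i in families.index],
                timestamps=lineage._numeric_timepoints(list(families.columns)),
                abundances=families.to_numpy(dtype=float),
                kind="absolute",
            )
            if not np.array_equal(fam_series.timestamps, series.timestamps):
                raise RuntimeError("taxon and barcode tables must share the time grid")
            series = AbundanceSeries(
                member_ids=series.member_ids + fam_series.member_ids,
                timestamps=timestamps,
                abundances=np.vstack([series.abundances, fam_series.abundances]),
                kind="absolute",
            )
        write_abundance(series, out / "combined_abundance.tsv")
        record(stage, t0, n_members=series.n_members)

        stage = "dcm"
        t0 = time.perf_counter()
        estimates = jacobian_trajectory(series, config.min_points)
        write_interactions(estimates, series.member_ids, out / "interactions.tsv")
        record(stage, t0, n_windows=len(estimates))

        stage = "spectrum"
        t0 = time.perf_counter()
        spectra = [eigen_decompose(e) for e in estimates]
        eig_matrix = assemble_eigen_matrix(spectra)
        write_eigen_matrix(eig_matrix, out / "eigen_matrix.tsv")
        record(stage, t0, n_eigenvalues=eig_matrix.n_eigenvalues)

        stage = "phases"
        t0 = time.perf_counter()
        segmentation = detect_phases(
            eig_matrix, kernel=config.kernel,
            tolerance_windows=config.tolerance_windows,
            quantile_settings=config.quantile_settings,
        )
        windows = expanding_windows(series, config.min_points)
        window_times = np.array([series.timestamps[w.end_index] for w in windows])
        write_phases(segmentation, window_times, out / "phases.tsv")
        record(stage, t0, n_boundaries=len(segmentation.boundaries))

        if families is not None and len(clusters) >= 2 and families.shape[0] >= 2:
            stage = "compare"
            t0 = time.perf_counter()
            co = compare.cocluster(families, clusters, config.min_family_nonzero)
            write_table(co.sbd_matrix, out / "sbd_matrix.tsv")
            (out / "cocluster.nwk").write_text(
                linkage_to_newick(co.linkage_matrix, co.labels) + "\n"
            )
            if len(co.clone_labels) >= 2 and len(co.family_labels) >= 2:
                mix = compare.mixing_index(co)
                (out / "mixing.json").write_text(
                    json.dumps({"D_cm": mix.D_cm}, indent=2) + "\n"
                )
            record(stage, t0, n_series=len(co.labels))
    except Exception as err:
        (out / "run_log.json").write_text(json.dumps(
            {"stages": log, "failed_stage": stage, "error": str(err)}, indent=2) + "\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err

    (out / "run_log.json").write_text(
        json.dumps({"stages": log, "config": json.loads(config.to_json())}, indent=2) + "\n"
    )
    return out
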