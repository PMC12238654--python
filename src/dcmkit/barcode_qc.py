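"""Cleaning of raw barcode read-count tables.

Two steps: a length filter (barcodes are nominally 15 nt; synthesis and
sequencing artifacts shift the observed length) and deletion-neighborhood
error correction, which merges low-count sequencing-error variants into
their high-count parent barcode when they lie within a small edit
distance and their read count is plausible as an error load under a
Poisson model.
"""

from __future__ import annotations

from collections import defaultdict
from itertools import combinations

import edlib
import numpy as np
import pandas as pd
from scipy.stats import poisson

__all__ = ["length_filter", "deletion_correct", "CorrectionReport"]


def length_filter(table: pd.DataFrame, min_len: int = 13, max_len: int = 17) -> pd.DataFrame:
    """Drop rows whose barcode key length lies outside [min_len, max_len]."""
    keep = [min_len <= len(str(bc)) <= max_len for bc in table.index]
    return table.loc[keep]


def _deletion_signatures(seq: str, max_deletions: int) -> set[str]:
    """All strings obtainable from seq by deleting up to max_deletions bases.

    Two sequences within Levenshtein distance d share at least one
    signature when each deletes at most d positions, so signature
    collisions form a complete candidate set for neighborhood search.
    """
    sigs = {seq}
    n = len(seq)
    for k in range(1, min(max_deletions, n) + 1):
        for idx in combinations(range(n), k):
            out = []
            j = 0
            for i, ch in enumerate(seq):
                if j < len(idx) and i == idx[j]:
                    j += 1
                else:
                    out.append(ch)
            sigs.add("".join(out))
    return sigs


class CorrectionReport(dict):
    """Maps corrected (variant) barcode -> centroid it was merged into."""


def _correct_once(
    table: pd.DataFrame,
    max_edits: int,
    min_counts_for_centroid: int,
    poisson_error_rate: float,
    report: CorrectionReport,
) -> tuple[pd.DataFrame, bool]:
    totals = table.sum(axis=1)
    # descending count; lexicographic tie-break for determinism
    order = sorted(table.index, key=lambda bc: (-totals[bc], bc))

    sig_index: dict[str, list[str]] = defaultdict(list)
    accepted: list[str] = []
    accepted_totals: dict[str, float] = {}
    merged_into: dict[str, str] = {}
    changed = False

    for bc in order:
        sigs = _deletion_signatures(str(bc), max_edits)
        candidates = {c for s in sigs for c in sig_index.get(s, [])}
        best: tuple[int, float, str] | None = None
        for cand in candidates:
            if accepted_totals[cand] < min_counts_for_centroid:
                continue
            d = edlib.align(str(bc), str(cand), task="distance", k=max_edits)["editDistance"]
            if d < 0 or d == 0:
                continue
            key = (d, -accepted_totals[cand], cand)
            if best is None or key < (best[0], -best[1], best[2]):
                best = (d, accepted_totals[cand], cand)
        if best is not None:
            lam = poisson_error_rate * best[1]
            if totals[bc] <= poisson.ppf(0.999, lam):
                merged_into[bc] = best[2]
                report[bc] = best[2]
                changed = True
                continue
        accepted.append(bc)
        accepted_totals[bc] = float(totals[bc])
        for s in sigs:
            sig_index[s].append(bc)

    if not changed:
        return table, False
    out = table.loc[accepted].copy()
    for var, cen in merged_into.items():
        out.loc[cen] += table.loc[var]
    return out, True


def deletion_correct(
    table: pd.DataFrame,
    max_edits: int = 3,
    min_counts_for_centroid: int = 2,
    poisson_error_rate: float = 0.1,
) -> pd.DataFrame:
    """Merge sequencing-error variants into their parent barcodes.

    Barcodes are ranked by total read count; each lower-count barcode
    within Levenshtein distance <= max_edits of a higher-count centroid
    (total >= min_counts_for_centroid) has its counts added to the
    nearest such centroid, provided its total is plausible as an error
    of the centroid: count <= upper 99.9% Poisson quantile with rate
    poisson_error_rate * centroid_count.  Candidate pairs are found via
    deletion signatures rather than all-pairs comparison.  The merge is
    iterated to a fixed point, so correction is idempotent; reads are
    re-assigned, never destroyed.  The returned table carries the merge
    map in ``attrs["correction_report"]``.
    """
    report = CorrectionReport()
    current = table
    for _ in range(100):
        current, changed = _correct_once(
            current, max_edits, min_counts_for_centroid, poisson_error_rate, report
        )
        if not changed:
            break
    current = current.copy()
    current.attrs["correction_report"] = report
    return current
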