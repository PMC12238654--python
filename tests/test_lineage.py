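"""Frequencies, Hill diversity, persistence, clustering, LOESS, threshold."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcmkit.glv import planted_lineage_groups
from dcmkit.lineage import (
    barcode_frequencies,
    cluster_lineages,
    diversity_profile,
    lineage_distances,
    loess_consensus,
    persistence_filter,
    select_threshold,
)


def _freqs(rows, columns=None):
    frame = pd.DataFrame(rows).T
    frame.columns = columns if columns is not None else np.arange(
        frame.shape[1], dtype=float
    )
    return frame


class TestFrequencies:
    def test_column_normalization(self):
        table = pd.DataFrame({0.0: [3, 1]}, index=["a", "b"])
        out = barcode_frequencies(table)
        assert np.allclose(out[0.0], [0.75, 0.25])

    def test_single_barcode_has_frequency_one(self):
        table = pd.DataFrame({0.0: [7], 1.0: [2]}, index=["a"])
        assert np.allclose(barcode_frequencies(table).to_numpy(), 1.0)

    def test_zero_columns_dropped_with_warning(self):
        table = pd.DataFrame({0.0: [3, 1], 1.0: [0, 0]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="all-zero"):
            out = barcode_frequencies(table)
        assert list(out.columns) == [0.0]


class TestDiversity:
    def test_uniform_distribution_gives_richness_at_every_order(self):
        f = _freqs({"a": [0.25], "b": [0.25], "c": [0.25], "d": [0.25]})
        prof = diversity_profile(f)
        assert prof.q0[0] == prof.q1[0] == pytest.approx(4.0)
        assert prof.qinf[0] == pytest.approx(4.0)

    def test_single_lineage_gives_one(self):
        f = _freqs({"a": [1.0], "b": [0.0], "c": [0.0]})
        prof = diversity_profile(f)
        assert prof.q0[0] == 1.0
        assert prof.q1[0] == pytest.approx(1.0)
        assert prof.qinf[0] == pytest.approx(1.0)

    def test_shannon_closed_form(self):
        f = _freqs({"a": [0.5], "b": [0.25], "c": [0.25]})
        prof = diversity_profile(f)
        assert prof.q1[0] == pytest.approx(2.0 ** 1.5)
        assert prof.qinf[0] == pytest.approx(2.0)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=12))
    def test_hill_ordering(self, weights):
        f = np.array(weights) / np.sum(weights)
        prof = diversity_profile(_freqs({f"b{i}": [v] for i, v in enumerate(f)}))
        assert prof.q0[0] + 1e-9 >= prof.q1[0] >= prof.qinf[0] - 1e-9


class TestPersistenceFilter:
    def test_below_count_threshold_excluded(self):
        T = 18
        row = np.zeros(T)
        row[:11] = 0.01
        f = _freqs({"a": row, "b": np.full(T, 0.01)})
        out = persistence_filter(f, min_timepoints=12, min_mean_freq=1e-6)
        assert list(out.index) == ["b"]

    def test_mean_frequency_boundary_inclusive(self):
        T = 18
        f = _freqs({"a": np.full(T, 5e-5)})
        out = persistence_filter(f, min_timepoints=12, min_mean_freq=5e-5)
        assert list(out.index) == ["a"]

    def test_hand_enumerated_toy_table(self):
        T = 18
        rows = {
            "keep_all": np.full(T, 1e-3),
            "low_mean": np.full(T, 1e-6),
            "few_points": np.concatenate([np.full(11, 0.1), np.zeros(7)]),
            "boundary_points": np.concatenate([np.full(12, 1e-3), np.zeros(6)]),
            "boundary_mean": np.full(T, 5e-5),
            "zero": np.zeros(T),
        }
        out = persistence_filter(_freqs(rows), 12, 5e-5)
        assert set(out.index) == {"keep_all", "boundary_points", "boundary_mean"}


class TestLineageDistances:
    def test_identical_trajectories_at_zero_distance(self):
        traj = [1e-3, 2e-3, 4e-3, 8e-3]
        D = lineage_distances(_freqs({"a": traj, "b": traj}))
        assert D.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_antilinear_log_trajectories_at_distance_two(self):
        up = 10.0 ** np.array([-4, -3, -2, -1.0])
        down = 10.0 ** np.array([-1, -2, -3, -4.0])
        D = lineage_distances(_freqs({"a": up, "b": down}))
        assert D.loc["a", "b"] == pytest.approx(2.0, abs=1e-12)

    def test_planted_groups_separated(self):
        table, labels = planted_lineage_groups(seed=2)
        D = lineage_distances(table).to_numpy()
        n = labels.size
        within, between = [], []
        for i in range(n):
            for j in range(i + 1, n):
                (within if labels[i] == labels[j] else between).append(D[i, j])
        within, between = np.array(within), np.array(between)
        frac = np.mean(within[:, None] < between[None, :])
        assert frac >= 0.95


class TestClustering:
    def test_upgma_merge_heights_match_hand_arithmetic(self):
        # leaves a,b,c,d: d(a,b)=0.2, d(c,d)=0.4, d({a,b},{c,d}) =
        # mean(0.6, 0.8, 0.6, 0.8) = 0.7
        ids = ["a", "b", "c", "d"]
        D = pd.DataFrame(
            [
                [0.0, 0.2, 0.6, 0.8],
                [0.2, 0.0, 0.6, 0.8],
                [0.6, 0.6, 0.0, 0.4],
                [0.8, 0.8, 0.4, 0.0],
            ],
            index=ids,
            columns=ids,
        )
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        Z = linkage(squareform(D.to_numpy()), method="average")
        assert np.allclose(sorted(Z[:, 2]), [0.2, 0.4, 0.7])
        freqs = _freqs({k: np.full(4, 0.25) for k in ids})
        two = cluster_lineages(D, freqs, threshold=0.5, min_cluster_size=1)
        assert sorted(tuple(c.members) for c in two) == [("a", "b"), ("c", "d")]

    def test_two_planted_groups_recovered_between_heights(self):
        table, labels = planted_lineage_groups(n_groups=2, seed=3)
        D = lineage_distances(table)
        clusters = cluster_lineages(D, table, threshold=0.5, min_cluster_size=2)
        assert len(clusters) == 2
        for c in clusters:
            group = {labels[int(m[2:])] for m in c.members}
            assert len(group) == 1

    def test_root_cut_gives_single_cluster(self):
        table, _ = planted_lineage_groups(seed=5)
        D = lineage_distances(table)
        clusters = cluster_lineages(D, table, threshold=1.999, min_cluster_size=1)
        assert len(clusters) == 1

    def test_labels_ranked_by_average_frequency(self):
        table, _ = planted_lineage_groups(seed=1)
        D = lineage_distances(table)
        clusters = cluster_lineages(D, table, threshold=0.5, min_cluster_size=2)
        means = [c.mean_frequency for c in clusters]
        assert means == sorted(means, reverse=True)
        assert [c.label for c in clusters] == [f"C{i+1}" for i in range(len(clusters))]

    def test_cluster_membership_invariant_to_row_order(self, rng):
        table, _ = planted_lineage_groups(seed=6)
        perm = rng.permutation(table.shape[0])
        shuffled = table.iloc[perm]
        a = cluster_lineages(lineage_distances(table), table, 0.5, 2)
        b = cluster_lineages(lineage_distances(shuffled), shuffled, 0.5, 2)
        assert [set(c.members) for c in a] == [set(c.members) for c in b]


class TestLoess:
    def test_constant_members_give_constant_consensus(self):
        f = _freqs({"a": np.full(10, 1e-3), "b": np.full(10, 1e-3)})
        out = loess_consensus(f, span=0.5)
        assert np.allclose(out, -3.0, atol=1e-9)

    def test_linear_log_trajectory_reproduced_exactly(self):
        t = np.arange(10, dtype=float)
        line = 10.0 ** (-4 + 0.2 * t)
        f = _freqs({"a": line, "b": line})
        out = loess_consensus(f, span=0.4)
        assert np.allclose(out, -4 + 0.2 * t, atol=1e-8)

    def test_smooths_noise_better_than_raw_mean(self, rng):
        t = np.linspace(0, 1, 40)
        truth = -3 + np.sin(2 * np.pi * t)
        members = {
            f"m{i}": 10.0 ** (truth + rng.normal(0, 0.5, t.size)) for i in range(4)
        }
        f = _freqs(members, columns=t)
        consensus = loess_consensus(f, span=0.3)
        raw_mean = np.log10(f.to_numpy()).mean(axis=0)
        rmse_loess = np.sqrt(np.mean((consensus - truth) ** 2))
        rmse_raw = np.sqrt(np.mean((raw_mean - truth) ** 2))
        assert rmse_loess < rmse_raw


class TestSelectThreshold:
    def test_planted_three_groups_selected(self):
        table, _ = planted_lineage_groups(seed=0)
        D = lineage_distances(table)
        thr = select_threshold(D, table, np.linspace(0.05, 1.5, 30), min_cluster_size=1)
        clusters = cluster_lineages(D, table, thr, min_cluster_size=1)
        assert len(clusters) == 3

    def test_monotone_curves_fall_back_to_largest(self):
        table, _ = planted_lineage_groups(n_groups=2, seed=7)
        D = lineage_distances(table)
        # only huge thresholds: a single cluster everywhere -> degenerate
        with pytest.warns(UserWarning):
            thr = select_threshold(D, table, [1.7, 1.8, 1.9], min_cluster_size=1)
        assert thr == 1.9

    def test_too_few_candidates_rejected(self):
        table, _ = planted_lineage_groups(seed=8)
        D = lineage_distances(table)
        with pytest.raises(ValueError, match="3 candidate"):
            select_threshold(D, table, [0.5, 1.0])
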