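"""Relative abundance, SBD, co-clustering, mixing, overlap statistics."""

import numpy as np
import pandas as pd
import pytest

from dcmkit.compare import (
    cocluster,
    mixing_index,
    overlap_significance,
    relative_abundance,
    sbd,
    znormalize,
)
from dcmkit.lineage import ClonalCluster


def brute_force_sbd(x, y):
    """Explicit shift loop over all zero-padded alignments."""
    L = x.size
    best = -np.inf
    for w in range(-(L - 1), L):
        if w >= 0:
            cc = np.dot(x[w:], y[: L - w])
        else:
            cc = np.dot(x[: L + w], y[-w:])
        best = max(best, cc / (np.linalg.norm(x) * np.linalg.norm(y)))
    return 1.0 - best


class TestRelativeAbundance:
    def test_rare_families_pooled_as_other(self):
        counts = pd.DataFrame(
            {0.0: [900, 90, 9, 1], 1.0: [900, 90, 9, 1]},
            index=["f1", "f2", "f3", "f4"],
        )
        out = relative_abundance(counts)
        # the cut is strict: a family at exactly 1e-3 stays
        assert list(out.index) == ["f1", "f2", "f3", "f4"]
        assert out.loc["f4", 0.0] == pytest.approx(0.001)
        below = pd.DataFrame(
            {0.0: [9000, 900, 95, 5], 1.0: [9000, 900, 95, 5]},
            index=["f1", "f2", "f3", "f4"],
        )
        out2 = relative_abundance(below)
        assert "Other" in out2.index and "f4" not in out2.index
        assert out2.loc["Other", 0.0] == pytest.approx(0.0005)
        assert np.allclose(out2.sum(axis=0), 1.0)

    def test_single_family_never_other(self):
        counts = pd.DataFrame({0.0: [10]}, index=["f1"])
        out = relative_abundance(counts)
        assert list(out.index) == ["f1"] and out.iloc[0, 0] == 1.0

    def test_no_other_row_when_all_common(self):
        counts = pd.DataFrame({0.0: [60, 40]}, index=["f1", "f2"])
        out = relative_abundance(counts)
        assert "Other" not in out.index


class TestZNormalize:
    def test_mean_zero_sd_one(self):
        out = znormalize(np.array([1.0, 2.0, 3.0]))
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_maps_to_zeros(self):
        assert np.allclose(znormalize(np.full(5, 7.0)), 0.0)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(20)
        assert np.allclose(znormalize(5 * x + 2), znormalize(x), atol=1e-12)


class TestSBD:
    def test_self_distance_zero(self, rng):
        x = znormalize(rng.standard_normal(30))
        assert sbd(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            x = znormalize(rng.standard_normal(17))
            y = znormalize(rng.standard_normal(17))
            assert sbd(x, y) == pytest.approx(brute_force_sbd(x, y), abs=1e-10)

    def test_negated_input_matches_oracle(self, rng):
        x = znormalize(rng.standard_normal(21))
        assert sbd(x, -x) == pytest.approx(brute_force_sbd(x, -x), abs=1e-10)

    def test_shifted_copy_closer_than_noise(self, rng):
        t = np.arange(50)
        x = znormalize(np.sin(2 * np.pi * t / 25))
        shifted = znormalize(np.roll(np.sin(2 * np.pi * t / 25), 2))
        noise = znormalize(rng.standard_normal(50))
        assert sbd(x, shifted) < sbd(x, noise)

    def test_bounds_symmetry_scale_invariance(self, rng):
        for _ in range(10):
            a = znormalize(rng.standard_normal(15))
            b = znormalize(rng.standard_normal(15))
            d = sbd(a, b)
            assert 0.0 <= d <= 2.0
            assert d == pytest.approx(sbd(b, a), abs=1e-12)
            assert sbd(znormalize(3.7 * a), b) == pytest.approx(d, abs=1e-12)

    def test_zero_norm_input_flagged(self):
        with pytest.warns(UserWarning, match="zero-norm"):
            assert sbd(np.zeros(5), np.ones(5)) == 1.0


def _clone(label, values, timepoints):
    return ClonalCluster(label=label, members=[], consensus=np.asarray(values, float),
                         mean_frequency=0.0, timepoints=list(timepoints))


class TestCocluster:
    def test_shifted_scaled_family_copy_pairs_with_clone(self, rng):
        t = np.arange(12, dtype=float)
        base = np.exp(np.sin(2 * np.pi * t / 6)) * 1e-2
        fam = pd.DataFrame(
            {c: v for c, v in zip(t, np.vstack([base, rng.uniform(1e-3, 1e-1, 12),
                                                rng.uniform(1e-3, 1e-1, 12)]).T)},
            index=["twin", "noise1", "noise2"],
        )
        clone_curve = np.roll(np.log10(base), 1) * 2.0  # scaled, 1-step shifted
        clones = [_clone("C1", clone_curve, t),
                  _clone("C2", rng.standard_normal(12), t)]
        res = cocluster(fam, clones, min_family_nonzero=7)
        off_diag = res.sbd_matrix.where(
            ~np.eye(len(res.labels), dtype=bool)
        )
        smallest = off_diag.stack().idxmin()
        assert set(smallest) == {"twin", "C1"}

    def test_identical_blocks_split_at_root(self):
        t = np.arange(10, dtype=float)
        up, down = 10.0 ** (0.2 * t - 4), 10.0 ** (-0.2 * t - 2)
        fam = pd.DataFrame([up, up], index=["f1", "f2"], columns=t)
        clones = [_clone("C1", np.log10(down), t), _clone("C2", np.log10(down), t)]
        res = cocluster(fam, clones)
        # final merge joins the family block and the clone block
        from scipy.cluster.hierarchy import fcluster

        two = fcluster(res.linkage_matrix, t=2, criterion="maxclust")
        groups = {}
        for lab, g in zip(res.labels, two):
            groups.setdefault(g, set()).add(lab)
        assert sorted(groups.values(), key=len) in (
            [{"f1", "f2"}, {"C1", "C2"}],
            [{"C1", "C2"}, {"f1", "f2"}],
        )

    def test_order_invariance(self, rng):
        t = np.arange(10, dtype=float)
        fam = pd.DataFrame(rng.uniform(1e-3, 1e-1, (3, 10)),
                           index=["f1", "f2", "f3"], columns=t)
        clones = [_clone("C1", rng.standard_normal(10), t),
                  _clone("C2", rng.standard_normal(10), t)]
        a = cocluster(fam, clones)
        b = cocluster(fam.iloc[[2, 0, 1]], clones[::-1])
        pd.testing.assert_frame_equal(
            a.sbd_matrix, b.sbd_matrix.loc[a.labels, a.labels]
        )

    def test_sparse_families_excluded(self, rng):
        t = np.arange(10, dtype=float)
        sparse = np.zeros(10)
        sparse[:5] = 0.1
        fam = pd.DataFrame([rng.uniform(0.01, 0.1, 10), sparse],
                           index=["dense", "sparse"], columns=t)
        clones = [_clone("C1", rng.standard_normal(10), t)]
        res = cocluster(fam, clones, min_family_nonzero=7)
        assert res.family_labels == ["dense"]


class TestMixingIndex:
    def _result_from_distances(self, D, clone_labels, family_labels):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        labels = list(D.index)
        Z = linkage(squareform(D.to_numpy(), checks=False), method="average")
        from dcmkit.compare import CoclusterResult

        return CoclusterResult(labels=labels, sbd_matrix=D, linkage_matrix=Z,
                               clone_labels=clone_labels, family_labels=family_labels)

    def test_interleaved_distances_give_high_mixing(self):
        # clones and families at identical mutual distances: tree distances
        # identically distributed -> D = 1
        labels = ["C1", "C2", "f1", "f2"]
        D = pd.DataFrame(1.0 - np.eye(4), index=labels, columns=labels)
        res = self._result_from_distances(D, ["C1", "C2"], ["f1", "f2"])
        assert mixing_index(res).D_cm == pytest.approx(1.0)

    def test_separated_blocks_give_low_mixing(self):
        labels = ["C1", "C2", "C3", "f1", "f2"]
        D = pd.DataFrame(np.full((5, 5), 1.9), index=labels, columns=labels)
        for block in (slice(0, 3), slice(3, 5)):
            D.iloc[block, block] = 0.05
        D.values[np.diag_indices(5)] = 0.0
        res = self._result_from_distances(D, ["C1", "C2", "C3"], ["f1", "f2"])
        assert mixing_index(res).D_cm == pytest.approx(0.0)

    def test_hand_computed_ecdf_sup_difference(self):
        labels = ["C1", "C2", "C3", "f1", "f2", "f3"]
        rng = np.random.default_rng(0)
        M = np.round(rng.uniform(0.1, 1.9, (6, 6)), 2)
        D = pd.DataFrame((M + M.T) / 2, index=labels, columns=labels)
        D.values[np.diag_indices(6)] = 0.0
        res = self._result_from_distances(D, labels[:3], labels[3:])
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        coph = squareform(cophenet(res.linkage_matrix))
        cc = [coph[i, j] for i in range(3) for j in range(i + 1, 3)]
        cm = [coph[i, j] for i in range(3) for j in range(3, 6)]
        grid = sorted(set(cc) | set(cm))
        sup = max(
            abs(np.mean([v <= g for v in cc]) - np.mean([v <= g for v in cm]))
            for g in grid
        )
        assert mixing_index(res).D_cm == pytest.approx(1.0 - sup, abs=1e-12)

    def test_too_few_members_rejected(self):
        labels = ["C1", "f1", "f2"]
        D = pd.DataFrame(1.0 - np.eye(3), index=labels, columns=labels)
        res = self._result_from_distances(D, ["C1"], ["f1", "f2"])
        with pytest.raises(ValueError, match=">= 2"):
            mixing_index(res)


class TestOverlap:
    def test_identical_sets_give_one(self):
        res = overlap_significance({"a", "b"}, {"a", "b"}, set("abcdefgh"), n_boot=50)
        assert res.oc == 1.0

    def test_disjoint_sets_give_zero(self):
        res = overlap_significance({"a"}, {"b"}, set("abcdefgh"), n_boot=50)
        assert res.oc == 0.0

    def test_worked_example_and_z_against_high_replicate_null(self):
        universe = {f"u{i}" for i in range(30)}
        A = {"u0", "u1", "u2"}
        B = {"u0", "u1", "u5", "u6"}
        res = overlap_significance(A, B, universe, n_boot=20_000, seed=1)
        assert res.oc == pytest.approx(2.0 / 3.0)
        oracle = overlap_significance(A, B, universe, n_boot=100_000, seed=2)
        assert res.z == pytest.approx(oracle.z, abs=0.1)

    def test_reproducible_given_seed(self):
        universe = {f"u{i}" for i in range(20)}
        a = overlap_significance({"u1"}, {"u2", "u3"}, universe, n_boot=200, seed=5)
        b = overlap_significance({"u1"}, {"u2", "u3"}, universe, n_boot=200, seed=5)
        assert a.z == b.z and a.null_mean == b.null_mean

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            overlap_significance(set(), {"a"}, {"a", "b"})
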