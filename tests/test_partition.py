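"""Merging, autoscaled PCA, Kennard-Stone selection, venetian blinds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from olivenir import (
    ChemTable,
    ConfigurationError,
    DataValidationError,
    RESPONSES,
    autoscale,
    kennard_stone,
    merge_dataset,
    pca_scores,
    venetian_blinds,
)

from conftest import make_block


def _chem_for(unit_ids):
    rng = np.random.default_rng(0)
    data = pd.DataFrame({name: rng.random(len(unit_ids)) + 1.0 for name in RESPONSES})
    data.insert(0, "replicate", 1)
    data.insert(0, "unit_id", unit_ids)
    return ChemTable(data=data)


class TestMerge:
    def test_width_is_sum_of_parts(self):
        units = [f"u{i}" for i in range(6)]
        chem = _chem_for(units)
        rng = np.random.default_rng(1)
        blocks = [
            make_block(rng.random((6, w)), unit_ids=units, replicates=np.zeros(6, int), name=f"b{w}")
            for w in (7, 11, 3)
        ]
        merged = merge_dataset(chem, blocks)
        assert merged.n_columns == 5 + 7 + 11 + 3
        assert merged.merged.shape == (6, merged.n_columns)

    def test_alignment_is_row_order_independent(self):
        units = [f"u{i}" for i in range(5)]
        chem = _chem_for(units)
        rng = np.random.default_rng(2)
        A = rng.random((5, 4))
        fwd = make_block(A, unit_ids=units, replicates=np.zeros(5, int))
        perm = np.array([3, 0, 4, 1, 2])
        rev = make_block(
            A[perm], unit_ids=np.array(units)[perm], replicates=np.zeros(5, int)
        )
        np.testing.assert_array_equal(
            merge_dataset(chem, [fwd]).merged, merge_dataset(chem, [rev]).merged
        )

    def test_unit_mismatch_reports_ids(self):
        chem = _chem_for(["a", "b", "c"])
        block = make_block(
            np.random.default_rng(3).random((3, 4)),
            unit_ids=["a", "b", "zzz"],
            replicates=np.zeros(3, int),
        )
        with pytest.raises(DataValidationError, match="zzz"):
            merge_dataset(chem, [block])

    @settings(deadline=None, max_examples=20)
    @given(widths=st.lists(st.integers(2, 12), min_size=1, max_size=4))
    def test_column_count_property(self, widths):
        units = [f"u{i}" for i in range(4)]
        chem = _chem_for(units)
        rng = np.random.default_rng(sum(widths))
        blocks = [
            make_block(
                rng.random((4, w)),
                unit_ids=units,
                replicates=np.zeros(4, int),
                name=f"b{k}",
            )
            for k, w in enumerate(widths)
        ]
        assert merge_dataset(chem, blocks).n_columns == 5 + sum(widths)


class TestAutoscale:
    def test_two_point_column(self):
        Z, centers, scales = autoscale(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(Z[:, 0], [-np.sqrt(0.5), np.sqrt(0.5)])
        assert centers[0] == 2.0

    def test_columns_standardized_and_reusable(self):
        M = np.random.default_rng(5).random((20, 6))
        Z, centers, scales = autoscale(M)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal((M - centers) / scales, Z)

    def test_constant_column_rejected(self):
        M = np.ones((4, 2))
        M[:, 0] = [1, 2, 3, 4]
        with pytest.raises(DataValidationError, match="1"):
            autoscale(M)


class TestPCA:
    def test_full_reconstruction_and_orthogonality(self):
        M = autoscale(np.random.default_rng(6).random((15, 5)))[0]
        scores, loadings, evr = pca_scores(M, 5)
        np.testing.assert_allclose(scores @ loadings.T, M, atol=1e-8)
        cov = scores.T @ scores
        np.testing.assert_allclose(cov - np.diag(np.diag(cov)), 0.0, atol=1e-8)
        np.testing.assert_allclose(loadings.T @ loadings, np.eye(5), atol=1e-10)

    def test_explained_variance_matches_eigen_oracle(self):
        """Brute force: eigenvalues of the correlation matrix."""
        X = np.random.default_rng(7).random((30, 6))
        Z = autoscale(X)[0]
        _, _, evr = pca_scores(Z, 6)
        eigvals = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
        np.testing.assert_allclose(evr, eigvals / eigvals.sum(), atol=1e-10)
        assert np.all(np.diff(evr) <= 1e-12)

    def test_rank_deficiency_raises(self):
        M = np.random.default_rng(8).random((10, 2))
        M = np.hstack([M, M])  # rank 2, 4 columns
        M = M - M.mean(axis=0)
        with pytest.raises(DataValidationError):
            pca_scores(M, 4)


def brute_force_ks(points, n_cal):
    """Direct max-min re-implementation used as the selection oracle."""
    points = np.asarray(points, float)
    n = len(points)
    dist = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    selected = [min(i, j), max(i, j)]
    while len(selected) < n_cal:
        best, best_d = None, -1.0
        for k in range(n):
            if k in selected:
                continue
            d = min(dist[k, s] for s in selected)
            if d > best_d:
                best, best_d = k, d
        selected.append(best)
    return set(selected)


class TestKennardStone:
    def test_farthest_pair_three_points(self):
        split = kennard_stone(np.array([[0.0], [1.0], [10.0]]), 2 / 3)
        assert set(split.calibration.tolist()) == {0, 2}
        assert split.prediction.tolist() == [1]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        pts = np.random.default_rng(seed).random((12, 2))
        split = kennard_stone(pts, 0.5)
        assert set(split.calibration.tolist()) == brute_force_ks(pts, 6)

    def test_split_sizes_round_half_up(self):
        pts = np.random.default_rng(9).random((267, 3))
        split = kennard_stone(pts, 0.70)
        assert split.calibration.size == 187
        assert split.prediction.size == 80

    def test_permutation_invariant_given_ids(self):
        rng = np.random.default_rng(10)
        pts = rng.random((15, 2))
        ids = np.array([f"u{i:02d}" for i in range(15)])
        perm = rng.permutation(15)
        a = kennard_stone(pts, 0.6, ids=ids)
        b = kennard_stone(pts[perm], 0.6, ids=ids[perm])
        assert a.calibration.tolist() == b.calibration.tolist()
        assert a.prediction.tolist() == b.prediction.tolist()

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 2**16), n=st.integers(5, 20))
    def test_calibration_contains_global_farthest_pair(self, seed, n):
        pts = np.random.default_rng(seed).random((n, 2))
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        i, j = np.unravel_index(np.argmax(dist), dist.shape)
        split = kennard_stone(pts, 0.5)
        assert {i, j} <= set(split.calibration.tolist())


class TestVenetianBlinds:
    def test_loo_pattern(self):
        seg = venetian_blinds(np.arange(10), 10)
        assert [seg.assignment[i] for i in range(10)] == list(range(10))

    def test_modular_assignment(self):
        seg = venetian_blinds(np.arange(20), 10)
        for i in range(10):
            assert seg.assignment[i] == seg.assignment[i + 10]

    def test_segment_sizes_187_over_10(self):
        seg = venetian_blinds(np.arange(187), 10)
        sizes = np.bincount(list(seg.assignment.values()))
        assert sorted(set(sizes.tolist())) == [18, 19]
        assert sizes.sum() == 187

    def test_too_few_segments_rejected(self):
        with pytest.raises(ConfigurationError):
            venetian_blinds(np.arange(5), 1)
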