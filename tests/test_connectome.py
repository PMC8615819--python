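"""Connectome construction: Pearson LOFC, profile-correlation HOFC, vectorization."""

import numpy as np
import pytest

from connpred.connectome import (
    ConnectivityMatrix,
    Kind,
    RegionTimeSeries,
    build_feature_pool,
    compute_hofc,
    compute_lofc,
    devectorize,
    fisher_z,
    vectorize,
)
from conftest import random_symmetric_unit_diag


def brute_force_lofc(V):
    T, R = V.shape
    C = np.eye(R)
    for i in range(R):
        for j in range(R):
            xi, xj = V[:, i], V[:, j]
            C[i, j] = ((xi - xi.mean()) * (xj - xj.mean())).sum() / (
                np.sqrt(((xi - xi.mean()) ** 2).sum() * ((xj - xj.mean()) ** 2).sum())
            )
    return C


def brute_force_hofc(L):
    R = L.shape[0]
    H = np.eye(R)
    for i in range(R):
        for j in range(R):
            if i == j:
                continue
            keep = [k for k in range(R) if k not in (i, j)]
            H[i, j] = np.corrcoef(L[i, keep], L[j, keep])[0, 1]
    return H


class TestLofc:
    def test_identical_and_negated_series(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        ts = RegionTimeSeries(np.column_stack([x, x, -x]))
        C = compute_lofc(ts).values
        assert C[0, 1] == pytest.approx(1.0)
        assert C[0, 2] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pairwise_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        V = rng.standard_normal((140, 5))
        C = compute_lofc(RegionTimeSeries(V)).values
        np.testing.assert_allclose(C, brute_force_lofc(V), atol=1e-10)

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(1)
        V = rng.standard_normal((60, 6))
        C = compute_lofc(RegionTimeSeries(V)).values
        W = V.copy()
        W[:, 2] = 3.5 * W[:, 2] + 11.0  # positive affine: invariant
        np.testing.assert_allclose(compute_lofc(RegionTimeSeries(W)).values, C, atol=1e-10)
        W[:, 2] = -W[:, 2]  # sign flip negates row/column 2
        D = compute_lofc(RegionTimeSeries(W)).values
        expect = C.copy()
        expect[2, :] *= -1
        expect[:, 2] *= -1
        expect[2, 2] = 1.0
        np.testing.assert_allclose(D, expect, atol=1e-10)

    def test_constant_region_errors_with_name(self):
        V = np.random.default_rng(2).standard_normal((30, 4))
        V[:, 1] = 7.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            compute_lofc(RegionTimeSeries(V, subject_id="s1"))
        C = compute_lofc(RegionTimeSeries(V), on_constant="zero").values
        assert np.all(C[1, [0, 2, 3]] == 0.0) and C[1, 1] == 1.0

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError, match="time points"):
            compute_lofc(RegionTimeSeries(np.ones((2, 4))))


class TestHofc:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_slicing_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = random_symmetric_unit_diag(rng, 10)
        H = compute_hofc(ConnectivityMatrix(L, Kind.LOFC)).values
        np.testing.assert_allclose(H, brute_force_hofc(L), atol=1e-10)

    def test_identical_profiles_give_one(self):
        rng = np.random.default_rng(1)
        L = random_symmetric_unit_diag(rng, 8)
        # make rows 0 and 1 identical outside the excluded {0, 1} entries
        L[1, 2:] = L[0, 2:]
        L[2:, 1] = L[1, 2:]
        H = compute_hofc(ConnectivityMatrix(L, Kind.LOFC)).values
        assert H[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_small_matrix_rejected(self):
        L = np.eye(3)
        with pytest.raises(ValueError, match="R >= 4"):
            compute_hofc(ConnectivityMatrix(L, Kind.LOFC))

    def test_requires_lofc_input(self):
        M = np.eye(5)
        with pytest.raises(ValueError, match="LOFC"):
            compute_hofc(ConnectivityMatrix(M, Kind.HOFC))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        L = random_symmetric_unit_diag(rng, 9)
        perm = rng.permutation(9)
        H = compute_hofc(ConnectivityMatrix(L, Kind.LOFC)).values
        Hp = compute_hofc(ConnectivityMatrix(L[np.ix_(perm, perm)], Kind.LOFC)).values
        np.testing.assert_allclose(Hp, H[np.ix_(perm, perm)], atol=1e-10)

    def test_full_row_profile_mode(self):
        rng = np.random.default_rng(6)
        L = random_symmetric_unit_diag(rng, 7)
        H = compute_hofc(ConnectivityMatrix(L, Kind.LOFC), profile="full-row-with-diagonal").values
        expect = np.corrcoef(L)
        np.fill_diagonal(expect, 1.0)
        np.testing.assert_allclose(H, expect, atol=1e-10)


class TestVectorize:
    def test_feature_count_and_ordering(self):
        rng = np.random.default_rng(0)
        M = random_symmetric_unit_diag(rng, 90)
        v = vectorize(ConnectivityMatrix(M, Kind.LOFC))
        assert v.values.size == 4005
        assert v.index_map[0] == ("LOFC", 0, 1)
        assert v.index_map[-1] == ("LOFC", 88, 89)
        # R=3 ordering convention: (0,1), (0,2), (1,2)
        M3 = np.array([[1.0, 0.1, 0.2], [0.1, 1.0, 0.3], [0.2, 0.3, 1.0]])
        v3 = vectorize(ConnectivityMatrix(M3, Kind.LOFC))
        np.testing.assert_array_equal(v3.values, [0.1, 0.2, 0.3])

    def test_round_trip_bit_identical(self):
        rng = np.random.default_rng(1)
        M = random_symmetric_unit_diag(rng, 15)
        cm = ConnectivityMatrix(M, Kind.HOFC)
        back = devectorize(vectorize(cm), 15)
        np.testing.assert_array_equal(back.values, cm.values)
        assert back.kind is Kind.HOFC


class TestFeaturePool:
    def _vecs(self, rng, n_sub, R, kind):
        return [
            vectorize(ConnectivityMatrix(random_symmetric_unit_diag(rng, R), kind))
            for _ in range(n_sub)
        ]

    def test_pool_shapes_and_block_order(self):
        rng = np.random.default_rng(0)
        lofc = self._vecs(rng, 3, 90, Kind.LOFC)
        hofc = self._vecs(rng, 3, 90, Kind.HOFC)
        X_l, im_l = build_feature_pool(lofc, None, "LOFC")
        X_b, im_b = build_feature_pool(lofc, hofc, "LOFC+HOFC")
        assert X_l.shape == (3, 4005) and X_b.shape == (3, 8010)
        np.testing.assert_array_equal(X_b[:, :4005], X_l)
        assert im_b[:4005] == im_l
        assert im_b[4005] == ("HOFC", 0, 1)

    def test_single_subject_small_r(self):
        rng = np.random.default_rng(1)
        lofc = self._vecs(rng, 1, 4, Kind.LOFC)
        hofc = self._vecs(rng, 1, 4, Kind.HOFC)
        assert build_feature_pool(lofc, None, "LOFC")[0].shape == (1, 6)
        assert build_feature_pool(lofc, hofc, "LOFC+HOFC")[0].shape == (1, 12)

    def test_subject_count_mismatch(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="mismatch"):
            build_feature_pool(
                self._vecs(rng, 3, 5, Kind.LOFC), self._vecs(rng, 2, 5, Kind.HOFC), "LOFC+HOFC"
            )


def test_fisher_z_monotone_and_zero_diagonal():
    rng = np.random.default_rng(0)
    M = random_symmetric_unit_diag(rng, 6)
    Z = fisher_z(ConnectivityMatrix(M, Kind.LOFC))
    assert np.all(np.diag(Z) == 0.0)
    off = ~np.eye(6, dtype=bool)
    assert np.all(np.sign(Z[off]) == np.sign(M[off]))
    assert np.all(np.abs(Z[off]) >= np.abs(M[off]) - 1e-12)
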