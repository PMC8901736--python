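"""Distance matrices, Mantel, BH adjustment, MMRR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from paleohab import (
    DistanceMatrix,
    bh_adjust,
    composition_distance,
    geographic_distance,
    mantel,
    mmrr,
    numeric_distance,
)
from paleohab.errors import (
    DegenerateScalingError,
    InvalidConfigError,
    InvalidMatrixError,
)
from paleohab.matstats import binary_attribute_distance, mantel_table


def random_dm(n, seed, labels=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    labels = labels or [f"o{i}" for i in range(n)]
    return DistanceMatrix(labels, squareform(pdist(X)))


class TestDistanceMatrixType:
    def test_asymmetric_rejected(self):
        v = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(InvalidMatrixError):
            DistanceMatrix(["a", "b"], v)

    def test_nonzero_diagonal_rejected(self):
        v = np.array([[1.0, 1.0], [1.0, 0.0]])
        with pytest.raises(InvalidMatrixError):
            DistanceMatrix(["a", "b"], v)

    def test_align_reorders_consistently(self):
        D = random_dm(4, 0, labels=["a", "b", "c", "d"])
        D2 = D.align(["d", "b", "a", "c"])
        assert D2.values[0, 1] == D.values[3, 1]

    def test_csv_roundtrip(self, tmp_path):
        D = random_dm(5, 1)
        path = tmp_path / "d.csv"
        D.to_csv(path)
        back = DistanceMatrix.from_csv(path)
        assert back.labels == D.labels
        np.testing.assert_allclose(back.values, D.values)


class TestCompositionDistance:
    def frame(self, rows):
        return pd.DataFrame(rows, index=[f"o{i}" for i in range(len(rows))])

    def test_identical_rows_zero(self):
        D = composition_distance(self.frame([[1, 0, 1], [1, 0, 1]]), "jaccard")
        assert D.values[0, 1] == 0.0

    def test_disjoint_nonempty_sets_jaccard_one(self):
        D = composition_distance(self.frame([[1, 1, 0, 0], [0, 0, 1, 1]]), "jaccard")
        assert D.values[0, 1] == 1.0

    def test_hand_computed_values(self):
        rows = [[1, 1, 0, 0], [1, 0, 1, 0]]
        Dj = composition_distance(self.frame(rows), "jaccard")
        Dh = composition_distance(self.frame(rows), "hamming")
        assert np.isclose(Dj.values[0, 1], 1.0 - 1.0 / 3.0)
        assert np.isclose(Dh.values[0, 1], 0.5)

    def test_empty_vs_empty_jaccard_zero(self):
        D = composition_distance(self.frame([[0, 0, 0], [0, 0, 0], [1, 0, 0]]), "jaccard")
        assert D.values[0, 1] == 0.0

    def test_nonbinary_rejected(self):
        with pytest.raises(InvalidConfigError):
            composition_distance(self.frame([[1, 2], [0, 1]]), "jaccard")


class TestSimpleDistances:
    def test_numeric_absolute_differences(self):
        D = numeric_distance(pd.Series([1.0, 4.0, 2.5], index=["a", "b", "c"]))
        assert D.values[0, 1] == 3.0
        rng = np.random.default_rng(2)
        v = rng.normal(size=10)
        D = numeric_distance(pd.Series(v, index=[f"o{i}" for i in range(10)]))
        for i in range(10):
            for j in range(10):
                assert np.isclose(D.values[i, j], abs(v[i] - v[j]))

    def test_binary_attribute_mismatch(self):
        D = binary_attribute_distance(pd.Series([0, 1, 1], index=["a", "b", "c"]))
        assert D.values[0, 1] == 1.0 and D.values[1, 2] == 0.0

    def test_greatcircle_one_degree_at_equator(self):
        coords = pd.DataFrame({"lon": [0.0, 1.0], "lat": [0.0, 0.0]}, index=["a", "b"])
        D = geographic_distance(coords)
        assert np.isclose(D.values[0, 1], 111.195, atol=0.001)

    def test_supplied_matrix_passthrough_and_validation(self):
        D = random_dm(4, 3)
        out = geographic_distance(mode="supplied", supplied=D)
        np.testing.assert_array_equal(out.values, D.values)
        with pytest.raises(InvalidMatrixError):
            geographic_distance(
                mode="supplied", supplied=D, labels=["x1", "x2", "x3", "x4"]
            )


class TestMantel:
    def test_self_correlation_is_one(self):
        D = random_dm(8, 4)
        res = mantel(D, D, n_perm=99, seed=0)
        assert np.isclose(res.r, 1.0)

    def test_exact_enumeration_matches_bruteforce_oracle(self):
        D1 = random_dm(4, 5)
        D2 = random_dm(4, 6)
        res = mantel(D1, D2, exact=True)
        # independent enumeration over all 24 label permutations
        i, j = np.tril_indices(4, k=-1)
        t1 = D1.values[i, j]
        stats = []
        for perm in itertools.permutations(range(4)):
            P = D2.values[np.ix_(perm, perm)]
            stats.append(np.corrcoef(t1, P[i, j])[0, 1])
        stats = np.array(stats)
        r_obs = np.corrcoef(t1, D2.values[i, j])[0, 1]
        assert np.isclose(res.r, r_obs)
        assert np.isclose(res.p, np.mean(stats >= r_obs - 1e-12))

    def test_symmetric_in_arguments(self):
        D1, D2 = random_dm(10, 7), random_dm(10, 8)
        r12 = mantel(D1, D2, n_perm=99, seed=0).r
        r21 = mantel(D2, D1, n_perm=99, seed=0).r
        assert np.isclose(r12, r21)

    def test_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        D1, D2 = random_dm(12, 9), random_dm(12, 10)
        res = mantel(D1, D2, n_perm=999, seed=1)
        r_sk, p_sk, _ = skbio_mantel(
            SkbioDM(D1.values, D1.labels),
            SkbioDM(D2.values, D2.labels),
            method="pearson",
            permutations=999,
            alternative="greater",
        )
        assert np.isclose(res.r, r_sk, atol=1e-12)
        assert abs(res.p - p_sk) < 0.05  # Monte-Carlo agreement

    def test_zero_variance_triangle_rejected(self):
        flat = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        D = random_dm(3, 11, labels=["a", "b", "c"])
        with pytest.raises(DegenerateScalingError):
            mantel(flat, D, n_perm=99)

    def test_mismatched_labels_rejected(self):
        with pytest.raises(InvalidMatrixError):
            mantel(random_dm(5, 1), random_dm(5, 2, labels=[f"x{i}" for i in range(5)]))

    def test_p_never_zero(self):
        D = random_dm(10, 12)
        res = mantel(D, D, n_perm=99, seed=0)
        assert res.p >= 1.0 / 100.0


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == 0.04

    def test_hand_stepup_triples(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_adjust([0.001, 0.5, 0.9]), [0.003, 0.75, 0.9])

    def test_order_invariance_and_dominance(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0.001, 1.0, 20)
        adj = bh_adjust(p)
        assert np.all(adj >= p)
        perm = rng.permutation(20)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(InvalidConfigError):
            bh_adjust([0.0, 0.5])


class TestMMRR:
    def test_exact_linear_relation_recovers_coefficient(self):
        Dx = random_dm(8, 14)
        Dy = DistanceMatrix(Dx.labels, 2.0 * Dx.values)
        res = mmrr(Dy, {"x": Dx}, n_perm=99, seed=0)
        assert np.isclose(res.coefficients["x"], 2.0)
        assert np.isclose(res.r_squared, 1.0)

    def test_single_predictor_r2_equals_mantel_r_squared(self):
        D1, D2 = random_dm(12, 15), random_dm(12, 16)
        res = mmrr(D1, {"x": D2}, n_perm=99, seed=0)
        r = mantel(D1, D2, n_perm=99, seed=0).r
        assert abs(res.r_squared - r**2) < 1e-10

    def test_orthogonal_predictors_keep_marginal_coefficients(self):
        # build two exactly orthogonal (uncorrelated) predictor triangles
        n = 6
        m = n * (n - 1) // 2
        rng = np.random.default_rng(17)
        a = rng.normal(size=m)
        b = rng.normal(size=m)
        a -= a.mean()
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)  # residualize: now centred and orthogonal
        i, j = np.tril_indices(n, k=-1)

        def to_dm(tri, shift):
            V = np.zeros((n, n))
            V[i, j] = tri + shift
            V += V.T
            return DistanceMatrix([f"o{k}" for k in range(n)], V)

        Da, Db = to_dm(a, 10.0), to_dm(b, 10.0)
        y = 1.5 * (a + 10.0) + 0.5 * (b + 10.0)
        Dy = to_dm(y - y.min() + 1.0, 0.0)
        both = mmrr(Dy, {"a": Da, "b": Db}, n_perm=99, seed=0)
        only_a = mmrr(Dy, {"a": Da}, n_perm=99, seed=0)
        only_b = mmrr(Dy, {"b": Db}, n_perm=99, seed=0)
        assert np.isclose(both.coefficients["a"], only_a.coefficients["a"])
        assert np.isclose(both.coefficients["b"], only_b.coefficients["b"])
        assert np.isclose(both.coefficients["a"], 1.5)

    def test_p_granularity_with_plus_one_estimator(self):
        D1, D2 = random_dm(10, 18), random_dm(10, 19)
        res = mmrr(D1, {"x": D2}, n_perm=99, seed=0)
        for p in list(res.coef_p.values()) + [res.p_model]:
            assert np.isclose(p * 100, round(p * 100))
            assert 0 < p <= 1

    def test_collinear_predictors_warn(self):
        Dx = random_dm(8, 20)
        Dx2 = DistanceMatrix(Dx.labels, 2.0 * Dx.values)
        Dy = random_dm(8, 21)
        with pytest.warns(RuntimeWarning, match="collinear"):
            res = mmrr(Dy, {"x": Dx, "x2": Dx2}, n_perm=99, seed=0)
        assert res.collinear

    def test_needs_enough_occupations(self):
        with pytest.raises(InvalidConfigError):
            mmrr(random_dm(3, 22), {"a": random_dm(3, 23), "b": random_dm(3, 24)}, n_perm=99)


def test_mantel_table_family_adjustment():
    Dy = random_dm(10, 25)
    others = {f"v{k}": random_dm(10, 30 + k) for k in range(4)}
    df = mantel_table(Dy, others, n_perm=99, seed=0)
    assert list(df["variable"]) == list(others)
    assert (df["p_adj"] >= df["p"] - 1e-12).all()
    np.testing.assert_allclose(df["p_adj"], bh_adjust(df["p"].to_numpy()))
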