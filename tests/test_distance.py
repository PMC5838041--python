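"""Haversine geometry, p-distances, locality averaging, Mantel tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import radpop as rp
from radpop.distance import (
    DistanceMatrix,
    EARTH_RADIUS_KM,
    average_by_locality,
    haversine_matrix,
    mantel_test,
    p_distance_matrix,
)
from conftest import make_dataset


class TestHaversine:
    def test_identical_points_are_at_zero(self):
        dm = haversine_matrix([(5.0, 10.0), (5.0, 10.0)])
        assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_half_circumference(self):
        dm = haversine_matrix([(0.0, 0.0), (0.0, 180.0)])
        assert dm.values[0, 1] == pytest.approx(math.pi * EARTH_RADIUS_KM, rel=1e-9)

    def test_one_degree_along_equator(self):
        dm = haversine_matrix([(0.0, 0.0), (0.0, 1.0)])
        assert dm.values[0, 1] == pytest.approx(
            2 * math.pi * EARTH_RADIUS_KM / 360.0, rel=1e-9
        )

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            haversine_matrix([(91.0, 0.0), (0.0, 0.0)])
        with pytest.raises(ValueError, match="out of range"):
            haversine_matrix([(0.0, 181.0), (0.0, 0.0)])

    @given(
        st.lists(
            st.tuples(
                st.floats(-89.0, 89.0, allow_nan=False),
                st.floats(-179.0, 179.0, allow_nan=False),
            ),
            min_size=3,
            max_size=3,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_and_triangle_inequality(self, coords):
        dm = haversine_matrix(coords).values
        assert np.allclose(dm, dm.T)
        assert dm[0, 1] <= dm[0, 2] + dm[2, 1] + 1e-6


class TestPDistance:
    def test_identical_samples_are_at_zero(self):
        dm = p_distance_matrix(make_dataset([[1, 1], [2, 2], [0, 0]]))
        assert dm.values[0, 1] == 0.0

    def test_hand_counted_example(self):
        # (0,0,2,2) vs (0,2,2,0): per-site diffs (0,1,0,1) -> 2/4
        ds = make_dataset([[0, 0], [0, 2], [2, 2], [2, 0]])
        dm = p_distance_matrix(ds)
        assert dm.values[0, 1] == pytest.approx(0.5)

    def test_het_counts_half(self):
        dm = p_distance_matrix(make_dataset([[0, 1], [2, 1]]))
        assert dm.values[0, 1] == pytest.approx(0.5)  # (0.5 + 0.5) / 2

    def test_pairwise_deletion_reduces_denominator(self):
        ds = make_dataset([[0, 2], [1, -1], [2, 0]])
        dm = p_distance_matrix(ds)
        assert dm.values[0, 1] == pytest.approx((1.0 + 1.0) / 2.0)

    def test_complete_deletion_mode(self):
        ds = make_dataset([[0, 2], [1, -1], [2, 0]])
        dm = p_distance_matrix(ds, deletion="complete")
        assert dm.values[0, 1] == pytest.approx(1.0)

    def test_no_shared_sites_is_an_error(self):
        ds = make_dataset([[0, -1], [-1, 2]])
        with pytest.raises(ValueError, match="no shared called sites"):
            p_distance_matrix(ds)

    def test_bounds_and_order_invariance(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.integers(-1, 3, (80, 5)))
        dm = p_distance_matrix(ds)
        assert (dm.values >= 0).all() and (dm.values <= 1).all()
        rev = ds.subset_samples(list(reversed(ds.sample_ids)))
        dm2 = p_distance_matrix(rev)
        np.testing.assert_allclose(dm2.values, dm.values[::-1, ::-1])


class TestAverageByLocality:
    def _popmap(self, assignment):
        coords = {p: (0.0, 0.0) for p in set(assignment.values())}
        return rp.PopulationMap.from_assignments(assignment, coords)

    def test_singleton_localities_preserve_values(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.4], [0.4, 0.0]]))
        pm = self._popmap({"a": "A", "b": "B"})
        out = average_by_locality(dm, pm)
        assert out.labels == ["A", "B"]
        assert out.values[0, 1] == pytest.approx(0.4)

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(1)
        n = 6
        v = rng.uniform(0.1, 1.0, (n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        labels = [f"s{i}" for i in range(n)]
        dm = DistanceMatrix(labels, v)
        assignment = {labels[i]: ("A" if i < 3 else "B") for i in range(n)}
        out = average_by_locality(dm, self._popmap(assignment))
        expected = np.mean([v[i, j] for i in range(3) for j in range(3, 6)])
        assert out.values[0, 1] == pytest.approx(expected)
        assert out.values[0, 0] == 0.0

    def test_empty_locality_dropped_with_warning(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.2], [0.2, 0.0]]))
        pm = self._popmap({"a": "A", "b": "B", "ghost": "C"})
        with pytest.warns(UserWarning, match="'C'"):
            out = average_by_locality(dm, pm)
        assert out.labels == ["A", "B"]


def random_distance_matrix(rng, labels):
    n = len(labels)
    v = rng.uniform(1.0, 10.0, (n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(list(labels), v)


class TestMantel:
    def test_self_comparison_gives_r_one_min_p(self):
        rng = np.random.default_rng(0)
        dm = random_distance_matrix(rng, "abcd")
        res = mantel_test(dm, dm, n_permutations=999, seed=1)
        assert res.r_observed == pytest.approx(1.0)
        # identity permutations are the only ones attaining r = 1
        assert res.p_value < 0.08

    def test_matches_exact_enumeration_for_four_localities(self):
        rng = np.random.default_rng(3)
        A = random_distance_matrix(rng, "abcd")
        B = random_distance_matrix(rng, "abcd")
        iu = np.triu_indices(4, 1)
        x = A.values[iu]
        r_obs = np.corrcoef(x, B.values[iu])[0, 1]
        hits = 0
        for perm in itertools.permutations(range(4)):
            y = B.values[np.ix_(perm, perm)][iu]
            hits += np.corrcoef(x, y)[0, 1] >= r_obs - 1e-12
        exact_p = hits / 24.0
        res = mantel_test(A, B, n_permutations=999, seed=7)
        mc_err = 3 * math.sqrt(exact_p * (1 - exact_p) / 999)
        assert abs(res.p_value - exact_p) <= mc_err + 2e-3

    def test_label_alignment(self):
        rng = np.random.default_rng(5)
        A = random_distance_matrix(rng, ["w", "x", "y", "z"])
        shuffled = A.reorder(["z", "w", "y", "x"])
        res = mantel_test(A, shuffled, n_permutations=99, seed=0)
        assert res.r_observed == pytest.approx(1.0)

    def test_joint_relabeling_leaves_p_invariant(self):
        rng = np.random.default_rng(6)
        A = random_distance_matrix(rng, "abcde")
        B = random_distance_matrix(rng, "abcde")
        perm = [2, 0, 4, 1, 3]
        labels = [A.labels[i] for i in perm]
        A2 = A.reorder(labels)
        B2 = B.reorder(labels)
        r1 = mantel_test(A, B, n_permutations=499, seed=3)
        r2 = mantel_test(A2, B2, n_permutations=499, seed=3)
        assert r1.r_observed == pytest.approx(r2.r_observed)
        assert abs(r1.p_value - r2.p_value) < 0.1

    def test_constant_matrix_is_an_error(self):
        flat = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        rng = np.random.default_rng(0)
        other = random_distance_matrix(rng, "abc")
        with pytest.raises(ValueError, match="constant"):
            mantel_test(flat, other, seed=0)

    def test_too_few_localities_is_an_error(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="at least 3"):
            mantel_test(dm, dm, seed=0)

    def test_agrees_with_skbio(self):
        """Cross-check r and p against the independent scikit-bio routine."""
        from skbio.stats.distance import DistanceMatrix as SkbioDM, mantel

        rng = np.random.default_rng(8)
        A = random_distance_matrix(rng, "abcdef")
        noise = random_distance_matrix(rng, "abcdef")
        B = DistanceMatrix(A.labels, A.values + 0.5 * noise.values)
        res = mantel_test(A, B, n_permutations=999, seed=2)
        r_sk, p_sk, _ = mantel(
            SkbioDM(A.values, A.labels), SkbioDM(B.values, B.labels),
            method="pearson", permutations=999, alternative="greater",
        )
        assert res.r_observed == pytest.approx(float(r_sk), abs=1e-12)
        assert abs(res.p_value - float(p_sk)) < 0.05


class TestDistanceMatrixContainer:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="non-negative"):
            DistanceMatrix(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        dm = random_distance_matrix(rng, ["north", "mid", "south"])
        dm.to_tsv(tmp_path / "d.tsv")
        back = DistanceMatrix.from_tsv(tmp_path / "d.tsv")
        assert back.labels == dm.labels
        np.testing.assert_allclose(back.values, dm.values)
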