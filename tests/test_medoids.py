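"""PAM clustering, the coverage criterion and minimal-k selection."""

import numpy as np
import pytest

from baitdesign.distance import DistanceMatrix, build_distance_matrix
from baitdesign.errors import ParameterError
from baitdesign.medoids import (
    SelectionParams,
    coverage_fraction,
    evaluate_reference_set,
    pam_best_of,
    pam_kmedoids,
    select_minimal_medoids,
)
from baitdesign.simulate import generate_clustered_alignment
from conftest import exhaustive_kmedoids


def matrix_from_values(values: np.ndarray, prefix: str = "s") -> DistanceMatrix:
    n = values.shape[0]
    return DistanceMatrix(
        ids=tuple(f"{prefix}{i}" for i in range(n)), values=np.asarray(values, float)
    )


def random_dissimilarity(rng: np.random.Generator, n: int) -> np.ndarray:
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


class TestPamKmedoids:
    def test_k_equals_n_is_zero_cost(self):
        dm = matrix_from_values(random_dissimilarity(np.random.default_rng(0), 6))
        med, cost = pam_kmedoids(dm, 6)
        assert list(med) == list(range(6))
        assert cost == 0.0

    def test_two_tight_pairs(self):
        # within-pair 0.01, between 0.5: optimum is one medoid per pair
        v = np.full((4, 4), 0.5)
        v[0, 1] = v[1, 0] = v[2, 3] = v[3, 2] = 0.01
        np.fill_diagonal(v, 0.0)
        med, cost = pam_kmedoids(matrix_from_values(v), 2)
        assert sorted(int(m) // 2 for m in med) == [0, 1]
        assert cost == pytest.approx(0.02)

    def test_k1_symmetric_ties_break_low_index(self):
        v = np.full((3, 3), 0.2)
        np.fill_diagonal(v, 0.0)
        med, cost = pam_kmedoids(matrix_from_values(v), 1)
        assert list(med) == [0]
        assert cost == pytest.approx(0.4)

    def test_k_out_of_range(self):
        dm = matrix_from_values(random_dissimilarity(np.random.default_rng(0), 4))
        with pytest.raises(ParameterError):
            pam_kmedoids(dm, 5)

    def test_deterministic_given_seed(self):
        dm = matrix_from_values(random_dissimilarity(np.random.default_rng(3), 20))
        a = pam_kmedoids(dm, 4, seed=7, init="random")
        b = pam_kmedoids(dm, 4, seed=7, init="random")
        assert list(a[0]) == list(b[0]) and a[1] == b[1]

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_optimum_small(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 12))
        k = int(rng.integers(1, 5))
        D = random_dissimilarity(rng, n)
        _, opt_cost = exhaustive_kmedoids(D, k)
        _, pam_cost = pam_best_of(D, k, seed=seed, restarts=20)
        assert pam_cost == pytest.approx(opt_cost, abs=1e-10)


class TestCoverageFraction:
    def test_all_reps_cover_everything(self):
        D = random_dissimilarity(np.random.default_rng(0), 7)
        assert coverage_fraction(D, range(7), 0.0) == 1.0

    def test_manual_enumeration(self):
        # 10 points: 9 within 0.30 of the single rep, 1 at 0.4
        v = np.zeros((10, 10))
        v[0, 1:] = v[1:, 0] = 0.25
        v[0, 9] = v[9, 0] = 0.4
        assert coverage_fraction(v, [0], 0.30) == pytest.approx(0.9)

    def test_threshold_one_covers_all(self):
        D = random_dissimilarity(np.random.default_rng(2), 12)
        assert coverage_fraction(D, [3], 1.0) == 1.0

    def test_threshold_comparison_is_inclusive(self):
        v = np.array([[0.0, 0.3], [0.3, 0.0]])
        assert coverage_fraction(v, [0], 0.3) == 1.0

    def test_empty_rep_set(self):
        with pytest.raises(ParameterError):
            coverage_fraction(np.zeros((3, 3)), [], 0.3)


class TestSelectMinimalMedoids:
    def test_all_close_passes_at_k_min(self):
        v = np.full((30, 30), 0.25)
        np.fill_diagonal(v, 0.0)
        sol = select_minimal_medoids(matrix_from_values(v), SelectionParams(seed=1))
        assert sol.passed and sol.k == 5 and sol.coverage == 1.0
        assert sol.restarts_used == 1

    def test_equidistant_points_fail(self):
        v = np.full((20, 20), 0.5)
        np.fill_diagonal(v, 0.0)
        sol = select_minimal_medoids(matrix_from_values(v), SelectionParams(seed=1))
        assert not sol.passed
        assert sol.coverage == pytest.approx(15 / 20)
        assert sol.k == 15  # best achievable coverage is at k_max

    def test_planted_clusters_recovered(self):
        aln, truth = generate_clustered_alignment(8, 10, 600, seed=42, gene_id="g")
        dm = build_distance_matrix(aln)
        sol = select_minimal_medoids(dm, SelectionParams(seed=42), gene_id="g")
        assert sol.passed and sol.k == 8
        assert len({truth.assignment[m] for m in sol.medoid_ids}) == 8
        assert coverage_fraction(
            dm, [dm.index(m) for m in sol.medoid_ids], 0.30
        ) >= 0.95

    def test_bit_for_bit_determinism(self):
        aln, _ = generate_clustered_alignment(6, 8, 400, seed=9, gene_id="g")
        dm = build_distance_matrix(aln)
        a = select_minimal_medoids(dm, SelectionParams(seed=5), gene_id="g")
        b = select_minimal_medoids(dm, SelectionParams(seed=5), gene_id="g")
        assert a == b

    def test_coverage_monotone_in_k_via_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            D = random_dissimilarity(rng, 10)
            best_cov = []
            for k in (1, 2, 3):
                covs = [
                    coverage_fraction(D, subset, 0.3)
                    for subset in __import__("itertools").combinations(range(10), k)
                ]
                best_cov.append(max(covs))
            assert best_cov == sorted(best_cov)

    def test_params_validation(self):
        with pytest.raises(ParameterError):
            SelectionParams(divergence_threshold=1.5)
        with pytest.raises(ParameterError):
            SelectionParams(k_min=6, k_max=5)
        with pytest.raises(ParameterError):
            SelectionParams(restarts=0)


class TestEvaluateReferenceSet:
    def _dm(self):
        # s0 is the reference; s1, s2 within 0.30; s3..s5 far
        v = np.full((6, 6), 0.6)
        v[0, 1] = v[1, 0] = 0.1
        v[0, 2] = v[2, 0] = 0.3
        np.fill_diagonal(v, 0.0)
        return matrix_from_values(v)

    def test_partial_coverage(self):
        assert evaluate_reference_set(self._dm(), ["s0"], 0.30) == pytest.approx(2 / 5)

    def test_full_coverage(self):
        assert evaluate_reference_set(self._dm(), ["s0"], 1.0) == 1.0

    def test_threshold_zero_no_duplicates(self):
        assert evaluate_reference_set(self._dm(), ["s0"], 0.0) == 0.0

    def test_reference_set_validation(self):
        dm = self._dm()
        with pytest.raises(ParameterError):
            evaluate_reference_set(dm, [], 0.3)
        with pytest.raises(ParameterError):
            evaluate_reference_set(dm, list(dm.ids), 0.3)
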