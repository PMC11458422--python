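"""Relationship-matrix algebra against dense oracles and hand computations."""

import numpy as np
import pytest

from crossblup import relmat

from conftest import random_pedigree


class TestTabularA:
    def test_unrelated_founder_pair_is_identity(self):
        A = relmat.a_matrix(np.array([0, 0]), np.array([0, 0]))
        np.testing.assert_allclose(A, np.eye(2))

    def test_parent_offspring_half_relationship(self):
        # sire-dam-offspring trio, parents unrelated
        A = relmat.a_matrix(np.array([0, 0, 1]), np.array([0, 0, 2]))
        assert A[2, 0] == pytest.approx(0.5)
        assert A[2, 1] == pytest.approx(0.5)
        assert A[2, 2] == pytest.approx(1.0)

    def test_full_sib_mating_inbreeding(self):
        # offspring of full sibs: F = 0.25, diagonal 1.25
        sire = np.array([0, 0, 1, 1, 3])
        dam = np.array([0, 0, 2, 2, 4])
        A = relmat.a_matrix(sire, dam)
        assert A[4, 4] == pytest.approx(1.25)
        f = relmat.inbreeding(sire, dam)
        assert f[4] == pytest.approx(0.25)

    def test_unsorted_pedigree_rejected(self):
        with pytest.raises(relmat.PedigreeError):
            relmat.a_matrix(np.array([2, 0]), np.array([0, 0]))


class TestSparseInverses:
    def test_founder_trio_inverse_values(self):
        ai = relmat.a_inverse(np.array([0, 0, 1]), np.array([0, 0, 2])).toarray()
        np.testing.assert_allclose(np.diag(ai), [1.5, 1.5, 2.0])
        assert ai[2, 0] == pytest.approx(-1.0)
        assert ai[2, 1] == pytest.approx(-1.0)

    def test_empty_pedigree(self):
        assert relmat.a_inverse(np.array([], int), np.array([], int)).shape == (0, 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_pedigree_matches_dense_inverse(self, seed):
        rng = np.random.default_rng(seed)
        sire, dam = random_pedigree(rng, 500, 50)
        A = relmat.a_matrix(sire, dam)
        ai = relmat.a_inverse(sire, dam).toarray()
        assert np.abs(ai - np.linalg.inv(A)).max() < 1e-8

    def test_mixed_unknown_parents_match_dense(self):
        rng = np.random.default_rng(3)
        sire, dam = random_pedigree(rng, 300, 30, p_unknown=0.15)
        A = relmat.a_matrix(sire, dam)
        ai = relmat.a_inverse(sire, dam).toarray()
        assert np.abs(ai - np.linalg.inv(A)).max() < 1e-8


class TestUnknownParentGroups:
    @staticmethod
    def _qp_oracle(sire, dam, grp, n_groups):
        """Dense Quaas-Pollak transform: A* = [[A^-1, -A^-1 Q],
        [-Q'A^-1, Q'A^-1 Q]], Q = (I-P)^-1 P_g."""
        n = len(sire)
        ai = relmat.a_inverse(sire, dam).toarray()
        P = np.zeros((n, n))
        Pg = np.zeros((n, n_groups))
        for i in range(n):
            for p in (sire[i], dam[i]):
                if p > 0:
                    P[i, p - 1] += 0.5
                else:
                    Pg[i, grp[i]] += 0.5
        Q = np.linalg.solve(np.eye(n) - P, Pg)
        return np.block([[ai, -ai @ Q], [-(ai @ Q).T, Q.T @ ai @ Q]])

    def test_matches_dense_qp_transform(self):
        rng = np.random.default_rng(4)
        n = 150
        sire = np.zeros(n, int)
        dam = np.zeros(n, int)
        grp = np.full(n, -1)
        for i in range(n):
            if i < 30 or rng.random() < 0.1:
                grp[i] = i % 2
            else:
                sire[i] = rng.integers(1, i + 1)
                dam[i] = rng.integers(1, i + 1)
                if dam[i] == sire[i]:
                    dam[i] = 0
                    grp[i] = rng.integers(0, 2)
        upg = relmat.a_inverse_upg(sire, dam, grp, 2).toarray()
        assert np.abs(upg - self._qp_oracle(sire, dam, grp, 2)).max() < 1e-8

    def test_no_unknown_parents_reduces_to_a_inverse(self):
        sire = np.array([0, 0, 1, 1])
        dam = np.array([0, 0, 2, 2])
        grp = np.array([0, 1, -1, -1])
        upg = relmat.a_inverse_upg(sire, dam, grp, 2).toarray()
        ai = relmat.a_inverse(sire, dam).toarray()
        np.testing.assert_allclose(upg[:4, :4], ai)
        # founders carry their group pointers; descendants add nothing new
        assert upg.shape == (6, 6)

    def test_unassigned_unknown_parent_fails(self):
        with pytest.raises(relmat.PedigreeError):
            relmat.a_inverse_upg(np.array([0]), np.array([0]),
                                 np.array([-1]), 2)


class TestGamma:
    def test_identical_frequency_vectors(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, 200)
        g = relmat.gamma_matrix(np.vstack([p, p]))
        assert g[0, 0] == pytest.approx(g[0, 1], rel=1e-6)
        assert g[0, 0] == pytest.approx(8 * p.var(), rel=1e-6)

    def test_all_half_frequencies_floor(self):
        # zero variance -> Gamma collapses to the PD floor
        g = relmat.gamma_matrix(np.full((2, 100), 0.5))
        assert np.abs(g).max() < 1e-6
        np.testing.assert_array_less(0, np.linalg.eigvalsh(g))

    def test_too_few_loci(self):
        with pytest.raises(ValueError):
            relmat.gamma_matrix(np.array([[0.5], [0.5]]))

    def test_drifted_breeds_within_exceeds_across(self, tiny_world):
        g = relmat.gamma_matrix(tiny_world.base_freqs)
        assert g[0, 0] > g[0, 1]
        assert g[1, 1] > g[0, 1]


class TestMetafounders:
    def test_single_metafounder_base_diagonal(self):
        # one base animal under gamma = 1: diagonal 1 + gamma/2 = 1.5
        gamma = np.array([[1.0]])
        s, d, ford = relmat.extend_with_metafounders(
            np.array([0]), np.array([0]), np.array([0]), 1)
        Ag = relmat.a_matrix(s, d, founder_cov=gamma, founder_ord=ford)
        assert Ag[1, 1] == pytest.approx(1.5)

    def test_gamma_zero_reduces_to_plain_a(self):
        rng = np.random.default_rng(5)
        sire, dam = random_pedigree(rng, 120, 20)
        mf = np.where((sire == 0) | (dam == 0), 0, -1)
        s, d, ford = relmat.extend_with_metafounders(sire, dam, mf, 1)
        Ag = relmat.a_matrix(s, d, founder_cov=np.array([[1e-12]]),
                             founder_ord=ford)
        A = relmat.a_matrix(sire, dam)
        assert np.abs(Ag[1:, 1:] - A).max() < 1e-9

    def test_two_breed_toy_matches_dense_inverse(self):
        rng = np.random.default_rng(6)
        sire, dam = random_pedigree(rng, 200, 40, p_unknown=0.05)
        mf = np.where((sire == 0) | (dam == 0),
                      rng.integers(0, 2, sire.size), -1)
        gamma = np.array([[0.7, 0.2], [0.2, 0.9]])
        s, d, ford = relmat.extend_with_metafounders(sire, dam, mf, 2)
        Ag = relmat.a_matrix(s, d, founder_cov=gamma, founder_ord=ford)
        agi = relmat.a_gamma_inverse(sire, dam, mf, gamma).toarray()
        assert np.abs(agi - np.linalg.inv(Ag)).max() < 1e-8


class TestSubmatrix:
    def test_colleau_matches_tabular(self):
        rng = np.random.default_rng(7)
        sire, dam = random_pedigree(rng, 400, 40, p_unknown=0.1)
        idx = np.sort(rng.choice(400, 80, replace=False))
        A = relmat.a_matrix(sire, dam)
        sub = relmat.a_submatrix(sire, dam, idx)
        assert np.abs(sub - A[np.ix_(idx, idx)]).max() < 1e-10

    def test_colleau_gamma_matches_tabular(self):
        rng = np.random.default_rng(8)
        sire, dam = random_pedigree(rng, 150, 30)
        mf = np.where((sire == 0) | (dam == 0),
                      rng.integers(0, 2, sire.size), -1)
        gamma = np.array([[0.5, 0.1], [0.1, 0.6]])
        s, d, ford = relmat.extend_with_metafounders(sire, dam, mf, 2)
        Ag = relmat.a_matrix(s, d, founder_cov=gamma, founder_ord=ford)
        idx = np.sort(rng.choice(150, 40, replace=False)) + 2
        sub = relmat.a_submatrix(s, d, idx, founder_cov=gamma,
                                 founder_ord=ford)
        assert np.abs(sub - Ag[np.ix_(idx, idx)]).max() < 1e-10


class TestGenomicMatrices:
    def test_homozygous_reference_diagonal(self):
        # one individual all-zero counts, p = 0.5 everywhere: z = -1,
        # diagonal = m / (m/2) = 2
        m = 50
        counts = np.zeros((1, m))
        g = relmat.g_vanraden(counts, freqs=np.full(m, 0.5))
        assert g[0, 0] == pytest.approx(2.0)

    def test_counts_at_2p_give_zero_row(self):
        p = np.array([0.25, 0.5, 0.75])
        counts = np.vstack([2 * p, 2 * p])
        g = relmat.g_vanraden(counts, freqs=p)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_monomorphic_locus_rejected(self):
        with pytest.raises(ValueError):
            relmat.g_vanraden(np.array([[0, 1], [0, 2]], float))

    def test_g_half_heterozygous_and_homozygous(self):
        counts = np.array([[1, 1, 1, 1], [2, 2, 0, 0]], float)
        g = relmat.g_half(counts)
        assert g[0, 0] == pytest.approx(0.0)
        assert g[1, 1] == pytest.approx(2.0)

    def test_g_half_equals_vanraden_at_half_frequencies(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 3, (20, 400)).astype(float)
        gv = relmat.g_vanraden(counts, freqs=np.full(400, 0.5))
        gh = relmat.g_half(counts)
        np.testing.assert_allclose(gv, gh, atol=1e-12)

    def test_mean_diagonal_tracks_genomic_inbreeding(self, tiny_world):
        rows = np.flatnonzero(tiny_world.population == 0)[:200]
        counts = tiny_world.marker_counts(rows).astype(float)
        p = counts.mean(axis=0) / 2
        poly = (p > 0) & (p < 1)
        g = relmat.g_vanraden(counts[:, poly])
        # VanRaden expectation: mean diagonal ~ 1 + F_genomic, F small
        assert abs(g.diagonal().mean() - 1.0) < 0.15


class TestHInverse:
    def test_no_genotyped_animals_identity(self):
        rng = np.random.default_rng(10)
        sire, dam = random_pedigree(rng, 100, 20)
        ai = relmat.a_inverse(sire, dam)
        h = relmat.h_inverse(ai, np.zeros((0, 0)), np.zeros((0, 0)),
                             np.array([], int))
        assert (h - ai).nnz == 0

    def test_g_equal_a22_cancels(self):
        rng = np.random.default_rng(11)
        sire, dam = random_pedigree(rng, 200, 30)
        ai = relmat.a_inverse(sire, dam)
        idx = np.arange(150, 200)
        a22 = relmat.a_submatrix(sire, dam, idx)
        h = relmat.h_inverse(ai, a22, a22, idx, blend_g=1.0, blend_a=0.0)
        assert np.abs((h - ai).toarray()).max() < 1e-9

    def test_blended_g_positive_definite(self, tiny_world):
        rows = tiny_world.pools["A"] - 1
        counts = tiny_world.marker_counts(rows).astype(float)
        p = counts.mean(axis=0) / 2
        g = relmat.g_vanraden(counts[:, (p > 0) & (p < 1)])
        a22 = relmat.a_submatrix(tiny_world.sire, tiny_world.dam, rows)
        gb = relmat.blend(g, a22)
        assert np.linalg.eigvalsh(gb).min() > 0
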