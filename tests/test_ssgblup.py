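"""Single-step machinery: H/H^-1 identities and the MME solver, checked
against dense oracles built directly from the partitioned definitions."""

import numpy as np
import pytest

from ssgblup_trends import nrm
from ssgblup_trends.grm import GenotypeMatrix
from ssgblup_trends.nrm import RelationshipMatrix
from ssgblup_trends.pedigree import Pedigree
from ssgblup_trends.ssgblup import (HInverse, ModelSpec, build_h,
                                    build_h_inverse, evaluate, pedigree_blup,
                                    solve_mme)

from conftest import random_pedigree


def spd_grm(A22, seed, scale=0.3):
    rng = np.random.default_rng(seed)
    B = rng.normal(size=(len(A22), 4 * len(A22))) / np.sqrt(4 * len(A22))
    return A22 + scale * (B @ B.T)


def make_hinv(ped, gids, G):
    """Assemble H^-1 from first principles for comparison."""
    gpos = ped.positions(gids)
    A22 = nrm.build_a22(ped, gids).values
    corr = np.linalg.inv(G) - np.linalg.inv(A22)
    return HInverse(nrm.build_nrm_inverse(ped).values.tocsr(), corr, gpos,
                    ped.ids, False)


class TestJointRelationshipMatrix:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dense_h_inverse_identity(self, seed):
        """inv(H) from the partitioned dense form equals sparse A^-1 plus
        the genomic correction block, on 20-50 animal instances."""
        n = [20, 35, 50][seed]
        ped = random_pedigree(n, 6, seed=seed)
        gids = np.sort(np.random.default_rng(seed).choice(
            ped.ids, n // 3, replace=False))
        A22 = nrm.build_a22(ped, gids).values
        G = spd_grm(A22, seed)
        H = build_h(ped, RelationshipMatrix(G, gids, "G"))
        hinv = make_hinv(ped, gids, G)
        perm = ped.positions(H.index)
        Hp = np.empty((n, n))
        Hp[np.ix_(perm, perm)] = H.values
        assert np.abs(np.linalg.inv(Hp) - hinv.to_dense()).max() < 1e-8

    def test_g_equal_a22_collapses_to_pedigree(self):
        ped = random_pedigree(25, 5, seed=3)
        gids = ped.ids[10:]
        A22 = nrm.build_a22(ped, gids).values
        H = build_h(ped, RelationshipMatrix(A22, gids, "G"))
        A = nrm.build_nrm(ped).values
        perm = ped.positions(H.index)
        assert np.abs(H.values - A[np.ix_(perm, perm)]).max() < 1e-8

    def test_single_genotyped_rank_one_adjustment(self):
        ped = random_pedigree(15, 4, seed=4)
        gids = ped.ids[-1:]
        A22 = nrm.build_a22(ped, gids).values
        G = A22 + 0.4
        H = build_h(ped, RelationshipMatrix(G, gids, "G"))
        A = nrm.build_nrm(ped).values
        perm = ped.positions(H.index)
        D = H.values - A[np.ix_(perm, perm)]
        assert np.linalg.matrix_rank(D, tol=1e-8) <= 1

    def test_gamma_h_inverse_identity(self):
        gamma = 0.5
        ped = random_pedigree(30, 8, seed=5)
        gids = ped.ids[18:]
        gpos = ped.positions(gids)
        Ag = nrm.build_gamma_nrm(ped, gamma).values
        A22g = Ag[np.ix_(gpos, gpos)]
        G = spd_grm(A22g, 6)
        H = build_h(ped, RelationshipMatrix(G, gids, "G"), gamma=gamma)
        Aginv = nrm.build_gamma_nrm_inverse(ped, gamma).values.toarray()
        Hinv = Aginv.copy()
        Hinv[np.ix_(gpos, gpos)] += np.linalg.inv(G) - np.linalg.inv(A22g)
        perm = ped.positions(H.index)
        Hp = np.empty((30, 30))
        Hp[np.ix_(perm, perm)] = H.values
        assert np.abs(np.linalg.inv(Hp) - Hinv).max() < 1e-8


class TestBuildHInverse:
    def test_no_genotypes_is_pedigree_inverse(self):
        ped = random_pedigree(20, 5, seed=7)
        hinv = build_h_inverse(ped, None, ModelSpec(model="PED"))
        assert hinv.correction is None
        assert np.abs(hinv.to_dense()
                      - nrm.build_nrm_inverse(ped).values.toarray()).max() == 0

    def test_correction_vanishes_when_g_equals_a22(self):
        ped = random_pedigree(20, 5, seed=8)
        gids = ped.ids[10:]
        A22 = nrm.build_a22(ped, gids)
        spec = ModelSpec(model="M0", diag_augment=0.0)
        hinv = build_h_inverse(ped, None, spec, A22=A22,
                               G=RelationshipMatrix(A22.values.copy(),
                                                    gids, "G"))
        assert np.abs(hinv.correction).max() < 1e-8


def records(ped, rng, sg=3.0, se=7.0):
    u = rng.normal(0, np.sqrt(sg), ped.n)
    return u + rng.normal(0, np.sqrt(se), ped.n)


class TestSolveMme:
    def test_two_unrelated_animals_shrinkage_formula(self):
        """With a fitted mean and two unrelated records, the scalar MME
        give EBV = (y_i - ybar) * sigma2_g/(sigma2_g + sigma2_e) * c with
        the exact 2-animal correction; check against the dense normal
        equations solved directly."""
        ped = Pedigree(ids=[1, 2], sire=[-1, -1], dam=[-1, -1], cohort=[0, 0])
        spec = ModelSpec(model="PED", sigma2_g=3.0, sigma2_e=7.0)
        y = np.array([4.0, 8.0])
        res = pedigree_blup(ped, y, [1, 2], spec)
        k = 7.0 / 3.0
        C = np.array([[2.0, 1.0, 1.0],
                      [1.0, 1.0 + k, 0.0],
                      [1.0, 0.0, 1.0 + k]])
        sol = np.linalg.solve(C, np.array([y.sum(), y[0], y[1]]))
        assert np.allclose(res.fixed, sol[:1])
        assert np.allclose(res.ebv.to_numpy(), sol[1:])

    def test_matches_dense_gls_oracle_with_progeny(self):
        """Parent with many progeny: solver output equals the dense
        mixed-model normal equations built from scratch."""
        n, nf = 40, 6
        ped = random_pedigree(n, nf, seed=9)
        rng = np.random.default_rng(10)
        y = records(ped, rng)
        spec = ModelSpec(model="PED", sigma2_g=3.0, sigma2_e=7.0)
        res = pedigree_blup(ped, y, ped.ids, spec)
        k = spec.variance_ratio
        Ainv = nrm.build_nrm_inverse(ped).values.toarray()
        C = np.zeros((n + 1, n + 1))
        C[0, 0] = n
        C[0, 1:] = 1
        C[1:, 0] = 1
        C[1:, 1:] = np.eye(n) + k * Ainv
        rhs = np.concatenate([[y.sum()], y])
        sol = np.linalg.solve(C, rhs)
        assert np.abs(res.ebv.to_numpy() - sol[1:]).max() < 1e-8
        assert res.diagnostics["residual"] < 1e-8

    def test_infinite_shrinkage_limit(self):
        ped = random_pedigree(15, 5, seed=11)
        rng = np.random.default_rng(12)
        y = records(ped, rng)
        spec = ModelSpec(model="PED", sigma2_g=1e-10, sigma2_e=7.0)
        res = pedigree_blup(ped, y, ped.ids, spec)
        assert np.abs(res.ebv.to_numpy()).max() < 1e-6

    def test_animals_without_records_get_ebv(self):
        ped = random_pedigree(20, 4, seed=13)
        rng = np.random.default_rng(14)
        y = records(ped, rng)[:10]
        res = pedigree_blup(ped, y, ped.ids[:10],
                            ModelSpec(model="PED"))
        assert len(res.ebv) == 20
        assert np.isfinite(res.ebv.to_numpy()).all()

    @pytest.mark.parametrize("c", [-1.0, 0.5, 10.0])
    def test_adding_constant_to_grm_leaves_contrasts_unchanged(self, c):
        """All animals genotyped and a fixed mean fitted: G + cJ shifts
        every EBV by a common constant (contrasts invariant)."""
        n = 18
        ped = random_pedigree(n, 6, seed=15)
        A22 = nrm.build_a22(ped, ped.ids).values
        G0 = spd_grm(A22, 16) + 1.5  # mean offset keeps G0 + cJ PD for c >= -1
        rng = np.random.default_rng(17)
        y = records(ped, rng)
        spec = ModelSpec(model="M0")
        base = solve_mme(y, None, ped.ids, make_hinv(ped, ped.ids, G0), spec)
        shifted = solve_mme(y, None, ped.ids,
                            make_hinv(ped, ped.ids, G0 + c), spec)
        d = shifted.ebv.to_numpy() - base.ebv.to_numpy()
        assert d.max() - d.min() < 1e-8

    def test_tau_omega_weighting_equals_harmonic_replacement(self):
        """Weighting G^-1 and A22^-1 in the correction equals replacing
        the genotyped block with the weighted harmonic combination."""
        n = 24
        ped = random_pedigree(n, 6, seed=18)
        gids = ped.ids[12:]
        gpos = ped.positions(gids)
        A22 = nrm.build_a22(ped, gids).values
        G = spd_grm(A22, 19)
        tau, omega = 0.9, 0.6
        rng = np.random.default_rng(20)
        y = records(ped, rng)
        spec = ModelSpec(model="M0")
        corr = tau * np.linalg.inv(G) - omega * np.linalg.inv(A22)
        h1 = HInverse(nrm.build_nrm_inverse(ped).values.tocsr(), corr, gpos,
                      ped.ids, False)
        r1 = solve_mme(y, None, ped.ids, h1, spec)
        Gstar = np.linalg.inv(tau * np.linalg.inv(G)
                              + (1 - omega) * np.linalg.inv(A22))
        r2 = solve_mme(y, None, ped.ids, make_hinv(ped, gids, Gstar), spec)
        assert np.abs(r1.ebv.to_numpy() - r2.ebv.to_numpy()).max() < 1e-8

    def test_ma_gamma_zero_equals_m0(self):
        n = 20
        ped = random_pedigree(n, 5, seed=21)
        gids = ped.ids[10:]
        A22 = nrm.build_a22(ped, gids)
        G = RelationshipMatrix(spd_grm(A22.values, 22), gids, "G")
        rng = np.random.default_rng(23)
        y = records(ped, rng)
        r0 = evaluate(ped, None, y, ped.ids,
                      ModelSpec(model="M0", diag_augment=0.0),
                      A22=A22, G=G)
        ra = evaluate(ped, None, y, ped.ids,
                      ModelSpec(model="MA", gamma=0.0, diag_augment=0.0),
                      A22=A22, G=G)
        assert np.abs(r0.ebv.to_numpy() - ra.ebv.to_numpy()).max() < 1e-10

    def test_metafounder_solution_reported(self):
        n = 20
        ped = random_pedigree(n, 5, seed=24)
        gids = ped.ids[10:]
        gpos = ped.positions(gids)
        gamma = 0.4
        Ag = nrm.build_gamma_nrm(ped, gamma).values
        A22g = Ag[np.ix_(gpos, gpos)]
        G = RelationshipMatrix(spd_grm(A22g, 25), gids, "G")
        rng = np.random.default_rng(26)
        y = records(ped, rng)
        res = evaluate(ped, None, y, ped.ids,
                       ModelSpec(model="MA", gamma=gamma, diag_augment=0.0),
                       A22=nrm.build_a22(ped, gids), G=G)
        assert res.mf_solution is not None
        assert len(res.ebv) == n  # metafounder excluded from animal EBV

    def test_pedigree_blup_equals_empty_genotype_set(self):
        ped = random_pedigree(15, 4, seed=27)
        rng = np.random.default_rng(28)
        y = records(ped, rng)
        spec = ModelSpec(model="M0")
        a = pedigree_blup(ped, y, ped.ids, spec)
        empty = GenotypeMatrix(np.zeros((0, 3), dtype=np.int8), np.array([]),
                               np.array(["a", "b", "c"]))
        b = evaluate(ped, empty, y, ped.ids, spec)
        assert np.abs(a.ebv.to_numpy() - b.ebv.to_numpy()).max() < 1e-12
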