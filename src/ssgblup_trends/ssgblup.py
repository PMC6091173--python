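"""Single-step GBLUP: H^-1 assembly and mixed-model equations.

The joint relationship matrix H combines pedigree relationships for all
animals with genomic relationships for the genotyped subset; its inverse
is sparse A^-1 plus a dense correction block

    tau G*^-1 - omega A22^-1

on the genotyped animals (tau = omega = 1 by default).  Three model
variants are supported:

* ``M0``: no alignment of G and A beyond diagonal augmentation.
* ``MG``: G is shifted by alpha J, with alpha matching the element means
  of G and A22.
* ``MA``: the pedigree side is rescaled instead, by augmenting the
  pedigree with a single metafounder of self-relationship gamma; A^-1
  and A22^-1 in the correction are replaced by their gamma counterparts
  and the metafounder enters the equations as an extra random level
  whose solution estimates the base-population shift of GEBV.
* ``PED``: pedigree BLUP, ignoring all genotypes.

Variance components are plugged in (simulation truth by default);
variance estimation is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import grm as grm_mod
from .grm import AlignmentParams, FrequencyPolicy, GenotypeMatrix
from .linalg import spd_factor, factor_solve, spd_inverse
from .nrm import (RelationshipMatrix, build_a22, build_gamma_nrm_inverse,
                  build_nrm, build_nrm_inverse)
from .pedigree import Pedigree

_DENSE_H_LIMIT = 2000


@dataclass
class ModelSpec:
    """Analysis configuration for one evaluation."""

    model: str = "M0"            # PED | M0 | MG | MA
    scheme: str = "all"          # frequency policy for centering
    lambda_: float = 1.0         # blending weight on G
    tau: float = 1.0             # weight on G^-1 in the correction
    omega: float = 1.0           # weight on A22^-1 in the correction
    gamma: float | None = None   # metafounder self-relationship (MA)
    diag_augment: float = 0.05   # constant added to diag(G)
    sigma2_g: float = 3.0        # additive genetic variance
    sigma2_e: float = 7.0        # residual variance

    def __post_init__(self):
        if self.model not in {"PED", "M0", "MG", "MA"}:
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "MA" and self.gamma is None:
            raise ValueError("model MA requires gamma")
        if self.sigma2_g <= 0 or self.sigma2_e <= 0:
            raise ValueError("variance components must be positive")

    @property
    def variance_ratio(self) -> float:
        """k = sigma2_e / sigma2_g, the shrinkage ratio in the MME."""
        return self.sigma2_e / self.sigma2_g


@dataclass
class HInverse:
    """H^-1 as sparse part + dense correction on the genotyped block.

    ``ids`` lists the random-effect levels (metafounder first under MA),
    ``genotyped_pos`` indexes the correction block within that ordering.
    The dense correction is kept separate and applied as an operator; a
    full dense H^-1 is only materialized for small test problems.
    """

    sparse: sp.csr_matrix
    correction: np.ndarray | None
    genotyped_pos: np.ndarray | None
    ids: np.ndarray
    has_metafounder: bool = False
    alignment: AlignmentParams | None = None

    @property
    def n(self) -> int:
        return self.sparse.shape[0]

    def to_dense(self) -> np.ndarray:
        out = self.sparse.toarray()
        if self.correction is not None:
            out[np.ix_(self.genotyped_pos, self.genotyped_pos)] += self.correction
        return out

    def to_sparse(self) -> sp.csc_matrix:
        out = self.sparse.tocsc()
        if self.correction is not None:
            g = self.genotyped_pos
            block = sp.csc_matrix(
                (self.correction.ravel(),
                 (np.repeat(g, len(g)), np.tile(g, len(g)))),
                shape=out.shape)
            out = out + block
        return out


@dataclass
class EvaluationResult:
    """Solutions of one evaluation: per-animal EBV (trait units),
    fixed-effect solutions, and under MA the metafounder solution."""

    ebv: pd.Series
    fixed: np.ndarray
    model: ModelSpec
    mf_solution: float | None = None
    alignment: AlignmentParams | None = None
    diagnostics: dict = field(default_factory=dict)


# ------------------------------------------------------------ G* pipeline


def prepare_gstar(ped: Pedigree, g: GenotypeMatrix, spec: ModelSpec,
                  A22: RelationshipMatrix | None = None,
                  G: RelationshipMatrix | None = None):
    """Centered, augmented and aligned GRM plus the matching A22.

    Returns (G_star, A22, params).  ``A22``/``G`` may be passed in
    precomputed (the experiment runner shares them across cells).
    Diagonal augmentation is applied before any alpha/beta alignment.
    """
    if A22 is None:
        A22 = build_a22(ped, g.animal_ids)
    params = AlignmentParams(lambda_=spec.lambda_, tau=spec.tau,
                             omega=spec.omega, gamma=spec.gamma,
                             diag_augment=spec.diag_augment, scheme=spec.scheme)
    if G is None:
        policy = FrequencyPolicy(spec.scheme)
        p = grm_mod.compute_frequencies(g, policy, ped)
        G, _ = grm_mod.build_grm(g, p, spec.diag_augment)
    if spec.lambda_ < 1.0:
        G = grm_mod.blend_with_a22(G, A22, spec.lambda_)
    if spec.model == "MG":
        al, G = grm_mod.align_mean(G, A22)
        params.alpha = al.alpha
        if params.alpha < 0:
            # negative overall-relationship offset: flag before the PD check
            params.beta = 1.0
        grm_mod.check_positive_definite(G.toarray(), "G* (MG)")
    return G, A22, params


def build_h_inverse(ped: Pedigree, g: GenotypeMatrix | None, spec: ModelSpec,
                    A22: RelationshipMatrix | None = None,
                    G: RelationshipMatrix | None = None) -> HInverse:
    """Assemble H^-1 for the requested model.

    With no genotypes (or model PED) this is plain sparse A^-1.  Under
    MA the sparse part is the inverse of the metafounder-augmented
    A_gamma (metafounder level retained, first) and the pedigree block
    subtracted in the correction is A22_gamma = (1-gamma/2) A22 + gamma J.
    """
    no_genomics = (g is None or g.n_animals == 0) and G is None
    if spec.model == "PED" or no_genomics:
        if spec.model == "MA" and spec.gamma:
            hi = build_gamma_nrm_inverse(ped, spec.gamma, keep_metafounder=True)
            return HInverse(hi.values.tocsr(), None, None, hi.index, True)
        return HInverse(build_nrm_inverse(ped).values.tocsr(), None, None,
                        ped.ids.copy(), False)

    Gs, A22, params = prepare_gstar(ped, g, spec, A22, G)
    Gv = Gs.toarray()
    Ginv = spd_inverse(Gv, "G*")

    A22v = A22.toarray()
    if spec.model == "MA" and spec.gamma > 0:
        gam = spec.gamma
        A22g = (1.0 - gam / 2.0) * A22v + gam
        pedinv = spd_inverse(A22g, "A22_gamma")
        sparse = build_gamma_nrm_inverse(ped, gam, keep_metafounder=True)
        ids = sparse.index
        offset = 1
        has_mf = True
    else:
        pedinv = spd_inverse(A22v, "A22")
        sparse = build_nrm_inverse(ped)
        ids = sparse.index
        offset = 0
        has_mf = False

    correction = spec.tau * Ginv - spec.omega * pedinv
    gids = g.animal_ids if g is not None else Gs.index
    gpos = ped.positions(gids) + offset
    return HInverse(sparse.values.tocsr(), correction, gpos, ids,
                    has_mf, params)


def build_h(ped: Pedigree, Gs: RelationshipMatrix,
            gamma: float = 0.0) -> RelationshipMatrix:
    """Dense joint relationship matrix H (testing scale only).

    Partitioned form with non-genotyped animals first:
        H11 = A11 + A12 inv(A22) (G - A22) inv(A22) A21
        H12 = A12 inv(A22) G,   H22 = G.
    ``Gs.index`` names the genotyped animals; with gamma > 0 the
    pedigree side uses A_gamma throughout.
    """
    if ped.n > _DENSE_H_LIMIT:
        raise MemoryError("build_h is for small test problems only")
    from .nrm import build_gamma_nrm

    A = (build_gamma_nrm(ped, gamma).values if gamma else build_nrm(ped).values)
    gpos = ped.positions(Gs.index)
    mask = np.zeros(ped.n, dtype=bool)
    mask[gpos] = True
    ng = np.where(~mask)[0]
    order = np.concatenate([ng, gpos])
    A11 = A[np.ix_(ng, ng)]
    A12 = A[np.ix_(ng, gpos)]
    A22 = A[np.ix_(gpos, gpos)]
    G = Gs.toarray()
    W = la.solve(A22, A12.T, assume_a="pos")      # inv(A22) A21
    H = np.empty((ped.n, ped.n))
    n1 = len(ng)
    H[:n1, :n1] = A11 + W.T @ (G - A22) @ W
    H[:n1, n1:] = W.T @ G
    H[n1:, :n1] = H[:n1, n1:].T
    H[n1:, n1:] = G
    return RelationshipMatrix(H, ped.ids[order], "H")


# ------------------------------------------------------------- MME solver


def solve_mme(y: np.ndarray, X: np.ndarray | None, record_ids,
              hinv: HInverse, spec: ModelSpec) -> EvaluationResult:
    """Solve Henderson's mixed-model equations

        [X'X   X'Z          ] [b]   [X'y]
        [Z'X   Z'Z + k H^-1 ] [u] = [Z'y]

    with k = sigma2_e/sigma2_g.  Dense Cholesky when the genomic
    correction block is a substantial part of the system (it is dense
    anyway), sparse LU otherwise.  Animals without records get EBV
    through relationships; the metafounder (no records) is reported
    separately.  The relative residual of the solve is stored in
    ``diagnostics['residual']``.
    """
    y = np.asarray(y, dtype=float)
    N = len(y)
    if X is None:
        X = np.ones((N, 1))
    X = np.asarray(X, dtype=float)
    q = hinv.n
    pos = {a: i for i, a in enumerate(hinv.ids.tolist())}
    zcols = np.array([pos[a] for a in np.asarray(record_ids).tolist()])
    Z = sp.csr_matrix((np.ones(N), (np.arange(N), zcols)), shape=(N, q))
    k = spec.variance_ratio
    p = X.shape[1]

    XtX = X.T @ X
    XtZ = (Z.T @ X).T
    ZtZ = sp.csr_matrix((np.ones(N), (zcols, zcols)), shape=(q, q))
    rhs = np.concatenate([X.T @ y, Z.T @ y])

    # a dense correction block makes sparse LU fill in heavily; factor dense
    # whenever one is present (and the system fits), sparse LU otherwise
    use_dense = q <= 3000 or (hinv.correction is not None and q <= 9000)

    if use_dense:
        C = np.zeros((p + q, p + q))
        C[:p, :p] = XtX
        C[:p, p:] = XtZ
        C[p:, :p] = XtZ.T
        C[p:, p:] = ZtZ.toarray() + k * hinv.sparse.toarray()
        if hinv.correction is not None:
            gi = hinv.genotyped_pos + p
            C[np.ix_(gi, gi)] += k * hinv.correction
        try:
            cf = spd_factor(C, "MME coefficient matrix")
        except np.linalg.LinAlgError as e:
            raise RuntimeError(
                "MME coefficient matrix not positive definite "
                "(confounded fixed-effect levels?)") from e
        sol = factor_solve(cf, rhs)
        resid = float(np.linalg.norm(C @ sol - rhs) / np.linalg.norm(rhs))
    else:
        C = sp.bmat([[sp.csr_matrix(XtX), sp.csr_matrix(XtZ)],
                     [sp.csr_matrix(XtZ.T), ZtZ + k * hinv.to_sparse()]],
                    format="csc")
        lu = spla.splu(C)
        sol = lu.solve(rhs)
        resid = float(np.linalg.norm(C @ sol - rhs) / np.linalg.norm(rhs))
    if resid > 1e-8:
        raise RuntimeError(f"MME solve did not reach tolerance: residual {resid:.2e}")

    u = sol[p:]
    mf = None
    ids = hinv.ids
    if hinv.has_metafounder:
        mf = float(u[0])
        u = u[1:]
        ids = ids[1:]
    ebv = pd.Series(u, index=ids, name="ebv")
    return EvaluationResult(ebv=ebv, fixed=sol[:p], model=spec,
                            mf_solution=mf, alignment=hinv.alignment,
                            diagnostics={"residual": resid, "n_equations": p + q})


def evaluate(ped: Pedigree, g: GenotypeMatrix | None, y: np.ndarray,
             record_ids, spec: ModelSpec, X: np.ndarray | None = None,
             A22: RelationshipMatrix | None = None,
             G: RelationshipMatrix | None = None) -> EvaluationResult:
    """Build H^-1 for ``spec`` and solve the single-trait animal model
    (overall mean as the only fixed effect unless ``X`` is given)."""
    hinv = build_h_inverse(ped, g, spec, A22=A22, G=G)
    return solve_mme(y, X, record_ids, hinv, spec)


def pedigree_blup(ped: Pedigree, y: np.ndarray, record_ids,
                  spec: ModelSpec | None = None,
                  X: np.ndarray | None = None) -> EvaluationResult:
    """Pedigree BLUP: the animal model with H^-1 = A^-1 (genotypes
    ignored)."""
    if spec is None:
        spec = ModelSpec(model="PED")
    base = ModelSpec(model="PED", sigma2_g=spec.sigma2_g, sigma2_e=spec.sigma2_e)
    hinv = build_h_inverse(ped, None, base)
    return solve_mme(y, X, record_ids, hinv, base)
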