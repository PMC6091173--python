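"""Pedigree-based relationship algebra.

Builds the numerator relationship matrix A (tabular method, with
inbreeding), its sparse inverse, the genotyped-animal block A22 (direct
extraction or the indirect solve-based route that avoids forming A), and
the metafounder-scaled variants

    A_gamma = (1 - gamma/2) A + gamma J,

where ``gamma`` in [0, 2) is the self-relationship of a single
metafounder acting as sire and dam of every pedigree founder.  A_gamma
and its sparse inverse are built by the metafounder-augmented pedigree
recursion; the closed form (a Sherman-Morrison rank-one update on the
founder block of A^-1, scaled by 1/(1 - gamma/2)) is provided as an
independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .pedigree import UNKNOWN, Pedigree

_DENSE_LIMIT = 15000  # dense A above this would not fit comfortably in memory

METAFOUNDER_ID = "__metafounder__"


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix with an animal-id index.

    ``values`` is dense (ndarray) or sparse (scipy CSR/CSC); ``index``
    holds external animal ids in row order; ``kind`` labels the algebraic
    role (A, A_inv, A22, A_gamma, G, H_inv, ...).
    """

    values: object
    index: np.ndarray
    kind: str

    def toarray(self) -> np.ndarray:
        if sp.issparse(self.values):
            return self.values.toarray()
        return np.asarray(self.values)

    @property
    def shape(self):
        return self.values.shape

    def write_coo(self, path) -> None:
        """Write as coordinate text (i, j, value), upper triangle, 1-based."""
        m = sp.coo_matrix(sp.triu(sp.csr_matrix(self.values)))
        with open(path, "w") as fh:
            for i, j, v in zip(m.row, m.col, m.data):
                fh.write(f"{i + 1} {j + 1} {v:.12g}\n")


# --------------------------------------------------------------- internals


def _augment(ped: Pedigree):
    """Return (sire, dam, parentless_diag) for the metafounder-augmented
    pedigree: metafounder at position 0, founders' parents set to it."""
    sire = np.concatenate(([UNKNOWN], np.where(ped.sire == UNKNOWN, -1, ped.sire + 1)))
    dam = np.concatenate(([UNKNOWN], np.where(ped.dam == UNKNOWN, -1, ped.dam + 1)))
    fou = np.where(ped.is_founder)[0] + 1
    sire[fou] = 0
    dam[fou] = 0
    return sire, dam


def _tabular(sire: np.ndarray, dam: np.ndarray, diag0: np.ndarray) -> np.ndarray:
    """Dense tabular recursion.  ``diag0[i]`` is the self-relationship of
    a parentless animal (1 for ordinary founders, gamma for a metafounder)."""
    n = len(sire)
    if n > _DENSE_LIMIT:
        raise MemoryError(f"dense tabular A for n={n} exceeds the size guard")
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            A[i, i] = diag0[i]
            continue
        if s == UNKNOWN or d == UNKNOWN:
            p = s if s != UNKNOWN else d
            row = 0.5 * A[p, :i]
            aii = 1.0
        else:
            row = 0.5 * (A[s, :i] + A[d, :i])
            aii = 1.0 + 0.5 * A[s, d]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = aii
    return A


def _dense_a(ped: Pedigree, gamma: float = 0.0, metafounder: bool = False) -> np.ndarray:
    """Dense A (gamma = 0) or A_gamma by the augmented-pedigree recursion.
    If ``metafounder`` the returned matrix keeps the metafounder row 0."""
    if gamma == 0.0 and not metafounder:
        diag0 = np.ones(ped.n)
        return _tabular(ped.sire, ped.dam, diag0)
    sire, dam = _augment(ped)
    diag0 = np.empty(ped.n + 1)
    diag0[0] = gamma
    A = _tabular(sire, dam, diag0)
    return A if metafounder else A[1:, 1:]


def _mendelian(ped: Pedigree, gamma: float = 0.0, metafounder: bool = False):
    """Mendelian sampling variances d_i = a_ii - (a_ss + a_dd)/4 - a_sd/2,
    plus the matching (sire, dam) arrays, for the plain or augmented pedigree.

    For the plain pedigree this reduces to the familiar
    d_i = 0.5 - 0.25 (F_s + F_d); with a metafounder of self-relationship
    gamma, d = gamma for the metafounder and 1 - gamma/2 for founders.
    """
    if metafounder:
        sire, dam = _augment(ped)
        A = _dense_a(ped, gamma, metafounder=True)
    else:
        sire, dam = ped.sire, ped.dam
        A = _dense_a(ped)
    n = len(sire)
    d = np.empty(n)
    diag = np.diag(A)
    for i in range(n):
        s, dd = sire[i], dam[i]
        if s == UNKNOWN and dd == UNKNOWN:
            d[i] = diag[i]
        elif s == UNKNOWN or dd == UNKNOWN:
            p = s if s != UNKNOWN else dd
            d[i] = diag[i] - 0.25 * diag[p]
        else:
            d[i] = diag[i] - 0.25 * (diag[s] + diag[dd]) - 0.5 * A[s, dd]
    return d, sire, dam


def _sparse_inverse(d: np.ndarray, sire: np.ndarray, dam: np.ndarray) -> sp.csr_matrix:
    """Assemble sum_i (1/d_i)(e_i - e_s/2 - e_d/2)(.)' as sparse CSR."""
    n = len(d)
    rows, cols, vals = [], [], []
    idx = np.arange(n)
    w = 1.0 / d
    rows.append(idx); cols.append(idx); vals.append(w)
    for par in (sire, dam):
        k = par != UNKNOWN
        i, p = idx[k], par[k]
        rows.append(i); cols.append(p); vals.append(-0.5 * w[k])
        rows.append(p); cols.append(i); vals.append(-0.5 * w[k])
    # parent x parent quarter contributions
    for pa in (sire, dam):
        for pb in (sire, dam):
            k = (pa != UNKNOWN) & (pb != UNKNOWN)
            rows.append(pa[k]); cols.append(pb[k]); vals.append(0.25 * w[k])
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n))


def _gamete_transmission(sire, dam, n) -> sp.csc_matrix:
    """Unit lower-triangular (I - B) with B holding 0.5 at parent slots."""
    rows = [np.arange(n)]
    cols = [np.arange(n)]
    vals = [np.ones(n)]
    idx = np.arange(n)
    for par in (sire, dam):
        k = par != UNKNOWN
        rows.append(idx[k]); cols.append(par[k]); vals.append(np.full(k.sum(), -0.5))
    m = sp.csc_matrix((np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n))
    m.sum_duplicates()
    return m


# ------------------------------------------------------------- public API


def build_nrm(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method (dense),
    including inbreeding: a_ii = 1 + F_i with F_i half the parents'
    relationship."""
    return RelationshipMatrix(_dense_a(ped), ped.ids.copy(), "A")


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F_i = a_ii - 1."""
    return np.diag(_dense_a(ped)) - 1.0


def build_nrm_inverse(ped: Pedigree) -> RelationshipMatrix:
    """Sparse A^-1 accounting for inbreeding (at most 9 entries contributed
    per animal, from the Mendelian-sampling decomposition)."""
    d, sire, dam = _mendelian(ped)
    return RelationshipMatrix(_sparse_inverse(d, sire, dam), ped.ids.copy(), "A_inv")


def build_gamma_nrm(ped: Pedigree, gamma: float, method: str = "recursion",
                    include_metafounder: bool = False) -> RelationshipMatrix:
    """A_gamma = (1 - gamma/2) A + gamma J.

    ``method='recursion'`` builds it through the metafounder-augmented
    tabular recursion; ``method='closed_form'`` evaluates the affine
    formula on A directly.  Both agree to machine precision.  With
    ``include_metafounder`` the metafounder row/column (self-relationship
    gamma, relationship gamma to every animal) is kept at position 0.
    """
    _check_gamma(gamma)
    if method == "closed_form":
        A = _dense_a(ped)
        Ag = (1.0 - gamma / 2.0) * A + gamma
        if include_metafounder:
            out = np.empty((ped.n + 1, ped.n + 1))
            out[0, 0] = gamma
            out[0, 1:] = gamma
            out[1:, 0] = gamma
            out[1:, 1:] = Ag
            Ag = out
    elif method == "recursion":
        Ag = _dense_a(ped, gamma, metafounder=True)
        if not include_metafounder:
            Ag = Ag[1:, 1:]
    else:
        raise ValueError(f"unknown method {method!r}")
    ids = ped.ids
    if include_metafounder:
        ids = np.concatenate(([METAFOUNDER_ID], ids.astype(object)))
    return RelationshipMatrix(Ag, np.asarray(ids), "A_gamma")


def build_gamma_nrm_inverse(ped: Pedigree, gamma: float,
                            keep_metafounder: bool = False) -> RelationshipMatrix:
    """Sparse inverse of A_gamma via the metafounder-augmented recursion.

    With ``keep_metafounder`` the (n+1) x (n+1) inverse of the augmented
    relationship matrix is returned (metafounder first); otherwise the
    metafounder is absorbed (Schur complement on its row/column), giving
    the inverse of A_gamma for the real animals.
    """
    _check_gamma(gamma)
    if gamma == 0.0:
        if keep_metafounder:
            raise ValueError("gamma=0 leaves the metafounder with zero variance; "
                             "use the plain inverse")
        return RelationshipMatrix(build_nrm_inverse(ped).values, ped.ids.copy(),
                                  "A_gamma_inv")
    d, sire, dam = _mendelian(ped, gamma, metafounder=True)
    Q = _sparse_inverse(d, sire, dam)
    if keep_metafounder:
        ids = np.concatenate(([METAFOUNDER_ID], ped.ids.astype(object)))
        return RelationshipMatrix(Q, np.asarray(ids), "A_gamma_inv")
    Q = Q.tocsc()
    q00 = Q[0, 0]
    col = Q[1:, [0]].toarray().ravel()
    Qrr = Q[1:, 1:]
    out = Qrr - sp.csr_matrix(np.outer(col, col) / q00)
    return RelationshipMatrix(out.tocsr(), ped.ids.copy(), "A_gamma_inv")


def gamma_nrm_inverse_closed_form(ped: Pedigree, gamma: float) -> np.ndarray:
    """Independent closed form for inv(A_gamma) (real animals only).

    Sherman-Morrison on A_gamma = (1 - gamma/2)(A + c 11') with
    c = gamma/(1 - gamma/2), using 1'A^-1 = (1_F' 0) and 1'A^-1 1 = F:

        inv(A_gamma) = [A^-1 - gamma/(1 - gamma/2 + gamma F) * J_F] / (1 - gamma/2)

    with J_F the all-ones block on founder rows/columns.
    """
    _check_gamma(gamma)
    Ainv = build_nrm_inverse(ped).values.toarray()
    F = ped.n_founders
    fou = ped.is_founder
    block = np.outer(fou.astype(float), fou.astype(float))
    return (Ainv - gamma / (1.0 - gamma / 2.0 + gamma * F) * block) / (1.0 - gamma / 2.0)


def _check_gamma(gamma: float) -> None:
    if not 0.0 <= gamma < 2.0:
        raise ValueError(f"gamma must be in [0, 2), got {gamma}")


def nrm_times(ped: Pedigree, v: np.ndarray, gamma: float = 0.0) -> np.ndarray:
    """Product A v (or A_gamma v) without forming A, via A = T D T' with
    T = inv(I - B) the gamete-transmission matrix (Colleau's indirect
    method).  ``v`` may be a vector or a matrix of columns."""
    v = np.asarray(v, dtype=float)
    one_d = v.ndim == 1
    V = v[:, None] if one_d else v
    if gamma == 0.0:
        d, sire, dam = _mendelian(ped)
        L = _gamete_transmission(sire, dam, ped.n)
        X = spla.spsolve_triangular(L.T.tocsr(), V, lower=False)
        X *= d[:, None]
        out = spla.spsolve_triangular(L.tocsr(), X, lower=True)
    else:
        d, sire, dam = _mendelian(ped, gamma, metafounder=True)
        L = _gamete_transmission(sire, dam, ped.n + 1)
        Vp = np.vstack([np.zeros((1, V.shape[1])), V])
        X = spla.spsolve_triangular(L.T.tocsr(), Vp, lower=False)
        X *= d[:, None]
        out = spla.spsolve_triangular(L.tocsr(), X, lower=True)[1:]
    return out.ravel() if one_d else out


def build_a22(ped: Pedigree, genotyped_ids, method: str = "auto") -> RelationshipMatrix:
    """Pedigree relationships among the genotyped animals, A22.

    ``method='direct'`` extracts the block from dense tabular A;
    ``method='indirect'`` computes the block column-by-column through
    triangular solves with the gamete-transmission factor, never forming
    A (the route of choice for large pedigrees with few genotyped
    animals).  ``'auto'`` picks direct for small problems.
    """
    g = ped.positions(genotyped_ids)
    if method == "auto":
        method = "direct" if ped.n <= 4000 or len(g) > 0.5 * ped.n else "indirect"
    if method == "direct":
        A = _dense_a(ped)
        vals = A[np.ix_(g, g)]
    elif method == "indirect":
        d, sire, dam = _mendelian(ped)
        L = _gamete_transmission(sire, dam, ped.n)
        S = np.zeros((ped.n, len(g)))
        S[g, np.arange(len(g))] = 1.0
        X = spla.spsolve_triangular(L.T.tocsr(), S, lower=False)
        vals = (X * d[:, None]).T @ X
    else:
        raise ValueError(f"unknown method {method!r}")
    return RelationshipMatrix(vals, np.asarray(genotyped_ids), "A22")


class A22InverseOperator:
    """Products with inv(A22) through the partitioned identity

        inv(A22) = A^22 - A^21 inv(A^11) A^12,

    where A^ij are blocks of sparse A^-1 (1 = non-genotyped,
    2 = genotyped).  Only A^11 is factorized (sparse LU); no large dense
    inverse is ever formed.  Also supports the analogous products for the
    gamma-scaled matrix via the affine identity on A22.
    """

    def __init__(self, ped: Pedigree, genotyped_ids):
        self.ped = ped
        self.genotyped_ids = np.asarray(genotyped_ids)
        g = ped.positions(genotyped_ids)
        mask = np.zeros(ped.n, dtype=bool)
        mask[g] = True
        order = np.argsort(g)  # caller order preserved via inverse permutation
        Ainv = build_nrm_inverse(ped).values.tocsc()
        ng = np.where(~mask)[0]
        self._perm = np.argsort(order)
        gg = g  # keep caller's order
        self.A22b = Ainv[gg][:, gg].tocsc()
        self.A21b = Ainv[gg][:, ng].tocsc()
        self.A11 = Ainv[ng][:, ng].tocsc()
        self._lu = spla.splu(self.A11) if self.A11.shape[0] else None

    def matvec(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        one_d = v.ndim == 1
        V = v[:, None] if one_d else v
        out = self.A22b @ V
        if self._lu is not None:
            t = self.A21b.T @ V
            out = out - self.A21b @ self._lu.solve(t)
        return out.ravel() if one_d else out

    def solve_ones(self) -> np.ndarray:
        return self.matvec(np.ones(len(self.genotyped_ids)))


def a22_inverse_times(ped: Pedigree, genotyped_ids, v: np.ndarray) -> np.ndarray:
    """inv(A22) @ v via the partitioned identity (factorizing A^11 only)."""
    return A22InverseOperator(ped, genotyped_ids).matvec(v)
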