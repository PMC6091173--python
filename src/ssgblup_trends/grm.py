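"""Genomic relationship matrices and G <-> A22 alignment.

The raw GRM follows the cross-product form

    G_M = (M - 2P)(M - 2P)' / s,    s = 2 sum_i p_i (1 - p_i),

with M the n2 x m matrix of allele counts in {0,1,2} and P the matrix of
centering frequencies.  Which frequencies go into P is the crux of the
trend-distortion problem, so centering is a first-class policy:
``all`` (observed, all genotyped animals), ``first`` (observed, earliest
genotyped cohort), ``founder`` (observed in the pedigree-founder cohort),
``half`` (p = 0.5 throughout, i.e. 2P = J) or an ``external`` vector.

Alignment transforms of the form G* = beta G + alpha J (mean/diagonal
matching, mean-only matching, the F_ST-style rescaling) and the
tau/omega weighted harmonic combination with A22 are provided, each with
a positive-definiteness check, since none of them guarantees a valid
covariance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linalg import NotPositiveDefiniteError, spd_factor, spd_inverse
from .nrm import RelationshipMatrix
from .pedigree import Pedigree


@dataclass
class GenotypeMatrix:
    """Allele-count matrix (n2 animals x m loci, counts in {0,1,2})."""

    counts: np.ndarray
    animal_ids: np.ndarray
    locus_ids: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.animal_ids = np.asarray(self.animal_ids)
        self.locus_ids = np.asarray(self.locus_ids)
        if self.counts.shape != (len(self.animal_ids), len(self.locus_ids)):
            raise ValueError("counts shape does not match id vectors")

    @property
    def n_animals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_loci(self) -> int:
        return self.counts.shape[1]

    def observed_frequencies(self) -> np.ndarray:
        """Per-locus allele frequency, mean(count)/2."""
        return self.counts.mean(axis=0) / 2.0

    def restrict_animals(self, ids) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.animal_ids.tolist())}
        take = np.array([pos[a] for a in np.asarray(ids).tolist()])
        return GenotypeMatrix(self.counts[take], np.asarray(ids), self.locus_ids)

    # ------------------------------------------------------------------ I/O

    def write_raw(self, path) -> None:
        """PLINK .raw-style text: header then one row per animal of
        id followed by 0/1/2 counts."""
        with open(path, "w") as fh:
            fh.write("IID " + " ".join(str(l) for l in self.locus_ids) + "\n")
            for a, row in zip(self.animal_ids, self.counts):
                fh.write(str(a) + " " + " ".join(str(int(c)) for c in row) + "\n")

    @classmethod
    def read_raw(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep=r"\s+")
        return cls(df.iloc[:, 1:].to_numpy(dtype=np.int8),
                   df.iloc[:, 0].to_numpy(), np.asarray(df.columns[1:]))

    def write_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("counts", data=self.counts.astype(np.int8),
                             compression="gzip")
            f.create_dataset("animal_ids",
                             data=np.asarray(self.animal_ids, dtype="S"))
            f.create_dataset("locus_ids",
                             data=np.asarray(self.locus_ids, dtype="S"))

    @classmethod
    def read_hdf5(cls, path) -> "GenotypeMatrix":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(f["counts"][...],
                       f["animal_ids"][...].astype(str),
                       f["locus_ids"][...].astype(str))


@dataclass
class FrequencyPolicy:
    """Which allele frequencies center the marker counts."""

    scheme: str  # all | first | founder | half | external
    reference_cohort: int | None = None
    external: np.ndarray | None = None

    def __post_init__(self):
        if self.scheme not in {"all", "first", "founder", "half", "external"}:
            raise ValueError(f"unknown frequency scheme {self.scheme!r}")


@dataclass
class AlignmentParams:
    """Record of the parameters that produced a modified GRM."""

    alpha: float = 0.0
    beta: float = 1.0
    lambda_: float = 1.0
    tau: float = 1.0
    omega: float = 1.0
    gamma: float | None = None
    diag_augment: float = 0.0
    scheme: str | None = None


# ----------------------------------------------------------------- filters


def maf_filter(g: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Drop loci whose observed minor allele frequency is below
    ``threshold`` (locus order preserved)."""
    if not 0.0 <= threshold < 0.5:
        raise ValueError("threshold must be in [0, 0.5)")
    p = g.observed_frequencies()
    keep = np.minimum(p, 1.0 - p) >= threshold
    if threshold > 0 and not keep.any():
        raise ValueError("MAF filter removed every locus")
    if keep.all():
        return g
    return GenotypeMatrix(g.counts[:, keep], g.animal_ids, g.locus_ids[keep])


def compute_frequencies(g: GenotypeMatrix, policy: FrequencyPolicy,
                        ped: Pedigree | None = None) -> np.ndarray:
    """Centering frequencies p_i under a policy.

    ``first``/``founder`` average counts over the genotyped animals of the
    earliest genotyped cohort / of the reference (founder) cohort, looked
    up in the pedigree; ``half`` is 0.5 everywhere.
    """
    if policy.scheme == "half":
        return np.full(g.n_loci, 0.5)
    if policy.scheme == "external":
        p = np.asarray(policy.external, dtype=float)
        if p.shape != (g.n_loci,):
            raise ValueError("external frequency vector has wrong length")
        return p
    if policy.scheme == "all":
        return g.observed_frequencies()
    if ped is None:
        raise ValueError(f"scheme {policy.scheme!r} needs a pedigree")
    cohorts = ped.cohort[ped.positions(g.animal_ids)]
    if policy.scheme == "first":
        ref = cohorts.min()
    else:  # founder
        ref = (policy.reference_cohort if policy.reference_cohort is not None
               else int(ped.cohort.min()))
    mask = cohorts == ref
    if not mask.any():
        raise ValueError(f"no genotyped animals in reference cohort {ref}")
    return g.counts[mask].mean(axis=0) / 2.0


# --------------------------------------------------------------------- GRM


def heterozygosity_scale(p: np.ndarray) -> float:
    """s = 2 sum_i p_i (1 - p_i)."""
    return float(2.0 * np.sum(p * (1.0 - p)))


def build_grm(g: GenotypeMatrix, p: np.ndarray,
              diag_augment: float = 0.0) -> tuple[RelationshipMatrix, float]:
    """VanRaden cross-product GRM from counts and centering frequencies.

    Returns (G, s).  ``diag_augment`` (0.05 in the default analysis
    pipeline) is added to the diagonal after the cross-product, ensuring
    a safely positive-definite matrix without blending.
    """
    p = np.asarray(p, dtype=float)
    s = heterozygosity_scale(p)
    if s <= 0.0:
        raise ValueError("heterozygosity scale s = 2*sum p(1-p) is zero")
    Mc = g.counts.astype(float) - 2.0 * p
    G = (Mc @ Mc.T) / s
    if diag_augment:
        G[np.diag_indices_from(G)] += diag_augment
    return RelationshipMatrix(G, g.animal_ids.copy(), "G"), s


def grm_from_crossproduct(mmt: np.ndarray, counts: np.ndarray, p: np.ndarray,
                          diag_augment: float = 0.0) -> tuple[np.ndarray, float]:
    """GRM from a precomputed raw cross-product MM'.

    Because centering is a per-locus constant shift,
    (M-2P)(M-2P)' = MM' - u1' - 1u' + (4 sum p_i^2) J with u = M (2p);
    this lets one GEMM on the raw counts serve every centering policy.
    Returns (G, s); equivalent to :func:`build_grm`.
    """
    p = np.asarray(p, dtype=float)
    s = heterozygosity_scale(p)
    if s <= 0.0:
        raise ValueError("heterozygosity scale s = 2*sum p(1-p) is zero")
    u = counts.astype(float) @ (2.0 * p)
    G = (mmt - u[:, None] - u[None, :] + np.sum((2.0 * p) ** 2)) / s
    if diag_augment:
        G[np.diag_indices_from(G)] += diag_augment
    return G, s


def check_positive_definite(G: np.ndarray, what: str = "G*") -> None:
    """Cholesky-based PD check; raises NotPositiveDefiniteError."""
    spd_factor(G, what)


# -------------------------------------------------------------- alignments


def blend_with_a22(G: RelationshipMatrix, A22: RelationshipMatrix,
                   lambda_: float) -> RelationshipMatrix:
    """G* = lambda G + (1 - lambda) A22 (shrink the GRM toward the NRM)."""
    if not 0.0 <= lambda_ <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    _check_conformable(G, A22)
    return RelationshipMatrix(lambda_ * G.toarray() + (1.0 - lambda_) * A22.toarray(),
                              G.index.copy(), "G_star")


def align_mean_diag(G: RelationshipMatrix, A22: RelationshipMatrix,
                    require_pd: bool = True):
    """Match both the mean diagonal and the overall mean of G to A22:

        alpha = [tr(A22) - tr(G)] / n2  ... combined with
        beta  = [tr(A22) - 1'A22 1/n2] / [tr(G) - 1'G 1/n2],

    returning (params, G* = beta G + alpha J).  alpha here follows from
    solving the two moment equations jointly; a near-zero beta
    denominator (G with no spread between diagonal and mean) fails.
    """
    _check_conformable(G, A22)
    Gv, Av = G.toarray(), A22.toarray()
    n2 = Gv.shape[0]
    den = np.trace(Gv) - Gv.sum() / n2
    if abs(den) < 1e-12 * max(1.0, abs(np.trace(Gv))):
        raise ZeroDivisionError("degenerate G: beta denominator ~ 0")
    beta = (np.trace(Av) - Av.sum() / n2) / den
    alpha = (np.trace(Av) - beta * np.trace(Gv)) / n2
    Gs = beta * Gv + alpha
    if require_pd:
        check_positive_definite(Gs)
    params = AlignmentParams(alpha=float(alpha), beta=float(beta))
    return params, RelationshipMatrix(Gs, G.index.copy(), "G_star")


def align_mean(G: RelationshipMatrix, A22: RelationshipMatrix):
    """Mean-only matching: alpha = (1'A22 1 - 1'G 1)/n2^2, beta = 1.

    After G* = G + alpha J the element means of G* and A22 agree exactly.
    A negative alpha (G on average larger than A22, e.g. under founder or
    half centering) is returned as-is; the caller decides whether the
    resulting G* is usable.
    """
    _check_conformable(G, A22)
    n2 = G.shape[0]
    alpha = float((A22.toarray().sum() - G.toarray().sum()) / n2 ** 2)
    Gs = G.toarray() + alpha
    params = AlignmentParams(alpha=alpha, beta=1.0)
    return params, RelationshipMatrix(Gs, G.index.copy(), "G_star")


def fst_adjust(G: RelationshipMatrix, alpha: float,
               require_pd: bool = True) -> RelationshipMatrix:
    """Base-population change via the fixation-index rescaling:
    G* = (1 - alpha/2) G + alpha J, with alpha the mean-matching offset
    (interpretable as twice F_ST of the pedigree base relative to the
    genomic base)."""
    Gs = (1.0 - alpha / 2.0) * G.toarray() + alpha
    if require_pd:
        check_positive_definite(Gs)
    return RelationshipMatrix(Gs, G.index.copy(), "G_star")


def tau_omega_combine(G: RelationshipMatrix, A22: RelationshipMatrix,
                      tau: float, omega: float) -> RelationshipMatrix:
    """Weighted harmonic combination G* = inv(tau G^-1 + (1-omega) A22^-1),
    the matrix replaced in H when G^-1 and A22^-1 get weights tau and
    omega in the H^-1 correction block."""
    _check_conformable(G, A22)
    Gi = spd_inverse(G.toarray(), "G")
    Ai = spd_inverse(A22.toarray(), "A22")
    M = tau * Gi + (1.0 - omega) * Ai
    Gs = spd_inverse(M, "tau/omega combination")
    check_positive_definite(Gs)
    return RelationshipMatrix(Gs, G.index.copy(), "G_star")


def _check_conformable(G: RelationshipMatrix, A22: RelationshipMatrix) -> None:
    if G.shape != A22.shape or not np.array_equal(G.index, A22.index):
        raise ValueError("G and A22 indices do not match")
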