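"""Estimation of the metafounder self-relationship gamma.

gamma (in [0, 2)) measures how related/inbred the pedigree founders are
relative to an ideal base with allele frequencies 0.5 at every locus; it
equals twice the F_ST of the founder population against that base.
Three estimators are implemented:

* ``gls``: per-locus generalised least-squares means of the uncentered
  allele counts, mu_i = (1'inv(A22)1)^-1 1'inv(A22) m_i (estimates of
  twice the founder frequencies); gamma = 2 * Var_loci(mu_i).
* ``summary``: closed-form moment estimator from 1'McMc'1, tr(McMc'),
  1'A22 1 and tr(A22), with Mc = M - J (counts centered at 0.5).
* ``likelihood``: 1-D profile maximum likelihood in gamma, with the
  heterozygosity scale s profiled out in closed form at each gamma.

All three need only genotypes and the pedigree; phenotype-augmented
estimation is not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la
from scipy.optimize import minimize_scalar

from .grm import GenotypeMatrix
from .nrm import A22InverseOperator, RelationshipMatrix, build_a22
from .pedigree import Pedigree


@dataclass
class GammaEstimate:
    gamma: float
    s: float
    method: str
    mu_hat: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        # the degenerate two-point estimate can reach exactly 2
        if not 0.0 <= self.gamma <= 2.0:
            raise ValueError(f"estimated gamma {self.gamma} outside [0, 2]")
        if self.s <= 0:
            raise ValueError("heterozygosity scale s must be positive")


# ------------------------------------------------------------------- GLS


def gls_founder_means(ped: Pedigree, g: GenotypeMatrix) -> np.ndarray:
    """GLS estimates mu_i of twice the founder allele frequencies.

    Uses the partitioned-inverse route for inv(A22) @ 1 (sparse
    factorization of the non-genotyped block of A^-1 only), so it scales
    to many genotyped animals.
    """
    if g.n_animals == 0:
        raise ValueError("no genotyped animals")
    op = A22InverseOperator(ped, g.animal_ids)
    w = op.solve_ones()                      # inv(A22) 1
    denom = float(w.sum())                   # 1' inv(A22) 1
    return (w @ g.counts.astype(float)) / denom


def gamma_gls(mu_hat: np.ndarray, s: float | None = None) -> GammaEstimate:
    """gamma = twice the across-locus variance of the GLS founder means
    (population-variance convention, denominator m)."""
    mu_hat = np.asarray(mu_hat, dtype=float)
    if mu_hat.size < 2:
        raise ValueError("need at least 2 loci")
    gamma = 2.0 * float(np.var(mu_hat))
    if s is None:
        # heterozygosity implied by the estimated frequencies p_i = mu_i/2
        p = mu_hat / 2.0
        s = float(2.0 * np.sum(p * (1.0 - p)))
    return GammaEstimate(gamma=gamma, s=s, method="gls", mu_hat=mu_hat)


def estimate_gamma_gls(ped: Pedigree, g: GenotypeMatrix) -> GammaEstimate:
    return gamma_gls(gls_founder_means(ped, g))


# --------------------------------------------------------------- summary


def gamma_summary(g: GenotypeMatrix, A22: RelationshipMatrix) -> GammaEstimate:
    """Closed-form moment estimators of s and gamma.

    With Mc = M - J (counts centered at frequency 0.5), q1 = 1'McMc'1,
    qt = tr(McMc'), a1 = 1'A22 1 and at = tr(A22):

        s     = [n2 qt (1 - a1/(2 n2^2)) - q1 (1 - at/(2 n2))]
                / (n2 at - a1)
        gamma = (q1/s - a1) / (n2^2 - a1/2)
    """
    Mc = g.counts.astype(float) - 1.0
    n2 = g.n_animals
    Av = A22.toarray()
    r = Mc.sum(axis=0)                       # 1'Mc per locus
    q1 = float(r @ r)                        # 1'McMc'1
    qt = float(np.einsum("ij,ij->", Mc, Mc)) # tr(McMc')
    a1 = float(Av.sum())
    at = float(np.trace(Av))
    den = n2 * at - a1
    if abs(den) < 1e-10 * max(1.0, abs(n2 * at)):
        raise ZeroDivisionError("degenerate A22: n2 tr(A22) = 1'A22 1")
    s = (n2 * qt * (1.0 - a1 / (2.0 * n2 ** 2))
         - q1 * (1.0 - at / (2.0 * n2))) / den
    if s <= 0:
        raise ValueError("summary estimator produced non-positive s")
    gamma = (q1 / s - a1) / (n2 ** 2 - a1 / 2.0)
    return GammaEstimate(gamma=float(np.clip(gamma, 0.0, 2.0 - 1e-9)),
                         s=s, method="summary")


def estimate_gamma_summary(ped: Pedigree, g: GenotypeMatrix) -> GammaEstimate:
    return gamma_summary(g, build_a22(ped, g.animal_ids))


# ------------------------------------------------------------ likelihood


def gamma_likelihood(ped: Pedigree, g: GenotypeMatrix,
                     xatol: float = 1e-4) -> GammaEstimate:
    """Profile maximum likelihood for gamma under half centering.

    Maximizes
        log L = -(m/2) [ n2 log s + log|A22_gamma|
                         + tr(inv(A22_gamma) McMc')/s ]
    over gamma in [0, 2), with
        s(gamma) = tr(inv(A22_gamma) McMc') / n2
    profiled out in closed form.  Bounded scalar search (1-D, smooth).
    """
    Mc = g.counts.astype(float) - 1.0
    n2, m = Mc.shape
    K = Mc @ Mc.T
    A22 = build_a22(ped, g.animal_ids).toarray()

    def neg_profile_loglik(gamma: float) -> float:
        Ag = (1.0 - gamma / 2.0) * A22 + gamma
        c, low = la.cho_factor(Ag, lower=True, check_finite=False)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        tr = float(np.trace(la.cho_solve((c, low), K, check_finite=False)))
        s = tr / n2
        return 0.5 * m * (n2 * np.log(s) + logdet + n2)

    res = minimize_scalar(neg_profile_loglik, bounds=(1e-6, 1.999),
                          method="bounded", options={"xatol": xatol})
    if not res.success:
        raise RuntimeError(f"gamma likelihood search failed: {res}")
    gamma = float(res.x)
    Ag = (1.0 - gamma / 2.0) * A22 + gamma
    s = float(np.trace(la.solve(Ag, K, assume_a="pos"))) / n2
    return GammaEstimate(gamma=gamma, s=s, method="likelihood")
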