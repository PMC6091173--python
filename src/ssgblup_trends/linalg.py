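"""Thin SPD linear-algebra helpers (direct LAPACK calls).

All dense symmetric-positive-definite work in the package (PD checks,
inverses for the H^-1 correction block, mixed-model solves) goes through
dpotrf/dpotri/dpotrs on Fortran-ordered arrays.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import lapack


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    """A matrix required to be positive definite failed its Cholesky."""


def spd_factor(a: np.ndarray, what: str = "matrix") -> np.ndarray:
    """Lower Cholesky factor (Fortran-ordered); raises if not PD."""
    c, info = lapack.dpotrf(np.asfortranarray(a), lower=1)
    if info != 0:
        raise NotPositiveDefiniteError(
            f"{what} is not positive definite (dpotrf info={info})")
    return c


def spd_inverse(a: np.ndarray, what: str = "matrix") -> np.ndarray:
    """Inverse of an SPD matrix via dpotrf + dpotri (symmetrized)."""
    c = spd_factor(a, what)
    inv, info = lapack.dpotri(c, lower=1)
    if info != 0:  # pragma: no cover - dpotri failure after good dpotrf
        raise np.linalg.LinAlgError(f"dpotri failed (info={info})")
    inv = np.tril(inv)
    return inv + np.tril(inv, -1).T


def spd_solve(a: np.ndarray, b: np.ndarray, what: str = "matrix") -> np.ndarray:
    """Solve a x = b for SPD a."""
    c = spd_factor(a, what)
    x, info = lapack.dpotrs(c, np.asfortranarray(b), lower=1)
    if info != 0:  # pragma: no cover
        raise np.linalg.LinAlgError(f"dpotrs failed (info={info})")
    return x


def factor_solve(c: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve with a precomputed lower factor from :func:`spd_factor`."""
    x, info = lapack.dpotrs(c, np.asfortranarray(b), lower=1)
    if info != 0:  # pragma: no cover
        raise np.linalg.LinAlgError(f"dpotrs failed (info={info})")
    return x


def factor_logdet(c: np.ndarray) -> float:
    """log|A| from a Cholesky factor of A."""
    return 2.0 * float(np.sum(np.log(np.diag(c))))
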