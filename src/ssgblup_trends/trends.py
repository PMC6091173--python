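"""Genetic-trend curves and the outcome metrics of the study.

A trend curve is the mean EBV per birth cohort.  Curves are compared
after standardizing their location (subtracting the generation-0 mean),
so the Euclidean (Frobenius) norm of the difference between a genomic
and the pedigree curve reflects only differences in *shape*.  Dispersion
of EBV is measured by the OLS slope of true on predicted breeding
values in the final cohort (slope < 1: overdispersion; > 1:
under-dispersion).  Under the metafounder model the metafounder solution
estimates the location shift of GEBV, and subtracting it re-aligns the
raw genomic curve with the pedigree one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ssgblup import EvaluationResult


@dataclass
class TrendCurve:
    cohorts: np.ndarray
    mean_ebv: np.ndarray
    model_label: str = ""
    standardized: bool = False

    def __post_init__(self):
        self.cohorts = np.asarray(self.cohorts)
        self.mean_ebv = np.asarray(self.mean_ebv, dtype=float)
        if len(self.cohorts) != len(self.mean_ebv):
            raise ValueError("cohort and mean vectors differ in length")
        if self.standardized and abs(self.mean_ebv[0]) > 1e-10:
            raise ValueError("standardized curve must start at 0")


def cohort_means(values: pd.Series | EvaluationResult, cohorts: np.ndarray,
                 label: str = "") -> TrendCurve:
    """Mean EBV per cohort, cohorts ascending.

    ``values`` is a per-animal Series (or an EvaluationResult, whose EBV
    are used); ``cohorts`` gives each animal's cohort in the same order.
    A pseudo-animal such as the metafounder must not appear here.
    """
    if isinstance(values, EvaluationResult):
        values = values.ebv
    v = values.to_numpy() if isinstance(values, pd.Series) else np.asarray(values)
    cohorts = np.asarray(cohorts)
    if len(v) != len(cohorts):
        raise ValueError("values and cohorts differ in length")
    labels = np.unique(cohorts)
    means = np.empty(len(labels))
    for i, c in enumerate(labels):
        sel = cohorts == c
        if not sel.any():
            raise ValueError(f"empty cohort {c}")
        means[i] = v[sel].mean()
    return TrendCurve(labels, means, label)


def standardize(curve: TrendCurve) -> TrendCurve:
    """Subtract the first (generation-0) value; location-free curve."""
    return replace(curve, mean_ebv=curve.mean_ebv - curve.mean_ebv[0],
                   standardized=True)


def trend_discrepancy_norm(genomic: TrendCurve, pedigree: TrendCurve) -> float:
    """Euclidean norm of the elementwise difference of two standardized
    curves over identical cohorts (shape discrepancy only)."""
    if not (genomic.standardized and pedigree.standardized):
        raise ValueError("standardize both curves first")
    if not np.array_equal(genomic.cohorts, pedigree.cohorts):
        raise ValueError("cohort labels do not match")
    return float(np.linalg.norm(genomic.mean_ebv - pedigree.mean_ebv))


def regression_true_on_predicted(tbv: np.ndarray, ebv: np.ndarray) -> float:
    """OLS slope of TBV on EBV (intercept fitted and discarded):
    cov(TBV, EBV)/var(EBV)."""
    tbv = np.asarray(tbv, dtype=float)
    ebv = np.asarray(ebv, dtype=float)
    var = np.var(ebv)
    if var == 0:
        raise ZeroDivisionError("zero EBV variance")
    return float(np.cov(tbv, ebv, bias=True)[0, 1] / var)


def metafounder_adjusted_trend(curve: TrendCurve, mf_solution: float) -> TrendCurve:
    """Subtract the metafounder solution from an (un-standardized) curve:
    the location correction that re-bases GEBV onto the pedigree base."""
    if mf_solution is None:
        raise ValueError("no metafounder solution available")
    if curve.standardized:
        raise ValueError("adjust the raw curve, not a standardized one")
    return replace(curve, mean_ebv=curve.mean_ebv - mf_solution)
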