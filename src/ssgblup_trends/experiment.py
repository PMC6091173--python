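"""Factorial experiment: models x centering schemes x genotyped
generations x replicates.

Each replicate simulates one population and evaluates every analysis
cell on it (the study design: one simulation, many analyses), recording
per cell the trend-discrepancy norm against pedigree BLUP (both the raw
Euclidean norm and its per-cohort RMS ``rms = norm/sqrt(n_cohorts)``,
which does not grow with the number of cohorts compared), the
final-generation slope of true on predicted breeding values, and the
alignment parameters (alpha, gamma, metafounder solution).  Cells whose
modified GRM is invalid (negative alpha making G* non-positive-definite,
which hits MG under founder or half centering) are recorded as failures
and skipped, not fatal.

The runner shares expensive intermediates across cells of a replicate:
dense A is built once, each genotype subset's raw cross-product MM'
serves every centering scheme, and the pedigree-BLUP solution is reused
as the reference for every norm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg as la

from . import grm as grm_mod
from .gamma import gamma_gls
from .grm import FrequencyPolicy, NotPositiveDefiniteError, maf_filter
from .linalg import spd_inverse
from .nrm import build_gamma_nrm_inverse, build_nrm_inverse, _dense_a
from .simulate import PopulationData, SimulationConfig, simulate, subset_genotypes
from .ssgblup import HInverse, ModelSpec, solve_mme
from .trends import (cohort_means, regression_true_on_predicted, standardize,
                     trend_discrepancy_norm)

log = logging.getLogger(__name__)

INVALID_CELLS = {("MG", "founder"), ("MG", "half")}


@dataclass
class ExperimentGrid:
    """The study grid.  ``cells`` are (model, scheme) pairs; pedigree
    BLUP is always run as the reference."""

    cells: tuple = (("M0", "all"), ("M0", "first"), ("M0", "founder"),
                    ("M0", "half"), ("MG", "all"), ("MA", "half"))
    first_genotyped_generations: tuple = (0, 2, 4, 7, 10)
    replicates: int = 5
    base_seed: int = 0
    config: SimulationConfig = field(default_factory=SimulationConfig.reduced)
    maf_threshold: float = 0.02
    diag_augment: float = 0.05
    thin_every: int | None = None

    def valid_cells(self):
        out = []
        for cell in self.cells:
            if cell in INVALID_CELLS:
                log.warning("skipping invalid cell %s (negative alpha -> "
                            "non-PD G*)", cell)
            else:
                out.append(cell)
        return out


@dataclass
class SummaryTable:
    """Per-cell means and SDs over replicates, plus the raw per-run rows."""

    per_run: pd.DataFrame
    summary: pd.DataFrame
    seeds: np.ndarray


def _replicate_seeds(base_seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(base_seed)
    return (ss.generate_state(n) & 0x7FFFFFFF).astype(np.int64)


def evaluate_replicate(pop: PopulationData, grid: ExperimentGrid,
                       seed: int) -> list[dict]:
    """All analysis cells on one simulated population."""
    ped = pop.pedigree
    n = ped.n
    cohorts = pop.generation_of
    final = cohorts == cohorts.max()
    tbv_final = pop.true_breeding_values[final]
    y = pop.phenotypes
    rec_ids = ped.ids
    cfg = grid.config
    spec0 = ModelSpec(model="PED", sigma2_g=cfg.h2 * cfg.phenotypic_variance,
                      sigma2_e=(1 - cfg.h2) * cfg.phenotypic_variance)

    rows = []

    def record(model, scheme, first_gen, **kw):
        rows.append(dict(seed=seed, model=model, scheme=scheme,
                         first_gen=first_gen, status=kw.pop("status", "ok"), **kw))

    n_cohorts = len(np.unique(cohorts))

    # ---- reference: pedigree BLUP -------------------------------------
    Ainv = build_nrm_inverse(ped)
    hinv_ped = HInverse(Ainv.values.tocsr(), None, None, ped.ids, False)
    res_ped = solve_mme(y, None, rec_ids, hinv_ped, spec0)
    curve_ped = standardize(cohort_means(res_ped, cohorts, "PED"))
    slope_ped = regression_true_on_predicted(tbv_final,
                                             res_ped.ebv.to_numpy()[final])
    record("PED", "-", -1, norm=0.0, rms=0.0, slope=slope_ped, alpha=np.nan,
           gamma=np.nan, mf_solution=np.nan)

    A = _dense_a(ped)  # shared across subsets
    founder_rows = np.where(cohorts == 0)[0]

    for first_gen in grid.first_genotyped_generations:
        gsub = maf_filter(subset_genotypes(pop, first_gen, grid.thin_every),
                          grid.maf_threshold)
        gpos = ped.positions(gsub.animal_ids)
        n2 = gsub.n_animals
        A22v = A[np.ix_(gpos, gpos)]
        A22inv = spd_inverse(A22v, "A22")
        counts = gsub.counts.astype(float)
        mmt = counts @ counts.T
        # founder frequencies at the subset's loci (simulation truth cohort)
        loc = {l: j for j, l in enumerate(pop.genotypes.locus_ids.tolist())}
        lcols = np.array([loc[l] for l in gsub.locus_ids.tolist()])
        p_fou = pop.genotypes.counts[np.ix_(founder_rows, lcols)].mean(axis=0) / 2.0

        # gamma for this subset (GLS through the cached dense inverse)
        w = A22inv @ np.ones(n2)
        mu_hat = (w @ counts) / w.sum()
        gam = gamma_gls(mu_hat).gamma

        def freqs(scheme):
            if scheme == "founder":
                return p_fou
            policy = FrequencyPolicy(scheme)
            return grm_mod.compute_frequencies(gsub, policy, ped)

        pcache: dict[str, np.ndarray] = {}

        def freqs_cached(scheme):
            if scheme not in pcache:
                pcache[scheme] = freqs(scheme)
            return pcache[scheme]

        ginv_cache: dict = {}   # (p-bytes, alpha) -> inv(G*)
        solved: dict = {}       # (pedigree-kind, p-bytes, alpha) -> result
        mf_sparse = None        # metafounder-augmented inverse, shared

        for model, scheme in grid.valid_cells():
            spec = ModelSpec(model=model, scheme=scheme,
                             gamma=gam if model == "MA" else None,
                             diag_augment=grid.diag_augment,
                             sigma2_g=spec0.sigma2_g, sigma2_e=spec0.sigma2_e)
            alpha = np.nan
            try:
                p = freqs_cached(scheme)
                pkey = hash(p.tobytes())
                a_off = 0.0
                if model == "MG":
                    G, _ = grm_mod.grm_from_crossproduct(
                        mmt, gsub.counts, p, grid.diag_augment)
                    alpha = float((A22v.sum() - G.sum()) / n2 ** 2)
                    a_off = round(alpha, 12)
                kind = "MA" if (model == "MA" and gam > 0) else "plain"
                skey = (kind, pkey, a_off)
                res = solved.get(skey)
                if res is None:
                    gkey = (pkey, a_off)
                    if gkey not in ginv_cache:
                        if model != "MG":
                            G, _ = grm_mod.grm_from_crossproduct(
                                mmt, gsub.counts, p, grid.diag_augment)
                        else:
                            G += alpha
                        ginv_cache[gkey] = spd_inverse(
                            G, f"G* ({model}/{scheme})")
                    Ginv = ginv_cache[gkey]
                    if kind == "MA":
                        A22g = (1.0 - gam / 2.0) * A22v + gam
                        corr = Ginv - spd_inverse(A22g, "A22_gamma")
                        if mf_sparse is None:
                            mf_sparse = build_gamma_nrm_inverse(
                                ped, gam, keep_metafounder=True)
                        hinv = HInverse(mf_sparse.values.tocsr(), corr,
                                        gpos + 1, mf_sparse.index, True)
                    else:
                        corr = Ginv - A22inv
                        hinv = HInverse(Ainv.values.tocsr(), corr, gpos,
                                        ped.ids, False)
                    res = solve_mme(y, None, rec_ids, hinv, spec)
                    solved[skey] = res
            except (NotPositiveDefiniteError, RuntimeError,
                    la.LinAlgError) as e:
                log.warning("cell %s/%s gen>=%s failed: %s", model, scheme,
                            first_gen, e)
                record(model, scheme, first_gen, norm=np.nan, rms=np.nan,
                       slope=np.nan,
                       alpha=alpha if model == "MG" else np.nan,
                       gamma=gam if model == "MA" else np.nan,
                       mf_solution=np.nan, status=f"failed: {e}")
                continue
            curve = standardize(cohort_means(res, cohorts, f"{model}/{scheme}"))
            norm = trend_discrepancy_norm(curve, curve_ped)
            slope = regression_true_on_predicted(tbv_final,
                                                 res.ebv.to_numpy()[final])
            record(model, scheme, first_gen, norm=norm,
                   rms=norm / np.sqrt(n_cohorts), slope=slope,
                   alpha=alpha, gamma=gam if model == "MA" else np.nan,
                   mf_solution=res.mf_solution if model == "MA" else np.nan)
    return rows


def run_experiment(grid: ExperimentGrid) -> SummaryTable:
    """Simulate ``replicates`` populations and evaluate the full grid on
    each; aggregate per-cell means and SDs.  Fully deterministic given
    ``base_seed`` (each replicate's seed is derived and recorded)."""
    seeds = _replicate_seeds(grid.base_seed, grid.replicates)
    rows = []
    for r, seed in enumerate(seeds):
        log.info("replicate %d/%d (seed %d)", r + 1, grid.replicates, seed)
        cfg = replace(grid.config, seed=int(seed))
        pop = simulate(cfg)
        rep_rows = evaluate_replicate(pop, grid, int(seed))
        for row in rep_rows:
            row["replicate"] = r
        rows.extend(rep_rows)
    per_run = pd.DataFrame(rows)
    ok = per_run[per_run.status == "ok"]
    summary = (ok.groupby(["model", "scheme", "first_gen"])
               .agg(norm_mean=("norm", "mean"), norm_sd=("norm", "std"),
                    rms_mean=("rms", "mean"), rms_sd=("rms", "std"),
                    slope_mean=("slope", "mean"), slope_sd=("slope", "std"),
                    alpha_mean=("alpha", "mean"), gamma_mean=("gamma", "mean"),
                    mf_mean=("mf_solution", "mean"), n=("norm", "size"))
               .reset_index())
    return SummaryTable(per_run=per_run, summary=summary, seeds=seeds)
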