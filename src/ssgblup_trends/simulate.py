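"""Forward-in-time simulation of a livestock population under
pedigree-BLUP truncation selection.

The scenario: an ancestral population at allele frequency 0.5 per locus
drifts for a configurable number of Wright-Fisher generations at small
effective size, so that the pedigree founders (generation 0) carry
ancestral relationships invisible to the pedigree (target metafounder
self-relationship gamma = 2 F_ST around 0.5).  Founders then form the
initial breeding herd, and 10 overlapping generations are bred by
truncation selection on pedigree-BLUP EBV: each cycle the lowest-EBV
sires and dams in service are replaced by the highest-EBV young
candidates of the matching sex, every dam in service produces one
offspring by a randomly drawn service sire, and a trait with heritability
h2 and phenotypic variance sigma2_P is recorded on both sexes.

Gametes segregate independently per locus (gene dropping without a
recombination map); QTL are a random subset of loci, excluded from the
marker panel, with normal effects rescaled so the founder TBV variance
equals h2 * sigma2_P exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grm import GenotypeMatrix
from .pedigree import UNKNOWN, Pedigree
from .ssgblup import ModelSpec, pedigree_blup


@dataclass
class SimulationConfig:
    """Simulation scenario; defaults reproduce the full-scale study design
    (2800 founders = 200 sires + 2600 dams in service, 2600 offspring per
    generation for 10 generations, 80/520 sire/dam replacements, trait
    with h2 = 0.3 and phenotypic variance 10, 46,500 loci incl. 500 QTL,
    MAF threshold 0.02)."""

    n_founders: int = 2800
    n_per_generation: int = 2600
    n_generations: int = 10
    n_sires_in_service: int = 200
    n_dams_in_service: int = 2600
    n_sire_replacements_per_gen: int = 80
    n_dam_replacements_per_gen: int = 520
    n_loci: int = 46500
    n_qtl: int = 500
    effective_size: int = 100        # historical-drift diploid N_e
    n_drift_generations: int = 60    # Wright-Fisher generations of drift
    h2: float = 0.3
    phenotypic_variance: float = 10.0
    maf_threshold: float = 0.02
    selection: bool = True           # False: random replacement (drift only)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if self.n_qtl >= self.n_loci:
            raise ValueError("n_qtl must be smaller than n_loci")
        if (self.n_sire_replacements_per_gen > self.n_sires_in_service
                or self.n_dam_replacements_per_gen > self.n_dams_in_service):
            raise ValueError("replacements exceed parents in service")
        if self.n_founders < self.n_sires_in_service + self.n_dams_in_service:
            raise ValueError("founders cannot fill the initial breeding herd")
        if self.n_per_generation != self.n_dams_in_service:
            raise ValueError("one offspring per dam in service: "
                             "n_per_generation must equal n_dams_in_service")

    @classmethod
    def reduced(cls, seed: int = 0, **kw) -> "SimulationConfig":
        """Desk-scale variant preserving the selected fractions of the
        full design (6% of male candidates, 40% of female candidates;
        40%/20% of sires/dams in service replaced per cycle)."""
        base = dict(n_founders=430, n_per_generation=400,
                    n_sires_in_service=30, n_dams_in_service=400,
                    n_sire_replacements_per_gen=12,
                    n_dam_replacements_per_gen=80,
                    n_loci=5000, n_qtl=500, seed=seed)
        base.update(kw)
        return cls(**base)


@dataclass
class FounderGenotypes:
    """Founder allele counts plus both frequency vectors (ancestral and
    realized post-drift, for the loci surviving the MAF filter)."""

    genotypes: GenotypeMatrix
    ancestral_freqs: np.ndarray
    realized_freqs: np.ndarray


@dataclass
class PopulationData:
    pedigree: Pedigree
    genotypes: GenotypeMatrix          # markers only, QTL excluded
    true_breeding_values: np.ndarray   # aligned with pedigree rows
    phenotypes: np.ndarray
    generation_of: np.ndarray
    qtl_locus_ids: np.ndarray = field(default=None, repr=False)
    founder_realized_freqs: np.ndarray = field(default=None, repr=False)


def _split_rng(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_founder_genotypes(cfg: SimulationConfig,
                               rng: np.random.Generator | None = None
                               ) -> FounderGenotypes:
    """Drifted founder genotypes.

    Wright-Fisher drift of per-locus frequencies (ancestral value 0.5)
    for ``n_drift_generations`` at diploid size ``effective_size``;
    founders then draw two gametes each from the final frequencies.
    Loci with realized founder minor-allele frequency below the MAF
    threshold are dropped.
    """
    if rng is None:
        rng = _split_rng(cfg.seed, 3)[0]
    two_n = 2 * cfg.effective_size
    p = np.full(cfg.n_loci, 0.5)
    for _ in range(cfg.n_drift_generations):
        p = rng.binomial(two_n, p) / two_n
    counts = rng.binomial(2, p, size=(cfg.n_founders, cfg.n_loci)).astype(np.int8)
    realized = counts.mean(axis=0) / 2.0
    keep = np.minimum(realized, 1.0 - realized) >= cfg.maf_threshold
    if not keep.any():
        raise RuntimeError(
            f"all {cfg.n_loci} loci fixed or below MAF {cfg.maf_threshold} after "
            f"{cfg.n_drift_generations} drift generations at N_e={cfg.effective_size}")
    locus_ids = np.array([f"L{i}" for i in np.where(keep)[0]])
    gm = GenotypeMatrix(counts[:, keep], np.arange(1, cfg.n_founders + 1), locus_ids)
    return FounderGenotypes(gm, np.full(keep.sum(), 0.5), realized[keep])


def _gametes(geno: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per row: homozygotes transmit deterministically,
    heterozygotes segregate independently per locus."""
    out = (geno == 2).astype(np.int8)
    het = geno == 1
    out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return out


def simulate_selected_population(cfg: SimulationConfig,
                                 founders: FounderGenotypes,
                                 rng: np.random.Generator | None = None
                                 ) -> PopulationData:
    """Breed ``n_generations`` of ``n_per_generation`` animals under
    truncation selection on pedigree-BLUP EBV (true variance components
    plugged in), starting from the drifted founders."""
    if rng is None:
        rng = _split_rng(cfg.seed, 3)[1]
    n_total = cfg.n_founders + cfg.n_generations * cfg.n_per_generation
    m = founders.genotypes.n_loci
    if cfg.n_qtl >= m:
        raise ValueError("fewer post-filter loci than requested QTL")

    geno = np.zeros((n_total, m), dtype=np.int8)
    geno[:cfg.n_founders] = founders.genotypes.counts
    qtl = np.sort(rng.choice(m, cfg.n_qtl, replace=False))
    is_qtl = np.zeros(m, dtype=bool)
    is_qtl[qtl] = True

    # QTL effects rescaled so founder TBV variance is exactly h2*sigma2_P
    sigma2_g = cfg.h2 * cfg.phenotypic_variance
    sigma2_e = (1.0 - cfg.h2) * cfg.phenotypic_variance
    effects = rng.normal(size=cfg.n_qtl)
    tbv_f = geno[:cfg.n_founders, qtl].astype(float) @ effects
    sd = tbv_f.std()
    if sigma2_g > 0 and sd > 0:
        effects *= np.sqrt(sigma2_g) / sd
    else:
        effects[:] = 0.0
    tbv = np.zeros(n_total)
    tbv[:cfg.n_founders] = geno[:cfg.n_founders, qtl].astype(float) @ effects
    tbv_shift = tbv[:cfg.n_founders].mean()   # founder mean defines TBV zero
    tbv[:cfg.n_founders] -= tbv_shift

    pheno = np.zeros(n_total)
    pheno[:cfg.n_founders] = (tbv[:cfg.n_founders]
                              + rng.normal(0, np.sqrt(sigma2_e), cfg.n_founders))

    sire = np.full(n_total, UNKNOWN, dtype=np.int64)
    dam = np.full(n_total, UNKNOWN, dtype=np.int64)
    sex = np.empty(n_total, dtype=np.int64)   # 0 male, 1 female
    gen = np.zeros(n_total, dtype=np.int64)

    ns, nd = cfg.n_sires_in_service, cfg.n_dams_in_service
    sex[:ns] = 0
    sex[ns:ns + nd] = 1
    if cfg.n_founders > ns + nd:
        sex[ns + nd:cfg.n_founders] = rng.integers(0, 2, cfg.n_founders - ns - nd)
    service_sires = list(range(ns))
    service_dams = list(range(ns, ns + nd))

    spec = ModelSpec(model="PED", sigma2_g=max(sigma2_g, 1e-12),
                     sigma2_e=max(sigma2_e, 1e-12))
    n_cur = cfg.n_founders

    for g in range(1, cfg.n_generations + 1):
        # ----- mate: one offspring per dam in service, random service sire
        dams = np.array(service_dams)
        sires = np.array(service_sires)[rng.integers(0, len(service_sires),
                                                     len(dams))]
        lo, hi = n_cur, n_cur + cfg.n_per_generation
        sire[lo:hi] = sires
        dam[lo:hi] = dams
        gen[lo:hi] = g
        geno[lo:hi] = _gametes(geno[sires], rng) + _gametes(geno[dams], rng)
        # offspring TBV on the founder-mean-zero scale
        tbv[lo:hi] = geno[lo:hi][:, qtl].astype(float) @ effects - tbv_shift
        pheno[lo:hi] = tbv[lo:hi] + rng.normal(0, np.sqrt(sigma2_e),
                                               cfg.n_per_generation)
        half = cfg.n_per_generation // 2
        sx = np.concatenate([np.zeros(half, dtype=np.int64),
                             np.ones(cfg.n_per_generation - half, dtype=np.int64)])
        sex[lo:hi] = rng.permutation(sx)
        n_cur = hi

        if g == cfg.n_generations:
            break

        # ----- select replacements among the newest generation
        young = np.arange(lo, hi)
        if cfg.selection and sigma2_g > 0:
            ped_now = Pedigree(ids=np.arange(1, n_cur + 1), sire=sire[:n_cur],
                               dam=dam[:n_cur], cohort=gen[:n_cur])
            res = pedigree_blup(ped_now, pheno[:n_cur], np.arange(1, n_cur + 1),
                                spec)
            ebv = res.ebv.to_numpy()
        else:
            ebv = rng.permutation(n_cur).astype(float)  # random ranking

        for sx_code, service, n_repl in ((0, service_sires,
                                          cfg.n_sire_replacements_per_gen),
                                         (1, service_dams,
                                          cfg.n_dam_replacements_per_gen)):
            cand = young[sex[young] == sx_code]
            if len(cand) < n_repl:
                raise RuntimeError(
                    f"infeasible scheme: {len(cand)} candidates of sex {sx_code} "
                    f"for {n_repl} replacements in generation {g}")
            best = cand[np.argsort(ebv[cand])[::-1][:n_repl]]
            worst = np.argsort(ebv[np.array(service)])[:n_repl]
            for slot, new in zip(worst, best):
                service[slot] = int(new)

    ped = Pedigree(ids=np.arange(1, n_total + 1), sire=sire, dam=dam,
                   cohort=gen, sex=sex,
                   genotyped=np.ones(n_total, dtype=bool))
    markers = GenotypeMatrix(geno[:, ~is_qtl], ped.ids.copy(),
                             founders.genotypes.locus_ids[~is_qtl])
    return PopulationData(pedigree=ped, genotypes=markers,
                          true_breeding_values=tbv, phenotypes=pheno,
                          generation_of=gen,
                          qtl_locus_ids=founders.genotypes.locus_ids[is_qtl],
                          founder_realized_freqs=founders.realized_freqs)


def simulate(cfg: SimulationConfig) -> PopulationData:
    """Full pipeline: drifted founders then selected generations, all
    randomness derived from ``cfg.seed`` via generator splitting."""
    r_fou, r_pop, _ = _split_rng(cfg.seed, 3)
    founders = simulate_founder_genotypes(cfg, r_fou)
    return simulate_selected_population(cfg, founders, r_pop)


def subset_genotypes(pop: PopulationData, first_generation: int,
                     thin_every: int | None = None) -> GenotypeMatrix:
    """Genotypes of animals born in cohorts >= ``first_generation``.

    ``thin_every=k`` additionally drops every k-th genotyped animal
    (floor(n/k) removed), reproducing the incomplete-genotyping
    robustness check.
    """
    mask = pop.generation_of >= first_generation
    if not mask.any():
        raise ValueError(f"no animals in generations >= {first_generation}")
    take = np.where(mask)[0]
    if thin_every:
        keep = (np.arange(len(take)) + 1) % thin_every != 0
        take = take[keep]
    return GenotypeMatrix(pop.genotypes.counts[take],
                          pop.pedigree.ids[take], pop.genotypes.locus_ids)


# ----------------------------------------------------------------- output


def write_population(pop: PopulationData, outdir, hdf5: bool = False) -> None:
    """Pedigree/phenotype/TBV CSVs and the genotype matrix (text .raw, or
    HDF5 for large runs)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pop.pedigree.write_csv(out / "pedigree.csv")
    pd.DataFrame({"id": pop.pedigree.ids, "trait": pop.phenotypes,
                  "mean": 1}).to_csv(out / "phenotypes.csv", index=False)
    pd.DataFrame({"id": pop.pedigree.ids,
                  "tbv": pop.true_breeding_values}).to_csv(out / "tbv.csv",
                                                           index=False)
    if hdf5:
        pop.genotypes.write_hdf5(out / "genotypes.h5")
    else:
        pop.genotypes.write_raw(out / "genotypes.raw")
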