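# ssgblup-trends

Genetic-trend estimation under single-step genomic BLUP (SS-GBLUP), and
how the choice of relationship-matrix alignment distorts it.

## The problem

Breeding programs report progress as the *genetic trend*: the mean
estimated breeding value (EBV) of animals born in successive cohorts.
SS-GBLUP evaluates genotyped and non-genotyped animals jointly through
the matrix **H**, whose inverse is sparse pedigree A⁻¹ plus a correction
G⁻¹ − A22⁻¹ on the genotyped block.  The pedigree NRM **A** is anchored
at the pedigree founders, while the genomic GRM

    G = (M − 2P)(M − 2P)′ / s,   s = 2 Σᵢ pᵢ(1 − pᵢ),

is anchored at whatever allele frequencies **P** center the marker
counts.  When genotyped animals are concentrated in recent, selected
cohorts, this base mismatch shifts and bends the estimated trend.  The
package implements the remedies discussed in the animal-breeding
literature — blending λG + (1−λ)A22, mean/diagonal moment matching
(G\* = βG + αJ), the mean-only offset α = (1′A22 1 − 1′G 1)/n₂²,
F_ST-style rescaling, τ/ω-weighted H⁻¹, and the *metafounder* model
A_γ = (1 − γ/2)A + γJ with γ (≈ 2·F_ST of the founders) estimated from
the genotypes — together with a forward simulator of a population under
BLUP truncation selection and the metrics used to judge trend quality.

It is written for quantitative geneticists who want a tested, inspectable
reference implementation of the whole chain: pedigree algebra (tabular A,
sparse A⁻¹, Colleau-style indirect A22, partitioned A22⁻¹ products,
metafounder recursion and its closed-form inverse), γ estimation (GLS,
summary statistics, profile likelihood), H⁻¹ assembly for models
M0/MG/MA, mixed-model solving, and the factorial trend study.

## Worked example

```python
import numpy as np
from ssgblup_trends.simulate import SimulationConfig, simulate, subset_genotypes
from ssgblup_trends.grm import maf_filter
from ssgblup_trends.gamma import estimate_gamma_gls
from ssgblup_trends.ssgblup import ModelSpec, evaluate, pedigree_blup
from ssgblup_trends.trends import (cohort_means, standardize,
                                   trend_discrepancy_norm,
                                   regression_true_on_predicted)

cfg = SimulationConfig.reduced(seed=11)      # 430 founders + 10x400, 5000 loci
pop = simulate(cfg)
gen = pop.generation_of

ped_res = pedigree_blup(pop.pedigree, pop.phenotypes, pop.pedigree.ids,
                        ModelSpec(model="PED", sigma2_g=3, sigma2_e=7))

g10 = maf_filter(subset_genotypes(pop, 10), 0.02)   # genotype gen 10 only
gamma = estimate_gamma_gls(pop.pedigree, g10).gamma
for spec in (ModelSpec(model="M0", scheme="all", sigma2_g=3, sigma2_e=7),
             ModelSpec(model="MA", scheme="half", gamma=gamma,
                       sigma2_g=3, sigma2_e=7)):
    res = evaluate(pop.pedigree, g10, pop.phenotypes, pop.pedigree.ids, spec)
    rms = trend_discrepancy_norm(
        standardize(cohort_means(res, gen)),
        standardize(cohort_means(ped_res, gen))) / np.sqrt(11)
    slope = regression_true_on_predicted(
        pop.true_breeding_values[gen == 10], res.ebv.to_numpy()[gen == 10])
    print(f"{spec.model}/{spec.scheme}: trend RMS vs PED {rms:.2f}, "
          f"slope of TBV on EBV {slope:.3f}")
```

prints

```
M0/all: trend RMS vs PED 2.41, slope of TBV on EBV 0.909
MA/half: trend RMS vs PED 0.07, slope of TBV on EBV 1.097
```

Read: with genotypes only in the last generation and no alignment, the
estimated trend departs from the pedigree trend by ~2.4 trait units per
cohort (RMS of the standardized difference) and final-generation GEBV
are overdispersed (slope < 1, here mildly for this seed).  Fitting a
single metafounder (γ̂ = 0.465 here) with p = 0.5 centering brings the
trend back onto the pedigree base (RMS 0.07); averaged over replicates
its slope sits at 1.01 (this seed draws 1.10).

The numbered drivers under `analysis/` run the full narrative:
`01_simulate_population.py` (one replicate, written to `results/`),
`02_alignment_parameters.py` (α and the three γ estimators per genotype
subset), `03_run_study.py` (the replicated factorial study, Table-style
summary), `04_trend_figure.py` (trend-curve figure).  A `ssgblup-trends`
console script exposes `simulate`, `estimate-gamma`, `evaluate` and
`run-study` for file-based use.

## Layout

- `src/ssgblup_trends/` — library: `pedigree`, `nrm`, `grm`, `gamma`,
  `ssgblup`, `trends`, `experiment`, `simulate`, `cli`.
- `analysis/` — numbered narrative drivers writing to `results/`.
- `docs/methods.md` — model, estimators, simulator design, numerical
  choices and limitations.
- `tests/` — unit + property tests and the study-level suite.
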