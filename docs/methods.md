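# Methods

## The problem

Single-step genomic BLUP (SS-GBLUP) evaluates genotyped and
non-genotyped animals jointly by replacing the pedigree numerator
relationship matrix (NRM, **A**) with a joint matrix **H** that carries
genomic relationships (GRM, **G**) for the genotyped block.  The two
matrices refer to different base populations: **A** is anchored at the
pedigree founders (expected mean breeding value zero), while **G** is
anchored at whatever allele frequencies center the marker counts.  In a
population under selection the genotyped animals are concentrated in
recent, genetically superior cohorts, so this base mismatch shifts and
distorts the *genetic trend* — the trajectory of cohort-mean EBV — which
is the headline statistic of a breeding program.  The package implements
the alignment methods proposed for this problem and measures their
effect on estimated trends in a controlled simulation.

## Relationship matrices

* **A** is built by the tabular recursion with inbreeding
  (a_ii = 1 + F_i); its sparse inverse comes from the Mendelian-sampling
  decomposition A^-1 = sum_i d_i^-1 (e_i - ½e_s - ½e_d)(·)', with
  d_i = ½ - ¼(F_s + F_d).  Parent inbreeding is read off the tabular
  diagonal; the implementation is dense-quadratic in pedigree size and
  deliberately capped (the study pedigrees are a few thousand animals).
* **A22** (genotyped block) is extracted directly from dense A for small
  problems, or computed without forming A through triangular solves with
  the gamete-transmission factor (A = T D T'), the indirect method of
  choice for large pedigrees.  Products inv(A22)·v use the partitioned
  identity inv(A22) = A^22 - A^21 inv(A^11) A^12, factorizing only the
  sparse non-genotyped block of A^-1.
* **G** follows the cross-product form G = (M-2P)(M-2P)'/s with
  s = 2·Σ p_i(1-p_i).  Centering frequencies are a policy: observed over
  all genotyped animals (`all`), over the earliest genotyped cohort
  (`first`), over the pedigree founders (`founder`), or 0.5 everywhere
  (`half`).  A constant (default 0.05) is added to the diagonal to keep
  G safely positive definite in place of blending; it is applied before
  any alpha/beta alignment (a switch exposes the alternative order).
* Alignments: blending λG + (1-λ)A22; mean/diagonal moment matching
  (alpha from the trace equation, beta from the spread ratio); mean-only
  matching alpha = (1'A22 1 - 1'G 1)/n2², beta = 1; the F_ST-style
  rescaling G* = (1-α/2)G + αJ; and the τ/ω weighted harmonic
  combination inv(τ inv(G) + (1-ω) inv(A22)).  None of these guarantees
  a positive definite result, so every modified matrix passes a Cholesky
  check and failures raise rather than being silently repaired.

## Metafounders

A single metafounder — a pseudo-ancestor acting as sire and dam of every
pedigree founder, with self-relationship γ ∈ [0, 2) — rescales the
pedigree side instead: A_γ = (1-γ/2)A + γJ.  γ equals twice the F_ST of
the founders relative to an ideal maximum-heterozygosity base (allele
frequencies 0.5), which is exactly the base that `half` centering gives
**G**.  A_γ and its sparse inverse are built by the augmented-pedigree
recursion (metafounder Mendelian variance γ, founder variance 1-γ/2);
the closed form of the inverse is

    inv(A_γ) = [A^-1 − γ/(1−γ/2+γF) · J_F] / (1−γ/2),

with F the founder count and J_F the all-ones block on founder
coordinates.  Note the leading scalar: deriving the Sherman-Morrison
update from A_γ gives 1/(1−γ/2) = 2/(2−γ); a transcribed prefactor of
2/(1−γ) circulating for this identity does not invert A_γ (dimensional
check at γ=0 fails), and the recursion and the closed form above agree
to machine precision for all tested pedigrees and γ.

γ is estimated from genotypes three ways: (i) GLS per-locus founder
means μ_i = (1'inv(A22)1)^-1 1'inv(A22) m_i with γ = 2·Var_loci(μ_i)
(population-variance convention, denominator m — the m−1 distinction is
negligible at realistic locus counts); (ii) closed-form summary
statistics from 1'McMc'1, tr(McMc'), 1'A22 1, tr(A22) under half
centering; (iii) 1-D profile maximum likelihood in γ with the
heterozygosity scale s profiled out, maximized by bounded scalar search
on [1e-6, 1.999] to 1e-4.  Phenotype-augmented estimation of γ is out of
scope.  On this generator the summary estimator tracks GLS to ~0.02
(slightly below it); the overestimation tendency sometimes reported for
it elsewhere presumably reflects a different simulation design.

## Models and solver

`M0` uses G unchanged, `MG` adds the mean-matching αJ, `MA` replaces
A^-1 and A22^-1 by their γ counterparts and carries the metafounder as
an extra random level whose solution estimates the GEBV location shift;
`PED` ignores genotypes.  H^-1 is stored as sparse A^-1 plus a dense
correction τ inv(G*) − ω inv(A22) on the genotyped block and never
materialized densely at scale.  The mixed-model equations (single-trait
animal model, overall mean as default fixed effect) are solved by dense
Cholesky whenever the genomic correction is present (the correction
makes sparse factors fill in anyway) and by sparse LU for purely
pedigree-based systems; the relative residual of every solve is checked
against 1e-8 and stored.  Variance components are inputs — the
simulation truth σ²_g = 3, σ²_e = 7 by default; variance estimation
(REML) is deliberately out of scope, so evaluation uses the base-
generation truth throughout.

## The simulator

The generator emulates a livestock nucleus under BLUP selection:

* **Founders.** Per-locus allele frequencies start at 0.5 and drift for
  60 Wright-Fisher generations at diploid effective size 100, so the
  2 F_ST of the founders (and hence the target γ) is
  2[1 − (1 − 1/200)^60] ≈ 0.52 — the drifted-base regime in which
  pedigree founders are unrelated in the pedigree but not in their genomes.
  Founders draw two gametes from the final frequencies; loci with
  founder MAF below 0.02 are dropped (truncation lowers the realized
  across-locus variance, so genotype-based γ estimates land near
  0.45-0.50 rather than the all-locus 0.52).
* **Scale.** Full-scale defaults: 2800 founders = 200 sires + 2600 dams
  in service, 2600 offspring per generation for 10 overlapping
  generations, 80/520 sire/dam replacements per cycle, 46,500 loci.
  The desk-scale configuration used by the analysis scripts, tests and
  the acceptance run keeps every selected *fraction* identical (6% of
  male candidates, 40% of female candidates; 40%/20% of service
  sires/dams replaced) at 430 founders, 400 per generation, 5,000 loci
  with 500 QTL; one replicate runs in a couple of minutes on one core.
* **Trait.** 500 QTL drawn from the post-filter loci (excluded from the
  marker panel), normal effects rescaled so founder TBV variance equals
  h²σ²_P = 3 exactly; phenotype = TBV + N(0, 7), recorded on both
  sexes, founder mean defining the TBV zero.
* **Selection.** Each cycle, pedigree BLUP (true variance ratio) on all
  records to date ranks the newest cohort; the lowest-EBV parents in
  service are culled and replaced by the highest-EBV young candidates of
  the matching sex; every dam in service produces one offspring by a
  randomly drawn service sire; sexes split evenly.  Gametes segregate
  independently per locus (no linkage map): relationship-matrix
  behaviour under drift and selection, not LD, drives the phenomena
  studied, and a chromosome map is left as a config extension.
* **Randomness.** Everything flows from one integer seed through
  `numpy` SeedSequence splitting; replicate seeds are recorded in every
  output.

What the generator does *not* emulate: linkage and LD (so marker-density
phenomena and within-chromosome structure are out of reach), mutation,
genotyping error, incomplete pedigrees, or multiple traits.  Passing
tests therefore demonstrate the relationship-algebra and base-alignment
phenomena, not marker-resolution realism.

## Outcome metrics

Trend curves are cohort means of EBV (the metafounder pseudo-animal is
excluded — it is not an animal).  Curves are standardized by subtracting
the generation-0 mean, so comparisons see only shape.  The discrepancy
between a genomic and the pedigree trend is the Euclidean norm of the
standardized difference vector; summaries additionally report the
per-cohort RMS (norm divided by sqrt(11 cohorts)), which reads as
"average trend deviation per cohort, in trait units" and does not grow
with the number of cohorts compared — it is the scale used for the
package's own summary tables.  Dispersion is the OLS slope of TBV
on EBV in the final cohort (intercept fitted and discarded): < 1 means
overdispersed EBV, > 1 under-dispersed.  Under MA the metafounder
solution estimates the GEBV location shift; subtracting it re-bases the
raw genomic curve onto the pedigree base.

## The factorial study

Per replicate one population is simulated and every analysis cell is
evaluated on it (models M0-all/1st/fou/half, MG-all, MA-half × first
genotyped generation 0/2/4/7/10), sharing dense A, the per-subset raw
cross-product MM' (each centering is a rank-one correction of it) and
the pedigree-BLUP reference.  MG×founder and MG×half are skipped a
priori (negative α ⇒ non-positive-definite G*); any other cell whose
modified GRM fails its Cholesky check is recorded as failed and the run
continues.  γ is re-estimated by GLS per genotype subset, as in the
source design.  Same base seed ⇒ bit-identical outputs.

## Numerical choices

Dense SPD work (PD checks, the correction-block inverses, the MME
factorizations) goes through direct LAPACK dpotrf/dpotri/dpotrs calls on
Fortran-ordered arrays; symmetry/inverse test tolerances are 1e-8
relative; the likelihood search tolerance is 1e-4 in γ; degenerate
inputs (all loci fixed, empty cohorts, confounded fixed effects,
non-positive-definite G*) raise explicit errors naming the offending
quantity rather than repairing silently.

## Known limitations

* Variance components are plugged in, not re-estimated per analysis; in
  strongly distorted cells (unaligned G with late genotyping) re-
  estimated variances would partly reshuffle the distortion between the
  trend shift and the dispersion slope.
* The reduced scale has ~6x the census drift of the full design, so
  absolute levels of cohort relatedness (and the α offsets) run above
  the full-scale values even though every ordering and mechanism is
  preserved.
* γ estimation uses genotypes only; the single-metafounder model covers
  one base population (no Γ matrix for crosses).
* No APY or other sparse-G approximations; the genotyped block is dense.
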