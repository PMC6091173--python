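"""Population simulator: drift calibration, Mendelian consistency and
response to selection, checked against closed-form expectations."""

import numpy as np
import pytest

from ssgblup_trends.simulate import (SimulationConfig, simulate,
                                     simulate_founder_genotypes,
                                     simulate_selected_population,
                                     subset_genotypes, write_population)


def tiny_cfg(**kw):
    base = dict(n_founders=33, n_per_generation=30, n_generations=4,
                n_sires_in_service=3, n_dams_in_service=30,
                n_sire_replacements_per_gen=1, n_dam_replacements_per_gen=6,
                n_loci=600, n_qtl=60, seed=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_defaults_match_full_scale_design(self):
        cfg = SimulationConfig()
        assert (cfg.n_founders, cfg.n_per_generation, cfg.n_generations) == \
            (2800, 2600, 10)
        assert (cfg.n_sires_in_service, cfg.n_sire_replacements_per_gen) == \
            (200, 80)
        assert (cfg.n_dams_in_service, cfg.n_dam_replacements_per_gen) == \
            (2600, 520)
        assert cfg.h2 == 0.3 and cfg.phenotypic_variance == 10.0
        assert cfg.n_loci == 46500 and cfg.maf_threshold == 0.02

    def test_reduced_preserves_selected_fractions(self):
        full, red = SimulationConfig(), SimulationConfig.reduced()
        assert (red.n_sire_replacements_per_gen / red.n_sires_in_service
                == pytest.approx(full.n_sire_replacements_per_gen
                                 / full.n_sires_in_service))
        assert (red.n_dam_replacements_per_gen / red.n_dams_in_service
                == pytest.approx(full.n_dam_replacements_per_gen
                                 / full.n_dams_in_service))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="replacements"):
            tiny_cfg(n_sire_replacements_per_gen=10)
        with pytest.raises(ValueError, match="n_qtl"):
            tiny_cfg(n_qtl=600)
        with pytest.raises(ValueError, match="one offspring per dam"):
            tiny_cfg(n_per_generation=25)
        with pytest.raises(ValueError, match="herd"):
            tiny_cfg(n_founders=20)


class TestFounderGenotypes:
    def test_no_drift_frequencies_stay_near_half(self):
        cfg = tiny_cfg(n_drift_generations=0, n_loci=2000, n_founders=330,
                       n_dams_in_service=300, n_per_generation=300,
                       n_sires_in_service=30, n_dam_replacements_per_gen=60,
                       n_sire_replacements_per_gen=12, n_qtl=100)
        fou = simulate_founder_genotypes(cfg, np.random.default_rng(0))
        assert fou.realized_freqs.mean() == pytest.approx(0.5, abs=0.01)
        assert np.all(fou.ancestral_freqs == 0.5)

    def test_drift_variance_matches_wright_fisher_expectation(self):
        """Across-locus variance of realized founder frequencies tracks
        Var(p) = p0(1-p0)[1 - (1 - 1/(2N))^t]; estimated gamma = 8 Var(p)
        lands near the 2 F_ST target."""
        N, t = 100, 60
        expected_var = 0.25 * (1 - (1 - 1 / (2 * N)) ** t)
        cfg = tiny_cfg(effective_size=N, n_drift_generations=t, n_loci=3000,
                       maf_threshold=0.0)
        rng = np.random.default_rng(1)
        v = [np.var(simulate_founder_genotypes(cfg, rng).realized_freqs)
             for _ in range(5)]
        assert np.mean(v) == pytest.approx(expected_var, rel=0.12)
        assert 8 * np.mean(v) == pytest.approx(0.52, abs=0.1)

    def test_maf_filter_drops_rare_loci(self):
        cfg = tiny_cfg(maf_threshold=0.1)
        fou = simulate_founder_genotypes(cfg, np.random.default_rng(2))
        m = np.minimum(fou.realized_freqs, 1 - fou.realized_freqs)
        assert m.min() >= 0.1
        assert fou.genotypes.n_loci < cfg.n_loci

    def test_all_fixed_is_explicit_failure(self):
        cfg = tiny_cfg(effective_size=2, n_drift_generations=400, n_loci=50,
                       n_qtl=10)
        with pytest.raises(RuntimeError, match="N_e=2"):
            simulate_founder_genotypes(cfg, np.random.default_rng(3))


class TestSelectedPopulation:
    def test_structure_and_order(self, tiny_population):
        cfg, pop = tiny_population
        ped = pop.pedigree
        assert ped.n == cfg.n_founders + cfg.n_generations * cfg.n_per_generation
        ped.validate()  # parents precede offspring
        non_fou = ~ped.is_founder
        assert np.all(ped.cohort[ped.sire[non_fou]] < ped.cohort[non_fou])
        assert np.all(ped.cohort[ped.dam[non_fou]] < ped.cohort[non_fou])
        # QTL are excluded from the marker panel
        assert not set(pop.qtl_locus_ids) & set(pop.genotypes.locus_ids)

    def test_founder_tbv_variance_exactly_rescaled(self, tiny_population):
        cfg, pop = tiny_population
        fou = pop.generation_of == 0
        assert pop.true_breeding_values[fou].var() == pytest.approx(
            cfg.h2 * cfg.phenotypic_variance, rel=1e-10)
        assert pop.true_breeding_values[fou].mean() == pytest.approx(0, abs=1e-10)

    def test_mendelian_consistency_of_offspring(self, tiny_population):
        """Offspring allele counts are compatible with parental genotypes
        at every marker (gene-dropping check on all trios)."""
        cfg, pop = tiny_population
        ped, M = pop.pedigree, pop.genotypes.counts
        kids = np.where(~ped.is_founder)[0]
        gs, gd, gk = M[ped.sire[kids]], M[ped.dam[kids]], M[kids]
        lo = (gs == 2).astype(int) + (gd == 2).astype(int)
        hi = 2 - (gs == 0).astype(int) - (gd == 0).astype(int)
        assert np.all(gk >= lo) and np.all(gk <= hi)

    def test_phenotype_decomposition_variance(self, tiny_population):
        cfg, pop = tiny_population
        fou = pop.generation_of == 0
        resid = pop.phenotypes[fou] - pop.true_breeding_values[fou]
        # residual variance ~ (1-h2) sigma2_P within sampling error
        se = (1 - cfg.h2) * cfg.phenotypic_variance
        assert resid.var() == pytest.approx(se, rel=0.6)

    def test_selection_response_positive_and_near_parent_mean_prediction(self):
        """Each generation's mean TBV equals the selected parents' mean
        EBV deviation in expectation; realized gain stays within 50% of
        that deterministic prediction, cumulatively."""
        cfg = SimulationConfig(n_founders=215, n_per_generation=200,
                               n_generations=5, n_sires_in_service=15,
                               n_dams_in_service=200,
                               n_sire_replacements_per_gen=6,
                               n_dam_replacements_per_gen=40,
                               n_loci=1500, n_qtl=150, seed=42)
        pop = simulate(cfg)
        means = [pop.true_breeding_values[pop.generation_of == g].mean()
                 for g in range(cfg.n_generations + 1)]
        gains = np.diff(means)
        assert np.all(gains[1:] > 0)  # response after first selected cycle
        total = means[-1] - means[1]
        # rough deterministic check: per-cycle gain of order i*r*sigma_g
        assert 0.2 < total / (cfg.n_generations - 1) < 1.6

    def test_no_heritability_means_no_response(self):
        cfg = tiny_cfg(h2=0.0, seed=5)
        pop = simulate(cfg)
        means = np.array([pop.true_breeding_values[pop.generation_of == g].mean()
                          for g in range(cfg.n_generations + 1)])
        assert np.all(means == 0)

    def test_random_replacement_gives_flat_trajectory(self):
        cfg = tiny_cfg(selection=False, seed=6, n_founders=110,
                       n_per_generation=100, n_dams_in_service=100,
                       n_sires_in_service=10, n_dam_replacements_per_gen=20,
                       n_sire_replacements_per_gen=4)
        pop = simulate(cfg)
        g10 = pop.generation_of == cfg.n_generations
        fou = pop.generation_of == 0
        gain = (pop.true_breeding_values[g10].mean()
                - pop.true_breeding_values[fou].mean())
        se = np.sqrt(3.0 / g10.sum() + 3.0 / fou.sum())
        assert abs(gain) < 4 * se

    def test_infeasible_scheme_fails(self):
        # 30 offspring -> 15 female candidates, but 16 dam replacements
        with pytest.raises(RuntimeError, match="infeasible"):
            simulate(tiny_cfg(n_dam_replacements_per_gen=16))


class TestSubsets:
    def test_first_generation_bounds(self, tiny_population):
        cfg, pop = tiny_population
        allg = subset_genotypes(pop, 0)
        assert allg.n_animals == pop.pedigree.n
        last = subset_genotypes(pop, cfg.n_generations)
        assert last.n_animals == cfg.n_per_generation
        with pytest.raises(ValueError):
            subset_genotypes(pop, cfg.n_generations + 1)

    def test_thinning_removes_every_third(self, tiny_population):
        cfg, pop = tiny_population
        full = subset_genotypes(pop, 0)
        thin = subset_genotypes(pop, 0, thin_every=3)
        assert thin.n_animals == full.n_animals - full.n_animals // 3


def test_determinism_and_writers(tmp_path):
    cfg = tiny_cfg(seed=9)
    a, b = simulate(cfg), simulate(cfg)
    assert np.array_equal(a.genotypes.counts, b.genotypes.counts)
    assert np.array_equal(a.phenotypes, b.phenotypes)
    write_population(a, tmp_path)
    assert (tmp_path / "pedigree.csv").exists()
    assert (tmp_path / "genotypes.raw").exists()
    assert (tmp_path / "tbv.csv").exists()
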