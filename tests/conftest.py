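import numpy as np
import pytest

from ssgblup_trends.pedigree import Pedigree


@pytest.fixture
def fullsib_pedigree():
    """Founders 1,2; full sibs 3,4 = (1,2); 5 = (3,4) (full-sib mating)."""
    return Pedigree(ids=np.arange(1, 6),
                    sire=np.array([-1, -1, 0, 0, 2]),
                    dam=np.array([-1, -1, 1, 1, 3]),
                    cohort=np.array([0, 0, 1, 1, 2]))


def random_pedigree(n, n_founders, seed, with_cohorts=False):
    """Random topologically ordered pedigree with both parents known for
    non-founders."""
    rng = np.random.default_rng(seed)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for i in range(n_founders, n):
        sire[i], dam[i] = rng.integers(0, i, 2)
    cohort = np.zeros(n, dtype=np.int64)
    if with_cohorts:
        cohort[n_founders:] = 1 + (np.arange(n - n_founders)
                                   * 3 // max(n - n_founders, 1))
    return Pedigree(ids=np.arange(1, n + 1), sire=sire, dam=dam, cohort=cohort)


@pytest.fixture
def random_pedigree_factory():
    return random_pedigree


@pytest.fixture(scope="session")
def tiny_population():
    """Small simulated population shared by read-only tests."""
    from ssgblup_trends.simulate import SimulationConfig, simulate

    cfg = SimulationConfig(n_founders=33, n_per_generation=30,
                           n_generations=4, n_sires_in_service=3,
                           n_dams_in_service=30,
                           n_sire_replacements_per_gen=1,
                           n_dam_replacements_per_gen=6,
                           n_loci=600, n_qtl=60, seed=123)
    return cfg, simulate(cfg)
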