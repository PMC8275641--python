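import pytest

from rpggkit.graph import build_rpgg
from rpggkit.simulate import SimConfig, gen_population


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared across tests: 6 loci, 3 diploid
    genomes, moderate copy numbers, fixed seed."""
    cfg = SimConfig(n_loci=6, n_genomes=3, copy_number_range=(5, 20), seed=11)
    haps, truth, catalog = gen_population(cfg)
    return cfg, haps, truth, catalog


@pytest.fixture(scope="session")
def small_rpgg(small_cohort):
    cfg, haps, truth, catalog = small_cohort
    return build_rpgg(catalog.regions(haps), k=cfg.k)
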