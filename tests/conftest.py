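import numpy as np
import pytest

from poolmap import popsim


@pytest.fixture(scope="session")
def small_genome():
    """2 chromosomes x 100 markers — fast stand-in for the 12x2000 default."""
    return popsim.toy_tomato_genome(n_chrom=2, markers_per_chrom=100)


@pytest.fixture(scope="session")
def linked_genome():
    """One near-zero-cM chromosome: every marker fully linked to the causal site."""
    positions = {"chA": np.array([100, 200, 300])}
    return popsim.GenomeMap(
        chromosomes=(("chA", 1000, 1e-9),),
        marker_positions=positions,
        known_catalog={"chA": frozenset({300})},
    )


def simulate_variants(genome, seed=0, **cfg_kw):
    """Simulate and return (config, truth, variant list)."""
    cfg = popsim.default_cross_config(genome, seed=seed, **cfg_kw)
    truth = popsim.simulate_f2(genome, cfg)
    return cfg, truth, list(popsim.sample_pooled_reads(truth, genome, cfg))
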