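import numpy as np
import pytest

import hostrace as hr


@pytest.fixture(scope="session")
def power_dataset():
    """Small standard power scenario shared across tests (read-only)."""
    cfg = hr.SimulationConfig(n_loci=500, n_per_pop=20, seed=5)
    return hr.simulate_metapopulation(cfg)


@pytest.fixture(scope="session")
def single_site_null():
    """One sympatric site with no host-divergent loci."""
    cfg = hr.SimulationConfig(n_sites=1, n_sympatric=1, n_loci=800, n_per_pop=20,
                              delta_p=0.0, n_host_loci=0, ld_block=0, seed=9)
    return hr.simulate_metapopulation(cfg)


def hard_call_table(rng, n_loci=30, n_samples=12, missing_frac=0.1):
    """GenotypeLikelihoodTable of unit-vector (certain) triplets with gaps."""
    dosage = rng.integers(0, 3, size=(n_loci, n_samples))
    probs = np.zeros((n_loci, n_samples, 3))
    for g in (0, 1, 2):
        probs[..., g] = dosage == g
    miss = rng.random((n_loci, n_samples)) < missing_frac
    probs[miss] = np.nan
    loci = [f"l{i}" for i in range(n_loci)]
    samples = [f"s{j}" for j in range(n_samples)]
    return hr.GenotypeLikelihoodTable(loci, samples, probs), dosage, miss
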