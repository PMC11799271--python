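import numpy as np
import pytest

from epiblup.pedigree import Pedigree


def make_random_pedigree(seed: int, n: int, p_founder: float = 0.2,
                         p_one_parent: float = 0.1) -> Pedigree:
    """Random valid pedigree: each animal's parents drawn from predecessors."""
    rng = np.random.default_rng(seed)
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    for i in range(1, n):
        r = rng.random()
        if r < p_founder:
            continue
        s = int(rng.integers(0, i)) + 1
        d = int(rng.integers(0, i)) + 1
        if d == s:
            d = 0
        if r < p_founder + p_one_parent:
            d = 0
        sire[i], dam[i] = s, d
    return Pedigree(sire=sire, dam=dam)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated dataset reused across integration tests."""
    from epiblup.simulate import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(n_founders=40, n_generations=4,
                           target_generation_size=160, seed=42, n_snps=120)
    return simulate_dataset(cfg, with_genotypes=True)
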