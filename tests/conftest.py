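import numpy as np
import pytest

from duporigin.colinearity import GenomeLayout


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def make_layout(species: str, chrom_sizes: dict[str, int], prefix: str | None = None) -> GenomeLayout:
    prefix = prefix or species
    chroms = {
        c: [f"{prefix}_{c}_{i}" for i in range(n)] for c, n in chrom_sizes.items()
    }
    return GenomeLayout(species, chroms)


@pytest.fixture
def small_sim():
    """A desk-scale simulation shared across tests (module-independent seed)."""
    from duporigin.simulate import SimConfig, simulate

    return simulate(SimConfig(n_ancestral_genes=400, seed=7))
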