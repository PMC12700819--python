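import numpy as np
import pytest

from chromodyn.polymer import ConfinementSpec, MonomerTyping, PolymerSystem, init_conformation
from chromodyn.synth import gen_annotations, gen_monomer_typing, gen_polII_series, gen_synthetic_map


@pytest.fixture(scope="session")
def desk_typing() -> MonomerTyping:
    """One desk-scale locus copy: 400 monomers, ~10 three-monomer C blocks."""
    return gen_monomer_typing(locus_monomers=400, spacer_monomers=0, copies=1, seed=0)


@pytest.fixture(scope="session")
def annotation_fixture():
    return gen_annotations(seed=3)


@pytest.fixture(scope="session")
def polII_fixture():
    return gen_polII_series(n_genes=100, spiking_fraction=0.4, seed=5)


@pytest.fixture(scope="session")
def decay_map_fixture():
    """Noiseless pure distance-decay map (300 bins at 500 bp)."""
    cmap, man = gen_synthetic_map(n_bins=300, noise="none", seed=0)
    return cmap, man


@pytest.fixture
def small_system():
    """20-monomer typed chain in a sphere, for force/energy checks."""
    rng = np.random.default_rng(7)
    codes = rng.integers(0, 3, 20).astype(np.int8)
    typing = MonomerTyping(codes)
    conf = ConfinementSpec("sphere", 0.25)
    coords = init_conformation(20, conf, seed=7)
    return PolymerSystem(coords, typing, confinement=conf)
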