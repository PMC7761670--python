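import numpy as np
import pytest

import rdna4c as r


@pytest.fixture(scope="session")
def default_sim():
    """One default-preset simulation shared across tests (seed 20)."""
    spec = r.default_genome_spec(seed=20)
    genes, repeats, states = r.simulate_annotation(spec, seed=20)
    tracks, manifest = r.simulate_contact_tracks(
        spec, genes, repeats, states, seed=120
    )
    return {
        "spec": spec,
        "genes": genes,
        "repeats": repeats,
        "states": states,
        "tracks": tracks,
        "manifest": manifest,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def small_genome():
    return {"chrA": 60_000, "chrB": 40_000}
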