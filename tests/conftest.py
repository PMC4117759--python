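import numpy as np
import pytest

import crisprprime as cp


@pytest.fixture(scope="session")
def plasmid():
    """A 6.7-kb random circular plasmid (the size class of the study replicon)."""
    return cp.generate_plasmid(6735, 0.5, seed=1, id="pSYN1")


@pytest.fixture(scope="session")
def primed(plasmid):
    """Plasmid with a 32-nt primed protospacer on the - strand and a TG PAM."""
    rng = np.random.default_rng(5)
    spacer = "".join(rng.choice(list("ACGT"), size=32))
    return cp.plant_primed_protospacer(plasmid, spacer, "-", 3000, "TG")


@pytest.fixture(scope="session")
def models():
    return cp.default_array_models(seed=7)


@pytest.fixture(scope="session")
def sim_cells(primed):
    """1000 clones under default parameters (~2400 acquisition events)."""
    pl, site = primed
    return cp.simulate_priming(pl, site, cp.SimParams(seed=1), n_cells=1000)


@pytest.fixture(scope="session")
def sim_records(primed, sim_cells):
    pl, site = primed
    return [
        cp.signed_distance(e.hit, site, len(pl)) for cell in sim_cells for e in cell
    ]
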