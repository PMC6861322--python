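import numpy as np
import pytest

from mimosa.fixtures_io import toy_network


@pytest.fixture(scope="session")
def pa_network():
    return toy_network("photoautotroph")


@pytest.fixture(scope="session")
def dz_network():
    return toy_network("diazotroph")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_network():
    """4-reaction chain with a hand-checkable optimum.

    R_in feeds metabolite x (capacity 5); the biomass and metabolite sinks
    both drain x; the maintenance reaction is an isolated zero column.  The
    scalarized objective splits the drain a:(1-a) between the two sinks, so
    at every weight the combined optimum is the inflow capacity, 5.
    """
    from mimosa.metabolic_core import MetabolicNetwork

    return MetabolicNetwork(
        reactions=["R_in", "R_bio", "R_met", "R_atpm"],
        metabolites=["x", "atp"],
        stoichiometry=np.array(
            [
                [1.0, -1.0, -1.0, 0.0],
                [0.0, 0.0, 0.0, -1.0],
            ]
        ),
        lower=np.zeros(4),
        upper=np.array([5.0, 10.0, 10.0, 0.0]),
        biomass_rxn="R_bio",
        metabolite_rxn="R_met",
        atp_maintenance_rxn="R_atpm",
    )
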