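import numpy as np
import pytest

from radscan import synthetic_data as sd


@pytest.fixture(scope="session")
def default_tree():
    return sd.default_species_tree()


@pytest.fixture(scope="session")
def three_species_tree():
    """3 species + outgroup; internal branch = 1 coalescent unit (80 ky at
    N_e = 1e5 and 2.5 generations/year)."""
    nwk = "(((A:200000,B:280000)ab:0,C:280000)abc:720000,O:1000000)root;"
    # rebuilt properly below (ultrametric): A,B split 200 ky, ABC split 280 ky
    nwk = "(((A:200000,B:200000)ab:80000,C:280000)abc:720000,O:1000000)root;"
    return sd.SimSpeciesTree(
        newick=nwk,
        accessions={"A_1": "A", "B_1": "B", "C_1": "C", "O_1": "O"},
        outgroup_species="O",
    )


@pytest.fixture(scope="session")
def quintet_tree():
    """Symmetric five-taxon tree ((P1,P2),(P3,P4)),O for D_FOIL work; the
    first pair is younger than the second, as the method requires."""
    nwk = (
        "(((P1:200000,P2:200000)p12:600000,(P3:400000,P4:400000)p34:400000)"
        "ing:1200000,O:2000000)root;"
    )
    return sd.SimSpeciesTree(
        newick=nwk,
        accessions={f"{s}_1": s for s in ("P1", "P2", "P3", "P4", "O")},
        outgroup_species="O",
    )
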