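import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sbmsaxs as sx
from sbmsaxs import synthetic as syn

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def two_domain():
    """Toy two-domain chain with its domain map and linker ranges."""
    return syn.make_two_domain(8, 4, seed=1)


@pytest.fixture(scope="session")
def two_domain_topology(two_domain):
    s, dom, link = two_domain
    return sx.build_topology(s, linker_residues=link, domain_map=dom)


@pytest.fixture(scope="session")
def compact_chain():
    """Single compact toy chain (all dihedrals restrained)."""
    return syn.make_toy_chain(8, seed=2)


@pytest.fixture(scope="session")
def compact_topology(compact_chain):
    return sx.build_topology(compact_chain)


@pytest.fixture(scope="session")
def params():
    return sx.ForceFieldParameters()


@pytest.fixture(scope="session")
def q_grid():
    return syn.default_q_grid()


def two_atom_structure(d=10.0):
    return sx.MolecularStructure(
        serial=[1, 2], name=["X1", "X2"], element=["C", "C"],
        res_index=[1, 1], res_name=["GLY", "GLY"], chain_id=["A", "A"],
        coord=[[0.0, 0.0, 0.0], [d, 0.0, 0.0]])


def random_cloud_structure(n, seed, box=12.0):
    rng = np.random.default_rng(seed)
    return sx.MolecularStructure(
        serial=np.arange(1, n + 1),
        name=np.array([f"X{i}" for i in range(n)]),
        element=np.array(["C"] * n),
        res_index=np.arange(1, n + 1),
        res_name=np.array(["GLY"] * n),
        chain_id=np.array(["A"] * n),
        coord=rng.uniform(0, box, size=(n, 3)))
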