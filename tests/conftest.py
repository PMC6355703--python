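import numpy as np
import pytest

from modedock import structio as st
from modedock import synthetic as syn


@pytest.fixture(scope="session")
def hinge():
    """Hinge dimer fixture with its analytic counter-rotation field."""
    return syn.make_hinge_dimer(nodes_per_lobe=20, hinge_width=2, seed=7)


@pytest.fixture(scope="session")
def hinge_partition(hinge):
    structure, _ = hinge
    residues = structure.unique_residues()
    sel_a = st.Selection(frozenset(k for k in residues if k[0] == "A"), label="A")
    sel_b = st.Selection(frozenset(k for k in residues if k[0] == "B"), label="B")
    return sel_a, sel_b


@pytest.fixture(scope="session")
def extended_peptide():
    return syn.build_peptide("RSSQTITHGNGNTYLY", conformation="extended")


@pytest.fixture(scope="session")
def helix_peptide():
    return syn.build_peptide("RSSQTITHGNGNTYLY", conformation="helix")


def toy_structure(coords, elements=None, names=None, chain="A", res_numbers=None,
                  res_names=None, hetero=False, charges=None):
    """Minimal pseudo-atom structure helper used across test modules."""
    n = len(coords)
    return st.Structure(
        coords=np.asarray(coords, dtype=float),
        names=names or [f"C{i+1}" for i in range(n)],
        elements=elements or ["C"] * n,
        res_names=res_names or ["UNK"] * n,
        res_numbers=res_numbers or list(range(1, n + 1)),
        chain_ids=[chain] * n,
        hetero=[hetero] * n,
        partial_charges=charges,
    )


@pytest.fixture
def make_toy():
    return toy_structure


def random_rotation(rng):
    """Haar-ish random rotation matrix from a random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    from modedock._geometry import quat_to_matrix

    return quat_to_matrix(q)
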