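import numpy as np
import pytest

from abdev.structure import AtomicStructure, AtomRecord, Chain, Residue, ResidueKey


def build_structure(atom_specs, struct_id="test", chain_residue_aa=None):
    """Structure from [(chain_id, resnum, aa, [(name, element, coords, radius), ...]), ...]."""
    chains: dict[str, Chain] = {}
    serial = 0
    for chain_id, resnum, aa, atoms in atom_specs:
        chain = chains.setdefault(chain_id, Chain(chain_id=chain_id))
        key = ResidueKey(chain_id=chain_id, seq_number=resnum, insertion_code="", aa=aa)
        residue = Residue(key=key, name="UNK" if aa == "X" else aa * 3, atoms=[])
        for name, element, coords, radius in atoms:
            serial += 1
            residue.atoms.append(AtomRecord(
                serial=serial, name=name, element=element,
                coords=np.asarray(coords, dtype=float), vdw_radius=radius))
        chain.residues.append(residue)
    return AtomicStructure(id=struct_id, chains=list(chains.values()))


def random_cluster_structure(rng, n_atoms, box=6.0):
    """n random atoms in a box, one per residue, radii in [1.5, 2.0]."""
    specs = []
    for i in range(n_atoms):
        coords = rng.uniform(-box / 2, box / 2, size=3)
        radius = rng.uniform(1.5, 2.0)
        specs.append(("A", i + 1, "X", [("X1", "C", coords, radius)]))
    return build_structure(specs, struct_id=f"cluster{n_atoms}")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_atom_structure():
    return build_structure([
        ("A", 1, "X", [("X1", "C", (0.0, 0.0, 0.0), 1.9)]),
        ("A", 2, "X", [("X1", "C", (3.3, 0.0, 0.0), 1.9)]),
    ])
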