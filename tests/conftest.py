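import numpy as np
import pytest

import frustmap as fm
from frustmap.energy import Contact
from frustmap.frustration import FrustrationProfile, FrustrationRecord, classify


def _pdb_atom(serial, name, res3, seq, x, y, z, b=20.0, record="ATOM  ", chain="A"):
    return (
        f"{record}{serial:>5d} {' ' + name:<4s} {res3:>3s} {chain}{seq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}          {'C':>2s}"
    )


@pytest.fixture
def tiny_pdb(tmp_path):
    """Hand-written 4-residue chain: MET, VAL, GLY (Cα only), LEU."""
    lines = [
        _pdb_atom(1, "CA", "MET", 1, 0.0, 0.0, 0.0),
        _pdb_atom(2, "CB", "MET", 1, 0.5, 0.5, 0.5, b=11.0),
        _pdb_atom(3, "CA", "VAL", 2, 3.8, 0.0, 0.0),
        _pdb_atom(4, "CB", "VAL", 2, 4.3, 0.7, 0.4, b=12.0),
        _pdb_atom(5, "CA", "GLY", 3, 7.6, 0.0, 0.0, b=13.0),
        _pdb_atom(6, "CA", "LEU", 4, 11.4, 0.0, 0.0),
        _pdb_atom(7, "CB", "LEU", 4, 11.9, 0.8, 0.2, b=14.0),
        "TER       8",
        "END",
    ]
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def potential():
    return fm.ContactPotential.default()


@pytest.fixture(scope="session")
def designed30(potential):
    return fm.generate_structure(
        fm.ToyFoldSpec(n_residues=30, topology="helix_bundle",
                       sequence_mode="designed", seed=3),
        potential,
    )


@pytest.fixture(scope="session")
def designed60(potential):
    return fm.generate_structure(
        fm.ToyFoldSpec(n_residues=60, topology="helix_bundle",
                       sequence_mode="designed", seed=2),
        potential,
    )


def make_chain(coords, sequence, bfactors=None, label="toy"):
    """Build a ProteinStructure directly from coordinates and a sequence."""
    coords = np.asarray(coords, dtype=float)
    if bfactors is None:
        bfactors = np.full(len(coords), 20.0)
    residues = tuple(
        fm.Residue(k + 1, sequence[k], coords[k], float(bfactors[k]))
        for k in range(len(coords))
    )
    return fm.ProteinStructure(label=label, residues=residues)


def make_profile(indices, label="toy", scheme="configurational"):
    """FrustrationProfile stub with given residue indices and dummy contacts."""
    records = tuple(
        FrustrationRecord(
            contact=Contact(i=sid, j=sid + 1000, distance=5.0, native_energy=0.0),
            z_score=v,
            class_label=classify(v),
        )
        for sid, v in indices.items()
    )
    return FrustrationProfile(
        structure_label=label,
        contact_records=records,
        residue_index=dict(indices),
        residue_aa={sid: "A" for sid in indices},
        scheme=scheme,
    )
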