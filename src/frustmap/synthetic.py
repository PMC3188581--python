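"""Desk-scale synthetic structure fixtures with controllable frustration.

The generator builds compact idealised folds (helix bundles or zigzag
sheets) and dresses them with sequences of three kinds:

* ``designed`` — identities drawn from an average protein composition, then
  optimised for the fold by simulated annealing over composition-preserving
  swaps, minimising the total native contact energy under the packaged
  potential.  These emulate evolved, minimally frustrated sequences.
* ``scrambled`` — a seeded random permutation of the designed sequence: the
  same composition with the optimisation undone, emulating a sequence that
  conflicts with its fold (high frustration expected).
* ``uniform`` — a single amino acid everywhere (degenerate edge case).

B-factor columns can be made anticorrelated with the fold's own frustration
profile, independent of it, or constant, so the flexibility stage is
testable end to end.  Everything is deterministic under the spec's seed.

The geometry is ideal, not physical: helices use a 100°-per-residue twist
with 1.5 Å rise and ~10 Å axis packing, chosen only to produce realistic
contact densities.  Fixtures are written as coarse-grained PDB files with
one representative atom per residue (Cβ; Cα for glycine).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .energy import ContactPotential, build_contact_map, switching_weight
from .structure_io import ProteinStructure, Residue

TOPOLOGIES = ("helix_bundle", "zigzag_sheet")
SEQUENCE_MODES = ("designed", "scrambled", "uniform")
BFACTOR_MODES = ("anticorrelated_with_frustration", "independent", "constant")

#: Average protein amino-acid composition (fractions), used to draw sequences.
COMPOSITION = {
    "A": 0.083, "R": 0.055, "N": 0.041, "D": 0.055, "C": 0.014,
    "Q": 0.039, "E": 0.067, "G": 0.071, "H": 0.023, "I": 0.059,
    "L": 0.097, "K": 0.058, "M": 0.024, "F": 0.039, "P": 0.047,
    "S": 0.066, "T": 0.054, "W": 0.011, "Y": 0.029, "V": 0.069,
}

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: Simulated-annealing schedule for sequence design.
DESIGN_STEPS: int = 10_000
DESIGN_T_START: float = 2.0
DESIGN_T_END: float = 0.02


@dataclass(frozen=True)
class ToyFoldSpec:
    """Parameters of one synthetic fixture."""

    n_residues: int = 60
    topology: str = "helix_bundle"
    sequence_mode: str = "designed"
    bfactor_mode: str = "constant"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 20 <= self.n_residues <= 200:
            raise ValueError("n_residues must be in [20, 200]")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"topology must be one of {TOPOLOGIES}")
        if self.sequence_mode not in SEQUENCE_MODES:
            raise ValueError(f"sequence_mode must be one of {SEQUENCE_MODES}")
        if self.bfactor_mode not in BFACTOR_MODES:
            raise ValueError(f"bfactor_mode must be one of {BFACTOR_MODES}")


def _helix_bundle_coords(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Idealised antiparallel helix bundle; returns (ca, cb) coordinates."""
    helix_len = 18
    n_helices = math.ceil(n / helix_len)
    # axis positions on a compact triangular grid, 10 Å spacing
    axis_xy = []
    for k in range(n_helices):
        row, col = divmod(k, 2)
        axis_xy.append((10.0 * col + 5.0 * (row % 2), 8.66 * row))
    ca = np.zeros((n, 3))
    cb = np.zeros((n, 3))
    twist = math.radians(100.0)
    rise = 1.5
    for t in range(n):
        k, s = divmod(t, helix_len)
        ax, ay = axis_xy[k]
        ang = twist * s + k * 1.3  # per-helix phase offset
        z = rise * s if k % 2 == 0 else rise * (helix_len - 1 - s)  # antiparallel
        ca[t] = (ax + 2.3 * math.cos(ang), ay + 2.3 * math.sin(ang), z)
        cb[t] = (ax + 3.4 * math.cos(ang), ay + 3.4 * math.sin(ang), z)
    return ca, cb


def _zigzag_sheet_coords(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Idealised antiparallel pleated sheet; returns (ca, cb) coordinates."""
    strand_len = 12
    ca = np.zeros((n, 3))
    cb = np.zeros((n, 3))
    for t in range(n):
        s, u = divmod(t, strand_len)
        x = 3.3 * u if s % 2 == 0 else 3.3 * (strand_len - 1 - u)  # antiparallel
        y = 0.9 * (-1) ** u
        z = 4.8 * s
        ca[t] = (x, y, z)
        cb[t] = (x, y + 1.5 * (-1) ** u, z)  # pleat: side chains alternate faces
    return ca, cb


def _design_sequence(
    seq: list[str],
    contacts: list[tuple[int, int, float]],
    potential: ContactPotential,
    rng: np.random.Generator,
    n_steps: int = DESIGN_STEPS,
) -> list[str]:
    """Composition-preserving simulated annealing on identity swaps."""
    eps = potential.epsilon
    codes = list(potential.encode("".join(seq)))
    incident: dict[int, list[tuple[int, int, float]]] = {}
    for a, b, w in contacts:
        incident.setdefault(a, []).append((a, b, w))
        incident.setdefault(b, []).append((a, b, w))

    def local_energy(pos: int) -> float:
        return sum(eps[codes[a], codes[b]] * w for a, b, w in incident.get(pos, ()))

    n = len(seq)
    temps = np.geomspace(DESIGN_T_START, DESIGN_T_END, n_steps)
    pq = rng.integers(0, n, size=(n_steps, 2))
    accept_u = rng.random(n_steps)
    for step in range(n_steps):
        p, q = int(pq[step, 0]), int(pq[step, 1])
        if p == q or codes[p] == codes[q]:
            continue
        before = local_energy(p) + local_energy(q)
        codes[p], codes[q] = codes[q], codes[p]
        after = local_energy(p) + local_energy(q)
        d_e = after - before
        if d_e > 0 and accept_u[step] >= math.exp(-d_e / temps[step]):
            codes[p], codes[q] = codes[q], codes[p]  # reject
    from .structure_io import STANDARD_AAS

    return [STANDARD_AAS[c] for c in codes]


def generate_structure(
    spec: ToyFoldSpec, potential: ContactPotential | None = None
) -> ProteinStructure:
    """Deterministically build the fixture described by ``spec``."""
    pot = potential if potential is not None else ContactPotential.default()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(7,)))
    n = spec.n_residues
    if spec.topology == "helix_bundle":
        ca, cb = _helix_bundle_coords(n)
    else:
        ca, cb = _zigzag_sheet_coords(n)

    if spec.sequence_mode == "uniform":
        seq = ["A"] * n
    else:
        aas = list(COMPOSITION)
        probs = np.array(list(COMPOSITION.values()))
        probs = probs / probs.sum()
        seq = list(rng.choice(aas, size=n, p=probs))
        # native contacts on the side-chain sites, weighted by the switching fn
        from scipy.spatial.distance import pdist, squareform

        dmat = squareform(pdist(cb))
        contacts = [
            (a, b, float(switching_weight(dmat[a, b])))
            for a in range(n)
            for b in range(a + 3, n)
            if dmat[a, b] <= 8.0
        ]
        seq = _design_sequence(seq, contacts, pot, rng)
        if spec.sequence_mode == "scrambled":
            seq = list(rng.permutation(seq))

    residues = tuple(
        Residue(
            author_seq_id=t + 1,
            aa=seq[t],
            rep_coord=ca[t] if seq[t] == "G" else cb[t],
            bfactor=20.0,
        )
        for t in range(n)
    )
    label = f"toy-{spec.topology}-{spec.sequence_mode}-n{n}-s{spec.seed}"
    structure = ProteinStructure(label=label, residues=residues)
    return _with_bfactors(structure, spec, pot, rng)


def _with_bfactors(
    structure: ProteinStructure,
    spec: ToyFoldSpec,
    potential: ContactPotential,
    rng: np.random.Generator,
) -> ProteinStructure:
    n = len(structure)
    if spec.bfactor_mode == "constant":
        b = np.full(n, 20.0)
    elif spec.bfactor_mode == "independent":
        b = rng.uniform(10.0, 60.0, size=n)
    else:  # anticorrelated_with_frustration
        from .frustration import profile_structure

        quick = profile_structure(
            structure, scheme="configurational", n_decoys=300, seed=spec.seed,
            potential=potential,
        )
        fi = np.array(
            [quick.residue_index.get(r.author_seq_id, 0.0) for r in structure.residues]
        )
        b = np.clip(30.0 - 8.0 * fi, 1.0, None)
    residues = tuple(
        Residue(r.author_seq_id, r.aa, r.rep_coord, float(b[k]))
        for k, r in enumerate(structure.residues)
    )
    return ProteinStructure(structure.label, residues, structure.state_tag)


def total_native_energy(
    structure: ProteinStructure, potential: ContactPotential | None = None
) -> float:
    """Sum of native contact energies at the default contact definition."""
    cmap = build_contact_map(structure, potential=potential)
    return float(sum(c.native_energy for c in cmap.contacts))


def write_fixture(structure: ProteinStructure, path: str | Path) -> None:
    """Write a coarse-grained single-chain PDB file.

    One ATOM record per residue: the representative atom, named CB (CA for
    glycine), chain A, occupancy 1.00, the residue's B-factor.  The file
    round-trips through the PDB reader losslessly (coordinates to 3 decimals,
    B-factors to 2).
    """
    if not structure.residues:
        raise ValueError("cannot write an empty structure")
    lines = []
    for serial, r in enumerate(structure.residues, start=1):
        name = "CA" if r.aa == "G" else "CB"
        x, y, z = r.rep_coord
        # wwPDB v3.3 fixed columns: name 13-16, resName 18-20, chain 22,
        # resSeq 23-26, x/y/z 31-54, occupancy 55-60, B 61-66, element 77-78
        lines.append(
            f"ATOM  {serial:>5d} {' ' + name:<4s} {_ONE_TO_THREE[r.aa]:>3s} A"
            f"{r.author_seq_id:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}"
            f"{r.bfactor:6.2f}          {'C':>2s}"
        )
    lines.append(f"TER   {len(structure.residues) + 1:>5d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
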