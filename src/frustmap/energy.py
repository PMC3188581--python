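"""Native contact definition and the pairwise statistical contact potential.

A native contact is a pair of residues whose representative atoms (Cβ, Cα for
glycine) lie within a distance cutoff and are separated in sequence by at
least ``min_sep`` positions.  Each contact carries a native pair energy

    E(a, b, d) = eps[a][b] * w(d)

where ``eps`` is a symmetric 20×20 residue-pair table (attractive = negative)
and ``w`` is a smooth switching function: 1 inside the interaction well
(d ≤ 6.5 Å by default), a cosine ramp down to 0 at the contact cutoff
(8.0 Å), and 0 beyond.

The packaged default table (``contact_potential_kdq_v1``) is an analytic
hydrophobicity-plus-charge potential built from the Kyte–Doolittle hydropathy
scale h (normalised by its maximum, 4.5) and formal side-chain charges q:

    eps[a][b] = -(h_a + h_b)/2 + 0.5 * q_a * q_b

so burial of hydrophobic pairs is stabilising and like-charge burial is
penalised.  Any table in the same plain-text format can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure_io import STANDARD_AAS, ProteinStructure

#: Default contact geometry (Cβ–Cβ).
DEFAULT_CUTOFF_A: float = 8.0
DEFAULT_MIN_SEP: int = 3
#: Inner radius of the interaction well: w(d) = 1 for d ≤ this.
DEFAULT_WELL_A: float = 6.5

_DEFAULT_TABLE = "contact_potential_kdq_v1.tsv"


@dataclass(frozen=True)
class ContactPotential:
    """A symmetric 20×20 residue-pair energy table."""

    epsilon: np.ndarray  # (20, 20), ordered as STANDARD_AAS
    label: str

    def __post_init__(self) -> None:
        eps = np.asarray(self.epsilon, dtype=float)
        if eps.shape != (20, 20):
            raise ValueError(f"epsilon must be 20x20, got {eps.shape}")
        if not np.all(np.isfinite(eps)):
            raise ValueError("epsilon entries must be finite")
        if not np.allclose(eps, eps.T):
            raise ValueError("epsilon must be symmetric")
        object.__setattr__(self, "epsilon", eps)

    _AA_INDEX = {aa: k for k, aa in enumerate(STANDARD_AAS)}

    def entry(self, aa_i: str, aa_j: str) -> float:
        """Raw table entry for an identity pair (no distance weighting)."""
        try:
            return float(self.epsilon[self._AA_INDEX[aa_i], self._AA_INDEX[aa_j]])
        except KeyError as exc:
            raise KeyError(f"unknown amino-acid code: {exc.args[0]!r}") from None

    def encode(self, sequence: str) -> np.ndarray:
        """Map a sequence to integer row indices of the table."""
        try:
            return np.array([self._AA_INDEX[a] for a in sequence], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown amino-acid code: {exc.args[0]!r}") from None

    @classmethod
    def from_file(cls, path: str | Path, label: str | None = None) -> "ContactPotential":
        """Load a table from plain text: header row of codes, one row per code."""
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().split()
        codes = header[1:] if header and header[0].lower() == "aa" else header
        if sorted(codes) != sorted(STANDARD_AAS):
            raise ValueError(f"potential table must cover the 20 standard codes, got {codes}")
        raw = np.loadtxt(path, skiprows=1, usecols=range(1, 21))
        # reorder rows/cols to canonical STANDARD_AAS order
        order = [codes.index(aa) for aa in STANDARD_AAS]
        eps = raw[np.ix_(order, order)]
        return cls(epsilon=eps, label=label or path.stem)

    @classmethod
    def default(cls) -> "ContactPotential":
        """The packaged hydrophobicity+charge table."""
        ref = resources.files("frustmap.data").joinpath(_DEFAULT_TABLE)
        with resources.as_file(ref) as p:
            return cls.from_file(p, label=_DEFAULT_TABLE.removesuffix(".tsv"))


def switching_weight(
    distance: float | np.ndarray,
    well: float = DEFAULT_WELL_A,
    cutoff: float = DEFAULT_CUTOFF_A,
) -> float | np.ndarray:
    """Smooth distance weight: 1 for d ≤ well, cosine ramp to 0 at cutoff."""
    d = np.asarray(distance, dtype=float)
    w = np.where(
        d <= well,
        1.0,
        np.where(d >= cutoff, 0.0, 0.5 * (1.0 + np.cos(np.pi * (d - well) / (cutoff - well)))),
    )
    return float(w) if np.isscalar(distance) else w


def pair_energy(
    aa_i: str,
    aa_j: str,
    distance: float,
    potential: ContactPotential | None = None,
    well: float = DEFAULT_WELL_A,
    cutoff: float = DEFAULT_CUTOFF_A,
) -> float:
    """Pairwise contact energy eps[aa_i][aa_j] * w(distance).

    Symmetric in the two identities; zero beyond the cutoff; equal to the raw
    table entry inside the well radius.
    """
    if distance <= 0:
        raise ValueError(f"distance must be positive, got {distance}")
    pot = potential if potential is not None else ContactPotential.default()
    return pot.entry(aa_i, aa_j) * switching_weight(distance, well, cutoff)


@dataclass(frozen=True)
class Contact:
    """A native residue pair, stored once with i < j (author numbering)."""

    i: int
    j: int
    distance: float
    native_energy: float

    def __post_init__(self) -> None:
        if self.j <= self.i:
            raise ValueError("contacts are stored with i < j")
        if not (np.isfinite(self.distance) and self.distance > 0):
            raise ValueError("distance must be positive and finite")
        if not np.isfinite(self.native_energy):
            raise ValueError("native_energy must be finite")


@dataclass(frozen=True)
class ContactMap:
    """All native contacts of one structure plus the geometry parameters."""

    structure_label: str
    contacts: tuple[Contact, ...]
    cutoff: float
    min_sep: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "contacts", tuple(self.contacts))
        pairs = [(c.i, c.j) for c in self.contacts]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate contacts")

    def __len__(self) -> int:
        return len(self.contacts)

    @property
    def distances(self) -> np.ndarray:
        return np.array([c.distance for c in self.contacts], dtype=float)

    def incident(self, author_seq_id: int) -> list[Contact]:
        return [c for c in self.contacts if author_seq_id in (c.i, c.j)]


def build_contact_map(
    structure: ProteinStructure,
    cutoff: float = DEFAULT_CUTOFF_A,
    min_sep: int = DEFAULT_MIN_SEP,
    potential: ContactPotential | None = None,
    well: float = DEFAULT_WELL_A,
) -> ContactMap:
    """Enumerate native contacts of a structure.

    A pair (i, j) is a contact iff the representative-atom distance is
    ≤ ``cutoff`` and the author-numbering separation j − i is ≥ ``min_sep``.
    Each contact is assigned its native pair energy under ``potential``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if min_sep < 1:
        raise ValueError("min_sep must be >= 1")
    pot = potential if potential is not None else ContactPotential.default()
    ids = structure.seq_ids
    dmat = squareform(pdist(structure.coords))
    seq = structure.sequence
    contacts = []
    n = len(structure)
    for a in range(n):
        for b in range(a + 1, n):
            if ids[b] - ids[a] < min_sep:
                continue
            d = dmat[a, b]
            if d > cutoff:
                continue
            contacts.append(
                Contact(
                    i=int(ids[a]),
                    j=int(ids[b]),
                    distance=float(d),
                    native_energy=pair_energy(seq[a], seq[b], float(d), pot, well, cutoff),
                )
            )
    return ContactMap(
        structure_label=structure.label,
        contacts=tuple(contacts),
        cutoff=float(cutoff),
        min_sep=int(min_sep),
    )
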