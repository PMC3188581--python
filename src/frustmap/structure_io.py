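"""Reading PDB structures into the coarse-grained residue model, and tabular output.

The pipeline works on one representative point per residue: the Cβ atom,
falling back to Cα for glycine.  Residues are addressed throughout by their
author (PDB) numbering, because kinase annotations (T315I, the catalytic-core
subdomain ranges) are conventionally given in author numbering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1_extended

logger = logging.getLogger("frustmap")

#: The 20 standard one-letter amino-acid codes.
STANDARD_AAS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Three-letter → one-letter mapping restricted to codes resolving to a
#: standard amino acid (covers MSE→M and similar parent mappings).
_THREE_TO_ONE: dict[str, str] = {
    k: v for k, v in protein_letters_3to1_extended.items()
    if len(v) == 1 and v in STANDARD_AAS
}

STATE_TAGS = ("inactive", "active", "unspecified")

RESIDUE_TABLE_COLUMNS = ["seq_id", "aa", "frustration_index", "class"]
CONTACT_TABLE_COLUMNS = ["i", "j", "distance_A", "native_energy", "z_score", "class"]


class StructureError(ValueError):
    """Raised for unusable structure input (missing chain, too few residues)."""


@dataclass(frozen=True)
class Residue:
    """One residue of a coarse-grained chain.

    Attributes
    ----------
    author_seq_id:
        PDB residue number (author numbering).
    aa:
        One-letter standard amino-acid code.
    rep_coord:
        Representative-atom coordinate in Å (Cβ; Cα for glycine).
    bfactor:
        Crystallographic temperature factor of the representative atom, Å².
    """

    author_seq_id: int
    aa: str
    rep_coord: np.ndarray
    bfactor: float

    def __post_init__(self) -> None:
        if self.aa not in STANDARD_AAS:
            raise ValueError(f"not a standard amino acid: {self.aa!r}")
        coord = np.asarray(self.rep_coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"rep_coord must be a finite 3-vector, got {self.rep_coord!r}")
        object.__setattr__(self, "rep_coord", coord)
        if not np.isfinite(self.bfactor) or self.bfactor < 0:
            raise ValueError(f"bfactor must be non-negative, got {self.bfactor!r}")


@dataclass(frozen=True)
class ProteinStructure:
    """An ordered single-chain residue list with author numbering."""

    label: str
    residues: tuple[Residue, ...]
    state_tag: str = "unspecified"

    def __post_init__(self) -> None:
        if self.state_tag not in STATE_TAGS:
            raise ValueError(f"state_tag must be one of {STATE_TAGS}")
        object.__setattr__(self, "residues", tuple(self.residues))
        ids = [r.author_seq_id for r in self.residues]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError("author_seq_id must be strictly increasing (no duplicates)")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def seq_ids(self) -> np.ndarray:
        return np.array([r.author_seq_id for r in self.residues], dtype=int)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of representative-atom coordinates, file order."""
        return np.array([r.rep_coord for r in self.residues], dtype=float)

    @property
    def bfactors(self) -> np.ndarray:
        return np.array([r.bfactor for r in self.residues], dtype=float)

    def residue_at(self, author_seq_id: int) -> Residue:
        try:
            return self._index()[author_seq_id]
        except KeyError:
            raise KeyError(f"no residue with author_seq_id {author_seq_id}") from None

    def __contains__(self, author_seq_id: int) -> bool:
        return author_seq_id in self._index()

    def _index(self) -> Mapping[int, Residue]:
        # built lazily; frozen dataclass, so stash on the instance dict via object.__setattr__
        cached = self.__dict__.get("_idx")
        if cached is None:
            cached = {r.author_seq_id: r for r in self.residues}
            object.__setattr__(self, "_idx", cached)
        return cached

    def with_residue(self, author_seq_id: int, **changes) -> "ProteinStructure":
        """Return a copy with one residue's fields replaced."""
        new = tuple(
            replace(r, **changes) if r.author_seq_id == author_seq_id else r
            for r in self.residues
        )
        return ProteinStructure(self.label, new, self.state_tag)


def _first_altloc(atom):
    """Resolve Biopython disordered atoms to their first alternate location."""
    if atom.is_disordered():
        return sorted(atom.disordered_get_list(), key=lambda a: a.get_altloc())[0]
    return atom


def read_structure(
    path: str | Path,
    chain: str,
    state_tag: str = "unspecified",
    label: str | None = None,
    min_residues: int = 1,
) -> ProteinStructure:
    """Parse one chain of a PDB file into a :class:`ProteinStructure`.

    One residue is emitted per standard amino acid carrying a representative
    atom (Cβ, or Cα for glycine).  HETATM records, waters and alternate
    locations other than the first are ignored; residues whose representative
    atom is missing, and residue codes with no standard parent, are dropped
    with a logged warning.  Only the first model of multi-model files is read.

    Parameters
    ----------
    path:
        PDB-format file.
    chain:
        Chain identifier to extract; an absent chain is an error.
    state_tag:
        Conformational-state label (``inactive``/``active``/``unspecified``).
    min_residues:
        Minimum number of usable residues; frustration analysis itself
        requires at least 20, enforced at profiling time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    model = parser.get_structure(path.stem, str(path))[0]
    if chain not in [c.id for c in model]:
        raise StructureError(
            f"chain {chain!r} not found in {path.name}; "
            f"available: {sorted(c.id for c in model)}"
        )
    residues: list[Residue] = []
    for res in model[chain]:
        hetflag, seq_id, icode = res.get_id()
        if hetflag.strip():
            resname = res.get_resname().strip()
            if resname not in _THREE_TO_ONE:
                continue  # true heteroatom group (water, ligand)
        resname = res.get_resname().strip()
        aa = _THREE_TO_ONE.get(resname)
        if aa is None:
            logger.warning("dropping non-standard residue %s %s%s", resname, seq_id, icode)
            continue
        rep_name = "CA" if aa == "G" else "CB"
        if rep_name not in res:
            logger.warning(
                "dropping residue %s%d: representative atom %s missing", aa, seq_id, rep_name
            )
            continue
        atom = _first_altloc(res[rep_name])
        residues.append(
            Residue(
                author_seq_id=int(seq_id),
                aa=aa,
                rep_coord=np.asarray(atom.get_coord(), dtype=float),
                bfactor=max(float(atom.get_bfactor()), 0.0),
            )
        )
    if len(residues) < min_residues:
        raise StructureError(
            f"chain {chain!r} of {path.name} has {len(residues)} usable residues "
            f"(minimum {min_residues})"
        )
    return ProteinStructure(
        label=label if label is not None else f"{path.stem}:{chain}",
        residues=tuple(residues),
        state_tag=state_tag,
    )


def write_profile_table(profile, path: str | Path, contact_path: str | Path | None = None) -> None:
    """Write a frustration profile as residue- and contact-level TSV tables.

    ``path`` receives the residue table (``seq_id aa frustration_index class``);
    the companion contact table (``i j distance_A native_energy z_score class``)
    goes to ``contact_path``, defaulting to ``<path stem>.contacts.tsv``.
    """
    if not profile.contact_records:
        raise ValueError("cannot write an empty profile")
    path = Path(path)
    if contact_path is None:
        contact_path = path.with_suffix(".contacts.tsv")
    res_rows = [
        (seq_id, profile.residue_aa[seq_id], idx, profile.classify_value(idx))
        for seq_id, idx in sorted(profile.residue_index.items())
    ]
    pd.DataFrame(res_rows, columns=RESIDUE_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )
    con_rows = [
        (
            rec.contact.i,
            rec.contact.j,
            rec.contact.distance,
            rec.contact.native_energy,
            rec.z_score,
            rec.class_label,
        )
        for rec in profile.contact_records
    ]
    pd.DataFrame(con_rows, columns=CONTACT_TABLE_COLUMNS).to_csv(
        contact_path, sep="\t", index=False, float_format="%.6f"
    )


def read_profile_table(path: str | Path) -> pd.DataFrame:
    """Read back a residue (or contact) TSV written by :func:`write_profile_table`."""
    return pd.read_csv(path, sep="\t")
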