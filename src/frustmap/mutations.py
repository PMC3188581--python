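"""Point-mutation scanning on a fixed backbone.

A mutation is applied as an identity substitution: the residue's amino acid
changes, every coordinate stays put.  This reads the mutant profile as the
energetic response of the native fold to the substitution — no side-chain
remodelling or relaxation is attempted, which is the main caveat when
comparing against experimentally refined mutant structures.

Wild-type and mutant profiles are meant to be computed with the same seed:
the decoy generator is keyed per contact, so shared seeds give common random
numbers and the per-residue difference profile is not dominated by sampling
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .frustration import (
    HIGHLY_FRUSTRATED,
    MINIMALLY_FRUSTRATED,
    NEUTRAL,
    FrustrationProfile,
    Thresholds,
    classify,
)
from .structure_io import STANDARD_AAS, ProteinStructure

LOCAL = "local"
ALLOSTERIC = "allosteric"

#: |Δ residue index| at or above which a residue counts as affected.
DEFAULT_EFFECT_THRESHOLD: float = 0.5
#: Cβ–Cβ distance (Å) separating local from allosteric effects.
DEFAULT_ALLOSTERIC_DISTANCE_A: float = 10.0

_CLASS_RANK = {HIGHLY_FRUSTRATED: 0, NEUTRAL: 1, MINIMALLY_FRUSTRATED: 2}


class WtMismatchError(ValueError):
    """The structure's residue identity disagrees with the mutation's wild type."""


class ProfileMismatchError(ValueError):
    """Two profiles do not cover the same residue set (or gene)."""


@dataclass(frozen=True)
class MutationSpec:
    """A single point substitution, e.g. ABL T315I."""

    gene: str
    wt_aa: str
    position: int
    mut_aa: str
    oncogenic_count: int = 0

    def __post_init__(self) -> None:
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in STANDARD_AAS:
                raise ValueError(f"not a standard amino acid: {aa!r}")
        if self.wt_aa == self.mut_aa:
            raise ValueError(
                f"{self.gene} {self.wt_aa}{self.position}{self.mut_aa}: "
                "wild-type and mutant amino acids must differ"
            )
        if self.oncogenic_count < 0:
            raise ValueError("oncogenic_count must be non-negative")

    @property
    def name(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    def validate_against(self, structure: ProteinStructure) -> None:
        if self.position not in structure:
            raise WtMismatchError(
                f"{self.gene} {self.name}: position {self.position} absent from "
                f"structure {structure.label!r}"
            )
        found = structure.residue_at(self.position).aa
        if found != self.wt_aa:
            raise WtMismatchError(
                f"{self.gene} {self.name}: structure {structure.label!r} has "
                f"{found} at position {self.position}, expected wild type {self.wt_aa}"
            )


@dataclass(frozen=True)
class MutationCatalog:
    """A set of point mutations, unique by (gene, wt, position, mut)."""

    entries: tuple[MutationSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        keys = [(m.gene, m.wt_aa, m.position, m.mut_aa) for m in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate mutation entries")

    def __len__(self) -> int:
        return len(self.entries)

    def for_gene(self, gene: str) -> list[MutationSpec]:
        return [m for m in self.entries if m.gene == gene]

    def positions(self, gene: str | None = None) -> list[int]:
        return sorted(
            {m.position for m in self.entries if gene is None or m.gene == gene}
        )


def read_mutation_list(path: str | Path) -> MutationCatalog:
    """Read a whitespace/tab-delimited mutation list.

    Columns: ``gene wt_aa position mut_aa [count]``; a header line starting
    with ``gene`` is skipped; ``#`` comments allowed.
    """
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0].lower() == "gene":
                continue
            if len(parts) < 4:
                raise ValueError(f"malformed mutation line: {line!r}")
            gene, wt, pos, mut = parts[:4]
            count = int(parts[4]) if len(parts) > 4 else 0
            entries.append(
                MutationSpec(
                    gene=gene, wt_aa=wt, position=int(pos), mut_aa=mut, oncogenic_count=count
                )
            )
    return MutationCatalog(entries=tuple(entries))


def apply_mutation(structure: ProteinStructure, spec: MutationSpec) -> ProteinStructure:
    """Substitute one residue identity on the fixed backbone.

    Coordinates and B-factors are untouched; the label records the mutation.
    """
    spec.validate_against(structure)
    mutated = structure.with_residue(spec.position, aa=spec.mut_aa)
    return ProteinStructure(
        label=f"{structure.label}|{spec.name}",
        residues=mutated.residues,
        state_tag=structure.state_tag,
    )


@dataclass(frozen=True)
class DeltaFrustrationProfile:
    """Residue-wise change in frustration induced by one mutation."""

    mutation: MutationSpec
    delta: dict[int, float]  # mutant residue index − wild-type residue index
    affected: tuple[tuple[int, float, str], ...]  # (seq_id, distance_to_mutation_A, label)

    @property
    def local_sites(self) -> list[int]:
        return [sid for sid, _, lab in self.affected if lab == LOCAL]

    @property
    def allosteric_sites(self) -> list[int]:
        return [sid for sid, _, lab in self.affected if lab == ALLOSTERIC]


def delta_profile(
    wt: FrustrationProfile,
    mut: FrustrationProfile,
    structure: ProteinStructure,
    spec: MutationSpec,
    effect_threshold: float = DEFAULT_EFFECT_THRESHOLD,
    allosteric_distance: float = DEFAULT_ALLOSTERIC_DISTANCE_A,
) -> DeltaFrustrationProfile:
    """Per-residue frustration change and its local/allosteric partition.

    A residue is *affected* when |Δindex| ≥ ``effect_threshold``; affected
    residues within ``allosteric_distance`` (representative-atom distance) of
    the mutated position are labelled local, the rest allosteric.
    """
    if set(wt.residue_index) != set(mut.residue_index):
        raise ProfileMismatchError(
            "wild-type and mutant profiles cover different residue sets"
        )
    mut_coord = structure.residue_at(spec.position).rep_coord
    delta = {
        sid: mut.residue_index[sid] - wt.residue_index[sid] for sid in wt.residue_index
    }
    affected = []
    for sid in sorted(delta):
        if abs(delta[sid]) < effect_threshold:
            continue
        dist = float(np.linalg.norm(structure.residue_at(sid).rep_coord - mut_coord))
        label = LOCAL if dist <= allosteric_distance else ALLOSTERIC
        affected.append((sid, dist, label))
    return DeltaFrustrationProfile(mutation=spec, delta=delta, affected=tuple(affected))


@dataclass(frozen=True)
class StateComparison:
    """How a mutation shifts residue frustration classes in one state."""

    state: str
    worsened: tuple[int, ...]  # class moved toward highly_frustrated
    improved: tuple[int, ...]  # class moved toward minimally_frustrated
    net_delta: float           # sum of (mutant − wild-type) residue indices


@dataclass(frozen=True)
class PairedStateReport:
    """Inactive/active comparison of a mutation's frustration effect.

    ``activation_consistent`` is True when the mutation raises net frustration
    in the inactive state (net index drop) while lowering it in the active
    state (net index rise) — the signature expected of an activating switch.
    """

    gene: str
    inactive: StateComparison
    active: StateComparison
    activation_consistent: bool


def _gene_of(profile: FrustrationProfile) -> str:
    import re

    return re.split(r"[^0-9A-Za-z]+", profile.structure_label, maxsplit=1)[0]


def _compare_state(
    wt: FrustrationProfile, mut: FrustrationProfile, state: str, thresholds: Thresholds
) -> StateComparison:
    if set(wt.residue_index) != set(mut.residue_index):
        raise ProfileMismatchError(f"{state}: residue sets differ between WT and mutant")
    worsened, improved = [], []
    net = 0.0
    for sid in sorted(wt.residue_index):
        w, m = wt.residue_index[sid], mut.residue_index[sid]
        net += m - w
        dr = _CLASS_RANK[classify(m, thresholds)] - _CLASS_RANK[classify(w, thresholds)]
        if dr < 0:
            worsened.append(sid)
        elif dr > 0:
            improved.append(sid)
    return StateComparison(
        state=state, worsened=tuple(worsened), improved=tuple(improved), net_delta=net
    )


def paired_state_report(
    wt_inactive: FrustrationProfile,
    mut_inactive: FrustrationProfile,
    wt_active: FrustrationProfile,
    mut_active: FrustrationProfile,
    thresholds: Thresholds | None = None,
) -> PairedStateReport:
    """Summarise a mutation's effect across the inactive and active states."""
    genes = {_gene_of(p) for p in (wt_inactive, mut_inactive, wt_active, mut_active)}
    if len(genes) != 1:
        raise ProfileMismatchError(f"profiles come from different genes: {sorted(genes)}")
    thr = thresholds if thresholds is not None else wt_inactive.thresholds
    inactive = _compare_state(wt_inactive, mut_inactive, "inactive", thr)
    active = _compare_state(wt_active, mut_active, "active", thr)
    return PairedStateReport(
        gene=genes.pop(),
        inactive=inactive,
        active=active,
        activation_consistent=(inactive.net_delta < 0 and active.net_delta > 0),
    )
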