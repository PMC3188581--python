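"""Decoy-based local frustration indices.

The local frustration index of a native contact (i, j) is the Z-score of its
native pair energy against an ensemble of N decoys:

    FI_ij = (mean(E_decoy) - E_native) / sd(E_decoy)

so a native pair that is more stabilising than typical decoys scores
positive.  Two decoy schemes are supported:

* ``mutational`` — decoys keep the native geometry and redraw both residue
  identities from the chain's own composition (implemented by drawing chain
  positions uniformly, which weights identities by their frequency);
* ``configurational`` — decoys additionally redraw the inter-residue distance
  uniformly from the structure's observed contact distances, so both the
  identities and the location of the pair are perturbed.

Contacts are classified by fixed thresholds: FI ≥ 0.78 minimally frustrated,
FI < −1 highly frustrated, neutral in between; sites with residue-level
FI < −2.0 are the conventional highlight set for structure mapping.

A residue-level index is the arithmetic mean of the indices of all contacts
incident to that residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .energy import (
    DEFAULT_CUTOFF_A,
    DEFAULT_MIN_SEP,
    DEFAULT_WELL_A,
    Contact,
    ContactMap,
    ContactPotential,
    build_contact_map,
    switching_weight,
)
from .structure_io import ProteinStructure

SCHEMES = ("configurational", "mutational")

#: Default number of decoys per contact.
DEFAULT_N_DECOYS: int = 1000

MINIMALLY_FRUSTRATED = "minimally_frustrated"
NEUTRAL = "neutral"
HIGHLY_FRUSTRATED = "highly_frustrated"

#: Analysis requires a minimally folded chain.
MIN_RESIDUES_FOR_PROFILE: int = 20


class Thresholds(NamedTuple):
    """Classification cutoffs on the frustration index."""

    minimal: float = 0.78       # FI >= minimal → minimally frustrated
    frustrated: float = -1.0    # FI < frustrated → highly frustrated
    highlight: float = -2.0     # residue FI < highlight → mapped as a frustrated site

    def validate(self) -> "Thresholds":
        if not (self.minimal > self.frustrated > self.highlight):
            raise ValueError("thresholds must be ordered minimal > frustrated > highlight")
        return self


DEFAULT_THRESHOLDS = Thresholds()


class DegenerateDecoyError(ValueError):
    """All decoys have identical energy: the Z-score is undefined."""


@dataclass(frozen=True)
class DecoyEnsemble:
    """Summary statistics of a decoy energy ensemble for one contact."""

    n_decoys: int
    mean_energy: float
    sd_energy: float
    scheme: str

    def __post_init__(self) -> None:
        if self.n_decoys < 2:
            raise ValueError("n_decoys must be >= 2")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if not (np.isfinite(self.sd_energy) and self.sd_energy > 0):
            raise DegenerateDecoyError(
                f"decoy ensemble has zero energy spread (scheme={self.scheme})"
            )


@dataclass(frozen=True)
class FrustrationRecord:
    """One contact with its frustration index and class."""

    contact: Contact
    z_score: float
    class_label: str
    ensemble: DecoyEnsemble | None = None


@dataclass(frozen=True)
class FrustrationProfile:
    """Contact- and residue-level frustration indices of one structure."""

    structure_label: str
    contact_records: tuple[FrustrationRecord, ...]
    residue_index: Mapping[int, float]
    residue_aa: Mapping[int, str]
    thresholds: Thresholds = DEFAULT_THRESHOLDS
    scheme: str = "configurational"

    def __post_init__(self) -> None:
        object.__setattr__(self, "contact_records", tuple(self.contact_records))
        self.thresholds.validate()

    def classify_value(self, z: float) -> str:
        return classify(z, self.thresholds)

    @property
    def residue_classes(self) -> dict[int, str]:
        return {sid: self.classify_value(v) for sid, v in self.residue_index.items()}

    def class_fractions(self) -> dict[str, float]:
        """Fraction of contacts in each frustration class."""
        n = len(self.contact_records)
        out = {MINIMALLY_FRUSTRATED: 0.0, NEUTRAL: 0.0, HIGHLY_FRUSTRATED: 0.0}
        for rec in self.contact_records:
            out[rec.class_label] += 1.0 / n
        return out

    def highlighted_sites(self) -> list[int]:
        """Residues below the mapping-highlight cutoff (frustrated sites)."""
        return sorted(
            sid for sid, v in self.residue_index.items() if v < self.thresholds.highlight
        )


def classify(z_score: float, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """Classify a frustration index against fixed cutoffs."""
    if not np.isfinite(z_score):
        raise ValueError(f"z_score must be finite, got {z_score}")
    if z_score >= thresholds.minimal:
        return MINIMALLY_FRUSTRATED
    if z_score < thresholds.frustrated:
        return HIGHLY_FRUSTRATED
    return NEUTRAL


def z_from_ensemble(native_energy: float, mean_energy: float, sd_energy: float) -> float:
    """Frustration index from ensemble moments: (mean − native) / sd."""
    if sd_energy <= 0 or not np.isfinite(sd_energy):
        raise DegenerateDecoyError("sd of decoy energies must be positive")
    return (mean_energy - native_energy) / sd_energy


def _contact_rng(seed: int, i: int, j: int) -> np.random.Generator:
    """Per-contact generator keyed by (seed, i, j).

    Keying by the contact gives common random numbers across runs that share
    a seed, so wild-type vs mutant comparisons are not dominated by decoy
    sampling noise.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i, j)))


def _decoy_energies(
    contact: Contact,
    structure: ProteinStructure,
    cmap: ContactMap,
    scheme: str,
    n_decoys: int,
    rng: np.random.Generator,
    potential: ContactPotential,
    well: float,
    cutoff: float,
) -> np.ndarray:
    codes = potential.encode(structure.sequence)
    n = len(codes)
    ia = rng.integers(0, n, size=n_decoys)
    ib = rng.integers(0, n, size=n_decoys)
    eps = potential.epsilon[codes[ia], codes[ib]]
    if scheme == "mutational":
        w = switching_weight(contact.distance, well, cutoff)
    else:  # configurational: redraw distance from the observed contact distances
        dists = cmap.distances
        w = switching_weight(dists[rng.integers(0, len(dists), size=n_decoys)], well, cutoff)
    return eps * w


def contact_frustration(
    contact: Contact,
    structure: ProteinStructure,
    cmap: ContactMap,
    scheme: str = "configurational",
    n_decoys: int = DEFAULT_N_DECOYS,
    rng_seed: int = 0,
    potential: ContactPotential | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    well: float = DEFAULT_WELL_A,
    energy_scale: float = 1.0,
    energy_shift: float = 0.0,
) -> FrustrationRecord:
    """Frustration index of one native contact as a decoy Z-score.

    ``energy_scale``/``energy_shift`` apply the same affine map to the native
    and every decoy energy; the Z-score is invariant to it by construction
    (useful for unit checks, harmless at the defaults).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    if n_decoys < 2:
        raise ValueError("n_decoys must be >= 2")
    pot = potential if potential is not None else ContactPotential.default()
    rng = _contact_rng(rng_seed, contact.i, contact.j)
    decoys = energy_scale * _decoy_energies(
        contact, structure, cmap, scheme, n_decoys, rng, pot, well, cmap.cutoff
    ) + energy_shift
    native = energy_scale * contact.native_energy + energy_shift
    mean = float(np.mean(decoys))
    sd = float(np.std(decoys, ddof=1))
    ensemble = DecoyEnsemble(n_decoys=n_decoys, mean_energy=mean, sd_energy=sd, scheme=scheme)
    z = z_from_ensemble(native, mean, sd)
    return FrustrationRecord(
        contact=contact, z_score=z, class_label=classify(z, thresholds), ensemble=ensemble
    )


def residue_frustration(
    records: Iterable[FrustrationRecord], structure: ProteinStructure
) -> dict[int, float]:
    """Residue-level index: mean Z-score over contacts incident to each residue.

    Residues without any contact are absent from the result.
    """
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for rec in records:
        for sid in (rec.contact.i, rec.contact.j):
            if sid not in structure:
                raise KeyError(f"contact endpoint {sid} not in structure")
            sums[sid] = sums.get(sid, 0.0) + rec.z_score
            counts[sid] = counts.get(sid, 0) + 1
    return {sid: sums[sid] / counts[sid] for sid in sums}


def profile_structure(
    structure: ProteinStructure,
    scheme: str = "configurational",
    n_decoys: int = DEFAULT_N_DECOYS,
    seed: int = 0,
    cutoff: float = DEFAULT_CUTOFF_A,
    min_sep: int = DEFAULT_MIN_SEP,
    potential: ContactPotential | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    well: float = DEFAULT_WELL_A,
    contact_map: ContactMap | None = None,
    energy_scale: float = 1.0,
    energy_shift: float = 0.0,
) -> FrustrationProfile:
    """Compute the full frustration profile of one structure.

    Deterministic for a fixed (structure, parameters, seed); each contact
    uses an independent generator keyed by (seed, i, j).
    """
    if len(structure) < MIN_RESIDUES_FOR_PROFILE:
        raise ValueError(
            f"frustration analysis needs >= {MIN_RESIDUES_FOR_PROFILE} residues, "
            f"got {len(structure)}"
        )
    pot = potential if potential is not None else ContactPotential.default()
    cmap = (
        contact_map
        if contact_map is not None
        else build_contact_map(structure, cutoff, min_sep, pot, well)
    )
    records = tuple(
        contact_frustration(
            c,
            structure,
            cmap,
            scheme=scheme,
            n_decoys=n_decoys,
            rng_seed=seed,
            potential=pot,
            thresholds=thresholds,
            well=well,
            energy_scale=energy_scale,
            energy_shift=energy_shift,
        )
        for c in cmap.contacts
    )
    return FrustrationProfile(
        structure_label=structure.label,
        contact_records=records,
        residue_index=residue_frustration(records, structure),
        residue_aa={r.author_seq_id: r.aa for r in structure.residues},
        thresholds=thresholds,
        scheme=scheme,
    )


def frustration_histogram(
    profiles: Sequence[FrustrationProfile], bin_width: float = 0.5
) -> pd.DataFrame:
    """Pooled histogram of residue-level frustration indices.

    Bins are aligned to multiples of ``bin_width`` and span at least
    [−4, +4], the conventional display range of the index.  Returns a
    DataFrame with ``bin_left``, ``bin_right``, ``count`` and normalised
    ``frequency`` columns (frequencies sum to 1).
    """
    if not profiles:
        raise ValueError("need at least one profile")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.concatenate([list(p.residue_index.values()) for p in profiles])
    lo = bin_width * np.floor(min(values.min(), -4.0) / bin_width)
    hi = bin_width * np.ceil(max(values.max(), 4.0) / bin_width)
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "frequency": counts / counts.sum(),
        }
    )
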