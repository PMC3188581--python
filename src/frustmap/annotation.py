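"""Kinase catalytic-core subdomain annotation and frustration/mutation mapping.

The catalytic domain is partitioned into twelve sequential subdomains
(SD1–SD12, with SD6 split into A/B), keyed to the author numbering of the
ABL catalytic domain in the 1IEP crystal form: SD1 242–261 (P-loop), SD3
279–291 (αC-helix), SD5 310–335 (hinge), SD6B 357–374 (catalytic loop),
SD7 375–393 (activation loop), SD8 394–416 (P+1 loop), out to SD12 481–498.
Other kinases need a shifted or user-supplied partition file.

Besides plain counting, :func:`collocation_score` quantifies whether mutation
sites cluster near highly frustrated sites in 3D, with a permutation null
that relabels the frustrated positions uniformly among all residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure_io import ProteinStructure

OUTSIDE = "outside"

_DEFAULT_PARTITION = "abl_1iep_subdomains.tsv"


@dataclass(frozen=True)
class SubdomainRange:
    name: str
    start: int
    end: int
    annotation: str = "-"

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end  # inclusive on both ends


@dataclass(frozen=True)
class SubdomainPartition:
    """Ordered, non-overlapping residue ranges of the catalytic core."""

    ranges: tuple[SubdomainRange, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranges", tuple(self.ranges))
        names = [r.name for r in self.ranges]
        if len(set(names)) != len(names):
            raise ValueError("subdomain names must be unique")
        for a, b in zip(self.ranges, self.ranges[1:]):
            if b.start <= a.end:
                raise ValueError(f"ranges overlap or are out of order: {a.name}, {b.name}")
        for r in self.ranges:
            if r.end < r.start:
                raise ValueError(f"empty range {r.name}")

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.ranges]

    @classmethod
    def from_file(cls, path: str | Path) -> "SubdomainPartition":
        """Load a partition from delimited text: ``name start end annotation``."""
        df = pd.read_csv(path, sep="\t")
        ranges = tuple(
            SubdomainRange(
                name=str(row["name"]),
                start=int(row["start"]),
                end=int(row["end"]),
                annotation=str(row.get("annotation", "-")),
            )
            for _, row in df.iterrows()
        )
        return cls(ranges=ranges)

    @classmethod
    def default(cls) -> "SubdomainPartition":
        """The packaged SD1–SD12 partition (ABL 1IEP author numbering)."""
        ref = resources.files("frustmap.data").joinpath(_DEFAULT_PARTITION)
        with resources.as_file(ref) as p:
            return cls.from_file(p)


def assign_subdomain(position: int, partition: SubdomainPartition | None = None) -> str:
    """Name of the subdomain containing ``position``, or ``outside``."""
    part = partition if partition is not None else SubdomainPartition.default()
    for r in part.ranges:
        if position in r:
            return r.name
    return OUTSIDE


def subdomain_distribution(
    items: Sequence[int], partition: SubdomainPartition | None = None
) -> pd.DataFrame:
    """Counts and fractions of positions per subdomain.

    Fractions are normalised over assigned items (positions falling inside a
    subdomain); the ``outside`` row reports the spill-over count with a NaN
    fraction.
    """
    part = partition if partition is not None else SubdomainPartition.default()
    counts = {name: 0 for name in part.names}
    counts[OUTSIDE] = 0
    for pos in items:
        counts[assign_subdomain(pos, part)] += 1
    n_assigned = sum(v for k, v in counts.items() if k != OUTSIDE)
    rows = []
    for r in part.ranges:
        frac = counts[r.name] / n_assigned if n_assigned else 0.0
        rows.append((r.name, r.start, r.end, r.annotation, counts[r.name], frac))
    rows.append((OUTSIDE, np.nan, np.nan, "-", counts[OUTSIDE], np.nan))
    return pd.DataFrame(
        rows, columns=["subdomain", "start", "end", "annotation", "count", "fraction"]
    )


def _overlap_count(
    frust_coords: np.ndarray, mut_coords: np.ndarray, radius: float
) -> int:
    """Mutation sites within ``radius`` of at least one frustrated site."""
    d = cdist(mut_coords, frust_coords)
    return int(np.sum(d.min(axis=1) <= radius))


def collocation_score(
    frustrated_sites: Sequence[int],
    mutation_sites: Sequence[int],
    structure: ProteinStructure,
    radius: float = 10.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[int, float]:
    """Spatial collocation of mutation sites with frustrated sites.

    Returns ``(observed_overlap, permutation_p)``: the number of mutation
    sites whose representative atom lies within ``radius`` of at least one
    frustrated site, and a one-sided permutation p-value from ``n_perm``
    uniform relabelings of the frustrated-site positions among all residues
    of the structure.  The p-value uses the add-one estimator, so it lies in
    [1/(n_perm+1), 1].
    """
    if not frustrated_sites or not mutation_sites:
        raise ValueError("both site lists must be nonempty")
    for sid in list(frustrated_sites) + list(mutation_sites):
        if sid not in structure:
            raise KeyError(f"site {sid} not in structure {structure.label!r}")
    coords = structure.coords
    sid_to_row = {sid: k for k, sid in enumerate(structure.seq_ids)}
    frust_rows = np.array([sid_to_row[s] for s in frustrated_sites])
    mut_coords = coords[[sid_to_row[s] for s in mutation_sites]]
    observed = _overlap_count(coords[frust_rows], mut_coords, radius)
    rng = np.random.default_rng(seed)
    k = len(frust_rows)
    n_ge = 0
    for _ in range(n_perm):
        perm_rows = rng.choice(len(coords), size=k, replace=False)
        if _overlap_count(coords[perm_rows], mut_coords, radius) >= observed:
            n_ge += 1
    return observed, (1 + n_ge) / (n_perm + 1)
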