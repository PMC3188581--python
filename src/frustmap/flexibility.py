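"""Frustration vs crystallographic flexibility.

B-factors are the flexibility proxy: frustrated regions are expected to be
more mobile, so the residue frustration index should anticorrelate with the
B-factor.  Rank correlation is the default because B-factor scales vary
between crystals and only the monotone relation is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .frustration import FrustrationProfile
from .structure_io import ProteinStructure

METHODS = ("spearman", "pearson")


class UndefinedCorrelationError(ValueError):
    """One of the paired columns is constant; the correlation is undefined."""


@dataclass(frozen=True)
class FlexibilityReport:
    n_residues: int
    correlation: float
    method: str
    paired_values: tuple[tuple[int, float, float], ...]  # (seq_id, bfactor, residue_index)


def bfactor_frustration_correlation(
    structure: ProteinStructure,
    profile: FrustrationProfile,
    method: str = "spearman",
) -> FlexibilityReport:
    """Correlate per-residue frustration indices with B-factors.

    Pairs every residue that has both a B-factor and a residue-level index
    (i.e. at least one contact); requires ≥ 5 pairs and nonzero variance in
    both columns.  The sign is reported as computed — anticorrelation
    (negative values) is the expected direction, since low (frustrated)
    indices should accompany high mobility.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    pairs = [
        (r.author_seq_id, r.bfactor, profile.residue_index[r.author_seq_id])
        for r in structure.residues
        if r.author_seq_id in profile.residue_index
    ]
    if len(pairs) < 5:
        raise ValueError(f"need >= 5 paired residues, got {len(pairs)}")
    b = np.array([p[1] for p in pairs])
    fi = np.array([p[2] for p in pairs])
    if np.ptp(b) == 0 or np.ptp(fi) == 0:
        raise UndefinedCorrelationError(
            "constant B-factors or frustration indices: correlation undefined"
        )
    if method == "spearman":
        corr = float(stats.spearmanr(b, fi).statistic)
    else:
        corr = float(stats.pearsonr(b, fi).statistic)
    return FlexibilityReport(
        n_residues=len(pairs),
        correlation=corr,
        method=method,
        paired_values=tuple(pairs),
    )


def write_flexibility_report(report: FlexibilityReport, path: str | Path) -> None:
    """TSV of paired values plus a trailing summary comment line."""
    df = pd.DataFrame(
        report.paired_values, columns=["seq_id", "bfactor", "frustration_index"]
    )
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")
        fh.write(
            f"# method={report.method} n={report.n_residues} "
            f"correlation={report.correlation:.6f}\n"
        )
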