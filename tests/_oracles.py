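"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's sampling code paths: the mutational
Z-score is computed by exhaustive composition-weighted enumeration over all
identity pairs, and the collocation null by full enumeration of frustrated-
site subsets.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from frustmap.energy import switching_weight


def exhaustive_mutational_z(contact, structure, potential) -> float:
    """Exact mutational frustration index by enumerating all identity pairs.

    Decoys keep the native distance and draw both identities independently
    from the chain's composition, so the exact decoy moments are the
    composition-weighted sums over the 20x20 identity pairs.
    """
    seq = structure.sequence
    aas, counts = np.unique(list(seq), return_counts=True)
    p = counts / counts.sum()
    w = switching_weight(contact.distance)
    energies, probs = [], []
    for a, pa in zip(aas, p):
        for b, pb in zip(aas, p):
            energies.append(potential.entry(a, b) * w)
            probs.append(pa * pb)
    energies, probs = np.asarray(energies), np.asarray(probs)
    mean = float((probs * energies).sum())
    var = float((probs * energies**2).sum() - mean**2)
    return (mean - contact.native_energy) / np.sqrt(var)


def mc_standard_error(z: float, n_decoys: int) -> float:
    """Delta-method standard error of a sampled Z-score estimate."""
    return float(np.sqrt((1.0 + z**2 / 2.0) / n_decoys))


def exhaustive_collocation_p(
    frustrated_sites, mutation_sites, structure, radius
) -> float:
    """Exact permutation p-value by enumerating every frustrated-site subset.

    Uses bitmask coverage: for each residue, the set of mutation sites within
    ``radius``; a subset's overlap is the popcount of the OR of its masks.
    """
    coords = structure.coords
    sid_to_row = {sid: k for k, sid in enumerate(structure.seq_ids)}
    mut_rows = [sid_to_row[s] for s in mutation_sites]
    n = len(coords)
    masks = []
    for r in range(n):
        mask = 0
        for b, m in enumerate(mut_rows):
            if np.linalg.norm(coords[r] - coords[m]) <= radius:
                mask |= 1 << b
        masks.append(mask)
    frust_rows = [sid_to_row[s] for s in frustrated_sites]
    observed = bin(int(np.bitwise_or.reduce([masks[r] for r in frust_rows]))).count("1")
    k = len(frust_rows)
    n_ge = total = 0
    for subset in combinations(range(n), k):
        acc = 0
        for r in subset:
            acc |= masks[r]
        total += 1
        if bin(acc).count("1") >= observed:
            n_ge += 1
    return n_ge / total
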