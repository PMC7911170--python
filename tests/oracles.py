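"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library's numeric encoding: counting compares
every window substring against every motif as strings; the D-ratio oracle
recomputes the three constituent counts monolithically; the MST oracle is a
plain Prim implementation on the dense distance matrix.
"""

from __future__ import annotations

import itertools

import numpy as np


def oracle_counts(sequence: str, k: int) -> dict[str, int]:
    """Count overlapping pure-ACGT windows by exhaustive string comparison."""
    motifs = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    subs = [sequence[i:i + k] for i in range(len(sequence) - k + 1)]
    subs = [s for s in subs if set(s) <= set("ACGT")]
    return {m: subs.count(m) for m in motifs}


def oracle_pobs(sequence: str, motif: str) -> float:
    counts = oracle_counts(sequence, len(motif))
    total = sum(counts.values())
    return counts[motif] / total if total else 0.0


def oracle_dratio(sequence: str, motif: str) -> float | None:
    """Monolithic D-ratio: count all constituent orders independently."""
    k = len(motif)
    pobs = oracle_pobs(sequence, motif)
    if k == 2:
        pexp = oracle_pobs(sequence, motif[0]) * oracle_pobs(sequence, motif[1])
    else:
        interior = oracle_pobs(sequence, motif[1:-1])
        if interior == 0.0:
            return None
        pexp = (oracle_pobs(sequence, motif[:-1])
                * oracle_pobs(sequence, motif[1:]) / interior)
    if pexp == 0.0:
        return None
    return pobs / pexp


def prim_mst_weights(points: np.ndarray) -> np.ndarray:
    """Sorted edge weights of the Euclidean MST, by Prim's algorithm."""
    n = points.shape[0]
    dist = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    in_tree = [0]
    best = dist[0].copy()
    weights = []
    for _ in range(n - 1):
        best[in_tree] = np.inf
        j = int(np.argmin(best))
        weights.append(best[j])
        in_tree.append(j)
        best = np.minimum(best, dist[j])
    return np.sort(np.array(weights))
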