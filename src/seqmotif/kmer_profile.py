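"""Overlapping k-mer counting and observed motif frequencies.

For each sequence and each motif length k (1..5 by default) every
overlapping window ``seq[i:i+k]`` is counted. Windows containing a non-ACGT
letter (IUPAC ambiguity codes such as N) are skipped and excluded from the
window total, so ambiguous positions never distort frequencies. The observed
frequency of a motif, P_obs, is its count divided by the number of valid
windows of the same length — which makes frequencies at a fixed k sum to 1
and is the normalization the downstream Markov model requires.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import ParameterError
from .sequence_io import SequenceRecord

#: Default upper bound on motif length. Larger k is possible but the motif
#: count grows as 4^k.
DEFAULT_KMAX = 5

ALPHABET = "ACGT"

# Byte-value → 2-bit code lookup; non-ACGT bytes map to -1.
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(ALPHABET.encode()):
    _CODE[_b] = _i


def enumerate_motifs(k: int, kmax: int = DEFAULT_KMAX) -> list[str]:
    """All 4^k motifs over {A,C,G,T} in lexicographic order (A<C<G<T)."""
    if not 1 <= k <= kmax:
        raise ParameterError(f"k must be in [1, {kmax}], got {k}")
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]


@dataclass
class KmerCountTable:
    """Overlapping k-mer counts for one sequence at one k.

    ``counts`` is defined over all 4^k ACGT motifs; ``valid_windows`` is the
    number of length-k windows made purely of A/C/G/T, and equals the sum of
    all counts.
    """

    k: int
    counts: dict[str, int]
    valid_windows: int

    def count_array(self) -> np.ndarray:
        """Counts as a 4^k vector in lexicographic motif order."""
        return np.array([self.counts[m] for m in enumerate_motifs(self.k, self.k)],
                        dtype=np.int64)


@dataclass
class MotifProfile:
    """Observed motif frequencies P_obs for one sequence at one k.

    A profile is *degenerate* when the sequence had no valid window of
    length k; all frequencies are then 0.
    """

    k: int
    pobs: dict[str, float]
    degenerate: bool = False

    def __getitem__(self, motif: str) -> float:
        return self.pobs[motif]


def _encode(sequence: str) -> np.ndarray:
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every valid (pure-ACGT) window, in sequence order."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return windows[valid] @ powers


def count_kmers(seq: SequenceRecord | str, k: int, kmax: int = DEFAULT_KMAX) -> KmerCountTable:
    """Count every overlapping length-k window of a sequence.

    Windows containing any non-ACGT character are skipped and excluded from
    ``valid_windows``. A sequence shorter than k yields an all-zero table.
    """
    if not 1 <= k <= kmax:
        raise ParameterError(f"k must be in [1, {kmax}], got {k}")
    sequence = seq.sequence if isinstance(seq, SequenceRecord) else seq
    motifs = enumerate_motifs(k, kmax)
    if len(sequence) < k:
        return KmerCountTable(k=k, counts=dict.fromkeys(motifs, 0), valid_windows=0)
    codes = _encode(sequence)
    wcodes = _window_codes(codes, k)
    vec = np.bincount(wcodes, minlength=4 ** k)
    counts = {m: int(c) for m, c in zip(motifs, vec)}
    return KmerCountTable(k=k, counts=counts, valid_windows=int(wcodes.size))


def observed_frequency(table: KmerCountTable) -> MotifProfile:
    """P_obs(m) = count(m) / valid_windows; all-zero degenerate profile if none."""
    if table.valid_windows == 0:
        return MotifProfile(k=table.k, pobs=dict.fromkeys(table.counts, 0.0),
                            degenerate=True)
    n = table.valid_windows
    return MotifProfile(k=table.k,
                        pobs={m: c / n for m, c in table.counts.items()})


def profile_sequence(seq: SequenceRecord | str, ks: Iterable[int],
                     kmax: int = DEFAULT_KMAX) -> dict[int, MotifProfile]:
    """Observed-frequency profiles of one sequence at each requested k."""
    ks = sorted(set(ks))
    for k in ks:
        if not 1 <= k <= kmax:
            raise ParameterError(f"k must be in [1, {kmax}], got {k}")
    return {k: observed_frequency(count_kmers(seq, k, kmax)) for k in ks}
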