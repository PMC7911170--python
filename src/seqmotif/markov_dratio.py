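"""Markov-model expected frequencies and the D-ratio (representation).

The representation of a motif is D = P_obs / P_exp, where P_exp is the
frequency the motif would have if it were fully determined by its shorter
constituents under a maximal-order Markov model:

    P_exp(m) = P_obs(prefix) * P_obs(suffix) / P_obs(interior)

with prefix = m[:-1], suffix = m[1:], interior = m[1:-1] — a first-order
model for trinucleotides, second-order for tetranucleotides, and the same
pattern (third order) for pentanucleotides. Dinucleotides use the
zeroth-order product of mononucleotide frequencies. D > 1 means the motif is
over-represented relative to the Markov null, D < 1 under-represented, and
D = 1 exactly as expected; by construction D of, say, TGGG is insensitive to
composition changes in TGG, GGG and GG themselves.

All constituent frequencies are taken from the *same* sequence's own
profiles (per-sequence D-ratio), each order with its own window count.
Zero expected frequency makes D undefined; undefined values are returned as
``None``, never as infinity, and are imputed (as 0, with a logged count)
only when feature matrices are assembled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from .errors import ParameterError
from .kmer_profile import (
    DEFAULT_KMAX,
    MotifProfile,
    enumerate_motifs,
    profile_sequence,
)
from .sequence_io import SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class DRatioProfile:
    """Per-sequence D-ratios and expected frequencies for all 4^k motifs.

    ``d[m]`` and ``pexp[m]`` are ``None`` exactly when the expected
    frequency is zero or cannot be formed (degenerate constituent profile).
    """

    k: int
    d: dict[str, float | None]
    pexp: dict[str, float | None]
    degenerate: bool = False


def _required_orders(k: int) -> tuple[int, ...]:
    if k == 2:
        return (1, 2)
    return (k - 2, k - 1, k)


def expected_frequency(motif: str,
                       profiles: Mapping[int, MotifProfile]) -> float | None:
    """Maximal-order Markov expected frequency of ``motif``.

    For k = |motif| >= 3 this is P_obs(m[:-1]) * P_obs(m[1:]) / P_obs(m[1:-1]);
    for k = 2 it is the product of the two mononucleotide frequencies.
    Returns ``None`` when the interior-motif denominator frequency is 0.
    """
    k = len(motif)
    if k < 2:
        raise ParameterError(
            "expected frequency requires motif length >= 2 "
            "(D of a mononucleotide is identically 1)")
    if k == 2:
        if 1 not in profiles:
            raise ParameterError("k=2 expectation requires the k=1 profile")
        p1 = profiles[1]
        return p1[motif[0]] * p1[motif[1]]
    for order in (k - 1, k - 2):
        if order not in profiles:
            raise ParameterError(
                f"k={k} expectation requires the k={order} profile")
    p_prefix = profiles[k - 1][motif[:-1]]
    p_suffix = profiles[k - 1][motif[1:]]
    p_interior = profiles[k - 2][motif[1:-1]]
    if p_interior == 0.0:
        return None
    return p_prefix * p_suffix / p_interior


def dratio(motif: str, profiles: Mapping[int, MotifProfile]) -> float | None:
    """D(motif) = P_obs / P_exp; ``None`` when P_exp is zero or undefined."""
    k = len(motif)
    pexp = expected_frequency(motif, profiles)
    if k not in profiles:
        raise ParameterError(f"D-ratio requires the k={k} profile")
    if pexp is None or pexp == 0.0:
        return None
    return profiles[k][motif] / pexp


def dratio_profile(seq: SequenceRecord | str, k: int,
                   kmax: int = DEFAULT_KMAX) -> DRatioProfile:
    """D-ratios of all 4^k motifs of one sequence, from a single profiling pass."""
    if not 2 <= k <= kmax:
        raise ParameterError(f"D-ratio requires 2 <= k <= {kmax}, got {k}")
    profiles = profile_sequence(seq, _required_orders(k), kmax)
    degenerate = any(p.degenerate for p in profiles.values())
    motifs = enumerate_motifs(k, kmax)
    if degenerate:
        seq_id = seq.id if isinstance(seq, SequenceRecord) else "<str>"
        logger.warning(
            "sequence %s has no valid windows at some order <= %d; "
            "all D-ratios undefined", seq_id, k)
        none_map: dict[str, float | None] = dict.fromkeys(motifs, None)
        return DRatioProfile(k=k, d=dict(none_map), pexp=dict(none_map),
                             degenerate=True)
    d: dict[str, float | None] = {}
    pexp: dict[str, float | None] = {}
    for m in motifs:
        e = expected_frequency(m, profiles)
        pexp[m] = e
        d[m] = None if (e is None or e == 0.0) else profiles[k][m] / e
    return DRatioProfile(k=k, d=d, pexp=pexp)
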