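"""Assembly of per-sequence profiles into a sequences × motifs matrix.

Rows are sequences in input order; columns are motif names grouped by
ascending k and lexicographic within k, so a matrix may mix several motif
lengths. The basis is either raw observed frequencies or D-ratios; undefined
D-ratios are imputed as 0 at build time with a logged count so the matrix is
always finite. Normalization is global max-abs scaling: the whole matrix is
divided by its largest absolute entry, mapping values into [-1, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import MotifLookupError, ParameterError
from .kmer_profile import DEFAULT_KMAX, enumerate_motifs, profile_sequence
from .markov_dratio import dratio_profile
from .sequence_io import SequenceRecord

logger = logging.getLogger(__name__)

BASES = ("frequency", "dratio")


@dataclass
class FeatureMatrix:
    """Sequences × motifs numeric table.

    ``df`` is indexed by sequence id with motif-name columns; ``basis``
    records whether values are observed frequencies or D-ratios;
    ``n_imputed`` counts undefined D-ratios imputed as 0 at build time.
    """

    df: pd.DataFrame
    basis: str
    normalized: bool = False
    n_imputed: int = 0

    def __post_init__(self) -> None:
        if self.basis not in BASES:
            raise ParameterError(f"basis must be one of {BASES}, got {self.basis!r}")
        if not np.isfinite(self.df.to_numpy(dtype=float)).all():
            raise ParameterError("feature matrix contains non-finite entries")

    @property
    def row_ids(self) -> list[str]:
        return [str(x) for x in self.df.index]

    @property
    def col_names(self) -> list[str]:
        return [str(c) for c in self.df.columns]

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape


def build_matrix(records: Sequence[SequenceRecord], basis: str,
                 ks: Iterable[int], kmax: int = DEFAULT_KMAX) -> FeatureMatrix:
    """Profile every record and assemble the feature matrix.

    ``basis='frequency'`` uses P_obs; ``basis='dratio'`` uses D with
    undefined values imputed as 0 (count logged and recorded on the result).
    """
    records = list(records)
    if not records:
        raise ParameterError("record list is empty")
    if basis not in BASES:
        raise ParameterError(f"basis must be one of {BASES}, got {basis!r}")
    ks = sorted(set(ks))
    if not ks:
        raise ParameterError("at least one motif length k is required")
    for k in ks:
        if not 1 <= k <= kmax:
            raise ParameterError(f"k must be in [1, {kmax}], got {k}")
    if basis == "dratio" and min(ks) < 2:
        raise ParameterError("D-ratio basis requires k >= 2")

    columns = [m for k in ks for m in enumerate_motifs(k, kmax)]
    n_imputed = 0
    rows = np.empty((len(records), len(columns)), dtype=float)
    for i, rec in enumerate(records):
        vals: list[float] = []
        if basis == "frequency":
            profiles = profile_sequence(rec, ks, kmax)
            for k in ks:
                prof = profiles[k]
                vals.extend(prof.pobs[m] for m in enumerate_motifs(k, kmax))
        else:
            for k in ks:
                prof = dratio_profile(rec, k, kmax)
                for m in enumerate_motifs(k, kmax):
                    v = prof.d[m]
                    if v is None:
                        n_imputed += 1
                        v = 0.0
                    vals.append(v)
        rows[i] = vals
    if n_imputed:
        logger.info("imputed %d undefined D-ratio value(s) as 0", n_imputed)
    df = pd.DataFrame(rows, index=[r.id for r in records], columns=columns)
    return FeatureMatrix(df=df, basis=basis, n_imputed=n_imputed)


def select_motifs(matrix: FeatureMatrix, names: Sequence[str] | None = None,
                  lengths: Iterable[int] | None = None) -> FeatureMatrix:
    """Column-subset a matrix by motif names and/or motif lengths (union).

    Row order and basis are preserved; original column order is kept.
    """
    if names is None and lengths is None:
        raise ParameterError("give at least one of names= or lengths=")
    have = matrix.col_names
    selected: set[str] = set()
    if names is not None:
        unknown = [n for n in names if n not in have]
        if unknown:
            raise MotifLookupError(unknown)
        selected.update(names)
    if lengths is not None:
        lengths = set(lengths)
        selected.update(c for c in have if len(c) in lengths)
    keep = [c for c in have if c in selected]
    if not keep:
        raise ParameterError("selection matched no columns")
    return replace(matrix, df=matrix.df[keep].copy())


def maxabs_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Divide the whole matrix by its global maximum absolute value.

    Output entries lie in [-1, 1]; an all-zero matrix is returned unchanged
    with a warning. Idempotent.
    """
    peak = float(np.abs(matrix.values).max()) if matrix.df.size else 0.0
    if peak == 0.0:
        logger.warning("matrix is all zeros; max-abs normalization is a no-op")
        return replace(matrix, df=matrix.df.copy(), normalized=True)
    return replace(matrix, df=matrix.df / peak, normalized=True)
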