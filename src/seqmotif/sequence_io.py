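"""FASTA input and delimited-text output.

Reads multi-record DNA FASTA files into :class:`SequenceRecord` objects and
writes feature matrices and cluster assignments as CSV/TSV. Parsing is
delegated to Biopython; this module adds the validation layer: uppercasing,
U→T mapping (so RNA-notated viral genomes load), IUPAC alphabet checking and
duplicate-id warnings.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ParameterError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .clustering import ClusteringResult
    from .feature_matrix import FeatureMatrix

logger = logging.getLogger(__name__)

#: Nucleotide letters accepted after sanitization: the four bases plus the
#: IUPAC ambiguity codes. Real viral genome sets contain Ns, so ambiguity
#: letters are accepted at load time and handled downstream by window-skipping.
IUPAC_NUCLEOTIDES = frozenset("ACGTNRYSWKMBDHV")


@dataclass(frozen=True)
class SequenceRecord:
    """One named DNA sequence.

    Attributes
    ----------
    id:
        First whitespace-delimited token of the FASTA header; non-empty.
    description:
        Remainder of the header (may be empty).
    sequence:
        Uppercase string over the IUPAC nucleotide alphabet.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record id must be non-empty")
        bad = set(self.sequence) - IUPAC_NUCLEOTIDES
        if bad:
            raise ValidationError(
                f"record {self.id!r}: invalid character(s) "
                f"{', '.join(sorted(bad))} outside the IUPAC nucleotide alphabet"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def sanitize_sequence(raw: str, record_id: str) -> str:
    """Uppercase, map U→T, and validate against the IUPAC alphabet."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - IUPAC_NUCLEOTIDES
    if bad:
        raise ValidationError(
            f"record {record_id!r}: invalid character(s) "
            f"{', '.join(sorted(bad))} outside the IUPAC nucleotide alphabet"
        )
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    Records are returned in file order; sequence lines are concatenated
    regardless of wrapping width; letters are uppercased and 'U' mapped to
    'T'. Duplicate ids are allowed but logged as a warning, as are
    zero-length records.

    Raises
    ------
    FormatError
        If the file is empty or contains no '>' header.
    ValidationError
        If a sequence contains a character outside the IUPAC alphabet.
    """
    path = Path(path)
    text_has_header = False
    with open(path) as handle:
        for line in handle:
            if line.lstrip().startswith(">"):
                text_has_header = True
                break
    if not text_has_header:
        raise FormatError(f"{path}: not FASTA (empty file or no '>' header)")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = sanitize_sequence(str(rec.seq), rec.id)
            if not seq:
                logger.warning("record %r has length 0", rec.id)
            if rec.id in seen:
                logger.warning("duplicate sequence id %r", rec.id)
            seen.add(rec.id)
            # SeqIO's .description includes the id token; strip it off.
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(SequenceRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise FormatError(f"{path}: no records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with lines wrapped at ``width`` columns."""
    path = Path(path)
    with open(path, "w") as handle:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            handle.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i:i + width] + "\n")
            if not rec.sequence:
                handle.write("\n")


_DELIMITERS = {"comma": ",", "tab": "\t", ",": ",", "\t": "\t"}


def write_matrix(matrix: "FeatureMatrix", path: str | Path, delimiter: str = "comma") -> None:
    """Write a feature matrix as delimited text.

    Header row is ``sequence_id`` followed by motif names; one row per
    sequence; floats rendered with 12 significant digits so the file
    round-trips through :func:`read_matrix` to better than 1e-9.
    """
    if delimiter not in _DELIMITERS:
        raise ParameterError(f"delimiter must be 'comma' or 'tab', got {delimiter!r}")
    if matrix.df.shape[0] < 1 or matrix.df.shape[1] < 1:
        raise ParameterError("matrix must have at least one row and one column")
    sep = _DELIMITERS[delimiter]
    matrix.df.to_csv(
        Path(path), sep=sep, index_label="sequence_id",
        float_format="%.12g", quoting=csv.QUOTE_MINIMAL,
    )


def read_matrix(path: str | Path, delimiter: str = "comma",
                basis: str = "frequency") -> "FeatureMatrix":
    """Read a matrix written by :func:`write_matrix`.

    The basis is not stored in the file, so the caller states it (default
    ``frequency``).
    """
    from .feature_matrix import FeatureMatrix

    if delimiter not in _DELIMITERS:
        raise ParameterError(f"delimiter must be 'comma' or 'tab', got {delimiter!r}")
    df = pd.read_csv(Path(path), sep=_DELIMITERS[delimiter], index_col="sequence_id")
    df.index = df.index.astype(str)
    return FeatureMatrix(df=df, basis=basis)


def write_labels(result: "ClusteringResult", path: str | Path) -> None:
    """Write cluster assignments as a two-column CSV (sequence_id, cluster_label)."""
    if len(result.labels) == 0:
        raise ParameterError("clustering result has no labels")
    if len(result.row_ids) != len(result.labels):
        raise ParameterError("one label per sequence id is required")
    df = pd.DataFrame({"sequence_id": result.row_ids,
                       "cluster_label": [int(x) for x in result.labels]})
    df.to_csv(Path(path), index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a labels file back (columns sequence_id, cluster_label)."""
    df = pd.read_csv(Path(path))
    df["sequence_id"] = df["sequence_id"].astype(str)
    return df
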