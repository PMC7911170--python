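"""Exception hierarchy.

All library errors derive from :class:`SeqMotifError` so callers (and the
command-line layer, which maps them onto exit codes) can distinguish usage
mistakes from malformed input and from failures during computation.
"""


class SeqMotifError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(SeqMotifError, ValueError):
    """A function argument is out of range or inconsistent (usage error)."""


class FormatError(SeqMotifError, ValueError):
    """An input file is structurally malformed (e.g. FASTA without headers)."""


class ValidationError(SeqMotifError, ValueError):
    """Input content violates the data contract (e.g. a non-IUPAC letter)."""


class MotifLookupError(SeqMotifError, KeyError):
    """A requested motif name is not present in a feature matrix."""

    def __init__(self, unknown: list[str]):
        self.unknown = list(unknown)
        super().__init__(f"unknown motif name(s): {', '.join(self.unknown)}")


class ComputationError(SeqMotifError, RuntimeError):
    """A computation failed on otherwise well-formed input."""
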