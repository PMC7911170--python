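import numpy as np
import pytest

from seqmotif import SequenceRecord, build_matrix, planted_clusters


@pytest.fixture
def fasta_file(tmp_path):
    """Write FASTA text to a temp file and return the path."""

    def _write(text: str, name: str = "input.fasta"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write


@pytest.fixture
def small_records():
    return [
        SequenceRecord(id="s1", sequence="ACGTACGTAC"),
        SequenceRecord(id="s2", sequence="GGGGCCCCGG"),
        SequenceRecord(id="s3", sequence="ATATATATAT"),
        SequenceRecord(id="s4", sequence="ACGTACGTAC"),
    ]


@pytest.fixture(scope="session")
def two_cluster_fixture():
    """GC-rich vs AT-rich planted composition clusters, 30 sequences each."""
    records, labels = planted_clusters(
        30, [(0.1, 0.4, 0.4, 0.1), (0.4, 0.1, 0.1, 0.4)], 2000, seed=1)
    matrix = build_matrix(records, basis="frequency", ks={2})
    return matrix, labels


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
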