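import random

import pytest

from cycmotif import BackgroundModel, SequenceRecord


@pytest.fixture
def uniform_bg():
    return BackgroundModel.uniform()


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write (id, seq) pairs to a temp FASTA and return its path."""

    def _write(entries, name="test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in entries:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


def random_protein(rng: random.Random, length: int,
                   alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture
def rng():
    return random.Random(20240315)


def record(seq: str, rid: str = "rec1") -> SequenceRecord:
    return SequenceRecord(rid, rid, seq)
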