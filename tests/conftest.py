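import gzip
from pathlib import Path

import pytest

from skipquant.exon_model import Exon, TranscriptModel

# 30-nt toy transcript: three 10-nt exons with distinct boundary bases so
# junction k-mers stay junction-specific even at 1-base overhang.
TOY_SEQ = "ACGTACGTAGCATTCGATCCGTTGCAAGTG"
#           exon1      exon2      exon3
#           1-10       11-20      21-30


@pytest.fixture
def toy_model() -> TranscriptModel:
    return TranscriptModel(
        "TOY1",
        TOY_SEQ,
        (Exon(1, 1, 10), Exon(2, 11, 20), Exon(3, 21, 30)),
    )


@pytest.fixture
def toy_fasta(tmp_path: Path) -> Path:
    path = tmp_path / "toy.fa"
    path.write_text(f">TOY1\n{TOY_SEQ}\n")
    return path


@pytest.fixture
def toy_exon_table(tmp_path: Path) -> Path:
    path = tmp_path / "exons.tsv"
    path.write_text(
        "exon_index\tstart\tend\n1\t1\t10\n2\t11\t20\n3\t21\t30\n"
    )
    return path


def write_fastq_gz(path: Path, records: list[tuple[str, str]]) -> Path:
    """Write (read_id, sequence) records as a 4-line gzip FASTQ."""
    with gzip.open(path, "wt") as fh:
        for read_id, seq in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


@pytest.fixture
def fastq_writer():
    return write_fastq_gz
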