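"""Stream paired droplet FASTQ files and find junction k-mer hits in cDNA.

In 10x Chromium 3' libraries read 1 carries the cell barcode and UMI
(16 + 12 bases for v3 chemistry) and read 2 carries the cDNA fragment, so
only R2 is searched for junction-spanning k-mers. Matching is exact — a hit
is an identical k-length substring — and, because every probe shares one
length k, multi-pattern search reduces to a hash lookup on each k-window of
the read. The scanner is streaming: memory does not grow with file size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import pysam

from .exon_model import KmerSet

__all__ = [
    "ChemistrySpec",
    "ReadPair",
    "HitRecord",
    "ScanStats",
    "PairStream",
    "parse_pairs",
    "scan_read",
    "scan_library",
    "write_hits",
]


@dataclass(frozen=True)
class ChemistrySpec:
    """Barcode/UMI layout of read 1. 10x 3' v3 is 16+12, v2 is 16+10."""

    barcode_len: int = 16
    umi_len: int = 12

    def __post_init__(self) -> None:
        if self.barcode_len < 1 or self.umi_len < 1:
            raise ValueError("barcode and UMI lengths must be >= 1")

    @classmethod
    def from_string(cls, text: str) -> "ChemistrySpec":
        text = text.strip().lower()
        if text == "v3":
            return cls(16, 12)
        if text == "v2":
            return cls(16, 10)
        if text.startswith("custom:"):
            try:
                bc, umi = text[len("custom:") :].split(",")
                return cls(int(bc), int(umi))
            except ValueError as exc:
                raise ValueError(
                    f"cannot parse chemistry {text!r}; expected custom:<bc>,<umi>"
                ) from exc
        raise ValueError(f"unknown chemistry {text!r}; use v3, v2 or custom:<bc>,<umi>")


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    barcode_raw: str
    umi: str
    cdna: str


@dataclass(frozen=True)
class HitRecord:
    read_id: str
    barcode_raw: str
    umi: str
    junction: str
    position: int  # 0-based offset of the k-mer within the cDNA read
    strand: str


@dataclass
class ScanStats:
    reads_processed: int = 0
    reads_with_hit: dict[str, int] = field(default_factory=dict)
    reads_multi_junction: int = 0
    reads_skipped_malformed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def _strip_mate_suffix(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


class PairStream:
    """Iterator over synchronized mate pairs with a malformed-read tally.

    Mates are paired by file order; the stripped read ids are verified at
    every record and a mismatch raises immediately (desynchronized files
    corrupt barcode assignment silently otherwise). R1 records shorter than
    barcode + UMI are counted in ``malformed`` and skipped.
    """

    def __init__(self, r1_path: str | Path, r2_path: str | Path, chem: ChemistrySpec):
        self.r1_path = str(r1_path)
        self.r2_path = str(r2_path)
        self.chem = chem
        self.malformed = 0

    def __iter__(self) -> Iterator[ReadPair]:
        bc_len, umi_len = self.chem.barcode_len, self.chem.umi_len
        min_r1 = bc_len + umi_len
        record = 0
        with pysam.FastxFile(self.r1_path) as f1, pysam.FastxFile(self.r2_path) as f2:
            while True:
                r1 = next(f1, None)
                r2 = next(f2, None)
                if r1 is None and r2 is None:
                    return
                record += 1
                if r1 is None or r2 is None:
                    short = self.r1_path if r1 is None else self.r2_path
                    raise ValueError(
                        f"truncated FASTQ: {short} ends before record {record}"
                    )
                id1 = _strip_mate_suffix(r1.name)
                id2 = _strip_mate_suffix(r2.name)
                if id1 != id2:
                    raise ValueError(
                        f"read id mismatch at record {record}: {id1!r} vs {id2!r} "
                        "(desynchronized files?)"
                    )
                seq1 = r1.sequence.upper()
                if len(seq1) < min_r1:
                    self.malformed += 1
                    continue
                yield ReadPair(
                    read_id=id1,
                    barcode_raw=seq1[:bc_len],
                    umi=seq1[bc_len : bc_len + umi_len],
                    cdna=r2.sequence.upper(),
                )


def parse_pairs(
    r1_path: str | Path, r2_path: str | Path, chem: ChemistrySpec
) -> PairStream:
    """Open paired (gz) FASTQ files as a stream of ReadPair records."""
    return PairStream(r1_path, r2_path, chem)


def scan_read(cdna: str, kmers: KmerSet) -> list[tuple[str, int, str]]:
    """Every exact k-mer occurrence in a read, ordered by position.

    Equivalent by contract to the naive algorithm testing all
    ``len(cdna) - k + 1`` windows against the k-mer map; reads containing N
    in a window never match because probe k-mers contain no N.
    """
    k = kmers.k
    entries = kmers.entries
    hits: list[tuple[str, int, str]] = []
    for i in range(len(cdna) - k + 1):
        entry = entries.get(cdna[i : i + k])
        if entry is not None:
            hits.append((entry.junction, i, entry.strand))
    return hits


def scan_library(
    r1_path: str | Path,
    r2_path: str | Path,
    chem: ChemistrySpec,
    kmers: KmerSet,
) -> tuple[list[HitRecord], ScanStats]:
    """Scan a paired library; returns every hit plus per-junction tallies.

    A read increments ``reads_with_hit[j]`` at most once per junction j no
    matter how many of j's k-mers it contains; a read hitting two or more
    distinct junctions also increments ``reads_multi_junction``.
    """
    stats = ScanStats()
    records: list[HitRecord] = []
    stream = parse_pairs(r1_path, r2_path, chem)
    for pair in stream:
        stats.reads_processed += 1
        hits = scan_read(pair.cdna, kmers)
        if not hits:
            continue
        junctions = set()
        for junction, position, strand in hits:
            junctions.add(junction)
            records.append(
                HitRecord(
                    read_id=pair.read_id,
                    barcode_raw=pair.barcode_raw,
                    umi=pair.umi,
                    junction=junction,
                    position=position,
                    strand=strand,
                )
            )
        for junction in junctions:
            stats.reads_with_hit[junction] = stats.reads_with_hit.get(junction, 0) + 1
        if len(junctions) >= 2:
            stats.reads_multi_junction += 1
    stats.reads_skipped_malformed = stream.malformed
    return records, stats


def write_hits(records: list[HitRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("read_id\tbarcode\tumi\tjunction\tposition\tstrand\n")
        for r in records:
            fh.write(
                f"{r.read_id}\t{r.barcode_raw}\t{r.umi}\t{r.junction}\t"
                f"{r.position}\t{r.strand}\n"
            )
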