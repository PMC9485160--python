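"""Spliced-transcript models and junction-spanning k-mer probe design.

Exon skipping removes an internal exon from the mature mRNA, creating a
splice junction between two non-adjacent exons. A length-k subsequence of
the spliced sequence that crosses an exon-exon boundary ("junction-spanning
k-mer") occurs in a sequencing read only if the read derives from that
splice form, so a set of such k-mers acts as an alignment-free probe panel
for targeted isoform detection. This module builds the panel: it loads a
transcript with its exon structure, constructs junction context sequences
for canonical (adjacent-exon) and skipping (non-adjacent) junctions, and
tiles every spanning k-window across each junction, optionally screening
out k-mers that would cross-react with the unmodified transcript or with
another junction's context.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "Exon",
    "TranscriptModel",
    "JunctionSpec",
    "KmerEntry",
    "KmerSet",
    "reverse_complement",
    "load_transcript",
    "junction_sequence",
    "design_kmers",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Exon:
    """One exon segment in transcript (mRNA) coordinates, 1-based inclusive."""

    index: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript sequence plus its ordered, covering exon segments.

    Exons are contiguous and covering: exon 1 starts at position 1, each
    exon starts where the previous one ended + 1, and the last exon ends at
    the sequence length. Coordinates are transcript (mRNA) coordinates —
    junction probes are designed from the spliced sequence, not the genome.
    """

    transcript_id: str
    sequence: str
    exons: tuple[Exon, ...]

    def __post_init__(self) -> None:
        for pos, base in enumerate(self.sequence, start=1):
            if base not in _VALID_BASES:
                raise ValueError(
                    f"invalid character {base!r} at position {pos} in "
                    f"transcript {self.transcript_id}"
                )
        if not self.exons:
            raise ValueError("transcript model requires at least one exon")
        indices = [e.index for e in self.exons]
        if indices != sorted(indices) or len(set(indices)) != len(indices):
            raise ValueError("exon indices must be strictly increasing")
        prev: Exon | None = None
        for exon in self.exons:
            if exon.length < 1:
                raise ValueError(f"exon {exon.index} has length < 1")
            if prev is None:
                if exon.start != 1:
                    raise ValueError(
                        f"exon {exon.index} must start at 1, starts at {exon.start}"
                    )
            elif exon.start != prev.end + 1:
                kind = "gap" if exon.start > prev.end + 1 else "overlap"
                raise ValueError(
                    f"{kind} between exon {prev.index} and exon {exon.index}"
                )
            prev = exon
        assert prev is not None
        if prev.end != len(self.sequence):
            raise ValueError(
                f"exon {prev.index} ends at {prev.end} but sequence length is "
                f"{len(self.sequence)}"
            )

    def exon(self, index: int) -> Exon:
        for e in self.exons:
            if e.index == index:
                return e
        raise ValueError(f"exon {index} not in model")

    def exon_sequence(self, index: int) -> str:
        e = self.exon(index)
        return self.sequence[e.start - 1 : e.end]


@dataclass(frozen=True)
class JunctionSpec:
    """A splice junction between two exons of a transcript model.

    ``right_exon == left_exon + 1`` is a canonical junction of the unmodified
    transcript; ``right_exon > left_exon + 1`` is a skipping junction in
    which every intervening exon is absent.
    """

    left_exon: int
    right_exon: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.right_exon <= self.left_exon:
            raise ValueError(
                f"right exon ({self.right_exon}) must exceed left exon "
                f"({self.left_exon})"
            )
        if not self.label:
            object.__setattr__(
                self, "label", f"e{self.left_exon}-e{self.right_exon}"
            )

    @property
    def is_skipping(self) -> bool:
        return self.right_exon > self.left_exon + 1


@dataclass(frozen=True)
class KmerEntry:
    junction: str
    offset: int  # junction point offset within the k-mer, sense orientation
    strand: Literal["sense", "antisense"]


@dataclass
class KmerSet:
    """Junction-spanning k-mers mapped to junction identity, offset, strand.

    ``entries`` maps each k-mer string to exactly one junction; ``dropped``
    records candidates removed by cross-reactivity screening together with
    the reason, so the screening outcome is auditable.
    """

    k: int
    min_overhang: int
    entries: dict[str, KmerEntry] = field(default_factory=dict)
    dropped: list[tuple[str, str, str]] = field(default_factory=list)  # kmer, junction, reason

    def junctions(self) -> list[str]:
        seen: dict[str, None] = {}
        for entry in self.entries.values():
            seen.setdefault(entry.junction, None)
        return list(seen)

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("kmer\tjunction\toffset\tstrand\n")
            for kmer, e in sorted(self.entries.items()):
                fh.write(f"{kmer}\t{e.junction}\t{e.offset}\t{e.strand}\n")
        if sidecar is not None:
            meta = {
                "k": self.k,
                "min_overhang": self.min_overhang,
                "n_entries": len(self.entries),
                "dropped": [
                    {"kmer": k, "junction": j, "reason": r}
                    for k, j, r in self.dropped
                ],
            }
            Path(sidecar).write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, sidecar: str | Path | None = None) -> "KmerSet":
        path = Path(path)
        entries: dict[str, KmerEntry] = {}
        with path.open() as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:4] != ["kmer", "junction", "offset", "strand"]:
                raise ValueError(f"unexpected k-mer table header in {path}")
            for line in fh:
                if not line.strip():
                    continue
                kmer, junction, offset, strand = line.rstrip("\n").split("\t")[:4]
                if strand not in ("sense", "antisense"):
                    raise ValueError(f"bad strand {strand!r} in {path}")
                entries[kmer] = KmerEntry(junction, int(offset), strand)  # type: ignore[arg-type]
        if not entries:
            raise ValueError(f"empty k-mer table {path}")
        lengths = {len(k) for k in entries}
        if len(lengths) != 1:
            raise ValueError("k-mer table mixes lengths")
        k = lengths.pop()
        min_overhang = 1
        if sidecar is not None and Path(sidecar).exists():
            meta = json.loads(Path(sidecar).read_text())
            k = int(meta.get("k", k))
            min_overhang = int(meta.get("min_overhang", min_overhang))
        return cls(k=k, min_overhang=min_overhang, entries=entries)


def _normalize_sequence(raw: str, transcript_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    for pos, base in enumerate(seq, start=1):
        if base not in _VALID_BASES:
            raise ValueError(
                f"invalid character {raw[pos - 1]!r} at position {pos} in "
                f"transcript {transcript_id}"
            )
    return seq


def load_transcript(fasta_path: str | Path, exon_table_path: str | Path) -> TranscriptModel:
    """Load a single-record FASTA and a TSV exon table into a model.

    The exon table has header ``exon_index<TAB>start<TAB>end`` with 1-based
    inclusive transcript coordinates. The sequence is upper-cased and RNA U
    is converted to DNA T.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"expected exactly one FASTA record in {fasta_path}, found {len(records)}"
        )
    record = records[0]
    sequence = _normalize_sequence(str(record.seq), record.id)

    exons: list[Exon] = []
    with Path(exon_table_path).open() as fh:
        header = [c.strip() for c in fh.readline().rstrip("\n").split("\t")]
        required = ["exon_index", "start", "end"]
        if header[: len(required)] != required:
            raise ValueError(
                f"exon table {exon_table_path} must start with columns "
                f"{required}, found {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                idx, start, end = int(parts[0]), int(parts[1]), int(parts[2])
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"malformed exon table line {lineno} in {exon_table_path}"
                ) from exc
            exons.append(Exon(idx, start, end))
    if not exons:
        raise ValueError(f"exon table {exon_table_path} contains no exons")
    return TranscriptModel(record.id, sequence, tuple(exons))


def junction_sequence(model: TranscriptModel, spec: JunctionSpec, flank: int) -> str:
    """Junction context: the last ``flank`` bases of the left exon followed by
    the first ``flank`` bases of the right exon (truncated at exon ends).

    For a skipping junction the intervening exon sequence is absent, so the
    result is a sequence that exists only in the skipped isoform.
    """
    if flank < 1:
        raise ValueError(f"flank must be >= 1, got {flank}")
    left = model.exon_sequence(spec.left_exon)
    right = model.exon_sequence(spec.right_exon)
    return left[-min(flank, len(left)) :] + right[: min(flank, len(right))]


def _candidate_windows(
    jseq: str, junction_point: int, k: int, min_overhang: int
) -> list[tuple[str, int]]:
    """All k-windows of a junction context whose junction point lies at least
    min_overhang bases from both window ends. Returns (kmer, offset) pairs,
    offset being the junction point position within the window."""
    out: list[tuple[str, int]] = []
    for start in range(0, len(jseq) - k + 1):
        offset = junction_point - start
        if min_overhang <= offset <= k - min_overhang:
            out.append((jseq[start : start + k], offset))
    return out


def design_kmers(
    model: TranscriptModel,
    specs: Sequence[JunctionSpec],
    k: int = 25,
    min_overhang: int = 1,
    strand_mode: Literal["sense", "both"] = "both",
    screen: bool = True,
) -> KmerSet:
    """Tile junction-spanning k-mers for each junction spec.

    Before screening there are exactly ``k - 2*min_overhang + 1`` candidate
    windows per junction per strand (fewer only if a flanking exon is shorter
    than ``k - min_overhang``). With ``screen`` enabled, a candidate for a
    skipping junction that also occurs in the full unmodified transcript (on
    either strand) would produce false skip calls and is dropped, as is any
    candidate occurring in another spec's junction context. Candidates
    containing N are never emitted. A k-mer string is always mapped to at
    most one junction; duplicates across junctions are dropped.
    """
    if k < 2 * min_overhang:
        raise ValueError(
            f"k ({k}) must be at least 2*min_overhang ({2 * min_overhang})"
        )
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    for spec in specs:
        model.exon(spec.left_exon)
        model.exon(spec.right_exon)

    flank = k - min_overhang
    contexts = {spec.label: junction_sequence(model, spec, flank) for spec in specs}
    junction_points = {
        spec.label: min(flank, model.exon(spec.left_exon).length) for spec in specs
    }

    kset = KmerSet(k=k, min_overhang=min_overhang)
    transcript_fwd = model.sequence
    transcript_rev = reverse_complement(model.sequence)
    # first pass: gather candidates per junction, per strand
    candidates: list[tuple[str, KmerEntry]] = []
    for spec in specs:
        jseq = contexts[spec.label]
        for kmer, offset in _candidate_windows(
            jseq, junction_points[spec.label], k, min_overhang
        ):
            if "N" in kmer:
                continue
            candidates.append((kmer, KmerEntry(spec.label, offset, "sense")))
            if strand_mode == "both":
                candidates.append(
                    (reverse_complement(kmer), KmerEntry(spec.label, offset, "antisense"))
                )

    # cross-junction duplicates violate the one-junction-per-kmer invariant
    owners: dict[str, set[str]] = {}
    for kmer, entry in candidates:
        owners.setdefault(kmer, set()).add(entry.junction)
    ambiguous = {kmer for kmer, juncs in owners.items() if len(juncs) > 1}

    spec_by_label = {spec.label: spec for spec in specs}
    for kmer, entry in candidates:
        if kmer in ambiguous:
            kset.dropped.append((kmer, entry.junction, "ambiguous across junctions"))
            continue
        if screen:
            spec = spec_by_label[entry.junction]
            if spec.is_skipping and (kmer in transcript_fwd or kmer in transcript_rev):
                kset.dropped.append(
                    (kmer, entry.junction, "matches unmodified transcript")
                )
                continue
            hit_other = next(
                (
                    other
                    for other, ctx in contexts.items()
                    if other != entry.junction and kmer in ctx
                ),
                None,
            )
            if hit_other is not None:
                kset.dropped.append(
                    (kmer, entry.junction, f"matches junction {hit_other}")
                )
                continue
        kset.entries[kmer] = entry

    for spec in specs:
        if not any(e.junction == spec.label for e in kset.entries.values()):
            raise ValueError(
                f"no k-mers survive screening for junction {spec.label}"
            )
    return kset


def parse_junction_label(label: str) -> JunctionSpec:
    """Parse a label like ``e22-e24`` into a JunctionSpec."""
    m = re.fullmatch(r"e(\d+)-e(\d+)", label)
    if not m:
        raise ValueError(f"cannot parse junction label {label!r}")
    return JunctionSpec(int(m.group(1)), int(m.group(2)), label)
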