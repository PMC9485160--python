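"""Barcode correction, PCR-duplicate collapse and per-cell-type skip summary.

Multiple reads carrying the same (cell barcode, UMI, junction) derive from
one original molecule, so deduplication collapses them to a single molecule
record — the unit of quantification. Molecules at a skipping junction
(non-adjacent exon pair) evidence the skipped isoform; molecules at a
canonical junction evidence the unmodified transcript. A nucleus is
"positive" for a junction when it carries at least one unique molecule of
it, and percentages are taken over all annotated nuclei in each
(condition, cell type) stratum, zero-count nuclei included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exon_model import JunctionSpec
from .read_scan import HitRecord

__all__ = [
    "BarcodeWhitelist",
    "DedupStats",
    "correct_barcode",
    "dedup",
    "classify_molecules",
    "read_annotations",
    "per_cluster_summary",
    "condition_ratio",
]

_BASES = "ACGT"


class BarcodeWhitelist:
    """A set of valid cell barcodes of uniform length."""

    def __init__(self, barcodes: Iterable[str]):
        self._set = frozenset(barcodes)
        if not self._set:
            raise ValueError("whitelist is empty")
        lengths = {len(b) for b in self._set}
        if len(lengths) != 1:
            raise ValueError("whitelist barcodes are not of uniform length")
        self.barcode_len = lengths.pop()

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._set

    def __len__(self) -> int:
        return len(self._set)

    def __iter__(self):
        return iter(self._set)

    @classmethod
    def from_file(cls, path: str | Path) -> "BarcodeWhitelist":
        with Path(path).open() as fh:
            return cls(line.strip() for line in fh if line.strip())


def _hamming1_neighbours(seq: str) -> Iterable[str]:
    for i, orig in enumerate(seq):
        for base in _BASES:
            if base != orig:
                yield seq[:i] + base + seq[i + 1 :]


def correct_barcode(
    raw: str, whitelist: BarcodeWhitelist, max_hamming: int = 1
) -> str | None:
    """Correct a raw barcode against a whitelist.

    Exact members return themselves; otherwise a unique whitelist entry
    within ``max_hamming`` substitutions is returned, and ambiguity (two or
    more candidates) or no candidate returns None — the read is then
    excluded from quantification rather than guessed.
    """
    if len(raw) != whitelist.barcode_len:
        raise ValueError(
            f"barcode length {len(raw)} does not match whitelist length "
            f"{whitelist.barcode_len}"
        )
    if raw in whitelist:
        return raw
    if max_hamming == 1:
        candidates = [n for n in _hamming1_neighbours(raw) if n in whitelist]
    else:
        candidates = [
            wl
            for wl in whitelist
            if sum(a != b for a, b in zip(raw, wl)) <= max_hamming
        ]
    return candidates[0] if len(candidates) == 1 else None


@dataclass
class DedupStats:
    reads_in: int = 0
    molecules_out: int = 0
    reads_discarded_barcode: int = 0
    umis_merged: int = 0


def _directional_umi_collapse(
    support: dict[str, int],
) -> dict[str, str]:
    """Map each UMI to its collapse representative within one (barcode,
    junction) group: UMIs are processed by descending support (ties broken
    lexicographically) and each merges into the first already-kept UMI at
    Hamming distance 1, absorbing likely amplification/sequencing errors of
    a higher-support UMI."""
    kept: list[str] = []
    mapping: dict[str, str] = {}
    for umi in sorted(support, key=lambda u: (-support[u], u)):
        target = next(
            (
                rep
                for rep in kept
                if sum(a != b for a, b in zip(umi, rep)) == 1
            ),
            None,
        )
        if target is None:
            kept.append(umi)
            mapping[umi] = umi
        else:
            mapping[umi] = target
    return mapping


def dedup(
    hits: Sequence[HitRecord],
    whitelist: BarcodeWhitelist | None = None,
    umi_collapse: str = "exact",
    max_hamming: int = 1,
) -> tuple[pd.DataFrame, DedupStats]:
    """Collapse hit records to unique molecules.

    Returns a molecule table with columns ``barcode, umi, junction, support``
    (support = number of reads collapsed into the molecule). With a
    whitelist, barcodes are corrected first and uncorrectable reads
    discarded; with ``umi_collapse="hamming1"`` near-identical UMIs within a
    (barcode, junction) group are merged directionally.

    A read hitting several k-mers of the same junction contributes a single
    read to that molecule's support (the hit table is de-duplicated on
    (read_id, barcode, umi, junction) first).
    """
    if umi_collapse not in ("exact", "hamming1"):
        raise ValueError(f"unknown umi_collapse mode {umi_collapse!r}")
    stats = DedupStats()

    seen_reads: set[tuple[str, str, str, str]] = set()
    rows: list[tuple[str, str, str]] = []
    read_ids_in: set[tuple[str, str, str]] = set()
    for h in hits:
        read_ids_in.add((h.read_id, h.barcode_raw, h.umi))
        key = (h.read_id, h.barcode_raw, h.umi, h.junction)
        if key in seen_reads:
            continue
        seen_reads.add(key)
        barcode = h.barcode_raw
        if whitelist is not None:
            corrected = correct_barcode(barcode, whitelist, max_hamming)
            if corrected is None:
                stats.reads_discarded_barcode += 1
                continue
            barcode = corrected
        rows.append((barcode, h.umi, h.junction))
    stats.reads_in = len(read_ids_in)

    if not rows:
        table = pd.DataFrame(columns=["barcode", "umi", "junction", "support"])
        return table, stats

    df = pd.DataFrame(rows, columns=["barcode", "umi", "junction"])
    if umi_collapse == "hamming1":
        merged_parts = []
        for (_, _), group in df.groupby(["barcode", "junction"], sort=False):
            support = group["umi"].value_counts().to_dict()
            mapping = _directional_umi_collapse(support)
            stats.umis_merged += sum(1 for u, rep in mapping.items() if u != rep)
            part = group.copy()
            part["umi"] = part["umi"].map(mapping)
            merged_parts.append(part)
        df = pd.concat(merged_parts, ignore_index=True)

    table = (
        df.groupby(["barcode", "umi", "junction"], sort=True)
        .size()
        .rename("support")
        .reset_index()
    )
    stats.molecules_out = len(table)
    return table, stats


def classify_molecules(
    molecules: pd.DataFrame, specs: Sequence[JunctionSpec]
) -> pd.DataFrame:
    """Per-barcode molecule counts by class: unskipped, skipped, ambiguous.

    Molecules at skipping junctions count as skipped, at canonical junctions
    as unskipped. A single (barcode, UMI) observed at both a skipping and a
    canonical junction is biologically impossible for mutually exclusive
    splice forms; it is counted once as ambiguous and excluded from both
    classes.
    """
    skip_by_label = {s.label: s.is_skipping for s in specs}
    unknown = set(molecules["junction"]) - set(skip_by_label)
    if unknown:
        raise ValueError(f"unknown junction label(s): {sorted(unknown)}")

    if molecules.empty:
        return pd.DataFrame(columns=["barcode", "unskipped", "skipped", "ambiguous"])

    df = molecules.copy()
    df["is_skipping"] = df["junction"].map(skip_by_label)
    out_rows = []
    for barcode, per_bc in df.groupby("barcode", sort=True):
        unskipped = skipped = ambiguous = 0
        for (_, _umi), per_umi in per_bc.groupby(["barcode", "umi"], sort=False):
            classes = set(per_umi["is_skipping"])
            if classes == {True, False}:
                ambiguous += 1
            elif classes == {True}:
                skipped += len(per_umi)
            else:
                unskipped += len(per_umi)
        out_rows.append((barcode, unskipped, skipped, ambiguous))
    return pd.DataFrame(
        out_rows, columns=["barcode", "unskipped", "skipped", "ambiguous"]
    )


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a nucleus annotation table: barcode, sample, condition, cluster."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = ["barcode", "sample", "condition", "cluster"]
    missing = [c for c in required if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation table {path} is missing columns {missing}")
    dup = ann.duplicated(subset=["barcode", "sample"])
    if dup.any():
        raise ValueError(
            f"annotation table {path} has duplicate (barcode, sample) rows"
        )
    return ann


def per_cluster_summary(
    molecules: pd.DataFrame,
    annotations: pd.DataFrame,
    restrict: Iterable[str] | None = None,
    junctions: Sequence[str] | None = None,
    drop_ambiguous_pairs: bool = True,
    specs: Sequence[JunctionSpec] | None = None,
) -> tuple[pd.DataFrame, set[str]]:
    """Per (condition, cluster, junction) positivity summary.

    A nucleus is positive for junction j iff it carries >= 1 unique molecule
    of j. Denominators are *all* annotated nuclei in the stratum, including
    nuclei with zero junction molecules; ``restrict`` limits the clusters
    considered (e.g. to myonuclei). Molecules whose (barcode, UMI) appears
    at both a skipping and a canonical junction are excluded when
    ``drop_ambiguous_pairs`` and ``specs`` are given. Returns the summary
    table plus the set of hit barcodes absent from the annotation.
    """
    ann = annotations
    if restrict is not None:
        restrict = set(restrict)
        ann = ann[ann["cluster"].isin(restrict)]

    mols = molecules
    if drop_ambiguous_pairs and specs is not None and not mols.empty:
        skip_by_label = {s.label: s.is_skipping for s in specs}
        flagged = mols.assign(is_skipping=mols["junction"].map(skip_by_label))
        n_classes = flagged.groupby(["barcode", "umi"])["is_skipping"].nunique()
        bad = set(n_classes[n_classes > 1].index)
        if bad:
            keys = list(zip(mols["barcode"], mols["umi"]))
            mols = mols[[k not in bad for k in keys]]

    annotated_barcodes = set(ann["barcode"])
    unmatched = set(mols["barcode"]) - set(annotations["barcode"])
    mols = mols[mols["barcode"].isin(annotated_barcodes)]

    if junctions is None:
        junctions = sorted(set(molecules["junction"]))

    bc_meta = ann.set_index("barcode")[["condition", "cluster"]]
    strata = ann.groupby(["condition", "cluster"]).size()

    rows = []
    for (condition, cluster), n_nuclei in strata.items():
        stratum_barcodes = set(
            ann[(ann["condition"] == condition) & (ann["cluster"] == cluster)][
                "barcode"
            ]
        )
        for junction in junctions:
            jm = mols[
                (mols["junction"] == junction)
                & (mols["barcode"].isin(stratum_barcodes))
            ]
            n_pos = jm["barcode"].nunique()
            pct = round(100.0 * n_pos / n_nuclei, 2) if n_nuclei > 0 else np.nan
            rows.append(
                (condition, cluster, junction, int(n_nuclei), n_pos, pct, len(jm))
            )
    summary = pd.DataFrame(
        rows,
        columns=[
            "condition",
            "cluster",
            "junction",
            "n_nuclei",
            "n_positive",
            "percent_positive",
            "n_molecules",
        ],
    )
    return summary, unmatched


def condition_ratio(
    summary: pd.DataFrame,
    junction: str,
    cond_a: str,
    cond_b: str,
    cluster: str | None = None,
) -> tuple[float, bool]:
    """Ratio of percent-positive between two conditions for one junction.

    Returns ``(ratio, is_infinite)``; a zero denominator is reported as
    infinite with the flag set rather than raising.
    """
    sel = summary[summary["junction"] == junction]
    if cluster is not None:
        sel = sel[sel["cluster"] == cluster]

    def _stratum(cond: str) -> float:
        rows = sel[sel["condition"] == cond]
        rows = rows[rows["n_nuclei"] > 0]
        if rows.empty:
            raise ValueError(
                f"no stratum with nuclei for condition {cond!r}, junction {junction!r}"
            )
        # pool across remaining clusters if not restricted to one
        n = rows["n_nuclei"].sum()
        pos = rows["n_positive"].sum()
        return 100.0 * pos / n

    pa, pb = _stratum(cond_a), _stratum(cond_b)
    if pb == 0.0:
        return float("inf"), True
    return pa / pb, False
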