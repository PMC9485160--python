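"""Synthetic 10x-style libraries, frequency cohorts and count matrices.

Every analysis step in this package is testable without downloading any
sequencing data: this module generates paired gzip FASTQ libraries that
mimic Chromium 3' v3 chemistry (16 bp cell barcode + 12 bp UMI in R1, a
cDNA fragment in R2), nucleus annotations, per-sample cell-type frequency
cohorts, and sparse count matrices — each with explicit ground truth so
recovery can be asserted rather than eyeballed.

The read simulator draws, per cell, a Poisson number of molecules; a
configurable fraction of molecules overlap the junction region of interest
and each such molecule is skipped with a per-condition probability
(skipped molecules use the exon-skipped transcript sequence, so the
skipping junction exists in their fragments and nowhere else). Fragments
place the junction point uniformly within the read, PCR duplicates
replicate reads with fresh per-base substitution errors, and everything is
fully determined by the seed.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_stats import FrequencyTable
from .exon_model import Exon, JunctionSpec, TranscriptModel
from .qc_matrix import CountMatrix
from .read_scan import ChemistrySpec
from scipy import sparse

__all__ = [
    "SimConfig",
    "SimTruth",
    "make_transcript",
    "default_junction_specs",
    "simulate_library",
    "simulate_frequency_cohort",
    "simulate_matrix",
]

_BASES = np.array(list("ACGT"))


def make_transcript(
    seed: int, n_exons: int = 6, exon_length: int = 120, transcript_id: str = "SYNTX1"
) -> TranscriptModel:
    """A random synthetic transcript with equal-length contiguous exons.

    The first and last base of each exon are forced to cycle through
    A/C/G/T by exon index, so neighbouring exons never share a boundary
    base. This keeps even minimal-overhang junction probes
    junction-specific: a k-mer with a single base of the downstream exon
    would otherwise be ambiguous between two junctions whenever two right
    exons happened to start with the same base.
    """
    rng = np.random.default_rng(seed)
    bases = rng.choice(_BASES, size=n_exons * exon_length)
    for i in range(n_exons):
        bases[i * exon_length] = _BASES[i % 4]
        bases[(i + 1) * exon_length - 1] = _BASES[i % 4]
    seq = "".join(bases)
    exons = tuple(
        Exon(i + 1, i * exon_length + 1, (i + 1) * exon_length)
        for i in range(n_exons)
    )
    return TranscriptModel(transcript_id, seq, exons)


def default_junction_specs() -> tuple[list[JunctionSpec], JunctionSpec]:
    """Canonical junctions flanking the skippable exon plus the skip spec.

    On the 6-exon synthetic transcript, exon 3 plays the role of the
    skippable exon: canonical junctions e2-e3 and e3-e4, skipping junction
    e2-e4.
    """
    canonical = [JunctionSpec(2, 3), JunctionSpec(3, 4)]
    skip = JunctionSpec(2, 4)
    return canonical, skip


@dataclass
class SimConfig:
    """Study conditions for a synthetic library.

    Defaults model an exon-skipping dosing experiment: an untreated disease
    condition with a low per-molecule skip rate, a treated condition with a
    10-fold higher rate, and a wild-type condition with none.
    """

    seed: int = 0
    n_cells: Mapping[str, int] = field(
        default_factory=lambda: {"WT": 700, "mdx": 700, "mdx_e23AON": 700}
    )
    skip_prob: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 0.0, "mdx": 0.02, "mdx_e23AON": 0.2}
    )
    mean_molecules: float = 8.0
    junction_overlap_frac: float = 0.25
    read_len_r2: int = 90
    chemistry: ChemistrySpec = field(default_factory=ChemistrySpec)
    dup_geom_p: float = 0.5  # reads per molecule ~ Geometric(p); p=1 disables
    error_rate: float = 0.005  # per-base substitution probability
    n_samples_per_condition: int = 1
    cluster: str = "myonuclei"
    transcript_seed: int = 7_001
    n_exons: int = 6
    exon_length: int = 120
    whitelist_size: int = 4096

    def __post_init__(self) -> None:
        if set(self.n_cells) != set(self.skip_prob):
            raise ValueError("n_cells and skip_prob must define the same conditions")
        for cond, p in self.skip_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"skip_prob[{cond!r}] must be in [0, 1]")
        if not 0.0 <= self.junction_overlap_frac <= 1.0:
            raise ValueError("junction_overlap_frac must be in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0.0 < self.dup_geom_p <= 1.0:
            raise ValueError("dup_geom_p must be in (0, 1]")
        if self.read_len_r2 < 2:
            raise ValueError("read_len_r2 must be >= 2")
        if self.read_len_r2 > self.exon_length:
            raise ValueError(
                "read_len_r2 must not exceed exon_length (fragments must fit "
                "within flanking exons)"
            )
        if self.mean_molecules <= 0:
            raise ValueError("mean_molecules must be positive")
        if self.n_samples_per_condition < 1:
            raise ValueError("n_samples_per_condition must be >= 1")
        if self.whitelist_size < sum(self.n_cells.values()):
            raise ValueError("whitelist_size must be >= total number of cells")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "chemistry" in raw and isinstance(raw["chemistry"], str):
            raw["chemistry"] = ChemistrySpec.from_string(raw["chemistry"])
        return cls(**raw)


@dataclass
class SimTruth:
    """Ground truth of a simulated library.

    ``per_cell`` has one row per cell with its barcode, condition, sample
    and true molecule counts per junction label plus skipped/unskipped
    totals; ``per_condition_skip_fraction`` is skipped/(skipped+unskipped)
    over junction-overlapping molecules, exactly; ``read_to_molecule`` maps
    every read id to its source molecule id.
    """

    per_cell: pd.DataFrame
    per_condition_skip_fraction: dict[str, float]
    read_to_molecule: dict[str, str]
    junction_labels: list[str]
    skip_label: str

    def percent_positive(self, junction: str, condition: str) -> float:
        """Percent of cells in a condition with >= 1 molecule of a junction."""
        sub = self.per_cell[self.per_cell["condition"] == condition]
        if sub.empty:
            raise ValueError(f"no cells for condition {condition!r}")
        return round(100.0 * float((sub[junction] > 0).mean()), 2)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_condition_skip_fraction": self.per_condition_skip_fraction,
            "junction_labels": self.junction_labels,
            "skip_label": self.skip_label,
            "n_cells": int(len(self.per_cell)),
            "n_reads": len(self.read_to_molecule),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _random_kmers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """n distinct random DNA strings of the given length."""
    out: set[str] = set()
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), length))
        for row in draw:
            out.add("".join(_BASES[row]))
            if len(out) == n:
                break
    return sorted(out)


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        current = arr[i].decode()
        choices = [b for b in "ACGT" if b != current]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode()


def _skipped_sequence(
    model: TranscriptModel, skip: JunctionSpec
) -> tuple[str, int]:
    """Exon-skipped transcript sequence and the junction position within it
    (number of bases before the junction point)."""
    left_end = model.exon(skip.left_exon).end
    right_start = model.exon(skip.right_exon).start
    seq = model.sequence[:left_end] + model.sequence[right_start - 1 :]
    return seq, left_end


def simulate_library(
    cfg: SimConfig, out_dir: str | Path
) -> tuple[Path, Path, Path, SimTruth]:
    """Write R1/R2 fastq.gz, an annotation TSV, a whitelist and truth files.

    Returns (r1_path, r2_path, annotation_path, truth). Output is fully
    determined by ``cfg.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    model = make_transcript(cfg.transcript_seed, cfg.n_exons, cfg.exon_length)
    canonical, skip = default_junction_specs()
    junction_labels = [s.label for s in canonical] + [skip.label]
    skipped_seq, skip_jpos = _skipped_sequence(model, skip)
    canonical_jpos = {s.label: model.exon(s.left_exon).end for s in canonical}

    whitelist = _random_kmers(rng, cfg.whitelist_size, cfg.chemistry.barcode_len)
    total_cells = sum(cfg.n_cells.values())
    cell_barcodes = [
        whitelist[i]
        for i in rng.choice(len(whitelist), size=total_cells, replace=False)
    ]

    read_len = cfg.read_len_r2
    r1_path = out_dir / "R1.fastq.gz"
    r2_path = out_dir / "R2.fastq.gz"
    ann_path = out_dir / "annotations.tsv"
    qual1 = "I" * (cfg.chemistry.barcode_len + cfg.chemistry.umi_len)
    qual2 = "I" * read_len

    per_cell_rows = []
    read_to_molecule: dict[str, str] = {}
    skip_counts = {cond: [0, 0] for cond in cfg.n_cells}  # [skipped, unskipped]

    cell_idx = 0
    with gzip.open(r1_path, "wt") as f1, gzip.open(r2_path, "wt") as f2, ann_path.open(
        "w"
    ) as fa:
        fa.write("barcode\tsample\tcondition\tcluster\n")
        for cond in cfg.n_cells:
            for local_idx in range(cfg.n_cells[cond]):
                barcode = cell_barcodes[cell_idx]
                sample = f"{cond}_s{local_idx % cfg.n_samples_per_condition + 1}"
                fa.write(f"{barcode}\t{sample}\t{cond}\t{cfg.cluster}\n")

                n_mols = int(rng.poisson(cfg.mean_molecules))
                counts = {label: 0 for label in junction_labels}
                umis: set[str] = set()
                for mol_idx in range(n_mols):
                    while True:
                        umi = "".join(
                            _BASES[rng.integers(0, 4, size=cfg.chemistry.umi_len)]
                        )
                        if umi not in umis:
                            umis.add(umi)
                            break
                    mol_id = f"c{cell_idx}m{mol_idx}"
                    overlaps = rng.random() < cfg.junction_overlap_frac
                    if overlaps:
                        is_skipped = rng.random() < cfg.skip_prob[cond]
                        if is_skipped:
                            label = skip.label
                            src, jpos = skipped_seq, skip_jpos
                            skip_counts[cond][0] += 1
                        else:
                            label = canonical[int(rng.integers(len(canonical)))].label
                            src, jpos = model.sequence, canonical_jpos[label]
                            skip_counts[cond][1] += 1
                        counts[label] += 1
                        left = int(rng.integers(1, read_len))  # 1..read_len-1
                        start = jpos - left
                        fragment = src[start : start + read_len]
                    else:
                        exon = model.exons[int(rng.integers(len(model.exons)))]
                        offset = int(
                            rng.integers(0, exon.length - read_len + 1)
                        )
                        start = exon.start - 1 + offset
                        fragment = model.sequence[start : start + read_len]

                    n_reads = (
                        1
                        if cfg.dup_geom_p >= 1.0
                        else int(rng.geometric(cfg.dup_geom_p))
                    )
                    r1_seq = barcode + umi
                    for copy in range(n_reads):
                        read_id = f"{mol_id}d{copy}"
                        read_to_molecule[read_id] = mol_id
                        s1 = _mutate(rng, r1_seq, cfg.error_rate)
                        s2 = _mutate(rng, fragment, cfg.error_rate)
                        f1.write(f"@{read_id}\n{s1}\n+\n{qual1}\n")
                        f2.write(f"@{read_id}\n{s2}\n+\n{qual2}\n")

                per_cell_rows.append(
                    {
                        "barcode": barcode,
                        "sample": sample,
                        "condition": cond,
                        **counts,
                        "skipped": counts[skip.label],
                        "unskipped": sum(
                            counts[s.label] for s in canonical
                        ),
                    }
                )
                cell_idx += 1

    with (out_dir / "whitelist.txt").open("w") as fh:
        for bc in whitelist:
            fh.write(bc + "\n")
    # the reference the reads were simulated from, so probe design can run
    # directly on the simulated output
    (out_dir / "transcript.fa").write_text(
        f">{model.transcript_id}\n{model.sequence}\n"
    )
    (out_dir / "exons.tsv").write_text(
        "exon_index\tstart\tend\n"
        + "".join(f"{e.index}\t{e.start}\t{e.end}\n" for e in model.exons)
    )

    per_condition_skip_fraction = {
        cond: (s / (s + u) if (s + u) > 0 else 0.0)
        for cond, (s, u) in skip_counts.items()
    }
    truth = SimTruth(
        per_cell=pd.DataFrame(per_cell_rows),
        per_condition_skip_fraction=per_condition_skip_fraction,
        read_to_molecule=read_to_molecule,
        junction_labels=junction_labels,
        skip_label=skip.label,
    )
    truth.to_json(out_dir / "truth.json")
    truth.per_cell.to_csv(out_dir / "truth_per_cell.tsv", sep="\t", index=False)
    return r1_path, r2_path, ann_path, truth


def simulate_frequency_cohort(
    seed: int,
    n_per_condition: Mapping[str, int],
    dirichlet_alpha: Mapping[str, Sequence[float]],
    cell_types: Sequence[str],
    nuclei_per_sample: int | None = None,
) -> tuple[FrequencyTable, dict]:
    """Per-sample cell-type compositions drawn from per-condition Dirichlet
    distributions, as percentages.

    With ``nuclei_per_sample`` set, multinomial counts are drawn from each
    composition first (introducing realistic discreteness and possible
    ties); otherwise percentages are the Dirichlet draws themselves. Truth
    records the generating parameters.
    """
    rng = np.random.default_rng(seed)
    if set(n_per_condition) != set(dirichlet_alpha):
        raise ValueError("conditions of n_per_condition and dirichlet_alpha differ")
    rows = []
    conds = []
    samples = []
    for cond in n_per_condition:
        alpha = np.asarray(dirichlet_alpha[cond], dtype=float)
        if alpha.shape != (len(cell_types),):
            raise ValueError(
                f"alpha for {cond!r} must have one entry per cell type"
            )
        if (alpha <= 0).any():
            raise ValueError("Dirichlet parameters must be positive")
        for i in range(n_per_condition[cond]):
            comp = rng.dirichlet(alpha)
            if nuclei_per_sample is not None:
                counts = rng.multinomial(nuclei_per_sample, comp)
                comp = counts / counts.sum()
            rows.append(100.0 * comp)
            conds.append(cond)
            samples.append(f"{cond}_s{i + 1}")
    values = pd.DataFrame(rows, index=samples, columns=list(cell_types))
    # guard against float drift in the row-sum invariant
    values = values.div(values.sum(axis=1), axis=0) * 100.0
    ft = FrequencyTable(values, pd.Series(conds, index=samples))
    truth = {
        "dirichlet_alpha": {c: list(map(float, dirichlet_alpha[c])) for c in dirichlet_alpha},
        "n_per_condition": dict(n_per_condition),
        "cell_types": list(cell_types),
        "nuclei_per_sample": nuclei_per_sample,
        "seed": seed,
    }
    return ft, truth


def simulate_matrix(
    seed: int,
    n_genes: int = 300,
    n_barcodes: int = 40,
    n_below_threshold: int = 10,
    threshold: int = 200,
    n_mito_genes: int = 5,
    mito_count: int = 3,
) -> tuple[CountMatrix, dict]:
    """A sparse count matrix with planted QC truth.

    ``n_below_threshold`` barcodes are constructed with fewer than
    ``threshold`` non-mitochondrial genes detected, the rest with at least
    ``threshold``; every barcode additionally expresses all mitochondrial
    genes (named with the mt- prefix) so the mito filter is observable.
    """
    rng = np.random.default_rng(seed)
    if n_below_threshold > n_barcodes:
        raise ValueError("n_below_threshold exceeds n_barcodes")
    n_regular = n_genes - n_mito_genes
    if threshold > n_regular:
        raise ValueError("threshold exceeds the number of non-mito genes")
    gene_names = [f"mt-g{i + 1}" for i in range(n_mito_genes)] + [
        f"gene{i + 1:05d}" for i in range(n_regular)
    ]
    genes = pd.DataFrame(
        {"gene_id": [f"ENSSYN{i + 1:05d}" for i in range(n_genes)],
         "gene_name": gene_names}
    )
    barcodes = _random_kmers(rng, n_barcodes, 16)
    below = set(rng.choice(n_barcodes, size=n_below_threshold, replace=False).tolist())

    rows, cols, vals = [], [], []
    truth_detected = {}
    truth_umi = {}
    for j in range(n_barcodes):
        if j in below:
            d = int(rng.integers(max(1, threshold // 4), threshold))
        else:
            d = int(rng.integers(threshold, n_regular + 1))
        chosen = rng.choice(n_regular, size=d, replace=False)
        umi_total = 0
        for g in chosen:
            c = int(1 + rng.poisson(2))
            rows.append(n_mito_genes + int(g))
            cols.append(j)
            vals.append(c)
            umi_total += c
        for m in range(n_mito_genes):
            rows.append(m)
            cols.append(j)
            vals.append(mito_count)
        truth_detected[barcodes[j]] = d
        truth_umi[barcodes[j]] = umi_total  # non-mito UMI
    mat = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(n_genes, n_barcodes), dtype=np.int64
    ).tocsc()
    cm = CountMatrix(genes, barcodes, mat)
    truth = {
        "genes_detected_nonmito": truth_detected,
        "total_umi_nonmito": truth_umi,
        "below_threshold_barcodes": sorted(barcodes[j] for j in below),
        "mito_gene_names": gene_names[:n_mito_genes],
        "threshold": threshold,
        "seed": seed,
    }
    return cm, truth
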