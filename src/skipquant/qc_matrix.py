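"""Sparse count-matrix I/O, per-nucleus QC metrics and nuclei/gene filters.

Droplet pipelines emit a gene x barcode count matrix as a MatrixMarket
coordinate trio (matrix.mtx, features.tsv, barcodes.tsv, optionally
gzipped). QC here is deliberately minimal: genes detected and total UMI per
barcode, per-sample and cohort summaries, removal of mitochondrial genes by
name prefix, and removal of low-complexity nuclei below a strict threshold
(< 200 genes detected by default; < 200 UMI selectable, since both
phrasings of the filter are in circulation). Mitochondrial genes are
removed *before* thresholding, so nuclei whose counts are mostly
mitochondrial fall below the threshold and are dropped — the order is
recorded in the filter report.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "CountMatrix",
    "QCReport",
    "FilterReport",
    "read_mtx",
    "write_mtx",
    "qc_metrics",
    "filter_nuclei",
    "summarize_cohort",
]


@dataclass
class CountMatrix:
    """Genes x barcodes sparse integer count matrix with feature metadata."""

    genes: pd.DataFrame  # columns: gene_id, gene_name
    barcodes: list[str]
    matrix: sparse.csc_matrix  # shape (n_genes, n_barcodes)

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def _open_maybe_gz(path: Path) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return path.open()


def _find(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        candidate = dir_path / name
        if candidate.exists():
            return candidate
    raise FileNotFoundError(f"{stem}(.gz) not found in {dir_path}")


def read_mtx(dir_path: str | Path) -> CountMatrix:
    """Read a MatrixMarket coordinate trio directory (gz tolerant).

    Indices are 1-based per the format; out-of-range triplets raise with
    their line number, non-integer counts raise, and duplicate (gene,
    barcode) triplets are summed with a warning.
    """
    dir_path = Path(dir_path)
    mtx_path = _find(dir_path, "matrix.mtx")
    features_path = _find(dir_path, "features.tsv")
    barcodes_path = _find(dir_path, "barcodes.tsv")

    with _open_maybe_gz(features_path) as fh:
        feat_rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    genes = pd.DataFrame(
        [(r[0], r[1] if len(r) > 1 else r[0]) for r in feat_rows],
        columns=["gene_id", "gene_name"],
    )
    with _open_maybe_gz(barcodes_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]

    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    with _open_maybe_gz(mtx_path) as fh:
        header = fh.readline()
        if not header.startswith("%%MatrixMarket matrix coordinate"):
            raise ValueError(f"{mtx_path} is not a MatrixMarket coordinate file")
        lineno = 1
        dims: tuple[int, int, int] | None = None
        for line in fh:
            lineno += 1
            if line.startswith("%") or not line.strip():
                continue
            parts = line.split()
            if dims is None:
                if len(parts) != 3:
                    raise ValueError(f"{mtx_path}:{lineno}: malformed size line")
                dims = (int(parts[0]), int(parts[1]), int(parts[2]))
                if dims[0] != len(genes) or dims[1] != len(barcodes):
                    raise ValueError(
                        f"{mtx_path}: header declares {dims[0]}x{dims[1]} but "
                        f"features/barcodes files have {len(genes)}/{len(barcodes)}"
                    )
                continue
            if len(parts) != 3:
                raise ValueError(f"{mtx_path}:{lineno}: malformed triplet")
            i, j = int(parts[0]), int(parts[1])
            try:
                v = int(parts[2])
            except ValueError:
                raise ValueError(
                    f"{mtx_path}:{lineno}: non-integer count {parts[2]!r}"
                ) from None
            if not (1 <= i <= dims[0]):
                raise ValueError(
                    f"{mtx_path}:{lineno}: gene index {i} out of range 1..{dims[0]}"
                )
            if not (1 <= j <= dims[1]):
                raise ValueError(
                    f"{mtx_path}:{lineno}: barcode index {j} out of range 1..{dims[1]}"
                )
            rows.append(i - 1)
            cols.append(j - 1)
            vals.append(v)
    if dims is None:
        raise ValueError(f"{mtx_path}: missing size line")
    if len(vals) != dims[2]:
        raise ValueError(
            f"{mtx_path}: header declares {dims[2]} entries, found {len(vals)}"
        )
    coo = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(len(genes), len(barcodes)), dtype=np.int64
    )
    if len(vals) != len(set(zip(rows, cols))):
        warnings.warn(f"{mtx_path}: duplicate triplets summed", stacklevel=2)
    return CountMatrix(genes, barcodes, coo.tocsc())


def write_mtx(cm: CountMatrix, dir_path: str | Path) -> None:
    """Write the uncompressed MatrixMarket trio (integer general field)."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    coo = cm.matrix.tocoo()
    with (dir_path / "matrix.mtx").open("w") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{cm.shape[0]} {cm.shape[1]} {coo.nnz}\n")
        order = np.lexsort((coo.row, coo.col))
        for idx in order:
            fh.write(f"{coo.row[idx] + 1} {coo.col[idx] + 1} {coo.data[idx]}\n")
    cm.genes.to_csv(dir_path / "features.tsv", sep="\t", header=False, index=False)
    with (dir_path / "barcodes.tsv").open("w") as fh:
        for bc in cm.barcodes:
            fh.write(bc + "\n")


@dataclass
class QCReport:
    per_barcode: pd.DataFrame  # barcode, sample, genes_detected, total_umi
    per_sample: pd.DataFrame  # sample, n_barcodes, mean/median genes & umi
    cohort: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cohort": self.cohort,
            "per_sample": self.per_sample.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def qc_metrics(
    cm: CountMatrix, barcode_to_sample: Mapping[str, str] | None = None
) -> QCReport:
    """Genes detected and total UMI per barcode, with sample/cohort rollups.

    Per-sample and cohort averages are rounded to integers for reporting;
    medians are reported alongside because published summaries use either.
    """
    mat = cm.matrix
    genes_detected = np.asarray((mat > 0).sum(axis=0)).ravel()
    total_umi = np.asarray(mat.sum(axis=0)).ravel()
    per_barcode = pd.DataFrame(
        {
            "barcode": cm.barcodes,
            "sample": [
                (barcode_to_sample or {}).get(bc, "all") for bc in cm.barcodes
            ],
            "genes_detected": genes_detected.astype(int),
            "total_umi": total_umi.astype(int),
        }
    )
    per_sample = (
        per_barcode.groupby("sample")
        .agg(
            n_barcodes=("barcode", "size"),
            mean_genes=("genes_detected", "mean"),
            median_genes=("genes_detected", "median"),
            mean_umi=("total_umi", "mean"),
            median_umi=("total_umi", "median"),
        )
        .reset_index()
    )
    for col in ("mean_genes", "mean_umi"):
        per_sample[col] = per_sample[col].round().astype(int)
    n_samples = per_sample.shape[0]
    cohort = {
        "n_barcodes": len(cm.barcodes),
        "n_samples": n_samples,
        "mean_barcodes_per_sample": int(round(len(cm.barcodes) / n_samples))
        if n_samples
        else 0,
        "mean_genes": int(round(float(genes_detected.mean()))) if len(cm.barcodes) else 0,
        "median_genes": float(np.median(genes_detected)) if len(cm.barcodes) else 0.0,
        "mean_umi": int(round(float(total_umi.mean()))) if len(cm.barcodes) else 0,
        "median_umi": float(np.median(total_umi)) if len(cm.barcodes) else 0.0,
    }
    return QCReport(per_barcode, per_sample, cohort)


@dataclass
class FilterReport:
    steps: list[tuple[str, int]] = field(default_factory=list)  # (step, n removed)

    def removed(self, step: str) -> int:
        for name, n in self.steps:
            if name == step:
                return n
        raise KeyError(step)


def filter_nuclei(
    cm: CountMatrix,
    min_value: int = 200,
    metric: str = "genes",
    drop_mito: bool = True,
    mito_prefix: str = "mt-",
    exclude_barcodes: Iterable[str] | None = None,
) -> tuple[CountMatrix, FilterReport]:
    """Apply the nucleus QC filter: optional exclusion list, mitochondrial
    gene removal (case-insensitive name prefix), then a strict < threshold
    on genes detected or total UMI.

    Returns the filtered matrix and a report of how many genes/barcodes each
    step removed, in application order. An empty result is a warning, not an
    error.
    """
    if min_value < 0:
        raise ValueError("min_value must be >= 0")
    if metric not in ("genes", "umi"):
        raise ValueError(f"unknown metric {metric!r}")
    report = FilterReport()
    mat = cm.matrix
    genes = cm.genes
    barcodes = list(cm.barcodes)

    if exclude_barcodes is not None:
        excl = set(exclude_barcodes)
        keep = [i for i, bc in enumerate(barcodes) if bc not in excl]
        report.steps.append(("excluded_barcodes", len(barcodes) - len(keep)))
        mat = mat[:, keep]
        barcodes = [barcodes[i] for i in keep]

    if drop_mito:
        prefix = mito_prefix.lower()
        is_mito = genes["gene_name"].str.lower().str.startswith(prefix)
        report.steps.append(("mito_genes_removed", int(is_mito.sum())))
        mat = mat[~is_mito.to_numpy(), :]
        genes = genes[~is_mito].reset_index(drop=True)

    if metric == "genes":
        values = np.asarray((mat > 0).sum(axis=0)).ravel()
    else:
        values = np.asarray(mat.sum(axis=0)).ravel()
    keep_mask = values >= min_value
    report.steps.append(
        (f"low_{metric}_barcodes_removed", int((~keep_mask).sum()))
    )
    mat = mat[:, keep_mask]
    barcodes = [bc for bc, k in zip(barcodes, keep_mask) if k]
    if not barcodes:
        warnings.warn("all barcodes removed by filtering", stacklevel=2)

    return CountMatrix(genes, barcodes, mat.tocsc()), report


def summarize_cohort(
    nuclei_per_sample: Mapping[str, int],
    sample_groups: Mapping[str, str] | None = None,
) -> dict:
    """Dataset summary arithmetic: totals, mean nuclei per sample (rounded to
    integer, as reported), and per-group totals when groups are supplied."""
    if not nuclei_per_sample:
        raise ValueError("no samples supplied")
    total = int(sum(nuclei_per_sample.values()))
    n_samples = len(nuclei_per_sample)
    out = {
        "total_nuclei": total,
        "n_samples": n_samples,
        "mean_nuclei_per_sample": int(round(total / n_samples)),
    }
    if sample_groups is not None:
        groups: dict[str, int] = {}
        for sample, n in nuclei_per_sample.items():
            group = sample_groups.get(sample)
            if group is None:
                raise ValueError(f"sample {sample!r} has no group")
            groups[group] = groups.get(group, 0) + int(n)
        out["per_group_totals"] = groups
    return out
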