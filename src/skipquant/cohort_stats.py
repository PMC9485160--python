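"""Cell-type frequency tables and exact Mann-Whitney condition comparisons.

Cohorts here are small (a handful of animals per condition), so the
two-sample comparison of per-sample cell-type percentages uses the exact
Mann-Whitney U test: the null distribution of U is enumerated over all
C(n1+n2, n1) rank assignments rather than approximated. With n1 = 3 and
n2 = 8 the smallest achievable two-sided exact p is 2/165 ~ 0.012 — the
floor for complete separation. When ties are present the exact distribution
no longer applies and a tie-corrected normal approximation with continuity
correction is used, flagged in the result.

Treatment-recovery scoring asks, per cell type, whether the treated group's
mean percentage moved back toward the healthy (wild-type) mean relative to
the untreated disease group.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FrequencyTable",
    "MWResult",
    "RecoveryCall",
    "build_frequency_table",
    "exact_null_counts",
    "mw_exact",
    "compare_conditions",
    "recovery_score",
    "format_p",
]


@dataclass
class FrequencyTable:
    """Per-sample cell-type percentages with a condition label per sample.

    ``values`` is a samples x cell-types DataFrame of percentages of total
    nuclei per sample; every row sums to 100 (within 1e-6).
    """

    values: pd.DataFrame  # index: sample ids; columns: cell types
    conditions: pd.Series  # index: sample ids; values: condition labels

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.conditions.index):
            raise ValueError("values and conditions must share the sample index")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("frequency table contains negative values")
        sums = self.values.sum(axis=1)
        bad = sums[(sums - 100.0).abs() > 1e-6]
        if not bad.empty:
            raise ValueError(
                f"rows must sum to 100; sample {bad.index[0]!r} sums to "
                f"{bad.iloc[0]:.6f}"
            )

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "condition", self.conditions)
        out.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyTable":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        if "condition" not in df.columns:
            raise ValueError(f"frequency table {path} lacks a condition column")
        conditions = df["condition"].astype(str).rename(None)
        values = df.drop(columns="condition").astype(float)
        values.index.name = None
        conditions.index.name = None
        return cls(values, conditions)


def build_frequency_table(annotations: pd.DataFrame) -> FrequencyTable:
    """Per-sample cell-type percentages from a nucleus annotation table.

    ``value[s, t] = 100 * n(type t in sample s) / n(sample s)``; cell types
    absent from a sample get 0. Every nucleus must carry sample, condition
    and cluster labels; a sample mapped to two conditions is an error.
    """
    required = {"sample", "condition", "cluster"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotations lack columns {sorted(missing)}")
    cond_per_sample = annotations.groupby("sample")["condition"].nunique()
    if (cond_per_sample > 1).any():
        bad = cond_per_sample[cond_per_sample > 1].index[0]
        raise ValueError(f"sample {bad!r} is annotated with multiple conditions")
    counts = (
        annotations.groupby(["sample", "cluster"]).size().unstack(fill_value=0)
    )
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("sample with zero nuclei")
    values = 100.0 * counts.div(totals, axis=0)
    values.columns.name = None
    conditions = annotations.groupby("sample")["condition"].first()
    return FrequencyTable(values, conditions.loc[values.index])


_NULL_CACHE: dict[tuple[int, int], np.ndarray] = {}


def exact_null_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank arrangements with U = u, for u = 0..n1*n2.

    Uses the standard recursion N(u; n1, n2) = N(u - n2; n1-1, n2) +
    N(u; n1, n2-1). The counts sum to C(n1+n2, n1) and are symmetric about
    n1*n2/2.
    """
    key = (n1, n2)
    cached = _NULL_CACHE.get(key)
    if cached is not None:
        return cached
    if n1 == 0 or n2 == 0:
        result = np.array([1.0])
    else:
        a = exact_null_counts(n1 - 1, n2)  # length (n1-1)*n2 + 1
        b = exact_null_counts(n1, n2 - 1)  # length n1*(n2-1) + 1
        result = np.zeros(n1 * n2 + 1)
        result[n2 : n2 + len(a)] += a
        result[: len(b)] += b
    _NULL_CACHE[key] = result
    return result


@dataclass(frozen=True)
class MWResult:
    U: float
    p_two_sided: float
    method: Literal["exact", "normal_tie_corrected"]
    n1: int
    n2: int


def mw_exact(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_limit: int = 25,
) -> MWResult:
    """Mann-Whitney U test with an exact small-sample null distribution.

    U counts pairs (x_i, y_j) with x_i > y_j, ties contributing 1/2. With no
    ties and n1 + n2 <= ``exact_limit`` the two-sided p is taken from the
    enumerated null distribution as 2*min(P(U <= u), P(U >= u)) capped at 1;
    otherwise a tie-corrected normal approximation with continuity
    correction is used and flagged in ``method``.
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")

    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    u = gt + 0.5 * eq

    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()

    if not has_ties and n1 + n2 <= exact_limit:
        counts = exact_null_counts(n1, n2)
        total = counts.sum()
        ui = int(round(u))
        lower = counts[: ui + 1].sum() / total
        upper = counts[ui:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return MWResult(U=float(ui), p_two_sided=float(p), method="exact", n1=n1, n2=n2)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return MWResult(
            U=float(u), p_two_sided=1.0, method="normal_tie_corrected", n1=n1, n2=n2
        )
    # continuity correction shrinks |U - mu| by 0.5
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return MWResult(
        U=float(u), p_two_sided=float(p), method="normal_tie_corrected", n1=n1, n2=n2
    )


def format_p(p: float) -> str:
    """Render a p-value at the 3-decimal reporting precision (0.012, 0.048)."""
    return f"{p:.3f}"


def compare_conditions(
    ft: FrequencyTable,
    group_a: str,
    group_b: str,
    adjust: str = "none",
    exact_limit: int = 25,
) -> pd.DataFrame:
    """Per-cell-type Mann-Whitney comparison of two conditions.

    Returns one row per cell type with U, p, method and the direction of the
    mean difference (group_a relative to group_b). ``adjust="bh"`` appends a
    Benjamini-Hochberg column without altering the raw p-values.
    """
    if adjust not in ("none", "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    for cond in (group_a, group_b):
        if cond not in set(ft.conditions):
            raise ValueError(f"condition {cond!r} not present in frequency table")
    a_samples = ft.conditions[ft.conditions == group_a].index
    b_samples = ft.conditions[ft.conditions == group_b].index

    rows = []
    for cell_type in ft.cell_types:
        x = ft.values.loc[a_samples, cell_type].to_numpy()
        y = ft.values.loc[b_samples, cell_type].to_numpy()
        res = mw_exact(x, y, exact_limit=exact_limit)
        diff = x.mean() - y.mean()
        direction = "increase" if diff > 0 else ("decrease" if diff < 0 else "none")
        rows.append(
            (cell_type, res.U, res.p_two_sided, res.method, direction, res.n1, res.n2)
        )
    out = pd.DataFrame(
        rows, columns=["cell_type", "U", "p", "method", "direction", "n1", "n2"]
    )
    if adjust == "bh":
        out["p_bh"] = sps.false_discovery_control(out["p"].to_numpy(), method="bh")
    return out


@dataclass(frozen=True)
class RecoveryCall:
    cell_type: str
    direction_vs_wt: Literal["increase", "decrease", "none"]
    recovered: bool | None  # None when disease and WT centers coincide


def recovery_score(
    ft: FrequencyTable,
    wt: str,
    disease: str,
    treated: str,
    center: str = "mean",
) -> list[RecoveryCall]:
    """Per cell type, did treatment move the percentage back toward WT?

    ``recovered`` is True when |center(treated) - center(WT)| <
    |center(disease) - center(WT)|; undefined (None) when the disease and WT
    centers coincide, because there is no deviation to recover from.
    """
    if center not in ("mean", "median"):
        raise ValueError(f"unknown center {center!r}")
    for cond in (wt, disease, treated):
        if cond not in set(ft.conditions):
            raise ValueError(f"condition {cond!r} not present in frequency table")
    agg = np.mean if center == "mean" else np.median

    calls: list[RecoveryCall] = []
    for cell_type in ft.cell_types:
        col = ft.values[cell_type]
        c_wt = agg(col[ft.conditions == wt].to_numpy())
        c_dis = agg(col[ft.conditions == disease].to_numpy())
        c_trt = agg(col[ft.conditions == treated].to_numpy())
        diff = c_dis - c_wt
        if diff > 0:
            direction = "increase"
        elif diff < 0:
            direction = "decrease"
        else:
            direction = "none"
        recovered = None if diff == 0 else bool(abs(c_trt - c_wt) < abs(diff))
        calls.append(RecoveryCall(cell_type, direction, recovered))
    return calls
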