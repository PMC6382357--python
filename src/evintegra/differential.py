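"""Differential profiling: fold changes, Z-score scaling, hierarchical
clustering orders, supervised top-k marker selection, comparative 2^-dCT
qPCR expression, and loading-control-normalized densitometry ratios.

Fold changes are ratios of group means, condition B relative to condition A
(the study convention is 3D relative to 2D).  Heatmap-style row scaling is
the usual per-feature Z-score with the sample (n-1) standard deviation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from evintegra.ev_yield_stats import mann_whitney_exact
from evintegra.tables_io import ExpressionMatrix


@dataclass(frozen=True)
class FoldChangeRecord:
    feature_id: str
    mean_a: float
    mean_b: float
    fc: float | None  # mean_b / mean_a, None when undefined
    log2fc: float | None
    status: str  # "ok" | "undefined_zero"


@dataclass(frozen=True)
class QpcrRecord:
    target_id: str
    replicate: str
    ct_condition_a: float
    ct_condition_b: float
    delta_ct: float  # ct_b - ct_a
    rel_expr: float  # 2 ** (-delta_ct)


@dataclass
class ClusterResult:
    """Agglomerative clustering output: leaf order plus merge history.

    ``merges`` lists (node_i, node_j, height) with scipy-style node ids
    (leaves 0..n-1, the m-th merge creates node n+m); heights are
    non-decreasing for single/complete/average linkage on a metric.
    """

    labels: list[str]
    leaf_order: list[int]
    merges: list[tuple[int, int, float]]

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]


def _group_means(
    matrix: ExpressionMatrix, sample_ids: Sequence[str]
) -> np.ndarray:
    sub = matrix.data[list(sample_ids)].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        return np.nanmean(sub, axis=1)


def fold_change(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    zero_policy: str = "undefined",
    epsilon: float = 1.0,
) -> list[FoldChangeRecord]:
    """Per-feature ratio of group means, B over A (e.g. 3D over 2D).

    Missing values are excluded from the means.  A zero denominator is
    handled per ``zero_policy``: "undefined" emits status undefined_zero
    with no ratio; "epsilon" adds ``epsilon`` to both means.  A feature
    that is all-missing in either group is undefined as well.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if not group_a or not group_b:
        raise ValueError("both groups need at least one sample")
    if zero_policy not in {"undefined", "epsilon"}:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    means_a = _group_means(matrix, group_a)
    means_b = _group_means(matrix, group_b)
    records = []
    for f, ma, mb in zip(matrix.feature_ids, means_a, means_b):
        if np.isnan(ma) or np.isnan(mb):
            records.append(FoldChangeRecord(f, float(ma), float(mb), None, None, "undefined_zero"))
            continue
        if zero_policy == "epsilon":
            ma, mb = ma + epsilon, mb + epsilon
        if ma == 0.0 or mb == 0.0:
            records.append(FoldChangeRecord(f, float(ma), float(mb), None, None, "undefined_zero"))
            continue
        fc = mb / ma
        records.append(
            FoldChangeRecord(f, float(ma), float(mb), float(fc), math.log2(fc), "ok")
        )
    return records


def fold_change_frame(records: Sequence[FoldChangeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "mean_a": [r.mean_a for r in records],
            "mean_b": [r.mean_b for r in records],
            "fc": [r.fc if r.fc is not None else np.nan for r in records],
            "log2fc": [r.log2fc if r.log2fc is not None else np.nan for r in records],
            "status": [r.status for r in records],
        }
    ).set_index("feature_id")


def zscore_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Row-wise Z-score: (x - row mean) / row sd, sample sd (n-1 divisor).

    Constant rows have no scale and are emitted as all-missing with a
    warning rather than silently zeroed."""
    if matrix.data.shape[1] < 2:
        raise ValueError("need at least two samples to Z-score")
    vals = matrix.data.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    const = (sd == 0.0).ravel()
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant row(s) emitted as missing", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    z[const, :] = np.nan
    data = pd.DataFrame(z, index=matrix.data.index, columns=matrix.data.columns)
    # Z-scores are signed; bypass the nonnegativity invariant deliberately
    out = ExpressionMatrix.__new__(ExpressionMatrix)
    out.data = data
    out.samples = list(matrix.samples)
    out.unit_label = "Z-score"
    return out


def hierarchical_order(
    matrix: ExpressionMatrix,
    axis: str = "features",
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering under Euclidean distance.

    Lance-Williams updates for single/complete/average linkage; ties in the
    minimum inter-cluster distance are broken by the lowest-index pair
    (row-major), making the dendrogram deterministic.  Caller is expected
    to Z-score rows first when emulating heatmap conventions.
    """
    if axis not in {"features", "samples"}:
        raise ValueError(f"unknown axis {axis!r}")
    if linkage not in {"average", "complete", "single"}:
        raise ValueError(f"unknown linkage {linkage!r}")
    pts = matrix.data.to_numpy(dtype=float)
    labels = matrix.feature_ids if axis == "features" else matrix.sample_ids
    if axis == "samples":
        pts = pts.T
    n = pts.shape[0]
    if n < 2:
        raise ValueError("need at least two items to cluster")
    if np.isnan(pts).any():
        raise ValueError("missing values present: impute or drop before clustering")

    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    active = list(range(n))  # positions in d currently alive
    node_of = list(range(n))  # cluster node id at each alive position
    sizes = [1] * n
    children: dict[int, tuple[int, int]] = {}
    merges: list[tuple[int, int, float]] = []
    alive = np.ones(n, dtype=bool)

    for step in range(n - 1):
        sub = d[np.ix_(alive.nonzero()[0], alive.nonzero()[0])]
        pos = np.unravel_index(np.argmin(sub), sub.shape)  # first min, row-major
        alive_idx = alive.nonzero()[0]
        i, j = int(alive_idx[pos[0]]), int(alive_idx[pos[1]])
        if i > j:
            i, j = j, i
        h = float(d[i, j])
        ni, nj = node_of[i], node_of[j]
        new_id = n + step
        children[new_id] = (ni, nj)
        merges.append((ni, nj, h))
        # Lance-Williams update into slot i
        si, sj = sizes[i], sizes[j]
        for k in alive_idx:
            if k == i or k == j:
                continue
            if linkage == "single":
                nd = min(d[i, k], d[j, k])
            elif linkage == "complete":
                nd = max(d[i, k], d[j, k])
            else:
                nd = (si * d[i, k] + sj * d[j, k]) / (si + sj)
            d[i, k] = d[k, i] = nd
        sizes[i] = si + sj
        node_of[i] = new_id
        alive[j] = False

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        return leaves(a) + leaves(b)

    order = leaves(2 * n - 2) if n > 1 else [0]
    return ClusterResult(labels=list(labels), leaf_order=order, merges=merges)


def top_discriminating(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    k: int,
    test: str = "t_welch",
    log2_transform: bool = True,
) -> pd.DataFrame:
    """The k features most significantly different between two groups.

    Default test is Welch's t on log2 abundances (small-n proteomics
    convention); Mann-Whitney (exact where applicable) is available.
    Ranking is by ascending p, ties broken by |log2fc| descending then
    feature id.  Zero-variance features with identical group means get
    p = 1 by convention.  Returns a DataFrame (feature_id index, columns
    p, log2fc) of the top k in rank order.
    """
    if test not in {"t_welch", "mannwhitney"}:
        raise ValueError(f"unknown test {test!r}")
    if k > len(matrix.feature_ids):
        raise ValueError("k exceeds feature count")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two samples")
    fc = fold_change_frame(fold_change(matrix, group_a, group_b, zero_policy="epsilon"))
    a = matrix.data[list(group_a)].to_numpy(dtype=float)
    b = matrix.data[list(group_b)].to_numpy(dtype=float)
    if log2_transform:
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(a > 0, np.log2(np.where(a > 0, a, 1.0)), np.nan)
            b = np.where(b > 0, np.log2(np.where(b > 0, b, 1.0)), np.nan)
    pvals = np.ones(len(matrix.feature_ids))
    for i in range(len(pvals)):
        xa = a[i][~np.isnan(a[i])]
        xb = b[i][~np.isnan(b[i])]
        if len(xa) < 2 or len(xb) < 2:
            pvals[i] = 1.0
            continue
        if xa.std() == 0 and xb.std() == 0:
            pvals[i] = 1.0 if xa.mean() == xb.mean() else 0.0
            continue
        if test == "t_welch":
            pvals[i] = stats.ttest_ind(xa, xb, equal_var=False).pvalue
        else:
            pvals[i] = mann_whitney_exact(xa, xb).p_two_sided
    df = pd.DataFrame(
        {"p": pvals, "log2fc": fc["log2fc"].to_numpy()},
        index=pd.Index(matrix.feature_ids, name="feature_id"),
    )
    df["_abs"] = df["log2fc"].abs().fillna(0.0)
    df = df.sort_values(
        by=["p", "_abs", "feature_id"], ascending=[True, False, True], kind="mergesort"
    ).drop(columns="_abs")
    return df.head(k)


def qpcr_relative_expression(ct_table: pd.DataFrame) -> list[QpcrRecord]:
    """Comparative 2^-dCT relative expression, per replicate pair.

    ``ct_table`` needs columns target_id, replicate, ct_2d, ct_3d; each row
    is one paired measurement.  dCT = CT(3D) - CT(2D) and relative
    expression is 2^-dCT, reported per replicate (not averaged).  Rows with
    a missing CT are skipped with a warning.
    """
    required = {"target_id", "replicate", "ct_2d", "ct_3d"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"ct_table missing columns: {sorted(missing)}")
    records = []
    for row in ct_table.itertuples():
        ct_a, ct_b = row.ct_2d, row.ct_3d
        if pd.isna(ct_a) or pd.isna(ct_b):
            warnings.warn(
                f"target {row.target_id} replicate {row.replicate}: missing CT, skipped",
                stacklevel=2,
            )
            continue
        delta = float(ct_b) - float(ct_a)
        records.append(
            QpcrRecord(
                target_id=str(row.target_id),
                replicate=str(row.replicate),
                ct_condition_a=float(ct_a),
                ct_condition_b=float(ct_b),
                delta_ct=delta,
                rel_expr=2.0 ** (-delta),
            )
        )
    return records


def control_normalized_ratio(
    signal: float, control: float, signal_ref: float, control_ref: float
) -> float:
    """Densitometry band ratio normalized to a loading control:
    (signal/control) / (signal_ref/control_ref)."""
    if control <= 0 or control_ref <= 0:
        raise ValueError("loading controls must be > 0")
    if signal < 0 or signal_ref < 0:
        raise ValueError("signals must be >= 0")
    if signal_ref == 0:
        raise ValueError("reference signal is zero; ratio undefined")
    return (signal / control) / (signal_ref / control_ref)
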