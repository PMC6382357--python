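"""Detection calls, Venn/exclusivity partitioning, biotype composition and
the housekeeping-candidate filter.

A feature is "detected" in a group when its abundance exceeds a threshold
(default: strictly > 0, i.e. FPKM > 0) in at least ``min_replicates``
replicates (default 1).  Venn regions partition the detected features by
their exact detection signature across groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from evintegra.tables_io import BiotypeMap, ExpressionMatrix


@dataclass
class DetectionTable:
    """Boolean feature x group detection calls plus the rule parameters."""

    detected: pd.DataFrame  # features x groups, bool
    threshold: float
    min_replicates: int

    @property
    def groups(self) -> list[str]:
        return list(self.detected.columns)

    def features_in(self, group: str) -> set[str]:
        return set(self.detected.index[self.detected[group]])


@dataclass
class FeatureSetPartition:
    """Disjoint Venn regions keyed by the tuple of groups a feature hits."""

    regions: dict[tuple[str, ...], set[str]] = field(default_factory=dict)

    def sizes(self) -> dict[tuple[str, ...], int]:
        return {r: len(v) for r, v in self.regions.items()}

    def all_features(self) -> set[str]:
        out: set[str] = set()
        for v in self.regions.values():
            out |= v
        return out


def make_grouping(
    matrix: ExpressionMatrix, by: Sequence[str] = ("condition", "entity")
) -> dict[str, list[str]]:
    """Map group label -> sample ids, grouping samples by metadata fields.

    ``by`` is any subset of {cell_line, condition, entity}; labels join the
    field values with "_" in the order given (e.g. "3D_EV").  Pooling over
    cell lines (the default) mirrors the two-cell-line Venn analysis.
    """
    groups: dict[str, list[str]] = {}
    for s in matrix.samples:
        label = "_".join(str(getattr(s, f)) for f in by)
        groups.setdefault(label, []).append(s.sample_id)
    return groups


def call_detected(
    matrix: ExpressionMatrix,
    grouping: Mapping[str, Sequence[str]],
    threshold: float = 0.0,
    min_replicates: int = 1,
) -> DetectionTable:
    """Per-group detection: value strictly above ``threshold`` in at least
    ``min_replicates`` replicates.  Missing values never exceed the
    threshold."""
    all_ids = set(matrix.sample_ids)
    seen: set[str] = set()
    for g, sids in grouping.items():
        if not sids:
            raise ValueError(f"empty group {g!r}")
        unknown = [s for s in sids if s not in all_ids]
        if unknown:
            raise ValueError(f"group {g!r} references unknown samples {unknown}")
        dup = seen & set(sids)
        if dup:
            raise ValueError(f"samples assigned to more than one group: {sorted(dup)}")
        seen |= set(sids)
    cols = {}
    for g, sids in grouping.items():
        sub = matrix.data[list(sids)].to_numpy(dtype=float)
        above = np.where(np.isnan(sub), False, sub > threshold)
        cols[g] = above.sum(axis=1) >= min_replicates
    det = pd.DataFrame(cols, index=matrix.data.index)
    return DetectionTable(det, threshold=threshold, min_replicates=min_replicates)


def venn_partition(
    det: DetectionTable, groups: Sequence[str] | None = None
) -> FeatureSetPartition:
    """Partition detected features into Venn regions by detection signature.

    Regions are keyed by the tuple of group labels (in the given order) the
    feature is detected in; features detected nowhere are excluded.
    """
    groups = list(groups) if groups is not None else det.groups
    if len(groups) < 2:
        raise ValueError("need at least two groups for a Venn partition")
    regions: dict[tuple[str, ...], set[str]] = {}
    sub = det.detected[groups]
    for feature, row in zip(sub.index, sub.to_numpy()):
        sig = tuple(g for g, hit in zip(groups, row) if hit)
        if not sig:
            continue
        regions.setdefault(sig, set()).add(feature)
    return FeatureSetPartition(regions)


def composite_set(
    det: DetectionTable,
    include: Sequence[str],
    exclude: Sequence[str] = (),
) -> set[str]:
    """Features detected in every ``include`` group and in no ``exclude``
    group (e.g. shared by 2D and 3D cells and 3D EVs but absent from 2D
    EVs)."""
    feats = set(det.detected.index)
    out = set.intersection(feats, *(det.features_in(g) for g in include))
    for g in exclude:
        out -= det.features_in(g)
    return out


def biotype_composition(
    matrix: ExpressionMatrix,
    biotypes: BiotypeMap,
    grouping: Mapping[str, Sequence[str]],
    threshold: float = 0.0,
    min_replicates: int = 1,
) -> pd.DataFrame:
    """Percentage of detected features per small-RNA biotype, per group.

    Rows are groups, columns biotypes; each row sums to 100.  A group with
    no detected features gets all-NaN (undefined), never zeros.
    """
    det = call_detected(matrix, grouping, threshold, min_replicates)
    detected_any = det.detected.any(axis=1)
    missing = [f for f in det.detected.index[detected_any] if f not in biotypes]
    if missing:
        raise ValueError(f"features missing from biotype map: {missing}")
    labels = sorted({biotypes[f] for f in det.detected.index[detected_any]})
    rows = {}
    for g in det.groups:
        feats = det.features_in(g)
        if not feats:
            rows[g] = {b: np.nan for b in labels}
            continue
        counts = {b: 0 for b in labels}
        for f in feats:
            counts[biotypes[f]] += 1
        rows[g] = {b: 100.0 * counts[b] / len(feats) for b in labels}
    return pd.DataFrame.from_dict(rows, orient="index", columns=labels)


def select_housekeeping_candidates(
    matrix: ExpressionMatrix,
    min_detect: float = 0.0,
    min_abundance: float = 10_000.0,
    max_fold_change: float = 1.5,
    mode: str = "pairwise",
    grouping: Mapping[str, Sequence[str]] | None = None,
) -> list[str]:
    """Housekeeping candidates for qPCR normalization.

    A feature qualifies when it is expressed in all samples
    (value > ``min_detect``), well detected in all samples
    (value > ``min_abundance``) and not differentially expressed: in
    "pairwise" mode the max/min ratio over all samples must not exceed
    ``max_fold_change`` (the strictest reading of 0.5 <= FC <= 1.5); in
    "group_mean" mode the ratio of group means is bounded instead
    (requires ``grouping``).  An empty result is a legal outcome.
    """
    if matrix.data.shape[1] < 2:
        raise ValueError("need at least two samples")
    if mode not in {"pairwise", "group_mean"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "group_mean" and grouping is None:
        raise ValueError("group_mean mode requires a grouping")
    out: list[str] = []
    vals = matrix.data.to_numpy(dtype=float)
    for i, f in enumerate(matrix.feature_ids):
        row = vals[i]
        if np.any(np.isnan(row)) or np.any(row <= min_detect) or np.any(
            row <= min_abundance
        ):
            continue
        if mode == "pairwise":
            ratio = row.max() / row.min()
        else:
            means = []
            for sids in grouping.values():  # type: ignore[union-attr]
                idx = [matrix.sample_ids.index(s) for s in sids]
                means.append(row[idx].mean())
            ratio = max(means) / min(means)
        if ratio <= max_fold_change:
            out.append(f)
    return out
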