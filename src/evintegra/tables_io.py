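"""Tabular I/O for expression matrices, target edges, biotype maps and
category databases.

All artifacts are plain delimited text (TAB by default, comma via ``sep``).
Empty cells and ``NA`` parse to missing (NaN), which is distinct from an
observed 0: proteomics abundances can be missing-not-zero while FPKM zeros
are true zeros.  miRNA and protein matrices are kept in separate
:class:`ExpressionMatrix` objects so their feature-id namespaces can never
collide; the network module joins them only through :class:`TargetEdge`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_CONDITIONS = ("2D", "3D")
VALID_ENTITIES = ("cell", "EV")
VALID_BIOTYPES = frozenset(
    {
        "miRNA",
        "misc_RNA",
        "mt_tRNA",
        "ribozyme",
        "rRNA",
        "scaRNA",
        "scRNA",
        "snoRNA",
        "snRNA",
    }
)
VALID_EVIDENCE = ("strong", "weak")

MISSING_TOKENS = {"", "NA", "NaN", "nan"}


class TableError(ValueError):
    """Structured parsing/validation failure for a tabular artifact."""


@dataclass(frozen=True)
class SampleMeta:
    """One sample of the (cell line x condition x entity x replicate) design."""

    sample_id: str
    cell_line: str
    condition: str  # "2D" | "3D"
    entity: str  # "cell" | "EV"
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in VALID_CONDITIONS:
            raise TableError(
                f"sample {self.sample_id!r}: condition {self.condition!r} "
                f"not in {VALID_CONDITIONS}"
            )
        if self.entity not in VALID_ENTITIES:
            raise TableError(
                f"sample {self.sample_id!r}: entity {self.entity!r} "
                f"not in {VALID_ENTITIES}"
            )
        if self.replicate < 1:
            raise TableError(
                f"sample {self.sample_id!r}: replicate must be >= 1"
            )

    @property
    def group_key(self) -> tuple[str, str, str]:
        return (self.cell_line, self.condition, self.entity)


@dataclass
class ExpressionMatrix:
    """Nonnegative feature x sample abundance matrix with sample metadata.

    ``data`` is a pandas DataFrame indexed by feature id with one column per
    sample, ordered exactly as ``samples``.  NaN marks a missing measurement;
    all observed values are >= 0.
    """

    data: pd.DataFrame
    samples: list[SampleMeta]
    unit_label: str = "FPKM"

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise TableError("duplicate sample_id in metadata")
        keys = [(s.cell_line, s.condition, s.entity, s.replicate) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise TableError("duplicate (cell_line, condition, entity, replicate) tuple")
        if list(self.data.columns) != ids:
            raise TableError("matrix columns do not match sample metadata order")
        dup = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup:
            raise TableError(f"duplicate feature ids: {dup}")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise TableError("negative abundance")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def sample_meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        keep = set(sample_ids)
        metas = [s for s in self.samples if s.sample_id in keep]
        order = [s.sample_id for s in metas]
        return ExpressionMatrix(self.data[order].copy(), metas, self.unit_label)


@dataclass(frozen=True)
class TargetEdge:
    """Directed miRNA -> protein link with miRTarBase-style evidence grade.

    "strong" marks reporter-assay-validated interactions, "weak" marks
    high-throughput (e.g. microarray) support.
    """

    mirna_id: str
    protein_id: str
    evidence: str

    def __post_init__(self) -> None:
        if self.evidence not in VALID_EVIDENCE:
            raise TableError(
                f"edge ({self.mirna_id}, {self.protein_id}): evidence "
                f"{self.evidence!r} not in {VALID_EVIDENCE}"
            )


@dataclass
class BiotypeMap:
    """feature_id -> small-RNA biotype, restricted to the closed Ensembl set."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {b for b in self.mapping.values() if b not in VALID_BIOTYPES}
        if bad:
            raise TableError(f"biotype labels outside closed set: {sorted(bad)}")

    def __getitem__(self, feature_id: str) -> str:
        return self.mapping[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.mapping


@dataclass
class CategoryDB:
    """category_id -> (name, member feature-id set) for enrichment tests."""

    categories: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [c for c, (_, m) in self.categories.items() if not m]
        if empty:
            raise TableError(f"empty categories: {empty}")

    def members(self, category_id: str) -> frozenset[str]:
        return self.categories[category_id][1]

    def __iter__(self):
        return iter(self.categories)

    def __len__(self) -> int:
        return len(self.categories)


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_sample_meta(path: str | Path, sep: str = "\t") -> list[SampleMeta]:
    """Read a sample metadata sheet with columns
    sample_id, cell_line, condition, entity, replicate."""
    df = _read_table(path, sep)
    required = {"sample_id", "cell_line", "condition", "entity", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise TableError(f"metadata sheet missing columns: {sorted(missing)}")
    metas = [
        SampleMeta(
            sample_id=row.sample_id,
            cell_line=row.cell_line,
            condition=row.condition,
            entity=row.entity,
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    ]
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise TableError("duplicate sample_id in metadata sheet")
    return metas


def read_expression_matrix(
    path: str | Path,
    meta_path: str | Path,
    sep: str = "\t",
    unit_label: str = "FPKM",
) -> ExpressionMatrix:
    """Read a feature x sample abundance table plus its metadata sheet.

    The first column holds feature ids; the header row holds sample ids.
    Columns are reordered to follow the metadata sheet, so the parse is
    independent of on-disk column order.  Empty cells and "NA" become NaN
    (missing); negative or non-numeric cells are rejected.
    """
    samples = read_sample_meta(meta_path, sep)
    raw = _read_table(path, sep)
    if raw.shape[1] < 2:
        raise TableError("expression table needs a feature column and >=1 sample")
    feat_col = raw.columns[0]
    features = raw[feat_col].tolist()
    dup = sorted({f for f in features if features.count(f) > 1})
    if dup:
        raise TableError(f"duplicate feature ids: {dup}")
    table_samples = list(raw.columns[1:])
    meta_ids = [s.sample_id for s in samples]
    missing = [sid for sid in meta_ids if sid not in table_samples]
    if missing:
        raise TableError(f"samples in metadata but not in table: {missing}")
    extra = [sid for sid in table_samples if sid not in meta_ids]
    if extra:
        raise TableError(f"samples in table but not in metadata: {extra}")

    def _cell(v: str, f: str, s: str) -> float:
        if v.strip() in MISSING_TOKENS:
            return np.nan
        try:
            x = float(v)
        except ValueError:
            raise TableError(f"non-numeric abundance {v!r} at ({f}, {s})") from None
        if x < 0:
            raise TableError(f"negative abundance {x} at ({f}, {s})")
        return x

    values = np.array(
        [
            [_cell(raw.iloc[i][sid], features[i], sid) for sid in meta_ids]
            for i in range(len(features))
        ],
        dtype=float,
    ).reshape(len(features), len(meta_ids))
    data = pd.DataFrame(values, index=pd.Index(features, name=feat_col), columns=meta_ids)
    return ExpressionMatrix(data, samples, unit_label)


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    meta_path: str | Path | None = None,
    sep: str = "\t",
) -> None:
    """Write matrix (and optionally its metadata sheet) as delimited text.

    Values are written at full float repr so a write/read round trip
    reproduces them exactly."""
    df = matrix.data.copy()
    df.index.name = df.index.name or "feature_id"
    df.to_csv(path, sep=sep, na_rep="NA")
    if meta_path is not None:
        write_sample_meta(matrix.samples, meta_path, sep)


def write_sample_meta(samples: Iterable[SampleMeta], path: str | Path, sep: str = "\t") -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "cell_line": s.cell_line,
            "condition": s.condition,
            "entity": s.entity,
            "replicate": s.replicate,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_target_edges(path: str | Path, sep: str = "\t") -> list[TargetEdge]:
    """Read a miRNA->protein edge list with columns mirna_id, protein_id,
    evidence.  Duplicate pairs are collapsed keeping the stronger grade;
    first-appearance order is preserved."""
    df = _read_table(path, sep)
    required = {"mirna_id", "protein_id", "evidence"}
    missing = required - set(df.columns)
    if missing:
        raise TableError(f"edge list missing columns: {sorted(missing)}")
    best: dict[tuple[str, str], str] = {}
    order: list[tuple[str, str]] = []
    for row in df.itertuples():
        if row.evidence not in VALID_EVIDENCE:
            raise TableError(
                f"edge ({row.mirna_id}, {row.protein_id}): evidence "
                f"{row.evidence!r} not in {VALID_EVIDENCE}"
            )
        pair = (row.mirna_id, row.protein_id)
        if pair not in best:
            best[pair] = row.evidence
            order.append(pair)
        elif row.evidence == "strong":
            best[pair] = "strong"
    return [TargetEdge(m, p, best[(m, p)]) for m, p in order]


def write_target_edges(edges: Iterable[TargetEdge], path: str | Path, sep: str = "\t") -> None:
    rows = [
        {"mirna_id": e.mirna_id, "protein_id": e.protein_id, "evidence": e.evidence}
        for e in edges
    ]
    pd.DataFrame(rows, columns=["mirna_id", "protein_id", "evidence"]).to_csv(
        path, sep=sep, index=False
    )


def read_biotype_map(path: str | Path, sep: str = "\t") -> BiotypeMap:
    """Read a two-column feature_id -> biotype table."""
    df = _read_table(path, sep)
    if df.shape[1] < 2:
        raise TableError("biotype map needs two columns")
    return BiotypeMap(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_biotype_map(biotypes: BiotypeMap, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(
        {"feature_id": list(biotypes.mapping), "biotype": list(biotypes.mapping.values())}
    ).to_csv(path, sep=sep, index=False)


def read_category_db(path: str | Path, sep: str = "\t") -> CategoryDB:
    """Read category definitions in either of two dialects (auto-detected by
    column count):

    * long format — two columns (category_id, member_id), one row per member;
    * GMT — one category per line: name TAB description TAB member TAB ...
    """
    lines = [
        ln.rstrip("\n")
        for ln in Path(path).read_text().splitlines()
        if ln.strip()
    ]
    if not lines:
        raise TableError("empty category file")
    ncols = {len(ln.split(sep)) for ln in lines}
    cats: dict[str, tuple[str, frozenset[str]]] = {}
    if ncols == {2}:
        rows = [ln.split(sep) for ln in lines]
        if rows and rows[0][0].lower() in {"category_id", "category"}:
            rows = rows[1:]
        agg: dict[str, set[str]] = {}
        order: list[str] = []
        for cid, member in rows:
            if cid not in agg:
                agg[cid] = set()
                order.append(cid)
            agg[cid].add(member)
        for cid in order:
            if not agg[cid]:
                raise TableError(f"category {cid!r} has no members")
            cats[cid] = (cid, frozenset(agg[cid]))
    else:
        for ln in lines:
            parts = ln.split(sep)
            if len(parts) < 3:
                raise TableError(f"GMT line with <3 fields: {ln!r}")
            cid, desc, *members = parts
            members = [m for m in members if m.strip()]
            if not members:
                raise TableError(f"category {cid!r} has no members")
            cats[cid] = (desc or cid, frozenset(members))
    return CategoryDB(cats)


def write_category_db(db: CategoryDB, path: str | Path) -> None:
    """Write a CategoryDB as GMT (members sorted for determinism)."""
    with open(path, "w") as fh:
        for cid, (name, members) in db.categories.items():
            fh.write("\t".join([cid, name, *sorted(members)]) + "\n")


def write_json(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
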