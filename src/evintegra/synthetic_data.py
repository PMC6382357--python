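"""Synthetic study generator with planted 2D/3D coregulation structure.

The generator emulates the study design the downstream analysis expects:
two gastric-cancer-like cell lines x {2D, 3D} culture x {cell, EV} entity
with a small number of biological replicates, log-normal FPKM-like
abundances with heavy zero-inflation in EV small-RNA samples, a set of
planted miRNAs upregulated in 3D whose strong-evidence target proteins are
downregulated in 3D EVs, group-exclusive features for the Venn analysis,
and decoy target edges as negatives for the network stage.  The protein
matrix covers EV samples only, because that is the only proteome measured.

Ground truth (planted edges, exclusive features, true log2 fold changes) is
returned alongside the data so recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from evintegra.ev_yield_stats import YieldRecord
from evintegra.tables_io import (
    BiotypeMap,
    ExpressionMatrix,
    SampleMeta,
    TargetEdge,
)

_OTHER_BIOTYPES = (
    "misc_RNA",
    "snRNA",
    "snoRNA",
    "rRNA",
    "scaRNA",
    "scRNA",
    "mt_tRNA",
    "ribozyme",
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Effects are on the log2 scale: planted miRNAs gain ``mirna_log2fc_3d``
    in all 3D samples, their target proteins gain ``protein_log2fc_3d`` in
    3D EV samples (also in cells when ``protein_effect_in_cells``).
    ``noise_sd_log`` is the per-measurement log2 noise sd.
    """

    n_mirna: int = 200
    n_protein: int = 150
    n_replicates: int = 2
    cell_lines: tuple[str, ...] = ("MKN45", "MKN74")
    n_planted_pairs: int = 20
    mirna_log2fc_3d: float = 1.5
    protein_log2fc_3d: float = -1.0
    noise_sd_log: float = 0.25
    zero_inflation_ev: float = 0.4
    baseline_log_mean: float = 7.0
    baseline_log_sd: float = 2.0
    frac_exclusive_per_group: float = 0.05
    n_decoy_edges: int = 200
    n_other_smallrna: int = 30
    protein_effect_in_cells: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_planted_pairs > min(self.n_mirna, self.n_protein):
            raise ValueError("n_planted_pairs exceeds min(n_mirna, n_protein)")
        for name in ("zero_inflation_ev", "frac_exclusive_per_group"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd_log <= 0:
            raise ValueError("noise_sd_log must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class GroundTruth:
    """What was planted: edges, per-group exclusive features, true log2FC."""

    planted_edges: list[TargetEdge] = field(default_factory=list)
    exclusive_features: dict[str, set[str]] = field(default_factory=dict)
    true_log2fc: dict[str, float] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "planted_edges": [asdict(e) for e in self.planted_edges],
            "exclusive_features": {
                g: sorted(v) for g, v in self.exclusive_features.items()
            },
            "true_log2fc": self.true_log2fc,
        }


def _design(config: SyntheticConfig, entities: tuple[str, ...]) -> list[SampleMeta]:
    samples = []
    for line in config.cell_lines:
        for cond in ("2D", "3D"):
            for ent in entities:
                for rep in range(1, config.n_replicates + 1):
                    samples.append(
                        SampleMeta(
                            sample_id=f"{line}_{cond}_{ent}_r{rep}",
                            cell_line=line,
                            condition=cond,
                            entity=ent,
                            replicate=rep,
                        )
                    )
    return samples


def generate_dataset(config: SyntheticConfig) -> dict:
    """Generate matched miRNA and protein matrices, target edges, a biotype
    map and the ground truth.

    Returns a dict with keys ``mirna_matrix``, ``protein_matrix``,
    ``edges``, ``biotypes``, ``truth``.  Identical config (including seed)
    gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    mirna_ids = [f"miR-{i:04d}" for i in range(config.n_mirna)]
    other_ids = [f"sRNA-{i:04d}" for i in range(config.n_other_smallrna)]
    smallrna_ids = mirna_ids + other_ids
    protein_ids = [f"PROT-{i:04d}" for i in range(config.n_protein)]

    biotypes = BiotypeMap(
        {
            **{m: "miRNA" for m in mirna_ids},
            **{
                s: _OTHER_BIOTYPES[i % len(_OTHER_BIOTYPES)]
                for i, s in enumerate(other_ids)
            },
        }
    )

    planted_mirnas = list(rng.choice(mirna_ids, size=config.n_planted_pairs, replace=False))
    planted_proteins = list(
        rng.choice(protein_ids, size=config.n_planted_pairs, replace=False)
    )
    planted_edges = [
        TargetEdge(m, p, "strong") for m, p in zip(planted_mirnas, planted_proteins)
    ]

    # decoy edges among non-planted features; negatives for network recovery
    free_m = [m for m in mirna_ids if m not in set(planted_mirnas)]
    free_p = [p for p in protein_ids if p not in set(planted_proteins)]
    decoys: list[TargetEdge] = []
    seen = set()
    while len(decoys) < config.n_decoy_edges and free_m and free_p:
        m = free_m[int(rng.integers(len(free_m)))]
        p = free_p[int(rng.integers(len(free_p)))]
        if (m, p) in seen:
            continue
        seen.add((m, p))
        decoys.append(TargetEdge(m, p, "strong" if rng.random() < 0.5 else "weak"))
    edges = planted_edges + decoys

    # group-exclusive small RNAs, keyed on (condition, entity) pooled over
    # cell lines, mirroring the Venn construction
    groups = [f"{cond}_{ent}" for ent in ("cell", "EV") for cond in ("2D", "3D")]
    protected = set(planted_mirnas)
    pool = [m for m in smallrna_ids if m not in protected]
    rng.shuffle(pool)
    n_excl = int(round(config.frac_exclusive_per_group * len(smallrna_ids)))
    exclusive: dict[str, set[str]] = {g: set() for g in groups}
    cursor = 0
    for g in groups:
        exclusive[g] = set(pool[cursor : cursor + n_excl])
        cursor += n_excl
    exclusive_all = set().union(*exclusive.values())

    mirna_samples = _design(config, ("cell", "EV"))
    protein_samples = _design(config, ("EV",))

    def _matrix(
        feature_ids: list[str],
        samples: list[SampleMeta],
        effect: dict[str, dict[str, float]],
        zero_inflate_ev: bool,
    ) -> ExpressionMatrix:
        base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, len(feature_ids))
        vals = np.empty((len(feature_ids), len(samples)))
        for j, s in enumerate(samples):
            log2 = base + rng.normal(0.0, config.noise_sd_log, len(feature_ids))
            for i, f in enumerate(feature_ids):
                log2[i] += effect.get(f, {}).get(f"{s.condition}_{s.entity}", 0.0)
            col = np.exp2(log2)
            if zero_inflate_ev and s.entity == "EV":
                drop = rng.random(len(feature_ids)) < config.zero_inflation_ev
                for i, f in enumerate(feature_ids):
                    if drop[i] and f not in protected and f not in exclusive_all:
                        col[i] = 0.0
            for i, f in enumerate(feature_ids):
                if f in exclusive_all:
                    g = f"{s.condition}_{s.entity}"
                    if f not in exclusive.get(g, set()):
                        col[i] = 0.0
            vals[:, j] = col
        data = pd.DataFrame(
            vals, index=pd.Index(feature_ids, name="feature_id"),
            columns=[s.sample_id for s in samples],
        )
        return ExpressionMatrix(data, samples)

    mirna_effect = {
        m: {"3D_cell": config.mirna_log2fc_3d, "3D_EV": config.mirna_log2fc_3d}
        for m in planted_mirnas
    }
    protein_effect = {
        p: (
            {"3D_EV": config.protein_log2fc_3d, "3D_cell": config.protein_log2fc_3d}
            if config.protein_effect_in_cells
            else {"3D_EV": config.protein_log2fc_3d}
        )
        for p in planted_proteins
    }

    mirna_matrix = _matrix(smallrna_ids, mirna_samples, mirna_effect, True)
    protein_matrix = _matrix(protein_ids, protein_samples, protein_effect, False)
    protein_matrix.unit_label = "abundance"

    truth = GroundTruth(
        planted_edges=list(planted_edges),
        exclusive_features={g: set(v) for g, v in exclusive.items()},
        true_log2fc={
            **{m: config.mirna_log2fc_3d for m in planted_mirnas},
            **{p: config.protein_log2fc_3d for p in planted_proteins},
        },
    )
    return {
        "mirna_matrix": mirna_matrix,
        "protein_matrix": protein_matrix,
        "edges": edges,
        "biotypes": biotypes,
        "truth": truth,
    }


def generate_categories(
    dataset: dict,
    n_random: int = 10,
    size_range: tuple[int, int] = (5, 20),
    seed: int = 0,
) -> "CategoryDB":
    """Category definitions over the synthetic miRNA universe: one category
    holding exactly the planted 3D-upregulated miRNAs plus ``n_random``
    categories of uniformly drawn miRNAs (null categories)."""
    from evintegra.tables_io import CategoryDB

    rng = np.random.default_rng(seed)
    truth: GroundTruth = dataset["truth"]
    mirna_ids = [
        f for f in dataset["mirna_matrix"].feature_ids
        if dataset["biotypes"][f] == "miRNA"
    ]
    cats: dict[str, tuple[str, frozenset[str]]] = {}
    planted = frozenset(e.mirna_id for e in truth.planted_edges)
    if planted:
        cats["planted_3d_up"] = ("planted 3D-upregulated miRNAs", planted)
    lo, hi = size_range
    for i in range(n_random):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(mirna_ids, size=size, replace=False))
        cats[f"random_{i:02d}"] = (f"random category {i}", members)
    return CategoryDB(cats)


def generate_qpcr_ct(
    dataset: dict,
    targets: list[str] | None = None,
    n_replicates: int = 3,
    ct_at_unit_expression: float = 35.0,
    ct_noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired CT tables for selected miRNAs, derived from the cell matrix.

    CT falls by one cycle per doubling of abundance
    (CT = ct_at_unit_expression - log2(mean FPKM) + noise), so planted
    3D-upregulated miRNAs come out with lower 3D CTs and 2^-dCT > 1.
    """
    rng = np.random.default_rng(seed)
    matrix: ExpressionMatrix = dataset["mirna_matrix"]
    truth: GroundTruth = dataset["truth"]
    if targets is None:
        targets = sorted(e.mirna_id for e in truth.planted_edges)[:6]
    rows = []
    for t in targets:
        if t not in matrix.data.index:
            raise ValueError(f"qPCR target {t!r} not in miRNA matrix")
        sids_2d = [s.sample_id for s in matrix.samples if s.condition == "2D" and s.entity == "cell"]
        sids_3d = [s.sample_id for s in matrix.samples if s.condition == "3D" and s.entity == "cell"]
        m2d = float(np.nanmean(matrix.data.loc[t, sids_2d]))
        m3d = float(np.nanmean(matrix.data.loc[t, sids_3d]))
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "target_id": t,
                    "replicate": f"r{rep}",
                    "ct_2d": ct_at_unit_expression
                    - math.log2(max(m2d, 1e-9))
                    + rng.normal(0.0, ct_noise_sd),
                    "ct_3d": ct_at_unit_expression
                    - math.log2(max(m3d, 1e-9))
                    + rng.normal(0.0, ct_noise_sd),
                }
            )
    return pd.DataFrame(rows)


def generate_yield_records(
    n_replicates: int,
    mean_ratio_2d: float,
    mean_ratio_3d: float,
    cv: float,
    seed: int,
    total_cells: float = 1e6,
) -> list[YieldRecord]:
    """Per-replicate EV particle and cell counts whose particles/cells
    ratios are log-normal with the given condition means and coefficient of
    variation (cv=0 degenerates to the exact means)."""
    if n_replicates < 4:
        raise ValueError("need at least four biological replicates per condition")
    if mean_ratio_2d <= 0 or mean_ratio_3d <= 0:
        raise ValueError("mean ratios must be positive")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[YieldRecord] = []
    for cond, mean in (("2D", mean_ratio_2d), ("3D", mean_ratio_3d)):
        if cv == 0.0:
            ratios = np.full(n_replicates, mean)
        else:
            sigma2 = math.log1p(cv * cv)
            mu = math.log(mean) - sigma2 / 2.0
            ratios = rng.lognormal(mu, math.sqrt(sigma2), n_replicates)
        for i, r in enumerate(ratios, start=1):
            records.append(
                YieldRecord(
                    replicate_id=f"{cond}_r{i}",
                    condition=cond,
                    total_particles=float(r * total_cells),
                    total_cells=float(total_cells),
                )
            )
    return records
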