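"""End-to-end pipeline: detection sets -> differential -> enrichment ->
integration network (-> EV-yield statistics), from a YAML config or a
one-command synthetic demo.

Every stage writes its tables under the output directory and the run
manifest records parameters, seed, versions and sha256 checksums so a rerun
at the same seed is bit-identical (timestamps excepted).  All randomness
flows from one root seed; per-stage seeds are derived deterministically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import networkx
import numpy
import pandas
import scipy
import yaml

import evintegra
from evintegra import detection_sets, differential, enrichment, integration_network
from evintegra import ev_yield_stats as yield_stats
from evintegra import synthetic_data, tables_io

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Either the ``synthetic`` section or the input paths must be present.
    Threshold defaults the source protocol leaves open are artifact
    defaults, documented in docs/methods.md.
    """

    out_dir: str = "evintegra_out"
    seed: int = 1
    synthetic: dict | None = None
    mirna_matrix: str | None = None
    mirna_meta: str | None = None
    protein_matrix: str | None = None
    protein_meta: str | None = None
    edges: str | None = None
    biotypes: str | None = None
    categories: str | None = None
    yield_records: str | None = None
    detection_threshold: float = 0.0
    min_replicates: int = 1
    network_mode: str = "opposite_sign"
    network_evidence: str = "strong_or_weak"
    min_abs_log2fc: float = 0.5
    top_k: int = 20
    alpha: float = 0.05
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        cfg = cls(**kwargs, extra=extra)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.synthetic is None:
            required = ("mirna_matrix", "mirna_meta", "protein_matrix", "protein_meta", "edges")
            missing = [r for r in required if getattr(self, r) is None]
            if missing:
                raise ValueError(
                    f"config needs a 'synthetic' section or input paths; missing {missing}"
                )
            for name in required + ("biotypes", "categories", "yield_records"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise ValueError(f"{name} path does not exist: {p}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")
        if self.network_mode not in {"opposite_sign", "pearson"}:
            raise ValueError(f"unknown network_mode {self.network_mode!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(root: int, stage: int) -> int:
    return (root * 1009 + stage * 7919) % (2**31 - 1)


def _sample_ids(matrix, condition: str, entity: str) -> list[str]:
    return [
        s.sample_id
        for s in matrix.samples
        if s.condition == condition and s.entity == entity
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the manifest (also written to
    manifest.json in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "created": datetime.now(timezone.utc).isoformat(),
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "versions": {
            "evintegra": evintegra.__version__,
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "networkx": networkx.__version__,
        },
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = {"status": "ok", **info}

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }

    try:
        # ---- inputs -------------------------------------------------------
        truth = None
        if config.synthetic is not None:
            syn_kwargs = dict(config.synthetic)
            syn_kwargs.setdefault("seed", _stage_seed(config.seed, 0))
            scfg = synthetic_data.SyntheticConfig(**syn_kwargs)
            ds = synthetic_data.generate_dataset(scfg)
            mirna, protein = ds["mirna_matrix"], ds["protein_matrix"]
            edges, biotypes, truth = ds["edges"], ds["biotypes"], ds["truth"]
            catdb = synthetic_data.generate_categories(
                ds, seed=_stage_seed(config.seed, 1)
            )
            tables_io.write_expression_matrix(
                mirna, out / "mirna_matrix.tsv", out / "mirna_meta.tsv"
            )
            tables_io.write_expression_matrix(
                protein, out / "protein_matrix.tsv", out / "protein_meta.tsv"
            )
            tables_io.write_target_edges(edges, out / "target_edges.tsv")
            tables_io.write_biotype_map(biotypes, out / "biotypes.tsv")
            tables_io.write_category_db(catdb, out / "categories.gmt")
            tables_io.write_json(truth.to_jsonable(), out / "truth.json")
            for name in (
                "mirna_matrix.tsv", "mirna_meta.tsv", "protein_matrix.tsv",
                "protein_meta.tsv", "target_edges.tsv", "biotypes.tsv",
                "categories.gmt", "truth.json",
            ):
                emit(name, out / name)
            record("simulate", config=asdict(scfg))
            yrecords = synthetic_data.generate_yield_records(
                n_replicates=5,
                mean_ratio_2d=2500.0,
                mean_ratio_3d=10000.0,
                cv=0.3,
                seed=_stage_seed(config.seed, 2),
            )
        else:
            mirna = tables_io.read_expression_matrix(config.mirna_matrix, config.mirna_meta)
            protein = tables_io.read_expression_matrix(
                config.protein_matrix, config.protein_meta, unit_label="abundance"
            )
            edges = tables_io.read_target_edges(config.edges)
            biotypes = (
                tables_io.read_biotype_map(config.biotypes) if config.biotypes else None
            )
            catdb = (
                tables_io.read_category_db(config.categories)
                if config.categories
                else None
            )
            yrecords = None
            if config.yield_records:
                df = pandas.read_csv(config.yield_records, sep="\t")
                yrecords = [
                    yield_stats.YieldRecord(
                        replicate_id=str(r.replicate_id),
                        condition=str(r.condition),
                        total_particles=float(r.total_particles),
                        total_cells=float(r.total_cells),
                    )
                    for r in df.itertuples()
                ]
            record("load", n_mirna_features=len(mirna.feature_ids),
                   n_protein_features=len(protein.feature_ids), n_edges=len(edges))

        # restrict small-RNA matrix to annotated miRNAs for miRNA stages
        if biotypes is not None:
            mirna_only_ids = [f for f in mirna.feature_ids if f in biotypes and biotypes[f] == "miRNA"]
            mirna_only = tables_io.ExpressionMatrix(
                mirna.data.loc[mirna_only_ids].copy(), mirna.samples, mirna.unit_label
            )
        else:
            mirna_only = mirna

        # ---- detection sets ----------------------------------------------
        grouping = detection_sets.make_grouping(mirna_only, by=("condition", "entity"))
        det = detection_sets.call_detected(
            mirna_only, grouping, config.detection_threshold, config.min_replicates
        )
        partition = detection_sets.venn_partition(det)
        venn = {
            "|".join(region): sorted(members)
            for region, members in sorted(partition.regions.items())
        }
        ev3d_specific = detection_sets.composite_set(
            det, include=["3D_EV"], exclude=["2D_EV", "2D_cell", "3D_cell"]
        )
        shared_cells_ev3d = detection_sets.composite_set(
            det, include=["2D_cell", "3D_cell", "3D_EV"], exclude=["2D_EV"]
        )
        sets_out = {
            "regions": venn,
            "region_sizes": {k: len(v) for k, v in venn.items()},
            "detected_per_group": {g: sorted(det.features_in(g)) for g in det.groups},
            "ev3d_specific": sorted(ev3d_specific),
            "shared_cells_and_3d_ev_only": sorted(shared_cells_ev3d),
        }
        tables_io.write_json(sets_out, out / "detection_sets.json")
        emit("detection_sets.json", out / "detection_sets.json")
        if biotypes is not None:
            comp = detection_sets.biotype_composition(mirna, biotypes, grouping)
            comp.to_csv(out / "biotype_composition.tsv", sep="\t")
            emit("biotype_composition.tsv", out / "biotype_composition.tsv")
        hk = detection_sets.select_housekeeping_candidates(mirna_only)
        record(
            "detection_sets",
            n_detected_3d_ev=len(det.features_in("3D_EV")),
            n_regions=len(partition.regions),
            housekeeping_candidates=hk,
        )

        # ---- differential -------------------------------------------------
        m_cell_fc = differential.fold_change(
            mirna_only,
            _sample_ids(mirna_only, "2D", "cell"),
            _sample_ids(mirna_only, "3D", "cell"),
            zero_policy="epsilon",
        )
        m_ev_fc = differential.fold_change(
            mirna_only,
            _sample_ids(mirna_only, "2D", "EV"),
            _sample_ids(mirna_only, "3D", "EV"),
            zero_policy="epsilon",
        )
        p_ev_fc = differential.fold_change(
            protein,
            _sample_ids(protein, "2D", "EV"),
            _sample_ids(protein, "3D", "EV"),
            zero_policy="epsilon",
        )
        differential.fold_change_frame(m_cell_fc).to_csv(
            out / "mirna_cell_fc.tsv", sep="\t"
        )
        differential.fold_change_frame(p_ev_fc).to_csv(
            out / "protein_ev_fc.tsv", sep="\t"
        )
        top = differential.top_discriminating(
            protein,
            _sample_ids(protein, "2D", "EV"),
            _sample_ids(protein, "3D", "EV"),
            k=min(config.top_k, len(protein.feature_ids)),
        )
        top.to_csv(out / "top_proteins.tsv", sep="\t")
        for name in ("mirna_cell_fc.tsv", "protein_ev_fc.tsv", "top_proteins.tsv"):
            emit(name, out / name)
        n_top_down = int((top["log2fc"] < 0).sum())
        record("differential", top_k=len(top), top_k_downregulated=n_top_down)

        # ---- enrichment ---------------------------------------------------
        if catdb is not None:
            universe = det.features_in("3D_EV")
            query = ev3d_specific & universe
            ora_records = enrichment.ora(query, universe, catdb, alpha=config.alpha)
            pandas.DataFrame([asdict(r) for r in ora_records]).to_csv(
                out / "ora.tsv", sep="\t", index=False
            )
            emit("ora.tsv", out / "ora.tsv")
            universe_matrix = tables_io.ExpressionMatrix(
                mirna_only.data.loc[sorted(universe)].copy(),
                mirna_only.samples,
                mirna_only.unit_label,
            )
            gsea = enrichment.gsea_ranked_mirnas(
                universe_matrix, catdb, rank_by="mean_abundance"
            )
            pandas.DataFrame(
                [
                    {
                        "category_id": r.category_id,
                        "list_size": r.list_size,
                        "members_in_list": r.members_in_list,
                        "rs_max": r.rs_max,
                        "p_exact": r.p_exact,
                    }
                    for r in gsea
                ]
            ).to_csv(out / "gsea.tsv", sep="\t", index=False)
            emit("gsea.tsv", out / "gsea.tsv")
            record(
                "enrichment",
                n_ora_significant=sum(r.significant for r in ora_records),
                n_gsea_significant=sum(r.p_exact < config.alpha for r in gsea),
                universe_size=len(universe),
            )
        else:
            record("enrichment", skipped="no category database supplied")

        # ---- integration network -----------------------------------------
        net = integration_network.build_network(
            m_cell_fc,
            p_ev_fc,
            edges,
            mode=config.network_mode,
            evidence=config.network_evidence,
            min_abs_log2fc=config.min_abs_log2fc,
            mirna_fc_secondary=m_ev_fc,
        )
        clusters = integration_network.extract_clusters(net)
        tables_io.write_json(
            integration_network.network_to_jsonable(net), out / "network.json"
        )
        integration_network.write_graphml(net, out / "network.graphml")
        pandas.DataFrame(
            [
                {"mirna_id": m, "protein_id": p, "evidence": e}
                for m, p, e in net.edges
            ],
            columns=["mirna_id", "protein_id", "evidence"],
        ).to_csv(out / "network_edges.tsv", sep="\t", index=False)
        for name in ("network.json", "network.graphml", "network_edges.tsv"):
            emit(name, out / name)
        net_info: dict[str, Any] = {
            "n_edges": net.graph.number_of_edges(),
            "n_clusters": len(clusters),
        }
        if truth is not None:
            found = {(m, p) for m, p, _ in net.edges}
            planted = {(e.mirna_id, e.protein_id) for e in truth.planted_edges}
            tp = len(found & planted)
            net_info["precision"] = tp / len(found) if found else float("nan")
            net_info["recall"] = tp / len(planted) if planted else float("nan")
        record("integration_network", **net_info)

        # ---- EV yield -----------------------------------------------------
        if yrecords is not None:
            summary = yield_stats.evs_per_cell(yrecords)
            a = [r.ratio for r in yrecords if r.condition == "2D"]
            b = [r.ratio for r in yrecords if r.condition == "3D"]
            test = yield_stats.mann_whitney_exact(a, b)
            yout = {
                "per_condition": summary,
                "mann_whitney": asdict(test),
            }
            tables_io.write_json(yout, out / "ev_yield.json")
            emit("ev_yield.json", out / "ev_yield.json")
            record("ev_yield_stats", p_two_sided=test.p_two_sided, method=test.method)
    except Exception as exc:  # record partial completion, then re-raise
        manifest["stages"]["__failed__"] = {"status": "error", "error": repr(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def demo(out_dir: str | Path, seed: int = 1) -> dict:
    """One-command synthetic demo at spec-default generator settings."""
    cfg = PipelineConfig(out_dir=str(out_dir), seed=seed, synthetic={})
    return run_pipeline(cfg)
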