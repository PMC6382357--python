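"""The 3D-specific miRNA->protein coregulation network.

An edge (miRNA m, protein p) enters the network only when both criteria
hold: (1) the target edge list (miRTarBase-like) links m to p at the
requested evidence level, and (2) their 3D-vs-2D deregulation is
anti-correlated.  With two biological replicates a correlation coefficient
is not meaningful, so the default anti-correlation criterion is
opposite-sign log2 fold changes with a magnitude threshold; a Pearson mode
is available for designs with enough matched samples.  Clusters are the
connected components of the resulting bipartite graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from evintegra.differential import FoldChangeRecord
from evintegra.tables_io import TargetEdge

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeregulationCall:
    """Direction of a feature's 3D-vs-2D change at a magnitude threshold."""

    feature_id: str
    entity: str  # "cell" | "EV"
    log2fc_3d_vs_2d: float
    direction: str  # "up" | "down" | "flat"
    magnitude_threshold: float


@dataclass
class CoregulationNetwork:
    graph: nx.Graph
    mirna_nodes: dict[str, DeregulationCall]
    protein_nodes: dict[str, DeregulationCall]
    provenance: dict = field(default_factory=dict)

    @property
    def edges(self) -> list[tuple[str, str, str]]:
        out = []
        for u, v, attrs in self.graph.edges(data=True):
            m, p = (u, v) if self.graph.nodes[u]["kind"] == "mirna" else (v, u)
            out.append((m, p, attrs["evidence"]))
        return sorted(out)


@dataclass
class Cluster:
    mirnas: list[str]
    proteins: list[str]
    edges: list[tuple[str, str, str]]
    shared_targets: list[str]  # proteins targeted by >1 cluster miRNA

    @property
    def size(self) -> int:
        return len(self.mirnas) + len(self.proteins)


def classify_direction(log2fc: float | None, threshold: float) -> str:
    if log2fc is None or not np.isfinite(log2fc):
        return "flat"
    if log2fc >= threshold:
        return "up"
    if log2fc <= -threshold:
        return "down"
    return "flat"


def _calls(
    records: Sequence[FoldChangeRecord], entity: str, threshold: float
) -> dict[str, DeregulationCall]:
    out = {}
    for r in records:
        out[r.feature_id] = DeregulationCall(
            feature_id=r.feature_id,
            entity=entity,
            log2fc_3d_vs_2d=r.log2fc if r.log2fc is not None else float("nan"),
            direction=classify_direction(r.log2fc, threshold),
            magnitude_threshold=threshold,
        )
    return out


def _combine(
    primary: DeregulationCall, secondary: DeregulationCall | None
) -> DeregulationCall:
    """Require a direction consistent across entities where both are called:
    a strictly opposite secondary direction flattens the call."""
    if secondary is None or secondary.direction == "flat":
        return primary
    if primary.direction == "flat":
        return primary
    if primary.direction != secondary.direction:
        return DeregulationCall(
            primary.feature_id,
            primary.entity,
            primary.log2fc_3d_vs_2d,
            "flat",
            primary.magnitude_threshold,
        )
    return primary


def build_network(
    mirna_fc: Sequence[FoldChangeRecord],
    protein_fc: Sequence[FoldChangeRecord],
    edges: Sequence[TargetEdge],
    mode: str = "opposite_sign",
    evidence: str = "strong_or_weak",
    min_abs_log2fc: float = 0.5,
    mirna_fc_secondary: Sequence[FoldChangeRecord] | None = None,
    mirna_expr: Mapping[str, Sequence[float]] | None = None,
    protein_expr: Mapping[str, Sequence[float]] | None = None,
    r_max: float = -0.5,
) -> CoregulationNetwork:
    """Assemble the bipartite miRNA->protein anti-correlation network.

    ``mirna_fc`` carries the primary miRNA fold changes (typically cells,
    3D over 2D); an optional ``mirna_fc_secondary`` (typically EVs) must
    agree in direction where both are non-flat, otherwise the miRNA is
    called flat.  ``protein_fc`` is the EV proteome.  In "opposite_sign"
    mode an edge survives when both calls are non-flat and strictly
    opposite; in "pearson" mode when the correlation of the matched
    expression vectors is <= ``r_max`` (which must be negative).  Features
    referenced by an edge but absent from the fold-change tables are
    skipped with a log entry.
    """
    if mode not in {"opposite_sign", "pearson"}:
        raise ValueError(f"unknown mode {mode!r}")
    if evidence not in {"strong_only", "strong_or_weak"}:
        raise ValueError(f"unknown evidence filter {evidence!r}")
    if mode == "pearson":
        if mirna_expr is None or protein_expr is None:
            raise ValueError("pearson mode needs mirna_expr and protein_expr")
        if r_max >= 0:
            raise ValueError("r_max must be negative")

    m_calls = _calls(mirna_fc, "cell", min_abs_log2fc)
    if mirna_fc_secondary is not None:
        sec = _calls(mirna_fc_secondary, "EV", min_abs_log2fc)
        m_calls = {f: _combine(c, sec.get(f)) for f, c in m_calls.items()}
    p_calls = _calls(protein_fc, "EV", min_abs_log2fc)

    g = nx.Graph()
    kept_m: dict[str, DeregulationCall] = {}
    kept_p: dict[str, DeregulationCall] = {}
    for e in edges:
        if evidence == "strong_only" and e.evidence != "strong":
            continue
        mc = m_calls.get(e.mirna_id)
        pc = p_calls.get(e.protein_id)
        if mc is None or pc is None:
            logger.info(
                "edge (%s, %s): feature absent from fold-change tables, skipped",
                e.mirna_id,
                e.protein_id,
            )
            continue
        if mode == "opposite_sign":
            ok = (
                mc.direction != "flat"
                and pc.direction != "flat"
                and mc.direction != pc.direction
            )
        else:
            xm = np.asarray(mirna_expr.get(e.mirna_id, ()), dtype=float)
            xp = np.asarray(protein_expr.get(e.protein_id, ()), dtype=float)
            if xm.size != xp.size or xm.size < 4:
                logger.info(
                    "edge (%s, %s): <4 matched samples for pearson, skipped",
                    e.mirna_id,
                    e.protein_id,
                )
                continue
            if xm.std() == 0 or xp.std() == 0:
                continue
            ok = bool(np.corrcoef(xm, xp)[0, 1] <= r_max)
        if ok:
            g.add_node(e.mirna_id, kind="mirna", **_node_attrs(mc))
            g.add_node(e.protein_id, kind="protein", **_node_attrs(pc))
            g.add_edge(e.mirna_id, e.protein_id, evidence=e.evidence, criterion=mode)
            kept_m[e.mirna_id] = mc
            kept_p[e.protein_id] = pc
    return CoregulationNetwork(
        graph=g,
        mirna_nodes=kept_m,
        protein_nodes=kept_p,
        provenance={
            "mode": mode,
            "evidence": evidence,
            "min_abs_log2fc": min_abs_log2fc,
            "r_max": r_max if mode == "pearson" else None,
            "secondary_mirna_fc": mirna_fc_secondary is not None,
        },
    )


def _node_attrs(call: DeregulationCall) -> dict:
    return {
        "log2fc": call.log2fc_3d_vs_2d,
        "direction": call.direction,
        "entity": call.entity,
    }


def extract_clusters(net: CoregulationNetwork) -> list[Cluster]:
    """Connected components of the bipartite graph, largest first (ties by
    lexicographically smallest node)."""
    comps = [set(c) for c in nx.connected_components(net.graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    clusters = []
    for nodes in comps:
        mirnas = sorted(n for n in nodes if net.graph.nodes[n]["kind"] == "mirna")
        proteins = sorted(n for n in nodes if net.graph.nodes[n]["kind"] == "protein")
        edges = []
        for u, v, attrs in net.graph.edges(nodes, data=True):
            m, p = (u, v) if net.graph.nodes[u]["kind"] == "mirna" else (v, u)
            edges.append((m, p, attrs["evidence"]))
        edges = sorted(edges)
        shared = sorted(p for p in proteins if net.graph.degree[p] > 1)
        clusters.append(Cluster(mirnas, proteins, edges, shared))
    return clusters


def network_to_jsonable(net: CoregulationNetwork) -> dict:
    return {
        "provenance": net.provenance,
        "mirna_nodes": {
            m: {"log2fc": c.log2fc_3d_vs_2d, "direction": c.direction}
            for m, c in sorted(net.mirna_nodes.items())
        },
        "protein_nodes": {
            p: {"log2fc": c.log2fc_3d_vs_2d, "direction": c.direction}
            for p, c in sorted(net.protein_nodes.items())
        },
        "edges": [list(e) for e in net.edges],
    }


def write_graphml(net: CoregulationNetwork, path) -> None:
    nx.write_graphml(net.graph, path)
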