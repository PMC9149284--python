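"""Typed regulatory-network assembly, recovery scoring, and graph export.

Edges are directed (regulator -> target) and typed by mechanism:
``tf_binding`` (TF source), ``mirna_cleavage`` (miRNA source), ``lnc_cis``
and ``lnc_trans`` (lncRNA source).  TF targets may themselves be edge
sources, so indirect chains (lncRNA -> TF -> gene) are representable.
Duplicate (source, target, mechanism) triples collapse to the single record
with the strongest evidence (lowest p-value or penalty).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

MECHANISMS = ("tf_binding", "mirna_cleavage", "lnc_cis", "lnc_trans")

#: which source role each mechanism demands
_MECH_SOURCE = {
    "tf_binding": "TF",
    "mirna_cleavage": "miRNA",
    "lnc_cis": "lncRNA",
    "lnc_trans": "lncRNA",
}

_EVIDENCE_KEYS = ("pcc", "pcc_p", "motif_hits", "penalty_score", "coherence")


class NetworkError(ValueError):
    pass


@dataclass
class RegulatoryEdge:
    source_id: str
    target_id: str
    mechanism: str
    source_role: str = ""
    target_role: str = ""
    evidence: dict = field(default_factory=dict)
    support: str = "prediction"  # "experiment" | "prediction"

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise NetworkError(f"unknown mechanism {self.mechanism!r}")
        if self.support not in ("experiment", "prediction"):
            raise NetworkError(f"unknown support {self.support!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source_id, self.target_id, self.mechanism)

    def strength(self) -> float:
        """Lower is stronger; used when collapsing duplicates."""
        if "pcc_p" in self.evidence:
            return float(self.evidence["pcc_p"])
        if "penalty_score" in self.evidence:
            return float(self.evidence["penalty_score"])
        return 0.0


@dataclass
class RegulatoryNetwork:
    nodes: dict[str, str]  # id -> role
    edges: list[RegulatoryEdge]

    def __post_init__(self) -> None:
        for e in self.edges:
            for endpoint in (e.source_id, e.target_id):
                if endpoint not in self.nodes:
                    raise NetworkError(f"edge endpoint {endpoint!r} is not a node")

    def edge_keys(self) -> set[tuple[str, str, str]]:
        return {e.key for e in self.edges}

    def mechanism_counts(self) -> dict[str, int]:
        out = {m: 0 for m in MECHANISMS}
        for e in self.edges:
            out[e.mechanism] += 1
        return out

    def role_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for role in self.nodes.values():
            out[role] = out.get(role, 0) + 1
        return out

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for nid, role in self.nodes.items():
            g.add_node(nid, role=role)
        for e in self.edges:
            attrs = {"mechanism": e.mechanism, "support": e.support}
            for k in _EVIDENCE_KEYS:
                if k in e.evidence and e.evidence[k] is not None:
                    attrs[k] = e.evidence[k]
            g.add_edge(e.source_id, e.target_id, key=e.mechanism, **attrs)
        return g


def assemble_network(
    edges: Iterable[RegulatoryEdge], role_map: Mapping[str, str]
) -> RegulatoryNetwork:
    """Union of accepted pairs as a typed network.

    Endpoint roles come from ``role_map``; a mechanism inconsistent with its
    source role, or two different roles claimed for one id, is an error.
    Duplicates collapse keeping the strongest evidence.  Assembly is
    idempotent: assembling an assembled edge list changes nothing.
    """
    best: dict[tuple[str, str, str], RegulatoryEdge] = {}
    nodes: dict[str, str] = {}
    for e in edges:
        for endpoint in (e.source_id, e.target_id):
            if endpoint not in role_map:
                raise NetworkError(f"no role for feature {endpoint!r}")
            role = role_map[endpoint]
            if nodes.setdefault(endpoint, role) != role:
                raise NetworkError(
                    f"role conflict for {endpoint!r}: "
                    f"{nodes[endpoint]} vs {role}"
                )
        want = _MECH_SOURCE[e.mechanism]
        src_role = role_map[e.source_id]
        if src_role != want:
            raise NetworkError(
                f"mechanism {e.mechanism} requires a {want} source, "
                f"{e.source_id} has role {src_role}"
            )
        e.source_role = src_role
        e.target_role = role_map[e.target_id]
        cur = best.get(e.key)
        if cur is None or e.strength() < cur.strength():
            best[e.key] = e
    ordered = sorted(best.values(), key=lambda e: e.key)
    used = sorted({e.source_id for e in ordered} | {e.target_id for e in ordered})
    return RegulatoryNetwork(nodes={n: nodes[n] for n in used}, edges=ordered)


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


def _prf(tp: int, fp: int, fn: int) -> dict[str, float]:
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision and recall
        else 0.0
    )
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def recovery_metrics(
    predicted: set[tuple[str, str, str]] | RegulatoryNetwork,
    truth: set[tuple[str, str, str]],
) -> dict[str, dict[str, float]]:
    """Precision/recall/F1 overall and per mechanism.

    Edge identity is (source, target, mechanism).  With no predictions
    precision is 0 by convention; F1 is 0 when either component is 0.
    """
    pred = (
        predicted.edge_keys()
        if isinstance(predicted, RegulatoryNetwork)
        else set(predicted)
    )
    out: dict[str, dict[str, float]] = {}
    out["overall"] = _prf(
        len(pred & truth), len(pred - truth), len(truth - pred)
    )
    for mech in MECHANISMS:
        p = {e for e in pred if e[2] == mech}
        t = {e for e in truth if e[2] == mech}
        out[mech] = _prf(len(p & t), len(p - t), len(t - p))
    return out


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

EDGE_TSV_COLUMNS = [
    "source_id",
    "source_role",
    "mechanism",
    "target_id",
    "target_role",
    "support",
    "pcc",
    "pcc_p",
    "motif_hits",
    "penalty_score",
    "coherence",
]


def export_network(network: RegulatoryNetwork, path: str | Path, fmt: str) -> None:
    """Write the network as SIF, GraphML or an edge TSV.

    SIF lines are ``source<TAB>mechanism<TAB>target``; GraphML carries role
    and evidence attributes; the edge TSV round-trips through
    :func:`read_edge_tsv` to the identical edge set.
    """
    path = Path(path)
    if fmt == "SIF":
        lines = [
            f"{e.source_id}\t{e.mechanism}\t{e.target_id}" for e in network.edges
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "GraphML":
        nx.write_graphml(network.to_networkx(), path)
    elif fmt == "TSV":
        rows = []
        for e in network.edges:
            row = {
                "source_id": e.source_id,
                "source_role": e.source_role,
                "mechanism": e.mechanism,
                "target_id": e.target_id,
                "target_role": e.target_role,
                "support": e.support,
            }
            for k in _EVIDENCE_KEYS:
                row[k] = e.evidence.get(k, "")
            rows.append(row)
        pd.DataFrame(rows, columns=EDGE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    else:
        raise NetworkError(f"unknown export format {fmt!r}")


def read_edge_tsv(path: str | Path) -> list[RegulatoryEdge]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    edges = []
    for row in df.itertuples():
        evidence = {}
        for k in _EVIDENCE_KEYS:
            v = getattr(row, k, "")
            if v != "":
                evidence[k] = v
        edges.append(
            RegulatoryEdge(
                source_id=row.source_id,
                target_id=row.target_id,
                mechanism=row.mechanism,
                source_role=row.source_role,
                target_role=row.target_role,
                support=row.support,
                evidence=evidence,
            )
        )
    return edges
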