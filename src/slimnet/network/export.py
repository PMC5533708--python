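"""Network assembly and export (GraphML, SIF, TSV edge list).

Nodes are the two paralog members plus every interactor; edges carry the
evidence class, the mediating site(s), the pathway annotation and — for
inferred edges — the transfer basis.  The TSV form round-trips losslessly.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import networkx as nx

from .inference import BindingSiteAssignment, InferredEdge
from .tables import Interactor, MEMBERS

FORMATS = ("graphml", "sif", "tsv")
MEMBER_LABELS = {"T1": "TANC1", "T2": "TANC2"}


class ExportError(ValueError):
    pass


def build_network(
    interactors: Sequence[Interactor],
    inferred: Sequence[InferredEdge] = (),
    assignments: Sequence[BindingSiteAssignment] = (),
    member_labels: dict[str, str] | None = None,
) -> nx.Graph:
    labels = member_labels or MEMBER_LABELS
    sites = {}
    for a in assignments:
        sites.setdefault((a.interactor, a.member), []).append(a.site)
    graph = nx.Graph()
    for m in MEMBERS:
        graph.add_node(labels[m], node_type="member")
    for i in interactors:
        graph.add_node(i.name, node_type="interactor", pathway=i.pathway)
        for m in i.members:
            graph.add_edge(
                i.name,
                labels[m],
                edge_type="known",
                evidence_class=i.evidence_class,
                site=";".join(sites.get((i.name, m), [])),
                basis="",
                pathway=i.pathway,
            )
    for e in inferred:
        graph.add_edge(
            e.interactor,
            labels[e.to_member],
            edge_type="inferred",
            evidence_class="",
            site=";".join(e.sites),
            basis=e.basis,
            pathway=graph.nodes[e.interactor].get("pathway", ""),
        )
    return graph


def export_network(graph: nx.Graph, path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, data in sorted(graph.edges(data=True)):
                relation = data.get("basis") or data.get("edge_type", "known")
                fh.write(f"{u}\t{relation}\t{v}\n")
            for node in sorted(nx.isolates(graph)):
                fh.write(f"{node}\n")
    elif fmt == "tsv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(
                ["source", "target", "edge_type", "evidence_class", "site", "basis", "pathway"]
            )
            for u, v, data in sorted(graph.edges(data=True)):
                writer.writerow(
                    [
                        u, v,
                        data.get("edge_type", ""),
                        data.get("evidence_class", ""),
                        data.get("site", ""),
                        data.get("basis", ""),
                        data.get("pathway", ""),
                    ]
                )
            for node, data in sorted(graph.nodes(data=True)):
                writer.writerow(
                    ["#node", node, data.get("node_type", ""), "", "", "", data.get("pathway", "")]
                )
    else:
        raise ExportError(f"unknown format {fmt!r} (choose from {FORMATS})")


def load_network_tsv(path: str | Path) -> nx.Graph:
    graph = nx.Graph()
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:2] != ["source", "target"]:
            raise ExportError(f"{path} is not a network TSV")
        for row in reader:
            if row[0] == "#node":
                _, node, node_type, _, _, _, pathway = row
                attrs = {"node_type": node_type}
                if node_type == "interactor":
                    attrs["pathway"] = pathway
                graph.add_node(node, **attrs)
            else:
                source, target, edge_type, evidence_class, site, basis, pathway = row
                graph.add_edge(
                    source,
                    target,
                    edge_type=edge_type,
                    evidence_class=evidence_class,
                    site=site,
                    basis=basis,
                    pathway=pathway,
                )
    return graph
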