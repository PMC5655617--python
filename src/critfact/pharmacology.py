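"""Compound / co-activator / critical-TF tripartite network analysis.

Herbal-preparation compounds are linked to predicted protein targets;
those targets reach critical TFs either directly or through transcriptional
co-activators connected by high-confidence protein-protein interactions
(confidence >= 0.5).  A critical TF reachable from any compound by either
route is nominated as a *final* TF — the drug-actionable subset of the
co-regulated critical TFs.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .transcriptome import DEFlags

log = logging.getLogger(__name__)

DEFAULT_MIN_CONFIDENCE = 0.5


def filter_ppi(ppi: pd.DataFrame, min_confidence: float = DEFAULT_MIN_CONFIDENCE) -> pd.DataFrame:
    """Keep PPI edges with confidence >= *min_confidence* (inclusive).

    Expects columns ``protein_a, protein_b, confidence``; confidences
    outside [0, 1] raise a validation error.
    """
    required = {"protein_a", "protein_b", "confidence"}
    missing = required - set(ppi.columns)
    if missing:
        raise ValueError(f"PPI table missing columns: {sorted(missing)}")
    conf = ppi["confidence"]
    if len(ppi) and ((conf < 0) | (conf > 1)).any():
        bad = ppi[(conf < 0) | (conf > 1)]
        raise ValueError(f"PPI confidences outside [0, 1]:\n{bad.head()}")
    return ppi[conf >= min_confidence].reset_index(drop=True)


def select_coactivators(
    candidate_coactivators: Iterable[str], de_flags: DEFlags
) -> frozenset[str]:
    """Co-activator candidates whose gene is differentially expressed in
    the treated-vs-model transition — the implemented reading of
    "co-expressed with their interacting critical TFs"."""
    de = de_flags.genes
    return frozenset(c for c in candidate_coactivators if c in de)


def build_pharmacology_network(
    compound_targets: pd.DataFrame,
    ppi_filtered: pd.DataFrame,
    critical_tfs: Iterable[str],
    coactivators: Iterable[str],
) -> nx.Graph:
    """Tripartite network of compounds, co-activators and critical TFs.

    Edges are drug-target links from the compound-target table whose target
    is a retained co-activator or a critical TF, plus PPI links between
    co-activators and critical TFs (*ppi_filtered* must already have passed
    :func:`filter_ppi`).  Nodes enter the graph only through an edge, so no
    isolated nodes appear.  Node attribute ``node_type`` is ``compound``,
    ``coactivator`` or ``tf``; edge attribute ``edge_type`` is
    ``drug_target`` or ``ppi`` (the latter with ``confidence``).
    """
    tf_set = set(critical_tfs)
    coact_set = set(coactivators)
    g = nx.Graph()

    ct = compound_targets.drop_duplicates(subset=["compound_id", "target_id"])
    for row in ct.sort_values(["compound_id", "target_id"]).itertuples(index=False):
        target = row.target_id
        if target in tf_set:
            ttype = "tf"
        elif target in coact_set:
            ttype = "coactivator"
        else:
            continue
        g.add_node(row.compound_id, node_type="compound")
        g.add_node(target, node_type=ttype)
        g.add_edge(row.compound_id, target, edge_type="drug_target")

    for row in ppi_filtered.sort_values(["protein_a", "protein_b"]).itertuples(index=False):
        a, b = row.protein_a, row.protein_b
        pair = None
        if a in coact_set and b in tf_set:
            pair = (a, b)
        elif b in coact_set and a in tf_set:
            pair = (b, a)
        if pair is None:
            continue
        coact, tf = pair
        g.add_node(coact, node_type="coactivator")
        g.add_node(tf, node_type="tf")
        g.add_edge(coact, tf, edge_type="ppi", confidence=float(row.confidence))
    return g


def identify_final_tfs(network: nx.Graph) -> frozenset[str]:
    """Critical TFs reachable from a compound either by a direct drug-target
    edge or through a co-activator bridged by a retained PPI edge.

    Marks matching TF nodes with ``final=True`` and ``final_rule`` set to
    ``direct`` or ``via_coactivator`` (direct wins when both apply), and
    returns the set.
    """
    compounds = {n for n, d in network.nodes(data=True) if d.get("node_type") == "compound"}
    final: set[str] = set()
    for tf, data in network.nodes(data=True):
        if data.get("node_type") != "tf":
            continue
        rule = None
        for nb in network.neighbors(tf):
            etype = network.edges[tf, nb].get("edge_type")
            if etype == "drug_target" and nb in compounds:
                rule = "direct"
                break
            if etype == "ppi" and network.nodes[nb].get("node_type") == "coactivator":
                if any(
                    network.edges[nb, nb2].get("edge_type") == "drug_target"
                    for nb2 in network.neighbors(nb)
                    if nb2 in compounds
                ):
                    rule = rule or "via_coactivator"
        if rule is not None:
            network.nodes[tf]["final"] = True
            network.nodes[tf]["final_rule"] = rule
            final.add(tf)
    return frozenset(final)


def network_to_frames(network: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge-list and node-attribute tables, importable by standard graph
    viewers."""
    edges = pd.DataFrame(
        [
            {
                "source": u,
                "target": v,
                "edge_type": d.get("edge_type"),
                "confidence": d.get("confidence"),
            }
            for u, v, d in network.edges(data=True)
        ]
    )
    nodes = pd.DataFrame(
        [
            {
                "node_id": n,
                "node_type": d.get("node_type"),
                "final": bool(d.get("final", False)),
                "final_rule": d.get("final_rule"),
            }
            for n, d in network.nodes(data=True)
        ]
    )
    if len(edges):
        edges = edges.sort_values(["source", "target"], ignore_index=True)
    if len(nodes):
        nodes = nodes.sort_values("node_id", ignore_index=True)
    return edges, nodes
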