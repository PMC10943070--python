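"""Integrated bait-prey proximity network with optional STRING-score edges.

The graph holds one proximity ("bioid") edge per (bait, prey) pair that is
significant in at least one condition, attributed with a condition class
(ca_only | hyper_only | both).  The two plakoglobin termini stay separate
bait nodes.  Known-association ("string") edges from a scored edge table are
added only between node pairs already in the network and classed
high (score >= 0.7) or low (< 0.7).  Exports: SIF, GraphML, edge-table TSV.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .errors import InputError, ParameterError
from .maturation import ProfileSet, dataset_label

HIGH_CONFIDENCE_CUTOFF = 0.7


def build_network(profiles: ProfileSet, calls: pd.DataFrame) -> nx.MultiGraph:
    """One bioid edge per (bait, prey) pair significant in >= 1 condition.

    Bait nodes carry ``is_bait=True``; prey nodes carry their maturation
    category and bait-sharing count from ``calls``.
    """
    net = nx.MultiGraph()
    call_idx = calls.set_index("prey")
    ca_cond, hyper_cond = profiles.conditions
    for bait in profiles.baits:
        net.add_node(bait, is_bait=True)
    for prey in profiles.preys:
        row = call_idx.loc[prey]
        net.add_node(
            prey,
            is_bait=False,
            category=row["category"],
            n_baits=int(row["n_baits"]),
        )
        for bait in profiles.baits:
            in_ca = bool(profiles.binary.at[prey, dataset_label(bait, ca_cond)])
            in_hyper = bool(profiles.binary.at[prey, dataset_label(bait, hyper_cond)])
            if not (in_ca or in_hyper):
                continue
            condition_class = (
                "both" if in_ca and in_hyper else "ca_only" if in_ca else "hyper_only"
            )
            net.add_edge(bait, prey, key="bioid", type="bioid", condition_class=condition_class)
    return net


def bioid_edge_count(net: nx.MultiGraph) -> int:
    return sum(1 for _, _, d in net.edges(data=True) if d.get("type") == "bioid")


def annotate_string_edges(
    net: nx.MultiGraph, string_table: pd.DataFrame, cutoff: float = HIGH_CONFIDENCE_CUTOFF
) -> nx.MultiGraph:
    """Add scored association edges between node pairs already in the network.

    ``string_table`` columns: ``a``, ``b``, ``score`` (combined score scaled
    to [0, 1]).  Edges are classed ``high`` at score >= cutoff (boundary
    inclusive), ``low`` below.  Existing proximity edges are untouched.
    """
    for row in string_table.itertuples(index=False):
        score = float(row.score)
        if not 0.0 <= score <= 1.0:
            raise InputError(f"STRING score outside [0, 1]: {score} ({row.a}-{row.b})")
        if row.a == row.b:
            continue
        if row.a not in net or row.b not in net:
            continue
        confidence = "high" if score >= cutoff else "low"
        net.add_edge(row.a, row.b, key="string", type="string", score=score, confidence=confidence)
    return net


def read_string_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b", "score"])
    df["score"] = pd.to_numeric(df["score"])
    return df


EDGE_TABLE_COLUMNS = ("source", "target", "type", "condition_class", "score", "confidence")


def export_network(net: nx.MultiGraph, path, fmt: str = "tsv") -> None:
    """Write the network as SIF, GraphML or an attribute-preserving edge table."""
    fmt = fmt.lower()
    if fmt == "sif":
        with open(path, "w") as handle:
            for u, v, d in net.edges(data=True):
                handle.write(f"{u}\t{d['type']}\t{v}\n")
    elif fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "tsv":
        rows = []
        for u, v, d in net.edges(data=True):
            rows.append(
                dict(
                    source=u,
                    target=v,
                    type=d.get("type", ""),
                    condition_class=d.get("condition_class", ""),
                    score=d.get("score", ""),
                    confidence=d.get("confidence", ""),
                )
            )
        pd.DataFrame(rows, columns=list(EDGE_TABLE_COLUMNS)).to_csv(path, sep="\t", index=False)
    else:
        raise ParameterError(f"unknown network export format: {fmt!r}")


def import_edge_table(path) -> nx.MultiGraph:
    """Re-import a TSV edge table (round-trips edge multisets and attributes)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    net = nx.MultiGraph()
    for row in df.itertuples(index=False):
        attrs = dict(type=row.type)
        if row.condition_class:
            attrs["condition_class"] = row.condition_class
        if row.score != "":
            attrs["score"] = float(row.score)
        if row.confidence:
            attrs["confidence"] = row.confidence
        net.add_edge(row.source, row.target, key=row.type, **attrs)
    return net
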