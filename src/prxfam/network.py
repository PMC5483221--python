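"""Hub-centred protein-interaction network with co-expression overlay.

Interaction predictions arrive as an edge table (hub, partner, optional
functional class and known-function flag). The network is an undirected
simple graph; duplicate rows collapse into one edge with multiplicity.
Edges between nodes present in an expression compendium are annotated
with the Pearson correlation of the two profiles and flagged
co-expressed when PCC exceeds a strict threshold (default > 0.5); edges
lacking expression data carry an explicit missing token, never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .expression import ConstantProfileError, ExpressionMatrix, pearson

#: Functional-class vocabulary (MapMan-bin-like legend classes).
CLASS_VOCABULARY = (
    "redox",
    "amino-acid metabolism",
    "cell cycle/lipid/photosynthesis/development",
    "DNA synthesis & repair",
    "protein degradation/PTM",
    "RNA/transcription",
    "signaling",
    "abiotic stress",
    "transport",
    "unknown",
    "other",
)

#: Token serialised for a PCC that could not be computed.
MISSING_PCC = "NA"


@dataclass
class InteractionTable:
    """Edge rows (hub, partner) with optional class / known-flag columns."""

    edges: pd.DataFrame  # columns: hub, partner[, class, known]

    def __post_init__(self) -> None:
        required = {"hub", "partner"}
        if not required <= set(self.edges.columns):
            raise ValueError("edge table needs 'hub' and 'partner' columns")

    @classmethod
    def from_tsv(cls, path) -> "InteractionTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def build_network(table: InteractionTable, hubs: list[str]) -> nx.Graph:
    """Undirected simple graph with hub/class/known annotations.

    Self-edges are dropped with a warning; duplicate rows collapse to one
    edge whose ``multiplicity`` records the row count. An unknown class
    label raises, listing the valid vocabulary.
    """
    node_ids = set(table.edges["hub"]) | set(table.edges["partner"])
    unknown_hubs = [h for h in hubs if h not in node_ids]
    if unknown_hubs:
        raise KeyError(f"hubs not in edge table: {unknown_hubs}")
    g = nx.Graph()
    has_class = "class" in table.edges.columns
    has_known = "known" in table.edges.columns
    for _, row in table.edges.iterrows():
        u, v = str(row["hub"]), str(row["partner"])
        if u == v:
            warnings.warn(f"dropping self-edge on {u}", stacklevel=2)
            continue
        if has_class and pd.notna(row["class"]):
            cls = str(row["class"])
            if cls not in CLASS_VOCABULARY:
                raise ValueError(
                    f"unknown class {cls!r}; valid classes: {list(CLASS_VOCABULARY)}"
                )
        else:
            cls = "unknown"
        for node in (u, v):
            if node not in g:
                g.add_node(node, cls="unknown", known=False, hub=False)
        # class/known describe the partner row; hubs keep their own row's class
        g.nodes[v]["cls"] = cls
        if has_known and pd.notna(row["known"]):
            g.nodes[v]["known"] = str(row["known"]).lower() in {"1", "true", "yes"}
        if g.has_edge(u, v):
            g.edges[u, v]["multiplicity"] += 1
        else:
            g.add_edge(u, v, multiplicity=1, pcc=None, coexpressed=False)
    for h in hubs:
        g.nodes[h]["hub"] = True
    return g


def overlay_coexpression(
    g: nx.Graph,
    m: ExpressionMatrix,
    threshold: float = 0.5,
) -> nx.Graph:
    """Annotate each edge with the PCC of its endpoint profiles.

    The co-expressed flag is strict: PCC must exceed ``threshold``
    (a PCC of exactly 0.5 is not flagged). Edges with an endpoint absent
    from the matrix — or with a constant profile — keep ``pcc=None``
    ("no data") and are never flagged.
    """
    genes = set(m.values.index)
    for u, v, data in g.edges(data=True):
        if u in genes and v in genes:
            try:
                r = pearson(
                    m.values.loc[u].to_numpy(dtype=float),
                    m.values.loc[v].to_numpy(dtype=float),
                )
            except ConstantProfileError:
                data["pcc"] = None
                data["coexpressed"] = False
                continue
            data["pcc"] = r
            data["coexpressed"] = bool(r > threshold)
        else:
            data["pcc"] = None
            data["coexpressed"] = False
    return g


@dataclass
class HubSummary:
    """Distinct-partner degrees per hub plus union and row counts."""

    degrees: dict[str, int]
    union: int
    interaction_rows: int

    @property
    def total_degree(self) -> int:
        return sum(self.degrees.values())


def hub_summary(g: nx.Graph) -> HubSummary:
    """Per-hub distinct-partner degree and the distinct-partner union.

    The union counts each partner once however many hubs it touches;
    ``interaction_rows`` additionally reports the raw edge-row total
    (multiplicities included), since interaction databases quote both.
    """
    hubs = sorted(n for n, d in g.nodes(data=True) if d.get("hub"))
    if not hubs:
        raise ValueError("network has no hub nodes")
    degrees: dict[str, int] = {}
    union: set[str] = set()
    for h in hubs:
        partners = {n for n in g.neighbors(h) if n not in hubs}
        degrees[h] = len(partners)
        union |= partners
    rows = sum(d["multiplicity"] for _, _, d in g.edges(data=True))
    return HubSummary(degrees=degrees, union=len(union), interaction_rows=rows)


def _edge_attr_out(value):
    return MISSING_PCC if value is None else value


def export_sif(g: nx.Graph, path) -> None:
    """Cytoscape SIF, one 'pp' line per edge."""
    with open(path, "w") as fh:
        for u, v in sorted(g.edges()):
            fh.write(f"{u}\tpp\t{v}\n")


def export_graphml(g: nx.Graph, path) -> None:
    """GraphML with all node/edge attributes; missing PCC as 'NA'."""
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        out.add_node(n, **d)
    for u, v, d in g.edges(data=True):
        d = dict(d)
        d["pcc"] = _edge_attr_out(d.get("pcc"))
        out.add_edge(u, v, **d)
    nx.write_graphml(out, path)


def import_graphml(path) -> nx.Graph:
    """Inverse of :func:`export_graphml` ('NA' back to None)."""
    g = nx.read_graphml(path)
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        out.add_node(str(n), **d)
    for u, v, d in g.edges(data=True):
        d = dict(d)
        if d.get("pcc") == MISSING_PCC:
            d["pcc"] = None
        if "multiplicity" in d:
            d["multiplicity"] = int(d["multiplicity"])
        out.add_edge(str(u), str(v), **d)
    return out


def export_node_edge_tsv(g: nx.Graph, node_path, edge_path) -> None:
    nodes = pd.DataFrame(
        [
            {"id": n, "class": d.get("cls", "unknown"),
             "known": d.get("known", False), "hub": d.get("hub", False)}
            for n, d in sorted(g.nodes(data=True))
        ]
    )
    edges = pd.DataFrame(
        [
            {"source": u, "target": v,
             "multiplicity": d.get("multiplicity", 1),
             "pcc": _edge_attr_out(d.get("pcc")),
             "coexpressed": d.get("coexpressed", False)}
            for u, v, d in sorted(g.edges(data=True))
        ]
    )
    nodes.to_csv(node_path, sep="\t", index=False)
    edges.to_csv(edge_path, sep="\t", index=False)


def export_network(g: nx.Graph, fmt: str, path, edge_path=None) -> None:
    """Dispatch to one of the supported export formats."""
    if fmt == "sif":
        export_sif(g, path)
    elif fmt == "graphml":
        export_graphml(g, path)
    elif fmt == "tsv":
        if edge_path is None:
            raise ValueError("tsv export needs both node and edge paths")
        export_node_edge_tsv(g, path, edge_path)
    else:
        raise ValueError(f"unsupported format {fmt!r} (sif, graphml, tsv)")
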