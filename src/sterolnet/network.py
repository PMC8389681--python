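"""Enzyme–partner network assembly, unique/common partner classification
and standard graph exports.

Partners bound by a single target enzyme are "unique" (List A); the full
partner set including multi-enzyme "common" partners is List B.  Common
partners act as connectors between sub-interactomes: tier2 connectors
bridge exactly two enzymes, tier3plus bridge three or more.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .consensus import ConfigurationError, ConsensusEdge

__all__ = [
    "PartnerClassification",
    "classify_partners",
    "partner_lists",
    "venn_partition",
    "build_network",
    "export_network",
    "import_network",
    "network_summary",
]


@dataclass(frozen=True)
class PartnerClassification:
    partner: str
    enzyme_degree: int
    # common_threshold is configurable in classify_partners; with the
    # default of 2 the tiers are tier2 (=2 enzymes) / tier3plus (>=3)
    partner_class: str  # {"unique", "common"}
    connector_tier: str  # {"none", "tier2", "tier3plus"}


def _enzyme_sets(edges: list[ConsensusEdge]) -> dict[str, set[str]]:
    by_partner: dict[str, set[str]] = defaultdict(set)
    for e in edges:
        by_partner[e.partner].add(e.enzyme)
    return by_partner


def classify_partners(
    edges: list[ConsensusEdge], common_threshold: int = 2
) -> list[PartnerClassification]:
    """Classify each partner by the number of distinct enzymes it binds."""
    if common_threshold < 2:
        raise ConfigurationError("common_threshold must be >= 2")
    out = []
    for partner, enzymes in sorted(_enzyme_sets(edges).items()):
        deg = len(enzymes)
        cls = "common" if deg >= common_threshold else "unique"
        tier = "none" if deg < 2 else ("tier2" if deg == 2 else "tier3plus")
        out.append(PartnerClassification(partner, deg, cls, tier))
    return out


def partner_lists(classifications: list[PartnerClassification]) -> dict[str, list[str]]:
    """List A (unique partners) and List B (all partners)."""
    unique = sorted(c.partner for c in classifications if c.partner_class == "unique")
    common = sorted(c.partner for c in classifications if c.partner_class == "common")
    return {"list_a": unique, "list_b": unique + common, "common": common}


def venn_partition(
    edges: list[ConsensusEdge], enzymes: list[str]
) -> dict[frozenset[str], set[str]]:
    """Sparse Venn cells: membership pattern -> partners with that pattern.

    Only occupied cells are returned, so the enumeration stays linear in
    the number of partners even for 17 enzymes.
    """
    if len(enzymes) > 30:
        raise ConfigurationError("venn_partition supports at most 30 enzymes")
    enzyme_set = set(enzymes)
    cells: dict[frozenset[str], set[str]] = defaultdict(set)
    for partner, bound in _enzyme_sets(edges).items():
        pattern = frozenset(bound & enzyme_set)
        if pattern:
            cells[pattern].add(partner)
    return dict(cells)


def build_network(
    edges: list[ConsensusEdge],
    localization_status: dict[tuple[str, str], str] | None = None,
) -> nx.Graph:
    """Assemble the bipartite enzyme–partner graph with edge provenance."""
    g = nx.Graph()
    classifications = {c.partner: c for c in classify_partners(edges)}
    for e in edges:
        g.add_node(e.enzyme, role="enzyme")
        if e.partner not in g or g.nodes[e.partner].get("role") != "enzyme":
            cls = classifications.get(e.partner)
            g.add_node(
                e.partner,
                role="partner",
                partner_class=cls.partner_class if cls else "unique",
                connector_tier=cls.connector_tier if cls else "none",
            )
        status = (localization_status or {}).get(e.pair, "")
        g.add_edge(
            e.enzyme,
            e.partner,
            n_sources=e.n_sources,
            sources=";".join(sorted(e.supporting_sources)),
            localization_pass=status,
            is_enzyme_enzyme=e.is_enzyme_enzyme,
        )
    return g


def export_network(network: nx.Graph, path: str | Path, fmt: str) -> Path:
    """Write the network as SIF, GraphML or an edge TSV.

    Exports are round-trip safe: re-importing yields an isomorphic graph
    with identical attributes (SIF keeps topology only, by design of the
    format).
    """
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(network.edges()):
                fh.write(f"{u}\tpp\t{v}\n")
            for node in sorted(n for n in network.nodes() if network.degree(n) == 0):
                fh.write(f"{node}\n")
    elif fmt == "graphml":
        nx.write_graphml(network, path)
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("enzyme\tpartner\tn_sources\tsources\tlocalization_pass\tis_enzyme_enzyme\n")
            for u, v, data in sorted(network.edges(data=True)):
                fh.write(
                    f"{u}\t{v}\t{data.get('n_sources', '')}\t{data.get('sources', '')}"
                    f"\t{data.get('localization_pass', '')}\t{data.get('is_enzyme_enzyme', '')}\n"
                )
    else:
        raise ConfigurationError(f"unknown export format {fmt!r}")
    return path


def import_network(path: str | Path, fmt: str) -> nx.Graph:
    path = Path(path)
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "sif":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                cols = line.rstrip("\n").split("\t")
                if len(cols) >= 3:
                    g.add_edge(cols[0], cols[2])
                elif cols[0]:
                    g.add_node(cols[0])
        return g
    if fmt == "tsv":
        g = nx.Graph()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                cols = dict(zip(header, line.rstrip("\n").split("\t")))
                g.add_edge(
                    cols["enzyme"],
                    cols["partner"],
                    n_sources=int(cols["n_sources"]) if cols["n_sources"] else None,
                    sources=cols["sources"],
                    localization_pass=cols["localization_pass"],
                    is_enzyme_enzyme=cols["is_enzyme_enzyme"] == "True",
                )
        return g
    raise ConfigurationError(f"unknown import format {fmt!r}")


def network_summary(edges: list[ConsensusEdge]) -> dict:
    classifications = classify_partners(edges)
    lists = partner_lists(classifications)
    tiers = defaultdict(int)
    for c in classifications:
        tiers[c.connector_tier] += 1
    return {
        "n_enzymes": len({e.enzyme for e in edges}),
        "n_partners": len(classifications),
        "n_unique": len(lists["list_a"]),
        "n_common": len(lists["common"]),
        "tiers": dict(tiers),
    }
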