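"""Bipartite disease-chemical network construction and export.

The disease-similarity layer's retained associations form a bipartite
graph: one node per related disease, one per chemical with at least one
retained association, edges typed by evidence (marker/mechanism,
therapeutic, literature-inferred).  Parallel edges of different
evidence types are kept distinct; same-type duplicates collapse.
Exports target Cytoscape-readable formats (SIF, GraphML, TSV edge
list).  The chemical-gene incidence matrix behind the heatmap view is
exported plot-ready; rendering is left to plotting packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .records import (
    ChemicalDiseaseAssociation,
    ChemicalProteinInteraction,
    RelatedDiseaseSet,
)

__all__ = [
    "BipartiteNetwork",
    "build_network",
    "degree_clusters",
    "export_network",
    "import_network_tsv",
    "chemical_gene_matrix",
]

EXPORT_FORMATS = ("sif", "graphml", "tsv")


@dataclass
class BipartiteNetwork:
    disease_nodes: set[str]
    chemical_nodes: set[str]
    edges: list[tuple[str, str, str]]  # (chemical, disease, evidence_type)

    def __post_init__(self) -> None:
        for chem, dis, _ in self.edges:
            if chem not in self.chemical_nodes or dis not in self.disease_nodes:
                raise ValueError(f"edge ({chem}, {dis}) references unknown node")
        if self.disease_nodes & self.chemical_nodes:
            raise ValueError("a node cannot be both a disease and a chemical")

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for d in sorted(self.disease_nodes):
            g.add_node(d, node_type="disease", bipartite=0)
        for c in sorted(self.chemical_nodes):
            g.add_node(c, node_type="chemical", bipartite=1)
        for chem, dis, ev in self.edges:
            g.add_edge(chem, dis, evidence_type=ev)
        return g


def build_network(
    associations: list[ChemicalDiseaseAssociation], related: RelatedDiseaseSet
) -> BipartiteNetwork:
    """Build the bipartite network from already-filtered associations.

    Every related disease becomes a node even if unlinked; chemicals
    appear only with at least one retained association.  Edges are
    (chemical, disease, evidence_type) triples, deduplicated, in
    deterministic sorted order.
    """
    edges = sorted(
        {
            (a.chemical_id, a.disease_id, a.evidence_type)
            for a in associations
            if a.disease_id in related.members
        }
    )
    return BipartiteNetwork(
        disease_nodes=set(related.members),
        chemical_nodes={chem for chem, _, _ in edges},
        edges=edges,
    )


def degree_clusters(net: BipartiteNetwork) -> dict[int, list[str]]:
    """Group chemicals by their number of distinct disease neighbours,
    name-sorted within each group (the colour clusters of the network
    figure: chemicals touching five diseases, four diseases, ...)."""
    neighbours: dict[str, set[str]] = {}
    for chem, dis, _ in net.edges:
        neighbours.setdefault(chem, set()).add(dis)
    clusters: dict[int, list[str]] = {}
    for chem, ds in neighbours.items():
        clusters.setdefault(len(ds), []).append(chem)
    return {deg: sorted(chems) for deg, chems in sorted(clusters.items())}


def export_network(net: BipartiteNetwork, path: str | Path, format: str = "sif") -> None:
    """Serialise the network as SIF, GraphML or a TSV edge list."""
    path = Path(path)
    if format == "sif":
        with open(path, "w") as fh:
            for chem, dis, ev in net.edges:
                fh.write(f"{chem}\t{ev}\t{dis}\n")
    elif format == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("chemical\tdisease\tevidence_type\n")
            for chem, dis, ev in net.edges:
                fh.write(f"{chem}\t{dis}\t{ev}\n")
            # isolated diseases are preserved as node-only rows
            linked = {dis for _, dis, _ in net.edges}
            for dis in sorted(net.disease_nodes - linked):
                fh.write(f"\t{dis}\t\n")
    else:
        raise ValueError(f"unknown format {format!r}; choose from {EXPORT_FORMATS}")


def import_network_tsv(path: str | Path) -> BipartiteNetwork:
    """Rebuild a network from its own TSV export (round-trip identity)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    edges = []
    diseases, chemicals = set(), set()
    for row in df.itertuples(index=False):
        diseases.add(row.disease)
        if row.chemical:
            chemicals.add(row.chemical)
            edges.append((row.chemical, row.disease, row.evidence_type))
    return BipartiteNetwork(disease_nodes=diseases, chemical_nodes=chemicals, edges=sorted(edges))


def chemical_gene_matrix(
    interactions: list[ChemicalProteinInteraction],
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Binary chemicals-by-genes incidence matrix (heatmap-ready).

    Rows are chemicals, columns genes, both sorted lexicographically;
    duplicate interaction rows still yield a single 1.  Written as TSV
    when ``path`` is given.
    """
    pairs = sorted({(i.chemical_id, i.gene_symbol) for i in interactions})
    chems = sorted({c for c, _ in pairs})
    genes = sorted({g for _, g in pairs})
    mat = pd.DataFrame(0, index=chems, columns=genes, dtype=int)
    for chem, gene in pairs:
        mat.at[chem, gene] = 1
    mat.index.name = "chemical"
    if path is not None:
        mat.to_csv(path, sep="\t")
    return mat
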