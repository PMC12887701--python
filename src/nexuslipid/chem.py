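"""Chemical-gene interaction networks: hub identification, community
structure, and cross-disease convergence on prioritized genes.

Hub degree counts *distinct prioritized genes* (a chemical with three
action rows on one gene has degree 1); interaction directions are
collapsed before counting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HubChemical:
    chemical: str
    degree: int
    rank: int


def dedupe_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Enforce (chemical_id, gene, action) uniqueness."""
    return edges.drop_duplicates(subset=["chemical_id", "gene_symbol", "action"])


def hub_chemicals(edges: pd.DataFrame, prioritized: set[str],
                  top_n: int = 5) -> list[HubChemical]:
    """Top chemicals by number of distinct prioritized gene targets.

    Sorted by degree descending, ties by chemical name ascending; ranks are
    contiguous from 1.  Returns an empty list (with a warning) when no
    chemical touches the prioritized set.
    """
    if not prioritized:
        raise ValueError("hub_chemicals: prioritized gene set is empty")
    sub = dedupe_edges(edges)
    sub = sub[sub["gene_symbol"].isin(prioritized)]
    if sub.empty:
        warnings.warn("hub_chemicals: no chemical interacts with the prioritized set")
        return []
    degrees = sub.groupby("chemical_name")["gene_symbol"].nunique()
    ordered = degrees.reset_index().sort_values(
        ["gene_symbol", "chemical_name"], ascending=[False, True],
        kind="mergesort")
    return [HubChemical(chemical=row.chemical_name, degree=int(row.gene_symbol),
                        rank=i + 1)
            for i, row in enumerate(ordered.head(top_n).itertuples(index=False))]


def build_bipartite(edges: pd.DataFrame) -> nx.Graph:
    """Simple undirected bipartite graph (chemical vs gene node sets)."""
    g = nx.Graph()
    for row in dedupe_edges(edges).itertuples(index=False):
        g.add_node(row.chemical_name, kind="chemical")
        g.add_node(row.gene_symbol, kind="gene")
        g.add_edge(row.chemical_name, row.gene_symbol)
    return g


def communities(edges: pd.DataFrame, seed: int = 0,
                resolution: float = 1.0) -> dict[str, int]:
    """Louvain communities on the bipartite graph (treated as simple
    undirected); deterministic given the seed.  Ids are integers from 1
    assigned in sorted order of each community's first node."""
    g = build_bipartite(edges)
    if g.number_of_nodes() == 0:
        raise ValueError("communities: graph is empty")
    parts = nx.community.louvain_communities(g, seed=seed, resolution=resolution)
    assignment: dict[str, int] = {}
    for part in parts:
        for node in part:
            assignment[node] = id(part)  # placeholder, relabeled below
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for node in sorted(assignment):
        c = assignment[node]
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        out[node] = relabel[c]
    return out


def integrate_bipartite(per_disease: dict[str, tuple[list[HubChemical], pd.DataFrame]]
                        ) -> tuple[nx.Graph, pd.DataFrame]:
    """Union the per-disease hub subnetworks into one bipartite network.

    ``per_disease`` maps disease context -> (selected hubs, full edge
    table).  Only edges incident to a selected hub are included; each edge
    records its provenance (set of disease contexts).  Convergence(g) is
    the number of distinct selected chemicals targeting gene g, counting a
    chemical once even if selected for several diseases.
    """
    if not per_disease:
        raise ValueError("integrate_bipartite: no disease contexts")
    g = nx.Graph()
    selected_all: set[str] = set()
    for disease, (hubs, edges) in per_disease.items():
        hub_names = {h.chemical for h in hubs}
        selected_all |= hub_names
        sub = dedupe_edges(edges)
        sub = sub[sub["chemical_name"].isin(hub_names)]
        for row in sub.itertuples(index=False):
            if g.has_edge(row.chemical_name, row.gene_symbol):
                g[row.chemical_name][row.gene_symbol]["diseases"].add(disease)
            else:
                g.add_node(row.chemical_name, kind="chemical")
                g.add_node(row.gene_symbol, kind="gene")
                g.add_edge(row.chemical_name, row.gene_symbol, diseases={disease})

    rows = []
    for node, data in g.nodes(data=True):
        if data.get("kind") != "gene":
            continue
        chems = {nb for nb in g.neighbors(node)}
        rows.append({"gene": node, "convergence": len(chems & selected_all)})
    conv = (pd.DataFrame(rows, columns=["gene", "convergence"])
            .sort_values(["convergence", "gene"], ascending=[False, True],
                         kind="mergesort")
            .reset_index(drop=True))
    return g, conv


def gene_connectivity(edges: pd.DataFrame, genes=None) -> pd.Series:
    """Distinct interacting chemicals per gene (0 for listed genes with no
    edges when ``genes`` is given)."""
    sub = dedupe_edges(edges)
    counts = sub.groupby("gene_symbol")["chemical_name"].nunique()
    if genes is not None:
        counts = counts.reindex(list(genes), fill_value=0)
    counts.index.name = "gene"
    return counts.rename("connectivity").astype(int)
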