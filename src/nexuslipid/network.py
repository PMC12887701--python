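"""Trait-level causal graph, module detection, bidirectional filtering,
instrument prioritization and positional gene mapping.

The directed trait graph is projected to a weighted undirected graph for
community detection (weight = number of parallel qualified results), since
random-walk communities are defined on undirected graphs.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoreRelationship:
    exposure: str
    outcome: str
    module_id: int


def build_trait_graph(associations) -> nx.DiGraph:
    """Directed trait graph from forward qualified associations.

    One edge per qualified (exposure, outcome) pair; duplicates from
    multiple sources collapse into an integer ``weight`` attribute.
    Non-qualified or reverse-direction inputs are ignored.
    """
    g = nx.DiGraph()
    n_used = 0
    for a in associations:
        if not a.qualified or a.direction != "forward":
            continue
        if a.exposure == a.outcome:
            continue
        n_used += 1
        if g.has_edge(a.exposure, a.outcome):
            g[a.exposure][a.outcome]["weight"] += 1
            g[a.exposure][a.outcome]["sources"].append(a.source)
        else:
            g.add_edge(a.exposure, a.outcome, weight=1,
                       beta=a.estimate.beta_hat, pval=a.estimate.pval,
                       sources=[a.source])
    if n_used == 0:
        log.warning("build_trait_graph: zero qualified forward associations")
    return g


def detect_modules(graph: nx.DiGraph | nx.Graph, walk_steps: int = 4,
                   seed: int = 0, weighted: bool = True) -> dict[str, int]:
    """Random-walk (Walktrap) communities on the undirected projection.

    The dendrogram is cut at maximum modularity; isolated nodes become
    singleton modules.  Module ids are integers from 1, assigned in
    sorted-trait order of each module's first member.  Walktrap itself is
    deterministic; ``seed`` is accepted for interface uniformity.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("detect_modules: graph is empty")
    und = graph.to_undirected() if graph.is_directed() else graph
    nodes = sorted(und.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in und.edges]
    weights = [float(und[u][v].get("weight", 1.0)) for u, v in und.edges] \
        if weighted else None

    g = ig.Graph(n=len(nodes), edges=edges)
    if edges:
        dendro = g.community_walktrap(weights=weights, steps=walk_steps)
        clustering = dendro.as_clustering()
        membership = clustering.membership
    else:
        membership = list(range(len(nodes)))

    # relabel communities 1..K by order of first appearance over sorted nodes
    relabel: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for n in nodes:
        c = membership[index[n]]
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        assignment[n] = relabel[c]
    return assignment


def core_relationships(graph: nx.DiGraph,
                       modules: dict[str, int]) -> set[CoreRelationship]:
    """Edges whose endpoints share a module."""
    uncovered = set(graph.nodes) - set(modules)
    if uncovered:
        raise ValueError(f"module assignment does not cover nodes: {sorted(uncovered)}")
    return {CoreRelationship(u, v, modules[u])
            for u, v in graph.edges if modules[u] == modules[v]}


def filter_bidirectional(forward, reverse, core: set[CoreRelationship]):
    """Keep forward pairs in the core and reverse pairs exactly inverting one."""
    core_pairs = {(c.exposure, c.outcome) for c in core}
    kept_forward = [a for a in forward if (a.exposure, a.outcome) in core_pairs]
    kept_reverse = [a for a in reverse if (a.outcome, a.exposure) in core_pairs]
    return kept_forward, kept_reverse


def snp_frequency(associations) -> pd.DataFrame:
    """Count, per (source, direction), the distinct module-supported
    relationships in which each SNP served as an instrument.

    Input associations must carry their post-filter instrument lists.
    Rankings are per stratum, ties broken by snp_id lexicographic order.
    """
    counts: Counter[tuple[str, str, str]] = Counter()
    for a in associations:
        for snp in set(a.instruments):
            counts[(snp, a.source, a.direction)] += 1
    rows = [{"snp": s, "source": src, "direction": d, "frequency": f}
            for (s, src, d), f in counts.items()]
    df = pd.DataFrame(rows, columns=["snp", "source", "direction", "frequency"])
    if df.empty:
        return df
    df = df.sort_values(["source", "direction", "frequency", "snp"],
                        ascending=[True, True, False, True]).reset_index(drop=True)
    df["rank"] = df.groupby(["source", "direction"]).cumcount() + 1
    return df


def _norm_chr(c: str) -> str:
    c = str(c)
    if c.lower().startswith("chr"):
        log.info("normalizing chromosome name %r", c)
        c = c[3:]
    return c


def map_genes(snps: pd.DataFrame, annotation: pd.DataFrame,
              flank_kb: float = 50.0) -> pd.DataFrame:
    """Nearest-gene assignment within a flanking window.

    ``snps`` needs columns snp/chr/pos (pos 1-based); ``annotation`` is a
    BED frame (0-based half-open).  Distance is 0 when the SNP lies inside
    the gene, else the gap to the nearest interval boundary; the
    minimum-distance gene is assigned iff distance <= flank_kb*1000.  Ties
    are broken by smaller start, then gene symbol.  Unmapped SNPs appear
    with gene=NA.
    """
    ann = annotation.copy()
    ann["chr"] = ann["chr"].map(_norm_chr)
    max_gap = flank_kb * 1000.0
    by_chr = {c: sub.sort_values(["start", "gene"]) for c, sub in ann.groupby("chr")}

    rows = []
    for _, row in snps.iterrows():
        c = _norm_chr(row["chr"])
        p0 = int(row["pos"]) - 1  # 1-based point -> 0-based
        best = None  # (distance, start, gene)
        for _, g in by_chr.get(c, pd.DataFrame(columns=ann.columns)).iterrows():
            if g["start"] <= p0 < g["end"]:
                d = 0
            elif p0 < g["start"]:
                d = g["start"] - p0
            else:
                d = p0 - (g["end"] - 1)
            key = (d, g["start"], g["gene"])
            if best is None or key < best:
                best = key
        if best is not None and best[0] <= max_gap:
            rows.append({"snp": row["snp"], "gene": best[2], "distance": int(best[0])})
        else:
            rows.append({"snp": row["snp"], "gene": pd.NA, "distance": pd.NA})
    return pd.DataFrame(rows, columns=["snp", "gene", "distance"])


def shared_snp_analysis(named_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Upset-style membership table over named SNP sets.

    Returns one row per non-empty pathway combination with its exclusive
    SNP count and members.
    """
    if len(named_sets) < 2:
        raise ValueError("shared_snp_analysis requires >= 2 named sets")
    names = sorted(named_sets)
    membership: dict[str, tuple[str, ...]] = {}
    for snp in set().union(*named_sets.values()):
        combo = tuple(n for n in names if snp in named_sets[n])
        membership.setdefault(combo, ())
        membership[combo] += (snp,)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            snps = sorted(membership.get(combo, ()))
            if snps:
                rows.append({"pathways": "&".join(combo), "n_pathways": r,
                             "count": len(snps), "snps": ",".join(snps)})
    return pd.DataFrame(rows, columns=["pathways", "n_pathways", "count", "snps"])
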