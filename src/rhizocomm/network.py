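"""Spearman co-occurrence networks, topology metrics and Zi-Pi node roles.

Edges connect prevalent taxa whose abundance profiles are strongly
rank-correlated: |rho| >= 0.7 and raw p <= 0.01 by default (negative
correlations are kept as negative edges).  Node roles follow the classic
within-module degree (Zi) / participation coefficient (Pi) scheme with
thresholds Zi = 2.5 and Pi = 0.62: module hubs and connectors are the
keystone candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from rhizocomm.matrix import CommunityMatrix, TaxonomyTable, prevalence_filter

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62

ROLE_PERIPHERAL = "peripheral"
ROLE_CONNECTOR = "connector"
ROLE_MODULE_HUB = "module hub"
ROLE_NETWORK_HUB = "network hub"


@dataclass
class CooccurrenceNetwork:
    """Thresholded signed Spearman graph over prevalent taxa."""

    graph: nx.Graph  # edge attrs: rho, p; node attrs: abundance, phylum
    rho_min: float
    p_max: float
    prevalence: float
    modules: dict | None = None  # taxon -> module index
    modularity: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "taxon_i": u,
                "taxon_j": v,
                "rho": d["rho"],
                "p": d["p"],
                "sign": "+" if d["rho"] > 0 else "-",
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows, columns=["taxon_i", "taxon_j", "rho", "p", "sign"]
        )


def spearman_edges(
    values: np.ndarray, rho_min: float, p_max: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs Spearman (midrank ties) and the thresholded edge mask.

    Returns the rho and p matrices and a boolean upper-triangular mask of
    pairs with |rho| >= rho_min and p <= p_max (raw p from the
    t-distribution approximation, no multiple-testing correction).
    """
    n_taxa = values.shape[0]
    rho, p = stats.spearmanr(values.T)
    if n_taxa == 2:  # scipy returns scalars for a single pair
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    rho = np.atleast_2d(rho)
    p = np.atleast_2d(p)
    mask = (np.abs(rho) >= rho_min) & (p <= p_max)
    np.fill_diagonal(mask, False)
    mask &= np.triu(np.ones((n_taxa, n_taxa), dtype=bool), k=1)
    return rho, p, mask


def build_network(
    m: CommunityMatrix,
    prevalence: float = 0.5,
    rho_min: float = 0.7,
    p_max: float = 0.01,
    taxonomy: TaxonomyTable | None = None,
) -> CooccurrenceNetwork:
    """Build the thresholded co-occurrence graph for one sample group.

    Taxa present in over ``prevalence`` of samples are correlated all
    against all (Spearman, midrank ties); surviving edges need
    |rho| >= ``rho_min`` and raw p <= ``p_max``.  Only edge-incident taxa
    become nodes.  Taxa with constant abundance after filtering have
    undefined correlations and are excluded with a warning.
    """
    if m.shape[1] < 4:
        raise ValueError("need at least 4 samples for meaningful Spearman p")
    kept = prevalence_filter(m, prevalence)
    rel = kept.data.div(m.data.sum(axis=0), axis=1)
    values = rel.to_numpy(float)
    constant = values.std(axis=1) == 0
    if constant.any():
        dropped = [t for t, c in zip(kept.taxon_ids, constant) if c]
        warnings.warn(
            f"excluding {len(dropped)} constant taxa with undefined "
            f"correlations (e.g. {dropped[:3]})",
            stacklevel=2,
        )
        rel = rel.loc[~constant]
        values = rel.to_numpy(float)
    taxa = list(rel.index)
    graph = nx.Graph()
    if len(taxa) >= 2:
        rho, p, mask = spearman_edges(values, rho_min, p_max)
        mean_abund = rel.mean(axis=1)
        phylum = taxonomy.phylum() if taxonomy is not None else None
        for i, j in zip(*np.nonzero(mask)):
            u, v = taxa[i], taxa[j]
            for node in (u, v):
                if node not in graph:
                    graph.add_node(
                        node,
                        abundance=float(mean_abund[node]),
                        phylum=(
                            str(phylum.get(node, ""))
                            if phylum is not None
                            else ""
                        ),
                    )
            graph.add_edge(u, v, rho=float(rho[i, j]), p=float(p[i, j]))
    return CooccurrenceNetwork(graph, rho_min, p_max, prevalence)


def detect_modules(
    g: CooccurrenceNetwork, method: str = "greedy", seed: int = 0
) -> tuple[dict, float]:
    """Modularity-maximizing partition on the unsigned (|rho|) graph.

    Greedy modularity (the default) is deterministic; Louvain is available
    behind the seed.  Returns (taxon -> module index, Q) and stores both on
    the network.
    """
    if g.n_edges < 1:
        raise ValueError("module detection needs at least one edge")
    work = nx.Graph()
    work.add_nodes_from(g.graph.nodes)
    for u, v, d in g.graph.edges(data=True):
        work.add_edge(u, v, weight=abs(d["rho"]))
    if method == "greedy":
        communities = nx.community.greedy_modularity_communities(
            work, weight="weight"
        )
    elif method == "louvain":
        communities = nx.community.louvain_communities(
            work, weight="weight", seed=seed
        )
    else:
        raise ValueError("method must be 'greedy' or 'louvain'")
    modules = {}
    for idx, comm in enumerate(communities):
        for node in comm:
            modules[node] = idx
    q = nx.community.modularity(work, communities, weight="weight")
    g.modules = modules
    g.modularity = float(q)
    return modules, float(q)


def topology_metrics(g: CooccurrenceNetwork) -> dict:
    """Graph-level topology record.

    * nodes/edges on the thresholded graph (edge-incident vertices only)
    * average degree = 2E / N
    * number of clusters = connected components
    * average clustering coefficient (unweighted, mean over nodes)
    * average path distance within the largest component (unweighted)
    * modularity Q of the detected partition (detected if absent)
    * connectedness = 1 - components / nodes
    * positive/negative link ratio (inf when no negative edges)
    """
    graph = g.graph
    n, e = g.n_nodes, g.n_edges
    if n == 0:
        raise ValueError("empty network")
    components = list(nx.connected_components(graph))
    n_comp = len(components)
    largest = graph.subgraph(max(components, key=len))
    if largest.number_of_nodes() > 1:
        avg_path = nx.average_shortest_path_length(largest)
    else:
        warnings.warn(
            "largest component is a single node; path distance reported as 0",
            stacklevel=2,
        )
        avg_path = 0.0
    if g.modularity is None:
        detect_modules(g)
    pos = sum(1 for _, _, d in graph.edges(data=True) if d["rho"] > 0)
    neg = e - pos
    ratio = pos / neg if neg > 0 else float("inf")
    return {
        "total_nodes": n,
        "total_edges": e,
        "average_degree": 2.0 * e / n,
        "n_clusters": n_comp,
        "average_clustering_coefficient": nx.average_clustering(graph),
        "average_path_distance": float(avg_path),
        "modularity": g.modularity,
        "n_modules": len(set(g.modules.values())),
        "connectedness": 1.0 - n_comp / n,
        "positive_negative_ratio": ratio,
    }


@dataclass
class NodeRole:
    taxon_id: str
    zi: float
    pi: float
    role: str
    module: int
    degree: int


def zi_pi(g: CooccurrenceNetwork, modules: dict | None = None) -> list[NodeRole]:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardizes a node's within-module degree against its module's
    mean and standard deviation (0 when the sd is 0); Pi = 1 - sum over
    modules s of (k_is / k_i)^2.  Roles: module hub (Zi > 2.5, Pi <= 0.62),
    connector (Zi <= 2.5, Pi > 0.62), network hub (both exceeded),
    peripheral otherwise.  Isolated nodes are excluded with a warning.
    """
    if modules is None:
        if g.modules is None:
            detect_modules(g)
        modules = g.modules
    graph = g.graph
    unassigned = [v for v in graph.nodes if v not in modules]
    if unassigned:
        raise ValueError(f"nodes without module assignment: {unassigned[:5]}")

    within_degree = {}
    for v in graph.nodes:
        own = modules[v]
        within_degree[v] = sum(
            1 for u in graph.neighbors(v) if modules[u] == own
        )
    by_module: dict[int, list] = {}
    for v in graph.nodes:
        by_module.setdefault(modules[v], []).append(v)
    module_stats = {}
    for mod, members in by_module.items():
        kd = np.array([within_degree[v] for v in members], dtype=float)
        module_stats[mod] = (kd.mean(), kd.std(ddof=0))

    roles = []
    for v in graph.nodes:
        k = graph.degree(v)
        if k == 0:
            warnings.warn(f"isolated node {v!r} excluded from Zi-Pi", stacklevel=2)
            continue
        mean_k, sd_k = module_stats[modules[v]]
        zi = (within_degree[v] - mean_k) / sd_k if sd_k > 0 else 0.0
        per_module: dict[int, int] = {}
        for u in graph.neighbors(v):
            per_module[modules[u]] = per_module.get(modules[u], 0) + 1
        pi = 1.0 - sum((ks / k) ** 2 for ks in per_module.values())
        if zi > ZI_THRESHOLD and pi > PI_THRESHOLD:
            role = ROLE_NETWORK_HUB
        elif zi > ZI_THRESHOLD:
            role = ROLE_MODULE_HUB
        elif pi > PI_THRESHOLD:
            role = ROLE_CONNECTOR
        else:
            role = ROLE_PERIPHERAL
        roles.append(NodeRole(v, float(zi), float(pi), role, modules[v], k))
    return roles


def keystone_report(
    roles: list[NodeRole], taxonomy: TaxonomyTable | None = None
) -> pd.DataFrame:
    """Non-peripheral nodes (keystone candidates), sorted by Zi descending."""
    phylum = taxonomy.phylum() if taxonomy is not None else None
    rows = [
        {
            "taxon_id": r.taxon_id,
            "role": r.role,
            "zi": r.zi,
            "pi": r.pi,
            "module": r.module,
            "degree": r.degree,
            "phylum": (
                str(phylum.get(r.taxon_id, "")) if phylum is not None else ""
            ),
        }
        for r in roles
        if r.role != ROLE_PERIPHERAL
    ]
    out = pd.DataFrame(
        rows,
        columns=["taxon_id", "role", "zi", "pi", "module", "degree", "phylum"],
    )
    return out.sort_values("zi", ascending=False).reset_index(drop=True)


def node_table(g: CooccurrenceNetwork, roles: list[NodeRole]) -> pd.DataFrame:
    rows = [
        {
            "taxon_id": r.taxon_id,
            "module": r.module,
            "zi": r.zi,
            "pi": r.pi,
            "role": r.role,
            "degree": r.degree,
            "abundance": g.graph.nodes[r.taxon_id].get("abundance", np.nan),
            "phylum": g.graph.nodes[r.taxon_id].get("phylum", ""),
        }
        for r in roles
    ]
    return pd.DataFrame(rows)
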