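"""Global and per-node attributes of signed interaction networks.

Global attributes follow the NetworkAnalyzer conventions used throughout
co-occurrence studies: mean local clustering, degree-based network
centralization (n/(n−2))·(k_max/(n−1) − density), the count and percentage
of reachable ordered pairs ("shortest paths"), the characteristic path
length, average neighbour count, density and heterogeneity (coefficient of
variation of the degree distribution, population variance).

Per-node attributes are the four standard centrality measures: degree
(NDC), closeness (NCC — reciprocal of the mean distance to reachable
nodes; 0 for isolated nodes), betweenness (NBC — normalised within the
node's connected component) and the local clustering coefficient (CCF,
defined as 0 for degree < 2).

Topology is sign-blind: all metrics act on |r| weights or plain hop
counts; the edge sign enters reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import SignedInteractionNetwork

__all__ = [
    "node_degree",
    "local_clustering",
    "closeness_centrality",
    "betweenness_centrality",
    "global_attributes",
    "node_table",
    "compare_classes",
    "GlobalNetworkAttributes",
    "GLOBAL_ATTRIBUTE_ORDER",
]

GLOBAL_ATTRIBUTE_ORDER = [
    "clustering_coefficient",
    "network_centralization",
    "shortest_paths_count",
    "characteristic_path_length",
    "avg_neighbors",
    "density",
    "heterogeneity",
]


def _graph(net) -> nx.Graph:
    return net.graph if isinstance(net, SignedInteractionNetwork) else net


def _weight_key(path_metric_mode: str):
    if path_metric_mode == "topological":
        return None
    if path_metric_mode == "weighted":
        return "weight"  # |r| as additive edge length
    raise ValueError("path_metric_mode must be 'topological' or 'weighted'")


def _require_node(g: nx.Graph, taxon) -> None:
    if taxon not in g:
        raise KeyError(f"unknown taxon {taxon!r}")


def node_degree(net, taxon) -> int:
    """NDC: number of direct links to a taxon, signs ignored."""
    g = _graph(net)
    _require_node(g, taxon)
    return int(g.degree(taxon))


def local_clustering(net, taxon) -> float:
    """CCF = 2·e_N/(k(k−1)); 0 for degree < 2."""
    g = _graph(net)
    _require_node(g, taxon)
    return float(nx.clustering(g, taxon))


def closeness_centrality(net, taxon, path_metric_mode: str = "topological") -> float:
    """NCC = 1 / mean(distance to every reachable node); isolated → 0."""
    g = _graph(net)
    _require_node(g, taxon)
    w = _weight_key(path_metric_mode)
    if w is None:
        return float(nx.closeness_centrality(g, taxon, wf_improved=False))
    return float(nx.closeness_centrality(g, taxon, distance=w, wf_improved=False))


def _component_betweenness(g: nx.Graph, path_metric_mode: str = "topological") -> dict:
    """Betweenness normalised by (m−1)(m−2)/2 with m the component size."""
    w = _weight_key(path_metric_mode)
    out: dict = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        out.update(nx.betweenness_centrality(sub, normalized=True, weight=w))
    return out


def betweenness_centrality(net, taxon, path_metric_mode: str = "topological") -> float:
    """NBC within the taxon's connected component, in [0, 1]."""
    g = _graph(net)
    _require_node(g, taxon)
    comp = nx.node_connected_component(g, taxon)
    sub = g.subgraph(comp)
    w = _weight_key(path_metric_mode)
    return float(nx.betweenness_centrality(sub, normalized=True, weight=w)[taxon])


@dataclass
class GlobalNetworkAttributes:
    """The seven headline network attributes plus bookkeeping fields.

    ``path_metrics_defined`` is False for edgeless/degenerate networks, in
    which case the path-based fields are NaN.
    """

    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    network_centralization: float
    shortest_paths_count: int
    shortest_paths_pct: float
    characteristic_path_length: float
    avg_neighbors: float
    density: float
    heterogeneity: float
    path_metrics_defined: bool = True
    n_isolated_excluded: int = 0

    def as_series(self) -> pd.Series:
        data = {
            "Clustering coefficient": self.clustering_coefficient,
            "Network centralization": self.network_centralization,
            "Shortest paths": self.shortest_paths_count,
            "Shortest paths (%)": self.shortest_paths_pct,
            "Characteristic path length": self.characteristic_path_length,
            "Average number of neighbors": self.avg_neighbors,
            "Network density": self.density,
            "Network heterogeneity": self.heterogeneity,
        }
        return pd.Series(data)


def global_attributes(
    net,
    include_isolated: bool = False,
    path_metric_mode: str = "topological",
) -> GlobalNetworkAttributes:
    """Compute the Table-2 attribute set for one network.

    By default nodes of degree 0 are excluded before computing density,
    centralization, clustering and path metrics (they are still reported in
    the node table); set ``include_isolated=True`` to keep them.
    """
    g = _graph(net)
    n_isolated = sum(1 for _, d in g.degree() if d == 0)
    if not include_isolated:
        g = g.subgraph([v for v, d in g.degree() if d > 0])
    n = g.number_of_nodes()
    e = g.number_of_edges()
    nan = float("nan")
    if n < 2 or e == 0:
        return GlobalNetworkAttributes(
            n_nodes=n, n_edges=e,
            clustering_coefficient=nan, network_centralization=nan,
            shortest_paths_count=0, shortest_paths_pct=nan,
            characteristic_path_length=nan,
            avg_neighbors=0.0 if n else nan,
            density=0.0 if n >= 2 else nan, heterogeneity=nan,
            path_metrics_defined=False, n_isolated_excluded=n_isolated,
        )
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    density = 2.0 * e / (n * (n - 1))
    avg_neighbors = 2.0 * e / n
    k_mean = degrees.mean()
    heterogeneity = float(np.sqrt(np.var(degrees)) / k_mean)
    if n > 2:
        centralization = (n / (n - 2.0)) * (degrees.max() / (n - 1.0) - density)
    else:
        centralization = nan
    clustering = float(np.mean(list(nx.clustering(g).values())))
    w = _weight_key(path_metric_mode)
    total_len = 0.0
    reachable_pairs = 0
    for src in g:
        if w is None:
            lengths = nx.single_source_shortest_path_length(g, src)
        else:
            lengths = nx.single_source_dijkstra_path_length(g, src, weight=w)
        for dst, dist in lengths.items():
            if dst != src:
                total_len += dist
                reachable_pairs += 1
    cpl = total_len / reachable_pairs if reachable_pairs else nan
    return GlobalNetworkAttributes(
        n_nodes=n, n_edges=e,
        clustering_coefficient=clustering,
        network_centralization=float(centralization),
        shortest_paths_count=reachable_pairs,
        shortest_paths_pct=100.0 * reachable_pairs / (n * (n - 1)),
        characteristic_path_length=float(cpl),
        avg_neighbors=float(avg_neighbors),
        density=float(density),
        heterogeneity=heterogeneity,
        path_metrics_defined=True,
        n_isolated_excluded=n_isolated,
    )


def node_table(net, sort_by=None, path_metric_mode: str = "topological") -> pd.DataFrame:
    """One row per node with NDC, NCC, NBC and CCF.

    Rows are ordered by taxon name; ``sort_by`` re-sorts by an attribute
    (descending) with ties broken by taxon name for deterministic output.
    """
    g = _graph(net)
    taxa = sorted(g.nodes, key=str)
    if not taxa:
        return pd.DataFrame(columns=["NDC", "NCC", "NBC", "CCF"])
    w = _weight_key(path_metric_mode)
    ccf = nx.clustering(g)
    nbc = _component_betweenness(g, path_metric_mode)
    rows = {}
    for t in taxa:
        if w is None:
            ncc = nx.closeness_centrality(g, t, wf_improved=False)
        else:
            ncc = nx.closeness_centrality(g, t, distance=w, wf_improved=False)
        rows[t] = {
            "NDC": int(g.degree(t)),
            "NCC": float(ncc),
            "NBC": float(nbc[t]),
            "CCF": float(ccf[t]),
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "taxon"
    if sort_by is not None:
        if sort_by not in frame.columns:
            raise KeyError(f"unknown attribute {sort_by!r}")
        frame = frame.sort_values(
            [sort_by, "taxon"], ascending=[False, True],
            key=lambda s: s if s.name == sort_by else s.astype(str),
        )
    return frame


#: default per-class NCC cut-offs mirroring the reported CW/MW/WW thresholds
DEFAULT_NCC_CUTS = {"CW": 0.5, "MW": 0.4, "WW": 0.3}


def compare_classes(
    nets: dict,
    ndc_cut: int = 10,
    nbc_cut: float = 0.2,
    ncc_cuts=None,
    include_isolated: bool = False,
    path_metric_mode: str = "topological",
):
    """Aligned attribute comparison across ≥ 2 class networks.

    Returns ``(attribute_table, top_taxa)``: a Table-2-shaped DataFrame
    (attributes × classes) and, per class, the taxa exceeding the NDC/NBC
    thresholds or the class-specific NCC cut (default 0.4 for classes
    without a configured cut).
    """
    if len(nets) < 2:
        raise ValueError("need at least two networks to compare")
    if ncc_cuts is None:
        ncc_cuts = DEFAULT_NCC_CUTS
    columns = {}
    top_taxa = {}
    for name, net in nets.items():
        ga = global_attributes(net, include_isolated=include_isolated,
                               path_metric_mode=path_metric_mode)
        columns[name] = ga.as_series()
        tbl = node_table(net, path_metric_mode=path_metric_mode)
        ncc_cut = ncc_cuts.get(name, 0.4) if isinstance(ncc_cuts, dict) else float(ncc_cuts)
        if len(tbl):
            mask = (tbl["NDC"] > ndc_cut) | (tbl["NBC"] > nbc_cut) | (tbl["NCC"] > ncc_cut)
            top_taxa[name] = tbl[mask]
        else:
            top_taxa[name] = tbl
    return pd.DataFrame(columns), top_taxa
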