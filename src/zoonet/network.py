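"""Signed co-occurrence network inference from a community matrix.

The procedure: autoscale each taxon's biomass to zero mean and unit
standard deviation, compute the pairwise correlation matrix, and keep as
edges exactly those pairs whose correlation is significant at P ≤ alpha for
the class's sample size.  The significance rule is expressed as a critical
absolute correlation r* = t*/√(df + t*²) with df = n − 2 and t* the
two-sided Student-t quantile — for Pearson correlations under normality
this is identical to thresholding per-pair p-values.  Positive edges read
as co-occurrence / shared-guild structure, negative edges as predation or
competition signatures; |r| serves as the edge weight.

The statsmodels-style entry point is :class:`CooccurrenceNetwork`, a model
built from one class's :class:`~zoonet.datatypes.CommunityMatrix`, whose
``fit()`` returns a :class:`CooccurrenceNetworkResults` carrying the
correlation matrix, the signed network and attribute tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CommunityMatrix, RunConfig

__all__ = [
    "autoscale",
    "critical_r",
    "correlation_matrix",
    "build_network",
    "CorrelationMatrix",
    "SignedInteractionNetwork",
    "CooccurrenceNetwork",
    "CooccurrenceNetworkResults",
]


def autoscale(matrix) -> tuple[pd.DataFrame, list]:
    """Standardise each taxon column to mean 0 and (sample, n−1) SD 1.

    Accepts a :class:`CommunityMatrix` or a samples × taxa DataFrame.
    Zero-variance columns cannot be scaled; they are dropped and returned in
    the exclusion list.
    """
    df = matrix.biomass if isinstance(matrix, CommunityMatrix) else pd.DataFrame(matrix)
    if df.shape[0] < 2:
        raise ValueError("autoscaling requires at least 2 samples")
    sd = df.std(axis=0, ddof=1)
    excluded = list(df.columns[(sd == 0) | sd.isna()])
    kept = df.drop(columns=excluded)
    scaled = (kept - kept.mean(axis=0)) / kept.std(axis=0, ddof=1)
    return scaled, excluded


def critical_r(n_samples: int, alpha: float) -> float:
    """Two-sided critical |r| at significance level ``alpha`` for n samples.

    r* = t*/√(df + t*²), df = n − 2, t* the (1 − alpha/2) Student-t
    quantile.  A pair is an edge iff |r| ≥ r*.
    """
    if n_samples < 4:
        raise ValueError("critical_r requires at least 4 samples")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    df = n_samples - 2
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t / np.sqrt(df + t * t))


@dataclass
class CorrelationMatrix:
    """Symmetric taxa × taxa correlation matrix with its sample size."""

    r: pd.DataFrame
    n_samples: int
    method: str

    def __post_init__(self) -> None:
        arr = self.r.to_numpy(dtype=float)
        arr = np.clip((arr + arr.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(arr, 1.0)
        self.r = pd.DataFrame(arr, index=self.r.index, columns=self.r.columns)

    @property
    def taxa(self) -> list:
        return list(self.r.columns)


def correlation_matrix(standardized: pd.DataFrame, method: str = "pearson") -> CorrelationMatrix:
    """Pairwise Pearson (default) or Spearman correlations between columns."""
    df = pd.DataFrame(standardized)
    if df.shape[0] < 4:
        raise ValueError("correlation requires at least 4 samples")
    if df.shape[1] < 2:
        raise ValueError("correlation requires at least 2 taxa")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    rdf = df.corr(method=method)
    return CorrelationMatrix(rdf, n_samples=df.shape[0], method=method)


@dataclass
class SignedInteractionNetwork:
    """Undirected taxon graph; edges carry r, sign and weight = |r|."""

    graph: nx.Graph
    n_samples: int
    alpha: float
    r_critical: float

    @classmethod
    def from_graph(cls, graph: nx.Graph, n_samples: int = 0, alpha: float = 0.05,
                   r_critical: float = 0.0) -> "SignedInteractionNetwork":
        """Wrap an existing graph, filling in edge sign/weight from ``r``
        (or defaulting r = weight = 1, sign positive)."""
        g = nx.Graph()
        g.add_nodes_from(graph.nodes(data=True))
        for u, v, data in graph.edges(data=True):
            r = float(data.get("r", 1.0))
            g.add_edge(u, v, r=r, weight=abs(r), sign="positive" if r > 0 else "negative")
        return cls(g, n_samples=n_samples, alpha=alpha, r_critical=r_critical)

    @property
    def taxa(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def isolated_taxa(self) -> list:
        return [n for n, d in self.graph.degree() if d == 0]

    def edge_frame(self) -> pd.DataFrame:
        """Edge list as a DataFrame (taxonA, taxonB, r, weight, sign)."""
        rows = [
            {"taxonA": u, "taxonB": v, "r": d["r"], "weight": d["weight"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        frame = pd.DataFrame(rows, columns=["taxonA", "taxonB", "r", "weight", "sign"])
        return frame.sort_values(["taxonA", "taxonB"]).reset_index(drop=True)

    def sign_counts(self) -> tuple[int, int]:
        pos = sum(1 for *_, d in self.graph.edges(data=True) if d["sign"] == "positive")
        return pos, self.n_edges - pos


def build_network(
    corr: CorrelationMatrix,
    alpha: float = 0.05,
    min_occurrence_mask=None,
) -> SignedInteractionNetwork:
    """Threshold a correlation matrix into a signed interaction network.

    Every pair with |r| ≥ r*(n, alpha) becomes an edge (ties at the
    threshold included).  Nodes that end up without edges stay in the node
    set and can be listed via :meth:`SignedInteractionNetwork.isolated_taxa`.
    ``min_occurrence_mask`` optionally restricts the node set to a taxon
    subset before thresholding.
    """
    taxa = list(corr.taxa)
    if min_occurrence_mask is not None:
        keep = set(min_occurrence_mask)
        taxa = [t for t in taxa if t in keep]
    rc = critical_r(corr.n_samples, alpha)
    g = nx.Graph()
    g.add_nodes_from(taxa)
    rsub = corr.r.loc[taxa, taxa].to_numpy()
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            r = float(rsub[i, j])
            if abs(r) >= rc:
                g.add_edge(
                    taxa[i], taxa[j], r=r, weight=abs(r),
                    sign="positive" if r > 0 else "negative",
                )
    return SignedInteractionNetwork(g, n_samples=corr.n_samples, alpha=alpha, r_critical=rc)


# --------------------------------------------------------------------------
# model / results objects
# --------------------------------------------------------------------------


class CooccurrenceNetwork:
    """Co-occurrence network model for one class's community matrix.

    Examples
    --------
    >>> model = CooccurrenceNetwork(community, alpha=0.05)
    >>> res = model.fit()
    >>> res.network.n_edges, res.r_critical  # doctest: +SKIP
    """

    def __init__(
        self,
        community: CommunityMatrix,
        *,
        alpha: float = 0.05,
        correlation_method: str = "pearson",
        min_occurrence_fraction: float = 0.0,
        path_metric_mode: str = "topological",
        class_name: str = "all",
    ) -> None:
        self.community = community
        self.alpha = alpha
        self.correlation_method = correlation_method
        self.min_occurrence_fraction = min_occurrence_fraction
        self.path_metric_mode = path_metric_mode
        self.class_name = class_name

    @classmethod
    def from_dataframe(cls, biomass: pd.DataFrame, **kwargs) -> "CooccurrenceNetwork":
        return cls(CommunityMatrix(biomass), **kwargs)

    @classmethod
    def from_config(cls, community: CommunityMatrix, config: RunConfig,
                    class_name: str = "all") -> "CooccurrenceNetwork":
        return cls(
            community,
            alpha=config.alpha,
            correlation_method=config.correlation_method,
            min_occurrence_fraction=config.min_occurrence_fraction,
            path_metric_mode=config.path_metric_mode,
            class_name=class_name,
        )

    def fit(self) -> "CooccurrenceNetworkResults":
        bio = self.community.biomass
        filtered: list = []
        if self.min_occurrence_fraction > 0:
            occ = (bio > 0).mean(axis=0)
            filtered = list(bio.columns[occ < self.min_occurrence_fraction])
            bio = bio.drop(columns=filtered)
        scaled, excluded = autoscale(bio)
        corr = correlation_matrix(scaled, self.correlation_method)
        net = build_network(corr, self.alpha)
        return CooccurrenceNetworkResults(
            model=self, corr=corr, network=net,
            excluded_taxa=excluded, filtered_taxa=filtered,
        )


@dataclass
class CooccurrenceNetworkResults:
    """Fitted network with its correlation matrix and attribute tables."""

    model: CooccurrenceNetwork
    corr: CorrelationMatrix
    network: SignedInteractionNetwork
    excluded_taxa: list = field(default_factory=list)
    filtered_taxa: list = field(default_factory=list)

    @property
    def r_critical(self) -> float:
        return self.network.r_critical

    def global_attributes(self, include_isolated: bool = False):
        from .metrics import global_attributes

        return global_attributes(
            self.network,
            include_isolated=include_isolated,
            path_metric_mode=self.model.path_metric_mode,
        )

    def node_table(self, sort_by=None) -> pd.DataFrame:
        from .metrics import node_table

        return node_table(self.network, sort_by=sort_by,
                          path_metric_mode=self.model.path_metric_mode)

    def summary(self) -> str:
        """Plain-text summary of the fitted network (Table-2 layout)."""
        ga = self.global_attributes()
        pos, neg = self.network.sign_counts()
        lines = [
            f"Co-occurrence network: class {self.model.class_name}",
            f"  samples: {self.network.n_samples}   taxa: {len(self.network.taxa)}"
            f"   constant taxa excluded: {len(self.excluded_taxa)}",
            f"  edge rule: |r| >= {self.r_critical:.4f}  (P <= {self.model.alpha:g},"
            f" {self.model.correlation_method})",
            f"  edges: {self.network.n_edges}  ({pos} positive / {neg} negative)",
            "",
            "  Global attributes",
            f"    Clustering coefficient       {ga.clustering_coefficient:.3f}",
            f"    Network centralization       {ga.network_centralization:.3f}",
            f"    Shortest paths               {ga.shortest_paths_count}"
            f" ({ga.shortest_paths_pct:.0f}%)",
            f"    Characteristic path length   {ga.characteristic_path_length:.3f}",
            f"    Average number of neighbors  {ga.avg_neighbors:.3f}",
            f"    Network density              {ga.density:.3f}",
            f"    Network heterogeneity        {ga.heterogeneity:.3f}",
        ]
        return "\n".join(lines)
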