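"""Reading and writing of tables, labels and networks.

Delimited text (comma or tab, auto-detected from the header line) for
community/environmental tables and labels; GraphML, SIF and edge-list TSV
for networks (the GraphML/SIF pair keeps the outputs loadable in Cytoscape).
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import CommunityMatrix, EnvironmentalTable
from .network import SignedInteractionNetwork

__all__ = [
    "read_community_table",
    "write_community_table",
    "read_environment_table",
    "write_environment_table",
    "read_labels",
    "write_labels",
    "write_network",
    "read_network_graphml",
    "write_ground_truth",
]

_FLOAT_FMT = "%.12g"


def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_numeric_table(path) -> pd.DataFrame:
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate row identifier: {dup!r}")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ValueError(f"duplicate column identifier: {dup!r}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {raw.index[i]!r}, column {raw.columns[j]!r}: "
            f"{raw.iat[i, j]!r}"
        )
    return numeric.astype(float)


def read_community_table(path, orientation: str = "taxa_rows", label_path=None) -> CommunityMatrix:
    """Read a delimited biomass table into a validated CommunityMatrix.

    ``orientation`` says whether taxa are rows (default) or columns in the
    file; the result is always samples × taxa.  ``label_path`` optionally
    points to a two-column sample → class file.
    """
    if orientation not in ("taxa_rows", "taxa_cols"):
        raise ValueError("orientation must be 'taxa_rows' or 'taxa_cols'")
    df = _read_numeric_table(path)
    if orientation == "taxa_rows":
        df = df.T
    neg = df.to_numpy() < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"negative biomass at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
        )
    labels = read_labels(label_path) if label_path is not None else None
    return CommunityMatrix(df, class_label=labels)


def write_community_table(community: CommunityMatrix, path, orientation: str = "taxa_rows",
                          sep: str = "\t") -> None:
    df = community.biomass
    if orientation == "taxa_rows":
        df = df.T
    elif orientation != "taxa_cols":
        raise ValueError("orientation must be 'taxa_rows' or 'taxa_cols'")
    df.to_csv(path, sep=sep, float_format=_FLOAT_FMT)


def read_environment_table(path) -> EnvironmentalTable:
    return EnvironmentalTable(_read_numeric_table(path))


def write_environment_table(env: EnvironmentalTable, path, sep: str = "\t") -> None:
    env.values.to_csv(path, sep=sep, float_format=_FLOAT_FMT)


def read_labels(path) -> pd.Series:
    sep = _sniff_sep(path)
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if frame.shape[1] != 1:
        raise ValueError("label file must have exactly two columns: sample, class")
    series = frame.iloc[:, 0]
    if series.index.duplicated().any():
        dup = series.index[series.index.duplicated()][0]
        raise ValueError(f"duplicate sample identifier in labels: {dup!r}")
    return series


def write_labels(labels: pd.Series, path, sep: str = "\t") -> None:
    pd.Series(labels, name="class").rename_axis("sample").to_csv(path, sep=sep)


def write_network(net: SignedInteractionNetwork, path, format: str = "edge_tsv",
                  node_attributes: pd.DataFrame | None = None) -> None:
    """Write a network as GraphML, SIF or an edge-list TSV.

    GraphML carries edge r/sign/weight and, when ``node_attributes`` (an
    NDC/NCC/NBC/CCF table) is given, per-node centrality annotations.  SIF
    uses interaction labels ``pos``/``neg``.
    """
    if format == "edge_tsv":
        net.edge_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    elif format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, d in sorted(net.graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
                label = "pos" if d["sign"] == "positive" else "neg"
                fh.write(f"{u}\t{label}\t{v}\n")
            for node in sorted(net.isolated_taxa(), key=str):
                fh.write(f"{node}\n")
    elif format == "graphml":
        g = net.graph.copy()
        g.graph.update(n_samples=net.n_samples, alpha=net.alpha, r_critical=net.r_critical)
        if node_attributes is not None:
            for taxon, row in node_attributes.iterrows():
                if taxon in g:
                    g.nodes[taxon].update({k: float(v) for k, v in row.items()})
        nx.write_graphml(g, path)
    else:
        raise ValueError("format must be 'graphml', 'sif' or 'edge_tsv'")


def read_network_graphml(path) -> SignedInteractionNetwork:
    g = nx.read_graphml(path)
    meta = g.graph
    return SignedInteractionNetwork.from_graph(
        g,
        n_samples=int(meta.get("n_samples", 0)),
        alpha=float(meta.get("alpha", 0.05)),
        r_critical=float(meta.get("r_critical", 0.0)),
    )


def write_ground_truth(truth, path, sep: str = "\t") -> None:
    """Ground-truth interaction list (taxonA, taxonB, sign, population_r)."""
    truth.to_frame().to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
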