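"""Diversity, evenness, similarity and between-class comparison statistics.

Implements the classical community-ecology battery used to characterise the
thermal classes: Shannon diversity H′, Pielou evenness J′, the Jaccard
similarity P′ (as a percentage), one-way ANOVA with Tukey HSD homogeneous
subsets (the a/b/c superscript convention), the Kruskal–Wallis test and
Spearman rank correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datatypes import LOG_BASES, CommunityMatrix

__all__ = [
    "shannon_diversity",
    "pielou_evenness",
    "jaccard_similarity",
    "compare_groups",
    "rank_correlation",
    "DiversityReport",
    "diversity_report",
    "jaccard_matrix",
    "GroupTestResult",
]


def _shares(vec) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if (v < 0).any():
        raise ValueError("vector must be nonnegative")
    total = v.sum()
    if total <= 0:
        raise ValueError("vector must contain at least one positive entry")
    return v[v > 0] / total


def shannon_diversity(biomass_or_counts, log_base: str = "e") -> float:
    """Shannon diversity H′ = −Σ pᵢ log pᵢ over positive shares.

    ``log_base`` is one of ``"e"`` (nats, default), ``"2"`` or ``"10"``.
    Zero entries are skipped; an all-zero vector raises ``ValueError``.
    """
    p = _shares(biomass_or_counts)
    h = float(-(p * np.log(p)).sum())
    return h / math.log(LOG_BASES[log_base])


def pielou_evenness(biomass_or_counts, log_base: str = "e") -> float:
    """Pielou evenness J′ = H′ / log S with S the observed richness.

    Returns NaN (with a warning) when richness < 2, where evenness is
    undefined.
    """
    p = _shares(biomass_or_counts)
    s = p.size
    if s < 2:
        warnings.warn("evenness undefined for richness < 2", stacklevel=2)
        return float("nan")
    h = float(-(p * np.log(p)).sum()) / math.log(LOG_BASES[log_base])
    return h / (math.log(s) / math.log(LOG_BASES[log_base]))


def jaccard_similarity(taxa_a, taxa_b) -> float:
    """Jaccard similarity P′ = 100·|A∩B|/|A∪B| in percent.

    Two empty sets are defined as 100 % similar (with a warning).
    """
    a, b = set(taxa_a), set(taxa_b)
    union = a | b
    if not union:
        warnings.warn("Jaccard of two empty sets defined as 100", stacklevel=2)
        return 100.0
    return 100.0 * len(a & b) / len(union)


@dataclass
class DiversityReport:
    """Per-class diversity summary (Table-1 shape: mean ± SD per sample)."""

    class_name: str
    n_samples: int
    richness: int
    H_prime: float
    H_prime_sd: float
    J_prime: float
    J_prime_sd: float
    mean_biomass: float
    biomass_sd: float


def diversity_report(
    community: CommunityMatrix, class_name: str = "all", log_base: str = "e"
) -> DiversityReport:
    """Summarise one class's community: per-sample H′/J′ mean ± SD, richness,
    mean total biomass.  Samples with zero total biomass are skipped."""
    bio = community.biomass
    totals = bio.sum(axis=1)
    hs, js = [], []
    for _, row in bio.iterrows():
        if row.sum() <= 0:
            continue
        hs.append(shannon_diversity(row.to_numpy(), log_base))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            js.append(pielou_evenness(row.to_numpy(), log_base))
    hs, js = np.asarray(hs), np.asarray(js)
    return DiversityReport(
        class_name=class_name,
        n_samples=community.n_samples,
        richness=len(community.observed_taxa()),
        H_prime=float(np.mean(hs)) if hs.size else float("nan"),
        H_prime_sd=float(np.std(hs, ddof=1)) if hs.size > 1 else float("nan"),
        J_prime=float(np.nanmean(js)) if js.size else float("nan"),
        J_prime_sd=float(np.nanstd(js, ddof=1)) if js.size > 1 else float("nan"),
        mean_biomass=float(totals.mean()),
        biomass_sd=float(totals.std(ddof=1)) if len(totals) > 1 else float("nan"),
    )


def jaccard_matrix(taxa_by_class: dict) -> pd.DataFrame:
    """Symmetric class × class matrix of Jaccard similarities in percent."""
    names = list(taxa_by_class)
    out = pd.DataFrame(100.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            p = jaccard_similarity(taxa_by_class[a], taxa_by_class[b])
            out.loc[a, b] = out.loc[b, a] = p
    return out


# --------------------------------------------------------------------------
# group comparison tests
# --------------------------------------------------------------------------


@dataclass
class GroupTestResult:
    method: str
    statistic: float
    p_value: float
    #: compact letter display (groups sharing a letter do not differ at 0.05);
    #: only assigned for ``anova_tukey`` with omnibus p ≤ 0.05.
    letters: dict | None = None


def _letter_display(names, means, nonsig_pairs) -> dict:
    """Compact letter display from the graph of non-significant pairs.

    Maximal cliques of the non-significance graph are the homogeneous
    subsets; letters are assigned to cliques in order of decreasing mean.
    """
    g = nx.Graph()
    g.add_nodes_from(names)
    g.add_edges_from(nonsig_pairs)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: (-max(means[n] for n in c), sorted(c)))
    letters: dict = {n: "" for n in names}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for n in clique:
            letters[n] += letter
    return {n: "".join(sorted(v)) for n, v in letters.items()}


def compare_groups(groups: dict, method: str = "anova_tukey", alpha: float = 0.05) -> GroupTestResult:
    """Omnibus test across ≥ 2 groups of values.

    ``anova_tukey`` runs one-way ANOVA; when the omnibus p ≤ alpha, Tukey's
    HSD assigns homogeneous-subset letters (groups sharing a letter are not
    significantly different).  ``kruskal_wallis`` runs the tie-corrected
    Kruskal–Wallis H test.  Degenerate input in which every group is a
    constant with equal means yields p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs at least two values")
    flat = np.concatenate(list(arrays.values()))
    degenerate = np.ptp(flat) == 0
    if method == "kruskal_wallis":
        if degenerate:
            return GroupTestResult("kruskal_wallis", 0.0, 1.0)
        stat, p = stats.kruskal(*arrays.values())
        return GroupTestResult("kruskal_wallis", float(stat), float(p))
    if method != "anova_tukey":
        raise ValueError("method must be 'anova_tukey' or 'kruskal_wallis'")
    if degenerate:
        return GroupTestResult("anova_tukey", 0.0, 1.0)
    stat, p = stats.f_oneway(*arrays.values())
    if not np.isfinite(p):  # zero within-group variance, equal means
        return GroupTestResult("anova_tukey", 0.0, 1.0)
    letters = None
    if p <= alpha:
        names = list(arrays)
        values = np.concatenate([arrays[n] for n in names])
        labels = np.concatenate([[n] * arrays[n].size for n in names])
        tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
        means = {n: float(arrays[n].mean()) for n in names}
        frame = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        nonsig = [
            (row["group1"], row["group2"])
            for _, row in frame.iterrows()
            if not row["reject"]
        ]
        letters = _letter_display(names, means, nonsig)
    return GroupTestResult("anova_tukey", float(stat), float(p), letters)


def rank_correlation(x, y):
    """Spearman rank correlation (mid-ranked ties, two-sided t-approximation p).

    Returns ``(rho, p)``; a constant input vector makes rho undefined and
    yields ``(nan, nan)`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("x and y must have equal length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("rank correlation undefined for a constant vector", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
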