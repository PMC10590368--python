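"""End-to-end analysis: per-class diversity, networks and attributes,
between-class tests, Jaccard similarity and variable-importance ranking.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import community_stats as cs
from .datatypes import CommunityMatrix, EnvironmentalTable, RunConfig
from .discrimination import ImportanceReport, rank_variables
from .metrics import GlobalNetworkAttributes
from .network import CooccurrenceNetwork, CooccurrenceNetworkResults

__all__ = ["AnalysisReport", "ClassReport", "run_pipeline"]


@dataclass
class ClassReport:
    name: str
    diversity: cs.DiversityReport
    network: CooccurrenceNetworkResults
    global_attrs: GlobalNetworkAttributes
    node_table: pd.DataFrame


@dataclass
class AnalysisReport:
    """Structured result of one pipeline run; serialisable to JSON/text."""

    config: RunConfig
    per_class: dict
    jaccard: pd.DataFrame | None = None
    group_tests: dict = field(default_factory=dict)
    importance: ImportanceReport | None = None

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, float) and math.isnan(x):
                return None
            if isinstance(x, (np.floating, np.integer)):
                return clean(float(x)) if isinstance(x, np.floating) else int(x)
            return x

        out: dict = {
            "config": {
                "alpha": self.config.alpha,
                "correlation_method": self.config.correlation_method,
                "shannon_log_base": self.config.shannon_log_base,
                "min_occurrence_fraction": self.config.min_occurrence_fraction,
                "path_metric_mode": self.config.path_metric_mode,
                "rng_seed": self.config.rng_seed,
            },
            "classes": {},
        }
        for name, rep in self.per_class.items():
            d, ga = rep.diversity, rep.global_attrs
            out["classes"][name] = {
                "n_samples": d.n_samples,
                "richness": d.richness,
                "H_prime": clean(d.H_prime), "H_prime_sd": clean(d.H_prime_sd),
                "J_prime": clean(d.J_prime), "J_prime_sd": clean(d.J_prime_sd),
                "mean_biomass": clean(d.mean_biomass), "biomass_sd": clean(d.biomass_sd),
                "r_critical": clean(rep.network.r_critical),
                "n_edges": rep.network.network.n_edges,
                "edge_signs": dict(zip(("positive", "negative"),
                                       rep.network.network.sign_counts())),
                "excluded_constant_taxa": list(rep.network.excluded_taxa),
                "global_attributes": {
                    k: clean(getattr(ga, k))
                    for k in ("n_nodes", "n_edges", "clustering_coefficient",
                              "network_centralization", "shortest_paths_count",
                              "shortest_paths_pct", "characteristic_path_length",
                              "avg_neighbors", "density", "heterogeneity",
                              "path_metrics_defined", "n_isolated_excluded")
                },
                "node_attributes": {
                    str(t): {k: clean(v) for k, v in row.items()}
                    for t, row in rep.node_table.iterrows()
                },
            }
        if self.jaccard is not None:
            out["jaccard_pct"] = {
                a: {b: clean(self.jaccard.loc[a, b]) for b in self.jaccard.columns}
                for a in self.jaccard.index
            }
        out["group_tests"] = {
            key: {"method": t.method, "statistic": clean(t.statistic),
                  "p_value": clean(t.p_value), "letters": t.letters}
            for key, t in self.group_tests.items()
        }
        if self.importance is not None:
            imp = self.importance
            out["importance"] = {
                "model": imp.model,
                "ranking": [[v, clean(s)] for v, s in imp.ranking],
                "train_accuracy": clean(imp.train_accuracy),
                "test_accuracy": clean(imp.test_accuracy),
                "split_spec": imp.split_spec,
                "seed": imp.seed,
            }
        return out

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_text(self) -> str:
        """Plain-text tables: global attributes × classes, then per-class
        diversity and top node attributes."""
        lines = []
        names = list(self.per_class)
        attr_table = pd.DataFrame(
            {n: rep.global_attrs.as_series() for n, rep in self.per_class.items()}
        )
        lines.append("Global network attributes")
        lines.append(attr_table.to_string(float_format=lambda v: f"{v:.3f}"))
        lines.append("")
        lines.append("Diversity (per-sample mean ± SD)")
        for n in names:
            d = self.per_class[n].diversity
            lines.append(
                f"  {n}: richness {d.richness}, H' {d.H_prime:.3f} ± {d.H_prime_sd:.3f}, "
                f"J' {d.J_prime:.3f} ± {d.J_prime_sd:.3f}, "
                f"biomass {d.mean_biomass:.4g} ± {d.biomass_sd:.4g} mg/l"
            )
        if self.jaccard is not None and len(names) > 1:
            lines.append("")
            lines.append("Jaccard similarity (%)")
            lines.append(self.jaccard.to_string(float_format=lambda v: f"{v:.1f}"))
        for key, t in self.group_tests.items():
            letters = f", letters {t.letters}" if t.letters else ""
            lines.append(f"Group test [{key}] {t.method}: statistic {t.statistic:.3f}, "
                         f"p {t.p_value:.4g}{letters}")
        if self.importance is not None:
            lines.append("")
            lines.append("Variable importance (top 5)")
            for v, s in self.importance.ranking[:5]:
                lines.append(f"  {v}: {s:.3g}")
            lines.append(
                f"  accuracy: train {self.importance.train_accuracy:.1f}%"
                f" / test {self.importance.test_accuracy:.1f}%"
            )
        return "\n".join(lines) + "\n"


def run_pipeline(
    config: RunConfig,
    community: CommunityMatrix,
    env: EnvironmentalTable | None = None,
) -> AnalysisReport:
    """Run the full analysis for a labelled (or single-class) community.

    Per class: diversity summary, signed network, global and node
    attributes.  Across classes: Jaccard similarity of taxon sets, ANOVA +
    Tukey on per-sample Shannon diversity, Kruskal–Wallis on per-sample
    total biomass, and (when ``env`` is given) the boosted-trees variable
    ranking.  Every class must contribute at least 4 samples, the minimum
    for the correlation significance rule.
    """
    classes = community.classes() or ["all"]
    per_class: dict = {}
    taxa_sets: dict = {}
    h_by_class: dict = {}
    biomass_by_class: dict = {}
    for name in classes:
        sub = community.subset_class(name) if community.class_label is not None else community
        if sub.n_samples < 4:
            raise ValueError(
                f"class {name!r} has {sub.n_samples} samples; at least 4 are required"
            )
        model = CooccurrenceNetwork.from_config(sub, config, class_name=name)
        res = model.fit()
        per_class[name] = ClassReport(
            name=name,
            diversity=cs.diversity_report(sub, name, config.shannon_log_base),
            network=res,
            global_attrs=res.global_attributes(),
            node_table=res.node_table(),
        )
        taxa_sets[name] = sub.observed_taxa()
        h_by_class[name] = [
            cs.shannon_diversity(row.to_numpy(), config.shannon_log_base)
            for _, row in sub.biomass.iterrows()
            if row.sum() > 0
        ]
        biomass_by_class[name] = sub.biomass.sum(axis=1).to_numpy()
    jaccard = cs.jaccard_matrix(taxa_sets) if len(classes) > 1 else None
    group_tests: dict = {}
    if len(classes) > 1:
        group_tests["shannon_anova"] = cs.compare_groups(h_by_class, "anova_tukey")
        group_tests["biomass_kruskal"] = cs.compare_groups(biomass_by_class, "kruskal_wallis")
    importance = None
    if env is not None and len(classes) > 1:
        importance = rank_variables(
            env, community.class_label, model="boosted_trees", seed=config.rng_seed
        )
    return AnalysisReport(
        config=config, per_class=per_class, jaccard=jaccard,
        group_tests=group_tests, importance=importance,
    )
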