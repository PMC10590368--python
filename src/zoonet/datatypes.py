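"""Core containers for community, environmental and configuration data.

The central object is :class:`CommunityMatrix`, a validated samples × taxa
biomass table (mg l⁻¹) with an optional class label (thermal class) per
sample.  :class:`EnvironmentalTable` carries the physico-chemical variables
measured alongside (temperature, DO, nutrients, suspended solids, ...).
Both wrap a :class:`pandas.DataFrame` so the usual pandas idioms remain
available via the ``.biomass`` / ``.values`` attributes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["CommunityMatrix", "EnvironmentalTable", "RunConfig", "LOG_BASES"]

#: Supported logarithm bases for diversity indices.
LOG_BASES = {"e": math.e, "2": 2.0, "10": 10.0}


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class CommunityMatrix:
    """Samples × taxa biomass table with optional per-sample class labels.

    Parameters
    ----------
    biomass
        DataFrame indexed by sample identifier with one column per taxon.
        Values are biomass in mg l⁻¹; must be finite and ≥ 0.
    class_label
        Optional mapping sample → class name (e.g. thermal class CW/MW/WW).
        When present it must cover every sample.
    sample_date
        Optional calendar date per sample.
    """

    biomass: pd.DataFrame
    class_label: pd.Series | None = None
    sample_date: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.biomass, pd.DataFrame):
            self.biomass = pd.DataFrame(self.biomass)
        _check_unique(self.biomass.index, "sample")
        _check_unique(self.biomass.columns, "taxon")
        values = self.biomass.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite biomass at sample "
                f"{self.biomass.index[bad[0]]!r}, taxon {self.biomass.columns[bad[1]]!r}"
            )
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                "negative biomass at sample "
                f"{self.biomass.index[bad[0]]!r}, taxon {self.biomass.columns[bad[1]]!r}"
            )
        if self.class_label is not None:
            self.class_label = pd.Series(self.class_label)
            missing = [s for s in self.biomass.index if s not in self.class_label.index]
            if missing:
                raise ValueError(f"class_label missing for samples: {missing[:5]}")
            self.class_label = self.class_label.reindex(self.biomass.index)
        if self.sample_date is not None:
            self.sample_date = pd.Series(self.sample_date).reindex(self.biomass.index)

    # -- convenience accessors -------------------------------------------------
    @property
    def samples(self) -> list:
        return list(self.biomass.index)

    @property
    def taxa(self) -> list:
        return list(self.biomass.columns)

    @property
    def n_samples(self) -> int:
        return self.biomass.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.biomass.shape[1]

    def classes(self) -> list:
        """Class names in order of first appearance (empty if unlabelled)."""
        if self.class_label is None:
            return []
        seen: dict = {}
        for c in self.class_label:
            seen.setdefault(c, None)
        return list(seen)

    def subset_class(self, name) -> "CommunityMatrix":
        """Rows belonging to one class, with all-absent taxa dropped."""
        if self.class_label is None:
            raise ValueError("community has no class labels")
        mask = self.class_label == name
        if not mask.any():
            raise KeyError(f"unknown class {name!r}")
        sub = self.biomass.loc[mask.to_numpy()]
        present = sub.columns[(sub > 0).any(axis=0)]
        dates = self.sample_date.loc[mask.to_numpy()] if self.sample_date is not None else None
        return CommunityMatrix(sub[present], class_label=None, sample_date=dates)

    def observed_taxa(self) -> set:
        """Taxa with positive biomass in at least one sample."""
        return set(self.biomass.columns[(self.biomass > 0).any(axis=0)])


@dataclass
class EnvironmentalTable:
    """Samples × variables table of physico-chemical measurements."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(self.values.columns, "variable")
        _check_unique(self.values.index, "sample")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError("environmental values must be finite or missing (NaN)")

    @property
    def samples(self) -> list:
        return list(self.values.index)

    @property
    def variables(self) -> list:
        return list(self.values.columns)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run.

    ``alpha`` is the two-sided significance level of the edge rule (a taxon
    pair becomes an edge iff its correlation is significant at P ≤ alpha for
    the class's sample size).  ``min_occurrence_fraction`` optionally drops
    taxa present in fewer than that fraction of a class's samples before
    network construction (off by default).
    """

    alpha: float = 0.05
    correlation_method: str = "pearson"
    shannon_log_base: str = "e"
    min_occurrence_fraction: float = 0.0
    path_metric_mode: str = "topological"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValueError("correlation_method must be 'pearson' or 'spearman'")
        if self.shannon_log_base not in LOG_BASES:
            raise ValueError(f"shannon_log_base must be one of {sorted(LOG_BASES)}")
        if not 0.0 <= self.min_occurrence_fraction <= 1.0:
            raise ValueError("min_occurrence_fraction must lie in [0, 1]")
        if self.path_metric_mode not in ("topological", "weighted"):
            raise ValueError("path_metric_mode must be 'topological' or 'weighted'")

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)
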