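"""Variable-importance ranking for discriminating thermal classes.

``boosted_trees`` mode fits a multiclass gradient-boosted tree ensemble
(XGBoost) on a stratified train split and reports each variable's
split-frequency importance (the boosting "F score") together with train
and test accuracy.  ``anova_f`` mode is the deterministic fallback/oracle:
the one-way ANOVA F statistic per variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import LabelEncoder

from .datatypes import EnvironmentalTable

__all__ = ["ImportanceReport", "rank_variables"]


@dataclass
class ImportanceReport:
    """Ranked variable importances plus the accuracy of the classifier."""

    ranking: list  # (variable, score) sorted by decreasing score
    train_accuracy: float  # percent; NaN for anova_f mode
    test_accuracy: float   # percent; NaN for anova_f mode
    split_spec: str
    seed: int
    model: str

    def __post_init__(self) -> None:
        scores = [s for _, s in self.ranking]
        if any(b > a + 1e-12 for a, b in zip(scores, scores[1:])):
            raise ValueError("ranking must be sorted by non-increasing score")

    def top_variable(self) -> str:
        return self.ranking[0][0]

    def rank_of(self, variable: str) -> int:
        """1-based rank of a variable (ties share the order they were sorted in)."""
        for i, (v, _) in enumerate(self.ranking, start=1):
            if v == variable:
                return i
        raise KeyError(variable)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranking, columns=["variable", "importance"])


def _anova_f_scores(values: pd.DataFrame, y: np.ndarray) -> dict:
    scores = {}
    for var in values.columns:
        col = values[var].to_numpy(dtype=float)
        groups = [col[y == k] for k in np.unique(y)]
        if np.ptp(col) == 0:
            warnings.warn(f"variable {var!r} is constant; importance set to 0", stacklevel=3)
            scores[var] = 0.0
            continue
        f, _ = stats.f_oneway(*groups)
        scores[var] = float(f) if np.isfinite(f) else 0.0
    return scores


def rank_variables(
    env: EnvironmentalTable,
    labels,
    model: str = "boosted_trees",
    split_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    importance_type: str = "weight",
    n_estimators: int = 500,
    max_depth: int = 3,
    learning_rate: float = 0.1,
) -> ImportanceReport:
    """Rank environmental variables by class-discriminating importance.

    ``labels`` maps each sample of ``env`` to its class.  ``importance_type``
    is XGBoost's notion: ``"weight"`` (split frequency, default) or
    ``"gain"``.  The number of boosting rounds is chosen by early stopping
    on a validation fold carved from the training split (rounds past the
    signal only accumulate noise splits, which would pollute the
    split-frequency importance); ``n_estimators`` is the cap.
    """
    values = env.values
    y_raw = pd.Series(labels).reindex(values.index)
    if y_raw.isna().any():
        raise ValueError("labels missing for some samples")
    classes = y_raw.unique()
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    y = LabelEncoder().fit_transform(y_raw)
    if model == "anova_f":
        scores = _anova_f_scores(values, y)
        ranking = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return ImportanceReport(ranking, float("nan"), float("nan"),
                                "none (deterministic F statistic)", seed, model)
    if model != "boosted_trees":
        raise ValueError("model must be 'boosted_trees' or 'anova_f'")
    counts = pd.Series(y).value_counts()
    if counts.min() < 8:
        raise ValueError("boosted mode needs >= 8 samples per class")
    from xgboost import XGBClassifier

    x_train, x_test, y_train, y_test = train_test_split(
        values, y, train_size=split_fraction, stratify=y, random_state=seed
    )
    x_fit, x_val, y_fit, y_val = train_test_split(
        x_train, y_train, train_size=0.8, stratify=y_train, random_state=seed
    )
    clf = XGBClassifier(
        n_estimators=n_estimators, max_depth=max_depth, learning_rate=learning_rate,
        random_state=seed, n_jobs=1, verbosity=0, eval_metric="mlogloss",
        early_stopping_rounds=20,
    )
    clf.fit(x_fit, y_fit, eval_set=[(x_val, y_val)], verbose=False)
    booster = clf.get_booster()[: clf.best_iteration + 1]
    booster_scores = booster.get_score(importance_type=importance_type)
    scores = {}
    for var in values.columns:
        if np.ptp(values[var].to_numpy(dtype=float)) == 0:
            warnings.warn(f"variable {var!r} is constant; importance set to 0", stacklevel=2)
        scores[var] = float(booster_scores.get(var, 0.0))
    ranking = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    train_acc = 100.0 * float((clf.predict(x_train) == y_train).mean())
    test_acc = 100.0 * float((clf.predict(x_test) == y_test).mean())
    split = (f"stratified split, train fraction {split_fraction:.3f} "
             f"({len(x_train)}/{len(values)} samples)")
    return ImportanceReport(ranking, train_acc, test_acc, split, seed, model)
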