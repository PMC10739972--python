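"""Dual feature ranking: impurity importance (FI) and information gain (IG).

FI is the mean impurity-decrease importance of a random-forest fit; IG is
parent label entropy minus the weighted entropy of the partition a feature
induces, with continuous features discretised into equal-frequency bins.
Both return a :class:`FeatureRanking` ordered by score descending, ties
broken alphabetically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _entropy
from sklearn.ensemble import RandomForestClassifier

from hfens.core_data import ClinicalTable


@dataclass
class FeatureRanking:
    method: str  # "FI" or "IG"
    scores: dict[str, float]
    order: list[str]

    def __post_init__(self) -> None:
        if sorted(self.order) != sorted(self.scores):
            raise ValueError("order must permute the scored features")


def _rank_order(scores: dict[str, float]) -> list[str]:
    return sorted(scores, key=lambda f: (-scores[f], f))


def label_entropy(y: np.ndarray) -> float:
    """Shannon entropy (base 2) of a label vector."""
    if len(y) == 0:
        return 0.0
    _, counts = np.unique(y, return_counts=True)
    return float(_entropy(counts, base=2))


def _discretize(values: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning; features with <= bins distinct values pass through."""
    uniq = np.unique(values)
    if len(uniq) <= bins:
        return np.searchsorted(uniq, values)
    qs = np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(qs, values, side="right")


def information_gain(table: ClinicalTable, feature: str, bins: int = 10) -> float:
    """IG(D, f) = I(D) - sum_j (N_j / N) * I(D_j), entropy base 2.

    The partition D_j is induced by the feature's values, after
    equal-frequency discretisation into ``bins`` bins for columns with
    more than ``bins`` distinct values. Constant features return 0.
    """
    col = table.column(feature)
    if table.n == 0:
        return 0.0
    parent = label_entropy(table.y)
    branches = _discretize(col, bins)
    child = 0.0
    for b in np.unique(branches):
        mask = branches == b
        child += mask.mean() * label_entropy(table.y[mask])
    return max(0.0, parent - child)


def rank_information_gain(table: ClinicalTable, bins: int = 10) -> FeatureRanking:
    scores = {
        name: information_gain(table, name, bins=bins)
        for name in table.feature_names
    }
    return FeatureRanking(method="IG", scores=scores, order=_rank_order(scores))


def rank_impurity_importance(
    table: ClinicalTable, forest_size: int = 100, seed: int = 0
) -> FeatureRanking:
    """Mean impurity-decrease importances of a random forest, normalised to 1."""
    if table.n < 10:
        raise ValueError("need at least 10 samples")
    if len(np.unique(table.y)) < 2:
        raise ValueError("both classes must be present")
    forest = RandomForestClassifier(
        n_estimators=forest_size, random_state=seed, n_jobs=1
    )
    forest.fit(table.X, table.y)
    imp = forest.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    scores = dict(zip(table.feature_names, imp.astype(float)))
    return FeatureRanking(method="FI", scores=scores, order=_rank_order(scores))


def top_k(ranking: FeatureRanking, k: int = 10) -> list[str]:
    """First k feature names of the ranking's descending order."""
    if not 1 <= k <= len(ranking.order):
        raise ValueError(f"k={k} out of range for {len(ranking.order)} features")
    return ranking.order[:k]
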