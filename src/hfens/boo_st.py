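"""BOO-ST hybrid resampler: boost weights -> weighted SMOTE -> Tomek cleaning.

Three stages rebalance an imbalanced clinical table:

1. ``boost_weights`` runs adaptive reweighting (AdaBoost-style rounds with a
   shallow stump) so hard-to-classify rows — concentrated in the minority
   class — end with larger sample weights.
2. ``weighted_smote`` synthesises minority rows by linear interpolation
   toward one of the seed's k minority nearest neighbours; seeds are drawn
   with probability proportional to their boost weight, biasing synthesis
   toward the under-represented, frequently misclassified minority region.
3. Tomek-link cleaning removes majority members of cross-class mutual
   nearest-neighbour pairs from the augmented table, sharpening the class
   boundary and discarding ambiguous synthetic points.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.tree import DecisionTreeClassifier

from hfens.core_data import ClinicalTable

logger = logging.getLogger(__name__)


@dataclass
class BoostConfig:
    """Adaptive-reweighting stage: T rounds of a depth-limited stump."""

    T: int = 10
    weak_learner_depth: int = 1
    learning_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


@dataclass
class SampleWeights:
    """Normalised positive per-row weights aligned to a table's rows."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if (self.w <= 0).any():
            raise ValueError("weights must be strictly positive")
        self.w = self.w / self.w.sum()


@dataclass
class SmoteConfig:
    k: int = 5
    target_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 < self.target_ratio <= 1.0:
            raise ValueError("target_ratio must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticRecord:
    """Provenance of one synthetic minority row: xs = seed + r * (nbr - seed)."""

    features: np.ndarray
    seed_index: int
    neighbor_index: int
    r: float


@dataclass(frozen=True)
class TomekPair:
    """Cross-class mutual nearest neighbours (a Tomek link)."""

    index_a: int
    index_b: int
    classes: tuple[int, int]
    distance: float


@dataclass
class ResampleReport:
    counts_before: dict[int, int]
    counts_after: dict[int, int]
    synthetic_records: list[SyntheticRecord] = field(default_factory=list)
    removed_pairs: list[TomekPair] = field(default_factory=list)
    removed_indices: list[int] = field(default_factory=list)
    boost_weights: np.ndarray | None = None

    def reconciles(self, minority_label: int) -> bool:
        """after = before + synthesised - removed, per class."""
        synth = {0: 0, 1: 0}
        synth[minority_label] = len(self.synthetic_records)
        removed = {0: 0, 1: 0}
        for p, idx in zip(self.removed_pairs, self.removed_indices):
            cls = p.classes[0] if p.index_a == idx else p.classes[1]
            removed[cls] += 1
        return all(
            self.counts_after[c]
            == self.counts_before[c] + synth[c] - removed[c]
            for c in (0, 1)
        )


def _minority_label(table: ClinicalTable) -> int:
    counts = table.class_counts()
    if counts[0] == counts[1]:
        return 1  # tie: treat the clinical positive class as minority
    return min(counts, key=counts.get)


def boost_weights(table: ClinicalTable, config: BoostConfig) -> SampleWeights:
    """Run T adaptive-reweighting rounds and return the final sample weights.

    Each round fits a depth-``weak_learner_depth`` tree on current weights,
    computes the weighted error eps, stage weight
    alpha = lr * 0.5 * ln((1 - eps) / eps), multiplies misclassified rows'
    weights by exp(alpha) and renormalises. eps = 0 stops early (nothing
    left to emphasise); eps >= 0.5 resets that round's weights to uniform
    and continues, so a failing weak learner cannot invert the emphasis.
    """
    if len(np.unique(table.y)) < 2:
        raise ValueError("both classes must be present")
    n = table.n
    w = np.full(n, 1.0 / n)
    for t in range(config.T):
        stump = DecisionTreeClassifier(
            max_depth=config.weak_learner_depth, random_state=config.seed + t
        )
        stump.fit(table.X, table.y, sample_weight=w)
        miss = stump.predict(table.X) != table.y
        eps = float(w[miss].sum())
        if eps <= 0.0:
            logger.debug("round %d: zero weighted error, stopping early", t)
            break
        if eps >= 0.5:
            logger.debug("round %d: eps=%.3f >= 0.5, resetting uniform", t, eps)
            w = np.full(n, 1.0 / n)
            continue
        alpha = config.learning_rate * 0.5 * math.log((1.0 - eps) / eps)
        w = w * np.exp(alpha * miss)
        w = w / w.sum()
    return SampleWeights(w=w)


def _interpolate(
    seed: np.ndarray, neighbor: np.ndarray, r: float, binary_mask: np.ndarray
) -> np.ndarray:
    """xs = seed + r * (neighbor - seed); binary dims copy the nearer endpoint."""
    xs = seed + r * (neighbor - seed)
    if binary_mask.any():
        xs[binary_mask] = np.where(r <= 0.5, seed, neighbor)[binary_mask]
    return xs


def weighted_smote(
    table: ClinicalTable,
    weights: SampleWeights | None = None,
    config: SmoteConfig = SmoteConfig(),
) -> tuple[ClinicalTable, list[SyntheticRecord]]:
    """Synthesise minority rows until minority = ceil(target_ratio * majority).

    Seed rows are drawn from the minority class with probability
    proportional to their boost weight (uniform if ``weights`` is None);
    the interpolation partner is uniform among the seed's k minority
    nearest neighbours (Euclidean); r ~ Uniform(0, 1]. Binary columns copy
    the nearer endpoint instead of interpolating. Synthetic rows get
    sample ids ``syn<i>`` and the minority label.
    """
    minority = _minority_label(table)
    min_idx = np.flatnonzero(table.y == minority)
    maj_count = int(np.sum(table.y != minority))
    if len(min_idx) < 2:
        raise ValueError(
            "minority class has a single member; SMOTE needs >= 2 "
            "(duplication-free fallback is not provided)"
        )
    n_syn = max(0, math.ceil(config.target_ratio * maj_count) - len(min_idx))
    if n_syn == 0:
        return table, []

    k = config.k
    if k > len(min_idx) - 1:
        k = len(min_idx) - 1
        logger.warning("k lowered to %d (minority count %d)", k, len(min_idx))

    Xmin = table.X[min_idx]
    dist = cdist(Xmin, Xmin)
    np.fill_diagonal(dist, np.inf)
    # k nearest minority neighbours per minority row, ties by lowest index
    nn = np.argsort(dist, axis=1, kind="stable")[:, :k]

    if weights is None:
        probs = np.full(len(min_idx), 1.0 / len(min_idx))
    else:
        w = np.asarray(weights.w, dtype=float)
        if len(w) != table.n:
            raise ValueError("weights misaligned with table rows")
        probs = w[min_idx] / w[min_idx].sum()

    rng = np.random.default_rng(config.seed)
    binary_mask = np.array([s.kind == "binary" for s in table.specs])
    records: list[SyntheticRecord] = []
    rows = np.empty((n_syn, table.X.shape[1]))
    for i in range(n_syn):
        local_seed = int(rng.choice(len(min_idx), p=probs))
        local_nbr = int(nn[local_seed, rng.integers(k)])
        r = float(1.0 - rng.random())  # Uniform(0, 1]
        xs = _interpolate(Xmin[local_seed], Xmin[local_nbr], r, binary_mask)
        rows[i] = xs
        records.append(SyntheticRecord(
            features=xs.copy(),
            seed_index=int(min_idx[local_seed]),
            neighbor_index=int(min_idx[local_nbr]),
            r=r,
        ))

    augmented = ClinicalTable(
        X=np.vstack([table.X, rows]),
        y=np.concatenate([table.y, np.full(n_syn, minority, dtype=int)]),
        specs=table.specs,
        sample_ids=list(table.sample_ids) + [f"syn{i}" for i in range(n_syn)],
    )
    return augmented, records


def find_tomek_links(table: ClinicalTable) -> list[TomekPair]:
    """All cross-class mutual-nearest-neighbour pairs (Euclidean distance).

    Nearest-neighbour ties break toward the lowest row index, which keeps
    the result deterministic for duplicate points. Pairs are reported once
    with index_a < index_b, sorted.
    """
    if len(np.unique(table.y)) < 2:
        raise ValueError("both classes must be present")
    dist = cdist(table.X, table.X)
    np.fill_diagonal(dist, np.inf)
    nearest = np.argmin(dist, axis=1)  # argmin takes the lowest index on ties
    pairs = []
    for a in range(table.n):
        b = int(nearest[a])
        if a < b and nearest[b] == a and table.y[a] != table.y[b]:
            pairs.append(TomekPair(
                index_a=a, index_b=b,
                classes=(int(table.y[a]), int(table.y[b])),
                distance=float(dist[a, b]),
            ))
    return pairs


def remove_tomek_majority(
    table: ClinicalTable,
    pairs: list[TomekPair],
    minority_label: int | None = None,
) -> ClinicalTable:
    """Drop the majority-class member of each Tomek pair.

    Minority members — including synthetic ones — are never dropped. When
    ``minority_label`` is None it is inferred from class counts (ties
    treat label 1 as minority).
    """
    if minority_label is None:
        minority_label = _minority_label(table)
    drop = set()
    for p in pairs:
        for idx, cls in ((p.index_a, p.classes[0]), (p.index_b, p.classes[1])):
            if idx < 0 or idx >= table.n:
                raise IndexError(f"pair index {idx} out of range")
            if cls != minority_label:
                drop.add(idx)
    if not drop:
        return table
    keep = np.array([i for i in range(table.n) if i not in drop], dtype=int)
    return table.take(keep)


def boo_st(
    table: ClinicalTable,
    boost_cfg: BoostConfig = BoostConfig(),
    smote_cfg: SmoteConfig = SmoteConfig(),
    iterate_tomek: bool = False,
) -> tuple[ClinicalTable, ResampleReport]:
    """Full resampler: boost weights, weighted SMOTE, Tomek-link cleaning.

    With ``iterate_tomek`` the cleaning pass repeats until no cross-class
    mutual nearest neighbours remain; the default is a single pass.
    """
    span = np.ptp(table.X, axis=0) if table.n else np.zeros(1)
    if span.size and span.max() > 10.0:
        warnings.warn(
            "feature ranges differ widely; distances will be dominated by "
            "large-scale columns — min-max scale the table first",
            stacklevel=2,
        )
    minority = _minority_label(table)
    counts_before = table.class_counts()

    weights = boost_weights(table, boost_cfg)
    augmented, records = weighted_smote(table, weights, smote_cfg)

    removed_pairs: list[TomekPair] = []
    removed_indices: list[int] = []
    current = augmented
    while True:
        pairs = find_tomek_links(current)
        majority_members = [
            (p, idx)
            for p in pairs
            for idx, cls in ((p.index_a, p.classes[0]), (p.index_b, p.classes[1]))
            if cls != minority
        ]
        for p, idx in majority_members:
            removed_pairs.append(p)
            removed_indices.append(idx)
        cleaned = remove_tomek_majority(current, pairs, minority_label=minority)
        done = cleaned.n == current.n or not iterate_tomek
        current = cleaned
        if done:
            break

    counts_after = current.class_counts()
    maj = 1 - minority
    if counts_after[maj] > 0:
        ratio = counts_after[minority] / counts_after[maj]
        if not 0.8 <= ratio <= 1.25 and smote_cfg.target_ratio == 1.0:
            logger.info("post-resampling class ratio %.3f outside [0.8, 1.25]", ratio)

    report = ResampleReport(
        counts_before=counts_before,
        counts_after=counts_after,
        synthetic_records=records,
        removed_pairs=removed_pairs,
        removed_indices=removed_indices,
        boost_weights=weights.w,
    )
    return current, report
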