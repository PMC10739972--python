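"""CBCEC hybrid classifier: best base learner, bagged, then voted with itself.

The construction has three steps:

1. *Selection* — the four candidate families (DT, GB, SVM, ET) are trained
   and the one with the highest validation accuracy becomes the
   best-performing classifier (BP-C); ties break in the fixed family order
   DT, GB, SVM, ET.
2. *Bagging* — BP-C is refit on B bootstrap resamples of the training
   table; the bag predicts the arithmetic mean of its members'
   class-probability vectors.
3. *Voting* — BP-C (fit on the full training table) and the bag are
   combined: soft voting takes the argmax of their averaged probability
   vectors; hard voting is a majority with a fixed-order tie-break; a
   weighted mode averages with supplied weights.

Base-learner internals are delegated to scikit-learn; this module owns the
selection, bagging and voting logic.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, GradientBoostingClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from hfens.core_data import ClinicalTable, SplitPlan, make_splits

logger = logging.getLogger(__name__)

FAMILY_ORDER = ("DT", "GB", "SVM", "ET")


@dataclass
class BaseLearnerSpec:
    """One candidate base family with hyperparameters and a seed.

    The default seed of 10 is the random state retained by the
    random-state ablation grid.
    """

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 10

    def __post_init__(self) -> None:
        if self.family not in FAMILY_ORDER:
            raise ValueError(f"family must be one of {FAMILY_ORDER}")

    def build(self):
        params = dict(self.hyperparameters)
        if self.family == "DT":
            return DecisionTreeClassifier(random_state=self.seed, **params)
        if self.family == "GB":
            return GradientBoostingClassifier(random_state=self.seed, **params)
        if self.family == "SVM":
            # probability=True calibrates decision scores so the sign-only
            # margin output can participate in soft voting
            params.setdefault("probability", True)
            return SVC(random_state=self.seed, **params)
        return ExtraTreesClassifier(random_state=self.seed, n_jobs=1, **params)


class FittedLearner:
    """Uniform train/predict-probability contract over any base family."""

    def __init__(self, spec: BaseLearnerSpec, estimator):
        self.spec = spec
        self.estimator = estimator
        self.classes_ = np.asarray(estimator.classes_, dtype=int)

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        """Two-class probability simplex per sample, columns = classes (0, 1)."""
        raw = self.estimator.predict_proba(np.asarray(X, dtype=float))
        out = np.zeros((raw.shape[0], 2))
        for j, cls in enumerate(self.classes_):
            out[:, cls] = raw[:, j]
        return out

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_probability(X), axis=1)


def train_base(spec: BaseLearnerSpec, train: ClinicalTable) -> FittedLearner:
    """Fit one base learner; errors on a single-class training table."""
    if len(np.unique(train.y)) < 2:
        raise ValueError("single-class training table")
    est = spec.build()
    with warnings.catch_warnings():
        # SVC(probability=True) is the stable way to get calibrated margins
        # across the supported scikit-learn range; silence its pending rename
        warnings.filterwarnings("ignore", category=FutureWarning,
                                message=".*probability.*")
        est.fit(train.X, train.y)
    return FittedLearner(spec, est)


@dataclass
class SelectionResult:
    scores: dict[str, float]
    chosen_family: str

    def __post_init__(self) -> None:
        if self.scores[self.chosen_family] != max(self.scores.values()):
            raise ValueError("chosen family must attain the maximum accuracy")


def select_best(
    families: list[BaseLearnerSpec],
    train: ClinicalTable,
    validation: ClinicalTable,
) -> SelectionResult:
    """Train every family, score validation accuracy, return the argmax.

    Ties break by the fixed family order DT, GB, SVM, ET.
    """
    if len(families) < 2:
        raise ValueError("need at least 2 candidate families")
    if validation.n == 0:
        raise ValueError("validation table is empty")
    scores: dict[str, float] = {}
    for spec in families:
        fitted = train_base(spec, train)
        scores[spec.family] = float(
            np.mean(fitted.predict_label(validation.X) == validation.y)
        )
    best = max(
        scores,
        key=lambda fam: (scores[fam], -FAMILY_ORDER.index(fam)),
    )
    return SelectionResult(scores=scores, chosen_family=best)


@dataclass
class BaggedEstimator:
    base: BaseLearnerSpec
    B: int
    members: list[FittedLearner]
    bootstrap_indices: list[np.ndarray]

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        probs = np.mean([m.predict_probability(X) for m in self.members], axis=0)
        return probs

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_probability(X), axis=1)


def fit_bagged(
    spec: BaseLearnerSpec, train: ClinicalTable, B: int = 10, seed: int = 0
) -> BaggedEstimator:
    """Fit B members on n-sized bootstrap resamples; aggregate by mean.

    A resample that drops a class entirely is redrawn (up to 10 attempts,
    logged) so every member sees both classes.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    members, index_sets = [], []
    for _ in range(B):
        for attempt in range(10):
            idx = rng.integers(0, train.n, size=train.n)
            if len(np.unique(train.y[idx])) == 2:
                break
            logger.info("bootstrap resample lost a class; redrawing (%d)", attempt)
        else:
            raise ValueError("could not draw a two-class bootstrap resample")
        members.append(train_base(spec, train.take(idx)))
        index_sets.append(idx)
    return BaggedEstimator(base=spec, B=B, members=members,
                           bootstrap_indices=index_sets)


@dataclass
class TrainedEnsemble:
    """The fitted hybrid: BP-C soft/hard/weighted-voted with its bagged copy."""

    bp_c: FittedLearner
    b_bg: BaggedEstimator
    voting: str = "soft"
    weights: tuple[float, float] = (0.5, 0.5)
    selection: SelectionResult | None = None
    feature_names: list[str] | None = None

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        p1 = self.bp_c.predict_probability(X)
        p2 = self.b_bg.predict_probability(X)
        if self.voting == "weighted":
            w1, w2 = self.weights
            total = w1 + w2
            return (w1 * p1 + w2 * p2) / total
        return (p1 + p2) / 2.0

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        if self.voting in ("soft", "weighted"):
            return np.argmax(self.predict_probability(X), axis=1)
        if self.voting == "hard":
            l1 = self.bp_c.predict_label(X)
            l2 = self.b_bg.predict_label(X)
            # two voters: agreement wins, disagreement falls back to the
            # first member in the fixed order (BP-C)
            return np.where(l1 == l2, l1, l1)
        raise ValueError(f"unknown voting type {self.voting!r}")


def fit_cbcec(
    train: ClinicalTable,
    validation: ClinicalTable | None = None,
    B: int = 10,
    voting: str = "soft",
    seed: int = 10,
    base_family: str | None = None,
    weights: tuple[float, float] = (0.5, 0.5),
    hyperparameters: dict | None = None,
    val_fraction: float = 0.2,
) -> TrainedEnsemble:
    """Select the best family, bag it, and combine the pair by voting.

    When ``validation`` is None a stratified ``val_fraction`` of the
    training table is carved out for selection only, and both ensemble
    members are refit on the full training table afterwards; passing the
    held-out test table instead reproduces selection-on-test behaviour.
    ``base_family`` skips selection (used by the ablation grids).
    """
    if voting not in ("soft", "hard", "weighted"):
        raise ValueError(f"unknown voting type {voting!r}")
    hp = hyperparameters or {}
    selection = None
    if base_family is None:
        if validation is None:
            plan = SplitPlan(train_fractions=(1.0 - val_fraction,), seed=seed)
            sel_train, sel_val = make_splits(train, plan)[0]
        else:
            sel_train, sel_val = train, validation
        families = [BaseLearnerSpec(f, dict(hp), seed=seed) for f in FAMILY_ORDER]
        selection = select_best(families, sel_train, sel_val)
        base_family = selection.chosen_family
    spec = BaseLearnerSpec(base_family, dict(hp), seed=seed)
    bp_c = train_base(spec, train)
    b_bg = fit_bagged(spec, train, B=B, seed=seed)
    return TrainedEnsemble(
        bp_c=bp_c, b_bg=b_bg, voting=voting, weights=weights,
        selection=selection, feature_names=train.feature_names,
    )


def run_ablation(
    train: ClinicalTable,
    validation: ClinicalTable,
    estimators: tuple[str, ...] = FAMILY_ORDER,
    random_states: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 35, 40),
    voting_types: tuple[str, ...] = ("hard", "weighted", "soft"),
    feature_sets: dict[str, list[str]] | None = None,
    B: int = 10,
) -> pd.DataFrame:
    """Full factorial over the three ablation grids x feature sets.

    Each cell fixes the base family (no selection), fits the hybrid on the
    training table and scores accuracy on the validation table. The
    returned frame has one row per (estimator, random_state, voting_type,
    feature_set) with an ``accepted`` flag marking the setting whose best
    accuracy across feature sets attains the grid maximum.
    """
    if not estimators or not random_states or not voting_types:
        raise ValueError("grids must be nonempty")
    if feature_sets is None:
        feature_sets = {"ALL": train.feature_names}
    rows = []
    for fam, rs, vt, (fs_name, cols) in itertools.product(
        estimators, random_states, voting_types, feature_sets.items()
    ):
        tr = train.select_features(cols)
        va = validation.select_features(cols)
        model = fit_cbcec(tr, B=B, voting=vt, seed=rs, base_family=fam)
        acc = float(np.mean(model.predict_label(va.X) == va.y))
        rows.append({
            "estimator": fam, "random_state": rs, "voting": vt,
            "feature_set": fs_name, "accuracy": acc,
        })
    out = pd.DataFrame(rows)
    setting_cols = ["estimator", "random_state", "voting"]
    best_per_setting = out.groupby(setting_cols)["accuracy"].transform("max")
    out["accepted"] = best_per_setting == out["accuracy"].max()
    return out
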