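"""Schema-aware clinical tables, CSV I/O, min-max scaling, stratified splits.

The canonical schema mirrors the 13-column heart-failure clinical-records
layout: 12 mixed binary/integer/continuous predictors plus the binary
``DEATH_EVENT`` target (1 = dead, 0 = survived).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

TARGET_COLUMN = "DEATH_EVENT"


class SchemaViolationError(ValueError):
    """A CSV cell or column does not conform to the declared schema."""


@dataclass(frozen=True)
class FeatureSpec:
    """Declared name, kind and valid range of one predictor column.

    kind is one of ``binary`` (values in {0,1}), ``integer`` or
    ``continuous``; valid_range is inclusive and stated in the feature's
    own units.
    """

    name: str
    kind: str
    unit: str = ""
    valid_range: tuple[float, float] = (-np.inf, np.inf)

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "integer", "continuous"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        low, high = self.valid_range
        if self.kind == "binary" and (low, high) != (0, 1):
            raise ValueError(f"binary feature {self.name!r} must have range (0, 1)")
        if low > high:
            raise ValueError(f"feature {self.name!r}: low > high in valid_range")

    def validate_column(self, values: np.ndarray) -> np.ndarray:
        """Return a boolean mask of rows violating this spec."""
        bad = ~np.isfinite(values)
        low, high = self.valid_range
        bad |= (values < low) | (values > high)
        if self.kind == "binary":
            bad |= ~np.isin(values, (0.0, 1.0))
        elif self.kind == "integer":
            bad |= values != np.round(values)
        return bad


#: Heart-failure clinical-records schema: name, kind, unit and range.
HEART_FAILURE_SCHEMA: tuple[FeatureSpec, ...] = (
    FeatureSpec("Age", "continuous", "years", (40, 95)),
    FeatureSpec("Anaemia", "binary", "bool", (0, 1)),
    FeatureSpec("High blood pressure", "binary", "bool", (0, 1)),
    FeatureSpec("Creatinine phosphokinase", "integer", "mcg/L", (23, 7861)),
    FeatureSpec("Diabetes", "binary", "bool", (0, 1)),
    FeatureSpec("Ejection fraction", "integer", "percent", (14, 80)),
    FeatureSpec("Sex", "binary", "bool", (0, 1)),
    FeatureSpec("Platelets", "continuous", "kiloplatelets/mL", (25.01, 850.0)),
    FeatureSpec("Serum creatinine", "continuous", "mg/dL", (0.5, 9.4)),
    FeatureSpec("Serum sodium", "integer", "mEq/L", (114, 148)),
    FeatureSpec("Smoking", "binary", "bool", (0, 1)),
    FeatureSpec("Time", "integer", "days", (4, 285)),
)

#: Common lowercase/underscored aliases for the canonical column names.
DEFAULT_ALIASES: dict[str, str] = {
    "age": "Age",
    "anaemia": "Anaemia",
    "high_blood_pressure": "High blood pressure",
    "creatinine_phosphokinase": "Creatinine phosphokinase",
    "diabetes": "Diabetes",
    "ejection_fraction": "Ejection fraction",
    "sex": "Sex",
    "platelets": "Platelets",
    "serum_creatinine": "Serum creatinine",
    "serum_sodium": "Serum sodium",
    "smoking": "Smoking",
    "time": "Time",
    "death_event": TARGET_COLUMN,
}


@dataclass
class ClinicalTable:
    """In-memory records-by-features matrix with binary mortality labels.

    ``X`` holds one column per FeatureSpec in ``specs``; ``y`` holds
    {0, 1} labels with 1 = dead; ``sample_ids`` are opaque identifiers
    carried through resampling so synthetic-row provenance survives.
    """

    X: np.ndarray
    y: np.ndarray
    specs: tuple[FeatureSpec, ...]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            self.X = self.X.reshape(len(self.y), -1)
        self.y = np.asarray(self.y, dtype=int)
        self.specs = tuple(self.specs)
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(len(self.y))]
        if self.X.shape[0] != len(self.y) or len(self.sample_ids) != len(self.y):
            raise ValueError("X rows, y and sample_ids must have equal length")
        if self.X.shape[1] != len(self.specs):
            raise ValueError("X columns must match specs")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def class_counts(self) -> dict[int, int]:
        return {0: int(np.sum(self.y == 0)), 1: int(np.sum(self.y == 1))}

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.column_index(name)]

    def column_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None

    def take(self, indices: np.ndarray | list[int]) -> "ClinicalTable":
        indices = np.asarray(indices, dtype=int)
        return ClinicalTable(
            X=self.X[indices].copy(),
            y=self.y[indices].copy(),
            specs=self.specs,
            sample_ids=[self.sample_ids[i] for i in indices],
        )

    def select_features(self, names: list[str]) -> "ClinicalTable":
        idx = [self.column_index(n) for n in names]
        return ClinicalTable(
            X=self.X[:, idx].copy(),
            y=self.y.copy(),
            specs=tuple(self.specs[i] for i in idx),
            sample_ids=list(self.sample_ids),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X.copy(), columns=self.feature_names)
        df[TARGET_COLUMN] = self.y
        return df


def read_table(
    path,
    schema: tuple[FeatureSpec, ...] = HEART_FAILURE_SCHEMA,
    aliases: dict[str, str] | None = None,
    validate_ranges: bool = True,
) -> ClinicalTable:
    """Read a schema-conformant CSV into a validated ClinicalTable.

    Header names are matched order-insensitively against the schema (and
    the target column), after alias normalisation. Rows violating a
    FeatureSpec are reported by column and row index. Missing values and
    non-numeric cells raise :class:`SchemaViolationError`.
    """
    aliases = {**DEFAULT_ALIASES, **(aliases or {})}
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [aliases.get(str(c).strip(), str(c).strip()) for c in df.columns]

    expected = {s.name for s in schema} | {TARGET_COLUMN}
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise SchemaViolationError(f"unknown columns: {unknown}")
    missing = sorted(expected - set(df.columns))
    if missing:
        raise SchemaViolationError(f"missing columns: {missing}")

    if df.empty:
        warnings.warn("empty table: header only, zero records", stacklevel=2)
        return ClinicalTable(
            X=np.empty((0, len(schema))), y=np.empty(0, dtype=int),
            specs=schema, sample_ids=[],
        )

    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaViolationError(
                f"column {col!r}: missing or non-numeric value at row {row}"
            )
        df[col] = series

    X = df[[s.name for s in schema]].to_numpy(dtype=float)
    y = df[TARGET_COLUMN].to_numpy()
    if not np.isin(y, (0, 1)).all():
        row = int(np.flatnonzero(~np.isin(y, (0, 1)))[0])
        raise SchemaViolationError(f"column {TARGET_COLUMN!r}: non-binary label at row {row}")

    if validate_ranges:
        for j, spec in enumerate(schema):
            bad = spec.validate_column(X[:, j])
            if bad.any():
                rows = np.flatnonzero(bad)[:10].tolist()
                raise SchemaViolationError(
                    f"column {spec.name!r}: {int(bad.sum())} rows violate "
                    f"{spec.kind} range {spec.valid_range} (rows {rows})"
                )

    return ClinicalTable(X=X, y=y.astype(int), specs=schema)


def write_table(table: ClinicalTable, path) -> None:
    """Write a ClinicalTable as a canonical-header CSV (round-trip exact)."""
    table.to_dataframe().to_csv(path, index=False, float_format="%.17g")


@dataclass
class ScalerState:
    """Per-column (min, max) pairs learned from a fitting table."""

    bounds: dict[str, tuple[float, float]]


def fit_minmax(table: ClinicalTable, columns: list[str] | None = None) -> ScalerState:
    """Learn per-column observed (min, max); default: all feature columns."""
    columns = columns if columns is not None else table.feature_names
    bounds = {}
    for name in columns:
        col = table.column(name)
        if col.size == 0:
            bounds[name] = (0.0, 0.0)
        else:
            bounds[name] = (float(col.min()), float(col.max()))
    return ScalerState(bounds=bounds)


def apply_minmax(state: ScalerState, table: ClinicalTable) -> ClinicalTable:
    """Map each fitted column x to (x - min) / (max - min), clipped to [0, 1].

    Zero-range columns map to 0 so downstream distance computations stay
    finite. Columns in the state but absent from the table are an error.
    """
    X = table.X.copy()
    names = table.feature_names
    for name, (low, high) in state.bounds.items():
        if name not in names:
            raise KeyError(f"scaler column {name!r} absent from table")
        j = names.index(name)
        if high > low:
            X[:, j] = np.clip((X[:, j] - low) / (high - low), 0.0, 1.0)
        else:
            X[:, j] = 0.0
    # scaled values no longer honour the raw valid ranges
    specs = tuple(
        replace(s, valid_range=(0, 1), unit="scaled") if s.name in state.bounds else s
        for s in table.specs
    )
    return ClinicalTable(X=X, y=table.y.copy(), specs=specs,
                         sample_ids=list(table.sample_ids))


def inverse_minmax(state: ScalerState, table: ClinicalTable) -> ClinicalTable:
    """Undo :func:`apply_minmax` for non-degenerate columns."""
    X = table.X.copy()
    names = table.feature_names
    for name, (low, high) in state.bounds.items():
        if name in names:
            j = names.index(name)
            X[:, j] = X[:, j] * (high - low) + low
    return ClinicalTable(X=X, y=table.y.copy(), specs=table.specs,
                         sample_ids=list(table.sample_ids))


@dataclass
class SplitPlan:
    """Multi-split hold-out protocol: one stratified split per train fraction.

    Defaults follow the 70/80/90% training-fraction protocol. ``repeats``
    re-draws each fraction with derived seeds so paired comparisons can
    use more than three splits.
    """

    train_fractions: tuple[float, ...] = (0.70, 0.80, 0.90)
    seed: int = 0
    stratified: bool = True
    repeats: int = 1

    def __post_init__(self) -> None:
        for f in self.train_fractions:
            if not 0.0 < f < 1.0:
                raise ValueError(f"train fraction {f} not in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing to ``total`` by the largest-remainder rule."""
    floors = np.floor(quotas).astype(int)
    remainder = total - floors.sum()
    if remainder > 0:
        frac = quotas - floors
        # ties broken toward the larger quota, then lower index
        order = np.lexsort((np.arange(len(quotas)), -quotas, -frac))
        floors[order[:remainder]] += 1
    return floors


def make_splits(
    table: ClinicalTable, plan: SplitPlan
) -> list[tuple[ClinicalTable, ClinicalTable]]:
    """Produce one stratified (train, test) pair per fraction (x repeats).

    Test size is round(n * (1 - fraction)); per-class test counts follow
    largest-remainder allocation of the global class proportions, keeping
    each side within one sample of the global mix. Deterministic under
    ``plan.seed``.
    """
    if table.n < 10:
        raise ValueError("need at least 10 samples to split")
    counts = table.class_counts()
    if min(counts.values()) == 0:
        raise ValueError("both classes must be present")

    classes = np.array([0, 1])
    class_indices = [np.flatnonzero(table.y == c) for c in classes]
    n = table.n
    splits = []
    for rep in range(plan.repeats):
        for k, fraction in enumerate(plan.train_fractions):
            rng = np.random.default_rng(
                np.random.SeedSequence([plan.seed, rep, k])
            )
            n_test = int(round(n * (1.0 - fraction)))
            n_test = min(max(n_test, 1), n - 1)
            if plan.stratified:
                quotas = np.array([len(ci) * n_test / n for ci in class_indices])
                alloc = _largest_remainder(quotas, n_test)
            else:
                alloc = None
            test_idx: list[np.ndarray] = []
            if plan.stratified:
                for ci, a in zip(class_indices, alloc):
                    if a < 1 or a >= len(ci):
                        raise ValueError(
                            f"fraction {fraction}: a class would be absent from "
                            "one side of the split"
                        )
                    test_idx.append(rng.choice(ci, size=a, replace=False))
                test = np.sort(np.concatenate(test_idx))
            else:
                test = np.sort(rng.choice(n, size=n_test, replace=False))
            train = np.setdiff1d(np.arange(n), test)
            for side in (train, test):
                if len(np.unique(table.y[side])) < 2:
                    raise ValueError(
                        f"fraction {fraction}: a class is absent from one side"
                    )
            splits.append((table.take(train), table.take(test)))
    return splits
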