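"""Synthetic clinical-records generator with a planted mortality signal.

Emulates the heart-failure records schema: 299 patients by default, a
203 / 96 class split (majority dead, minority survived), Table-style value
ranges, and a latent logistic dependence of mortality on follow-up time,
serum creatinine, ejection fraction and age — the four features the real
data ranks on top — so every downstream stage (resampling, ranking,
classification, explanation) is testable without any external download.

The latent model is z = sum_j w_j * standardized(x_j) + eps with
eps ~ N(0, noise_sd^2); labels are Bernoulli(sigmoid(z + b)) with the
intercept b solved by bisection so the expected minority share matches the
configured fraction, then trimmed exactly by flipping the most borderline
labels. Skewed laboratory features (CPK, platelets, serum creatinine) are
drawn truncated log-normal; remaining numerics are uniform over their
declared ranges; binaries are Bernoulli at dataset-like prevalences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hfens.core_data import ClinicalTable, FeatureSpec, HEART_FAILURE_SCHEMA

#: Default latent effect weights on the standardized features, signed in the
#: clinically expected direction for death risk (shorter follow-up, higher
#: serum creatinine, lower ejection fraction, higher age -> death).
DEFAULT_SIGNAL: dict[str, float] = {
    "Time": -1.2,
    "Serum creatinine": 1.0,
    "Ejection fraction": -0.8,
    "Age": 0.6,
}

#: Stronger planted weights used when signal-recovery behaviour itself is
#: under test; same features and signs, higher signal-to-noise.
STRONG_SIGNAL: dict[str, float] = {
    "Time": -2.0,
    "Serum creatinine": 2.0,
    "Ejection fraction": -1.5,
    "Age": 1.5,
}

# (mu, sigma) of the untruncated log-normal for right-skewed lab values
_LOGNORMAL_PARAMS: dict[str, tuple[float, float]] = {
    "Creatinine phosphokinase": (5.6, 1.0),
    "Platelets": (5.55, 0.35),
    "Serum creatinine": (0.1, 0.4),
}

_BINARY_PREVALENCE: dict[str, float] = {
    "Anaemia": 0.43,
    "High blood pressure": 0.35,
    "Diabetes": 0.42,
    "Sex": 0.65,
    "Smoking": 0.32,
}


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic clinical-table generator.

    minority_fraction is the share of the minority class (default the
    96/299 survivor share); minority_label says which label is the
    minority (default 0 = survived). overlap >= 0 shrinks the planted
    signal, increasing class overlap.
    """

    n_samples: int = 299
    minority_fraction: float = 96 / 299
    minority_label: int = 0
    signal_features: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIGNAL)
    )
    noise_sd: float = 1.0
    overlap: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if not 0.0 < self.minority_fraction <= 0.5:
            raise ValueError("minority_fraction must be in (0, 0.5]")
        if self.minority_fraction * self.n_samples < 2:
            raise ValueError(
                f"minority_fraction {self.minority_fraction} infeasible for "
                f"n_samples {self.n_samples}: fewer than 2 minority samples"
            )
        if self.minority_label not in (0, 1):
            raise ValueError("minority_label must be 0 or 1")
        predictors = {s.name for s in HEART_FAILURE_SCHEMA}
        unknown = set(self.signal_features) - predictors
        if unknown:
            raise ValueError(f"signal features not in schema: {sorted(unknown)}")
        if self.noise_sd < 0 or self.overlap < 0:
            raise ValueError("noise_sd and overlap must be nonnegative")


def _draw_feature(spec: FeatureSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    low, high = spec.valid_range
    if spec.kind == "binary":
        p = _BINARY_PREVALENCE.get(spec.name, 0.5)
        return (rng.random(n) < p).astype(float)
    if spec.name in _LOGNORMAL_PARAMS:
        mu, sigma = _LOGNORMAL_PARAMS[spec.name]
        out = np.empty(n)
        filled = 0
        while filled < n:  # rejection-truncate to the declared range
            draw = rng.lognormal(mu, sigma, size=2 * (n - filled) + 8)
            keep = draw[(draw >= low) & (draw <= high)][: n - filled]
            out[filled: filled + len(keep)] = keep
            filled += len(keep)
        vals = out
    else:
        vals = rng.uniform(low, high, size=n)
    if spec.kind == "integer":
        vals = np.clip(np.round(vals), low, high)
    return vals


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _solve_intercept(z: np.ndarray, target_mean: float) -> float:
    """Bisection for b with mean(sigmoid(z + b)) = target_mean."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sigmoid(z + mid).mean() < target_mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate(config: GeneratorConfig) -> ClinicalTable:
    """Draw one reproducible synthetic clinical table under ``config``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    schema = HEART_FAILURE_SCHEMA
    X = np.column_stack([_draw_feature(s, n, rng) for s in schema])
    names = [s.name for s in schema]

    z = np.zeros(n)
    attenuation = 1.0 / (1.0 + config.overlap)
    for feat, w in config.signal_features.items():
        col = X[:, names.index(feat)]
        sd = col.std()
        if sd > 0:
            z += attenuation * w * (col - col.mean()) / sd
    z += rng.normal(0.0, config.noise_sd, size=n)

    # death (label 1) prevalence implied by the minority specification
    death_share = (
        config.minority_fraction
        if config.minority_label == 1
        else 1.0 - config.minority_fraction
    )
    b = _solve_intercept(z, death_share)
    p = _sigmoid(z + b)
    y = (rng.random(n) < p).astype(int)

    # trim to the exact minority count by flipping the most borderline rows
    n_minority = int(round(config.minority_fraction * n))
    target_pos = n_minority if config.minority_label == 1 else n - n_minority
    while y.sum() > target_pos:
        candidates = np.flatnonzero(y == 1)
        y[candidates[np.argmin(p[candidates])]] = 0
    while y.sum() < target_pos:
        candidates = np.flatnonzero(y == 0)
        y[candidates[np.argmax(p[candidates])]] = 1

    return ClinicalTable(X=X, y=y, specs=schema,
                         sample_ids=[f"sim{i}" for i in range(n)])


def describe(table: ClinicalTable) -> pd.DataFrame:
    """Per-feature min/max/mean summary plus class counts (as attrs).

    Mirrors a dataset-details table: one row per feature with its declared
    kind and range next to the observed statistics.
    """
    rows = []
    for j, spec in enumerate(table.specs):
        col = table.X[:, j]
        empty = col.size == 0
        rows.append({
            "feature": spec.name,
            "kind": spec.kind,
            "unit": spec.unit,
            "declared_low": spec.valid_range[0],
            "declared_high": spec.valid_range[1],
            "min": float(col.min()) if not empty else np.nan,
            "max": float(col.max()) if not empty else np.nan,
            "mean": float(col.mean()) if not empty else np.nan,
        })
    out = pd.DataFrame(rows)
    out.attrs["class_counts"] = table.class_counts()
    out.attrs["n"] = table.n
    return out
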