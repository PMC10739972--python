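"""Partial dependence and riskiest-value-range extraction.

A partial-dependence curve sweeps one feature over a grid while every
other feature keeps its observed per-row value, averaging the model's
positive-class probability over the rows at each grid point. Risk ranges
are the contiguous grid intervals where the curve is relatively high —
by default above mean(pd) + 0.5 * sd(pd).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hfens.core_data import ClinicalTable


@dataclass
class PdpCurve:
    feature: str
    grid: np.ndarray
    pd: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.pd = np.asarray(self.pd, dtype=float)
        if len(self.grid) != len(self.pd):
            raise ValueError("grid and pd must have equal length")
        if len(self.grid) > 1 and not (np.diff(self.grid) > 0).all():
            raise ValueError("grid must be strictly increasing")
        if ((self.pd < 0) | (self.pd > 1)).any():
            raise ValueError("pd values must lie in [0, 1]")


@dataclass(frozen=True)
class RiskRange:
    feature: str
    low: float
    high: float
    criterion: str


def pdp(model, table: ClinicalTable, feature: str, grid_size: int = 20) -> PdpCurve:
    """Partial dependence of the positive-class probability on one feature.

    The grid is the set of equal-frequency quantiles of the observed
    values (deduplicated); binary features use {0, 1}. Other features are
    held at their observed per-row values.
    """
    j = table.column_index(feature)
    col = table.X[:, j]
    if table.specs[j].kind == "binary":
        grid = np.array([0.0, 1.0])
    else:
        qs = np.linspace(0, 1, grid_size)
        grid = np.unique(np.quantile(col, qs))
    pd_vals = np.empty(len(grid))
    X = table.X.copy()
    for i, v in enumerate(grid):
        X[:, j] = v
        pd_vals[i] = float(model.predict_probability(X)[:, 1].mean())
    return PdpCurve(feature=feature, grid=grid, pd=pd_vals)


def risk_ranges(curve: PdpCurve, threshold: float | None = None) -> list[RiskRange]:
    """Contiguous grid intervals where partial dependence is relatively high.

    The default rule flags grid points strictly above
    mean(pd) + 0.5 * sd(pd) and merges adjacent flagged points into
    (low, high) intervals; a flat curve yields no ranges.
    """
    if len(curve.grid) == 0:
        raise ValueError("empty curve")
    if threshold is None:
        threshold = float(curve.pd.mean() + 0.5 * curve.pd.std())
        criterion = "mean + 0.5 sd"
    else:
        criterion = f"pd > {threshold:g}"
    above = curve.pd > threshold
    ranges: list[RiskRange] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            ranges.append(RiskRange(curve.feature, float(curve.grid[start]),
                                    float(curve.grid[i - 1]), criterion))
            start = None
    if start is not None:
        ranges.append(RiskRange(curve.feature, float(curve.grid[start]),
                                float(curve.grid[-1]), criterion))
    return ranges
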