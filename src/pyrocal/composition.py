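"""Composition tables and their descriptive statistics.

The dependent-variable block of the calibration problem is a sample ×
component content matrix (19 conventional tobacco analytes: sugars,
alkaloids, nitrogen, inorganics, ...). This module holds the container and
the two descriptive analyses run before modelling: per-component density
distributions and the inter-component Pearson correlation matrix, which
motivates modelling each component independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CompositionTable",
    "CorrelationMatrix",
    "density_distribution",
    "correlation_matrix",
    "high_correlation_pairs",
]


@dataclass
class CompositionTable:
    """Sample × component content matrix with per-component units.

    ``data`` is indexed by sample id with one column per component; units
    map component name → one of ``%``, ``mg/g`` or ``pH-unit``.
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("composition table contains missing values")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("composition table contains non-finite values")
        for name, unit in self.units.items():
            if unit == "pH-unit" and len(self.data) and name in self.data.columns:
                col = self.data[name]
                if ((col <= 0) | (col >= 14)).any():
                    raise ValueError(f"column '{name}': pH values must lie in (0, 14)")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def component_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    def values_for(self, component: str) -> np.ndarray:
        return self.data[component].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.data.rename_axis("sample_id").to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path, units: dict[str, str] | None = None) -> "CompositionTable":
        df = pd.read_csv(path, index_col="sample_id")
        return cls(data=df, units=units or {})


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over components.

    Constant columns yield NaN rows/columns (flagged in ``undefined``).
    """

    names: list[str]
    values: np.ndarray
    undefined: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.names)
        if self.values.shape != (k, k):
            raise ValueError("correlation matrix shape does not match names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("component").to_csv(path)


def density_distribution(
    table: CompositionTable, n_bins: int = 20
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Binned probability distribution of each component's content.

    For each component the observed range [min, max] is divided into
    ``n_bins`` equal-width intervals and the fraction of samples per
    interval is reported. Returns component → (bin_edges, probabilities);
    probabilities sum to 1. A constant column collapses to one degenerate
    bin with probability 1.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    if table.n_samples < 1:
        raise ValueError("need at least one sample")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in table.component_names:
        x = table.values_for(name)
        lo, hi = float(np.min(x)), float(np.max(x))
        if lo == hi:
            out[name] = (np.array([lo, hi]), np.array([1.0]))
            continue
        counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
        out[name] = (edges, counts / counts.sum())
    return out


def correlation_matrix(
    table: CompositionTable, method: str = "pearson"
) -> CorrelationMatrix:
    """Pairwise correlation over all components.

    Pearson (linear) correlation by default; ``method='spearman'`` is
    available for rank correlation. Components with zero variance are
    flagged and their pairs reported as NaN.
    """
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method '{method}'")
    constant = [
        name
        for name in table.component_names
        if float(np.std(table.values_for(name))) == 0.0
    ]
    corr = table.data.corr(method=method)
    values = corr.to_numpy()
    np.fill_diagonal(values, 1.0)
    for name in constant:
        i = table.component_names.index(name)
        values[i, :] = np.nan
        values[:, i] = np.nan
        values[i, i] = 1.0
    return CorrelationMatrix(
        names=table.component_names, values=values, undefined=constant
    )


def high_correlation_pairs(
    matrix: CorrelationMatrix, threshold: float = 0.9
) -> list[tuple[str, str, float]]:
    """Component pairs with |r| above ``threshold``, strongest first.

    Each unordered pair appears once; pairs with undefined correlation are
    omitted.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    pairs = []
    k = len(matrix.names)
    for i in range(k):
        for j in range(i + 1, k):
            r = matrix.values[i, j]
            if np.isfinite(r) and abs(r) > threshold:
                pairs.append((matrix.names[i], matrix.names[j], float(r)))
    return sorted(pairs, key=lambda p: abs(p[2]), reverse=True)
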