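"""Variable importance in projection (VIP) and temperature-interval screening.

For a fitted PLS model, the VIP score of predictor j aggregates its
contribution to each latent variable, weighted by how much response
variance that latent variable explains:

    VIP_j = sqrt( p · Σ_a SS_a (w_ja / ‖w_a‖)² / Σ_a SS_a )

The mean squared VIP is exactly 1, so VIP > 1 flags above-average
importance. Contiguous runs of above-threshold grid points become
characteristic temperature intervals; a PLS model refitted on those
columns alone validates the screening (its test R² should drop only
marginally when the intervals carry the signal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .models import NipalsPLS, SplitSpec, r_squared, rmse, select_n_latent

__all__ = [
    "VIPProfile",
    "IntervalSet",
    "vip_scores",
    "extract_intervals",
    "restrict_to_intervals",
    "refit_and_compare",
    "RefitComparison",
    "interval_jaccard",
    "VIPIntervalSelector",
]


@dataclass
class VIPProfile:
    """VIP score per temperature grid point of one fitted model."""

    temperatures: np.ndarray
    vip: np.ndarray
    component: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.vip = np.asarray(self.vip, dtype=float)
        if len(self.temperatures) != len(self.vip):
            raise ValueError("temperature/vip length mismatch")
        if np.any(self.vip < 0):
            raise ValueError("VIP scores are non-negative by definition")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"temperature_C": self.temperatures, "vip": self.vip}
        ).to_csv(path, index=False)


@dataclass
class IntervalSet:
    """Sorted, pairwise-disjoint closed temperature intervals."""

    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        iv = sorted((float(lo), float(hi)) for lo, hi in self.intervals)
        for lo, hi in iv:
            if lo > hi:
                raise ValueError(f"interval ({lo}, {hi}) has lo > hi")
        for (alo, ahi), (blo, bhi) in zip(iv, iv[1:]):
            if blo <= ahi:
                raise ValueError("intervals overlap; merge them first")
        self.intervals = iv

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def total_length(self) -> float:
        return sum(hi - lo for lo, hi in self.intervals)

    def compact(self, fmt: str = "{lo:g}-{hi:g}") -> str:
        """The 'lo-hi,lo-hi' string form used in reports."""
        return ",".join(fmt.format(lo=lo, hi=hi) for lo, hi in self.intervals)

    def to_json(self) -> str:
        return json.dumps({"intervals": self.intervals})

    @classmethod
    def from_json(cls, text: str) -> "IntervalSet":
        return cls(intervals=[tuple(p) for p in json.loads(text)["intervals"]])


def vip_scores(model: NipalsPLS, temperatures: np.ndarray, component: str = "") -> VIPProfile:
    """VIP score per predictor of a fitted :class:`NipalsPLS`.

    Satisfies the normalization identity Σ_j VIP_j² = p; with a single
    predictor the score is exactly 1.
    """
    check_is_fitted(model, "coef_")
    temperatures = np.asarray(temperatures, dtype=float)
    W = model.x_weights_
    ss = model.ss_y_
    p = W.shape[0]
    if len(temperatures) != p:
        raise ValueError("temperatures length does not match model predictors")
    total = float(ss.sum())
    if total <= 0:
        raise ValueError("degenerate fit: no response variance explained")
    wn2 = W**2 / np.sum(W**2, axis=0)  # (w_ja/‖w_a‖)², columns sum to 1
    vip = np.sqrt(p * (wn2 @ ss) / total)
    return VIPProfile(temperatures=temperatures, vip=vip, component=component)


def extract_intervals(
    profile: VIPProfile,
    threshold: float = 1.0,
    min_run: float = 2.0,
    merge_gap: float = 5.0,
) -> IntervalSet:
    """Temperature intervals where VIP exceeds ``threshold``.

    Maximal runs of consecutive above-threshold grid points are reported
    at grid temperatures; runs separated by gaps of at most ``merge_gap``
    °C are merged, and merged runs spanning less than ``min_run`` °C are
    dropped. The defaults (5 °C gap, 2 °C run) suppress the fragmentation
    that pointwise thresholding at fine grid resolution produces.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_run < 0 or merge_gap < 0:
        raise ValueError("min_run and merge_gap must be non-negative")
    mask = profile.vip > threshold
    temps = profile.temperatures
    runs: list[list[float]] = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            runs.append([float(temps[i]), float(temps[j])])
            i = j + 1
        else:
            i += 1
    merged: list[list[float]] = []
    for lo, hi in runs:
        if merged and lo - merged[-1][1] <= merge_gap:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])
    kept = [(lo, hi) for lo, hi in merged if hi - lo >= min_run]
    return IntervalSet(intervals=kept)


def restrict_to_intervals(
    X: np.ndarray, temperatures: np.ndarray, intervals: IntervalSet
) -> tuple[np.ndarray, np.ndarray]:
    """Keep the DTG columns whose temperature falls in any interval.

    Returns ``(X_restricted, kept_temperatures)`` with column order
    preserved.
    """
    if len(intervals) == 0:
        raise ValueError("empty interval set: nothing to fit")
    temperatures = np.asarray(temperatures, dtype=float)
    mask = np.zeros(len(temperatures), dtype=bool)
    for lo, hi in intervals:
        mask |= (temperatures >= lo) & (temperatures <= hi)
    if not mask.any():
        raise ValueError("intervals select no grid columns")
    return np.asarray(X, dtype=float)[:, mask], temperatures[mask]


@dataclass
class RefitComparison:
    """Full-grid vs interval-restricted PLS performance."""

    component: str
    intervals: IntervalSet
    r2_train_full: float
    r2_train_restricted: float
    rmse_train_full: float
    rmse_train_restricted: float
    r2_test_full: float
    r2_test_restricted: float
    rmse_test_full: float
    rmse_test_restricted: float
    n_latent_full: int
    n_latent_restricted: int

    @property
    def delta_r2_train(self) -> float:
        return self.r2_train_full - self.r2_train_restricted

    @property
    def delta_r2_test(self) -> float:
        return self.r2_test_full - self.r2_test_restricted

    def to_dict(self) -> dict:
        return {
            "component": self.component,
            "intervals": self.intervals.compact(),
            "r2_train_full": self.r2_train_full,
            "r2_train_restricted": self.r2_train_restricted,
            "rmse_train_full": self.rmse_train_full,
            "rmse_train_restricted": self.rmse_train_restricted,
            "r2_test_full": self.r2_test_full,
            "r2_test_restricted": self.r2_test_restricted,
            "rmse_test_full": self.rmse_test_full,
            "rmse_test_restricted": self.rmse_test_restricted,
            "delta_r2_train": self.delta_r2_train,
            "delta_r2_test": self.delta_r2_test,
            "n_latent_full": self.n_latent_full,
            "n_latent_restricted": self.n_latent_restricted,
        }


def refit_and_compare(
    X: np.ndarray,
    y: np.ndarray,
    temperatures: np.ndarray,
    intervals: IntervalSet,
    split: SplitSpec,
    max_components: int = 30,
    cv_folds: int = 10,
    seed: int = 0,
    component: str = "",
) -> RefitComparison:
    """Compare PLS on the full grid vs restricted to ``intervals``.

    Both fits use the same train/test split; the latent-variable count is
    re-selected after restriction because the restricted predictor block
    has different rank.
    """
    if split.train_idx is None:
        raise ValueError("split must be populated via split_dataset")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Xr, _ = restrict_to_intervals(X, temperatures, intervals)

    out = {}
    for tag, Xblock in (("full", X), ("restricted", Xr)):
        Xtr, Xte = Xblock[split.train_idx], Xblock[split.test_idx]
        ytr, yte = y[split.train_idx], y[split.test_idx]
        max_A = min(max_components, Xblock.shape[1], len(ytr) - 1)
        A = select_n_latent(Xtr, ytr, max_A, cv_folds=cv_folds, seed=seed)
        m = NipalsPLS(A).fit(Xtr, ytr)
        out[tag] = {
            "r2_train": r_squared(ytr, m.predict(Xtr)),
            "rmse_train": rmse(ytr, m.predict(Xtr)),
            "r2_test": r_squared(yte, m.predict(Xte)),
            "rmse_test": rmse(yte, m.predict(Xte)),
            "A": m.n_components_,
        }
    return RefitComparison(
        component=component,
        intervals=intervals,
        r2_train_full=out["full"]["r2_train"],
        r2_train_restricted=out["restricted"]["r2_train"],
        rmse_train_full=out["full"]["rmse_train"],
        rmse_train_restricted=out["restricted"]["rmse_train"],
        r2_test_full=out["full"]["r2_test"],
        r2_test_restricted=out["restricted"]["r2_test"],
        rmse_test_full=out["full"]["rmse_test"],
        rmse_test_restricted=out["restricted"]["rmse_test"],
        n_latent_full=out["full"]["A"],
        n_latent_restricted=out["restricted"]["A"],
    )


def interval_jaccard(a: IntervalSet | Sequence, b: IntervalSet | Sequence) -> float:
    """Jaccard overlap of two interval unions (length of ∩ / length of ∪)."""

    def _union(iv):
        iv = sorted((float(lo), float(hi)) for lo, hi in iv)
        merged = []
        for lo, hi in iv:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        return merged

    ua, ub = _union(list(a)), _union(list(b))
    if not ua and not ub:
        return 1.0
    inter = 0.0
    for alo, ahi in ua:
        for blo, bhi in ub:
            inter += max(0.0, min(ahi, bhi) - max(alo, blo))
    len_a = sum(hi - lo for lo, hi in ua)
    len_b = sum(hi - lo for lo, hi in ub)
    union = len_a + len_b - inter
    return inter / union if union > 0 else 1.0


class VIPIntervalSelector(BaseEstimator, TransformerMixin):
    """sklearn transformer: fit PLS, score VIP, keep characteristic columns.

    Parameters mirror :func:`extract_intervals`; ``n_components=None``
    selects the latent-variable count by the cumulative-contribution +
    RMSECV rule. After ``fit(X, y)`` the fitted attributes expose the
    profile (``vip_``), the interval set (``intervals_``) and the column
    mask (``support_``); ``transform`` restricts a matrix to the selected
    columns.
    """

    def __init__(
        self,
        temperatures: np.ndarray | None = None,
        threshold: float = 1.0,
        min_run: float = 2.0,
        merge_gap: float = 5.0,
        n_components: int | None = None,
        max_components: int = 30,
        cv_folds: int = 10,
        seed: int = 0,
    ):
        self.temperatures = temperatures
        self.threshold = threshold
        self.min_run = min_run
        self.merge_gap = merge_gap
        self.n_components = n_components
        self.max_components = max_components
        self.cv_folds = cv_folds
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "VIPIntervalSelector":
        X = np.asarray(X, dtype=float)
        temps = (
            np.asarray(self.temperatures, dtype=float)
            if self.temperatures is not None
            else np.arange(X.shape[1], dtype=float)
        )
        A = self.n_components or select_n_latent(
            X, y, min(self.max_components, X.shape[1], X.shape[0] - 1),
            cv_folds=self.cv_folds, seed=self.seed,
        )
        self.pls_ = NipalsPLS(A).fit(X, y)
        profile = vip_scores(self.pls_, temps)
        self.vip_ = profile
        self.intervals_ = extract_intervals(
            profile, self.threshold, self.min_run, self.merge_gap
        )
        mask = np.zeros(len(temps), dtype=bool)
        for lo, hi in self.intervals_:
            mask |= (temps >= lo) & (temps <= hi)
        self.support_ = mask
        self.temperatures_ = temps
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "support_")
        return np.asarray(X, dtype=float)[:, self.support_]
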