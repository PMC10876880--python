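"""TGA trace preprocessing: normalization, differentiation, gridding.

A thermogravimetric analyzer records (time, temperature, mass) triples
during a drying hold followed by a constant-rate ramp. Calibration models
need one mass-loss-rate value per shared temperature grid point, so raw
traces are normalized to the dry reference mass, differentiated with
respect to temperature, and linearly interpolated onto a uniform grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .grids import GridSpec

__all__ = [
    "TGATrace",
    "DTGCurve",
    "normalize_trace",
    "differentiate",
    "interpolate_to_grid",
    "preprocess_trace",
    "compute_nrmse",
    "read_tga_csv",
    "write_tga_csv",
    "curves_to_matrix",
    "write_dtg_matrix_csv",
    "read_dtg_matrix_csv",
]


@dataclass
class TGATrace:
    """A raw or normalized thermobalance record for one sample.

    ``mass_mg`` holds milligrams for raw traces and a dimensionless
    fraction of the reference (dry) mass once :func:`normalize_trace` has
    been applied, in which case ``reference_mass_mg`` is set.
    """

    sample_id: str
    time_min: np.ndarray
    temperature_C: np.ndarray
    mass_mg: np.ndarray
    segments: np.ndarray | None = None  # optional per-point 'hold'/'ramp'
    reference_mass_mg: float | None = None

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.mass_mg = np.asarray(self.mass_mg, dtype=float)
        n = len(self.time_min)
        if not (len(self.temperature_C) == len(self.mass_mg) == n):
            raise ValueError("time/temperature/mass lengths differ")
        if n < 2:
            raise ValueError("a trace needs at least 2 points")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.mass_mg <= 0):
            raise ValueError("mass must stay positive")

    def __len__(self) -> int:
        return len(self.time_min)


@dataclass
class DTGCurve:
    """Normalized mass-loss rate on a uniform temperature grid.

    ``rate`` is in fraction of reference mass per °C; positive values mean
    mass loss. Length always equals ``grid.count``.
    """

    sample_id: str
    grid: GridSpec
    rate: np.ndarray

    def __post_init__(self) -> None:
        self.rate = np.asarray(self.rate, dtype=float)
        if len(self.rate) != self.grid.count:
            raise ValueError(
                f"rate length {len(self.rate)} != grid count {self.grid.count}"
            )
        if not np.all(np.isfinite(self.rate)):
            raise ValueError("rate contains non-finite values")

    def temperatures(self) -> np.ndarray:
        return self.grid.temperatures()


def normalize_trace(
    trace: TGATrace, grid_start: float = 105.0, hold_tol: float = 1e-6
) -> TGATrace:
    """Normalize mass to the dry reference and trim to the ramp.

    The reference is the mass at the end of the drying hold: the last
    recorded point whose temperature does not exceed ``grid_start`` (by
    more than ``hold_tol``), or, when segment labels are present, the last
    point labelled ``'hold'``. The returned trace has mass expressed as a
    fraction of that reference and is trimmed to temperatures at or above
    ``grid_start``.
    """
    if trace.segments is not None and np.any(trace.segments == "hold"):
        ref_idx = int(np.max(np.nonzero(trace.segments == "hold")[0]))
    else:
        below = np.nonzero(trace.temperature_C <= grid_start + hold_tol)[0]
        if len(below) == 0:
            raise ValueError(
                f"trace '{trace.sample_id}' has no point at/before the "
                f"{grid_start} °C hold end"
            )
        ref_idx = int(below[-1])
    ref = float(trace.mass_mg[ref_idx])
    if ref <= 0:
        raise ValueError(f"reference mass must be positive, got {ref}")

    keep = trace.temperature_C >= grid_start - hold_tol
    keep[ref_idx] = True  # always keep the reference point itself
    return TGATrace(
        sample_id=trace.sample_id,
        time_min=trace.time_min[keep],
        temperature_C=trace.temperature_C[keep],
        mass_mg=trace.mass_mg[keep] / ref,
        segments=None if trace.segments is None else trace.segments[keep],
        reference_mass_mg=ref,
    )


def differentiate(trace: TGATrace) -> tuple[np.ndarray, np.ndarray]:
    """Mass-loss rate versus temperature by central differences.

    Consecutive points sharing a temperature (e.g. residual hold samples)
    are collapsed by averaging their masses before differencing. Returns
    ``(temperatures, rate)`` where ``rate_i`` is the negative derivative of
    normalized mass with respect to temperature (central differences at
    interior points, one-sided at the ends), so mass loss is positive.
    """
    order = np.argsort(trace.temperature_C, kind="stable")
    t = trace.temperature_C[order]
    m = trace.mass_mg[order]
    # collapse duplicate temperatures by averaging mass
    uniq_t, inverse = np.unique(t, return_inverse=True)
    if len(uniq_t) != len(t):
        sums = np.bincount(inverse, weights=m)
        counts = np.bincount(inverse)
        m = sums / counts
        t = uniq_t
    if len(t) < 2:
        raise ValueError("need at least 2 distinct temperatures to differentiate")
    rate = -np.gradient(m, t)
    return t, rate


def interpolate_to_grid(
    temperatures: np.ndarray,
    rate: np.ndarray,
    grid: GridSpec,
    sample_id: str = "",
    margin: float = 1.0,
) -> DTGCurve:
    """Linearly interpolate raw (temperature, rate) samples onto ``grid``.

    The data must span the grid up to ``margin`` °C of allowed edge
    extrapolation (values are held at the nearest data point within the
    margin).
    """
    temperatures = np.asarray(temperatures, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if grid.start < temperatures[0] - margin:
        raise ValueError(
            f"grid start {grid.start} °C lies {temperatures[0] - grid.start:.2f} °C "
            f"below the data minimum {temperatures[0]:.2f} °C (margin {margin})"
        )
    last = grid.temperatures()[-1]
    if last > temperatures[-1] + margin:
        raise ValueError(
            f"grid end {last} °C lies {last - temperatures[-1]:.2f} °C above the "
            f"data maximum {temperatures[-1]:.2f} °C (margin {margin})"
        )
    values = np.interp(grid.temperatures(), temperatures, rate)
    return DTGCurve(sample_id=sample_id, grid=grid, rate=values)


def preprocess_trace(
    trace: TGATrace,
    grid: GridSpec,
    margin: float = 1.0,
    smooth: bool = False,
    smooth_window: int = 21,
    smooth_order: int = 2,
) -> DTGCurve:
    """Full raw-trace → DTG pipeline: normalize, differentiate, grid.

    Optional Savitzky–Golay smoothing of the gridded rate is off by
    default; the window is in grid points and must be odd.
    """
    norm = normalize_trace(trace, grid_start=grid.start)
    t, rate = differentiate(norm)
    curve = interpolate_to_grid(t, rate, grid, sample_id=trace.sample_id, margin=margin)
    if smooth:
        curve = replace(
            curve, rate=savgol_filter(curve.rate, smooth_window, smooth_order)
        )
    return curve


def compute_nrmse(ref: DTGCurve, other: DTGCurve) -> float:
    """Range-normalized RMSE between two curves, in percent.

    ``100 * RMSE(ref, other) / (max(ref) - min(ref))``. The normalization
    uses the *first* argument's range, so the measure is asymmetric: pass
    the reference trial first.
    """
    if ref.grid != other.grid:
        raise ValueError("curves must share a grid")
    rng = float(np.max(ref.rate) - np.min(ref.rate))
    if rng == 0:
        raise ValueError("reference curve is constant; NRMSE undefined")
    rmse = float(np.sqrt(np.mean((ref.rate - other.rate) ** 2)))
    return 100.0 * rmse / rng


# ---------------------------------------------------------------------------
# I/O


def read_tga_csv(path: str | Path, sample_id: str | None = None) -> TGATrace:
    """Read a trace CSV with columns time_min, temperature_C, mass_mg."""
    df = pd.read_csv(path)
    cols = {"time_min", "temperature_C", "mass_mg"}
    if not cols.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(cols)}")
    return TGATrace(
        sample_id=sample_id or Path(path).stem,
        time_min=df["time_min"].to_numpy(),
        temperature_C=df["temperature_C"].to_numpy(),
        mass_mg=df["mass_mg"].to_numpy(),
        segments=df["segment"].to_numpy() if "segment" in df.columns else None,
    )


def write_tga_csv(trace: TGATrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_min": trace.time_min,
            "temperature_C": trace.temperature_C,
            "mass_mg": trace.mass_mg,
        }
    )
    if trace.segments is not None:
        df["segment"] = trace.segments
    df.to_csv(path, index=False)


def curves_to_matrix(curves: list[DTGCurve]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack curves into an (n_samples, n_grid) matrix.

    Returns ``(X, temperatures, sample_ids)``; all curves must share a grid.
    """
    if not curves:
        raise ValueError("no curves given")
    grid = curves[0].grid
    for c in curves:
        if c.grid != grid:
            raise ValueError("curves are on different grids")
    X = np.vstack([c.rate for c in curves])
    return X, grid.temperatures(), [c.sample_id for c in curves]


def write_dtg_matrix_csv(
    curves: list[DTGCurve], path: str | Path, meta_path: str | Path | None = None
) -> None:
    """Write curves as a matrix CSV (temperature_C + one column per sample)."""
    X, temps, ids = curves_to_matrix(curves)
    df = pd.DataFrame(X.T, columns=ids)
    df.insert(0, "temperature_C", temps)
    df.to_csv(path, index=False)
    if meta_path is not None:
        g = curves[0].grid
        meta = {
            "grid": {"start": g.start, "stop": g.stop, "step": g.step, "count": g.count},
            "sample_ids": ids,
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2))


def read_dtg_matrix_csv(path: str | Path) -> list[DTGCurve]:
    df = pd.read_csv(path)
    temps = df["temperature_C"].to_numpy()
    step = float(np.median(np.diff(temps)))
    grid = GridSpec(float(temps[0]), float(temps[-1]) + step / 2, step)
    if grid.count != len(temps):
        grid = GridSpec(float(temps[0]), float(temps[-1]), step)
    return [
        DTGCurve(sample_id=col, grid=grid, rate=df[col].to_numpy())
        for col in df.columns
        if col != "temperature_C"
    ]
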