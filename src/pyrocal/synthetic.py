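"""Synthetic tobacco pyrolysis data with the structure calibration assumes.

The generator emulates a 157-sample thermogravimetric study: a composition
table of 19 conventional analytes with non-uniform marginals and a few
strongly correlated pairs, DTG curves built from two shared pyrolysis
stages (≈105–230 °C volatiles, ≈230–500 °C biopolymers) plus per-component
Gaussian signal windows, temperature-correlated instrument noise, and raw
thermobalance traces sampled at 120 points/min along a 105 °C hold +
10 °C/min ramp.

Design notes
------------
* The composition → DTG map is exactly affine when ``curve_noise_sd = 0``:
  each component adds ``content × Σ gaussian windows`` to the shared
  baseline. Peak shapes are Gaussian — the simplest smooth unimodal form,
  adequate for exercising linear calibration.
* Curve noise is band-limited: white noise smoothed to a correlation
  length of a few °C, matching what differentiated, interpolated balance
  readings look like. Its default magnitude is set so replicate curves
  disagree by an NRMSE of order 1%, the repeatability level of a
  well-maintained thermobalance.
* Measured compositions carry wet-chemistry assay error
  (``assay_noise_frac`` of each component's between-sample spread),
  applied by :func:`measure_composition` so the table used as regression
  target is a noisy reading of the contents that actually shaped the
  curves.
* Correlated component pairs are produced by a Gaussian copula with
  truncated-normal marginals, which controls Pearson r approximately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter1d
from scipy.stats import norm, truncnorm

from .composition import CompositionTable
from .grids import GridSpec
from .preprocess import DTGCurve, TGATrace

__all__ = [
    "SignalWindow",
    "ComponentDef",
    "BaselinePeak",
    "SyntheticSpec",
    "default_components",
    "default_corr_pairs",
    "default_baseline_peaks",
    "generate_composition",
    "measure_composition",
    "generate_dtg_curves",
    "render_tga_trace",
    "make_replicates",
    "correlated_noise",
]


@dataclass(frozen=True)
class SignalWindow:
    """One temperature window where a component imprints on the DTG curve.

    The contribution is a Gaussian centred at the window midpoint with
    standard deviation ``width`` °C, scaled by ``amplitude`` (rate units,
    fraction/°C) per unit of content. ``(t_lo, t_hi)`` is the nominal
    support used as ground truth in interval-recovery experiments.
    """

    t_lo: float
    t_hi: float
    amplitude: float
    width: float

    def __post_init__(self) -> None:
        if self.t_lo >= self.t_hi:
            raise ValueError(f"window requires t_lo < t_hi, got ({self.t_lo}, {self.t_hi})")
        if self.width <= 0:
            raise ValueError("window width must be positive")
        if not np.isfinite(self.amplitude):
            raise ValueError("window amplitude must be finite")

    @property
    def center(self) -> float:
        return 0.5 * (self.t_lo + self.t_hi)

    def profile(self, temperatures: np.ndarray) -> np.ndarray:
        z = (temperatures - self.center) / self.width
        return self.amplitude * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class ComponentDef:
    """Content distribution and DTG imprint of one chemical component."""

    name: str
    unit: str  # '%', 'mg/g' or 'pH-unit'
    dist_mean: float
    dist_sd: float
    bounds: tuple[float, float]
    signal_windows: tuple[SignalWindow, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if lo >= hi:
            raise ValueError(f"{self.name}: bounds require lo < hi")
        if self.dist_sd < 0:
            raise ValueError(f"{self.name}: dist_sd must be non-negative")
        if self.unit not in ("%", "mg/g", "pH-unit"):
            raise ValueError(f"{self.name}: unknown unit '{self.unit}'")

    def profile(self, temperatures: np.ndarray) -> np.ndarray:
        """Per-unit-content DTG contribution on a temperature array."""
        out = np.zeros_like(temperatures, dtype=float)
        for w in self.signal_windows:
            out += w.profile(temperatures)
        return out


@dataclass(frozen=True)
class BaselinePeak:
    """A pseudo-biopolymer decomposition peak shared by every sample."""

    center: float
    width: float
    amplitude: float

    def profile(self, temperatures: np.ndarray) -> np.ndarray:
        z = (temperatures - self.center) / self.width
        return self.amplitude * np.exp(-0.5 * z * z)


def _win(t_lo: float, t_hi: float, peak_sd: float, dist_sd: float, width: float | None = None) -> SignalWindow:
    """Window whose per-sample peak contribution has sd ``peak_sd`` (rate units)."""
    width = width if width is not None else (t_hi - t_lo) / 6.0
    amp = peak_sd / dist_sd if dist_sd > 0 else 0.0
    return SignalWindow(t_lo=t_lo, t_hi=t_hi, amplitude=amp, width=width)


# Peak signal levels (rate units, fraction/°C): most components contribute
# comparable between-sample curve variance regardless of their content units;
# the two sugar components get a larger imprint because sugars dominate the
# first pyrolysis stage of tobacco.
_S_MAIN = 8.0e-5
_S_SEC = 5.0e-5
_S_SUGAR_MAIN = 1.4e-4
_S_SUGAR_SEC = 9.8e-5


def default_components() -> tuple[ComponentDef, ...]:
    """The 19-component default panel.

    Content distributions are illustrative values typical of flue-cured
    tobacco; signal windows cluster in the 130–470 °C region where tobacco
    constituents decompose, with the three representative components
    (total phytoaloids, reducing sugar, total nitrogen) given narrower,
    better-separated windows than the remaining panel.
    """

    def comp(name, unit, mean, sd, bounds, wins):
        return ComponentDef(
            name=name, unit=unit, dist_mean=mean, dist_sd=sd, bounds=bounds,
            signal_windows=tuple(_win(lo, hi, s, sd, w) for (lo, hi, s, w) in wins),
        )

    return (
        comp("Total phytoaloids", "%", 2.4, 0.6, (0.5, 5.0),
             [(200, 260, _S_MAIN, 10.0), (330, 380, 5.6e-5, 8.3)]),
        comp("Reducing sugar", "%", 20.0, 5.0, (5.0, 35.0),
             [(166, 244, _S_SUGAR_MAIN, 13.0), (252, 318, _S_SUGAR_SEC, 11.0)]),
        comp("Total sugar", "%", 24.0, 5.5, (6.0, 40.0),
             [(162, 258, _S_SUGAR_MAIN, 16.0), (253, 337, _S_SUGAR_SEC, 14.0)]),
        comp("Total nitrogen", "%", 2.2, 0.45, (1.0, 4.0),
             [(214, 286, _S_MAIN, 12.0), (290, 350, 5.6e-5, 10.0)]),
        comp("Potassium", "%", 2.0, 0.55, (0.5, 4.0),
             [(198, 322, _S_MAIN, 25.0), (348, 472, _S_SEC, 25.0)]),
        comp("Chlorine", "%", 0.45, 0.25, (0.02, 1.8),
             [(118, 242, _S_MAIN, 25.0), (288, 412, _S_SEC, 25.0)]),
        comp("pH", "pH-unit", 5.4, 0.25, (4.5, 6.5),
             [(140, 250, 2.0e-5, 22.0), (240, 360, 1.5e-5, 24.0)]),
        comp("Starch", "%", 3.5, 1.2, (0.5, 8.0),
             [(150, 260, _S_MAIN, 22.0), (250, 370, _S_SEC, 24.0)]),
        comp("Dichloromethane extract", "%", 6.5, 1.6, (2.0, 12.0),
             [(175, 305, _S_MAIN, 26.0), (318, 442, _S_SEC, 25.0)]),
        comp("Solanesol", "mg/g", 15.0, 4.5, (3.0, 30.0),
             [(185, 315, _S_MAIN, 26.0), (328, 452, _S_SEC, 25.0)]),
        comp("Sulfate", "mg/g", 12.0, 3.5, (2.0, 25.0),
             [(115, 225, _S_MAIN, 22.0), (360, 500, _S_SEC, 28.0)]),
        comp("Phosphate", "mg/g", 4.5, 1.2, (1.0, 9.0),
             [(160, 280, _S_MAIN, 24.0), (390, 530, _S_SEC, 28.0)]),
        comp("Magnesium", "%", 0.55, 0.16, (0.1, 1.2),
             [(165, 295, _S_MAIN, 26.0), (355, 485, _S_SEC, 26.0)]),
        comp("Calcium", "%", 2.2, 0.65, (0.5, 4.5),
             [(155, 275, _S_MAIN, 24.0), (275, 405, _S_SEC, 26.0)]),
        comp("Polyphenols", "mg/g", 28.0, 6.5, (8.0, 50.0),
             [(195, 315, _S_MAIN, 24.0), (265, 395, _S_SEC, 26.0)]),
        comp("Refractory acid", "mg/g", 45.0, 14.0, (10.0, 90.0),
             [(165, 285, _S_MAIN, 24.0), (295, 425, _S_SEC, 26.0)]),
        comp("Amino acids", "mg/g", 12.0, 3.5, (2.0, 25.0),
             [(125, 225, _S_MAIN, 20.0), (210, 330, _S_SEC, 24.0)]),
        comp("Amadori compounds", "mg/g", 10.0, 3.0, (1.0, 20.0),
             [(110, 210, _S_MAIN, 20.0), (230, 350, _S_SEC, 24.0)]),
        comp("Neophytadiene", "mg/g", 1.6, 0.45, (0.2, 3.5),
             [(140, 230, _S_MAIN, 18.0), (195, 295, _S_SEC, 20.0)]),
    )


def default_corr_pairs() -> tuple[tuple[str, str, float], ...]:
    """Strongly correlated analyte pairs in the default panel."""
    return (
        ("Total sugar", "Reducing sugar", 0.95),
        ("Dichloromethane extract", "Solanesol", 0.92),
        ("Calcium", "Refractory acid", 0.91),
    )


def default_baseline_peaks() -> tuple[BaselinePeak, ...]:
    """Two pyrolysis stages plus a small high-temperature char peak."""
    return (
        BaselinePeak(center=185.0, width=28.0, amplitude=1.0e-3),
        BaselinePeak(center=330.0, width=55.0, amplitude=1.2e-3),
        BaselinePeak(center=700.0, width=70.0, amplitude=3.0e-4),
    )


@dataclass
class SyntheticSpec:
    """Full description of one simulated study.

    The defaults describe the kind of study the calibration targets:
    157 samples, the
    19-component panel, three |r| > 0.9 pairs, two shared pyrolysis
    stages, and noise levels calibrated so replicate DTG curves differ by a
    range-normalized RMSE of a few tenths of a percent, inside the
    repeatability band a well-maintained thermobalance achieves.
    """

    n_samples: int = 157
    components: tuple[ComponentDef, ...] = field(default_factory=default_components)
    corr_pairs: tuple[tuple[str, str, float], ...] = field(default_factory=default_corr_pairs)
    baseline_peaks: tuple[BaselinePeak, ...] = field(default_factory=default_baseline_peaks)
    curve_noise_sd: float = 1.6e-5  # fraction/°C, per grid point
    curve_noise_corr: float = 8.0  # correlation length of curve noise, °C
    replicate_noise_sd: float = 5.0e-5  # mg, per balance reading
    assay_noise_frac: float = 0.25  # assay error as fraction of dist_sd
    grid: GridSpec = field(default_factory=GridSpec)
    hold_min: float = 30.0  # drying hold duration
    ramp_rate: float = 10.0  # °C/min
    points_per_min: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")
        if self.curve_noise_sd < 0 or self.replicate_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.assay_noise_frac < 0:
            raise ValueError("assay_noise_frac must be non-negative")
        names = {c.name for c in self.components}
        if len(names) != len(self.components):
            raise ValueError("duplicate component names")
        for a, b, r in self.corr_pairs:
            for nm in (a, b):
                if nm not in names:
                    raise ValueError(f"corr_pair component '{nm}' not in the panel")
            if not abs(r) < 1:
                raise ValueError(f"corr_pair target |r| must be < 1, got {r}")
        for c in self.components:
            for w in c.signal_windows:
                if w.t_lo < self.grid.start - 1e-9 or w.t_hi > self.grid.stop + 1e-9:
                    raise ValueError(
                        f"{c.name}: window ({w.t_lo}, {w.t_hi}) outside grid span"
                    )

    @property
    def component_names(self) -> list[str]:
        return [c.name for c in self.components]

    def units(self) -> dict[str, str]:
        return {c.name: c.unit for c in self.components}

    # deterministic per-stage random generators
    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(8)[stream])

    # ---- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "components": [
                {
                    "name": c.name, "unit": c.unit, "dist_mean": c.dist_mean,
                    "dist_sd": c.dist_sd, "bounds": list(c.bounds),
                    "signal_windows": [
                        {"t_lo": w.t_lo, "t_hi": w.t_hi,
                         "amplitude": w.amplitude, "width": w.width}
                        for w in c.signal_windows
                    ],
                }
                for c in self.components
            ],
            "corr_pairs": [list(p) for p in self.corr_pairs],
            "baseline_peaks": [
                {"center": p.center, "width": p.width, "amplitude": p.amplitude}
                for p in self.baseline_peaks
            ],
            "curve_noise_sd": self.curve_noise_sd,
            "curve_noise_corr": self.curve_noise_corr,
            "replicate_noise_sd": self.replicate_noise_sd,
            "assay_noise_frac": self.assay_noise_frac,
            "grid": {"start": self.grid.start, "stop": self.grid.stop, "step": self.grid.step},
            "hold_min": self.hold_min,
            "ramp_rate": self.ramp_rate,
            "points_per_min": self.points_per_min,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        comps = tuple(
            ComponentDef(
                name=c["name"], unit=c["unit"], dist_mean=c["dist_mean"],
                dist_sd=c["dist_sd"], bounds=tuple(c["bounds"]),
                signal_windows=tuple(SignalWindow(**w) for w in c["signal_windows"]),
            )
            for c in d.pop("components")
        )
        peaks = tuple(BaselinePeak(**p) for p in d.pop("baseline_peaks"))
        pairs = tuple((a, b, float(r)) for a, b, r in d.pop("corr_pairs"))
        g = d.pop("grid")
        return cls(
            components=comps, baseline_peaks=peaks, corr_pairs=pairs,
            grid=GridSpec(g["start"], g["stop"], g["step"]), **d,
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticSpec":
        path = Path(path)
        if path.suffix == ".json":
            return cls.from_dict(json.loads(path.read_text()))
        return cls.from_dict(yaml.safe_load(path.read_text()))


# ---------------------------------------------------------------------------
# composition


def _pair_correlation_matrix(spec: SyntheticSpec) -> np.ndarray:
    names = spec.component_names
    k = len(names)
    R = np.eye(k)
    for a, b, r in spec.corr_pairs:
        i, j = names.index(a), names.index(b)
        R[i, j] = R[j, i] = r
    # ensure positive semi-definiteness (overlapping pairs could break it)
    w, V = np.linalg.eigh(R)
    if w.min() < 1e-10:
        w = np.clip(w, 1e-10, None)
        R = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R


def generate_composition(spec: SyntheticSpec) -> CompositionTable:
    """Draw a composition table via a Gaussian copula.

    Marginals are truncated normals (``dist_mean``, ``dist_sd``, ``bounds``);
    designated pairs are coupled through the copula so their sample Pearson
    correlation lands near the target. Reproducible for a fixed seed.
    """
    rng = spec._rng(0)
    names = spec.component_names
    n, k = spec.n_samples, len(names)
    ids = [f"S{i + 1:03d}" for i in range(n)]
    if n == 0:
        df = pd.DataFrame(np.empty((0, k)), columns=names)
        return CompositionTable(data=df, units=spec.units())

    L = np.linalg.cholesky(_pair_correlation_matrix(spec) + 1e-12 * np.eye(k))
    Z = rng.standard_normal((n, k)) @ L.T
    X = np.empty((n, k))
    for j, c in enumerate(spec.components):
        if c.dist_sd == 0:
            X[:, j] = c.dist_mean
            continue
        lo, hi = c.bounds
        a, b = (lo - c.dist_mean) / c.dist_sd, (hi - c.dist_mean) / c.dist_sd
        u = norm.cdf(Z[:, j])
        X[:, j] = truncnorm.ppf(u, a, b, loc=c.dist_mean, scale=c.dist_sd)
    df = pd.DataFrame(X, index=ids, columns=names)
    return CompositionTable(data=df, units=spec.units())


def measure_composition(table: CompositionTable, spec: SyntheticSpec) -> CompositionTable:
    """Emulate the wet-chemistry assay of a composition table.

    Adds independent Gaussian measurement error with standard deviation
    ``assay_noise_frac × dist_sd`` per component (clipped to the component
    bounds), mimicking flow-analyzer / HPLC reading error. With
    ``assay_noise_frac = 0`` the table is returned unchanged.
    """
    if spec.assay_noise_frac == 0 or table.n_samples == 0:
        return CompositionTable(data=table.data.copy(), units=dict(table.units))
    rng = spec._rng(2)
    df = table.data.copy()
    by_name = {c.name: c for c in spec.components}
    for name in df.columns:
        c = by_name.get(name)
        if c is None or c.dist_sd == 0:
            continue
        noisy = df[name].to_numpy() + rng.normal(
            0.0, spec.assay_noise_frac * c.dist_sd, len(df)
        )
        df[name] = np.clip(noisy, c.bounds[0], c.bounds[1])
    return CompositionTable(data=df, units=dict(table.units))


# ---------------------------------------------------------------------------
# curves and traces


def correlated_noise(
    rng: np.random.Generator, shape: tuple[int, int], sd: float, corr_pts: float
) -> np.ndarray:
    """Band-limited Gaussian noise along the last axis.

    White noise smoothed with a Gaussian kernel of ``corr_pts`` grid points
    and rescaled so each entry has standard deviation ``sd`` (using the
    continuous-kernel variance ``1/(2·corr_pts·sqrt(pi))``).
    """
    white = rng.standard_normal(shape)
    if corr_pts < 0.5:
        return sd * white
    smoothed = gaussian_filter1d(white, corr_pts, axis=-1, mode="reflect")
    theory_sd = 1.0 / np.sqrt(2.0 * corr_pts * np.sqrt(np.pi))
    return (sd / theory_sd) * smoothed


def baseline_profile(spec: SyntheticSpec, temperatures: np.ndarray | None = None) -> np.ndarray:
    temps = spec.grid.temperatures() if temperatures is None else temperatures
    out = np.zeros_like(temps, dtype=float)
    for p in spec.baseline_peaks:
        out += p.profile(temps)
    return out


def component_profiles(spec: SyntheticSpec, temperatures: np.ndarray | None = None) -> np.ndarray:
    """(n_components, n_grid) per-unit-content contribution matrix."""
    temps = spec.grid.temperatures() if temperatures is None else temperatures
    return np.vstack([c.profile(temps) for c in spec.components])


def generate_dtg_curves(table: CompositionTable, spec: SyntheticSpec) -> list[DTGCurve]:
    """One DTG curve per sample: baseline + content-weighted windows + noise.

    With ``curve_noise_sd = 0`` the composition → curve map is exactly
    affine, so superposition holds: doubling one component's content
    doubles that component's contribution.
    """
    if list(table.component_names) != spec.component_names:
        raise ValueError("table columns do not match the spec's component panel")
    rng = spec._rng(1)
    temps = spec.grid.temperatures()
    base = baseline_profile(spec)
    profiles = component_profiles(spec)
    contents = table.data.to_numpy(dtype=float)
    rates = base[None, :] + contents @ profiles
    if spec.curve_noise_sd > 0 and table.n_samples > 0:
        corr_pts = spec.curve_noise_corr / spec.grid.step
        rates = rates + correlated_noise(
            rng, (table.n_samples, len(temps)), spec.curve_noise_sd, corr_pts
        )
    return [
        DTGCurve(sample_id=sid, grid=spec.grid, rate=rates[i])
        for i, sid in enumerate(table.sample_ids)
    ]


def render_tga_trace(
    curve: DTGCurve, initial_mass_mg: float = 10.0, spec: SyntheticSpec | None = None
) -> TGATrace:
    """Integrate a DTG curve into a raw thermobalance trace.

    The simulated program is a ``hold_min`` isothermal hold at the grid
    start temperature followed by a ``ramp_rate`` °C/min ramp to the grid
    end, sampled at ``points_per_min`` readings per minute (temperature
    step ``ramp_rate / points_per_min`` °C between ramp samples). Mass
    starts at ``initial_mass_mg``, is constant during the hold (the sample
    is already dry), and follows ``m(T) = m0·(1 − ∫ rate dT)`` on the ramp.
    """
    spec = spec or SyntheticSpec(grid=curve.grid)
    if initial_mass_mg <= 0:
        raise ValueError("initial mass must be positive")
    g = curve.grid
    pps = spec.points_per_min
    dt = 1.0 / pps

    t_hold = np.arange(0.0, spec.hold_min, dt)
    n_ramp = int(np.floor((g.stop - g.start) / spec.ramp_rate * pps + 1e-9)) + 1
    t_ramp = spec.hold_min + dt * np.arange(n_ramp)
    temp_ramp = g.start + spec.ramp_rate * (t_ramp - spec.hold_min)

    # cumulative normalized mass lost, evaluated exactly for the
    # piecewise-linear rate at arbitrary ramp temperatures
    grid_t = g.temperatures()
    lost_knots = np.concatenate([[0.0], cumulative_trapezoid(curve.rate, grid_t)])
    k = np.clip(np.searchsorted(grid_t, temp_ramp, side="right") - 1, 0, g.count - 1)
    rate_at = np.interp(temp_ramp, grid_t, curve.rate)
    lost = lost_knots[k] + 0.5 * (curve.rate[k] + rate_at) * (temp_ramp - grid_t[k])
    mass_ramp = initial_mass_mg * (1.0 - lost)
    if np.any(mass_ramp <= 0):
        raise ValueError("integrated mass loss exceeds initial mass")

    time = np.concatenate([t_hold, t_ramp])
    temperature = np.concatenate([np.full(len(t_hold), g.start), temp_ramp])
    mass = np.concatenate([np.full(len(t_hold), initial_mass_mg), mass_ramp])
    segments = np.array(["hold"] * len(t_hold) + ["ramp"] * len(t_ramp))
    return TGATrace(
        sample_id=curve.sample_id,
        time_min=time,
        temperature_C=temperature,
        mass_mg=mass,
        segments=segments,
    )


def make_replicates(
    trace: TGATrace, n_reps: int, spec: SyntheticSpec, seed: int | None = None
) -> list[TGATrace]:
    """Simulate repeat runs of one sample.

    Each replicate is the input trace plus independent balance-reading
    noise of standard deviation ``replicate_noise_sd`` (mg). With zero
    noise all replicates are identical to the input.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    rng = np.random.default_rng(seed) if seed is not None else spec._rng(3)
    reps = []
    for i in range(n_reps):
        noise = (
            rng.normal(0.0, spec.replicate_noise_sd, len(trace))
            if spec.replicate_noise_sd > 0
            else np.zeros(len(trace))
        )
        reps.append(
            replace(
                trace,
                sample_id=f"{trace.sample_id}_rep{i + 1}",
                mass_mg=trace.mass_mg + noise,
                segments=None if trace.segments is None else trace.segments.copy(),
            )
        )
    return reps
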