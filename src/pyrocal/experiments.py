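"""Reference synthetic experiments used for validation and benchmarking.

These functions assemble complete, seeded study designs from the
synthetic generator and run the calibration/screening machinery on them.
They exist so that the validation suite and the reproduction script
exercise exactly the same conditions.

Problem sizes: experiments run on a 1 °C grid (796 predictors over
105–900 °C) with the default 157-sample panel — large enough for the
p ≫ n regime the calibration targets, small enough for quick Monte-Carlo
repetition.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .grids import GridSpec
from .models import (
    NipalsPLS,
    SplitSpec,
    fit_baseline,
    r_squared,
    select_n_latent,
    split_dataset,
)
from .preprocess import curves_to_matrix
from .synthetic import (
    ComponentDef,
    SignalWindow,
    SyntheticSpec,
    default_components,
    generate_composition,
    generate_dtg_curves,
    measure_composition,
)
from .vip import (
    IntervalSet,
    extract_intervals,
    interval_jaccard,
    refit_and_compare,
    vip_scores,
)

__all__ = [
    "COARSE_GRID",
    "single_target_spec",
    "single_target_experiment",
    "interval_recovery_trial",
    "restricted_refit_trial",
    "model_ordering_trial",
]

#: 1 °C analysis grid used by the reference experiments (796 points).
COARSE_GRID = GridSpec(105.0, 900.0, 1.0)

#: Ground-truth signal windows of the screening target.
TARGET_WINDOWS = ((200.0, 260.0), (330.0, 380.0))


def single_target_spec(
    seed: int,
    grid: GridSpec = COARSE_GRID,
    n_samples: int = 157,
    windows: tuple[tuple[float, float], ...] = TARGET_WINDOWS,
) -> tuple[SyntheticSpec, str]:
    """A study in which only one component imprints on the DTG curve.

    The target keeps its default content distribution but is given the
    requested signal windows; every other component's windows are removed,
    so the curve-side signal attributable to the response is unambiguous.
    Peak signal-to-noise is ≥ 8e-5 / 1.6e-5 = 5 at the default noise.
    Returns ``(spec, target_name)``.
    """
    comps = []
    target_name = "Total phytoaloids"
    for c in default_components():
        if c.name == target_name:
            sd = c.dist_sd
            wins = tuple(
                SignalWindow(lo, hi, amplitude=amp / sd, width=(hi - lo) / 6.0)
                for (lo, hi), amp in zip(windows, (1.0e-4, 8.0e-5))
            )
            comps.append(replace(c, signal_windows=wins))
        else:
            comps.append(replace(c, signal_windows=()))
    spec = SyntheticSpec(
        n_samples=n_samples, components=tuple(comps), grid=grid, seed=seed
    )
    return spec, target_name


def single_target_experiment(seed: int, **kwargs):
    """Generate the single-target study: returns (X, temps, y, spec, target)."""
    spec, target = single_target_spec(seed, **kwargs)
    truth = generate_composition(spec)
    curves = generate_dtg_curves(truth, spec)
    measured = measure_composition(truth, spec)
    X, temps, _ = curves_to_matrix(curves)
    y = measured.values_for(target)
    return X, temps, y, spec, target


def interval_recovery_trial(
    seed: int,
    threshold: float = 1.0,
    min_run: float = 2.0,
    merge_gap: float = 5.0,
    max_components: int = 10,
) -> tuple[float, IntervalSet]:
    """One seeded interval-recovery run.

    Fits PLS (latent count by the selection rule) on the single-target
    study, extracts VIP > threshold intervals, and returns the Jaccard
    overlap against the true signal windows together with the extracted
    set.
    """
    X, temps, y, spec, target = single_target_experiment(seed)
    split = split_dataset(len(y), SplitSpec(seed=seed))
    Xtr, ytr = X[split.train_idx], y[split.train_idx]
    A = select_n_latent(Xtr, ytr, max_components, seed=seed)
    model = NipalsPLS(A).fit(Xtr, ytr)
    profile = vip_scores(model, temps, component=target)
    found = extract_intervals(profile, threshold, min_run, merge_gap)
    truth = IntervalSet(intervals=list(TARGET_WINDOWS))
    return interval_jaccard(found, truth), found


def restricted_refit_trial(seed: int, max_components: int = 10):
    """Full-grid vs VIP-interval-restricted PLS on the single-target study."""
    X, temps, y, spec, target = single_target_experiment(seed)
    split = split_dataset(len(y), SplitSpec(seed=seed))
    Xtr, ytr = X[split.train_idx], y[split.train_idx]
    A = select_n_latent(Xtr, ytr, max_components, seed=seed)
    model = NipalsPLS(A).fit(Xtr, ytr)
    intervals = extract_intervals(vip_scores(model, temps))
    return refit_and_compare(
        X, y, temps, intervals, split,
        max_components=max_components, seed=seed, component=target,
    )


def model_ordering_trial(
    seed: int,
    target: str = "Reducing sugar",
    grid: GridSpec = COARSE_GRID,
    max_components: int = 30,
) -> dict[str, float]:
    """PLS vs minimum-norm MLR test R² on one default-panel study.

    The default panel at 1 °C resolution has p = 796 predictors against
    118 training samples, with temperature-correlated curve noise and
    assay error on the response — the regime where interpolating least
    squares collapses out of sample while PLS generalizes.
    """
    spec = SyntheticSpec(grid=grid, seed=seed)
    truth = generate_composition(spec)
    curves = generate_dtg_curves(truth, spec)
    measured = measure_composition(truth, spec)
    X, temps, _ = curves_to_matrix(curves)
    y = measured.values_for(target)
    split = split_dataset(len(y), SplitSpec(seed=seed))
    Xtr, Xte = X[split.train_idx], X[split.test_idx]
    ytr, yte = y[split.train_idx], y[split.test_idx]

    A = select_n_latent(Xtr, ytr, max_components, seed=seed)
    pls = NipalsPLS(A).fit(Xtr, ytr)
    mlr, _ = fit_baseline(Xtr, ytr, "MLR")
    return {
        "pls_test_r2": r_squared(yte, pls.predict(Xte)),
        "mlr_test_r2": r_squared(yte, mlr.predict(Xte)),
        "n_latent": A,
    }
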