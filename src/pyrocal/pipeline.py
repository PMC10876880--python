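"""End-to-end orchestration: simulate → preprocess → stats → fit → screen → report.

The pipeline ties the stage modules together behind a single validated
configuration, so a whole study — synthetic data generation, descriptive
statistics, six-model calibration, VIP interval screening and restricted
refitting — reproduces from one seed. Every artifact lands in the output
directory with a checksum manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import (
    CompositionTable,
    correlation_matrix,
    density_distribution,
    high_correlation_pairs,
)
from .grids import GridSpec
from .models import (
    MODEL_NAMES,
    NipalsPLS,
    SplitSpec,
    evaluate_all,
    results_to_frame,
    select_n_latent,
    split_dataset,
)
from .preprocess import curves_to_matrix, write_dtg_matrix_csv
from .synthetic import (
    SyntheticSpec,
    generate_composition,
    generate_dtg_curves,
    measure_composition,
)
from .vip import VIPProfile, extract_intervals, refit_and_compare, vip_scores

log = logging.getLogger("pyrocal")

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "write_report"]

_KNOWN_KEYS = {
    "grid": {"start", "stop", "step"},
    "split": {"test_fraction", "seed"},
    "synthetic": {"n_samples", "spec_path", "assay_noise_frac"},
    "models": None,  # list
    "components": None,  # list or None
    "vip": {"threshold", "min_run", "merge_gap"},
    "max_components": None,
    "cv_folds": None,
    "seed": None,
    "out_dir": None,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Unknown keys in a config file are rejected by name so typos surface
    immediately rather than silently falling back to defaults.
    """

    grid: GridSpec = field(default_factory=lambda: GridSpec(105.0, 900.0, 1.0))
    test_fraction: float = 0.25
    split_seed: int | None = None  # defaults to seed
    n_samples: int = 157
    spec_path: str | None = None
    assay_noise_frac: float | None = None
    models: list[str] = field(default_factory=lambda: list(MODEL_NAMES))
    components: list[str] | None = None
    vip_threshold: float = 1.0
    vip_min_run: float = 2.0
    vip_merge_gap: float = 5.0
    max_components: int = 30
    cv_folds: int = 10
    seed: int = 0
    out_dir: str = "pyrocal_out"

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("config lists no models to fit")
        for m in self.models:
            if m not in MODEL_NAMES:
                raise ValueError(f"unknown model '{m}' (choose from {MODEL_NAMES})")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        for key in raw:
            if key not in _KNOWN_KEYS:
                raise ValueError(f"unknown config key '{key}'")
            sub = _KNOWN_KEYS[key]
            if sub is not None and isinstance(raw[key], dict):
                for k2 in raw[key]:
                    if k2 not in sub:
                        raise ValueError(f"unknown config key '{key}.{k2}'")
        kwargs: dict[str, Any] = {}
        if "grid" in raw:
            g = raw["grid"]
            kwargs["grid"] = GridSpec(
                g.get("start", 105.0), g.get("stop", 900.0), g.get("step", 1.0)
            )
        if "split" in raw:
            kwargs["test_fraction"] = raw["split"].get("test_fraction", 0.25)
            kwargs["split_seed"] = raw["split"].get("seed")
        if "synthetic" in raw:
            s = raw["synthetic"]
            kwargs["n_samples"] = s.get("n_samples", 157)
            kwargs["spec_path"] = s.get("spec_path")
            if "assay_noise_frac" in s:
                kwargs["assay_noise_frac"] = s["assay_noise_frac"]
        if "vip" in raw:
            v = raw["vip"]
            kwargs["vip_threshold"] = v.get("threshold", 1.0)
            kwargs["vip_min_run"] = v.get("min_run", 2.0)
            kwargs["vip_merge_gap"] = v.get("merge_gap", 5.0)
        for key in ("models", "components", "max_components", "cv_folds", "seed", "out_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(raw or {})

    def build_spec(self) -> SyntheticSpec:
        if self.spec_path:
            spec = SyntheticSpec.load(self.spec_path)
            return spec
        kwargs: dict[str, Any] = dict(
            n_samples=self.n_samples, grid=self.grid, seed=self.seed
        )
        if self.assay_noise_frac is not None:
            kwargs["assay_noise_frac"] = self.assay_noise_frac
        return SyntheticSpec(**kwargs)


@dataclass
class ReportBundle:
    """Everything one pipeline run produced, plus provenance."""

    evaluation: pd.DataFrame
    correlation: pd.DataFrame
    high_pairs: list[tuple[str, str, float]]
    densities: dict
    vip_profiles: dict[str, VIPProfile]
    interval_sets: dict[str, Any]
    refit_comparisons: list
    composition: CompositionTable | None = None
    curves: list | None = None
    provenance: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis described by ``config``.

    Idempotent for a fixed seed. A component whose model fit fails is
    logged and skipped; the remaining components still complete.
    """
    spec = config.build_spec()
    log.info("simulate: %d samples on %d-point grid", spec.n_samples, spec.grid.count)
    truth = generate_composition(spec)
    curves = generate_dtg_curves(truth, spec)
    measured = measure_composition(truth, spec)
    X, temps, _ = curves_to_matrix(curves)

    log.info("stats: correlation matrix and densities")
    corr = correlation_matrix(measured)
    pairs = high_correlation_pairs(corr, 0.9)
    dens = {
        name: {"edges": edges.tolist(), "probability": probs.tolist()}
        for name, (edges, probs) in density_distribution(measured).items()
    }

    split = split_dataset(
        spec.n_samples,
        SplitSpec(
            test_fraction=config.test_fraction,
            seed=config.seed if config.split_seed is None else config.split_seed,
        ),
    )
    components = config.components or measured.component_names

    log.info("fit: %d components × %s", len(components), config.models)
    evaluation = evaluate_all(
        X,
        measured,
        split,
        components=components,
        models=config.models,
        max_components=config.max_components,
        cv_folds=config.cv_folds,
        seed=config.seed,
    )

    log.info("screen: VIP intervals and restricted refits")
    vip_profiles: dict[str, VIPProfile] = {}
    interval_sets: dict[str, Any] = {}
    refits = []
    for comp in components:
        if comp not in measured.component_names:
            continue
        try:
            y = measured.values_for(comp)
            Xtr, ytr = X[split.train_idx], y[split.train_idx]
            A = select_n_latent(
                Xtr, ytr,
                min(config.max_components, X.shape[1], len(ytr) - 1),
                cv_folds=config.cv_folds, seed=config.seed,
            )
            model = NipalsPLS(A).fit(Xtr, ytr)
            profile = vip_scores(model, temps, component=comp)
            intervals = extract_intervals(
                profile, config.vip_threshold, config.vip_min_run, config.vip_merge_gap
            )
            vip_profiles[comp] = profile
            interval_sets[comp] = intervals
            if len(intervals):
                refits.append(
                    refit_and_compare(
                        X, y, temps, intervals, split,
                        max_components=config.max_components,
                        cv_folds=config.cv_folds, seed=config.seed, component=comp,
                    )
                )
        except Exception as exc:  # noqa: BLE001 - per-component isolation
            log.warning("screen failed for component '%s': %s", comp, exc)

    provenance = {
        "pyrocal_version": __version__,
        "seed": config.seed,
        "n_samples": spec.n_samples,
        "grid": {"start": spec.grid.start, "stop": spec.grid.stop, "step": spec.grid.step},
        "split": {
            "test_fraction": config.test_fraction,
            "n_train": int(len(split.train_idx)),
            "n_test": int(len(split.test_idx)),
        },
        "models": list(config.models),
    }
    return ReportBundle(
        evaluation=results_to_frame(evaluation),
        correlation=corr.to_frame(),
        high_pairs=pairs,
        densities=dens,
        vip_profiles=vip_profiles,
        interval_sets=interval_sets,
        refit_comparisons=refits,
        composition=measured,
        curves=curves,
        provenance=provenance,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_report(bundle: ReportBundle, out_dir: str | Path) -> dict[str, str]:
    """Write all bundle artifacts to ``out_dir``; returns the manifest.

    The manifest (also written as ``manifest.json``) maps each file name
    to its SHA-256 checksum, with the provenance block embedded.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if bundle.evaluation is not None and len(bundle.evaluation):
        bundle.evaluation.to_csv(out / "evaluation.csv", index=False)
    if bundle.correlation is not None and len(bundle.correlation):
        bundle.correlation.rename_axis("component").to_csv(out / "correlation.csv")
        (out / "high_correlation_pairs.json").write_text(
            json.dumps(
                [{"a": a, "b": b, "r": r} for a, b, r in bundle.high_pairs], indent=2
            )
        )
    if bundle.densities:
        (out / "densities.json").write_text(json.dumps(bundle.densities, indent=2))
    if bundle.composition is not None:
        bundle.composition.to_csv(out / "composition.csv")
    if bundle.curves:
        write_dtg_matrix_csv(bundle.curves, out / "dtg_matrix.csv")
    for comp, profile in bundle.vip_profiles.items():
        profile.to_csv(out / f"vip_{_slug(comp)}.csv")
    if bundle.interval_sets:
        (out / "intervals.json").write_text(
            json.dumps(
                {c: list(iv) for c, iv in bundle.interval_sets.items()}, indent=2
            )
        )
        (out / "intervals_compact.txt").write_text(
            "\n".join(
                f"{c}\t{iv.compact()}" for c, iv in bundle.interval_sets.items()
            )
            + "\n"
        )
    if bundle.refit_comparisons:
        pd.DataFrame([r.to_dict() for r in bundle.refit_comparisons]).to_csv(
            out / "refit_comparison.csv", index=False
        )

    files = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "provenance": bundle.provenance,
        "files": {p.name: _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    summary = [f"pyrocal report ({bundle.provenance.get('seed', '?')} seed)"]
    if bundle.evaluation is not None and len(bundle.evaluation):
        pls = bundle.evaluation[bundle.evaluation["model"] == "PLS"]
        if len(pls):
            summary.append(
                f"PLS median test R² over {len(pls)} components: "
                f"{pls['r2_test'].median():.3f}"
            )
    summary.append(f"{len(bundle.interval_sets)} interval sets written")
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    manifest["files"]["summary.txt"] = _sha256(out / "summary.txt")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest["files"]


def _slug(name: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in name.lower())
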