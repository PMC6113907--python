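"""End-to-end in-silico experiments.

Each experiment builds seeded islet networks, runs the silencing protocol
over a grid of inhibited fractions, and reduces the trajectories to
dose-response fits.  Two resolution tiers share identical code paths:
``desk`` (small islets, few fractions and seeds; minutes on one CPU) and
``paper`` (750–1600-cell islets, fine fraction grids, six seeds; hours).
Every result table carries the configuration hash and master seed, so
rerunning an experiment with the same configuration reproduces it exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import (DoseResponse, compare_species,
                       dose_response_from_results)
from .architecture import generate_human_like, generate_mouse_like
from .assembly import assemble_network
from .engine import SimulationProtocol, run_inhibition_series

__all__ = [
    "ExperimentConfig",
    "desk_scale_config",
    "paper_scale_config",
    "run_dose_response",
    "experiment_glucose_exploration",
    "experiment_hub_vs_nonhub",
    "experiment_serca_scan",
    "experiment_gj_mode_comparison",
    "experiment_species_comparison",
]

EXPERIMENT_NAMES = ("glucose-exploration", "hub-vs-nonhub", "serca-scan",
                    "gj-mode-comparison", "species-comparison")


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared configuration for the in-silico experiments."""

    n_cells: int = 750
    species: str = "mouse-like"            # architecture generator
    hub_fraction: float = 0.10
    g_hub: float = 11.0
    g_nonhub_interval: tuple = (6.0, 7.0)
    gj_mode: str = "bimodal"
    heterogeneity_cv: float = 0.2
    fractions_pct: tuple = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0)
    seeds: tuple = (0, 1, 2, 3, 4, 5)
    equilibration_s: float = 100.0
    baseline_s: float = 60.0
    inhibition_s: float = 60.0
    recovery_s: float = 0.0
    rtol: float = 1e-6
    metric: str = "amplitude"
    p_serca_scale: float = 1.0
    output_dir: str | None = None

    def protocol(self) -> SimulationProtocol:
        return SimulationProtocol(
            equilibration_s=self.equilibration_s,
            baseline_s=self.baseline_s,
            inhibition_s=self.inhibition_s,
            recovery_s=self.recovery_s,
            rtol=self.rtol)

    def with_(self, **kw) -> "ExperimentConfig":
        return dataclasses.replace(self, **kw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("g_nonhub_interval", "fractions_pct", "seeds"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def desk_scale_config(**overrides) -> ExperimentConfig:
    """Small configuration that finishes in minutes on one CPU."""
    base = ExperimentConfig(
        n_cells=120, fractions_pct=(0.0, 2.5, 5.0, 7.5), seeds=(0,),
        equilibration_s=40.0, baseline_s=30.0, inhibition_s=30.0,
        rtol=1e-5)
    return base.with_(**overrides)


def paper_scale_config(**overrides) -> ExperimentConfig:
    """Full-size configuration (hours of CPU per dose-response curve)."""
    return ExperimentConfig().with_(**overrides)


def _make_architecture(config: ExperimentConfig, seed: int):
    if config.species == "mouse-like":
        return generate_mouse_like(config.n_cells, rng_seed=seed)
    if config.species == "human-like":
        return generate_human_like(config.n_cells, rng_seed=seed)
    raise ValueError(f"unknown species {config.species!r}")


def run_dose_response(config: ExperimentConfig, target: str = "hub",
                      architecture=None, swap_bimodal_means: bool = False,
                      ) -> DoseResponse:
    """Dose-response for one target population under one configuration.

    One islet per seed (architecture reused across seeds when supplied),
    nested inhibited sets within each seed, logistic fit on the per-fraction
    seed means.
    """
    results_per_seed = []
    for seed in config.seeds:
        arch = architecture if architecture is not None \
            else _make_architecture(config, seed)
        net = assemble_network(
            arch, master_seed=seed, hub_fraction=config.hub_fraction,
            g_hub=config.g_hub, g_nonhub_interval=config.g_nonhub_interval,
            gj_mode=config.gj_mode,
            heterogeneity_cv=config.heterogeneity_cv,
            p_serca_scale=config.p_serca_scale,
            swap_bimodal_means=swap_bimodal_means)
        results = run_inhibition_series(
            net, config.fractions_pct, target=target, rng_seed=seed,
            protocol=config.protocol())
        results_per_seed.append(results)
    return dose_response_from_results(config.fractions_pct, results_per_seed,
                                      metric=config.metric)


def _fit_row(dr: DoseResponse, **labels) -> dict:
    return {**labels, "x0_pct": dr.x0, "k": dr.k, "r2": dr.r2,
            "flagged": dr.flagged, "n_seeds": dr.n_seeds}


def _finalise(table: pd.DataFrame, config: ExperimentConfig,
              name: str) -> pd.DataFrame:
    table = table.copy()
    table["experiment"] = name
    table["config_hash"] = config.config_hash()
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / f"{name}.csv", index=False)
        manifest = {"experiment": name,
                    "config": dataclasses.asdict(config),
                    "config_hash": config.config_hash()}
        (outdir / f"{name}.manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))
    return table


def experiment_glucose_exploration(config: ExperimentConfig,
                                   intervals=((6.0, 7.0), (6.5, 7.5)),
                                   ) -> dict:
    """Hub-inhibition dose-response per non-hub glucose interval.

    The narrower, lower interval leaves most non-hubs below their firing
    threshold, making the islet depend on hub drive; the higher interval
    produces intrinsically active non-hubs and a right-shifted IC50.
    """
    out = {"dose_responses": {}, "table": None}
    rows = []
    for interval in intervals:
        cfg = config.with_(g_nonhub_interval=tuple(interval))
        dr = run_dose_response(cfg, target="hub")
        out["dose_responses"][tuple(interval)] = dr
        rows.append(_fit_row(dr, g_nonhub_interval=str(tuple(interval)),
                             target="hub"))
    out["table"] = _finalise(pd.DataFrame(rows), config,
                             "glucose-exploration")
    return out


def experiment_hub_vs_nonhub(config: ExperimentConfig) -> dict:
    """Hub- vs non-hub-inhibition dose-responses under one GJ mode."""
    out = {"dose_responses": {}, "table": None}
    rows = []
    for target in ("hub", "nonhub"):
        dr = run_dose_response(config, target=target)
        out["dose_responses"][target] = dr
        rows.append(_fit_row(dr, target=target, gj_mode=config.gj_mode))
    out["table"] = _finalise(pd.DataFrame(rows), config, "hub-vs-nonhub")
    return out


def experiment_serca_scan(config: ExperimentConfig,
                          pserca_scales=(1.0, 0.9, 0.8, 0.7, 0.6)) -> dict:
    """Hub- and non-hub-inhibition curves under graded SERCA reduction."""
    if any(not 0 < s <= 1 for s in pserca_scales):
        raise ValueError("SERCA scales must lie in (0, 1]")
    out = {"dose_responses": {}, "table": None}
    rows = []
    for scale in pserca_scales:
        cfg = config.with_(p_serca_scale=float(scale))
        for target in ("hub", "nonhub"):
            dr = run_dose_response(cfg, target=target)
            out["dose_responses"][(float(scale), target)] = dr
            rows.append(_fit_row(dr, p_serca_scale=float(scale),
                                 target=target))
    table = _finalise(pd.DataFrame(rows), config, "serca-scan")
    out["table"] = table
    hub = table[table.target == "hub"].sort_values("p_serca_scale")
    out["hub_ic50_vs_scale"] = dict(zip(hub.p_serca_scale, hub.x0_pct))
    return out


def experiment_gj_mode_comparison(config: ExperimentConfig,
                                  modes=("unimodal", "bimodal")) -> dict:
    """Hub- and non-hub-inhibition curves per gap-junction mode."""
    out = {"dose_responses": {}, "table": None}
    rows = []
    for mode in modes:
        cfg = config.with_(gj_mode=mode)
        for target in ("hub", "nonhub"):
            dr = run_dose_response(cfg, target=target)
            out["dose_responses"][(mode, target)] = dr
            rows.append(_fit_row(dr, gj_mode=mode, target=target))
    out["table"] = _finalise(pd.DataFrame(rows), config,
                             "gj-mode-comparison")
    return out


def experiment_species_comparison(config: ExperimentConfig,
                                  n_islets_per_species: int = 8) -> dict:
    """Per-islet hub-inhibition IC50s for size-matched mouse- and
    human-like architectures, with a paired t-test on the fitted IC50s."""
    fits = {"mouse-like": [], "human-like": []}
    rows = []
    for islet_idx in range(n_islets_per_species):
        for species in ("mouse-like", "human-like"):
            cfg = config.with_(species=species)
            arch = _make_architecture(cfg, seed=1000 + islet_idx)
            dr = run_dose_response(cfg, target="hub", architecture=arch)
            fits[species].append(dr)
            rows.append(_fit_row(dr, species=species, islet=islet_idx))
    mouse_ic50 = [d.x0 for d in fits["mouse-like"]]
    human_ic50 = [d.x0 for d in fits["human-like"]]
    test = compare_species(mouse_ic50, human_ic50,
                           paired=n_islets_per_species >= 2)
    out = {"fits": fits,
           "mouse_ic50": mouse_ic50,
           "human_ic50": human_ic50,
           "test": test,
           "table": _finalise(pd.DataFrame(rows), config,
                              "species-comparison")}
    return out
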