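"""Config-driven end-to-end orchestration.

Stages: build/ingest geography -> synthesize or load data -> cohort
aggregation -> fit the requested model variants -> convergence diagnostics
and DIC -> model choice -> SIR surfaces and correlation summaries.  Every
run writes a manifest with seeds, a config hash, per-stage timings and the
produced artifact paths; given the same config and seeds two runs produce
identical outputs (timings aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import StudyWindow, cohort_to_mapping_inputs
from .diagnostics import diagnostics_report
from .geography import AdjacencyGraph, read_adjacency
from .mcar import MCARModelSpec, MCMCControl, fit_mcmc
from .results import conditional_correlation, export_maps, sir_surface
from .synthetic import (
    DISEASES,
    CohortConfig,
    default_ground_truth,
    lattice_map,
    simulate_cohort,
    simulate_counts,
)

logger = logging.getLogger("comap")

__all__ = ["RunConfig", "run", "sensitivity_rerun"]

_MODEL_SIMPLICITY = {"M2": 0, "M1": 1, "M3": 2}  # tie-break order by parameter count


@dataclass
class RunConfig:
    """Validated configuration of one end-to-end run."""

    mode: str = "synthetic"              # synthetic | individual-csv | aggregated-csv
    outdir: str = "results/run"
    seed: int = 0
    models: tuple = ("M1", "M2", "M3")
    window: StudyWindow = field(default_factory=StudyWindow)
    iterations: int = 20_000
    burn_in: int = 10_000
    thin: int = 10
    n_chains: int = 2
    prior_sd_upper: float = 10.0
    paths: dict = field(default_factory=dict)     # csv inputs per mode
    synthetic_kind: str = "aggregated"            # aggregated | cohort
    synthetic_expected: float = 200.0             # E per cell (aggregated kind)
    n_persons: int = 10_000                       # cohort kind
    credible_level: float = 0.95
    make_maps: bool = True

    def validate(self) -> None:
        if self.mode not in ("synthetic", "individual-csv", "aggregated-csv"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.models:
            raise ValueError("at least one model must be requested")
        for m in self.models:
            if m not in _MODEL_SIMPLICITY:
                raise ValueError(f"unknown model {m!r}")
        if self.seed is None:
            raise ValueError("a seed is required (no silent nondeterminism)")
        if self.prior_sd_upper <= 0:
            raise ValueError("prior_sd_upper must be > 0")

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        win = raw.pop("window", None)
        cfg = RunConfig(**raw)
        if win:
            cfg.window = StudyWindow(**win)
        if isinstance(cfg.models, (list, tuple)):
            cfg.models = tuple(cfg.models)
        return cfg

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["window"] = {
            "start": str(self.window.start), "end": str(self.window.end),
            "min_age": self.window.min_age,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _load_geography(config: RunConfig) -> AdjacencyGraph:
    if config.mode == "synthetic" or "edges" not in config.paths:
        return lattice_map()
    return read_adjacency(config.paths["edges"], config.paths["adjacency_sidecar"])


def _load_counts(config: RunConfig, graph: AdjacencyGraph):
    """Return (Y, E, extras) arrays for fitting; runs the cohort stage when
    individual-level data are in play."""
    extras = {}
    if config.mode == "aggregated-csv":
        ydf = pd.read_csv(config.paths["observed"])
        edf = pd.read_csv(config.paths["expected"])
        diseases = [c for c in ydf.columns if c != "area"]
        order = {a: i for i, a in enumerate(graph.area_ids)}
        ydf = ydf.sort_values("area", key=lambda s: s.map(order))
        edf = edf.sort_values("area", key=lambda s: s.map(order))
        Y = ydf[diseases].to_numpy(float)
        E = edf[diseases].to_numpy(float)
        extras["diseases"] = tuple(diseases)
        return Y, E, extras
    if config.mode == "synthetic" and config.synthetic_kind == "aggregated":
        truth = default_ground_truth(graph, seed=config.seed)
        E = np.full((graph.n_areas, 3), float(config.synthetic_expected))
        Y = simulate_counts(truth, E, seed=config.seed + 1)
        extras["truth"] = truth
        extras["diseases"] = DISEASES
        return Y.astype(float), E, extras
    # individual-level: synthetic cohort or CSV input
    if config.mode == "synthetic":
        cohort = simulate_cohort(
            CohortConfig(n_persons=config.n_persons, n_areas=graph.n_areas),
            seed=config.seed,
            area_ids=graph.area_ids,
        )
    else:
        from .synthetic import SyntheticCohort

        persons = pd.read_csv(config.paths["persons"], parse_dates=[
            "birth_date", "death_date", "emigration_date",
            *(f"dx_{d}" for d in DISEASES)])
        py = pd.read_csv(config.paths["person_years"])
        cohort = SyntheticCohort(persons, py, CohortConfig())
    stage = cohort_to_mapping_inputs(cohort, graph.area_ids, config.window)
    extras["cohort_stage"] = stage
    extras["diseases"] = DISEASES
    return stage["observed"].Y.astype(float), stage["expected"].E, extras


def run(config: RunConfig) -> dict:
    """Execute all stages and return (and persist) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "comap_version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "mode": config.mode,
        "models": list(config.models),
        "stages": {},
        "outputs": {},
    }
    t0 = time.perf_counter()

    def stage_done(name):
        manifest["stages"][name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done (%.1fs total)", name, time.perf_counter() - t0)

    try:
        graph = _load_geography(config)
        stage_done("geography")
        Y, E, extras = _load_counts(config, graph)
        diseases = extras["diseases"]
        stage_done("data")
        if "cohort_stage" in extras:
            extras["cohort_stage"]["crude_table"].to_csv(
                outdir / "crude_rates.csv", index=False
            )
            manifest["outputs"]["crude_rates"] = str(outdir / "crude_rates.csv")

        fits, dics, reports = {}, {}, {}
        for m in config.models:
            spec = MCARModelSpec(variant=m, n_diseases=Y.shape[1],
                                 prior_sd_upper=config.prior_sd_upper)
            control = MCMCControl(
                n_chains=config.n_chains, iterations=config.iterations,
                burn_in=config.burn_in, thin=config.thin, seed=config.seed,
            )
            fits[m] = fit_mcmc(spec, Y, E, graph, control)
            rep = diagnostics_report(fits[m], Y=Y)
            reports[m] = rep
            dics[m] = rep.dic
            rep.to_json(outdir / f"diagnostics_{m}.json")
            manifest["outputs"][f"diagnostics_{m}"] = str(outdir / f"diagnostics_{m}.json")
        stage_done("fit")

        selected = select_model(dics)
        manifest["dic"] = {m: round(v, 2) for m, v in dics.items()}
        manifest["selected_model"] = selected

        spec_sel = MCARModelSpec(variant=selected, n_diseases=Y.shape[1],
                                 prior_sd_upper=config.prior_sd_upper)
        surface = sir_surface(fits[selected], E, graph.area_ids, diseases,
                              level=config.credible_level)
        surface.to_csv(outdir / "sir_surface.csv")
        manifest["outputs"]["sir_surface"] = str(outdir / "sir_surface.csv")
        corr = conditional_correlation(fits[selected], spec_sel, diseases,
                                       level=config.credible_level)
        corr.to_json(outdir / "correlations.json")
        manifest["outputs"]["correlations"] = str(outdir / "correlations.json")
        if config.make_maps and graph.n_areas == 98:
            maps = export_maps(surface, outdir / "maps", lattice_shape=(7, 14))
            manifest["outputs"].update(maps)
        stage_done("results")
    except Exception as exc:
        manifest["failed_stage"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    manifest["fits"] = {
        m: {"n_draws": int(fits[m].n_draws)} for m in fits
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    manifest["_fits"] = fits  # in-memory extras for callers; not serialized
    manifest["_surface"] = surface
    manifest["_correlations"] = corr
    manifest["_graph"] = graph
    manifest["_data"] = (Y, E, extras)
    return manifest


def select_model(dics: dict) -> str:
    """Minimum-DIC model; ties (|delta DIC| < 1) go to the simpler model
    (M2 before M1 before M3, by parameter count)."""
    best = min(dics.values())
    tied = [m for m, v in dics.items() if v - best < 1.0]
    return sorted(tied, key=lambda m: _MODEL_SIMPLICITY[m])[0]


def sensitivity_rerun(config: RunConfig, overrides: Optional[dict] = None,
                      base_manifest: Optional[dict] = None) -> dict:
    """Refit with overridden priors and report the largest absolute changes
    in SIR medians and correlation medians.

    Mirrors the standard robustness check of widening the uniform prior on
    the field standard deviations (e.g. from upper bound 10 to 100).
    """
    overrides = dict(overrides or {})
    if "prior_sd_upper" in overrides and overrides["prior_sd_upper"] <= 0:
        raise ValueError("prior_sd_upper override must be > 0")
    if base_manifest is None:
        base_manifest = run(config)
    alt_config = dataclasses.replace(
        config,
        outdir=str(Path(config.outdir).with_name(Path(config.outdir).name + "_sensitivity")),
        **{k: v for k, v in overrides.items() if hasattr(config, k)},
    )
    alt_manifest = run(alt_config)

    s0 = base_manifest["_surface"].table.set_index(["area", "disease"])["sir_median"]
    s1 = alt_manifest["_surface"].table.set_index(["area", "disease"])["sir_median"]
    c0 = base_manifest["_correlations"].table.set_index("pair")["median"]
    c1 = alt_manifest["_correlations"].table.set_index("pair")["median"]
    report = {
        "overrides": overrides,
        "max_abs_delta_sir_median": float((s0 - s1).abs().max()),
        "max_abs_delta_correlation_median": float((c0 - c1).abs().max())
        if len(c0) and len(c1) else 0.0,
        "base_selected": base_manifest["selected_model"],
        "alt_selected": alt_manifest["selected_model"],
    }
    out = Path(config.outdir) / "sensitivity.json"
    out.write_text(json.dumps(report, indent=2))
    return report
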