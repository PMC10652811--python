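"""Reproducible multi-stage pipeline: synth → fit → select-m → pk-sim → trial.

A run is described by a :class:`RunConfig` (YAML-serializable, unknown
keys rejected). A single global seed is expanded into per-stage seeds
through ``numpy.random.SeedSequence`` spawning keyed by stage order, so
every stage is independently reproducible. Stages whose outputs already
exist under the output directory with a matching config hash are
skipped; deleting a stage's outputs reruns it and everything downstream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assays import (
    CellCycleAssayConfig,
    SynergyAssayConfig,
    default_truth,
    generate_cellcycle,
    generate_synergy,
)
from .inference import SamplerConfig, fit, select_m
from .io import read_assay_csv, write_assay_csv, write_truth_json
from .pk import SCHEDULES, default_pk_sampler, make_profiles, regimen_from_schedule, sample_patient
from .trial import SyntheticPosterior, build_cohort, compare_schedules, fraction_below, run_trial

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("synth", "fit", "select-m", "pk-sim", "trial", "report")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    outdir: str = "runs/default"
    seed: int = 0
    profile: str = "sensitive_plusDOX"
    stages: tuple = STAGES
    # synth
    synergy_doses_P: tuple = (0.0, 12.5, 25.0, 50.0, 100.0)
    synergy_doses_F: tuple = (0.0, 0.65, 1.3, 2.6, 5.2)
    replicates: int = 3
    # fit / select-m
    m: int | None = None  # None -> use the profile's m
    m_candidates: tuple = (1, 2, 4)
    n_walkers: int = 32
    n_steps: int = 800
    n_burn: int = 300
    thin: int = 4
    # trial
    schedules: tuple = ("standard", "daily_100", "daily_75", "bid_50_50", "bid_50_25")
    n_patients: int = 100
    horizon_days: float = 100.0
    pd_step_days: float = 0.05
    use_fitted_posterior: bool = False  # False -> synthetic posterior from profile

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}; known: {STAGES}")
        for s in self.schedules:
            if s not in SCHEDULES:
                raise ValueError(f"unknown schedule {s!r}; known: {sorted(SCHEDULES)}")
        # profile validated eagerly so misconfiguration fails before any work
        default_truth(self.profile)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("stages", "m_candidates", "schedules", "synergy_doses_P", "synergy_doses_F"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Everything needed to re-execute a run bit-comparably."""

    config: dict
    version: str
    stage_seeds: dict
    outputs: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _stage_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {s: int(c.generate_state(1)[0] % (2**31)) for s, c in zip(STAGES, children)}


def _fresh(stage_dir: Path, config_hash: str) -> bool:
    marker = stage_dir / ".hash"
    return marker.exists() and marker.read_text().strip() == config_hash


def _mark(stage_dir: Path, config_hash: str) -> None:
    (stage_dir / ".hash").write_text(config_hash)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages in dependency order.

    Stage outputs are cached under ``outdir/<stage>/``; a stage is
    skipped when its outputs exist for the same config hash.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    chash = config.content_hash()
    manifest = RunManifest(config=config.to_dict(), version=__version__, stage_seeds=seeds)
    truth = default_truth(config.profile)

    syn_cfg = SynergyAssayConfig(
        doses_P=config.synergy_doses_P,
        doses_F=config.synergy_doses_F,
        replicates=config.replicates,
    )
    cc_cfg = CellCycleAssayConfig(replicates=config.replicates)
    sampler_cfg = SamplerConfig(
        n_walkers=config.n_walkers,
        n_steps=config.n_steps,
        n_burn=config.n_burn,
        thin=config.thin,
    )

    def stage_dir(name: str) -> Path:
        d = out / name
        d.mkdir(exist_ok=True)
        return d

    data = None
    posterior = None

    def load_data():
        d = out / "synth"
        return read_assay_csv(d / "synergy.csv"), read_assay_csv(d / "cellcycle.csv")

    if "synth" in config.stages:
        d = stage_dir("synth")
        if not _fresh(d, chash):
            logger.info("[synth] generating assay tables")
            syn = generate_synergy(truth, syn_cfg, seed=seeds["synth"])
            cc = generate_cellcycle(truth, cc_cfg, seed=seeds["synth"] + 1)
            write_assay_csv(syn, d / "synergy.csv")
            write_assay_csv(cc, d / "cellcycle.csv")
            write_truth_json(truth, d / "truth.json", seed=seeds["synth"])
            _mark(d, chash)
        else:
            logger.info("[synth] cached")
        manifest.outputs["synth"] = str(d)
        data = load_data()

    if "fit" in config.stages:
        d = stage_dir("fit")
        if data is None:
            if not (out / "synth" / "synergy.csv").exists():
                raise FileNotFoundError("fit stage requires synth outputs; run synth first")
            data = load_data()
        if not _fresh(d, chash):
            logger.info("[fit] sampling posterior")
            m = config.m or truth.cell_cycle.m
            posterior = fit(data, m=m, sampler_cfg=sampler_cfg, seed=seeds["fit"])
            posterior.samples.to_csv(d / "posterior.csv", index=False)
            (d / "diagnostics.json").write_text(
                json.dumps(posterior.diagnostics, indent=2)
            )
            _mark(d, chash)
        else:
            logger.info("[fit] cached")
        manifest.outputs["fit"] = str(d)

    if "select-m" in config.stages:
        d = stage_dir("select-m")
        if data is None:
            data = load_data()
        if not _fresh(d, chash):
            logger.info("[select-m] comparing m candidates %s", config.m_candidates)
            comp = select_m(
                data, candidates=config.m_candidates, sampler_cfg=sampler_cfg,
                seed=seeds["select-m"],
            )
            comp.table.assign(selected=comp.table["m"] == comp.selected_m).to_csv(
                d / "comparison.csv", index=False
            )
            _mark(d, chash)
        else:
            logger.info("[select-m] cached")
        manifest.outputs["select-m"] = str(d)

    if "pk-sim" in config.stages:
        d = stage_dir("pk-sim")
        if not _fresh(d, chash):
            logger.info("[pk-sim] writing concentration grids")
            palbo, fulv = sample_patient(default_pk_sampler(), seeds["pk-sim"])
            for sched in config.schedules:
                pr, fr = regimen_from_schedule(sched, config.horizon_days)
                profiles = make_profiles(palbo, fulv, pr, fr)
                t, cp = profiles["palbociclib"].grid(0, config.horizon_days, 0.05)
                _, cf = profiles["fulvestrant"].grid(0, config.horizon_days, 0.05)
                pd.DataFrame(
                    {"time_days": t, "palbociclib_ng_ml": cp, "fulvestrant_ng_ml": cf}
                ).to_csv(d / f"profile_{sched}.csv", index=False)
            _mark(d, chash)
        else:
            logger.info("[pk-sim] cached")
        manifest.outputs["pk-sim"] = str(d)

    if "trial" in config.stages:
        d = stage_dir("trial")
        if not _fresh(d, chash):
            logger.info("[trial] %d patients × %d schedules", config.n_patients,
                        len(config.schedules))
            if config.use_fitted_posterior:
                pcsv = out / "fit" / "posterior.csv"
                if not pcsv.exists():
                    raise FileNotFoundError(
                        "use_fitted_posterior requires fit outputs; run fit first"
                    )

                class _Fitted:  # posterior-like: samples + m
                    samples = pd.read_csv(pcsv)
                    m = config.m or truth.cell_cycle.m

                post = _Fitted()
            else:
                post = SyntheticPosterior(truth, n_draws=500, seed=seeds["trial"])
            cohort = build_cohort(post, n=config.n_patients, seed=seeds["trial"])
            result = run_trial(
                cohort, config.schedules, horizon=config.horizon_days,
                step=config.pd_step_days, seed=seeds["trial"],
            )
            result.to_frame().to_csv(d / "day100.csv", index=False)
            cmp_ = compare_schedules(result)
            cmp_["pairwise"].to_csv(d / "pairwise.csv", index=False)
            cmp_["ranking"].to_csv(d / "ranking.csv", index=False)
            cmp_["waterfall"].to_csv(d / "waterfall.csv", index=False)
            fraction_below(result).to_csv(d / "fraction_below.csv")
            _mark(d, chash)
        else:
            logger.info("[trial] cached")
        manifest.outputs["trial"] = str(d)

    if "report" in config.stages:
        d = stage_dir("report")
        summary = {"stages_run": list(config.stages), "seed": config.seed}
        for name in ("fit", "select-m", "trial"):
            p = out / name
            if p.exists():
                summary[name] = sorted(f.name for f in p.iterdir() if f.suffix == ".csv")
        (d / "summary.json").write_text(json.dumps(summary, indent=2))
        _mark(d, chash)
        manifest.outputs["report"] = str(d)

    manifest.write(out / "manifest.json")
    return manifest
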