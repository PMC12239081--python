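"""End-to-end orchestration: plan -> forces -> ΔG -> D_z -> P (+ structure).

A :class:`RunConfig` collects every tunable of the campaign (grid geometry,
analysis window, ACF truncation, temperature, convergence threshold,
hydrogen-bond criteria, seed) and validates before any work.  Runs are
deterministic given the seed; every output file carries provenance metadata
(resolved config hash, package version, seed), and re-running with the same
inputs reproduces outputs byte for byte.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from . import __version__
from .constants import DEFAULT_TEMPERATURE_K
from .core import ForceTimeSeries
from .diffusion import DiffusionProfile, diffusion_profile
from .errors import ConfigError, ScpermError, StageError
from .io import write_table
from .permeability import (
    PermeabilityResult,
    compare_permeability,
    isd_permeability,
    permeability_draws,
)
from .plan import GridSpec, SamplingPlan, plan_insertions
from .pmf import FreeEnergyProfile, bin_forces, integrate_pmf, symmetrize_forces
from .synthetic import (
    SyntheticRunSpec,
    generate_run,
    landscape_presets,
    read_run_xvg,
)

log = logging.getLogger("scperm")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_comparison",
           "load_config"]


class GridConfig(BaseModel):
    rc_length: float = Field(9.0, gt=0)
    window_spacing: float = Field(0.1, gt=0)
    origin: float | None = None


class HBondConfig(BaseModel):
    max_da_distance: float = Field(0.35, gt=0)
    max_hda_angle: float = Field(30.0, gt=0, le=90)


class RunConfig(BaseModel):
    """Validated configuration of one analysis campaign."""

    grid: GridConfig = GridConfig()
    per_config_spacing: float = Field(1.5, gt=0)
    coverage: int = Field(4, ge=1)

    mode: Literal["synthetic", "xvg"] = "synthetic"
    landscape: str = "sc_like"  # synthetic mode: preset name
    xvg_dir: str | None = None  # xvg mode: directory of pull-force files
    n_steps: int = Field(100_000, ge=2)
    dt: float = Field(0.05, gt=0)  # ps between force samples (synthetic)
    # Uniform partitioning offset added to ΔG in the permeability integral
    # (a constant offset is invisible to constraint forces, which only see
    # dG/dz, so it is applied at the solubility-diffusion stage).
    dG_offset_kJ_mol: float = 0.0

    temperature: float = Field(DEFAULT_TEMPERATURE_K, gt=0)
    analysis_window: tuple[float, float] | None = None  # ps; None = full series
    acf_max_lag: float = Field(5.0, gt=0)  # ps (use 50 ps for real MD input)
    convergence_threshold: float = Field(0.05, gt=0, lt=1)
    n_blocks: int = Field(5, ge=2)
    symmetrize_diffusion: bool = True
    bounds: tuple[float, float] | None = None
    mc_draws: int = Field(2000, ge=100)
    hbond: HBondConfig = HBondConfig()
    selections: dict[str, str] = Field(default_factory=dict)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.analysis_window is not None and self.analysis_window[0] >= self.analysis_window[1]:
            raise ValueError("analysis_window start must precede its end")
        if self.mode == "xvg" and not self.xvg_dir:
            raise ValueError("xvg mode requires xvg_dir")
        if self.mode == "synthetic" and self.landscape not in landscape_presets():
            raise ValueError(
                f"unknown landscape {self.landscape!r}; "
                f"choose from {sorted(landscape_presets())}"
            )
        return self

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return RunConfig(**raw)
    except ValidationError as e:
        raise ConfigError(str(e)) from e


@dataclass
class PipelineResult:
    plan: SamplingPlan
    free_energy: FreeEnergyProfile
    diffusion: DiffusionProfile
    permeability: PermeabilityResult
    draws: np.ndarray
    config: RunConfig


def _provenance(config: RunConfig) -> dict:
    return {
        "package": "scperm",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "units": {"length": "nm", "time": "ps", "energy": "kJ/mol", "P": "cm/s"},
    }


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (ScpermError, ValueError) as e:
                raise StageError(name, str(e)) from e
        return wrapped
    return deco


def acquire_forces(config: RunConfig, plan: SamplingPlan) -> list[ForceTimeSeries]:
    """Synthetic generation or XVG ingestion, per the config mode."""
    if config.mode == "synthetic":
        preset = landscape_presets()[config.landscape]
        spec = SyntheticRunSpec(
            landscape=preset,
            plan=plan,
            dt=config.dt,
            n_steps=config.n_steps,
            temperature=config.temperature,
            seed=config.seed,
        )
        return generate_run(spec)
    return read_run_xvg(config.xvg_dir, plan)


def run_pipeline(config: RunConfig, outdir=None) -> PipelineResult:
    """Execute plan -> forces -> PMcF -> Kubo -> permeability.

    With ``outdir`` the resolved config, profiles (TSV + metadata sidecars)
    and the permeability result JSON are written; a stage failure leaves a
    machine-readable ``error.json`` manifest instead.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    try:
        result = _run_stages(config)
    except StageError as e:
        if outdir is not None:
            (outdir / "error.json").write_text(
                json.dumps({"stage": e.stage, "message": str(e)}, indent=2) + "\n"
            )
        raise
    if outdir is not None:
        _write_outputs(result, outdir)
    return result


def _run_stages(config: RunConfig) -> PipelineResult:
    grid = GridSpec(
        rc_length=config.grid.rc_length,
        window_spacing=config.grid.window_spacing,
        origin=config.grid.origin,
    )
    plan = _stage("plan")(plan_insertions)(
        grid, config.per_config_spacing, config.coverage, seed=config.seed
    )
    log.info("plan: %d windows, %d configs, %d tracers/config",
             grid.n_windows, plan.n_configs, plan.molecules_per_config)

    series = _stage("forces")(acquire_forces)(config, plan)
    n_samples = sum(s.n_samples for s in series)
    log.info("forces: %d series, %d samples total", len(series), n_samples)

    stats = _stage("pmf")(bin_forces)(series, grid, config.analysis_window)
    sym = _stage("pmf")(symmetrize_forces)(stats)
    profile = _stage("pmf")(integrate_pmf)(sym)
    log.info("pmf: %d windows, retained %d samples, max |dG| = %.3f kJ/mol",
             len(stats), sum(s.n_samples for s in stats), np.abs(profile.dG).max())

    dprof = _stage("diffusion")(diffusion_profile)(
        series, grid, config.acf_max_lag, config.temperature,
        threshold=config.convergence_threshold,
        n_blocks=config.n_blocks,
        symmetrize=config.symmetrize_diffusion,
    )
    log.info("diffusion: %d/%d windows converged",
             int(dprof.converged_mask.sum()), grid.n_windows)

    perm = _stage("permeability")(isd_permeability)(
        profile, dprof, config.temperature, config.bounds,
        dG_offset=config.dG_offset_kJ_mol,
    )
    draws = _stage("permeability")(permeability_draws)(
        profile, dprof, config.temperature, config.bounds,
        n_draws=config.mc_draws, seed=config.seed,
        dG_offset=config.dG_offset_kJ_mol,
    )
    perm = PermeabilityResult(
        P=perm.P,
        P_error=float(draws.std(ddof=1)),
        z=perm.z,
        resistance=perm.resistance,
        bounds_used=perm.bounds_used,
        temperature=perm.temperature,
    )
    log.info("permeability: P = %.6g +- %.2g cm/s", perm.P, perm.P_error)
    return PipelineResult(plan, profile, dprof, perm, draws, config)


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    meta = _provenance(result.config)
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(result.config.model_dump(), sort_keys=True)
    )
    result.plan.to_json(outdir / "plan.json")

    fe = result.free_energy
    write_table(
        pd.DataFrame({"z_nm": fe.z, "dG_kJ_mol": fe.dG, "dG_err_kJ_mol": fe.dG_error}),
        outdir / "free_energy.tsv",
        {**meta, "anchored_at_nm": fe.anchored_at},
    )
    dp = result.diffusion
    write_table(
        pd.DataFrame({
            "z_nm": dp.z,
            "D_nm2_ps": dp.D,
            "D_err_nm2_ps": dp.D_error,
            "converged": dp.converged_mask.astype(int),
        }),
        outdir / "diffusion.tsv",
        {**meta, "symmetrized": dp.symmetrized},
    )
    pr = result.permeability
    write_table(
        pd.DataFrame({"z_nm": pr.z, "resistance_s_cm_per_nm": pr.resistance}),
        outdir / "resistance.tsv",
        meta,
    )
    (outdir / "permeability.json").write_text(
        json.dumps(
            {
                "P_cm_s": pr.P,
                "P_error_cm_s": pr.P_error,
                "bounds_nm": list(pr.bounds_used),
                "temperature_K": pr.temperature,
                **{"provenance": meta},
            },
            indent=2,
        )
        + "\n"
    )


def run_comparison(config_a: RunConfig, config_b: RunConfig, outdir=None):
    """Run two campaigns and compare their permeabilities (Student t test)."""
    ra = run_pipeline(config_a)
    rb = run_pipeline(config_b)
    cmp = compare_permeability(ra.draws, rb.draws)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "comparison.json").write_text(
            json.dumps(
                {
                    "P_a_cm_s": ra.permeability.P,
                    "P_b_cm_s": rb.permeability.P,
                    "ratio": cmp.ratio,
                    "t_statistic": cmp.t_statistic,
                    "p_value": cmp.p_value,
                    "significant_0.05": cmp.significant,
                },
                indent=2,
            )
            + "\n"
        )
    return ra, rb, cmp
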