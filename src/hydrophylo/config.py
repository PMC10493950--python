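"""Run configuration: a single YAML file with per-stage parameter blocks.

Unknown keys are rejected, values are range-checked, and a validated config
has a reproducible SHA-256 hash recorded in every output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = [
    "OpticalParams", "ConductanceParams", "ComparativeParams",
    "SimulateParams", "InputPaths", "RunConfig", "validate_config",
]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OpticalParams(_Block):
    diff_threshold: float = Field(10000.0, gt=0)
    min_event_px: int = Field(4, ge=1)


class ConductanceParams(_Block):
    window: int = Field(5, ge=3)
    rel_tol: float = Field(0.15, gt=0, lt=1)
    double_sided: bool = True
    p_atm_kpa: float = Field(101.6, gt=0)
    per_replicate_tp: bool = False


class ComparativeParams(_Block):
    n_perm: int = Field(999, ge=99)
    bonferroni_m: int = Field(2, ge=1)
    outlier_d_factor: float = Field(4.0, gt=0)  # flag when D > factor/n
    loess_span: float = Field(1.5, gt=0)
    lambda_mode: str = "ml"


class ImageSimParams(_Block):
    height: int = Field(64, ge=32)
    width: int = Field(64, ge=32)
    n_frames: int = Field(150, ge=20)
    noise_sd: float = Field(300.0, ge=0)
    shrink_events: int = Field(20, ge=0)
    slope_vc: float = Field(50.0, gt=0)
    psi_start: float = Field(-0.5, le=0)
    psi_end: float = Field(-8.0, lt=0)


class MassSimParams(_Block):
    rh: float = Field(40.0, ge=0, lt=100)
    noise_sd_mass_g: float = Field(0.0005, ge=0)
    leaf_area_m2: float = Field(0.02, gt=0)
    closure_tau_s: float = Field(600.0, gt=0)
    duration_s: float = Field(10800.0, gt=0)
    dt_s: float = Field(300.0, gt=0)

    @field_validator("rh")
    @classmethod
    def _rh_range(cls, v):
        if not (0 <= v < 100):
            raise ValueError("rh must be in [0, 100) percent")
        return v


class TraitSimParams(_Block):
    # gmin(25 C) = b0 + b1 * PC1 + b2 * subgenus + phylogenetic noise
    beta_gmin: tuple[float, float, float] = (6.5, -1.0, 0.0)
    lambda_resid: float = Field(0.3, ge=0, le=1)
    sigma2_resid: float = Field(0.09, gt=0)
    p50_intercept: float = Field(-4.8)
    p50_pc1_slope: float = Field(-0.15)
    p50_sd: float = Field(0.3, ge=0)
    tp_mean: float = Field(36.0, gt=25, lt=48)
    tp_sd: float = Field(1.5, ge=0)
    gmin_slope_above_tp: float = Field(0.4, gt=0)
    outlier_shift: float = Field(-4.0)  # planted low-g_min outlier


class SimulateParams(_Block):
    n_species: int = Field(14, ge=5)
    n_image_reps: int = Field(2, ge=1)
    n_mass_reps: int = Field(2, ge=1)
    temps_c: tuple[float, ...] = (25.0, 28.0, 32.0, 36.0, 40.0, 44.0, 48.0)
    image: ImageSimParams = ImageSimParams()
    mass: MassSimParams = MassSimParams()
    traits: TraitSimParams = TraitSimParams()


class InputPaths(_Block):
    """Locations of measured inputs (one stack/psi pair per species
    replicate, one mass-series directory, a tree and a table)."""
    tree: str | None = None
    table: str | None = None
    stacks: str | None = None   # directory of <species>_<rep>.npz/.tif
    mass_dir: str | None = None


class RunConfig(_Block):
    seed: int = Field(0, ge=0)
    out_dir: str = "hydrophylo_out"
    verbosity: int = Field(1, ge=0, le=2)
    simulate: SimulateParams | None = None
    inputs: InputPaths | None = None
    optical: OpticalParams = OpticalParams()
    conductance: ConductanceParams = ConductanceParams()
    comparative: ComparativeParams = ComparativeParams()

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing blocks are filled with documented defaults; unknown keys and
    out-of-range values raise ``ValueError`` naming the key.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:
        raise ValueError(f"invalid config {path}: {exc}") from exc
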