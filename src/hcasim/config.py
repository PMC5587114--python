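"""Configuration models for the cage simulator, baseplate reader and analysis.

All tunables live in pydantic models with strict (unknown-key rejecting)
validation, so a YAML/JSON run configuration round-trips losslessly and a
typo'd key fails loudly with the offending name.

Clock convention: ``t = 0`` is lights-on; within each 24 h day the light
phase occupies ``[0, photoperiod[0])`` hours and the dark phase the rest.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

SCHEMA_VERSION = "1"

IMPLANT_SITES = (
    "ventral_midline",
    "flank_vertical",
    "flank_horizontal",
    "interscapular",
)

PERTURBATION_KINDS = ("cage_change", "single_housing", "gavage")


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration input."""


def _load_calibration() -> dict:
    with resources.files("hcasim.data").joinpath("calibration_v1.json").open() as fh:
        return json.load(fh)


_CALIBRATION = _load_calibration()


def calibration_constants() -> dict:
    """Return the shipped, versioned calibration constants (copy)."""
    return json.loads(json.dumps(_CALIBRATION))


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class RestBoutParams(_StrictModel):
    """Two-state semi-Markov rest/active alternation (seconds).

    Defaults are phase-independent so the realized dark:light step-count
    ratio equals the configured circadian ratio in expectation.
    """

    rest_mean_s: float = Field(150.0, gt=0)
    active_mean_s: float = Field(60.0, gt=0)
    rest_mean_s_dark: Optional[float] = Field(None, gt=0)
    active_mean_s_dark: Optional[float] = Field(None, gt=0)

    def means_for_phase(self, dark: bool) -> tuple[float, float]:
        if dark:
            return (
                self.rest_mean_s_dark or self.rest_mean_s,
                self.active_mean_s_dark or self.active_mean_s,
            )
        return self.rest_mean_s, self.active_mean_s


class VerticalEventRates(_StrictModel):
    """Poisson rates (events/h) and fixed durations (s) for rearing/climbing."""

    rearing_per_h_light: float = Field(12.0, ge=0)
    rearing_per_h_dark: float = Field(25.0, ge=0)
    rearing_duration_s: float = Field(2.0, gt=0)
    climbing_per_h_light: float = Field(2.0, ge=0)
    climbing_per_h_dark: float = Field(5.0, ge=0)
    climbing_duration_s: float = Field(4.0, gt=0)


class SimConfig(_StrictModel):
    """Ground-truth cohort generator configuration.

    Defaults encode the study conditions: 3 rats on a 38 x 50 cm plate,
    12:12 photoperiod, dark:light activity ratio 1.4, subcutaneous
    temperature 37.5 degC baseline with a 0.5 degC dark-phase elevation.
    """

    cage_length_cm: float = Field(50.0, gt=0)
    cage_width_cm: float = Field(38.0, gt=0)
    n_animals: int = Field(3, ge=1)
    photoperiod_h: tuple[float, float] = (12.0, 12.0)
    duration_s: float = Field(86400.0, ge=0)
    timestep_s: float = Field(0.1, gt=0)
    dark_light_activity_ratio: float = Field(1.4, ge=0)
    base_step_rate_hz: float = Field(0.9, gt=0)  # steps/s while active, light phase
    step_length_mean_cm: float = Field(3.0, gt=0)
    step_length_sd_cm: float = Field(1.0, ge=0)
    heading_turn_sd_rad: float = Field(0.6, ge=0)
    rest_bout_params: RestBoutParams = RestBoutParams()
    vertical_events: VerticalEventRates = VerticalEventRates()
    implant_site: Literal[IMPLANT_SITES] = "ventral_midline"
    pitch_wobble_sd_deg: float = Field(12.0, ge=0)
    pitch_wobble_tau_s: float = Field(2.0, gt=0)
    temp_baseline_c: float = Field(37.5)
    temp_dark_elevation_c: float = Field(0.5)
    temp_noise_sd_c: float = Field(0.15, ge=0)
    temp_noise_tau_s: float = Field(600.0, gt=0)
    temp_animal_sd_c: float = Field(0.15, ge=0)  # stable per-animal baseline offset
    seed: int = Field(0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        lo, hi = self.photoperiod_h
        if lo <= 0 or hi <= 0:
            raise ValueError("photoperiod phases must be positive")
        return self

    @property
    def day_length_s(self) -> float:
        return 3600.0 * (self.photoperiod_h[0] + self.photoperiod_h[1])

    @property
    def light_length_s(self) -> float:
        return 3600.0 * self.photoperiod_h[0]


class PerturbationEvent(_StrictModel):
    """A husbandry perturbation injected into the generator schedule.

    ``magnitude`` is a step-rate multiplier for cage_change/gavage and a
    temperature decrement in degC for single_housing.
    """

    kind: Literal[PERTURBATION_KINDS]
    t0_s: float = Field(ge=0)
    duration_s: float = Field(gt=0)
    magnitude: Optional[float] = None

    def effective_magnitude(self) -> float:
        if self.magnitude is not None:
            return self.magnitude
        return {"cage_change": 3.0, "single_housing": 0.5, "gavage": 2.5}[self.kind]


class AntennaArray(_StrictModel):
    """The 3 x 4 coil array and its sequential polling schedule.

    75 ms activation inside a 90 ms slot resolves the printed 75 ms x 12
    activations against the 1080 ms total cycle (15 ms settle gap per slot).
    """

    n_rows: int = Field(3, ge=1)
    n_cols: int = Field(4, ge=1)
    plate_length_cm: float = Field(50.0, gt=0)
    plate_width_cm: float = Field(38.0, gt=0)
    slot_duration_ms: float = Field(90.0, gt=0)
    active_duration_ms: float = Field(75.0, gt=0)
    read_order: Optional[tuple[int, ...]] = None  # default: row-major serpentine

    @model_validator(mode="after")
    def _check(self) -> "AntennaArray":
        if self.active_duration_ms > self.slot_duration_ms:
            raise ValueError("active_duration_ms must not exceed slot_duration_ms")
        order = self.effective_read_order()
        if sorted(order) != list(range(self.n_antennae)):
            raise ValueError("read_order must be a permutation of antenna indices")
        return self

    @property
    def n_antennae(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cycle_duration_s(self) -> float:
        return self.n_antennae * self.slot_duration_ms / 1000.0

    def effective_read_order(self) -> tuple[int, ...]:
        if self.read_order is not None:
            return self.read_order
        order: list[int] = []
        for j in range(self.n_rows):
            row = [j * self.n_cols + i for i in range(self.n_cols)]
            if j % 2 == 1:
                row.reverse()
            order.extend(row)
        return tuple(order)

    def centroids(self):
        """(n_antennae, 2) antenna centre coordinates, row-major indexing."""
        import numpy as np

        dx = self.plate_length_cm / self.n_cols
        dy = self.plate_width_cm / self.n_rows
        xs = (np.arange(self.n_cols) + 0.5) * dx
        ys = (np.arange(self.n_rows) + 0.5) * dy
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


class CouplingModel(_StrictModel):
    """Tag-coil coupling: vertical magnetic dipole field, projected on the
    tag axis, with a detection threshold, a charge-dwell requirement and a
    per-activation lognormal interference term.

    field_scale/read_threshold/coupling_noise_sd/shielding_gain default to
    the shipped calibration constants (fitted so 24 h simulated read rates
    reproduce the in vivo per-site values).
    """

    field_scale: float = Field(float(_CALIBRATION["field_scale"]), gt=0)
    read_threshold: float = Field(float(_CALIBRATION["read_threshold"]), gt=0)
    coupling_noise_sd: float = Field(float(_CALIBRATION["coupling_noise_sd"]), ge=0)
    shielding_gain: float = Field(float(_CALIBRATION["shielding_gain"]), ge=1.0)
    upgraded: bool = False
    min_dwell_ms: float = Field(60.0, gt=0)
    coil_radius_cm: float = Field(5.0, gt=0)
    n_dwell_samples: int = Field(5, ge=1)
    temp_range_c: tuple[float, float] = (33.0, 43.0)
    temp_accuracy_c: float = Field(0.5, ge=0)
    temp_quantum_c: float = Field(0.1, gt=0)

    @property
    def gain(self) -> float:
        return self.shielding_gain if self.upgraded else 1.0


class CameraConfig(_StrictModel):
    """Synthetic side-view camera: orthographic projection along cage depth."""

    width_px: int = Field(320, ge=16)
    height_px: int = Field(180, ge=16)
    fps: float = Field(25.0, gt=0)
    px_per_cm: float = Field(6.4, gt=0)
    floor_row: int = Field(170, ge=0)
    noise_sd: float = Field(1.0, ge=0)

    def row_for_height(self, height_cm: float) -> int:
        """Image row of a horizontal line ``height_cm`` above the floor."""
        return int(round(self.floor_row - height_cm * self.px_per_cm))


class AnalysisConfig(_StrictModel):
    bin_size_s: float = Field(900.0, gt=0)
    min_temp_reads: int = Field(3, ge=1)
    max_gap_s: float = Field(5.0, gt=0)
    flicker_rule: Literal["two_consecutive", "majority_of_3"] = "two_consecutive"
    diff_threshold: float = Field(10.0, gt=0)
    min_frames: int = Field(3, ge=1)
    vertical_line_cm: float = Field(8.0, gt=0)


class RunConfig(_StrictModel):
    """Top-level run configuration embedding all component configs."""

    schema_version: str = SCHEMA_VERSION
    seed: int = Field(0, ge=0)
    sim: SimConfig = SimConfig()
    array: AntennaArray = AntennaArray()
    coupling: CouplingModel = CouplingModel()
    camera: CameraConfig = CameraConfig()
    analysis: AnalysisConfig = AnalysisConfig()

    @model_validator(mode="after")
    def _check_version(self) -> "RunConfig":
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"config schema_version {self.schema_version!r} does not match "
                f"reader version {SCHEMA_VERSION!r}"
            )
        return self


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        if err["type"] == "extra_forbidden":
            parts.append(f"unknown key {loc!r}")
        else:
            parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    An empty file yields the all-defaults configuration; unknown keys are
    rejected with the offending key named in the error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(f"{path}: {_format_validation_error(exc)}") from exc


def dump_config(cfg: RunConfig) -> dict:
    return json.loads(cfg.model_dump_json())


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = dump_config(cfg)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


def config_checksum(cfg: RunConfig) -> str:
    """Stable sha256 over the canonical JSON form of a configuration."""
    canon = json.dumps(dump_config(cfg), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()
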