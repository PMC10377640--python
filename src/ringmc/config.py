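"""Experiment configuration, validation, and run manifests.

One structured YAML file drives every command.  All physical quantities
carry their unit in the key name (``*_cm``, ``*_nm``, ``*_hz``).  Defaults
reproduce the reference measurement protocol: the standard finger geometry,
the embedded layer property table, systolic/diastolic cardiac states, a PD
angle grid of 25-95 degrees in 5-degree steps, wavelengths 660/940 nm and
surround reflectance 0 (absorbing) and 1 (mirror).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__ as _pkg_version
from .properties import DEFAULT_LAYER_TABLE, LAYERS
from .spectra import ChromophoreSpectra
from .tissue import (FingerGeometry, FingerModel, LayerComposition,
                     PhysiologicalState)

__all__ = ["ExperimentConfig", "RunManifest", "load_config",
           "apply_overrides"]


class GeometrySection(BaseModel):
    ring_diameter_cm: float = 1.7
    bone_center_cm: tuple[float, float] = (0.0, 0.3)
    bone_semi_axes_cm: tuple[float, float] = (0.25, 0.15)
    artery_abs_x_cm: float = 0.4
    artery_y_cm: float = 0.45
    artery_radius_cm: float = 0.08
    skin_thickness_cm: tuple[float, float, float, float, float] = (
        0.010, 0.020, 0.008, 0.080, 0.030)
    cylinder_length_cm: float = 4.0
    pd_size_cm: tuple[float, float] = (0.3, 0.3)
    led_radius_cm: float = 0.15


class LayerSection(BaseModel):
    fractions: dict[str, float]
    mu_s_per_cm: dict[float, float]
    g: float
    n: float
    thickness_cm: Optional[float] = None


class StatesSection(BaseModel):
    """Cardiac-phase parameters (systolic/diastolic columns)."""

    artery_radius_systolic_cm: float = 0.08
    artery_radius_diastolic_cm: float = 0.092
    capillary_multiplier_systolic: float = 1.0
    capillary_multiplier_diastolic: float = 1.5


class SourceSection(BaseModel):
    angle_deg: float = 0.0
    radius_cm: float = 0.15
    profile: str = "lambertian"

    @field_validator("profile")
    @classmethod
    def _profile(cls, v):
        if v not in ("lambertian", "normal"):
            raise ValueError("profile must be 'lambertian' or 'normal'")
        return v


class DetectorSection(BaseModel):
    theta_pl_deg: float = 25.0
    size_cm: tuple[float, float] = (0.3, 0.3)


class BoundarySection(BaseModel):
    rho: float = Field(0.0, ge=0.0, le=1.0)
    index_handling: str = "matched"

    @field_validator("index_handling")
    @classmethod
    def _mode(cls, v):
        if v not in ("matched", "fresnel"):
            raise ValueError("index_handling must be 'matched' or 'fresnel'")
        return v


class SweepSection(BaseModel):
    thetas_deg: list[float] = Field(
        default_factory=lambda: [float(t) for t in range(25, 100, 5)])
    wavelengths_nm: list[float] = Field(
        default_factory=lambda: [660.0, 940.0])
    spo2: list[float] = Field(
        default_factory=lambda: [0.7, 0.8, 0.9, 1.0])
    rho: list[float] = Field(default_factory=lambda: [0.0, 1.0])
    n_photons: int = Field(100_000, ge=1)
    n_repeats: int = Field(1, ge=1)


class TransportSection(BaseModel):
    rr_threshold: float = Field(0.1, gt=0.0, le=1.0)
    rr_survival: float = Field(0.1, gt=0.0, le=1.0)
    max_steps: int = Field(500_000, ge=1)
    fluence: bool = False
    fluence_resolution: int = Field(200, ge=8)


class ExperimentConfig(BaseModel):
    """Schema-validated, resolvable experiment description."""

    geometry: GeometrySection = Field(default_factory=GeometrySection)
    layers: dict[str, LayerSection] = Field(default_factory=dict)
    spectra_csv: Optional[str] = None
    states: StatesSection = Field(default_factory=StatesSection)
    source: SourceSection = Field(default_factory=SourceSection)
    detector: DetectorSection = Field(default_factory=DetectorSection)
    boundary: BoundarySection = Field(default_factory=BoundarySection)
    sweep: SweepSection = Field(default_factory=SweepSection)
    transport: TransportSection = Field(default_factory=TransportSection)
    seed: int = 0
    output_dir: str = "results"

    # ---- resolution ------------------------------------------------------

    def finger_geometry(self) -> FingerGeometry:
        return FingerGeometry(**self.geometry.model_dump())

    def compositions(self) -> list[LayerComposition]:
        merged = {}
        for name in LAYERS:
            base = DEFAULT_LAYER_TABLE[name]
            sec = self.layers.get(name)
            if sec is None:
                merged[name] = LayerSection(**base)
            else:
                merged[name] = sec
        return [LayerComposition(
                    layer=name,
                    fractions=dict(merged[name].fractions),
                    mu_s_per_cm={float(k): float(v) for k, v in
                                 merged[name].mu_s_per_cm.items()},
                    g=merged[name].g, n=merged[name].n,
                    thickness_cm=merged[name].thickness_cm)
                for name in LAYERS]

    def chromophore_spectra(self) -> ChromophoreSpectra:
        if self.spectra_csv:
            return ChromophoreSpectra.from_csv(self.spectra_csv)
        return ChromophoreSpectra.default()

    def finger_model(self) -> FingerModel:
        return FingerModel(geometry=self.finger_geometry(),
                           compositions=tuple(self.compositions()),
                           spectra=self.chromophore_spectra())

    def state(self, phase: str, spo2: float) -> PhysiologicalState:
        s = self.states
        if phase == "systolic":
            return PhysiologicalState(
                spo2=spo2, phase=phase,
                artery_radius_cm=s.artery_radius_systolic_cm,
                capillary_multiplier=s.capillary_multiplier_systolic)
        if phase == "diastolic":
            return PhysiologicalState(
                spo2=spo2, phase=phase,
                artery_radius_cm=s.artery_radius_diastolic_cm,
                capillary_multiplier=s.capillary_multiplier_diastolic)
        raise ValueError(f"phase must be systolic|diastolic, got {phase!r}")

    def run_kwargs(self) -> dict:
        t = self.transport
        return {"rr_threshold": t.rr_threshold,
                "rr_survival": t.rr_survival,
                "max_steps": t.max_steps}

    # ---- I/O -------------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh,
                           sort_keys=False)


def _coerce(value: str):
    try:
        return yaml.safe_load(value)
    except yaml.YAMLError:
        return value


def apply_overrides(config: ExperimentConfig,
                    overrides: list[str]) -> ExperimentConfig:
    """Apply ``section.key=value`` overrides (values parsed as YAML)."""
    data = config.model_dump()
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override {item!r} must look like key=value")
        key, raw = item.split("=", 1)
        parts = key.split(".")
        node = data
        for p in parts[:-1]:
            if p not in node:
                raise KeyError(f"unknown config section {p!r} in {key!r}")
            node = node[p]
        if parts[-1] not in node:
            raise KeyError(f"unknown config field {key!r}")
        node[parts[-1]] = _coerce(raw)
    return ExperimentConfig.model_validate(data)


def load_config(path: str | Path | None,
                overrides: list[str] | None = None) -> ExperimentConfig:
    cfg = ExperimentConfig() if path is None \
        else ExperimentConfig.from_yaml(path)
    if overrides:
        cfg = apply_overrides(cfg, list(overrides))
    return cfg


class RunManifest:
    """Everything needed to regenerate a result bitwise: resolved config,
    package version, consumed seeds, per-run ledgers, output inventory."""

    def __init__(self, config: ExperimentConfig, command: str):
        self.data = {
            "command": command,
            "package_version": _pkg_version,
            "config": json.loads(config.model_dump_json()),
            "seeds": [],
            "runs": [],
            "outputs": [],
        }

    def add_run(self, seed: int, summary: dict) -> None:
        self.data["seeds"].append(int(seed))
        self.data["runs"].append(summary)

    def add_output(self, path: str | Path) -> None:
        self.data["outputs"].append(str(path))

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, default=float)
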