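"""Validated JSON configuration for pipeline runs.

An empty or absent-keys file yields pure defaults: the measured
crystallotype presets, 500-run Monte Carlo on a 380-780 nm grid, the
calibrated NE dilation factors and the track-generator settings.
Unknown keys are rejected with the offending key path in the message.
"""
from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, ValidationError

from .cell_dynamics import TrackGeneratorParams
from .errors import ConfigError
from .physiology import NEModel
from .presets import DISORDERED, ORDERED, CrystallotypePreset
from .tmm import MonteCarloConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PresetConfig(_Strict):
    crystal_thickness_mean: float
    crystal_thickness_sd: float
    cytoplasm_mean: float
    cytoplasm_sd: float
    layer_count_min: int
    layer_count_max: int
    n_crystal: float = 1.83
    n_cytoplasm: float = 1.33

    def to_preset(self, name: str) -> CrystallotypePreset:
        return CrystallotypePreset(name=name, **self.model_dump())

    @classmethod
    def from_preset(cls, p: CrystallotypePreset) -> "PresetConfig":
        return cls(
            crystal_thickness_mean=p.crystal_thickness_mean,
            crystal_thickness_sd=p.crystal_thickness_sd,
            cytoplasm_mean=p.cytoplasm_mean,
            cytoplasm_sd=p.cytoplasm_sd,
            layer_count_min=p.layer_count_min,
            layer_count_max=p.layer_count_max,
            n_crystal=p.n_crystal,
            n_cytoplasm=p.n_cytoplasm,
        )


class SimulationConfig(_Strict):
    n_runs: int = 500
    wavelength_min: float = 380.0
    wavelength_max: float = 780.0
    wavelength_step: float = 1.0
    angle: float = 0.0
    polarization: str = "unpolarized"
    convention: str = "paper_eq3"

    def to_mc(self, rng_seed: int) -> MonteCarloConfig:
        return MonteCarloConfig(rng_seed=rng_seed, **self.model_dump())


class NEConfig(_Strict):
    dilation_ordered: float = 1.35
    dilation_disordered: float = 1.0

    def to_model(self) -> NEModel:
        return NEModel(**self.model_dump())


class TracksConfig(_Strict):
    n_dense: int = 200
    n_loose: int = 200
    dt_min: float = 5.0
    duration_h: float = 15.0
    dense_jitter_um: float = 0.3
    loose_jitter_um: float = 1.5
    loose_drift_dv_um_per_frame: float = -0.3
    kappa_dense: float = 4.0
    division_rate_dense: float = 0.01
    division_rate_loose: float = 0.02
    min_displacement_um: float = 20.0

    def to_params(self) -> TrackGeneratorParams:
        return TrackGeneratorParams(
            dt_min=self.dt_min,
            duration_h=self.duration_h,
            dense_jitter_um=self.dense_jitter_um,
            loose_jitter_um=self.loose_jitter_um,
            loose_drift_um_per_frame=(0.0, self.loose_drift_dv_um_per_frame),
            kappa_dense=self.kappa_dense,
            division_rate_dense=self.division_rate_dense,
            division_rate_loose=self.division_rate_loose,
        )


class AppConfig(_Strict):
    seed: int = 0
    ordered: PresetConfig = PresetConfig.from_preset(ORDERED)
    disordered: PresetConfig = PresetConfig.from_preset(DISORDERED)
    simulation: SimulationConfig = SimulationConfig()
    ne: NEConfig = NEConfig()
    tracks: TracksConfig = TracksConfig()
    include_tracks: bool = True

    def ordered_preset(self) -> CrystallotypePreset:
        return self.ordered.to_preset("ordered")

    def disordered_preset(self) -> CrystallotypePreset:
        return self.disordered.to_preset("disordered")


def load_config(path: str | Path | None = None) -> AppConfig:
    """Load and validate a JSON configuration file.

    ``None`` or an empty file yields pure defaults; unknown keys raise
    :class:`ConfigError` naming the key.
    """
    if path is None:
        return AppConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    text = path.read_text().strip()
    if not text:
        return AppConfig()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a JSON object")
    try:
        return AppConfig.model_validate(raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigError(f"{path}: {details}") from exc
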