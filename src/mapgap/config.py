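"""Validated configuration models for simulation, detection and the pipeline.

All models are pydantic v2 ``BaseModel`` s with ``extra="forbid"`` so that a
mistyped key in a YAML file fails loudly at load time instead of silently
falling back to a default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class SimulationConfig(BaseModel):
    """Parameters of the synthetic intracardiac recording generator.

    The contact-force threshold distribution (``threshold_mean`` /
    ``threshold_sd``, in grams) describes viable tissue: the force that must
    be exceeded before a monophasic action potential (MAP) appears at a site.
    MAP amplitude and duration ranges are generator conventions — the source
    experiments report only the detection floor (2 mV, 100 ms), not the
    distribution of supra-threshold waveforms — and are therefore arbitrary
    within physiologically sensible bounds.
    """

    model_config = ConfigDict(extra="forbid")

    sample_rate_hz: float = Field(default=1000.0, ge=500.0)
    heart_rate_bpm: float = Field(default=80.0, gt=20.0, lt=250.0)
    threshold_mean: float = Field(default=7.6, gt=0.0)
    threshold_sd: float = Field(default=4.4, ge=0.0)
    threshold_floor_g: float = Field(default=0.5, gt=0.0)
    map_amplitude_low_mv: float = Field(default=3.0, gt=0.0)
    map_amplitude_high_mv: float = Field(default=6.0, gt=0.0)
    map_duration_low_ms: float = Field(default=150.0, gt=0.0)
    map_duration_high_ms: float = Field(default=250.0, gt=0.0)
    noise_sd: float = Field(default=0.05, ge=0.0)
    farfield_amplitude_mv: float = Field(default=0.3, ge=0.0)
    respiration_amplitude: float = Field(default=0.2, ge=0.0)
    respiration_force_amplitude_g: float = Field(default=0.3, ge=0.0)
    respiration_period_s: float = Field(default=4.0, gt=0.0)
    breath_hold: bool = False
    sensor_slope_g_per_nm: float = Field(default=5.0)
    sensor_intercept_g: float = Field(default=0.0)
    sensor_noise_nm: float = Field(default=0.02, ge=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _ranges(self) -> "SimulationConfig":
        if self.map_amplitude_high_mv < self.map_amplitude_low_mv:
            raise ValueError("map amplitude range inverted")
        if self.map_duration_high_ms < self.map_duration_low_ms:
            raise ValueError("map duration range inverted")
        if self.sensor_slope_g_per_nm == 0:
            raise ValueError("sensor slope must be nonzero")
        return self

    @property
    def beat_period_s(self) -> float:
        return 60.0 / self.heart_rate_bpm


class DetectorConfig(BaseModel):
    """MAP detector settings.

    Defaults encode the acquisition conventions of the assessment protocol:
    a 0.1–120 Hz recording band, a MAP recognised only when its amplitude
    exceeds 2 mV (strictly) and its duration reaches 100 ms (inclusively),
    and a site declared MAP-positive only after 4 consecutive waveforms with
    similar characteristics.
    """

    model_config = ConfigDict(extra="forbid")

    band_low: float = Field(default=0.1, gt=0.0)
    band_high: float = Field(default=120.0, gt=0.0)
    min_amplitude: float = Field(default=2.0, gt=0.0)  # mV, strict >
    min_duration: float = Field(default=100.0, gt=0.0)  # ms, inclusive >=
    consistency_run: int = Field(default=4, ge=1)
    similarity_tolerance: float = Field(default=0.15, ge=0.0)
    repolarization_fraction: float = Field(default=0.9, gt=0.0, lt=1.0)
    amplitude_mode: Literal["peak_to_baseline", "peak_to_peak"] = "peak_to_baseline"
    pre_qrs_offset_s: float = Field(default=0.05, ge=0.0)

    @model_validator(mode="after")
    def _band(self) -> "DetectorConfig":
        if self.band_low >= self.band_high:
            raise ValueError("band_low must be below band_high")
        return self


class PipelineConfig(BaseModel):
    """Top-level configuration binding the pipeline stages together."""

    model_config = ConfigDict(extra="forbid")

    detector: DetectorConfig = Field(default_factory=DetectorConfig)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    reference_mode: Literal["site_matched_first", "cohort_only"] = "site_matched_first"
    output_dir: Path = Path("mapgap_out")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path: str | Path) -> None:
        data = self.model_dump(mode="json")
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
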