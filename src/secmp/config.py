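"""Structured run configuration.

Every manual step of the bench workflow (baseline anchors, peak
boundaries, mass windows) is an explicit, unit-annotated config value, so
any number in a report is recomputable from its inputs.  Configs are YAML
or JSON; units are spelled out in the key names.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Literal

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .chromatogram import BaselineSpec, PeakWindow
from .errors import ConfigurationError
from .mp_analysis import (
    DEFAULT_BIN_WIDTH_KDA,
    DEFAULT_HALF_WIDTH_KDA,
    DEFAULT_SIGMA_MAX_KDA,
    DEFAULT_TOTAL_WINDOW,
    MIN_EVENTS_FOR_FIT,
    MassWindow,
)
from .scenarios import GenomeSpec
from .simulate import NoiseModel, Species, SpeciesMix
from .uv_quant import DEFAULT_EXTINCTION, AcquisitionGeometry, ExtinctionSet


class ExtinctionConfig(BaseModel):
    eps_cap280_per_M_per_cm: float = DEFAULT_EXTINCTION.eps_cap280
    eps_cap260_per_M_per_cm: float = DEFAULT_EXTINCTION.eps_cap260
    eps_dna280_mL_per_mg_per_cm: float = DEFAULT_EXTINCTION.eps_dna280
    eps_dna260_mL_per_mg_per_cm: float = DEFAULT_EXTINCTION.eps_dna260
    max_condition: float = 1e6

    def build(self) -> ExtinctionSet:
        return ExtinctionSet(
            eps_cap280=self.eps_cap280_per_M_per_cm,
            eps_cap260=self.eps_cap260_per_M_per_cm,
            eps_dna280=self.eps_dna280_mL_per_mg_per_cm,
            eps_dna260=self.eps_dna260_mL_per_mg_per_cm,
            max_condition=self.max_condition,
        )


class GeometryConfig(BaseModel):
    path_length_cm: float = 1.0
    injection_volume_ml: float = 0.01

    def build(self) -> AcquisitionGeometry:
        return AcquisitionGeometry(
            path_length_cm=self.path_length_cm,
            injection_volume_ml=self.injection_volume_ml,
        )


Channel = float | tuple[tuple[float, float], tuple[float, float]]


class BaselineConfig(BaseModel):
    """Per channel: a constant (mAU) or two ``[volume_mL, mAU]`` anchors."""

    a280: Any = 0.0
    a260: Any = 0.0

    @staticmethod
    def _coerce(v) -> Channel:
        if isinstance(v, (int, float)):
            return float(v)
        try:
            (v1, a1), (v2, a2) = v
            return ((float(v1), float(a1)), (float(v2), float(a2)))
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"baseline channel spec {v!r} is neither a constant "
                                     "nor two [volume, absorbance] anchors") from exc

    def build(self) -> BaselineSpec:
        return BaselineSpec(a280=self._coerce(self.a280), a260=self._coerce(self.a260))


class PeakWindowConfig(BaseModel):
    v_start_ml: float
    v_end_ml: float

    def build(self) -> PeakWindow:
        return PeakWindow(self.v_start_ml, self.v_end_ml)


class MPConfig(BaseModel):
    total_window_kda: tuple[float, float] = DEFAULT_TOTAL_WINDOW
    full_mass_kda: float | None = None  # theoretical fully packaged virion mass
    half_width_kda: float = DEFAULT_HALF_WIDTH_KDA
    sigma_max_kda: float = DEFAULT_SIGMA_MAX_KDA
    bin_width_kda: float = DEFAULT_BIN_WIDTH_KDA
    min_events: int = MIN_EVENTS_FOR_FIT
    max_peaks: int = 4

    def total(self) -> MassWindow:
        return MassWindow(*self.total_window_kda)


class GenomeConfig(BaseModel):
    n_nt: int | None = None
    m_genome_da: float | None = None

    def build(self) -> GenomeSpec:
        return GenomeSpec(n_nt=self.n_nt, m_genome_da=self.m_genome_da)

    @property
    def empty(self) -> bool:
        return self.n_nt is None and self.m_genome_da is None


class RunConfig(BaseModel):
    extinction: ExtinctionConfig = Field(default_factory=ExtinctionConfig)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    baseline: BaselineConfig = Field(default_factory=BaselineConfig)
    peak_window: PeakWindowConfig | None = None
    mp: MPConfig = Field(default_factory=MPConfig)
    genome: GenomeConfig = Field(default_factory=GenomeConfig)
    scenario_override: Literal[1, 2, 3] | None = None
    clamp_rel_tol: float = 0.02
    genome_tol_knt: float = 0.1
    seed: int = 0

    def echo(self) -> dict:
        """Full resolved config for report provenance."""
        return json.loads(self.model_dump_json())


class SpeciesConfig(BaseModel):
    label: str
    kind: Literal["capsid", "dna", "protein"] = "capsid"
    mass_kda: float
    genome_mass_da: float = 0.0
    number_conc_per_ml: float
    elution_ml: float
    sigma_v_ml: float = 0.1
    full: bool = False
    monomer: bool = True
    molar_ext_scale: float = 1.0

    def build(self) -> Species:
        return Species(
            label=self.label,
            kind=self.kind,
            mass_kda=self.mass_kda,
            genome_mass_da=self.genome_mass_da,
            number_conc=self.number_conc_per_ml,
            elution_ml=self.elution_ml,
            sigma_v_ml=self.sigma_v_ml,
            full=self.full,
            monomer=self.monomer,
            molar_ext_scale=self.molar_ext_scale,
        )


class NoiseConfig(BaseModel):
    chrom_noise_sd_mau: float = 0.1
    drift_slope_mau_per_ml: float = 0.05
    mp_mass_sd_kda: float = 120.0

    def build(self, seed: int) -> NoiseModel:
        return NoiseModel(
            chrom_noise_sd_mau=self.chrom_noise_sd_mau,
            drift_slope_mau_per_ml=self.drift_slope_mau_per_ml,
            mp_mass_sd_kda=self.mp_mass_sd_kda,
            seed=seed,
        )


class GridConfig(BaseModel):
    start_ml: float = 4.0
    stop_ml: float = 13.0
    step_ml: float = 0.002


class SimulateConfig(BaseModel):
    species: list[SpeciesConfig]
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    n_mp_events: int = 10000
    seed: int = 0

    @model_validator(mode="after")
    def _nonempty(self):
        if not self.species:
            raise ValueError("simulate config needs at least one species")
        return self

    def mix(self) -> SpeciesMix:
        return SpeciesMix(species=tuple(s.build() for s in self.species))


def _load_structured(path) -> dict:
    text = Path(path).read_text()
    try:
        if str(path).endswith(".json"):
            return json.loads(text)
        return yaml.safe_load(text)
    except Exception as exc:
        raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc


def load_run_config(path) -> RunConfig:
    data = _load_structured(path)
    try:
        return RunConfig.model_validate(data or {})
    except ValidationError as exc:
        raise ConfigurationError(f"invalid run config {path}: {exc}") from exc


def load_simulate_config(path) -> SimulateConfig:
    data = _load_structured(path)
    try:
        return SimulateConfig.model_validate(data or {})
    except ValidationError as exc:
        raise ConfigurationError(f"invalid simulate config {path}: {exc}") from exc
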