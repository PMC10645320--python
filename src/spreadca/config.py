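"""Pipeline configuration: YAML in, schema-validated pydantic models out.

Unknown keys are rejected everywhere (``extra="forbid"``) so typos in a
config file fail loudly instead of silently running defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .ca import DispersalParams
from .occurrences import ThinningConfig
from .habitat import SelectionConfig
from .synthetic import SyntheticSpec

__all__ = ["SynthSection", "ThinningSection", "SelectionSection",
           "DispersalSection", "PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", populate_by_name=True)


class SynthSection(_Strict):
    nx: int = 100
    ny: int = 100
    cell_size: float = 200.0
    forest_fraction: float = 0.46
    builtup_fraction: float = 0.11
    paddy_fraction: float = 0.20
    water_fraction: float = 0.03
    autocorr_range: float = 1000.0
    response_coefficients: dict[str, float] = Field(
        default_factory=lambda: {"temperature": 1.5, "precipitation": -1.0, "hfp": 1.0})
    intercept: float = 0.0

    def to_spec(self, seed: int) -> SyntheticSpec:
        return SyntheticSpec(seed=seed, **self.model_dump())


class ThinningSection(_Strict):
    """Defaults here are scaled to the synthetic demo domain (a few tens of
    km), not to the continental occurrence-cleaning defaults of
    :class:`ThinningConfig` itself."""

    max_uncertainty: float = 100.0
    min_interpoint: float = 800.0
    pa_min_dist: float = 400.0
    n_pseudo_absence: int = 150

    def to_config(self, seed: int) -> ThinningConfig:
        return ThinningConfig(seed=seed, **self.model_dump())


class SelectionSection(_Strict):
    corr_threshold: float = 0.8
    vif_threshold: float = 4.0

    def to_config(self) -> SelectionConfig:
        return SelectionConfig(**self.model_dump())


class DispersalSection(_Strict):
    lam: float = Field(0.005, alias="lambda")
    sdd_max: float = 600.0
    ldd_min: float = 600.0
    ldd_max: float = 10_000.0
    ldd_freq: float = 0.0005
    maturity_age: int = 1
    n_replicates: int = 10

    def to_params(self, seed: int) -> DispersalParams:
        return DispersalParams(seed=seed, **self.model_dump())


class PipelineConfig(_Strict):
    """One document driving the full synthetic pipeline run."""

    seed: int = 0
    synth: SynthSection = Field(default_factory=SynthSection)
    thinning: ThinningSection = Field(default_factory=ThinningSection)
    selection: SelectionSection = Field(default_factory=SelectionSection)
    dispersal: DispersalSection = Field(default_factory=DispersalSection)
    invasibility_threshold: float = 0.5
    horizon_years: int = 60
    n_occurrences: int = 400
    n_trees: int = 300
    init_buffer_radius: float = 1000.0
    init_merge_dist: float = 2000.0
    n_init_points: int = 2
    downscale_target_cell: float | None = None
    calibrate: bool = False
    calibration_horizon: int = 13


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(raw)
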