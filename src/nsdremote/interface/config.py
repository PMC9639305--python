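"""Config-file schema (JSON or YAML-compatible dicts) for cohort generation
and study runs, validated with pydantic."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, model_validator

from ..phantom import NOISE_MODELS, CohortTemplate, PhantomSpec

Range = tuple[float, float]


class TemplateConfig(BaseModel):
    """Per-site phantom template. Angles in degrees, lengths in mm,
    intensities on the normalized [0, 1] scale. ``*_range`` fields request
    per-slice uniform sampling of the corresponding geometry field."""

    grid_size: int = 128
    pixel_spacing: float = 1.5
    center: Range | None = None
    endo_radius: float = 20.0
    epi_radius: float = 30.0
    infarct_center_angle: float = 0.0
    infarct_extent: float = 90.0
    transmurality: float = 1.0
    mvo_fraction: float = 0.0
    mvo_mean: float | None = None
    remote_mean: float = 0.1
    remote_sd: float = 0.02
    infarct_mean: float = 0.7
    infarct_sd: float = 0.05
    noise_model: str = "rician"
    coil_count: int = 1
    bias_amplitude: float = 0.0
    bias_scale: float = 40.0
    edge_smooth_px: float = 0.0
    infarct_center_angle_range: Range | None = None
    infarct_extent_range: Range | None = None
    transmurality_range: Range | None = None
    mvo_fraction_range: Range | None = None

    @model_validator(mode="after")
    def _check(self):
        if self.epi_radius <= self.endo_radius:
            raise ValueError(
                f"epi_radius ({self.epi_radius}) must exceed endo_radius ({self.endo_radius})"
            )
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")
        return self

    def to_template(self, site_label: str) -> CohortTemplate:
        spec_fields = {
            k: v
            for k, v in self.model_dump().items()
            if not k.endswith("_range") or k == "center"
        }
        spec_fields.pop("infarct_center_angle_range", None)
        base = PhantomSpec(site_label=site_label, **spec_fields)
        base.validate()
        return CohortTemplate(
            base=base,
            infarct_center_angle_range=self.infarct_center_angle_range,
            infarct_extent_range=self.infarct_extent_range,
            transmurality_range=self.transmurality_range,
            mvo_fraction_range=self.mvo_fraction_range,
        )


class SiteConfig(BaseModel):
    label: str
    count: int = Field(ge=1)
    template: TemplateConfig = TemplateConfig()


class CohortConfig(BaseModel):
    master_seed: int = 0
    sites: list[SiteConfig] = Field(min_length=1)

    def site_specs(self) -> list[tuple[CohortTemplate, int]]:
        return [(s.template.to_template(s.label), s.count) for s in self.sites]


class StudyRunConfig(BaseModel):
    """Study-level knobs mirrored onto ``variability_study.StudyConfig``."""

    baseline_n: float = 3.5
    baseline_width: float = 45.0
    rim_fraction: float = 0.15
    n_grid: list[float] = [2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
    size_grid: list[float] = [15.0, 30.0, 45.0, 60.0, 75.0, 90.0, 105.0]
    min_step: float = 10.0
    max_positions: int = 7
    remove_spurious: bool = False
    min_island: int = 10
    connectivity: int = 8

    def to_study_config(self):
        from ..variability_study import StudyConfig

        return StudyConfig(
            baseline_n=self.baseline_n,
            baseline_width=self.baseline_width,
            rim_fraction=self.rim_fraction,
            n_grid=tuple(self.n_grid),
            size_grid=tuple(self.size_grid),
            min_step=self.min_step,
            max_positions=self.max_positions,
            remove_spurious=self.remove_spurious,
            min_island=self.min_island,
            connectivity=self.connectivity,
        )


def load_cohort_config(path: str | Path) -> CohortConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return CohortConfig.model_validate(data)
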