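"""Run configuration: schema-validated, fully defaulted settings.

A run configuration is loaded from YAML or JSON.  Unknown keys are rejected
(typos should fail loudly, not silently fall back to defaults), and every
default is materialised on load so the effective configuration logged at run
start fully reconstructs the run.

A single global ``seed`` is split deterministically into independent
per-purpose streams (optimizer, phantom, image noise, trial perturbations)
via :class:`numpy.random.SeedSequence`, so changing how many draws one stage
consumes can never shift another stage's randomness.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .pose import RigidTransform, default_view_change

__all__ = [
    "GeometryConfig",
    "SimilarityConfig",
    "WeightsConfig",
    "OptimizerConfig",
    "PhantomConfig",
    "RegistrationSection",
    "RunConfig",
    "load_config",
    "split_seed",
]

_STREAMS = ("optimizer", "phantom", "image_noise", "trials")


def split_seed(seed: int, stream: str) -> int:
    """Deterministic per-purpose child seed of the global seed (< 2**31)."""
    if stream not in _STREAMS:
        raise ValueError(f"unknown seed stream {stream!r}; known: {_STREAMS}")
    children = np.random.SeedSequence(int(seed)).spawn(len(_STREAMS))
    return int(children[_STREAMS.index(stream)].generate_state(1)[0] % (2**31))


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class GeometryConfig(_Section):
    """Projection geometry: distances in mm, detector in pixels."""

    source_to_iso: float = Field(default=1000.0, gt=0)
    iso_to_detector: float = Field(default=200.0, gt=0)
    detector_shape: tuple[int, int] = (256, 256)
    pixel_spacing: float = Field(default=1.0, gt=0)
    step: float | None = Field(default=None, gt=0, description="ray step in mm; None = half the smallest voxel spacing")
    view_change: list[float] | None = Field(
        default=None, description="row-major 16-number frontal-to-lateral transform; None = +90 deg about Y"
    )

    def view_change_transform(self) -> RigidTransform:
        if self.view_change is None:
            return default_view_change()
        return RigidTransform.from_list(self.view_change)


class SimilarityConfig(_Section):
    """Contour bands (pixels), band weights and Canny settings."""

    a_band: float = Field(default=1.0, gt=0)
    b_band: float = Field(default=3.0, gt=0)
    w1: float = Field(default=0.8, gt=0, le=1)
    w2: float = Field(default=0.5, gt=0, le=1)
    canny_sigma: float = Field(default=1.0, gt=0)
    canny_low_quantile: float = Field(default=0.70, ge=0, lt=1)
    canny_high_quantile: float = Field(default=0.90, gt=0, le=1)

    @model_validator(mode="after")
    def _check(self):
        if not self.a_band < self.b_band:
            raise ValueError(f"bands must satisfy a_band < b_band, got {self.a_band} >= {self.b_band}")
        if not self.w1 > self.w2:
            raise ValueError(f"band weights must satisfy w1 > w2, got {self.w1} <= {self.w2}")
        if not self.canny_low_quantile < self.canny_high_quantile:
            raise ValueError("canny_low_quantile must be below canny_high_quantile")
        return self


class WeightsConfig(_Section):
    """Composite frontal/lateral weights; the frontal view must dominate."""

    wf: float = Field(default=0.6, gt=0, lt=1)
    wl: float = Field(default=0.4, gt=0, lt=1)

    @model_validator(mode="after")
    def _check(self):
        if not self.wf > self.wl:
            raise ValueError(f"the frontal weight must exceed the lateral one (wf > wl), got wf={self.wf}, wl={self.wl}")
        if self.wf + self.wl > 1 + 1e-12:
            raise ValueError(f"wf + wl must not exceed 1, got {self.wf + self.wl}")
        return self


class OptimizerConfig(_Section):
    """Phased-DE settings; F/CR switch values at the halfway generation."""

    np_size: int = Field(default=10, ge=6)
    gmax: int = Field(default=50, ge=1)
    f_first: float = Field(default=0.5, gt=0, le=2)
    f_second: float = Field(default=0.8, gt=0, le=2)
    cr_first: float = Field(default=0.9, ge=0, lt=1)
    cr_second: float = Field(default=0.3, ge=0, lt=1)
    f_dim_scale: list[float] | None = Field(
        default=None,
        description="per-dimension F multiplier; None = 0.8 on the depth translation (tz), 1 elsewhere",
    )

    @model_validator(mode="after")
    def _check(self):
        if not self.cr_first > 0.5 > self.cr_second:
            raise ValueError(
                f"the CR schedule must straddle 0.5 (cr_first > 0.5 > cr_second), got {self.cr_first}, {self.cr_second}"
            )
        return self

    def dim_scale(self, dim: int = 6) -> tuple[float, ...]:
        if self.f_dim_scale is not None:
            if len(self.f_dim_scale) != dim:
                raise ValueError(f"f_dim_scale must have {dim} entries, got {len(self.f_dim_scale)}")
            return tuple(self.f_dim_scale)
        scale = [1.0] * dim
        if dim >= 3:
            scale[2] = 0.8
        return tuple(scale)


class PhantomConfig(_Section):
    """Synthetic phantom defaults (see :mod:`drrpose.phantom`)."""

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background: float = 100.0
    bone_intensity: float = 300.0
    volume_noise_sd: float = Field(default=5.0, ge=0)
    image_noise_sd: float = Field(default=2.0, ge=0)


class RegistrationSection(_Section):
    """Registration mode, initial pose and per-DOF search half-widths."""

    mode: str = Field(default="dual", pattern="^(dual|single)$")
    initial_pose: list[float] = Field(default=[0.0] * 6, min_length=6, max_length=6)
    half_widths: list[float] = Field(
        default=[10.0] * 6, min_length=6, max_length=6, description="(mm, mm, mm, deg, deg, deg)"
    )
    inject_initial: bool = Field(default=True, description="seed the DE population with the initial pose")

    @model_validator(mode="after")
    def _check(self):
        if any(h <= 0 for h in self.half_widths):
            raise ValueError("search half-widths must be positive")
        return self


class RunConfig(_Section):
    geometry: GeometryConfig = GeometryConfig()
    similarity: SimilarityConfig = SimilarityConfig()
    weights: WeightsConfig = WeightsConfig()
    optimizer: OptimizerConfig = OptimizerConfig()
    phantom: PhantomConfig = PhantomConfig()
    registration: RegistrationSection = RegistrationSection()
    seed: int = 0

    def effective_dict(self) -> dict:
        return self.model_dump()


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    An empty file yields the all-defaults configuration.  Schema violations
    (unknown keys, ill-ordered weights, degenerate geometry) are reported
    with their key paths.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text) if text.strip() else {}
    else:
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return RunConfig(**raw)
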