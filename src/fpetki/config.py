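"""Run configuration: one validated schema for simulation and quantification.

Defaults encode the acquisition protocol the package targets: 20:80
bolus:infusion over a 50 min scan, 60 s frames, task blocks of 5 min at
10/20/30/40 min, Patlak t* = 25 min, 2.5 min low-pass cutoff and a fixed
5% whole-blood fraction.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .frames import FrameSchedule
from .types import AdministrationSchedule, TaskSchedule


class FramesConfig(BaseModel):
    duration: float = 50.0  # minutes
    frame_length: float = 1.0  # minutes

    def build(self) -> FrameSchedule:
        return FrameSchedule.uniform(self.duration, self.frame_length)


class TaskConfig(BaseModel):
    onsets: list[float] = Field(default_factory=lambda: [10.0, 20.0, 30.0, 40.0])
    duration: float = 5.0
    conditions: list[str] = Field(default_factory=lambda: ["gain", "loss", "gain", "loss"])

    def build(self) -> TaskSchedule:
        return TaskSchedule(tuple(self.onsets), self.duration, tuple(self.conditions))


class AdministrationConfig(BaseModel):
    bolus_fraction: float = 0.20
    infusion_duration: float = 50.0
    total_activity: float = 1.0
    scan_duration: float = 50.0

    def build(self) -> AdministrationSchedule:
        return AdministrationSchedule(
            self.bolus_fraction, self.infusion_duration, self.total_activity, self.scan_duration
        )


class BloodModelConfig(BaseModel):
    parent_amps: list[float] = Field(default_factory=lambda: [40.0, 10.0])
    parent_rates: list[float] = Field(default_factory=lambda: [0.08, 0.6])
    k_met: float = 0.012
    lam_met: float = 0.02
    ratio_intercept: float = 1.10
    ratio_slope: float = 0.0015

    def build(self):
        from .synthetic.blood_model import BloodModelParams

        return BloodModelParams(
            parent_amps=tuple(self.parent_amps),
            parent_rates=tuple(self.parent_rates),
            k_met=self.k_met,
            lam_met=self.lam_met,
            ratio_intercept=self.ratio_intercept,
            ratio_slope=self.ratio_slope,
        )


class RegionConfig(BaseModel):
    """One simulated region.

    Target and gray-matter regions share the fast-exchange two-tissue
    kinetics; the reference region has no trapping. ``task_ki`` gives the
    generative task-specific net-influx increment (1/min) per condition for
    target regions.
    """

    name: str
    role: Literal["target", "gray", "reference"] = "gray"
    K1: float = 0.6  # mL/cm3/min
    k2: float = 12.0  # 1/min
    ki_baseline: float = 0.009  # 1/min (ignored for reference)
    task_ki: dict[str, float] = Field(default_factory=dict)  # condition -> delta Ki

    @model_validator(mode="after")
    def _check(self):
        if self.role == "reference" and self.task_ki:
            raise ValueError("reference region cannot have task modulation")
        if self.role != "target" and self.task_ki:
            raise ValueError("only target regions carry task modulation")
        return self


def default_regions(
    ki_baseline: float = 0.009,
    task_ki: dict[str, float] | None = None,
) -> list[RegionConfig]:
    """Default synthetic grid: one task-modulated target (ventral striatum),
    six gray-matter regions sharing the target's baseline kinetics with
    scaled delivery (K1), and a trapping-free occipital reference.

    Gray matter deliberately shares (k2, k3) with the target — baseline
    influx scales with delivery K1 — so the gray-matter average is
    shape-proportional to the target's baseline uptake, the assumption
    behind using it as the GLM baseline regressor.
    """
    if task_ki is None:
        task_ki = {"gain": 0.014, "loss": 0.009}
    regions = [
        RegionConfig(name="vstr", role="target", ki_baseline=ki_baseline, task_ki=dict(task_ki))
    ]
    for i, scale in enumerate((0.8, 0.9, 1.0, 1.1, 1.2, 1.05)):
        regions.append(
            RegionConfig(
                name=f"gm{i + 1}",
                role="gray",
                K1=0.6 * scale,
                ki_baseline=ki_baseline * scale,
            )
        )
    regions.append(RegionConfig(name="occipital", role="reference", K1=0.06, k2=0.05))
    return regions


class MidConfig(BaseModel):
    trials_per_block: int = 20
    staircase_step: float = 20.0  # ms
    initial_limit: float = 500.0  # ms
    manipulation_bias: float = 150.0  # ms
    amounts: list[float] = Field(default_factory=lambda: [1.0, 2.0, 3.0])
    rt_noise_sd: float = 100.0  # ms
    # mean RT model: intercept + linear*amount + quadratic*amount^2 (ms)
    rt_intercept: float = 500.0
    rt_linear: float = 0.0
    rt_quadratic: float = 0.0

    def rt_model(self):
        return lambda a: self.rt_intercept + self.rt_linear * a + self.rt_quadratic * a * a


class QuantConfig(BaseModel):
    t_star: float = 25.0  # minutes
    cutoff_period: float = 2.5  # minutes
    vB: float = 0.05
    extrapolation_margin: float = 5.0  # minutes past last blood sample
    grid_dt: float = 1.0 / 60.0  # input-function grid step, minutes


class RunConfig(BaseModel):
    frames: FramesConfig = Field(default_factory=FramesConfig)
    task: TaskConfig = Field(default_factory=TaskConfig)
    administration: AdministrationConfig = Field(default_factory=AdministrationConfig)
    blood_model: BloodModelConfig = Field(default_factory=BloodModelConfig)
    regions: list[RegionConfig] = Field(default_factory=default_regions)
    mid: MidConfig = Field(default_factory=MidConfig)
    quant: QuantConfig = Field(default_factory=QuantConfig)
    metabolite_kinetics: tuple[float, float] = (0.06, 0.05)  # K1m, k2m (uniform)
    noise_sd: float = 0.0  # TAC noise, kBq/mL
    motion_sd: float = 0.02  # sd of the stationary frame-to-frame motion jitter
    blood_sample_interval: float = 1.0 / 6.0  # minutes (10 s sampling)
    exclusion: list[str] = Field(default_factory=lambda: ["vstr"])
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        roles = [r.role for r in self.regions]
        if roles.count("reference") != 1:
            raise ValueError("exactly one reference region required")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        self.task.build().validate_within(self.frames.duration)
        if self.frames.duration > self.administration.scan_duration + 1e-9:
            raise ValueError("frames extend beyond the administration scan_duration")
        return self

    # ---- convenience ----------------------------------------------------
    @property
    def reference_name(self) -> str:
        return next(r.name for r in self.regions if r.role == "reference")

    @property
    def target_names(self) -> list[str]:
        return [r.name for r in self.regions if r.role == "target"]

    @property
    def gray_names(self) -> list[str]:
        return [r.name for r in self.regions if r.role in ("gray", "target")]

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.model_validate(data or {})

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False))
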