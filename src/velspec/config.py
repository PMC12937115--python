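"""Run configuration: YAML round-trippable description of an experiment.

Sections: phantom (geometry + laminar model), encoding (ladder + axis,
user units G/cm and cm/s), corruption (measurement model), recon (stage
toggles) and io (paths). Every run writes the resolved config next to its
outputs so the experiment is auditable.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .encode import CorruptionSpec
from .physics import LadderScheme, MomentLadder, ladder_for_axis, make_ladder
from .recon import ReconConfig


@dataclass
class PhantomConfig:
    kind: str = "multitube"  # "multitube" | "loop"
    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 2.0
    model: str = "paper"  # laminar density model
    bath: str = "sphere"
    supersample: int = 4
    # multitube
    n_tubes: int = 8
    d_min_mm: float = 2.25
    d_max_mm: float = 4.0
    calibration_mean_cm_s: float = 7.24
    # loop
    tube_diameter_mm: float = 12.7
    v_mean_cm_s: float = 1.0


@dataclass
class EncodingConfig:
    n_encodes: int = 30
    scheme: str = "asymmetric"
    # exactly one of these pins the axis; delta_v wins if both set
    delta_v_cm_s: float | None = 0.576
    m1_max: float | None = None  # T·s²/m
    max_grad_G_per_cm: float = 4.0
    gap_scale: float = 1.0

    def ladder(self) -> MomentLadder:
        if self.delta_v_cm_s is not None:
            return ladder_for_axis(self.n_encodes, self.scheme, delta_v_cm_s=self.delta_v_cm_s)
        if self.m1_max is None:
            raise ValueError("encoding config needs delta_v_cm_s or m1_max")
        return make_ladder(self.n_encodes, self.m1_max, LadderScheme(self.scheme))


@dataclass
class CorruptionConfig:
    noise_sd: float = 0.0
    drift_coeffs: tuple = ()
    background_phase: float = 0.0

    def spec(self, seed: int) -> CorruptionSpec:
        return CorruptionSpec(
            noise_sd=self.noise_sd,
            drift_coeffs=tuple(self.drift_coeffs),
            background_phase=self.background_phase,
            seed=seed,
        )

    @property
    def is_clean(self) -> bool:
        return self.noise_sd == 0 and not self.drift_coeffs and self.background_phase == 0


@dataclass
class IOConfig:
    out_dir: str = "velspec_out"
    stem: str = "run"


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    corruption: CorruptionConfig = field(default_factory=CorruptionConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    io: IOConfig = field(default_factory=IOConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phantom"]["shape"] = list(self.phantom.shape)
        d["corruption"]["drift_coeffs"] = list(self.corruption.drift_coeffs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        ph = PhantomConfig(**{**d.get("phantom", {})})
        ph.shape = tuple(ph.shape)
        enc = EncodingConfig(**d.get("encoding", {}))
        cor = CorruptionConfig(**d.get("corruption", {}))
        cor.drift_coeffs = tuple(cor.drift_coeffs)
        rec = ReconConfig(**d.get("recon", {}))
        io_ = IOConfig(**d.get("io", {}))
        return cls(
            phantom=ph, encoding=enc, corruption=cor, recon=rec, io=io_,
            seed=int(d.get("seed", 0)),
        )

    def save(self, path: str | Path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
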