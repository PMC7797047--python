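"""Run configuration: YAML-backed, with every analysis threshold at its
published default (R^2 0.70, near-zero exemption +/-0.05, depth floor 10,
Dixon Q at 95%, minimum 3 replicates, SGoF gamma and metatest alpha 0.05,
logistic bounds [0, 1.15] / [0, 14] with starts (meanL, meanH, 1, 6))."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["EnvironmentConfig", "RunConfig"]


@dataclass
class EnvironmentConfig:
    name: str
    schedule_hours: tuple[float, ...]
    doublings_per_hour: float

    def validate(self) -> None:
        hrs = list(self.schedule_hours)
        if not hrs or hrs[0] != 0 or any(b <= a for a, b in zip(hrs, hrs[1:])):
            raise ValueError(
                f"environment {self.name!r}: schedule must start at 0 and increase"
            )
        if self.doublings_per_hour <= 0:
            raise ValueError(f"environment {self.name!r}: doublings_per_hour must be > 0")


def _default_envs() -> list[EnvironmentConfig]:
    return [
        EnvironmentConfig("glucose", (0, 2, 4, 6, 10, 12, 14), 0.94),
        EnvironmentConfig("glycerol", (0, 2, 6, 10, 14), 0.53),
    ]


@dataclass
class RunConfig:
    seed: int = 0
    # inputs
    genes_fasta: str | None = None  # None: generate synthetic genes
    n_genes: int = 12
    gene_length: int = 600
    background_fasta: str | None = None
    # design
    library: str = "full"  # full | compact
    n_negc: int = 45
    gc_min: float = 0.45
    gc_max: float = 0.80
    polyt_max: int = 4
    # simulation
    environments: list[EnvironmentConfig] = field(default_factory=_default_envs)
    depth: int = 200_000
    escape_prob: float = 0.01
    replicate_jitter_sd: float = 0.01
    floor_raw_truth: float = -1.23
    # growth analysis
    reference: str = "auto"
    floor: float | str = "auto"
    depth_floor: int = 10
    r2_min: float = 0.70
    exempt: float = 0.05
    min_replicates: int = 3
    # steps / gxe
    scopes: tuple[str, ...] = ("all", "compounding", "single", "compact")
    gamma: float = 0.05
    alpha: float = 0.05
    min_points: int = 8

    def validate(self) -> None:
        if self.library not in ("full", "compact"):
            raise ValueError("library must be 'full' or 'compact'")
        if not self.environments:
            raise ValueError("at least one environment is required")
        for env in self.environments:
            env.validate()
        if not (0 < self.gc_min < self.gc_max < 1):
            raise ValueError("need 0 < gc_min < gc_max < 1")
        if isinstance(self.floor, (int, float)) and self.floor >= 0:
            raise ValueError("floor must be negative or 'auto'")
        if self.seed < 0 or self.seed >= 2**31:
            raise ValueError("seed must be in [0, 2**31)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        envs = raw.pop("environments", None)
        cfg = cls(**raw)
        cfg.scopes = tuple(cfg.scopes)
        if envs is not None:
            cfg.environments = [
                EnvironmentConfig(
                    e["name"], tuple(e["schedule_hours"]), e["doublings_per_hour"]
                )
                for e in envs
            ]
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["environments"] = [
            {
                "name": e.name,
                "schedule_hours": list(e.schedule_hours),
                "doublings_per_hour": e.doublings_per_hour,
            }
            for e in self.environments
        ]
        data["scopes"] = list(self.scopes)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
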