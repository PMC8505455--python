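"""Run configuration: every tunable of the pipeline, with study defaults.

Defaults follow the study protocol where it states one: 45 concepts, 6
presentations, 120 stable voxels per region, 10 factors per lobe, 0.4
loading threshold, minimum cluster size 2, 5 voxels per forward-model
cluster feature, 6 voxels per group-comparison cluster feature.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

DEFAULT_STAGES = (
    "simulate",
    "preprocess",
    "decoding",
    "factors",
    "forward_model",
    "group_compare",
)

# stage -> stages that must run (or be loadable) first
STAGE_DEPENDENCIES = {
    "preprocess": ("simulate",),
    "decoding": ("simulate", "preprocess"),
    "factors": ("simulate", "preprocess", "decoding"),
    "forward_model": ("simulate", "preprocess", "factors"),
    "group_compare": ("simulate", "preprocess"),
}


@dataclass
class RunConfig:
    # cohort / generator
    seed: int = 0
    n_concepts: int = 45
    n_presentations: int = 6
    n_faculty: int = 10
    n_students: int = 9
    grid_shape: tuple[int, int, int] = (12, 12, 8)
    voxel_size_mm: tuple[float, float, float] = (3.125, 3.125, 6.0)
    clusters_per_dimension: int = 3
    cluster_size_range: tuple[int, int] = (6, 10)
    noise_sd: float = 0.1
    participant_sd: float = 0.1
    group_effect: float = 0.5
    n_raters: int = 6
    rater_noise_sd: float = 1.0
    # preprocessing / selection
    n_per_lobe: int = 120
    n_features: int = 120
    # factor analysis
    n_factors: int = 10
    loading_threshold: float = 0.4
    variance_threshold: float = 0.02
    min_cluster_size: int = 2
    connectivity: int = 6
    n_fa_participants: int = 3
    extremes_k: int = 10
    # decoding
    n_test_presentations: int = 2
    n_permutations: int = 200
    # forward model
    forward_n_voxels: int = 5
    cuboid_radius: int = 1
    # group comparison
    group_n_voxels: int = 6
    group_min_participants: int = 4
    group_fa_factors: int = 4
    stepwise_beam_width: int = 16
    # orchestration
    stages: tuple[str, ...] = DEFAULT_STAGES
    bundle_path: str | None = None
    outdir: str = "neurosem_run"

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        for stage, deps in STAGE_DEPENDENCIES.items():
            if stage in self.stages:
                missing = [d for d in deps if d not in self.stages
                           and not (d == "simulate" and self.bundle_path)]
                if missing:
                    raise ValueError(
                        f"stage {stage!r} requires {missing} to run first"
                    )
        if "group_compare" in self.stages and (
            self.n_faculty < 2 or self.n_students < 2
        ):
            raise ValueError(
                "group_compare requires at least 2 participants in each group"
            )
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("grid_shape", "voxel_size_mm", "cluster_size_range", "stages"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
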