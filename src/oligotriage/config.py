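"""Run configuration: one seed, one config object, reproducible sub-seeds."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .ihc import ScoringConfig
from .simulate import SimImageParams


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    Every stochastic step (field simulation per case, FISH tables) derives its
    seed deterministically from ``seed`` via a SeedSequence, so a run is fully
    reproducible from the config alone.
    """

    seed: int = 0
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    image_params: SimImageParams = field(default_factory=SimImageParams)
    linkage: str = "average"
    tree_min_leaf: int = 5
    write_images: bool = True
    n_fields: int = 3

    def validate(self) -> None:
        self.scoring.validate()
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")
        base = replace(self.image_params, stained_fraction=0.5)
        base.validate()

    def spawn_seeds(self, n: int) -> list[int]:
        """n child seeds derived deterministically from the run seed."""
        return [int(s) for s in
                np.random.SeedSequence(self.seed).generate_state(n) % (2**31)]


def _build(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if cls is SimImageParams and "nucleus_radius_range" in data:
        data = dict(data)
        data["nucleus_radius_range"] = tuple(data["nucleus_radius_range"])
    return cls(**data)


def load_config(path=None, seed: int | None = None) -> RunConfig:
    """Load a RunConfig from a TOML file; ``seed`` overrides the file's seed.

    Recognized TOML tables: top-level scalars of RunConfig, ``[scoring]`` and
    ``[image_params]``.
    """
    data: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    scoring = _build(ScoringConfig, data.pop("scoring", {}))
    image_params = _build(SimImageParams, data.pop("image_params", {}))
    cfg = _build(RunConfig, {**data, "scoring": scoring, "image_params": image_params})
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cfg.validate()
    return cfg
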