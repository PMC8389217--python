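"""Run configuration: validated settings with the study's default protocol.

Defaults follow the reference protocol: deterministic probe at 16,200 s,
1000 s stochastic windows, the fc switch at 7000 s, 5 replicates, and the
condition sets fc in {1.0, 0.3, 0.1}, bf/uf in {0.5, 1.0, 1.5}.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    model: str = "full"  # "full" | "reduced" | path to a model file
    fc_set: list = field(default_factory=lambda: [1.0, 0.3, 0.1])
    bf_set: list = field(default_factory=lambda: [0.5, 1.0, 1.5])
    uf_set: list = field(default_factory=lambda: [0.5, 1.0, 1.5])
    n_reps: int = 5
    t_probe: float = 16200.0
    t_run: float = 1000.0
    t_switch: float = 7000.0
    t_end: float = 40000.0
    grid_dt: float = 1.0
    base_seed: int = 0
    out_dir: str = "phobr_out"

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for name in ("t_probe", "t_run", "t_switch", "t_end", "grid_dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("fc_set", "bf_set", "uf_set"):
            vals = getattr(self, name)
            if not vals or any(v < 0 for v in vals):
                raise ValueError(f"{name} must be non-empty and non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Read a YAML/JSON config; unknown keys are an error, missing keys
    take the protocol defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
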