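"""Structured run configuration (YAML-serialisable)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .anatomy import AnatomyConfig
from .deployment import ContactParams
from .lbm import FluidProps, LatticeConfig
from .stent import StentDesign

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to run the full study end to end.

    The stiffness ratio list spans the chronicity range of the dissection
    flap: 1 (chronic, wall-stiff) to 0.01 (acute, highly mobile).
    """

    anatomy: AnatomyConfig = field(default_factory=AnatomyConfig)
    stent: StentDesign = field(default_factory=StentDesign)
    contacts: ContactParams = field(default_factory=ContactParams)
    fluid: FluidProps = field(default_factory=FluidProps)
    lattice: LatticeConfig = field(default_factory=lambda: LatticeConfig(dx=2.0e-3))
    stiffness_ratios: tuple = (1.0, 0.1, 0.01)
    outlet_mode: str = "constant"          # constant | oscillating
    n_slices: int = 20
    random_seed: int = 0
    output_dir: str = "archstent_out"

    def __post_init__(self) -> None:
        if len(self.stiffness_ratios) == 0:
            raise ValueError("stiffness ratio list must be non-empty")
        if any(r <= 0 for r in self.stiffness_ratios):
            raise ValueError("stiffness ratios must be positive")
        if self.outlet_mode not in ("constant", "oscillating"):
            raise ValueError(f"unknown outlet mode {self.outlet_mode!r}")


def _to_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(x) for x in obj]
    return obj


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(config), sort_keys=False))


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; missing keys take their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    sub = {"anatomy": AnatomyConfig, "stent": StentDesign,
           "contacts": ContactParams, "fluid": FluidProps,
           "lattice": LatticeConfig}
    for key, cls in sub.items():
        if key in raw:
            d = dict(raw.pop(key) or {})
            d.pop("material", None)          # material block handled by defaults
            for k, v in list(d.items()):
                if isinstance(v, list):
                    d[k] = tuple(v)
            kwargs[key] = cls(**d)
    for k, v in raw.items():
        kwargs[k] = tuple(v) if isinstance(v, list) else v
    return RunConfig(**kwargs)
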