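"""Run configuration, presets and checkpoint I/O.

Configurations are YAML mappings with four sections — ``geometry``,
``stimulus``, ``architecture`` and ``learning`` — plus run-level scalars
(``n_steps``, ``checkpoint_interval``, ``eval_steps``, ``seeds``).  Every
field has a default matching the training condition, so a preset only needs
to state what it changes.  Validation happens on load and names the
offending field.

Checkpoints are written as an ``.npz`` array container (weights, mask,
flat-index arrays) next to a JSON manifest holding the architecture sizes,
the step counter and a SHA-256 checksum of the array file; loading verifies
the checksum.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .network import Architecture, ConnectivityMask, build_architecture
from .rtrl import LearningConfig
from .world import Geometry, InputLayout, Rect, StimulusValues

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "load_preset",
    "preset_names",
    "save_checkpoint",
    "load_checkpoint",
    "CheckpointError",
]


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the field."""


@dataclass(frozen=True)
class RunConfig:
    """Fully validated configuration of one experiment."""

    geometry: Geometry = field(default_factory=Geometry)
    stimulus: StimulusValues = field(default_factory=StimulusValues)
    architecture: Architecture = field(default_factory=Architecture)
    learning: LearningConfig = field(default_factory=LearningConfig)
    n_steps: int = 50_000_000
    checkpoint_interval: int = 1_000_000
    eval_steps: int = 10_000
    assembly_threshold: float = 0.9
    seeds: tuple[int, ...] = tuple(range(10))

    def __post_init__(self) -> None:
        layout = InputLayout.from_geometry(self.geometry)
        if layout.total != self.architecture.n_input:
            raise ConfigError(
                f"architecture.n_input: input blocks sum to {layout.total} "
                f"(visual {layout.n_visual} + proprio {layout.n_proprio} + "
                f"corollary {layout.n_corollary}) but the architecture "
                f"declares {self.architecture.n_input}")
        if self.n_steps < 1:
            raise ConfigError("n_steps: must be >= 1")
        if self.checkpoint_interval < 1:
            raise ConfigError("checkpoint_interval: must be >= 1")
        if self.eval_steps < 1:
            raise ConfigError("eval_steps: must be >= 1")
        if not 0.0 < self.assembly_threshold <= 1.0:
            raise ConfigError("assembly_threshold: must be in (0, 1]")
        if not 0.0 <= self.learning.move_threshold < 1.0:
            raise ConfigError("learning.move_threshold: must be in [0, 1)")

    def build_network(self) -> tuple[Architecture, ConnectivityMask]:
        return build_architecture(self.architecture)


def _take(section: dict, name: str, caster, context: str):
    value = section[name]
    try:
        return caster(value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}.{name}: {value!r} is invalid ({exc})") from exc


def _build_section(section: dict | None, context: str, casters: dict,
                   factory):
    section = dict(section or {})
    unknown = set(section) - set(casters)
    if unknown:
        raise ConfigError(f"{context}: unknown fields {sorted(unknown)}")
    kwargs = {k: _take(section, k, c, context) for k, c in casters.items()
              if k in section}
    try:
        return factory(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def _rect(value) -> Rect:
    if isinstance(value, dict):
        return Rect(**{k: int(v) for k, v in value.items()})
    x0, y0, x1, y1 = (int(v) for v in value)
    return Rect(x0, y0, x1, y1)


def load_config(path_or_mapping) -> RunConfig:
    """Load and validate a run configuration from YAML (or a mapping)."""
    if isinstance(path_or_mapping, (str, Path)):
        text = Path(path_or_mapping).read_text()
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"unparseable config file: {exc}") from exc
    else:
        raw = path_or_mapping
    raw = dict(raw or {})

    geometry = _build_section(
        raw.pop("geometry", None), "geometry",
        {"width": int, "height": int, "fov": _rect, "fov_center": _rect},
        Geometry)
    stimulus = _build_section(
        raw.pop("stimulus", None), "stimulus",
        {"hand_visual": float, "other_visual": float, "n_others": int,
         "hand_visual_on": bool, "corollary_on": bool, "confine_others": bool},
        StimulusValues)
    architecture = _build_section(
        raw.pop("architecture", None), "architecture",
        {"n_input": int, "n_hidden_own": int, "n_hidden_agency": int,
         "n_output": int},
        Architecture)
    learning = _build_section(
        raw.pop("learning", None), "learning",
        {"eta": float, "alpha": float, "update_interval": int,
         "move_threshold": float, "init_bound": float},
        LearningConfig)

    scalars = {"n_steps": int, "checkpoint_interval": int, "eval_steps": int,
               "assembly_threshold": float,
               "seeds": lambda v: tuple(int(s) for s in v)}
    unknown = set(raw) - set(scalars)
    if unknown:
        raise ConfigError(f"unknown top-level fields {sorted(unknown)}")
    kwargs = {k: _take(raw, k, c, "run") for k, c in scalars.items() if k in raw}
    return RunConfig(geometry=geometry, stimulus=stimulus,
                     architecture=architecture, learning=learning, **kwargs)


def preset_names() -> list[str]:
    files = resources.files("handregard").joinpath("presets")
    return sorted(p.name[:-5] for p in files.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> RunConfig:
    """Load a shipped preset (``default`` or ``case1`` ... ``case9``)."""
    res = resources.files("handregard").joinpath("presets", f"{name}.yaml")
    if not res.is_file():
        raise ConfigError(f"unknown preset {name!r}; available: {preset_names()}")
    return load_config(yaml.safe_load(res.read_text()))


class CheckpointError(IOError):
    """A checkpoint file is missing, corrupt or fails its checksum."""


def save_checkpoint(path, weights: np.ndarray, mask: ConnectivityMask,
                    step: int) -> Path:
    """Write weights + mask + metadata; returns the manifest path.

    Arrays go to ``<path>.npz``; the manifest ``<path>.json`` records the
    architecture sizes, the step counter and the SHA-256 of the array file.
    """
    path = Path(path)
    npz_path = path.with_suffix(".npz")
    manifest_path = path.with_suffix(".json")
    np.savez(npz_path, weights=weights, allowed=mask.allowed)
    digest = hashlib.sha256(npz_path.read_bytes()).hexdigest()
    arch = mask.arch
    manifest = {
        "format": "handregard-checkpoint-v1",
        "step": int(step),
        "sha256": digest,
        "architecture": {
            "n_input": arch.n_input,
            "n_hidden_own": arch.n_hidden_own,
            "n_hidden_agency": arch.n_hidden_agency,
            "n_output": arch.n_output,
        },
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_checkpoint(path) -> tuple[np.ndarray, ConnectivityMask, int]:
    """Read a checkpoint back, verifying the stored checksum bit-exactly."""
    path = Path(path)
    npz_path = path.with_suffix(".npz")
    manifest_path = path.with_suffix(".json")
    if not npz_path.exists() or not manifest_path.exists():
        raise CheckpointError(f"checkpoint files missing for {path}")
    manifest = json.loads(manifest_path.read_text())
    digest = hashlib.sha256(npz_path.read_bytes()).hexdigest()
    if digest != manifest.get("sha256"):
        raise CheckpointError(
            f"checksum mismatch for {npz_path}: file is corrupt or truncated")
    with np.load(npz_path) as data:
        weights = data["weights"].copy()
        allowed = data["allowed"].copy()
    arch = Architecture(**manifest["architecture"])
    mask = ConnectivityMask(allowed=allowed, arch=arch)
    return weights, mask, int(manifest["step"])
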