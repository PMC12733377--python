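"""YAML configuration for the pipeline and the phantom generator.

Every default equals the method's stated value where one exists (disk size
55, Gaussian size 63 with sigma 53, threshold 0.1, at least six landmark
pairs); unknown keys are rejected rather than ignored so typos cannot
silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import yaml

from .extraction import DEFAULT_CLOSING_RADIUS, DEFAULT_DIFF_THRESHOLD
from .phantom import PhantomParams
from .tissue import TissueMaskParams
from .transfer import DEFAULT_EROSION_SIZE, PipelineParams

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class RegistrationConfig:
    normalization: str = "per_axis"
    condition_cap: float = 1e8


@dataclass(frozen=True)
class ExtractionConfig:
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD
    closing_radius: int = DEFAULT_CLOSING_RADIUS


@dataclass(frozen=True)
class TransferConfig:
    erosion_size: int = DEFAULT_EROSION_SIZE
    overlay_color: tuple[int, int, int] = (0, 255, 0)
    overlay_thickness: int = 3


@dataclass(frozen=True)
class MetricsConfig:
    extractor: str = "builtin"  # "builtin" or "plugin:<module>:<attr>"
    quantile_rule: str = "linear"


@dataclass(frozen=True)
class PipelineConfig:
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    tissue_mask: TissueMaskParams = field(default_factory=TissueMaskParams)
    transfer: TransferConfig = field(default_factory=TransferConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    simulate: PhantomParams = field(default_factory=PhantomParams)
    seed: int = 0
    out_dir: str = "."
    verbosity: str = "info"

    def pipeline_params(self) -> PipelineParams:
        """Collapse the config into the parameter object ``run_pipeline`` takes."""
        return PipelineParams(
            diff_threshold=self.extraction.diff_threshold,
            closing_radius=self.extraction.closing_radius,
            tissue=self.tissue_mask,
            erosion_size=self.transfer.erosion_size,
            overlay_color=tuple(self.transfer.overlay_color),
            overlay_thickness=self.transfer.overlay_thickness,
            normalization=self.registration.normalization,
            condition_cap=self.registration.condition_cap,
        )


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or 'root'!r} must be a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} in section {path or 'root'!r}"
        )
    kwargs = {}
    for name, val in data.items():
        f = known[name]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.default_factory, type) and dataclasses.is_dataclass(f.default_factory)
        ):
            kwargs[name] = _build(f.default_factory, val, f"{path}.{name}".lstrip("."))
        elif isinstance(val, list):
            kwargs[name] = tuple(val)
        else:
            kwargs[name] = val
    return cls(**kwargs)


def load_config(path_or_dict) -> PipelineConfig:
    """Parse a YAML file (or pre-parsed mapping) into a validated config."""
    if isinstance(path_or_dict, dict):
        data = path_or_dict
    else:
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh) or {}
    return _build(PipelineConfig, data, "")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def dump_config(config: PipelineConfig, path=None) -> str:
    """Serialize a config to YAML; parsing it back yields an equal config."""
    text = yaml.safe_dump(_to_plain(config), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
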