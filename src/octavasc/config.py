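"""Study configuration: a strict, file-round-trippable parameter bundle."""

from __future__ import annotations

import dataclasses
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .phantom import (
    CLASS_LABELS,
    TIMEPOINTS,
    DilationScenario,
    PhantomSpec,
    high_intensity_scenario,
    low_intensity_scenario,
    sham_scenario,
)
from .vessel_seg import SegmentationParams

__all__ = ["StudyConfig", "load_config", "save_config", "scenario_by_name"]


def scenario_by_name(name: str, n_animals: int | None = None) -> DilationScenario:
    makers = {
        "sham": sham_scenario,
        "low": low_intensity_scenario,
        "high": high_intensity_scenario,
    }
    if name not in makers:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(makers)}")
    return makers[name]() if n_animals is None else makers[name](n_animals)


def _strict_build(cls, data: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {name} key(s): {sorted(unknown)}")
    kwargs = dict(data)
    # YAML turns tuples into lists; restore tuple-typed fields
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


@dataclass
class StudyConfig:
    """Everything needed to reproduce one simulated study end to end."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    scenario: str = "low"
    n_animals: int = 10
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    n_repeats: int = 4
    m_bands: int = 4
    band_overlap: float = 0.5
    tracking_tol_um: float = 5.0
    depth_range_um: tuple[float, float] = (0.0, 400.0)
    depth_bin_um: float = 50.0
    seed: int = 0
    output_dir: str = "study_out"

    def build_scenario(self) -> DilationScenario:
        return scenario_by_name(self.scenario, self.n_animals)

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, tuple):
                return [listify(v) for v in obj]
            if isinstance(obj, list):
                return [listify(v) for v in obj]
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            return obj

        return listify(asdict(self))

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data)
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "phantom" in data and isinstance(data["phantom"], dict):
            ph = dict(data["phantom"])
            if "domain_size_um" in ph and isinstance(ph["domain_size_um"], list):
                ph["domain_size_um"] = tuple(ph["domain_size_um"])
            if "depth_profile" in ph:
                ph["depth_profile"] = {
                    k: (v[0], tuple(v[1])) for k, v in ph["depth_profile"].items()
                }
            data["phantom"] = _strict_build(PhantomSpec, ph, "phantom")
        if "segmentation" in data and isinstance(data["segmentation"], dict):
            data["segmentation"] = _strict_build(
                SegmentationParams, data["segmentation"], "segmentation"
            )
        if "depth_range_um" in data and isinstance(data["depth_range_um"], list):
            data["depth_range_um"] = tuple(data["depth_range_um"])
        return cls(**data)


def save_config(config: StudyConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path: str | Path) -> StudyConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return StudyConfig.from_dict(data)
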