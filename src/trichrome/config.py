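"""Pipeline configuration: a single YAML file with one section per stage.

Unknown keys are rejected so typos surface immediately; every run writes
the fully resolved configuration next to its outputs together with a
JSON-lines provenance log (package version, seed, parameter hash).
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .core import InvalidParameterError

__all__ = ["PipelineConfig", "load_config", "write_provenance"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Section):
    shape: tuple[int, int] = (900, 900)
    n_per_population: tuple[int, int, int] = (12, 12, 12)
    curvature: float = 0.1
    width_px: float = 3.0
    overlap_fraction: float = 0.0
    block_px: int = 30
    read_noise_sd: float = 0.0
    gain: float = 0.0
    bead_n: int = 1012
    bead_fov_um: float = 500.0


class PreprocessConfig(_Section):
    crop_margin_px: int = 0
    blur_sigma_px: Optional[float] = None
    search_radius_px: int = 10
    score_threshold: float = 0.3
    blend: Literal["feather", "max", "overwrite"] = "feather"


class UnmixConfig(_Section):
    mode: Literal["max_roi", "barycentre"] = "max_roi"
    negatives: Literal["clip", "keep"] = "clip"


class ChromaticConfig(_Section):
    axial_degree: int = 2
    reject_outliers: bool = False
    fov_um: float = 500.0
    grid_step_um: float = 5.0
    effective_subfield_um: float = 350.0
    threshold_um: float = 0.6


class ProjectConfig(_Section):
    block_px: int = 30
    n_classes: int = 3
    min_component_px: int = 4
    exclusive: bool = True
    enhance: bool = False


class InterfaceConfig(_Section):
    degree: int = 1
    grid_step_um: float = 0.5


class MorphometryConfig(_Section):
    max_cluster_size_for_layers: int = 3
    exclude_pial: bool = True


class PipelineConfig(_Section):
    seed: int = 0
    output_dir: str = "trichrome_out"
    simulate: SimulateConfig = SimulateConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    unmix: UnmixConfig = UnmixConfig()
    chromatic: ChromaticConfig = ChromaticConfig()
    project: ProjectConfig = ProjectConfig()
    interface: InterfaceConfig = InterfaceConfig()
    morphometry: MorphometryConfig = MorphometryConfig()


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML/JSON config; ``None`` gives the defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        raise InvalidParameterError(f"invalid configuration: {exc}") from exc


def _parameter_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_provenance(
    config: PipelineConfig, out_dir: str | Path, stage: str, **extra
) -> Path:
    """Write the resolved config and append a provenance record.

    The record (JSON lines, ``provenance.jsonl``) includes the package
    version, seed, stage name, and a hash of the full parameter set.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "resolved_config.json").write_text(
        json.dumps(config.model_dump(mode="json"), indent=2) + "\n"
    )
    record = {
        "stage": stage,
        "version": __version__,
        "seed": config.seed,
        "parameter_hash": _parameter_hash(config),
        "python": platform.python_version(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        **extra,
    }
    log_path = out_dir / "provenance.jsonl"
    with log_path.open("a") as fh:
        fh.write(json.dumps(record, sort_keys=True) + "\n")
    return log_path
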