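"""Shared pipeline configuration and the SfM parameter file emitter.

The dense-reconstruction step itself (VisualSFM + CMVS/PMVS2) is external
to this package, but the parameter set that makes it work on small-leaved
plants is part of the workflow: :func:`emit_sfm_config` writes those five
PMVS/CMVS options as a key=value file for users running the external tools.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cleaning import CleaningParams
from .meshing import MeshingParams

__all__ = [
    "PipelineConfig",
    "SFM_PARAMS",
    "emit_sfm_config",
    "parse_sfm_config",
]

# CMVS/PMVS2 settings tuned for dense reconstruction of small-leaved plants:
# analyse the whole image set at once, require each point in >= 4 images,
# halve the cell size for a denser cloud, widen the photometric window and
# relax the consistency threshold.
SFM_PARAMS: dict[str, float | int] = {
    "max_images": 120,
    "min_images": 4,
    "csize": 1,
    "wsize": 12,
    "threshold": 0.45,
}

_SFM_COMMENTS = {
    "max_images": "CMVS: images clustered per reconstruction batch",
    "min_images": "PMVS2: minimum images a 3D point must be visible in",
    "csize": "PMVS2: cell size; smaller gives a denser point cloud",
    "wsize": "PMVS2: photometric consistency window size, px",
    "threshold": "PMVS2: photometric consistency acceptance threshold",
}


def emit_sfm_config(path: str | Path, overrides: dict | None = None) -> None:
    """Write the SfM option file (key=value with explanatory comments)."""
    params = dict(SFM_PARAMS)
    if overrides:
        unknown = set(overrides) - set(params)
        if unknown:
            raise KeyError(f"unknown SfM parameters: {sorted(unknown)}")
        params.update(overrides)
    lines = ["# CMVS/PMVS2 parameters for single-plant reconstruction"]
    for key, value in params.items():
        lines.append(f"# {_SFM_COMMENTS[key]}")
        lines.append(f"{key}={value}")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_sfm_config(path: str | Path) -> dict[str, float]:
    """Parse a key=value option file written by :func:`emit_sfm_config`."""
    params: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        num = float(value)
        params[key.strip()] = int(num) if num == int(num) else num
    return params


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, serializable to YAML."""

    cleaning: CleaningParams = field(default_factory=CleaningParams)
    meshing: MeshingParams = field(default_factory=MeshingParams)
    plant_id: str = "plant"
    timepoint: float = 0.0
    projection_resolution_mm_per_px: float = 0.25
    bin_width_mm: float = 1.0
    measured_reference_length: float | None = None  # in raw model units
    orient_to_ground: bool = True
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cleaning = data.pop("cleaning", {}) or {}
        meshing = data.pop("meshing", {}) or {}
        for key in ("hue_range_deg", "crop_min", "crop_max"):
            if cleaning.get(key) is not None:
                cleaning[key] = tuple(cleaning[key])
        if meshing.get("ball_radii") is not None:
            meshing["ball_radii"] = tuple(meshing["ball_radii"])
        return cls(
            cleaning=CleaningParams(**cleaning),
            meshing=MeshingParams(**meshing),
            **data,
        )
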