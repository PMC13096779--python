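"""Volume, table and configuration IO.

Volumes travel as multi-page TIFF (one page per z-slice) with an
authoritative JSON sidecar (``<name>.json``) carrying voxel size,
timestamp and frame index; TIFF ImageJ resolution metadata is written too
and used as a fallback when the sidecar is missing, since z-spacing
conventions inside TIFF alone are unreliable.  Frames are named
``t{frame:04d}.tif``.

The run configuration is a YAML mapping with sections mirroring the model
dataclasses (``growth``, ``imaging``, ``tracking``, ``phantom``,
``postreg``) plus ``seed`` and ``out_dir``; unknown keys are rejected by
name and every invariant is validated on load.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import ConfigError, InvalidMetadataError
from .looptrack import TrackingConfig
from .phantom import GrowthModel, ImagingModel
from .regcore import VolumeImage

__all__ = [
    "RunConfig",
    "PhantomInit",
    "PostregOptions",
    "read_volume",
    "write_volume",
    "load_config",
    "frame_path",
    "frame_index_from_name",
]

logger = logging.getLogger(__name__)

_FRAME_RE = re.compile(r"t(\d+)\.tiff?$")

_SUPPORTED_DTYPES = ("uint8", "uint16", "float32", "float64")


def frame_path(out_dir: Path, frame: int) -> Path:
    return Path(out_dir) / f"t{frame:04d}.tif"


def frame_index_from_name(path) -> int | None:
    """Parse ``t0007.tif`` → 7; None if the name does not match."""
    m = _FRAME_RE.search(Path(path).name)
    return int(m.group(1)) if m else None


def write_volume(v: VolumeImage, path) -> None:
    """Write a volume as multi-page TIFF plus JSON sidecar (lossless)."""
    path = Path(path)
    data = v.data
    if data.dtype.name not in _SUPPORTED_DTYPES:
        data = data.astype(np.float32) if data.dtype.kind == "f" else data
    vz, vy, vx = (float(s) for s in v.voxel_size)
    tifffile.imwrite(
        path,
        data,
        imagej=data.dtype.name in ("uint8", "uint16", "float32"),
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"spacing": vz, "unit": "um", "axes": "ZYX"},
    )
    sidecar = {
        "voxel_size_um": [vz, vy, vx],
        "timestamp_min": float(v.timestamp),
        "frame_index": int(v.frame_index),
        "dtype": data.dtype.name,
        "shape": list(data.shape),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def _voxel_size_from_tags(tif: tifffile.TiffFile) -> list[float] | None:
    try:
        page = tif.pages[0]
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        vx = xres[1] / xres[0]
        vy = yres[1] / yres[0]
        vz = None
        if tif.imagej_metadata and "spacing" in tif.imagej_metadata:
            vz = float(tif.imagej_metadata["spacing"])
        if vz is None:
            return None
        return [vz, float(vy), float(vx)]
    except (KeyError, ZeroDivisionError, IndexError):
        return None


def read_volume(path) -> VolumeImage:
    """Read a TIFF volume; voxel size from sidecar, else resolution tags.

    Raises
    ------
    InvalidMetadataError
        If no voxel size can be recovered, naming the file.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        tag_voxel = _voxel_size_from_tags(tif)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    timestamp = 0.0
    frame_index = frame_index_from_name(path)
    voxel = None
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        voxel = meta.get("voxel_size_um")
        timestamp = float(meta.get("timestamp_min", 0.0))
        if "frame_index" in meta:
            frame_index = int(meta["frame_index"])
    if voxel is None:
        voxel = tag_voxel
    if voxel is None:
        raise InvalidMetadataError(
            f"no voxel size for {path}: sidecar {sidecar_path.name} missing and "
            "TIFF resolution tags incomplete"
        )
    return VolumeImage(
        data=data,
        voxel_size=np.asarray(voxel, dtype=float),
        timestamp=timestamp,
        frame_index=frame_index if frame_index is not None else 0,
    )


@dataclass(frozen=True)
class PhantomInit:
    """Initial-tissue parameters: nucleus count and seeding box (µm)."""

    n_nuclei: int = 150
    extent: tuple[float, float, float] = (40.0, 60.0, 60.0)
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_nuclei < 1:
            raise ConfigError("phantom.n_nuclei must be >= 1")
        if len(self.extent) != 3 or any(e <= 0 for e in self.extent):
            raise ConfigError("phantom.extent components must be > 0")
        object.__setattr__(self, "extent", tuple(float(e) for e in self.extent))
        object.__setattr__(
            self, "axis_direction", tuple(float(a) for a in self.axis_direction)
        )


@dataclass(frozen=True)
class PostregOptions:
    """Post-processing options: target voxel, fallback floor, grid budget."""

    target_um: float = 1.0
    confidence_floor: float = 0.03
    voxel_budget: int = 2**28

    def __post_init__(self) -> None:
        if self.target_um <= 0:
            raise ConfigError("postreg.target_um must be > 0")
        if not 0.0 <= self.confidence_floor <= 1.0:
            raise ConfigError("postreg.confidence_floor must lie in [0, 1]")
        if self.voxel_budget < 1:
            raise ConfigError("postreg.voxel_budget must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Fully validated run configuration with documented defaults."""

    growth: GrowthModel = field(default_factory=GrowthModel)
    imaging: ImagingModel = field(default_factory=ImagingModel)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    phantom: PhantomInit = field(default_factory=PhantomInit)
    postreg: PostregOptions = field(default_factory=PostregOptions)
    seed: int = 0
    out_dir: str = "."

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=lambda o: list(o)))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


_SECTIONS = {
    "growth": GrowthModel,
    "imaging": ImagingModel,
    "tracking": TrackingConfig,
    "phantom": PhantomInit,
    "postreg": PostregOptions,
}
_SCALARS = {"seed": int, "out_dir": str}

_TUPLE_FIELDS = {
    "voxel_size", "fov_shape", "psf_sigma", "extent", "axis_direction",
    "max_correction",
}


def _build_section(name: str, cls, mapping: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(
            f"unknown key '{name}.{sorted(unknown)[0]}' in configuration"
        )
    kwargs = {}
    for key, value in mapping.items():
        if key in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (ConfigError, ValueError) as exc:
        raise ConfigError(f"invalid value in section '{name}': {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields all defaults; unknown keys are rejected naming the
    offending key; every sub-config invariant is enforced.  The effective
    configuration (defaults filled in) is echoed to the run log, including
    the resulting registration period in minutes.
    """
    raw = yaml.safe_load(Path(path).read_text()) if Path(path).exists() else None
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - set(_SECTIONS) - set(_SCALARS)
    if unknown:
        raise ConfigError(f"unknown key '{sorted(unknown)[0]}' in configuration")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        if section is None:
            section = {}
        if not isinstance(section, dict):
            raise ConfigError(f"section '{name}' must be a mapping")
        kwargs[name] = _build_section(name, cls, section)
    for name, caster in _SCALARS.items():
        if name in raw:
            kwargs[name] = caster(raw[name])
    cfg = RunConfig(**kwargs)
    logger.info(
        "effective configuration (hash %s):\n%s",
        cfg.config_hash(),
        yaml.safe_dump(cfg.to_dict(), sort_keys=False),
    )
    logger.info(
        "registration period: %.1f min (frame_interval %.1f min × stride %d)",
        cfg.tracking.registration_period_min,
        cfg.tracking.frame_interval,
        cfg.tracking.registration_stride,
    )
    return cfg


def write_provenance(out_dir, command: str, cfg: RunConfig, seed: int) -> None:
    """Write a provenance record (config hash, seed, versions) for a run."""
    import scipy

    from . import __version__

    record = {
        "command": command,
        "config_hash": cfg.config_hash(),
        "seed": int(seed),
        "versions": {
            "tailtrack": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "tifffile": tifffile.__version__,
        },
    }
    Path(out_dir, "provenance.json").write_text(json.dumps(record, indent=1))
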