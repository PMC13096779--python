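"""Online tracking: closed-loop stage feedback from image registration.

A virtual acquisition loop images the phantom every ``frame_interval``
minutes.  At every ``registration_stride``-th frame it phase-correlates the
current as-acquired volume against the volume acquired ``stride`` frames
earlier, converts the estimated sample drift into a stage move, and applies
it before the next frame, re-centring the growing tissue in the field of
view.  With the defaults (2-minute framing, stride 5) registration events
are spaced 10 minutes apart.

Because the reference volume may have been acquired at a different stage
position than the current one, the apparent image shift is the sample drift
*minus* the intervening stage motion; the controller adds back its own
known stage delta so the commanded move equals the estimated sample drift.
Without that term a constant drift is only half-compensated and the sample
is eventually lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidArgumentError
from .phantom import (
    GrowthModel,
    ImagingModel,
    StageState,
    TissueState,
    derive_seed,
    init_tissue,
    render_volume,
    step_tissue,
    tissue_centroid,
    _CAMERA_STREAM,
    _TISSUE_STREAM,
)
from .regcore import ShiftVector, VolumeImage, estimate_shift

__all__ = [
    "TrackingConfig",
    "SessionLog",
    "ClosedLoopResult",
    "StageState",
    "world_to_fov",
    "fov_to_world",
    "should_register",
    "compute_correction",
    "run_closed_loop",
    "centroid_diagnostics",
]

logger = logging.getLogger(__name__)

SESSION_COLUMNS = [
    "frame", "time_min",
    "stage_z", "stage_y", "stage_x",
    "shift_z", "shift_y", "shift_x", "conf",
    "corr_z", "corr_y", "corr_x",
    "cen_z", "cen_y", "cen_x",
    "in_fov",
]


@dataclass(frozen=True)
class TrackingConfig:
    """Parameters of the online tracking loop.

    frame_interval : minutes between acquired frames (default 2).
    registration_stride : frames between registration events, giving one
        event every ``frame_interval * stride`` minutes; the default 5
        yields the 10-minute registration cadence at 2-minute framing.
    gain : fraction of the estimated drift fed back to the stage; 1 means
        full re-centring, 0 disables correction (open loop).
    margin : µm — the tissue centroid must stay at least this far from
        every FOV face for the frame to count as "in FOV".
    max_correction : µm per axis per event; a wildly wrong correlation peak
        must not throw the sample out of the FOV in a single move.  None
        resolves to a quarter of the FOV extent per axis.
    pre_downsample : integer block-mean factor applied to volumes before
        registration (1 = register at full resolution).
    latency_frames : actuation delay — a computed correction is applied
        this many frames after its registration event (default 0:
        instantaneous, applied before the next frame).
    """

    frame_interval: float = 2.0
    registration_stride: int = 5
    gain: float = 1.0
    margin: float = 5.0
    max_correction: tuple[float, float, float] | None = None
    pre_downsample: int = 1
    latency_frames: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise InvalidArgumentError("frame_interval must be > 0")
        if self.registration_stride < 1:
            raise InvalidArgumentError("registration_stride must be >= 1")
        if not 0.0 <= self.gain <= 1.0:
            raise InvalidArgumentError("gain must lie in [0, 1]")
        if self.margin < 0:
            raise InvalidArgumentError("margin must be >= 0")
        if self.max_correction is not None:
            mc = tuple(float(v) for v in np.atleast_1d(self.max_correction))
            if len(mc) == 1:
                mc = mc * 3
            if len(mc) != 3 or any(v <= 0 for v in mc):
                raise InvalidArgumentError("max_correction must be > 0 per axis")
            object.__setattr__(self, "max_correction", mc)
        if self.pre_downsample < 1:
            raise InvalidArgumentError("pre_downsample must be >= 1")
        if self.latency_frames < 0:
            raise InvalidArgumentError("latency_frames must be >= 0")

    def resolved_max_correction(self, imaging: ImagingModel) -> np.ndarray:
        """Per-axis correction clamp, µm (default: quarter FOV extent)."""
        if self.max_correction is not None:
            return np.asarray(self.max_correction, dtype=float)
        return imaging.fov_extent_um / 4.0

    @property
    def registration_period_min(self) -> float:
        return self.frame_interval * self.registration_stride


@dataclass
class SessionLog:
    """Per-frame audit trail of a tracking run.

    One record per acquired frame; shift/correction fields are filled only
    at registration events (frames where ``frame % stride == 0, frame >
    0``).  Serializes to/from the session CSV schema in
    :data:`SESSION_COLUMNS`.
    """

    records: list[dict] = field(default_factory=list)

    def append(self, record: dict) -> None:
        if self.records and record["frame"] != self.records[-1]["frame"] + 1:
            raise InvalidArgumentError("session records must be consecutive in frame")
        self.records.append(record)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records, columns=SESSION_COLUMNS)
        df["in_fov"] = df["in_fov"].astype(int)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.3f")

    @classmethod
    def from_csv(cls, path) -> "SessionLog":
        df = pd.read_csv(path)
        missing = [c for c in SESSION_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidArgumentError(f"session CSV missing columns: {missing}")
        log = cls()
        for rec in df.to_dict("records"):
            log.records.append(rec)
        return log

    def stage_offsets(self) -> np.ndarray:
        """(n, 3) stage offsets at acquisition time, µm."""
        return np.array(
            [[r["stage_z"], r["stage_y"], r["stage_x"]] for r in self.records]
        )


@dataclass
class ClosedLoopResult:
    """Everything a tracking run produces: log, truth states, frames."""

    log: SessionLog
    states: list[TissueState]
    volumes: list[VolumeImage] | None = None


def world_to_fov(
    position: np.ndarray, stage: StageState, imaging: ImagingModel
) -> np.ndarray:
    """World µm → fractional FOV voxel coordinates (no clipping)."""
    return (np.asarray(position, dtype=float) - stage.offset) / np.asarray(
        imaging.voxel_size
    )


def fov_to_world(
    voxels: np.ndarray, stage: StageState, imaging: ImagingModel
) -> np.ndarray:
    """Inverse of :func:`world_to_fov`."""
    return np.asarray(voxels, dtype=float) * np.asarray(imaging.voxel_size) + stage.offset


def should_register(frame_index: int, config: TrackingConfig) -> bool:
    """True at frames {stride, 2·stride, ...} — never at frame 0."""
    if frame_index < 0:
        raise InvalidArgumentError("frame_index must be >= 0")
    return frame_index > 0 and frame_index % config.registration_stride == 0


def compute_correction(
    shift: ShiftVector,
    config: TrackingConfig,
    imaging: ImagingModel | None = None,
) -> tuple[np.ndarray, bool]:
    """Stage move (µm) for an estimated sample drift, with clamp flag.

    The stage follows the sample: a sample drift of ``+s`` µm commands a
    move of ``+gain·s`` µm so the sample returns to its former FOV
    position.  Each component is clamped to ``±max_correction``; the
    returned flag reports whether clamping occurred.
    """
    drift = np.asarray(shift.micrometres, dtype=float)
    if not np.all(np.isfinite(drift)):
        raise InvalidArgumentError(f"non-finite shift {drift}")
    if config.max_correction is None and imaging is None:
        raise InvalidArgumentError(
            "imaging model required to resolve the default max_correction"
        )
    limit = config.resolved_max_correction(imaging) if imaging is not None else np.asarray(
        config.max_correction, dtype=float
    )
    move = config.gain * drift
    clamped = bool(np.any(np.abs(move) > limit))
    return np.clip(move, -limit, limit), clamped


def _block_mean(data: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return data
    trimmed = data[
        : data.shape[0] // factor * factor,
        : data.shape[1] // factor * factor,
        : data.shape[2] // factor * factor,
    ]
    return trimmed.reshape(
        trimmed.shape[0] // factor, factor,
        trimmed.shape[1] // factor, factor,
        trimmed.shape[2] // factor, factor,
    ).mean(axis=(1, 3, 5))


def _centroid_in_fov(
    centroid: np.ndarray, stage: StageState, imaging: ImagingModel, margin: float
) -> bool:
    local = centroid - stage.offset
    extent = imaging.fov_extent_um
    return bool(np.all(local >= margin) and np.all(extent - local >= margin))


def run_closed_loop(
    model: GrowthModel,
    imaging: ImagingModel,
    config: TrackingConfig,
    n_frames: int,
    seed: int,
    n_nuclei: int = 150,
    extent: tuple[float, float, float] = (40.0, 60.0, 60.0),
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0),
    dynamics=None,
    keep_volumes: bool = False,
    frame_sink=None,
) -> ClosedLoopResult:
    """Run the virtual acquisition loop for ``n_frames`` frames.

    Per frame: advance the tissue (``dynamics(state, frame, seed)``,
    defaulting to :func:`~tailtrack.phantom.step_tissue`), render the
    as-acquired volume at the current stage position, and log the
    ground-truth centroid and its in-FOV status.  At registration events
    the drift since the previous event's frame is estimated on the
    as-acquired volumes (Hann-windowed, subpixel), converted to a stage
    move via :func:`compute_correction`, and applied before the next frame
    (or after ``latency_frames`` frames).

    The initial stage position centres the frame-0 tissue centroid in the
    FOV.  Degenerate registration (constant frames) logs a warning and
    applies zero correction.  ``frame_sink(frame_index, volume)`` is called
    for every acquired volume when given (used by the CLI to write TIFFs).
    Deterministic given ``seed``.
    """
    if n_frames < config.registration_stride + 1:
        raise InvalidArgumentError(
            f"n_frames must be >= registration_stride + 1 "
            f"= {config.registration_stride + 1}, got {n_frames}"
        )
    if dynamics is None:
        dynamics = lambda state, frame, master: step_tissue(
            state, model, derive_seed(master, frame, _TISSUE_STREAM)
        )

    state = init_tissue(
        model, n_nuclei, extent, derive_seed(seed, 0, _TISSUE_STREAM), axis_direction
    )
    stage = StageState(offset=tissue_centroid(state) - imaging.fov_extent_um / 2.0)
    max_corr = config.resolved_max_correction(imaging)
    cfg = config if config.max_correction is not None else TrackingConfig(
        frame_interval=config.frame_interval,
        registration_stride=config.registration_stride,
        gain=config.gain,
        margin=config.margin,
        max_correction=tuple(max_corr),
        pre_downsample=config.pre_downsample,
        latency_frames=config.latency_frames,
    )

    log = SessionLog()
    states: list[TissueState] = []
    volumes: list[VolumeImage] | None = [] if keep_volumes else None
    reference: tuple[VolumeImage, np.ndarray] | None = None  # (volume, stage offset)
    pending: list[tuple[int, np.ndarray]] = []  # (apply-before-frame, move)

    for i in range(n_frames):
        if i > 0:
            state = dynamics(state, i, seed)
        # apply corrections scheduled for before this frame (summed if several)
        due_now = [mv for due, mv in pending if due <= i]
        if due_now:
            pending = [(due, mv) for due, mv in pending if due > i]
            stage.move(max(i - 1, 0), np.sum(due_now, axis=0))

        offset_at_acq = stage.offset.copy()
        vol = render_volume(state, imaging, stage, derive_seed(seed, i, _CAMERA_STREAM))
        vol = VolumeImage(vol.data, vol.voxel_size, i * config.frame_interval, i)
        if volumes is not None:
            volumes.append(vol)
        if frame_sink is not None:
            frame_sink(i, vol)

        shift_um = (np.nan, np.nan, np.nan)
        conf = np.nan
        corr = (np.nan, np.nan, np.nan)
        if should_register(i, cfg):
            ref_vol, ref_offset = reference
            try:
                a, b = ref_vol, vol
                if cfg.pre_downsample > 1:
                    f = cfg.pre_downsample
                    a = VolumeImage(_block_mean(a.data, f), a.voxel_size * f)
                    b = VolumeImage(_block_mean(b.data, f), b.voxel_size * f)
                sv = estimate_shift(a, b, window=True, subpixel=True)
                # apparent shift + known stage motion = sample drift
                drift_um = sv.micrometres + (offset_at_acq - ref_offset)
                drift_sv = ShiftVector(
                    voxels=drift_um / np.asarray(imaging.voxel_size),
                    micrometres=drift_um,
                    confidence=sv.confidence,
                )
                move, clamped = compute_correction(drift_sv, cfg, imaging)
                if clamped:
                    logger.warning(
                        "frame %d: correction clamped to %s µm", i, np.round(move, 3)
                    )
                shift_um = tuple(drift_um)
                conf = sv.confidence
            except DegenerateInputError as exc:
                logger.warning("frame %d: degenerate registration (%s)", i, exc)
                move = np.zeros(3)
            corr = tuple(move)
            pending.append((i + 1 + cfg.latency_frames, move))

        if i % cfg.registration_stride == 0:
            reference = (vol, offset_at_acq)

        centroid = tissue_centroid(state)
        log.append(
            {
                "frame": i,
                "time_min": i * cfg.frame_interval,
                "stage_z": offset_at_acq[0],
                "stage_y": offset_at_acq[1],
                "stage_x": offset_at_acq[2],
                "shift_z": shift_um[0], "shift_y": shift_um[1], "shift_x": shift_um[2],
                "conf": conf,
                "corr_z": corr[0], "corr_y": corr[1], "corr_x": corr[2],
                "cen_z": centroid[0], "cen_y": centroid[1], "cen_x": centroid[2],
                "in_fov": _centroid_in_fov(centroid, StageState(offset_at_acq), imaging, cfg.margin),
            }
        )
        states.append(state)

    return ClosedLoopResult(log=log, states=states, volumes=volumes)


def centroid_diagnostics(
    log: SessionLog, imaging: ImagingModel
) -> pd.DataFrame:
    """Per-frame centroid diagnostics of a tracking session.

    Returns a table with the centroid in FOV-voxel coordinates, its
    distance (µm) to the nearest FOV face per axis, and the cumulative
    stage path length; ``df.attrs`` carries ``in_fov_fraction`` and
    ``net_stage_displacement_um``.
    """
    if not log.records:
        raise InvalidArgumentError("session log is empty")
    df = log.to_dataframe()
    stage = df[["stage_z", "stage_y", "stage_x"]].to_numpy()
    cen = df[["cen_z", "cen_y", "cen_x"]].to_numpy()
    voxel = np.asarray(imaging.voxel_size)
    extent = imaging.fov_extent_um
    local = cen - stage
    fov_vox = local / voxel
    face_dist = np.minimum(local, extent - local)
    steps = np.linalg.norm(np.diff(stage, axis=0), axis=1)
    cum_path = np.concatenate([[0.0], np.cumsum(steps)])
    out = pd.DataFrame(
        {
            "frame": df["frame"],
            "cen_vox_z": fov_vox[:, 0],
            "cen_vox_y": fov_vox[:, 1],
            "cen_vox_x": fov_vox[:, 2],
            "face_dist_z": face_dist[:, 0],
            "face_dist_y": face_dist[:, 1],
            "face_dist_x": face_dist[:, 2],
            "cum_stage_path_um": cum_path,
            "in_fov": df["in_fov"],
        }
    )
    out.attrs["in_fov_fraction"] = float(df["in_fov"].mean())
    out.attrs["net_stage_displacement_um"] = float(
        np.linalg.norm(stage[-1] - stage[0])
    )
    return out
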