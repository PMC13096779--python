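"""Post-acquisition processing: isotropic downscaling and global registration.

After an online tracking run the saved timepoints live on an anisotropic
grid and jump whenever the stage moved.  This module (1) resamples each
volume so a voxel represents 1 µm³, (2) registers consecutive timepoints
with the same phase-correlation estimator used online and accumulates the
pairwise shifts into per-frame cumulative shifts relative to frame 0, and
(3) resamples every frame onto one common global grid, removing the
visible stage movements and residual sample drift.

Registration runs on the isotropic grid, so voxel shifts equal micrometre
shifts.  Shifts are accumulated along the chain of consecutive pairs (no
loop closure; a time series is a single chain).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage

from .errors import InvalidArgumentError, ResourceLimitError
from .looptrack import SessionLog
from .regcore import VolumeImage, estimate_shift

__all__ = [
    "RegisteredSeries",
    "downscale_isotropic",
    "register_series",
    "resample_to_global",
    "stabilization_report",
]

logger = logging.getLogger(__name__)

#: pairwise estimates with confidence below this fall back to the stage-log
#: offset (or zero); chosen to trip only on flat/degenerate surfaces
DEFAULT_CONFIDENCE_FLOOR = 0.03

#: refuse to allocate a global grid larger than this many voxels per volume
DEFAULT_VOXEL_BUDGET = 2**28

SHIFT_COLUMNS = ["frame", "cum_z_um", "cum_y_um", "cum_x_um", "conf", "fallback"]


@dataclass
class RegisteredSeries:
    """A 4D series on one common isotropic global grid.

    ``cumulative_shifts_um[k]`` is the content displacement of frame *k*
    relative to frame 0 (frame 0 is zero by definition);
    ``global_origin_um`` locates the global grid origin in frame-0 grid
    coordinates (µm, possibly negative when later frames extend below it);
    ``provenance`` records per frame the source and the applied transform.
    """

    volumes: list[VolumeImage]
    cumulative_shifts_um: np.ndarray
    global_origin_um: np.ndarray
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.cumulative_shifts_um):
            raise InvalidArgumentError("one cumulative shift per frame is required")
        if len(self.volumes) and np.any(self.cumulative_shifts_um[0] != 0):
            raise InvalidArgumentError("frame 0 cumulative shift must be zero")


def _resample_matrix_1d(n_in: int, voxel: float, target: float) -> np.ndarray:
    """(n_out, n_in) weights resampling one axis from ``voxel`` to ``target``.

    Voxel centres sit at integer grid coordinates; input cell *i* spans
    ``[(i-0.5)·voxel, (i+0.5)·voxel]`` µm.  When ``target >= voxel`` each
    output cell averages the input cells it overlaps, weighted by overlap
    length and normalized over the actual support (so edge/partial blocks
    average over what exists).  When ``target < voxel`` the axis is
    upsampled by linear interpolation at the output cell centres (clamped
    at the ends).
    """
    n_out = int(np.ceil(n_in * voxel / target))
    W = np.zeros((n_out, n_in))
    if target >= voxel:
        for j in range(n_out):
            lo, hi = (j - 0.5) * target, (j + 0.5) * target
            i0 = max(int(np.floor(lo / voxel + 0.5)), 0)
            i1 = min(int(np.ceil(hi / voxel - 0.5)), n_in - 1)
            for i in range(i0, i1 + 1):
                overlap = min(hi, (i + 0.5) * voxel) - max(lo, (i - 0.5) * voxel)
                if overlap > 0:
                    W[j, i] = overlap
            total = W[j].sum()
            if total > 0:
                W[j] /= total
    else:
        for j in range(n_out):
            x = np.clip(j * target / voxel, 0.0, n_in - 1.0)
            i0 = int(np.floor(x))
            frac = x - i0
            W[j, i0] += 1.0 - frac
            if frac > 0:
                W[j, i0 + 1] += frac
    return W


def downscale_isotropic(v: VolumeImage, target: float = 1.0) -> VolumeImage:
    """Resample a volume to isotropic ``target`` µm voxels.

    Axes coarser than ``target`` are linearly interpolated up; axes finer
    than ``target`` are anti-aliased by area (block) averaging, with the
    last partial block averaged over its actual support.  The output grid
    covers the same physical extent (to within one target voxel per axis)
    and preserves the mean intensity of interior regions.
    """
    if target <= 0:
        raise InvalidArgumentError(f"target voxel size must be > 0, got {target}")
    voxel = np.asarray(v.voxel_size, dtype=float)
    if voxel.shape != (3,) or np.any(~np.isfinite(voxel)) or np.any(voxel <= 0):
        raise InvalidArgumentError(f"volume lacks a valid voxel size: {voxel}")
    data = v.data.astype(float)
    for axis in range(3):
        W = _resample_matrix_1d(data.shape[axis], voxel[axis], target)
        data = np.moveaxis(np.tensordot(W, data, axes=([1], [axis])), 0, axis)
    return VolumeImage(
        data=data,
        voxel_size=np.full(3, float(target)),
        timestamp=v.timestamp,
        frame_index=v.frame_index,
    )


def register_series(
    frames: list[VolumeImage],
    stage_log: SessionLog | None = None,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
    window: bool = True,
) -> pd.DataFrame:
    """Sequential registration of a time series into cumulative shifts.

    Phase-correlates every consecutive pair and prefix-sums the pairwise
    shifts; frame 0 is defined as shift zero.  When a ``stage_log`` is
    given, the known stage delta between the two acquisitions initializes
    each pairwise estimate (the moving frame is pre-rolled by the rounded
    stage jump before correlation), which keeps large tracking jumps inside
    the correlation search range.  Pairs whose confidence falls below
    ``confidence_floor`` fall back to the stage-log offset alone (or zero
    without a log) and are flagged.

    Returns a table with columns ``frame, cum_z_um, cum_y_um, cum_x_um,
    conf, fallback`` (``conf`` is NaN for frame 0).
    """
    if len(frames) < 2:
        raise InvalidArgumentError(f"need >= 2 frames, got {len(frames)}")
    shape = frames[0].shape
    for f in frames[1:]:
        if f.shape != shape:
            raise InvalidArgumentError(
                f"all frames must share one shape, got {shape} and {f.shape}"
            )
    offsets = None
    if stage_log is not None:
        offsets = stage_log.stage_offsets()
        if len(offsets) != len(frames):
            raise InvalidArgumentError(
                f"stage log has {len(offsets)} frames, series has {len(frames)}"
            )

    voxel = np.asarray(frames[0].voxel_size, dtype=float)
    rows = [(frames[0].frame_index, 0.0, 0.0, 0.0, np.nan, False)]
    cum = np.zeros(3)
    for k in range(1, len(frames)):
        a, b = frames[k - 1], frames[k]
        # apparent content shift includes -Δstage; the stage-only prior is
        # therefore -Δoffset (sample assumed still)
        stage_prior_um = -(offsets[k] - offsets[k - 1]) if offsets is not None else np.zeros(3)
        pre_roll = np.round(stage_prior_um / voxel).astype(int)
        b_data = np.roll(b.data, shift=tuple(-pre_roll), axis=(0, 1, 2)) if np.any(pre_roll) else b.data
        b_init = VolumeImage(b_data, b.voxel_size, b.timestamp, b.frame_index)
        try:
            sv = estimate_shift(a, b_init, window=window, subpixel=True)
            conf = sv.confidence
            pair_um = sv.micrometres + pre_roll * voxel
            fallback = conf < confidence_floor
        except Exception as exc:  # degenerate pair
            logger.warning("pair %d->%d: registration failed (%s)", k - 1, k, exc)
            conf, fallback = 0.0, True
            pair_um = stage_prior_um
        if fallback and conf < confidence_floor:
            pair_um = stage_prior_um
            logger.warning(
                "pair %d->%d: confidence %.4f below floor %.4f, using stage prior",
                k - 1, k, conf, confidence_floor,
            )
        cum = cum + pair_um
        rows.append((b.frame_index, cum[0], cum[1], cum[2], conf, bool(fallback)))
    return pd.DataFrame(rows, columns=SHIFT_COLUMNS)


def resample_to_global(
    frames: list[VolumeImage],
    shifts: pd.DataFrame,
    voxel_budget: int = DEFAULT_VOXEL_BUDGET,
) -> RegisteredSeries:
    """Place every frame on one common grid at its cumulative shift.

    The global grid is the union bounding box of all shifted frames; each
    frame is placed by trilinear interpolation (content translated by
    ``-cum`` so that co-moving structure lands on the same global voxel in
    every frame), with zeros outside the data.

    Raises
    ------
    ResourceLimitError
        If the global grid would exceed ``voxel_budget`` voxels.
    """
    if len(frames) != len(shifts):
        raise InvalidArgumentError("one shift row per frame is required")
    voxel = np.asarray(frames[0].voxel_size, dtype=float)
    cum_um = shifts[["cum_z_um", "cum_y_um", "cum_x_um"]].to_numpy()
    cum_vox = cum_um / voxel
    shape = np.asarray(frames[0].shape)

    # 1e-9 slack so sub-nanometre shift residues do not grow the box
    lo = np.floor((-cum_vox).min(axis=0) + 1e-9).astype(int)
    hi = np.ceil((shape[None, :] - cum_vox).max(axis=0) - 1e-9).astype(int)
    out_shape = hi - lo
    n_vox = int(np.prod(out_shape))
    if n_vox > voxel_budget:
        raise ResourceLimitError(
            f"global grid {tuple(out_shape)} = {n_vox} voxels exceeds the "
            f"budget of {voxel_budget}"
        )

    volumes = []
    provenance = []
    for k, frame in enumerate(frames):
        # output[g] = frame[g + lo + cum_k]  (trilinear, zero outside)
        placed = scipy.ndimage.affine_transform(
            frame.data.astype(float),
            matrix=np.eye(3),
            offset=lo + cum_vox[k],
            output_shape=tuple(out_shape),
            order=1,
            mode="constant",
            cval=0.0,
        )
        volumes.append(
            VolumeImage(placed, voxel, frame.timestamp, frame.frame_index)
        )
        provenance.append(
            {
                "frame": int(frame.frame_index),
                "cum_shift_um": cum_um[k].tolist(),
                "fallback": bool(shifts["fallback"].iloc[k]),
            }
        )
    return RegisteredSeries(
        volumes=volumes,
        cumulative_shifts_um=cum_um,
        global_origin_um=lo * voxel,
        provenance=provenance,
    )


def stabilization_report(
    series: RegisteredSeries,
    truth: pd.DataFrame,
    stage_offsets_um: np.ndarray | None = None,
) -> dict:
    """Quantify how well registration stabilized the series against truth.

    Maps each ground-truth nucleus position into as-acquired grid
    coordinates (using the per-frame stage offsets when the series came
    from a tracking run) and into the registered global grid, then reports
    the per-frame RMS residual to the frame-0 positions before and after
    registration, restricted to nuclei present in every frame.  The
    ``reduction_ratio`` is overall after/before RMS (≈ 1 for a series that
    never drifted, « 1 for a well-stabilized drifting series).
    """
    n_frames = len(series.volumes)
    frames_present = sorted(truth["frame"].unique())
    if len(frames_present) != n_frames:
        raise InvalidArgumentError(
            f"truth covers {len(frames_present)} frames, series has {n_frames}"
        )
    if stage_offsets_um is None:
        stage_offsets_um = np.zeros((n_frames, 3))
    stage_offsets_um = np.asarray(stage_offsets_um, dtype=float)
    voxel = np.asarray(series.volumes[0].voxel_size, dtype=float)
    cum_vox = series.cumulative_shifts_um / voxel
    origin_vox = series.global_origin_um / voxel

    counts = truth.groupby("id")["frame"].count()
    persistent = counts[counts == n_frames].index
    sub = truth[truth["id"].isin(persistent)].sort_values(["id", "frame"])
    if sub.empty:
        raise InvalidArgumentError("no nucleus persists across every frame")
    n_ids = len(persistent)
    pos = sub[["z_um", "y_um", "x_um"]].to_numpy().reshape(n_ids, n_frames, 3)

    acquired_vox = (pos - stage_offsets_um[None, :, :]) / voxel[None, None, :]
    global_vox = acquired_vox - cum_vox[None, :, :] - origin_vox[None, None, :]

    res_before = np.linalg.norm(acquired_vox - acquired_vox[:, :1, :], axis=2)
    res_after = np.linalg.norm(global_vox - global_vox[:, :1, :], axis=2)
    rms_before = np.sqrt((res_before**2).mean(axis=0))
    rms_after = np.sqrt((res_after**2).mean(axis=0))
    overall_before = float(np.sqrt((res_before**2).mean()))
    overall_after = float(np.sqrt((res_after**2).mean()))
    return {
        "n_nuclei": int(n_ids),
        "rms_before_per_frame": rms_before,
        "rms_after_per_frame": rms_after,
        "rms_before": overall_before,
        "rms_after": overall_after,
        "reduction_ratio": overall_after / overall_before if overall_before > 0 else 1.0,
    }
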