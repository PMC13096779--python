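"""Synthetic growing-tailbud phantom with exact ground truth.

Emulates the imaging subject of a long-term light-sheet experiment: a
posteriorly elongating, proliferating tissue of fluorescent nuclei (an
all-nuclei label such as H2B::GFP) observed through a limited field of
view.  The phantom provides what deposited microscope data cannot — exact
per-nucleus ground truth — so both the online tracking loop and the offline
registration can be validated end-to-end.

The growth model is deliberately minimal: nuclei advect along the body axis
with a posterior-fastest graded velocity field, divide stochastically, and
new nuclei are added in a posterior progenitor zone.  No cell death, no
excluded volume, no tissue types.

Axis order is ``(z, y, x)`` and world coordinates are micrometres
throughout; the body axis defaults to ``+x``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .regcore import VolumeImage

__all__ = [
    "Nucleus",
    "GrowthModel",
    "TissueState",
    "ImagingModel",
    "StageState",
    "init_tissue",
    "step_tissue",
    "render_volume",
    "ground_truth_tracks",
    "tissue_centroid",
    "write_tracks",
    "read_tracks",
]

# the tissue (growth) and camera (noise) RNG streams are decoupled by fixed
# seed offsets so that changing the noise realisation never changes the
# trajectory; all derived seeds stay below 2**31
_SEED_MOD = 2**31
_TISSUE_STREAM = 0
_CAMERA_STREAM = 1_000_003
_FRAME_STRIDE = 9176

# photon counts at or above this use the Gaussian approximation to Poisson
_POISSON_GAUSSIAN_CROSSOVER = 20.0

TRACK_COLUMNS = ["frame", "id", "parent_id", "z_um", "y_um", "x_um"]


def derive_seed(master_seed: int, frame: int, stream: int) -> int:
    """Deterministic per-frame, per-stream seed below 2**31."""
    return (master_seed + stream + _FRAME_STRIDE * frame) % _SEED_MOD


@dataclass(frozen=True)
class Nucleus:
    """One labelled nucleus in world coordinates.

    ``position`` is ``(z, y, x)`` micrometres; ``radius`` micrometres;
    ``intensity`` arbitrary fluorescence units; ``parent_id`` names the
    mother for nuclei created by division, else None.
    """

    id: int
    position: np.ndarray
    radius: float
    intensity: float
    parent_id: int | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise InvalidArgumentError("nucleus position must be a 3-vector")
        if self.radius <= 0:
            raise InvalidArgumentError(f"nucleus radius must be > 0, got {self.radius}")
        if self.intensity <= 0:
            raise InvalidArgumentError(
                f"nucleus intensity must be > 0, got {self.intensity}"
            )
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class GrowthModel:
    """Kinematic parameters of the elongating tissue.

    elongation_rate : µm/frame
        Speed of the posterior tip along the body axis; material anterior
        of the tip moves proportionally slower (graded weight, 1 at the tip
        decaying to 0 at the anterior end).
    proliferation_prob : probability/frame
        Per-nucleus division probability per frame.
    addition_rate : nuclei/frame
        Expected number of new nuclei appearing in the posterior zone each
        frame (progenitor influx).
    posterior_zone : µm
        Length of the region at the posterior end where addition occurs.
    motion_noise_sd : µm
        Per-axis Gaussian random-walk scale applied to every nucleus each
        frame.
    """

    elongation_rate: float = 2.0
    proliferation_prob: float = 0.01
    addition_rate: float = 0.1
    posterior_zone: float = 20.0
    motion_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.elongation_rate < 0:
            raise InvalidArgumentError("elongation_rate must be >= 0")
        if not 0.0 <= self.proliferation_prob <= 1.0:
            raise InvalidArgumentError("proliferation_prob must lie in [0, 1]")
        if self.addition_rate < 0:
            raise InvalidArgumentError("addition_rate must be >= 0")
        if self.posterior_zone <= 0:
            raise InvalidArgumentError("posterior_zone must be > 0")
        if self.motion_noise_sd < 0:
            raise InvalidArgumentError("motion_noise_sd must be >= 0")


@dataclass(frozen=True)
class TissueState:
    """Ground-truth tissue snapshot: nuclei plus the body-axis direction."""

    frame_index: int
    nuclei: tuple[Nucleus, ...]
    axis_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise InvalidArgumentError("frame_index must be >= 0")
        axis = np.asarray(self.axis_direction, dtype=float)
        norm = np.linalg.norm(axis)
        if axis.shape != (3,) or not math.isclose(norm, 1.0, rel_tol=1e-9):
            raise InvalidArgumentError("axis_direction must be a unit 3-vector")
        ids = [n.id for n in self.nuclei]
        if len(ids) != len(set(ids)):
            raise InvalidArgumentError("nucleus ids must be unique within a state")
        object.__setattr__(self, "nuclei", tuple(self.nuclei))
        object.__setattr__(self, "axis_direction", axis)

    def positions(self) -> np.ndarray:
        """(n, 3) array of nucleus positions, world micrometres."""
        if not self.nuclei:
            return np.zeros((0, 3))
        return np.stack([n.position for n in self.nuclei])


@dataclass(frozen=True)
class ImagingModel:
    """Image-formation parameters of the virtual light-sheet detector.

    The defaults are anisotropic (2 µm z-steps, 0.5 µm lateral pixels) as is
    typical for scanned light sheets, which makes the isotropic 1 µm³
    downscaling downstream non-trivial in both directions.

    ``photon_scale`` converts intensity units to expected photons for shot
    noise (variance = signal / photon_scale in intensity units); set it to
    ``inf`` to disable shot noise.  ``read_noise_sd = 0`` disables read
    noise.
    """

    voxel_size: tuple[float, float, float] = (2.0, 0.5, 0.5)
    fov_shape: tuple[int, int, int] = (40, 192, 192)
    psf_sigma: tuple[float, float, float] = (1.5, 0.75, 0.75)
    background: float = 10.0
    photon_scale: float = 2.0
    read_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not all(v > 0 for v in self.voxel_size):
            raise InvalidArgumentError("voxel_size components must be > 0")
        if not all(int(n) >= 8 for n in self.fov_shape):
            raise InvalidArgumentError("fov_shape components must be >= 8")
        if not all(s >= 0 for s in self.psf_sigma):
            raise InvalidArgumentError("psf_sigma components must be >= 0")
        if self.background < 0:
            raise InvalidArgumentError("background must be >= 0")
        if not self.photon_scale > 0:
            raise InvalidArgumentError("photon_scale must be > 0")
        if self.read_noise_sd < 0:
            raise InvalidArgumentError("read_noise_sd must be >= 0")
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "fov_shape", tuple(int(n) for n in self.fov_shape))
        object.__setattr__(self, "psf_sigma", tuple(float(s) for s in self.psf_sigma))

    @property
    def fov_extent_um(self) -> np.ndarray:
        """Physical FOV extent per axis, micrometres."""
        return np.asarray(self.fov_shape) * np.asarray(self.voxel_size)


@dataclass
class StageState:
    """Virtual 3-axis stage: world position of the FOV origin, micrometres.

    ``history`` records every commanded position as ``(frame_index,
    offset)`` pairs, strictly increasing in frame index; the current offset
    always equals the last entry.
    """

    offset: np.ndarray
    history: list[tuple[int, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float).copy()
        if self.offset.shape != (3,):
            raise InvalidArgumentError("stage offset must be a 3-vector")
        if not self.history:
            self.history = [(0, self.offset.copy())]

    def move(self, frame_index: int, delta_um: np.ndarray) -> None:
        """Apply a relative move after acquiring ``frame_index``."""
        if self.history and frame_index <= self.history[-1][0] and len(self.history) > 1:
            raise InvalidArgumentError(
                f"stage history must be strictly increasing, got frame {frame_index}"
            )
        self.offset = self.offset + np.asarray(delta_um, dtype=float)
        self.history.append((frame_index, self.offset.copy()))


def tissue_centroid(state: TissueState) -> np.ndarray:
    """Mean nucleus position, world micrometres."""
    pos = state.positions()
    if len(pos) == 0:
        raise InvalidArgumentError("cannot take the centroid of an empty tissue")
    return pos.mean(axis=0)


def init_tissue(
    model: GrowthModel,
    n_nuclei: int,
    extent: tuple[float, float, float],
    seed: int,
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> TissueState:
    """Seed a frame-0 tissue with nuclei uniform in an axis-aligned box.

    ``extent`` is the ``(z, y, x)`` box size in micrometres with one corner
    at ``origin``.  Radii are drawn uniform in [2, 3] µm and intensities
    uniform in [80, 120] — nuclear-scale blobs with moderate brightness
    variation.  Deterministic given ``seed``.
    """
    extent = np.asarray(extent, dtype=float)
    if n_nuclei < 1:
        raise InvalidArgumentError(f"n_nuclei must be >= 1, got {n_nuclei}")
    if extent.shape != (3,) or np.any(extent <= 0):
        raise InvalidArgumentError(f"extent components must be > 0, got {extent}")
    rng = np.random.default_rng(seed)
    positions = np.asarray(origin, dtype=float) + rng.uniform(0, 1, (n_nuclei, 3)) * extent
    radii = rng.uniform(2.0, 3.0, n_nuclei)
    intensities = rng.uniform(80.0, 120.0, n_nuclei)
    nuclei = [
        Nucleus(id=i, position=positions[i], radius=radii[i], intensity=intensities[i])
        for i in range(n_nuclei)
    ]
    return TissueState(frame_index=0, nuclei=tuple(nuclei), axis_direction=axis_direction)


def _axis_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``axis`` (deterministic)."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def step_tissue(state: TissueState, model: GrowthModel, seed: int) -> TissueState:
    """Advance the tissue by one frame.

    Every nucleus advects by ``elongation_rate * w(position)`` along the
    body axis, where ``w`` ramps linearly from 0 at the anterior-most
    nucleus to 1 at the posterior tip (recomputed each frame), plus
    isotropic Gaussian jitter.  Divisions then duplicate nuclei (daughter
    carries ``parent_id``), and Poisson(``addition_rate``) new nuclei appear
    inside the posterior zone.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    axis = state.axis_direction
    pos = state.positions()
    n = len(pos)
    if n == 0:
        return replace(state, frame_index=state.frame_index + 1)

    s = pos @ axis
    s_min, s_max = float(s.min()), float(s.max())
    if s_max > s_min:
        w = np.clip((s - s_min) / (s_max - s_min), 0.0, 1.0)
    else:
        w = np.ones(n)
    drift = model.elongation_rate * w[:, None] * axis[None, :]
    jitter = rng.normal(0.0, model.motion_noise_sd, (n, 3)) if model.motion_noise_sd > 0 else 0.0
    new_pos = pos + drift + jitter

    next_id = max(nuc.id for nuc in state.nuclei) + 1
    nuclei: list[Nucleus] = []
    for i, nuc in enumerate(state.nuclei):
        nuclei.append(replace(nuc, position=new_pos[i]))

    # divisions: mother keeps her id, daughter records the lineage link
    divide = rng.random(n) < model.proliferation_prob
    for i in np.flatnonzero(divide):
        mother = nuclei[i]
        direction = rng.normal(0.0, 1.0, 3)
        direction /= max(np.linalg.norm(direction), 1e-12)
        daughter_pos = mother.position + direction * mother.radius
        nuclei.append(
            Nucleus(
                id=next_id,
                position=daughter_pos,
                radius=mother.radius,
                intensity=mother.intensity,
                parent_id=mother.id,
            )
        )
        next_id += 1

    # progenitor influx confined to the posterior zone along the axis
    n_new = rng.poisson(model.addition_rate) if model.addition_rate > 0 else 0
    if n_new > 0:
        e1, e2 = _axis_frame(axis)
        s_now = np.stack([nuc.position for nuc in nuclei]) @ axis
        s_hi = float(s_now.max())
        s_lo = s_hi - model.posterior_zone
        v = np.stack([nuc.position for nuc in nuclei]) @ e1
        u = np.stack([nuc.position for nuc in nuclei]) @ e2
        for _ in range(n_new):
            s_new = rng.uniform(s_lo, s_hi)
            v_new = rng.uniform(v.min(), v.max())
            u_new = rng.uniform(u.min(), u.max())
            nuclei.append(
                Nucleus(
                    id=next_id,
                    position=s_new * axis + v_new * e1 + u_new * e2,
                    radius=float(rng.uniform(2.0, 3.0)),
                    intensity=float(rng.uniform(80.0, 120.0)),
                    parent_id=None,
                )
            )
            next_id += 1

    return TissueState(
        frame_index=state.frame_index + 1,
        nuclei=tuple(nuclei),
        axis_direction=axis,
    )


def render_volume(
    state: TissueState,
    imaging: ImagingModel,
    stage: StageState,
    seed: int,
) -> VolumeImage:
    """Render the tissue as seen through the stage-positioned FOV.

    Each nucleus inside (or within 4 PSF sigmas of) the FOV contributes a
    Gaussian blob with per-axis sd ``psf_sigma`` (micrometres, converted to
    voxels) and peak amplitude equal to its intensity, clipped at the FOV
    border; a constant background is added, then shot noise (Poisson,
    Gaussian-approximated at >= 20 expected photons) and Gaussian read
    noise.  Deterministic given ``seed``; the noise stream is independent of
    the tissue stream.
    """
    shape = imaging.fov_shape
    voxel = np.asarray(imaging.voxel_size)
    # float32 throughout: ample for photon-limited data, halves FFT cost
    img = np.full(shape, imaging.background, dtype=np.float32)

    sigma_vox = np.asarray(imaging.psf_sigma) / voxel
    support = np.maximum(np.ceil(4.0 * sigma_vox).astype(int), 0)
    pos = state.positions()
    if len(pos):
        vox_pos = (pos - stage.offset) / voxel
        for nuc, vp in zip(state.nuclei, vox_pos):
            lo = np.floor(vp - support).astype(int)
            hi = np.ceil(vp + support).astype(int) + 1
            lo_c = np.maximum(lo, 0)
            hi_c = np.minimum(hi, shape)
            if np.any(lo_c >= hi_c):
                continue  # entirely outside the FOV
            profiles = []
            for ax in range(3):
                idx = np.arange(lo_c[ax], hi_c[ax], dtype=float)
                if sigma_vox[ax] > 0:
                    profiles.append(np.exp(-0.5 * ((idx - vp[ax]) / sigma_vox[ax]) ** 2))
                else:
                    p = np.zeros(len(idx))
                    nearest = int(round(vp[ax]))
                    if lo_c[ax] <= nearest < hi_c[ax]:
                        p[nearest - lo_c[ax]] = 1.0
                    profiles.append(p)
            blob = nuc.intensity * (
                profiles[0][:, None, None] * profiles[1][None, :, None] * profiles[2][None, None, :]
            )
            img[lo_c[0]:hi_c[0], lo_c[1]:hi_c[1], lo_c[2]:hi_c[2]] += blob

    rng = np.random.default_rng(seed)
    if np.isfinite(imaging.photon_scale):
        photons = img * np.float32(imaging.photon_scale)
        noisy = photons + rng.standard_normal(shape, dtype=np.float32) * np.sqrt(photons)
        low = photons < _POISSON_GAUSSIAN_CROSSOVER
        if np.any(low):
            noisy[low] = rng.poisson(photons[low].astype(float))
        img = noisy / np.float32(imaging.photon_scale)
    if imaging.read_noise_sd > 0:
        img += rng.standard_normal(shape, dtype=np.float32) * np.float32(imaging.read_noise_sd)
    np.clip(img, 0.0, None, out=img)

    return VolumeImage(
        data=img,
        voxel_size=voxel,
        timestamp=0.0,
        frame_index=state.frame_index,
    )


def ground_truth_tracks(states: list[TissueState]) -> pd.DataFrame:
    """Long-format exact track table for a sequence of tissue states.

    Columns: ``frame, id, parent_id, z_um, y_um, x_um``; ``parent_id`` is a
    nullable integer (NA for root nuclei).  States must be consecutive in
    ``frame_index``.
    """
    if not states:
        raise InvalidArgumentError("at least one state is required")
    frames = [st.frame_index for st in states]
    if frames != list(range(frames[0], frames[0] + len(frames))):
        raise InvalidArgumentError(
            f"states must be consecutive in frame_index, got {frames}"
        )
    rows = []
    for st in states:
        for nuc in st.nuclei:
            rows.append(
                (st.frame_index, nuc.id, nuc.parent_id, *nuc.position)
            )
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df["parent_id"] = df["parent_id"].astype("Int64")
    return df


def write_tracks(df: pd.DataFrame, path) -> None:
    """Write a track table as CSV; ``parent_id`` empty for root nuclei."""
    df.to_csv(path, index=False)


def read_tracks(path) -> pd.DataFrame:
    """Read a track table written by :func:`write_tracks`."""
    df = pd.read_csv(path)
    df["parent_id"] = df["parent_id"].astype("Int64")
    return df
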