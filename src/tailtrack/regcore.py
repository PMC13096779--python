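"""3D translation estimation by phase correlation.

The estimator recovers the rigid XYZ shift between two intensity volumes
from the phase of their normalized cross-power spectrum.  It is the single
registration primitive of the package: the online tracking loop uses it to
drive stage corrections, and the post-acquisition registration reuses it to
align the saved timepoints.

Conventions (fixed once, used everywhere):

* axis order is ``(z, y, x)``; voxel indices are 0-based with the voxel
  centre at integer coordinates; world coordinates are micrometres;
* the returned shift ``s`` satisfies ``b ≈ a translated by s``, i.e. image
  content moved by ``+s`` voxels going from ``a`` to ``b``.  A caller that
  wants to map ``b`` back onto ``a`` must translate ``b`` by ``-s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

from .errors import DegenerateInputError, InvalidArgumentError

__all__ = [
    "VolumeImage",
    "ShiftVector",
    "cross_power_spectrum",
    "correlation_surface",
    "wrap_to_signed",
    "subpixel_refine",
    "estimate_shift",
    "oracle_shift",
]

#: relative normalization guard for the cross-power spectrum, scaled by the
#: maximum raw spectrum magnitude so it is invariant to intensity units.
#: Frequencies whose magnitude falls below the guard are divided by it
#: instead of their own magnitude, soft-downweighting noise-dominated bins
#: (whitening smooth content otherwise hands pure-noise frequencies full
#: weight); phases are untouched, so noiseless shift recovery stays exact.
EPS_RELATIVE = 3e-2

_MIN_DIM = 8


@dataclass(frozen=True)
class VolumeImage:
    """One 3D intensity snapshot with physical voxel spacing.

    Parameters
    ----------
    data
        Intensity grid with axes ``(z, y, x)``; every dimension must be at
        least 8 voxels and all values finite.
    voxel_size
        Physical voxel extent in micrometres, ``(z, y, x)``.
    timestamp
        Minutes since acquisition start.
    frame_index
        Position of this volume in the time series.
    """

    data: np.ndarray
    voxel_size: np.ndarray
    timestamp: float = 0.0
    frame_index: int = 0

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise InvalidArgumentError(f"volume must be 3D, got ndim={data.ndim}")
        if min(data.shape) < _MIN_DIM:
            raise InvalidArgumentError(
                f"every volume dimension must be >= {_MIN_DIM}, got {data.shape}"
            )
        if not np.all(np.isfinite(data)):
            raise InvalidArgumentError("volume contains non-finite values")
        voxel = np.asarray(self.voxel_size, dtype=float)
        if voxel.shape != (3,) or not np.all(voxel > 0):
            raise InvalidArgumentError(
                f"voxel_size must be 3 positive values, got {self.voxel_size!r}"
            )
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size", voxel)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent_um(self) -> np.ndarray:
        """Physical extent of the grid per axis, micrometres."""
        return np.asarray(self.shape) * self.voxel_size


@dataclass(frozen=True)
class ShiftVector:
    """Signed 3D translation in voxels and micrometres, with confidence.

    ``micrometres`` always equals ``voxels * voxel_size``; ``confidence`` is
    the peak of the normalized phase-correlation surface (peak over the
    maximum a fully coherent pair could reach), in ``[0, 1]`` — near 1 for
    a clean single peak, near 0 for a flat/noise surface.
    """

    voxels: np.ndarray
    micrometres: np.ndarray
    confidence: float

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        um = np.asarray(self.micrometres, dtype=float)
        if vox.shape != (3,) or um.shape != (3,):
            raise InvalidArgumentError("shift components must be 3-vectors")
        if not (0.0 <= self.confidence <= 1.0):
            raise InvalidArgumentError(
                f"confidence must lie in [0, 1], got {self.confidence}"
            )
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "micrometres", um)

    @classmethod
    def from_voxels(
        cls, voxels: np.ndarray, voxel_size: np.ndarray, confidence: float
    ) -> "ShiftVector":
        voxels = np.asarray(voxels, dtype=float)
        voxel_size = np.asarray(voxel_size, dtype=float)
        return cls(voxels=voxels, micrometres=voxels * voxel_size, confidence=confidence)


def _check_pair(a: VolumeImage, b: VolumeImage) -> None:
    if a.shape != b.shape:
        raise InvalidArgumentError(
            f"volume shapes differ: {a.shape} vs {b.shape}"
        )
    if not np.allclose(a.voxel_size, b.voxel_size):
        raise InvalidArgumentError(
            f"voxel sizes differ: {a.voxel_size} vs {b.voxel_size}"
        )


def _hann_window(shape: tuple[int, ...]) -> np.ndarray:
    win = np.ones(shape)
    for axis, n in enumerate(shape):
        w = np.hanning(n)
        win *= w.reshape([-1 if ax == axis else 1 for ax in range(len(shape))])
    return win


def cross_power_spectrum(
    a: VolumeImage, b: VolumeImage, eps: float | None = None
) -> np.ndarray:
    """Magnitude-normalized cross-power spectrum ``F(a)·conj(F(b)) / |·|``.

    The normalization divisor is ``max(|F(a)·conj(F(b))|, eps)`` elementwise;
    when *eps* is None it defaults to :data:`EPS_RELATIVE` times the maximum
    spectrum magnitude, so noise-dominated frequencies are downweighted
    rather than amplified and two all-zero volumes yield an all-zero
    spectrum instead of a division error.
    """
    _check_pair(a, b)
    raw = scipy.fft.fftn(a.data) * np.conj(scipy.fft.fftn(b.data))
    mag = np.abs(raw)
    peak = mag.max()
    if peak == 0.0:
        return np.zeros_like(raw)
    if eps is None:
        eps = EPS_RELATIVE * peak
    if eps <= 0:
        raise InvalidArgumentError(f"eps must be positive, got {eps}")
    return raw / np.maximum(mag, eps)


def correlation_surface(
    a: VolumeImage, b: VolumeImage, window: bool = False
) -> np.ndarray:
    """Real phase-correlation surface whose argmax is the (wrapped) shift.

    With ``window=True`` a separable Hann window is applied to both inputs
    first, suppressing the spectral leakage of non-periodic content; exact
    circular-shift recovery requires ``window=False``.

    For ``b = a`` translated by ``+s`` voxels (circularly) the surface peaks
    at the wrapped index of ``+s``; the conjugated spectrum is inverted so
    the correlation lag carries that sign.
    """
    surface, _ = _surface_and_coherence(a, b, window)
    return surface


def _surface_and_coherence(
    a: VolumeImage, b: VolumeImage, window: bool
) -> tuple[np.ndarray, float]:
    """Correlation surface plus the coherent-peak ceiling.

    The ceiling (mean normalized-spectrum magnitude) is the largest peak a
    perfectly phase-coherent pair could produce; dividing the observed peak
    by it yields a size-invariant confidence.
    """
    _check_pair(a, b)
    ad, bd = a.data, b.data
    if window:
        win = _hann_window(a.shape)
        ad = ad * win
        bd = bd * win
    # real-input fast path: the cross spectrum of real volumes is Hermitian,
    # so the half-spectrum (rfftn) normalization is identical to the full one
    raw = np.conj(scipy.fft.rfftn(ad)) * scipy.fft.rfftn(bd)
    mag = np.abs(raw)
    peak = mag.max()
    if peak == 0.0:
        return np.zeros(a.shape), 0.0
    eps = EPS_RELATIVE * peak
    norm = raw / np.maximum(mag, eps)
    return scipy.fft.irfftn(norm, s=a.shape), float(np.abs(norm).mean())


def wrap_to_signed(peak_index: np.ndarray, dims: np.ndarray) -> np.ndarray:
    """Map FFT peak indices to signed shifts in ``[-dim/2, dim/2)``.

    Correlation computed with FFTs is circular, so a negative shift appears
    near the far edge of the surface; indices at or above ``dim/2`` have
    ``dim`` subtracted.
    """
    peak_index = np.asarray(peak_index, dtype=int)
    dims = np.asarray(dims, dtype=int)
    if peak_index.shape != (3,) or dims.shape != (3,):
        raise InvalidArgumentError("peak_index and dims must be 3-vectors")
    if np.any(peak_index < 0) or np.any(peak_index >= dims):
        raise InvalidArgumentError(
            f"peak index {peak_index.tolist()} out of range for dims {dims.tolist()}"
        )
    return np.where(2 * peak_index >= dims, peak_index - dims, peak_index)


def subpixel_refine(surface: np.ndarray, peak_index: np.ndarray) -> np.ndarray:
    """Per-axis 3-point parabolic refinement of a correlation peak.

    Fits a parabola through the peak and its two circular neighbours on each
    axis and returns the vertex offset ``0.5*(c- − c+)/(c- − 2c0 + c+)`` per
    axis, each in ``(-1, 1)``.  A degenerate fit (non-concave: denominator
    >= 0, or non-finite) returns 0 for that axis.
    """
    peak_index = np.asarray(peak_index, dtype=int)
    offsets = np.zeros(3)
    c0 = surface[tuple(peak_index)]
    for axis in range(3):
        lo = peak_index.copy()
        hi = peak_index.copy()
        n = surface.shape[axis]
        lo[axis] = (peak_index[axis] - 1) % n
        hi[axis] = (peak_index[axis] + 1) % n
        cm, cp = surface[tuple(lo)], surface[tuple(hi)]
        denom = cm - 2.0 * c0 + cp
        # a concave peak has denom < 0; anything else is degenerate
        if not np.isfinite(denom) or denom >= 0:
            continue
        off = 0.5 * (cm - cp) / denom
        if np.isfinite(off) and -1.0 < off < 1.0:
            offsets[axis] = off
    return offsets


def estimate_shift(
    a: VolumeImage,
    b: VolumeImage,
    window: bool = True,
    subpixel: bool = True,
) -> ShiftVector:
    """Estimate the translation taking ``a`` onto ``b``.

    Returns a :class:`ShiftVector` ``s`` such that ``b ≈ a`` with content
    moved by ``+s`` voxels.  Peak ties are broken toward the smallest
    lexicographic ``(z, y, x)`` index; confidence is the surface peak
    normalized by the largest value a perfectly phase-coherent pair could
    produce, clipped to ``[0, 1]`` — 1 for identical/noiseless shifted
    pairs, of order ``sqrt(log N / N)`` for unrelated noise.

    Raises
    ------
    DegenerateInputError
        If both volumes are constant (no signal to correlate).
    """
    _check_pair(a, b)
    if np.ptp(a.data) == 0 and np.ptp(b.data) == 0:
        raise DegenerateInputError(
            f"both volumes are constant (frames {a.frame_index} and "
            f"{b.frame_index}); shift is undefined"
        )
    surface, ceiling = _surface_and_coherence(a, b, window)
    # np.argmax scans in C order, i.e. smallest lexicographic (z, y, x) first
    peak_index = np.array(np.unravel_index(np.argmax(surface), surface.shape))
    shift = wrap_to_signed(peak_index, np.array(surface.shape)).astype(float)
    if subpixel:
        shift = shift + subpixel_refine(surface, peak_index)
    peak_value = surface[tuple(peak_index)]
    # a near-constant surface (correlation mass spread uniformly) carries no
    # localization information regardless of its peak value
    if ceiling <= 0 or np.ptp(surface) <= 1e-6 * abs(peak_value):
        confidence = 0.0
    else:
        confidence = float(np.clip(peak_value / ceiling, 0.0, 1.0))
    return ShiftVector.from_voxels(shift, a.voxel_size, confidence)


def oracle_shift(a: VolumeImage, b: VolumeImage) -> np.ndarray:
    """Brute-force integer shift by exhaustive circular cross-correlation.

    Evaluates ``sum(a * roll(b, -s))`` for every integer shift ``s`` in the
    spatial domain — O(N²) in voxel count, intended for small test volumes
    (≤ 32³) as an FFT-free oracle.  Returns the signed shift maximizing the
    correlation, wrapped like :func:`wrap_to_signed`.
    """
    _check_pair(a, b)
    dims = a.shape
    best = (-np.inf, (0, 0, 0))
    ad = a.data
    bd = b.data
    for sz in range(dims[0]):
        rz = np.roll(bd, -sz, axis=0)
        for sy in range(dims[1]):
            rzy = np.roll(rz, -sy, axis=1)
            for sx in range(dims[2]):
                # roll(b, -s)[x] == b[x + s]; peak where b = a shifted by +s
                corr = float(np.vdot(ad, np.roll(rzy, -sx, axis=2)))
                if corr > best[0]:
                    best = (corr, (sz, sy, sx))
    return wrap_to_signed(np.array(best[1]), np.array(dims))
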