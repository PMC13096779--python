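import numpy as np
import pytest

from tailtrack import GrowthModel, ImagingModel, TrackingConfig, VolumeImage


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_volume(rng):
    """16³ random volume with unit voxels — the standard registration fixture."""
    return VolumeImage(rng.random((16, 16, 16)), (1.0, 1.0, 1.0))


def rolled(volume: VolumeImage, shift) -> VolumeImage:
    """Circularly shift a volume's content by +shift voxels."""
    return VolumeImage(
        np.roll(volume.data, tuple(int(s) for s in shift), axis=(0, 1, 2)),
        volume.voxel_size,
        volume.timestamp,
        volume.frame_index + 1,
    )


@pytest.fixture
def default_growth():
    return GrowthModel()


@pytest.fixture
def default_imaging():
    return ImagingModel()


@pytest.fixture
def quiet_imaging():
    """Default optics with all noise sources disabled."""
    return ImagingModel(photon_scale=float("inf"), read_noise_sd=0.0)


@pytest.fixture
def default_tracking():
    return TrackingConfig()
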