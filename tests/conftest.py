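import numpy as np
import pytest

from spinedx import DicomSlice, PhantomSpec, generate_subject


def make_slice(
    position=(0.0, 0.0, 0.0),
    row_direction=(1.0, 0.0, 0.0),
    column_direction=(0.0, 1.0, 0.0),
    spacing=(1.0, 1.0),
    shape=(64, 64),
    instance_number=1,
    series_id="test-series",
    pixels=None,
):
    """A minimal valid slice for geometry-level tests."""
    if pixels is None:
        pixels = np.zeros(shape)
    return DicomSlice(
        pixel_matrix=pixels,
        image_position=np.asarray(position, dtype=float),
        row_direction=np.asarray(row_direction, dtype=float),
        column_direction=np.asarray(column_direction, dtype=float),
        pixel_spacing=spacing,
        instance_number=instance_number,
        series_id=series_id,
    )


def random_frame(rng):
    """A random orthonormal (row, column) direction pair."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    return q[:, 0], q[:, 1]


@pytest.fixture(scope="session")
def default_subject():
    return generate_subject(PhantomSpec(), subject_seed=7)


@pytest.fixture(scope="session")
def noise_free_subject():
    return generate_subject(PhantomSpec(noise_sd=0.0), subject_seed=5)
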