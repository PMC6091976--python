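"""Shared fixtures: synthetic phantoms and their tracked/decomposed products.

Expensive artifacts (tracked movies, spectral decompositions) are session
scoped so the suite builds each one once.
"""

import logging

import numpy as np
import pytest

from morphospec import (
    Block, BlobMovieSpec, CoupledActivitySpec, Mode, PlantedMapSpec,
    block_labels, decompose_map, discrete_windows, extract_contour,
    gen_blob_movie, gen_coupled_activity, gen_planted_map, sample_movie,
    sector_velocity_map, track_movie,
)

logging.getLogger("morphospec").setLevel(logging.ERROR)


def disk(n: int = 128, radius: float = 30.0, cx=None, cy=None) -> np.ndarray:
    c = (n - 1) / 2.0
    cx = c if cx is None else cx
    cy = c if cy is None else cy
    yy, xx = np.mgrid[0:n, 0:n]
    return np.hypot(xx - cx, yy - cy) <= radius


def sector_angles(window_set, center):
    """Boundary angle (image-center frame) of each slice midpoint."""
    from shapely.geometry import Point

    ring = window_set.contour.ring()
    s0 = ring.project(Point(window_set.origin))
    L = window_set.contour.length
    mids_um = 0.5 * (window_set.slice_edges[:-1] + window_set.slice_edges[1:])
    angles = []
    for m_um in mids_um:
        pt = ring.interpolate((s0 + m_um / window_set.pixel_size) % L)
        angles.append(np.arctan2(pt.y - center[1], pt.x - center[0]) % (2 * np.pi))
    return np.asarray(angles)


# --------------------------------------------------------------------------
# blob movie with two planted angular modes
# --------------------------------------------------------------------------

BLOB_SPEC = BlobMovieSpec(
    image_size=128, n_frames=40, dt=10.0, pixel_size=0.3,
    base_radius=14.0, n_sectors=24, noise_sd=0.0, seed=11,
    modes=(
        Mode(frequency=0.02, amplitude=1.5, phase=0.4, theta_range=(0.2, 2.8)),
        Mode(frequency=0.005, amplitude=1.5, phase=1.3, theta_range=(3.4, 6.0)),
    ),
)


@pytest.fixture(scope="session")
def blob_movie():
    return gen_blob_movie(BLOB_SPEC)


@pytest.fixture(scope="session")
def blob_edgemaps(blob_movie):
    return track_movie(blob_movie.masks, dt=BLOB_SPEC.dt,
                       pixel_size=BLOB_SPEC.pixel_size)


@pytest.fixture(scope="session")
def blob_windows(blob_movie):
    sets = []
    c = (BLOB_SPEC.image_size - 1) / 2.0
    for mask in blob_movie.masks:
        ct = extract_contour(mask)
        edges = np.linspace(0.0, ct.length * BLOB_SPEC.pixel_size,
                            BLOB_SPEC.n_sectors + 1)
        sets.append(discrete_windows(
            mask, [0.0, 3.0], edges, (c + 50, c), BLOB_SPEC.pixel_size,
            contour=ct))
    return sets


@pytest.fixture(scope="session")
def blob_vmap(blob_edgemaps, blob_windows):
    return sector_velocity_map(blob_edgemaps, blob_windows, dt=BLOB_SPEC.dt)


# --------------------------------------------------------------------------
# planted two-block map (fast / slow tone, SNR 5)
# --------------------------------------------------------------------------

PLANTED_SPEC = PlantedMapSpec(
    n_sectors=64, n_frames=120, dt=10.0,
    blocks=(
        Block((0, 32), (0, 120), frequency=0.02, amplitude=2.0),
        Block((32, 64), (0, 120), frequency=0.005, amplitude=2.0),
    ),
    noise_sd=0.4, seed=3,
)


@pytest.fixture(scope="session")
def planted_map():
    return gen_planted_map(PLANTED_SPEC)


@pytest.fixture(scope="session")
def planted_truth():
    return block_labels(PLANTED_SPEC)


@pytest.fixture(scope="session")
def planted_field(planted_map):
    return decompose_map(planted_map)


# --------------------------------------------------------------------------
# coupled movie: broadband motion, activity delayed by 50 s
# --------------------------------------------------------------------------

COUPLED_BLOB = BlobMovieSpec(
    image_size=128, n_frames=100, dt=10.0, pixel_size=0.3,
    base_radius=14.0, n_sectors=24, noise_sd=0.0, seed=1,
    modes=(
        Mode(0.004, 1.0, 0.3), Mode(0.0073, 1.0, 1.1),
        Mode(0.0117, 1.0, 2.2), Mode(0.019, 0.6, 0.5),
    ),
)
COUPLED_SPEC = CoupledActivitySpec(
    blob=COUPLED_BLOB, lag=50.0, gain=5.0, band_depth=3.0,
    baseline=500.0, noise_sd=1.0,
)


@pytest.fixture(scope="session")
def coupled_maps():
    """(velocity map, band-1 activity map, band-2 activity map)."""
    movie = gen_blob_movie(COUPLED_BLOB)
    activity = gen_coupled_activity(movie, COUPLED_SPEC)
    emaps = track_movie(movie.masks, dt=COUPLED_BLOB.dt,
                        pixel_size=COUPLED_BLOB.pixel_size)
    c = (COUPLED_BLOB.image_size - 1) / 2.0
    wsets = []
    for mask in movie.masks:
        ct = extract_contour(mask)
        edges = np.linspace(0.0, ct.length * COUPLED_BLOB.pixel_size, 25)
        wsets.append(discrete_windows(
            mask, [0.0, 3.0, 6.0], edges, (c + 47, c),
            COUPLED_BLOB.pixel_size, contour=ct))
    vmap = sector_velocity_map(emaps, wsets, dt=COUPLED_BLOB.dt)
    amap1 = sample_movie(activity, wsets, band=0, dt=COUPLED_BLOB.dt)
    amap2 = sample_movie(activity, wsets, band=1, dt=COUPLED_BLOB.dt)
    return vmap, amap1, amap2
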