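"""Synthetic movies and activity maps with analytic ground truth.

Every downstream stage of the pipeline (segmentation, edge tracking,
windowing, spectral decomposition, region merging, motion/signal coupling)
is exercised against data generated here, where the true edge position,
normal velocity and signaling coupling are known in closed form.

The cell phantom is a star-convex "blob": a closed boundary given in polar
coordinates by

    rho(theta, t) = R0 + sum_k  a_k * w_k(theta) * sin(2*pi*f_k*t + phi_k)

with raised-cosine angular windows ``w_k`` so the boundary (and hence the
normal velocity field) is smooth in space.  For such a radial
parameterization the analytic normal velocity is d(rho)/dt up to a small
geometric correction of order (d rho/d theta / rho)^2, which is negligible
for the gentle deformations used here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Mode:
    """One radial oscillation mode of the blob boundary.

    theta_range : (start, end) in radians, or None for a global mode.
        The amplitude is tapered by a raised-cosine (Hann) profile across
        the window so the velocity field has no angular discontinuity.
    frequency : temporal frequency in Hz.
    amplitude : radial amplitude in micrometers.
    phase : phase offset in radians.
    """

    frequency: float
    amplitude: float
    phase: float = 0.0
    theta_range: Optional[tuple[float, float]] = None

    def window(self, theta: np.ndarray) -> np.ndarray:
        if self.theta_range is None:
            return np.ones_like(theta)
        t0, t1 = self.theta_range
        width = (t1 - t0) % (2 * np.pi)
        if width == 0.0:
            width = 2 * np.pi
        rel = (theta - t0) % (2 * np.pi)
        w = np.zeros_like(theta)
        inside = rel <= width
        w[inside] = 0.5 * (1.0 - np.cos(2 * np.pi * rel[inside] / width))
        return w


@dataclass(frozen=True)
class BlobMovieSpec:
    """Parameters of a synthetic deforming-blob movie.

    Defaults mirror a typical fibroblast time-lapse: 10 s frame interval,
    0.3 um pixels, a ~15 um cell radius and 30 min of imaging.
    """

    image_size: int = 128
    n_frames: int = 60
    dt: float = 10.0                 # seconds
    pixel_size: float = 0.3          # micrometers per pixel
    base_radius: float = 15.0        # micrometers
    modes: tuple[Mode, ...] = ()
    noise_sd: float = 20.0           # intensity units
    fg_intensity: float = 1000.0
    bg_intensity: float = 100.0
    n_sectors: int = 64              # angular sectors of the ground-truth map
    seed: int = 0

    def validate(self) -> None:
        nyquist = 1.0 / (2.0 * self.dt)
        for m in self.modes:
            if m.frequency >= nyquist:
                raise ValueError(
                    f"mode frequency {m.frequency} Hz violates the Nyquist "
                    f"limit 1/(2*dt) = {nyquist} Hz"
                )
        total_amp = sum(abs(m.amplitude) for m in self.modes)
        if self.base_radius - total_amp <= 0:
            raise ValueError("total mode amplitude exceeds base radius; the mask could vanish")


@dataclass(frozen=True)
class CoupledActivitySpec:
    """Activity channel coupled to edge velocity with a known time lag.

    Within ``band_depth`` of the instantaneous edge the activity is
    ``baseline + gain * v(theta, t - lag)``; elsewhere it is ``baseline``.
    ``gain`` is in activity units per (um/min); ``lag`` must be an integer
    multiple of the frame interval.
    """

    blob: BlobMovieSpec
    lag: float = 50.0          # seconds; positive = activity delayed vs motion
    gain: float = 1.0
    band_depth: float = 3.0    # micrometers
    baseline: float = 500.0
    noise_sd: float = 1.0      # activity units, i.i.d. measurement noise

    def validate(self) -> None:
        self.blob.validate()
        if abs(self.lag / self.blob.dt - round(self.lag / self.blob.dt)) > 1e-9:
            raise ValueError("lag must be an integer multiple of dt")
        if self.band_depth <= 0:
            raise ValueError("band_depth must be positive")
        if abs(self.lag) >= self.blob.n_frames * self.blob.dt:
            raise ValueError("lag exceeds the movie duration")


@dataclass(frozen=True)
class Block:
    """One homogeneous block of a planted activity map."""

    sector_range: tuple[int, int]    # half-open [s0, s1)
    time_range: tuple[int, int]      # half-open [t0, t1)
    frequency: float                 # Hz
    amplitude: float                 # um/min
    phase: float = 0.0


@dataclass(frozen=True)
class PlantedMapSpec:
    """Block-structured sectors x time velocity map with additive noise."""

    n_sectors: int = 64
    n_frames: int = 120
    dt: float = 10.0
    blocks: tuple[Block, ...] = ()
    noise_sd: float = 0.0            # um/min
    seed: int = 0

    def validate(self) -> None:
        cover = np.zeros((self.n_sectors, self.n_frames), dtype=int)
        for b in self.blocks:
            s0, s1 = b.sector_range
            t0, t1 = b.time_range
            cover[s0:s1, t0:t1] += 1
        if self.blocks and cover.max() > 1:
            raise ValueError("blocks overlap")
        if self.blocks and cover.min() < 1:
            raise ValueError("blocks do not tile the sector x time grid")


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------

@dataclass
class BlobMovie:
    images: np.ndarray          # (T, H, W) float
    masks: np.ndarray           # (T, H, W) bool, ground truth
    velocities: np.ndarray      # (n_sectors, T-1) um/min, analytic d(rho)/dt
    sector_theta: np.ndarray    # (n_sectors,) sector center angles
    spec: BlobMovieSpec

    @property
    def center(self) -> tuple[float, float]:
        c = (self.spec.image_size - 1) / 2.0
        return (c, c)


def _radius(spec: BlobMovieSpec, theta: np.ndarray, t: float) -> np.ndarray:
    """Boundary radius rho(theta, t) in micrometers."""
    rho = np.full_like(theta, float(spec.base_radius))
    for m in spec.modes:
        rho = rho + m.amplitude * m.window(theta) * np.sin(
            2 * np.pi * m.frequency * t + m.phase
        )
    return rho


def _radial_velocity(spec: BlobMovieSpec, theta: np.ndarray, t: float) -> np.ndarray:
    """Analytic d(rho)/dt in micrometers per minute."""
    v = np.zeros_like(theta)
    for m in spec.modes:
        v = v + (
            m.amplitude
            * m.window(theta)
            * 2 * np.pi * m.frequency
            * np.cos(2 * np.pi * m.frequency * t + m.phase)
        )
    return v * 60.0


def gen_blob_movie(spec: BlobMovieSpec) -> BlobMovie:
    """Generate images, ground-truth masks and the analytic velocity map.

    The velocity map has one row per angular sector and ``n_frames - 1``
    columns; column t holds d(rho)/dt evaluated at the frame midpoint
    (t + 1/2)*dt, which is what a finite-difference tracker of frames t and
    t+1 estimates.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r_px = np.hypot(xx - c, yy - c)
    theta_px = np.arctan2(yy - c, xx - c) % (2 * np.pi)

    masks = np.empty((spec.n_frames, n, n), dtype=bool)
    images = np.empty((spec.n_frames, n, n), dtype=float)
    for k in range(spec.n_frames):
        rho_px = _radius(spec, theta_px, k * spec.dt) / spec.pixel_size
        mask = r_px <= rho_px
        masks[k] = mask
        img = np.where(mask, spec.fg_intensity, spec.bg_intensity)
        images[k] = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    sector_theta = (np.arange(spec.n_sectors) + 0.5) * 2 * np.pi / spec.n_sectors
    vel = np.empty((spec.n_sectors, spec.n_frames - 1), dtype=float)
    for k in range(spec.n_frames - 1):
        vel[:, k] = _radial_velocity(spec, sector_theta, (k + 0.5) * spec.dt)
    return BlobMovie(images, masks, vel, sector_theta, spec)


def gen_coupled_activity(movie: BlobMovie, spec: CoupledActivitySpec) -> np.ndarray:
    """Per-pixel activity stack coupled to the analytic edge velocity.

    Pixel activity inside the edge band follows the velocity of its angular
    position, delayed by ``spec.lag`` seconds.
    """
    spec.validate()
    from scipy import ndimage

    blob = spec.blob
    n = blob.image_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    theta_px = np.arctan2(yy - c, xx - c) % (2 * np.pi)
    band_px = spec.band_depth / blob.pixel_size

    rng = np.random.default_rng(blob.seed + 7919)
    stack = np.full((blob.n_frames, n, n), float(spec.baseline))
    for k in range(blob.n_frames):
        mask = movie.masks[k]
        dist = ndimage.distance_transform_edt(mask)
        band = mask & (dist <= band_px)
        v = _radial_velocity(blob, theta_px[band], k * blob.dt - spec.lag)
        stack[k][band] = spec.baseline + spec.gain * v
    if spec.noise_sd > 0:
        stack = stack + rng.normal(0.0, spec.noise_sd, size=stack.shape)
    return stack


def gen_planted_map(spec: PlantedMapSpec):
    """Planted block-sinusoid activity map (sectors x time, um/min)."""
    from .windowing import ActivityMap

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    v = np.zeros((spec.n_sectors, spec.n_frames))
    t = np.arange(spec.n_frames) * spec.dt
    for b in spec.blocks:
        s0, s1 = b.sector_range
        t0, t1 = b.time_range
        v[s0:s1, t0:t1] = b.amplitude * np.sin(
            2 * np.pi * b.frequency * t[t0:t1] + b.phase
        )
    if spec.noise_sd > 0:
        v = v + rng.normal(0.0, spec.noise_sd, size=v.shape)
    counts = np.ones_like(v, dtype=int)
    return ActivityMap(
        values=v,
        counts=counts,
        units="um/min",
        dt=spec.dt,
        meta={"kind": "planted", "seed": spec.seed},
    )


def block_labels(spec: PlantedMapSpec) -> np.ndarray:
    """Ground-truth block membership of each (sector, time) grid cell."""
    lab = np.zeros((spec.n_sectors, spec.n_frames), dtype=int)
    for j, b in enumerate(spec.blocks):
        s0, s1 = b.sector_range
        t0, t1 = b.time_range
        lab[s0:s1, t0:t1] = j
    return lab


# --------------------------------------------------------------------------
# disk IO
# --------------------------------------------------------------------------

def save_movie(movie: BlobMovie, outdir: str | Path) -> None:
    """Write TIFF stacks plus ground truth (TSV + JSON sidecar)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img16 = np.clip(movie.images, 0, 65535).astype(np.uint16)
    tifffile.imwrite(outdir / "movie.tif", img16, photometric="minisblack")
    tifffile.imwrite(outdir / "masks.tif", (movie.masks * 255).astype(np.uint8),
                     photometric="minisblack")
    np.savetxt(outdir / "velocity_truth.tsv", movie.velocities, delimiter="\t")
    sidecar = {
        "dt": movie.spec.dt,
        "pixel_size": movie.spec.pixel_size,
        "seed": movie.spec.seed,
        "spec": _spec_dict(movie.spec),
        "velocity_units": "um/min",
    }
    (outdir / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))


def _spec_dict(spec) -> dict:
    d = asdict(spec)
    return d
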