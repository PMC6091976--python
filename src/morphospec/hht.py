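"""Empirical mode decomposition and Hilbert spectral analysis.

A series X(t) is sifted into intrinsic mode functions (IMFs): at each step
the mean of the cubic-spline envelopes through the local maxima and minima
is subtracted until the result satisfies the IMF conditions (extrema and
zero-crossing counts differ by at most one; zero envelope mean), giving

    X(t) = sum_i c_i(t) + r_n(t)        (complete to machine precision).

Each IMF admits a well-defined instantaneous frequency via the analytic
signal: F(t) = (1/2pi) d/dt arg(c + i H[c]), A(t) = |c + i H[c]|.

Activity maps are decomposed row-wise (temporal axis, frequencies in Hz)
and column-wise (spatial axis along the closed cell boundary, frequencies
in cycles/sector).  The number of IMFs is fixed (default six) so spectra
are comparable across cells; series that exhaust earlier pad with zero
components, which are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

from .windowing import ActivityMap

logger = logging.getLogger(__name__)

DEFAULT_N_IMF = 6


# --------------------------------------------------------------------------
# EMD
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SiftConfig:
    """Sift stop: Cauchy-type SD = sum (h_prev - h)^2 / sum h_prev^2 < sd_threshold."""

    sd_threshold: float = 0.2
    max_sifts: int = 100


@dataclass
class IMFSet:
    source: np.ndarray            # X(t)
    imfs: np.ndarray              # (n_imf, T); padded rows are zero
    residual: np.ndarray
    sift_counts: list
    n_active: int                 # IMFs actually extracted (rest are padding)

    def reconstruct(self) -> np.ndarray:
        return self.imfs.sum(axis=0) + self.residual


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateau midpoints)."""
    n = len(x)
    d = np.sign(np.diff(x))
    # collapse plateaus: carry the last nonzero slope forward
    nz = d != 0
    if not nz.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    filled = d.copy()
    last = 0.0
    for i in range(len(d)):
        if filled[i] == 0:
            filled[i] = last
        else:
            last = filled[i]
    turn = np.diff(filled)
    maxima = np.where(turn < 0)[0] + 1
    minima = np.where(turn > 0)[0] + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, with the two nearest extrema
    mirrored about each series end."""
    t = np.arange(len(x), dtype=float)
    ti, vi = t[idx], x[idx]
    k = min(2, len(ti))
    left_t = 2 * t[0] - ti[:k][::-1]
    left_v = vi[:k][::-1]
    right_t = 2 * t[-1] - ti[-k:][::-1]
    right_v = vi[-k:][::-1]
    tt = np.concatenate([left_t, ti, right_t])
    vv = np.concatenate([left_v, vi, right_v])
    tt, uniq = np.unique(tt, return_index=True)
    vv = vv[uniq]
    if len(tt) < 2:
        return np.full_like(x, vv[0] if len(vv) else 0.0)
    spl = CubicSpline(tt, vv, bc_type="natural")
    return spl(t)


def n_zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    return int(np.sum(s[:-1] != s[1:]))


def is_imf(x: np.ndarray) -> bool:
    """Extrema and zero-crossing counts differ by at most one."""
    maxima, minima = _local_extrema(x)
    n_ext = len(maxima) + len(minima)
    if n_ext < 2:
        return False
    return abs(n_ext - n_zero_crossings(x)) <= 1


def emd(series: np.ndarray, n_imf: int = DEFAULT_N_IMF,
        sift_config: SiftConfig = SiftConfig()) -> IMFSet:
    """Empirical mode decomposition with a fixed number of components.

    Missing values are linearly interpolated first (logged).  A series
    whose residual runs out of extrema before ``n_imf`` components returns
    zero-padded IMFs with ``n_active`` marking the genuine ones.
    """
    x = np.asarray(series, dtype=float).copy()
    if len(x) < 8:
        raise ValueError("series too short for EMD (need >= 8 samples)")
    bad = ~np.isfinite(x)
    if bad.any():
        logger.debug("interpolating %d missing samples before EMD", bad.sum())
        t = np.arange(len(x))
        x[bad] = np.interp(t[bad], t[~bad], x[~bad])

    imfs = np.zeros((n_imf, len(x)))
    sift_counts = []
    residual = x.copy()
    n_active = 0
    for i in range(n_imf):
        maxima, minima = _local_extrema(residual)
        if len(maxima) < 2 or len(minima) < 2:
            break
        h = residual.copy()
        count = 0
        for _ in range(sift_config.max_sifts):
            maxima, minima = _local_extrema(h)
            if len(maxima) < 2 or len(minima) < 2:
                break
            m = 0.5 * (_envelope(h, maxima) + _envelope(h, minima))
            h_new = h - m
            count += 1
            denom = float(np.sum(h ** 2))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sift_config.sd_threshold and is_imf(h):
                break
        imfs[i] = h
        residual = residual - h
        sift_counts.append(count)
        n_active += 1
    if n_active < n_imf:
        logger.debug("EMD exhausted after %d of %d IMFs; padding with zeros",
                     n_active, n_imf)
    return IMFSet(source=x, imfs=imfs, residual=residual,
                  sift_counts=sift_counts, n_active=n_active)


# --------------------------------------------------------------------------
# Hilbert spectra
# --------------------------------------------------------------------------

@dataclass
class SpectrumSeries:
    frequency: np.ndarray        # Hz (temporal) or cycles/sector (spatial)
    amplitude: np.ndarray        # >= 0
    valid: np.ndarray            # bool; boundary samples excluded


def hilbert_spectrum(imf: np.ndarray, dt: float = 1.0) -> SpectrumSeries:
    """Instantaneous frequency and amplitude of one IMF.

    F(t) is the central-difference derivative of the unwrapped analytic
    phase over 2*pi (one-sided at the two valid ends); A(t) the analytic
    amplitude.  The first and last samples are marked invalid; an all-zero
    component yields an empty (all-invalid) spectrum.
    """
    c = np.asarray(imf, dtype=float)
    T = len(c)
    if not np.any(c):
        logger.debug("all-zero IMF; empty spectrum")
        return SpectrumSeries(np.full(T, np.nan), np.zeros(T), np.zeros(T, dtype=bool))
    analytic = hilbert(c)
    phase = np.unwrap(np.angle(analytic))
    freq = np.gradient(phase, dt) / (2 * np.pi)
    amp = np.abs(analytic)
    valid = np.ones(T, dtype=bool)
    valid[0] = valid[-1] = False
    return SpectrumSeries(frequency=freq, amplitude=amp, valid=valid)


# --------------------------------------------------------------------------
# map decomposition
# --------------------------------------------------------------------------

@dataclass
class SpectralField:
    """Instantaneous spectra over the (sector, time) grid.

    Arrays are (n_imf, n_sectors, n_time); ``*_t`` channels come from
    per-row temporal decomposition (Hz), ``*_s`` channels from per-column
    spatial decomposition along the circular sector axis (cycles/sector).
    """

    freq_t: np.ndarray
    amp_t: np.ndarray
    imf_t: np.ndarray
    valid_t: np.ndarray
    freq_s: np.ndarray
    amp_s: np.ndarray
    imf_s: np.ndarray
    valid_s: np.ndarray
    resid_t: np.ndarray          # (n_sectors, n_time)
    dt: float
    n_imf: int
    meta: dict = field(default_factory=dict)

    @property
    def n_sectors(self) -> int:
        return self.freq_t.shape[1]

    @property
    def n_time(self) -> int:
        return self.freq_t.shape[2]

    def save(self, path) -> None:
        np.savez(
            path,
            **{k: getattr(self, k) for k in (
                "freq_t", "amp_t", "imf_t", "valid_t",
                "freq_s", "amp_s", "imf_s", "valid_s", "resid_t",
            )},
            dt=self.dt, n_imf=self.n_imf,
        )

    @classmethod
    def load(cls, path) -> "SpectralField":
        z = np.load(path)
        return cls(
            freq_t=z["freq_t"], amp_t=z["amp_t"], imf_t=z["imf_t"],
            valid_t=z["valid_t"].astype(bool),
            freq_s=z["freq_s"], amp_s=z["amp_s"], imf_s=z["imf_s"],
            valid_s=z["valid_s"].astype(bool), resid_t=z["resid_t"],
            dt=float(z["dt"]), n_imf=int(z["n_imf"]),
        )


def decompose_map(amap: ActivityMap, n_imf: int = DEFAULT_N_IMF,
                  sift_config: SiftConfig = SiftConfig(),
                  spatial_boundary: str = "periodic",
                  axes: tuple = ("temporal", "spatial")) -> SpectralField:
    """HHT of every row (temporal) and column (spatial) of an activity map.

    The spatial axis follows the closed cell boundary; with
    ``spatial_boundary='periodic'`` each column is decomposed on a
    three-period extension and the central period kept, avoiding artificial
    boundary extrema.  Degenerate series (too few extrema) leave their
    channels flagged invalid.
    """
    if spatial_boundary not in ("periodic", "open"):
        raise ValueError("spatial_boundary must be 'periodic' or 'open'")
    v = np.asarray(amap.values, dtype=float)
    S, T = v.shape
    if S < 8 or T < 8:
        raise ValueError("map must be at least 8 x 8 for spectral decomposition")

    shape = (n_imf, S, T)
    out = {k: np.full(shape, np.nan) for k in ("freq_t", "amp_t", "freq_s", "amp_s")}
    out["imf_t"] = np.zeros(shape)
    out["imf_s"] = np.zeros(shape)
    out["valid_t"] = np.zeros(shape, dtype=bool)
    out["valid_s"] = np.zeros(shape, dtype=bool)
    resid_t = np.zeros((S, T))

    if "temporal" in axes:
        for s in range(S):
            dec = emd(v[s], n_imf, sift_config)
            resid_t[s] = dec.residual
            for i in range(n_imf):
                spec = hilbert_spectrum(dec.imfs[i], amap.dt)
                out["imf_t"][i, s] = dec.imfs[i]
                out["freq_t"][i, s] = spec.frequency
                out["amp_t"][i, s] = spec.amplitude
                out["valid_t"][i, s] = spec.valid & (i < dec.n_active)

    if "spatial" in axes:
        for t in range(T):
            col = v[:, t]
            if spatial_boundary == "periodic":
                ext = np.concatenate([col, col, col])
                dec = emd(ext, n_imf, sift_config)
                sl = slice(S, 2 * S)
            else:
                dec = emd(col, n_imf, sift_config)
                sl = slice(0, S)
            for i in range(n_imf):
                spec = hilbert_spectrum(dec.imfs[i], 1.0)   # cycles/sector
                out["imf_s"][i, :, t] = dec.imfs[i][sl]
                out["freq_s"][i, :, t] = spec.frequency[sl]
                out["amp_s"][i, :, t] = spec.amplitude[sl]
                out["valid_s"][i, :, t] = spec.valid[sl] & (i < dec.n_active)

    return SpectralField(
        freq_t=out["freq_t"], amp_t=out["amp_t"], imf_t=out["imf_t"],
        valid_t=out["valid_t"], freq_s=out["freq_s"], amp_s=out["amp_s"],
        imf_s=out["imf_s"], valid_s=out["valid_s"], resid_t=resid_t,
        dt=amap.dt, n_imf=n_imf,
        meta={"spatial_boundary": spatial_boundary},
    )


def reconstruct_imf_map(field: SpectralField, imf_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-IMF velocity map and its integrated displacement map.

    ``imf_index`` is zero-based.  The displacement map is the cumulative
    time integral of the IMF velocity (um, assuming velocities in um/min
    and dt in seconds); seeded from zero, i.e. relative to the first true
    edge position.
    """
    vmap = field.imf_t[imf_index]
    disp = np.cumsum(vmap, axis=1) * field.dt / 60.0
    return vmap, disp
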