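"""Coupling between edge motion regimens and windowed signaling activity.

Given a protrusion velocity map, band-wise biosensor activity maps sampled
on the same sector grid, and a motion-regimen labeling, this module
quantifies per-regimen activity levels and the lagged cross-correlation
between edge velocity and activity.

Lag conventions.  ``xcorr`` correlates v(t) with a(t + lag): a peak at a
positive lag means the activity follows the motion.  ``regimen_xcorr``
reports curves on the conventional plotting axis of edge-motion/signaling
studies, where activity that is *delayed* relative to protrusion peaks at a
*negative* lag; the two axes are mirror images of each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .srm import RegionLabeling
from .windowing import ActivityMap

logger = logging.getLogger(__name__)

MIN_RUN_FRAMES = 20


# --------------------------------------------------------------------------
# cross-correlation curves
# --------------------------------------------------------------------------

@dataclass
class XCorrCurve:
    lags: np.ndarray             # seconds
    values: np.ndarray           # mean curve, in [-1, 1]
    n_eff: np.ndarray            # paired samples per lag
    bounds: np.ndarray           # heuristic 95% bounds, +-1.96/sqrt(n_eff)
    per_sector: Optional[np.ndarray] = None    # (n_sectors, n_lags)

    def extremum_lag(self) -> float:
        k = int(np.nanargmax(np.abs(self.values)))
        return float(self.lags[k])

    def significant(self) -> bool:
        """Whether any lobe exceeds chance at the 5% family-wise level.

        The per-lag ``bounds`` are pointwise; testing every lag against
        them would flag white noise in about half the curves, so the curve
        test applies a Sidak correction over the number of lags.
        """
        from scipy.stats import norm

        m = max(int(np.sum(np.isfinite(self.values))), 1)
        alpha_c = 1.0 - 0.95 ** (1.0 / m)
        factor = norm.ppf(1.0 - alpha_c / 2.0) / 1.96
        with np.errstate(invalid="ignore"):
            return bool(np.any(np.abs(self.values) > factor * self.bounds))

    def fwhm(self) -> Optional[float]:
        """Full width at half maximum of the dominant significant lobe,
        measured on the averaged curve with linear interpolation."""
        if not self.significant():
            return None
        k = int(np.nanargmax(np.abs(self.values)))
        if not np.abs(self.values[k]) > self.bounds[k]:
            return None
        peak = self.values[k]
        half = abs(peak) / 2.0
        y = self.values * np.sign(peak)
        left = self.lags[k]
        for i in range(k, 0, -1):
            if y[i - 1] < half <= y[i]:
                frac = (half - y[i - 1]) / (y[i] - y[i - 1])
                left = self.lags[i - 1] + frac * (self.lags[i] - self.lags[i - 1])
                break
        else:
            left = self.lags[0]
        right = self.lags[k]
        for i in range(k, len(y) - 1):
            if y[i + 1] < half <= y[i]:
                frac = (y[i] - half) / (y[i] - y[i + 1])
                right = self.lags[i] + frac * (self.lags[i + 1] - self.lags[i])
                break
        else:
            right = self.lags[-1]
        return float(right - left)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return np.nan, n
    xv, yv = x[ok] - x[ok].mean(), y[ok] - y[ok].mean()
    sx, sy = xv.std(), yv.std()
    if sx < 1e-12 or sy < 1e-12:
        return np.nan, n
    return float(np.mean(xv * yv) / (sx * sy)), n


def xcorr(velocity: np.ndarray, activity: np.ndarray, max_lag: float,
          dt: float) -> XCorrCurve:
    """Lagged Pearson correlation of one sector's velocity and activity.

    curve(lag) = corr( v(t), a(t + lag) ) at integer-frame lags up to
    ``max_lag`` seconds; pairwise-complete samples, mean subtraction only.
    Positive-lag peak = activity follows motion.
    """
    v = np.asarray(velocity, dtype=float)
    a = np.asarray(activity, dtype=float)
    n = min(len(v), len(a))
    v, a = v[:n], a[:n]
    if np.sum(np.isfinite(v) & np.isfinite(a)) < MIN_RUN_FRAMES:
        raise ValueError(f"need >= {MIN_RUN_FRAMES} valid paired samples")
    K = int(round(max_lag / dt))
    lags = np.arange(-K, K + 1)
    vals = np.full(len(lags), np.nan)
    n_eff = np.zeros(len(lags), dtype=int)
    for idx, k in enumerate(lags):
        if k >= 0:
            r, m = _pearson(v[: n - k], a[k:])
        else:
            r, m = _pearson(v[-k:], a[: n + k])
        vals[idx], n_eff[idx] = r, m
    with np.errstate(divide="ignore"):
        bounds = np.where(n_eff > 0, 1.96 / np.sqrt(np.maximum(n_eff, 1)), np.inf)
    return XCorrCurve(lags=lags * dt, values=vals, n_eff=n_eff, bounds=bounds)


# --------------------------------------------------------------------------
# per-regimen summaries
# --------------------------------------------------------------------------

def regimen_activity(activity_map: ActivityMap, labeling: RegionLabeling) -> dict:
    """Activity distribution per motion regimen.

    Columns of the activity map beyond the labeling grid (velocity maps
    have one column fewer than biosensor maps) are ignored.
    """
    S, T = labeling.labels.shape
    vals = activity_map.values[:, :T]
    if vals.shape[0] != S:
        raise ValueError("labeling and activity map sector grids differ")
    out = {}
    for r in range(labeling.n_regions):
        sel = vals[labeling.labels[:, : vals.shape[1]] == r]
        sel = sel[np.isfinite(sel)]
        if len(sel) == 0:
            out[r] = {"n": 0, "mean": np.nan, "median": np.nan, "iqr": np.nan,
                      "values": sel}
            continue
        q1, q3 = np.percentile(sel, [25, 75])
        out[r] = {"n": len(sel), "mean": float(np.mean(sel)),
                  "median": float(np.median(sel)), "iqr": float(q3 - q1),
                  "values": sel}
    return out


def _label_runs(row_labels: np.ndarray, regimen: int, min_run: int) -> list[slice]:
    """Maximal runs of >= min_run frames carrying the given label."""
    is_r = row_labels == regimen
    runs = []
    start = None
    for t, flag in enumerate(is_r):
        if flag and start is None:
            start = t
        elif not flag and start is not None:
            if t - start >= min_run:
                runs.append(slice(start, t))
            start = None
    if start is not None and len(is_r) - start >= min_run:
        runs.append(slice(start, len(is_r)))
    return runs


def regimen_xcorr(velocity_map: ActivityMap,
                  activity_maps_by_band: Sequence[ActivityMap],
                  labeling: RegionLabeling, max_lag: float,
                  min_run: int = MIN_RUN_FRAMES) -> dict:
    """Cross-correlation per (regimen, band) on the reporting lag axis.

    For each sector, time spans are the maximal runs of at least
    ``min_run`` frames carrying the regimen label; per-sector curves are
    averaged into the reported curve.  On the reported axis a negative-lag
    peak means the activity is delayed relative to the motion (matching
    the plotting convention of edge-motion/signaling correlation studies).
    Regimens without a sufficient span in any sector are omitted.
    """
    dt = velocity_map.dt
    K = int(round(max_lag / dt))
    lags_f = np.arange(-K, K + 1)
    S, Tlab = labeling.labels.shape
    result: dict = {}
    for band, amap in enumerate(activity_maps_by_band):
        for r in range(labeling.n_regions):
            sector_curves = []
            for s in range(S):
                runs = _label_runs(labeling.labels[s], r, min_run)
                if not runs:
                    continue
                vals = np.full(len(lags_f), np.nan)
                for idx, k in enumerate(lags_f):
                    xs, ys = [], []
                    for run in runs:
                        for t in range(run.start, run.stop):
                            t2 = t + k
                            if run.start <= t2 < run.stop and t < velocity_map.values.shape[1] \
                                    and t2 < amap.values.shape[1]:
                                xs.append(velocity_map.values[s, t])
                                ys.append(amap.values[s, t2])
                    if len(xs) >= min_run:
                        vals[idx], _ = _pearson(np.asarray(xs), np.asarray(ys))
                if np.any(np.isfinite(vals)):
                    sector_curves.append(vals)
            if not sector_curves:
                logger.debug("regimen %d band %d: no sector spans >= %d frames",
                             r, band, min_run)
                continue
            per_sector = np.asarray(sector_curves)
            with np.errstate(invalid="ignore"):
                mean_curve = np.nanmean(per_sector, axis=0)
                n_eff = np.sum(np.isfinite(per_sector), axis=0)
            # report on the mirrored axis: negative lag = activity delayed
            n_pairs = np.nanmean([np.sum(np.isfinite(c)) for c in per_sector])
            npair_lag = np.maximum((Tlab - np.abs(lags_f)), 1)
            bounds = 1.96 / np.sqrt(npair_lag * max(len(sector_curves), 1))
            curve = XCorrCurve(
                lags=-lags_f[::-1] * dt,
                values=mean_curve[::-1],
                n_eff=(n_eff * npair_lag)[::-1],
                bounds=bounds[::-1],
                per_sector=per_sector[:, ::-1],
            )
            result[(r, band)] = curve
    return result
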