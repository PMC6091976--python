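"""Motion-regimen clustering by statistical region merging (SRM).

Each (sector, time) grid cell carries a 12-dimensional feature vector of
amplitude-weighted instantaneous frequencies,

    phi(s,t) = [ F_{i,t}(s) * A_{i,t}^2(s) / A_max,t^2(s) ]_{i=1..6}
            ++ [ F_{i,s}(t) * A_{i,s}^2(t) / A_max,s^2(t) ]_{i=1..6}

where the quadratic amplitude weights reflect the instantaneous relative
energy carried by each IMF; A_max,t(s) is the maximum amplitude of a sector
along the time axis and A_max,s(t) the maximum of a time point along the
sector axis (taken over all IMF orders, since the weight measures energy
relative to the strongest oscillation present).

Two adjacent regions merge when every feature channel differs by less than
a size-dependent statistical bound with merging delicacy Q:

    |phi_i(R1) - phi_i(R2)| <= sqrt(T^2(R1) + T^2(R2))   for all i = 1..12
    T(R) = sqrt( Rmax^2 * c(Q) / |R|
                 * [ min(|R|, Rmax) * ln(|R|+1) + ln(6 Nt Ns) ] )

with c(Q) = 2^-(Q+3).  Before merging, channels are mapped onto [0, Rmax]
by their fixed physical range (zero to the Nyquist frequency of the
corresponding axis), so the bound scale Rmax is dimensionally coherent,
maps are comparable across cells, and heavy-tailed instantaneous-frequency
outliers cannot compress the scale.  The feature field is median-filtered
over a persistence window (default 3 sectors x 15 frames, circular along
sectors) before merging: motion regimens persist over minutes, and the
filter keeps sample-level spectral noise from scrambling the merge
schedule.  Merging proceeds over the 4-connected grid edges (circular
along sectors, open along time) in ascending order of the max-channel
dissimilarity and is iterated until no pair of adjacent regions fulfils
the merging criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .hht import SpectralField

logger = logging.getLogger(__name__)

# calibration of the unitless constant in T(R): fixed so that on maps of a
# few thousand grid cells the delicacy range Q in [0, 8] spans the full
# coarse-to-fine regime (one or two regimens at Q = 0, shattered regions at
# Q = 8), with the knee of the explained-variance curve near Q = 3
_DELICACY_OFFSET = 3.0


# --------------------------------------------------------------------------
# feature field
# --------------------------------------------------------------------------

@dataclass
class FeatureField:
    phi: np.ndarray              # (12, S, T), physical units (Hz, cycles/sector)
    imputed: np.ndarray          # bool (12, S, T), entries filled by median
    n_imputed: int
    dt: float                    # frame interval, s (sets the temporal Nyquist)

    @property
    def shape(self) -> tuple[int, int]:
        return self.phi.shape[1:]

    def nyquist(self) -> np.ndarray:
        """Physical frequency range per channel (temporal Hz, spatial
        cycles/sector)."""
        n_half = self.phi.shape[0] // 2
        return np.array([0.5 / self.dt] * n_half + [0.5] * n_half)


def feature_field(spectral: SpectralField, normalizer: str = "joint") -> FeatureField:
    """Amplitude-weighted instantaneous-frequency features (12 channels).

    ``normalizer='joint'`` (default) takes A_max over all IMF orders;
    ``'per_imf'`` normalizes each order by its own maximum.  Missing or
    invalid entries are imputed with the per-channel median and flagged.
    """
    if normalizer not in ("joint", "per_imf"):
        raise ValueError("normalizer must be 'joint' or 'per_imf'")
    import warnings

    n_imf, S, T = spectral.freq_t.shape
    phi = np.full((2 * n_imf, S, T), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="All-NaN slice")
        a_t = np.where(spectral.valid_t, spectral.amp_t, np.nan)
        a_s = np.where(spectral.valid_s, spectral.amp_s, np.nan)
        if normalizer == "joint":
            amax_t = np.nanmax(np.abs(a_t), axis=(0, 2), keepdims=True)  # per sector
            amax_s = np.nanmax(np.abs(a_s), axis=(0, 1), keepdims=True)  # per time point
        else:
            amax_t = np.nanmax(np.abs(a_t), axis=2, keepdims=True)
            amax_s = np.nanmax(np.abs(a_s), axis=1, keepdims=True)
        amax_t = np.broadcast_to(amax_t, a_t.shape)
        amax_s = np.broadcast_to(amax_s, a_s.shape)
        for i in range(n_imf):
            f = np.where(spectral.valid_t[i], spectral.freq_t[i], np.nan)
            w = np.where(amax_t[i] > 0, (a_t[i] / amax_t[i]) ** 2, 0.0)
            phi[i] = f * w
        for i in range(n_imf):
            f = np.where(spectral.valid_s[i], spectral.freq_s[i], np.nan)
            w = np.where(amax_s[i] > 0, (a_s[i] / amax_s[i]) ** 2, 0.0)
            phi[n_imf + i] = f * w
    imputed = ~np.isfinite(phi)
    n_imputed = int(imputed.sum())
    if n_imputed:
        logger.debug("imputing %d feature entries with channel medians", n_imputed)
        for c in range(phi.shape[0]):
            finite = phi[c][~imputed[c]]
            med = np.median(finite) if finite.size else 0.0
            phi[c][imputed[c]] = med
    return FeatureField(phi=phi, imputed=imputed, n_imputed=n_imputed, dt=spectral.dt)


# --------------------------------------------------------------------------
# SRM
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SRMConfig:
    q: float = 3.0
    r_max: int = 256             # |R_j|_max; also the feature rescaling range
    circular_sectors: bool = True
    persistence_window: tuple = (3, 15)   # (sectors, frames) median prefilter
    max_passes: int = 10

    def validate(self) -> None:
        if self.q < 0:
            raise ValueError("Q must be >= 0")
        if self.r_max < 1:
            raise ValueError("r_max must be >= 1")


@dataclass
class RegionLabeling:
    labels: np.ndarray           # (S, T) int, contiguous regions
    sizes: np.ndarray            # per region
    means: np.ndarray            # (n_regions, 12) feature means (rescaled units)
    n_regions: int
    q: float


def srm_threshold(region_size: int, cfg: SRMConfig, n_grid: int) -> float:
    """Merging bound T(R) for a region of ``region_size`` grid cells;
    ``n_grid`` is Nt*Ns."""
    r = float(region_size)
    g = float(cfg.r_max)
    log_term = min(r, g) * np.log(r + 1.0) + np.log(6.0 * n_grid)
    return float(np.sqrt(
        g * g * 2.0 ** (-(cfg.q + _DELICACY_OFFSET)) / r * log_term))


def prepare_features(feats: FeatureField, cfg: SRMConfig = SRMConfig()) -> np.ndarray:
    """Clip channels to their physical frequency range, rescale to
    [0, r_max], and median-filter over the persistence window."""
    phi = feats.phi
    nyq = feats.nyquist()
    out = np.empty_like(phi)
    for c in range(phi.shape[0]):
        out[c] = np.clip(phi[c], 0.0, nyq[c]) / nyq[c] * cfg.r_max
    ws, wt = cfg.persistence_window
    S, T = feats.shape
    ws = min(ws if ws % 2 else ws + 1, S if S % 2 else S - 1)
    wt = min(wt if wt % 2 else wt + 1, T if T % 2 else T - 1)
    if ws < 2 and wt < 2:
        return out
    k = max(ws // 2, 0)
    filt = np.empty_like(out)
    for c in range(out.shape[0]):
        padded = np.pad(out[c], ((k, k), (0, 0)), mode="wrap") if (
            cfg.circular_sectors and k) else out[c]
        f = ndimage.median_filter(padded, size=(max(ws, 1), max(wt, 1)), mode="nearest")
        filt[c] = f[k:-k] if (cfg.circular_sectors and k) else f
    return filt


class _UnionFind:
    def __init__(self, n: int, feats: np.ndarray):
        self.parent = np.arange(n)
        self.size = np.ones(n, dtype=np.int64)
        self.sum = feats.copy()              # (n, C) per-root feature sums

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, a: int, b: int) -> None:
        if self.size[a] < self.size[b]:
            a, b = b, a
        self.parent[b] = a
        self.size[a] += self.size[b]
        self.sum[a] += self.sum[b]


def _grid_edges(S: int, T: int, circular: bool) -> np.ndarray:
    """4-connected edges of the S x T grid as (cell_a, cell_b) flat index
    pairs, circular along the sector axis."""
    idx = np.arange(S * T).reshape(S, T)
    right = np.column_stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()])
    if circular and S > 2:
        down = np.column_stack([idx.ravel(), np.roll(idx, -1, axis=0).ravel()])
    else:
        down = np.column_stack([idx[:-1].ravel(), idx[1:].ravel()])
    return np.vstack([right, down])


def srm_cluster(feats: FeatureField, cfg: SRMConfig = SRMConfig()) -> RegionLabeling:
    """Partition the (sector, time) grid into motion regimens.

    Deterministic: edges are processed in ascending max-channel
    dissimilarity with lexicographic (flat-index) tie-breaks, and the scan
    is repeated until no pair of adjacent regions satisfies the merge
    predicate.
    """
    cfg.validate()
    S, T = feats.shape
    n_grid = S * T
    phi = prepare_features(feats, cfg)                   # (12, S, T)
    flat = phi.reshape(phi.shape[0], -1).T               # (S*T, 12)

    edges = _grid_edges(S, T, cfg.circular_sectors)
    weights = np.max(np.abs(flat[edges[:, 0]] - flat[edges[:, 1]]), axis=1)
    order = np.lexsort((edges[:, 1], edges[:, 0], weights))

    uf = _UnionFind(n_grid, flat)
    for _ in range(cfg.max_passes):
        merged = False
        for e in order:
            a = uf.find(int(edges[e, 0]))
            b = uf.find(int(edges[e, 1]))
            if a == b:
                continue
            mean_a = uf.sum[a] / uf.size[a]
            mean_b = uf.sum[b] / uf.size[b]
            ta = srm_threshold(int(uf.size[a]), cfg, n_grid)
            tb = srm_threshold(int(uf.size[b]), cfg, n_grid)
            if np.all(np.abs(mean_a - mean_b) <= np.sqrt(ta * ta + tb * tb)):
                uf.union(a, b)
                merged = True
        if not merged:
            break

    roots = np.array([uf.find(i) for i in range(n_grid)])
    uniq, labels_flat = np.unique(roots, return_inverse=True)
    # relabel in order of first occurrence scanning (s, t)
    first = {}
    for i, lab in enumerate(labels_flat):
        first.setdefault(int(lab), i)
    remap = {old: new for new, old in enumerate(sorted(first, key=first.get))}
    labels_flat = np.array([remap[int(l)] for l in labels_flat])
    labels = labels_flat.reshape(S, T)

    n_regions = len(uniq)
    sizes = np.bincount(labels_flat, minlength=n_regions)
    means = np.zeros((n_regions, flat.shape[1]))
    for r in range(n_regions):
        means[r] = flat[labels_flat == r].mean(axis=0)
    return RegionLabeling(labels=labels, sizes=sizes, means=means,
                          n_regions=n_regions, q=cfg.q)


# --------------------------------------------------------------------------
# Q scan
# --------------------------------------------------------------------------

@dataclass
class QScanResult:
    q_values: np.ndarray
    explained: np.ndarray        # fraction of variance explained per Q
    n_regions: np.ndarray
    knee: float                  # smallest Q past which gains are marginal


def q_scan(feats: FeatureField, q_values: Sequence[float],
           cfg: SRMConfig = SRMConfig()) -> QScanResult:
    """Explained-variance curve over merging delicacy Q.

    Per Q the explained fraction is 1 - SSW/SST of the (prepared) feature
    field, averaged over channels with nonzero total variance.  The knee is
    the Q at which the largest single-step gain occurs — beyond it the
    explained fraction increases only marginally.
    """
    q_values = np.asarray(sorted(q_values), dtype=float)
    if len(q_values) < 2:
        raise ValueError("need at least 2 Q values")
    phi = prepare_features(feats, cfg).reshape(feats.phi.shape[0], -1)   # (12, N)
    sst = np.sum((phi - phi.mean(axis=1, keepdims=True)) ** 2, axis=1)
    keep = sst > 0
    explained = np.zeros(len(q_values))
    n_regions = np.zeros(len(q_values), dtype=int)
    for k, q in enumerate(q_values):
        sub = SRMConfig(q=q, r_max=cfg.r_max, circular_sectors=cfg.circular_sectors,
                        persistence_window=cfg.persistence_window,
                        max_passes=cfg.max_passes)
        lab = srm_cluster(feats, sub)
        n_regions[k] = lab.n_regions
        flat_lab = lab.labels.ravel()
        ssw = np.zeros_like(sst)
        for r in range(lab.n_regions):
            block = phi[:, flat_lab == r]
            ssw += np.sum((block - block.mean(axis=1, keepdims=True)) ** 2, axis=1)
        explained[k] = float(np.mean(1.0 - ssw[keep] / sst[keep])) if keep.any() else 0.0

    gains = np.diff(explained)
    knee = q_values[int(np.argmax(gains)) + 1] if np.any(gains > 0) else q_values[0]
    return QScanResult(q_values=q_values, explained=explained,
                       n_regions=n_regions, knee=float(knee))
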