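"""Single-cell segmentation of fluorescence frames.

A frame is prefiltered with a Gaussian matched to the point-spread function,
thresholded at the first valley of the smoothed intensity histogram after the
background mode, and cleaned up morphologically (small-hole filling, closure,
retain the largest connected component) so exactly one foreground component
remains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, interpolate
from skimage import morphology


# 4-connectivity for foreground components, 8-connectivity for holes.
_STRUCT4 = ndimage.generate_binary_structure(2, 1)
_STRUCT8 = ndimage.generate_binary_structure(2, 2)


@dataclass(frozen=True)
class SegmentationConfig:
    psf_sigma: float = 1.5              # pixels; 0 disables prefiltering
    threshold_override: Optional[float] = None
    closure_radius: int = 3             # pixels
    max_hole_area: int = 100            # pixels^2
    histogram_bins: int = 128
    spline_smoothing: float = 0.05      # smoothing factor on max-normalized counts

    def validate(self) -> None:
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if self.histogram_bins < 32:
            raise ValueError("histogram_bins must be >= 32")


class UnimodalHistogramError(ValueError):
    pass


def auto_threshold(image: np.ndarray, config: SegmentationConfig = SegmentationConfig()) -> float:
    """Histogram-valley threshold separating background from cell foreground.

    A smoothing spline is fitted to the intensity histogram; the returned
    threshold is the intensity of the first local minimum of the smoothed
    histogram after the lowest-intensity local maximum (the background mode).

    Raises
    ------
    UnimodalHistogramError
        If the smoothed histogram has no interior valley; select a threshold
        manually via ``threshold_override`` in that case.
    """
    config.validate()
    if config.threshold_override is not None:
        return float(config.threshold_override)

    data = np.asarray(image, dtype=float).ravel()
    counts, edges = np.histogram(data, bins=config.histogram_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if counts.max() == 0 or np.ptp(data) == 0:
        raise UnimodalHistogramError(
            "intensity histogram is unimodal; select a threshold manually "
            "(threshold_override)"
        )

    # Fit on normalized coordinates so the smoothing factor is scale free.
    x = np.linspace(0.0, 1.0, len(counts))
    y = counts / counts.max()
    spl = interpolate.UnivariateSpline(x, y, s=config.spline_smoothing * len(counts) / 128.0)
    xf = np.linspace(0.0, 1.0, 4096)
    yf = spl(xf)

    d = np.diff(yf)
    maxima = (np.where((d[:-1] > 0) & (d[1:] < 0))[0] + 1).tolist()
    # modes can sit at the histogram ends (boundary maxima)
    if d[0] < 0:
        maxima.insert(0, 0)
    if d[-1] > 0:
        maxima.append(len(yf) - 1)
    maxima = np.asarray(maxima)
    # ignore spurious smoothing wiggles: a mode must reach 5% of the peak
    maxima = maxima[yf[maxima] >= 0.05 * yf.max()]
    # two maxima are distinct modes only if separated by a pronounced
    # valley (below half the lower of the two peaks)
    lo = maxima[0] if len(maxima) else 0
    yv = np.maximum(yf, 0.0)        # spline undershoot is not a real valley
    for hi in maxima[1:]:
        seg = yv[lo:hi + 1]
        vmin = seg.min()
        if vmin < 0.5 * min(yf[lo], yf[hi]):
            # midpoint of the valley floor (ties are common when the modes
            # are well separated and the floor is flat)
            ties = np.where(seg <= vmin + 0.02 * min(yf[lo], yf[hi]))[0]
            valley = lo + int(ties[len(ties) // 2])
            pos = xf[valley]
            return float(centers[0] + pos * (centers[-1] - centers[0]))
        if yf[hi] > yf[lo]:
            lo = hi
    raise UnimodalHistogramError(
        "smoothed histogram is unimodal; select a threshold manually "
        "(threshold_override)"
    )


def segment_frame(image: np.ndarray, config: SegmentationConfig = SegmentationConfig()) -> np.ndarray:
    """Binary single-component cell mask for one frame.

    Pipeline: Gaussian prefilter -> threshold -> fill holes up to
    ``max_hole_area`` -> morphological closure -> keep the largest
    4-connected component.
    """
    config.validate()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or not np.all(np.isfinite(image)):
        raise ValueError("image must be a finite 2-D array")

    smoothed = ndimage.gaussian_filter(image, config.psf_sigma) if config.psf_sigma > 0 else image
    if config.threshold_override is not None:
        thr = float(config.threshold_override)
    else:
        thr = auto_threshold(smoothed, config)
    mask = smoothed > thr
    if not mask.any():
        raise ValueError(f"empty foreground after thresholding at {thr:.3g}")

    mask = fill_small_holes(mask, config.max_hole_area)
    if config.closure_radius > 0:
        mask = ndimage.binary_closing(
            mask, structure=morphology.disk(config.closure_radius))
        mask = fill_small_holes(mask, config.max_hole_area)
    mask = largest_component(mask)
    return mask


def fill_small_holes(mask: np.ndarray, max_area: int) -> np.ndarray:
    """Fill 8-connected background holes of area <= max_area."""
    inv = ~mask
    lab, n = ndimage.label(inv, structure=_STRUCT8)
    if n == 0:
        return mask
    # components touching the border are true background, not holes
    border = np.unique(np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]]))
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    fill = np.zeros(n + 1, dtype=bool)
    for j in range(1, n + 1):
        if j not in border and sizes[j - 1] <= max_area:
            fill[j] = True
    return mask | fill[lab]


def largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=_STRUCT4)
    if n == 0:
        raise ValueError("mask has no foreground component")
    if n == 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return lab == keep


def segment_movie(stack: np.ndarray, config: SegmentationConfig = SegmentationConfig()) -> np.ndarray:
    """Segment every frame of a (T, H, W) stack."""
    return np.stack([segment_frame(frame, config) for frame in stack])
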