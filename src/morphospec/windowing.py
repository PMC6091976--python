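"""Edge-attached sampling windows and activity maps.

The cell interior is subdivided into windows indexed by a band (distance
from the edge) and a slice (arclength position along the edge).  Two
constructions are provided:

* a discrete pixel-space method: every interior pixel is binned by its
  Euclidean distance to the boundary and by the arclength position of its
  nearest boundary pixel (exact partition of each band);
* a sub-pixel method: windows are polygons bounded by sub-pixel isocontours
  of the distance transform and by slice curves obtained by gradient ascent
  of the distance transform from slice start positions on a master contour.

Sampling a per-pixel image over the windows of one band, frame by frame,
produces an activity map (rows = slices/sectors, columns = time).  Edge
velocities are sampled analogously by averaging the signed normal velocity
of the edge nodes falling into each first-band sector.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure
from shapely.geometry import LineString, Point, Polygon, MultiLineString
from shapely.ops import unary_union, polygonize

from .edgetrack import Contour, EdgeMap, extract_contour

logger = logging.getLogger(__name__)

_STRUCT4 = ndimage.generate_binary_structure(2, 1)


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class ActivityMap:
    """Sectors x time matrix of a sampled quantity.

    ``values[s, t]`` is the statistic for sector ``s`` at time ``t``;
    ``counts`` holds the number of samples contributing to each entry
    (0 marks a missing value, stored as NaN).
    """

    values: np.ndarray
    counts: np.ndarray
    units: str
    dt: float
    meta: dict = field(default_factory=dict)

    @property
    def n_sectors(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.values, delimiter=",")
        sidecar = {
            "units": self.units,
            "dt": self.dt,
            "n_sectors": int(self.n_sectors),
            "n_frames": int(self.n_frames),
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
        np.savetxt(path.with_suffix(".counts.csv"), self.counts, delimiter=",", fmt="%d")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ActivityMap":
        path = Path(path)
        values = np.atleast_2d(np.loadtxt(path, delimiter=","))
        sidecar_path = path.with_suffix(path.suffix + ".json")
        units, dt, meta = "unknown", 1.0, {}
        if sidecar_path.exists():
            sc = json.loads(sidecar_path.read_text())
            units, dt, meta = sc.get("units", units), sc.get("dt", dt), sc.get("meta", {})
        counts_path = path.with_suffix(".counts.csv")
        if counts_path.exists():
            counts = np.atleast_2d(np.loadtxt(counts_path, delimiter=",")).astype(int)
        else:
            counts = np.where(np.isnan(values), 0, 1)
        return cls(values=values, counts=counts, units=units, dt=dt, meta=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


@dataclass
class WindowSet:
    """Sampling windows of one frame, indexed by (band m, slice p).

    Discrete windows store flat pixel indices into the mask grid; sub-pixel
    windows store polygons.  ``excluded`` lists (m, p) windows dropped by
    the stated exclusion rules (distance-transform ridges, image border).
    """

    method: str                                   # "discrete" | "subpixel"
    shape: tuple[int, int]
    band_edges: np.ndarray                        # um from edge, length M+1
    slice_edges: np.ndarray                       # um along edge, length P+1
    origin: tuple[float, float]
    pixel_size: float
    pixels: dict = field(default_factory=dict)    # (m, p) -> flat indices
    polygons: dict = field(default_factory=dict)  # (m, p) -> shapely Polygon
    excluded: list = field(default_factory=list)
    contour: Optional[Contour] = None

    @property
    def n_bands(self) -> int:
        return len(self.band_edges) - 1

    @property
    def n_slices(self) -> int:
        return len(self.slice_edges) - 1

    def window_pixels(self, m: int, p: int) -> np.ndarray:
        """Flat indices of pixels whose centers lie in window (m, p)."""
        if self.method == "discrete":
            return self.pixels.get((m, p), np.empty(0, dtype=int))
        poly = self.polygons.get((m, p))
        if poly is None or poly.is_empty:
            return np.empty(0, dtype=int)
        return _pixels_in_polygon(poly, self.shape)


def _pixels_in_polygon(poly: Polygon, shape: tuple[int, int]) -> np.ndarray:
    from matplotlib.path import Path as MplPath

    minx, miny, maxx, maxy = poly.bounds
    x0, x1 = int(np.floor(minx)), int(np.ceil(maxx))
    y0, y1 = int(np.floor(miny)), int(np.ceil(maxy))
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, shape[1] - 1), min(y1, shape[0] - 1)
    if x1 < x0 or y1 < y0:
        return np.empty(0, dtype=int)
    yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    ext = np.asarray(poly.exterior.coords)
    inside = MplPath(ext).contains_points(pts)
    for hole in poly.interiors:
        inside &= ~MplPath(np.asarray(hole.coords)).contains_points(pts)
    sel = pts[inside]
    return sel[:, 1] * shape[1] + sel[:, 0]


# --------------------------------------------------------------------------
# slice-edge helpers
# --------------------------------------------------------------------------

def make_slice_edges(edge_length_um: float, slice_width_um: float = 3.0) -> np.ndarray:
    """Equal slice edges covering [0, L] with width as close as possible to
    the requested ~3 um sector width."""
    n = max(int(round(edge_length_um / slice_width_um)), 1)
    return np.linspace(0.0, edge_length_um, n + 1)


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    b = mask & ~ndimage.binary_erosion(mask, structure=_STRUCT4)
    return np.column_stack(np.nonzero(b))        # (K, 2) as (row, col)


def _snap_origin(origin, boundary_rc: np.ndarray) -> tuple[float, float]:
    """Snap an (x, y) origin to the nearest boundary pixel."""
    ox, oy = origin
    d2 = (boundary_rc[:, 1] - ox) ** 2 + (boundary_rc[:, 0] - oy) ** 2
    k = int(np.argmin(d2))
    if d2[k] > 0:
        logger.warning("origin (%.1f, %.1f) not on boundary; snapped", ox, oy)
    return float(boundary_rc[k, 1]), float(boundary_rc[k, 0])


def _arclengths_on_ring(ring: LineString, pts_xy: np.ndarray, origin_xy,
                        total: float) -> np.ndarray:
    """Arclength (from origin, along ring orientation) of each point."""
    s0 = ring.project(Point(origin_xy))
    s = np.array([ring.project(Point(p)) for p in pts_xy])
    return (s - s0) % total


# --------------------------------------------------------------------------
# discrete windows
# --------------------------------------------------------------------------

def discrete_windows(mask: np.ndarray, b_edges_um: Sequence[float],
                     s_edges_um: Sequence[float], origin: tuple[float, float],
                     pixel_size: float = 0.3,
                     contour: Optional[Contour] = None) -> WindowSet:
    """Discrete pixel-space windows.

    Every pixel of the segmented cell is assigned the distance ``d`` to its
    nearest boundary pixel and the arclength position ``l`` of that boundary
    pixel from the origin; windows bin (d, l) with
    ``b_m < d <= b_{m+1}`` and ``s_p < l <= s_{p+1}``.
    """
    mask = np.asarray(mask, dtype=bool)
    if contour is None:
        contour = extract_contour(mask)
    boundary_rc = _boundary_pixels(mask)
    origin = _snap_origin(origin, boundary_rc)

    bnd = np.zeros_like(mask)
    bnd[boundary_rc[:, 0], boundary_rc[:, 1]] = True
    dist, (iy, ix) = ndimage.distance_transform_edt(~bnd, return_indices=True)

    ring = contour.ring()
    l_boundary = _arclengths_on_ring(
        ring, boundary_rc[:, ::-1].astype(float), origin, contour.length
    )
    l_of = np.full(mask.shape, np.nan)
    l_of[boundary_rc[:, 0], boundary_rc[:, 1]] = l_boundary

    cell = np.nonzero(mask)
    d_px = dist[cell]
    l_px = l_of[iy[cell], ix[cell]]

    b_px = np.asarray(b_edges_um, dtype=float) / pixel_size
    s_px = np.asarray(s_edges_um, dtype=float) / pixel_size
    m_idx = np.searchsorted(b_px, d_px, side="left") - 1
    p_idx = np.searchsorted(s_px, l_px, side="left") - 1
    # the slice axis is circular: l == 0 (nearest boundary pixel is the
    # origin itself) wraps to the last slice, l == L stays in it
    p_idx = np.where(l_px <= s_px[0], len(s_px) - 2, p_idx)
    p_idx = np.clip(p_idx, None, len(s_px) - 2)

    flat = cell[0] * mask.shape[1] + cell[1]
    ws = WindowSet(
        method="discrete",
        shape=mask.shape,
        band_edges=np.asarray(b_edges_um, dtype=float),
        slice_edges=np.asarray(s_edges_um, dtype=float),
        origin=origin,
        pixel_size=pixel_size,
        contour=contour,
    )
    valid = (m_idx >= 0) & (m_idx < len(b_px) - 1) & (d_px > b_px[0])
    for m in range(len(b_px) - 1):
        in_m = valid & (m_idx == m)
        for p in range(len(s_px) - 1):
            sel = flat[in_m & (p_idx == p)]
            if len(sel):
                ws.pixels[(m, p)] = np.sort(sel)
    return ws


# --------------------------------------------------------------------------
# sub-pixel windows
# --------------------------------------------------------------------------

def _isocontour(mask: np.ndarray, dist: np.ndarray, level_px: float) -> np.ndarray:
    """Sub-pixel isocontour of the distance transform, as (x, y) ring."""
    if level_px <= 0:
        rings = measure.find_contours(mask.astype(float), 0.5)
    else:
        rings = measure.find_contours(dist, level_px)
    if not rings:
        raise ValueError(f"no isocontour at distance level {level_px} px")
    ring = max(rings, key=len)
    pts = np.column_stack([ring[:, 1], ring[:, 0]])
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[:1]])
    return pts


def _gradient_ascent(dist, gx_i, gy_i, start_xy, stop_level,
                     step: float = 0.5, tol: float = 1e-3,
                     max_steps: int = 10000):
    """Ascend the distance transform from ``start_xy`` until crossing
    ``stop_level``; returns (polyline, stalled)."""
    h, w = dist.shape
    pos = np.array(start_xy, dtype=float)
    path = [pos.copy()]
    for _ in range(max_steps):
        yx = ([np.clip(pos[1], 0, h - 1)], [np.clip(pos[0], 0, w - 1)])
        g = np.array([gx_i(yx), gy_i(yx)]).ravel()
        norm = np.linalg.norm(g)
        if norm < tol:
            return np.array(path), True
        pos = pos + step * g / norm
        path.append(pos.copy())
        d_here = ndimage.map_coordinates(dist, [[pos[1]], [pos[0]]], order=1)[0]
        if d_here >= stop_level:
            return np.array(path), False
    return np.array(path), True


def subpixel_windows(mask: np.ndarray, b_values_um: Sequence[float],
                     s_edges_um: Sequence[float],
                     origin: tuple[float, float],
                     pixel_size: float = 0.3,
                     master_level: float = 0.0,
                     contour: Optional[Contour] = None) -> WindowSet:
    """Sub-pixel polygon windows bounded by distance-transform isocontours
    and gradient-ascent slice curves.

    ``b_values_um`` are the band isovalues (first is typically 0 = the cell
    edge); slice start positions sit at arclengths ``s_edges_um`` along the
    master contour (default: the edge itself).  Windows adjacent to a
    stalled ascent (distance-transform ridge) or to the image border are
    excluded and logged.
    """
    mask = np.asarray(mask, dtype=bool)
    if contour is None:
        contour = extract_contour(mask)
    b_um = np.asarray(b_values_um, dtype=float)
    if master_level not in b_um:
        raise ValueError("master_level must be one of the band isovalues")
    s_um = np.asarray(s_edges_um, dtype=float)
    dist = ndimage.distance_transform_edt(mask)
    b_px = b_um / pixel_size

    iso = {m: _isocontour(mask, dist, b) for m, b in enumerate(b_px)}

    # master contour, arclength aligned at the origin
    mu = int(np.where(b_um == master_level)[0][0])
    master = iso[mu]
    ring = LineString(master)
    total = ring.length
    boundary_rc = _boundary_pixels(mask)
    origin = _snap_origin(origin, boundary_rc)
    s0 = ring.project(Point(origin))

    # interpolated gradient field of the distance transform
    gy, gx = np.gradient(dist)
    from scipy.interpolate import RegularGridInterpolator
    yy = np.arange(dist.shape[0])
    xx = np.arange(dist.shape[1])
    gx_i = RegularGridInterpolator((yy, xx), gx, bounds_error=False, fill_value=0.0)
    gy_i = RegularGridInterpolator((yy, xx), gy, bounds_error=False, fill_value=0.0)

    # scale slice positions from the edge to the master contour length
    s_px = s_um / pixel_size
    span = s_px[-1] - s_px[0]
    frac = (s_px - s_px[0]) / span if span > 0 else s_px * 0.0
    stop_level = b_px[-1] + 0.75

    curves = []
    stalled_p = set()
    for p, f in enumerate(frac[:-1]):
        start = ring.interpolate((s0 + f * total) % total)
        path, stalled = _gradient_ascent(
            dist, gx_i, gy_i, (start.x, start.y), stop_level
        )
        if stalled:
            stalled_p.add(p)
            logger.warning("gradient ascent stalled at slice start %d (ridge)", p)
        # extend outward a little past the edge so the split is clean
        if len(path) >= 2:
            d0 = path[0] - path[1]
            d0 /= max(np.linalg.norm(d0), 1e-9)
            path = np.vstack([path[0] + 1.5 * d0, path])
        curves.append(LineString(path))

    ws = WindowSet(
        method="subpixel",
        shape=mask.shape,
        band_edges=b_um,
        slice_edges=s_um,
        origin=origin,
        pixel_size=pixel_size,
        contour=contour,
    )

    n_slices = len(frac) - 1
    h, w_img = mask.shape
    for m in range(len(b_px) - 1):
        outer = Polygon(iso[m]).buffer(0)
        inner = Polygon(iso[m + 1]).buffer(0)
        band = outer.difference(inner)
        pieces = polygonize(unary_union([band.boundary, MultiLineString(curves)]))
        assigned: dict[int, list] = {}
        for piece in pieces:
            if not band.buffer(1e-6).contains(piece.representative_point()):
                continue
            rp = piece.representative_point()
            s_here = (ring.project(rp) - s0) % total
            p = min(int(s_here / total * n_slices), n_slices - 1)
            assigned.setdefault(p, []).append(piece)
        for p, plist in assigned.items():
            poly = unary_union(plist)
            if poly.geom_type == "MultiPolygon":
                poly = max(poly.geoms, key=lambda g: g.area)
            reason = None
            if p in stalled_p or ((p + 1) % n_slices) in stalled_p:
                reason = "ridge"
            minx, miny, maxx, maxy = poly.bounds
            if minx < 1 or miny < 1 or maxx > w_img - 2 or maxy > h - 2:
                reason = reason or "border"
            if reason:
                ws.excluded.append((m, p, reason))
            else:
                ws.polygons[(m, p)] = poly
    return ws


# --------------------------------------------------------------------------
# propagation through time
# --------------------------------------------------------------------------

PROPAGATION_METHODS = (
    "constant_slice_count",
    "origin_by_displacement",
    "origin_by_closest_point",
    "follow_edge_vectors",
)


def propagate_windows(window_set: WindowSet, mask_t1: np.ndarray,
                      edgemap: Optional[EdgeMap] = None,
                      method: str = "constant_slice_count") -> WindowSet:
    """Windows for the next frame.

    * ``constant_slice_count`` (default): slice count preserved; slice
      widths rescale with the new edge length; origin follows the closest
      boundary point.
    * ``origin_by_closest_point`` / ``origin_by_displacement``: absolute
      slice spacing preserved (slice count may change); only the origin is
      propagated.
    * ``follow_edge_vectors``: every slice start follows the edge
      displacement vector adjacent to it.

    Bands always keep their distance from the new cell edge.
    """
    if method not in PROPAGATION_METHODS:
        raise ValueError(f"unknown propagation method {method!r}")
    mask_t1 = np.asarray(mask_t1, dtype=bool)
    contour1 = extract_contour(mask_t1)
    px = window_set.pixel_size
    old_L_um = window_set.contour.length * px
    new_L_um = contour1.length * px

    if method == "origin_by_displacement":
        if edgemap is None:
            raise ValueError("origin_by_displacement requires an edge map")
        d2 = np.sum((edgemap.nodes - np.asarray(window_set.origin)) ** 2, axis=1)
        d2[~np.isfinite(edgemap.displacements[:, 0])] = np.inf
        k = int(np.argmin(d2))
        new_origin = tuple(edgemap.nodes[k] + edgemap.displacements[k])
        s_edges = window_set.slice_edges
    elif method == "follow_edge_vectors":
        if edgemap is None:
            raise ValueError("follow_edge_vectors requires an edge map")
        s_edges = _map_slice_edges(window_set, edgemap, contour1)
        new_origin = window_set.origin
        # origin follows its own vector
        ring1 = contour1.ring()
        pt = ring1.interpolate(0.0)
        new_origin = (pt.x, pt.y)
    else:
        new_origin = _closest_boundary_point(window_set.origin, mask_t1)
        if method == "constant_slice_count":
            fracs = (window_set.slice_edges - window_set.slice_edges[0]) / (
                window_set.slice_edges[-1] - window_set.slice_edges[0]
            )
            s_edges = fracs * new_L_um
        else:
            s_edges = window_set.slice_edges

    if window_set.method == "discrete":
        return discrete_windows(
            mask_t1, window_set.band_edges, s_edges, new_origin, px, contour=contour1
        )
    return subpixel_windows(
        mask_t1, window_set.band_edges, s_edges, new_origin, px,
        master_level=window_set.band_edges[0], contour=contour1,
    )


def _closest_boundary_point(origin, mask) -> tuple[float, float]:
    boundary_rc = _boundary_pixels(mask)
    return _snap_origin(origin, boundary_rc)


def _map_slice_edges(window_set: WindowSet, edgemap: EdgeMap,
                     contour1: Contour) -> np.ndarray:
    """Map slice boundary arclengths through the edge correspondence."""
    px = window_set.pixel_size
    ring0 = window_set.contour.ring()
    s_origin = ring0.project(Point(window_set.origin))
    valid = np.isfinite(edgemap.target_params)
    p_src = (edgemap.params[valid] - s_origin) % window_set.contour.length
    o_tgt = edgemap.target_params[valid]
    order = np.argsort(p_src)
    p_src, o_tgt = p_src[order], o_tgt[order]
    s_old_px = window_set.slice_edges / px
    o_new = np.interp(s_old_px, p_src, o_tgt)
    o_new_um = np.sort(o_new) * px
    return o_new_um


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------

STATISTICS = {
    "mean": np.mean,
    "sd": lambda v: np.std(v, ddof=1) if len(v) > 1 else 0.0,
    "max": np.max,
    "min": np.min,
    "median": np.median,
}


def sample_windows(image: np.ndarray, window_set: WindowSet, statistic: str = "mean",
                   band: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice statistic of one band for one frame.

    Returns ``(values, counts)`` of length ``n_slices``; empty windows give
    NaN with count 0.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {sorted(STATISTICS)}")
    fn = STATISTICS[statistic]
    flat = np.asarray(image, dtype=float).ravel()
    values = np.full(window_set.n_slices, np.nan)
    counts = np.zeros(window_set.n_slices, dtype=int)
    for p in range(window_set.n_slices):
        idx = window_set.window_pixels(band, p)
        counts[p] = len(idx)
        if len(idx):
            values[p] = fn(flat[idx])
    return values, counts


def sample_movie(stack: np.ndarray, window_sets: Sequence[WindowSet],
                 statistic: str = "mean", band: int = 0, dt: float = 10.0,
                 units: str = "a.u.") -> ActivityMap:
    """Sample a per-pixel activity stack into a sectors x time map."""
    cols = [sample_windows(img, ws, statistic, band) for img, ws in zip(stack, window_sets)]
    values = np.column_stack([c[0] for c in cols])
    counts = np.column_stack([c[1] for c in cols])
    return ActivityMap(values=values, counts=counts, units=units, dt=dt,
                       meta={"statistic": statistic, "band": band})


def sector_velocity_map(edgemaps: Sequence[EdgeMap],
                        window_sets: Sequence[WindowSet],
                        dt: float = 10.0) -> ActivityMap:
    """Mean signed normal velocity per first-band sector and frame pair.

    Entry (s, t) averages the velocities of the edge nodes (frame t ->
    t+1) whose source arclength falls into sector s of frame t's windows;
    the contributing vector count is stored alongside.  The map has
    ``n_frames - 1`` columns.
    """
    n_t = len(edgemaps)
    n_s = window_sets[0].n_slices
    values = np.full((n_s, n_t), np.nan)
    counts = np.zeros((n_s, n_t), dtype=int)
    for t, emap in enumerate(edgemaps):
        ws = window_sets[min(t, len(window_sets) - 1)]
        px = ws.pixel_size
        ring = ws.contour.ring()
        s_origin = ring.project(Point(ws.origin))
        l_um = ((emap.params - s_origin) % ws.contour.length) * px
        edges = ws.slice_edges
        sec = np.searchsorted(edges, l_um, side="right") - 1
        sec = np.clip(sec, 0, ws.n_slices - 1)
        for s in range(ws.n_slices):
            v = emap.velocities[(sec == s) & np.isfinite(emap.velocities)]
            counts[s, t] = len(v)
            if len(v):
                values[s, t] = float(np.mean(v))
            else:
                logger.debug("sector %d frame %d: no displacement vectors", s, t)
    return ActivityMap(values=values, counts=counts, units="um/min", dt=dt,
                       meta={"kind": "protrusion"})
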