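"""Lumen detection, periodic spline fitting and wall unwrapping.

The wall is straightened by fitting a closed smoothing spline to the lumen
edge of each trans-axial slice and resampling the image along lines
perpendicular to the spline at equal arc intervals.  Rows of the unwrapped
image are arc positions along the lumen; columns are signed radial offsets
along the outward normal (column ``inner_margin`` sits exactly on the
spline).  The transform is invertible in closed form, which is how extracted
boundary contours are wrapped back onto the trans-axial slices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import interpolate
from scipy.ndimage import center_of_mass, map_coordinates
from shapely.geometry import LineString, Point, Polygon
from skimage.measure import find_contours

from .volume import Tomogram


class LumenNotFoundError(ValueError):
    """No closed below-threshold region enclosing the centre hint."""


class SplineFitError(ValueError):
    """Spline fit failed (too few points or self-intersecting result)."""


def bilateral_filter_axial(
    vol: Tomogram,
    sigma_spatial_vox: float = 1.5,
    sigma_range_grey: float | None = None,
    window_vox: int = 7,
) -> Tomogram:
    """1D bilateral filter applied along the vessel axis.

    Each voxel is replaced by the range-and-distance-weighted mean of its 1D
    axial neighbourhood; windows truncate at volume edges.  When
    ``sigma_range_grey`` is None it is estimated robustly as the MAD-based
    noise SD of axial first differences.
    """
    if window_vox < 1 or window_vox % 2 == 0:
        raise ValueError("window_vox must be odd and >= 1")
    if not sigma_spatial_vox > 0:
        raise ValueError("sigma_spatial_vox must be > 0")
    arr = np.moveaxis(vol.values, vol.axial_axis, 0).astype(np.float64)
    if sigma_range_grey is None:
        if arr.shape[0] > 1:
            d = np.diff(arr, axis=0)
            sigma_range_grey = 1.4826 * float(np.median(np.abs(d))) / math.sqrt(2.0)
        else:
            sigma_range_grey = 0.0
        sigma_range_grey = max(sigma_range_grey, 1e-6)
    elif not sigma_range_grey > 0:
        raise ValueError("sigma_range_grey must be > 0")

    h = window_vox // 2
    n = arr.shape[0]
    num = np.zeros_like(arr)
    den = np.zeros_like(arr)
    inv2ss = 1.0 / (2.0 * sigma_spatial_vox**2)
    inv2sr = 1.0 / (2.0 * sigma_range_grey**2)
    for off in range(-h, h + 1):
        w_sp = math.exp(-(off**2) * inv2ss)
        src = slice(max(off, 0), n + min(off, 0))
        dst = slice(max(-off, 0), n + min(-off, 0))
        shifted = arr[src]
        centre = arr[dst]
        w = w_sp * np.exp(-((shifted - centre) ** 2) * inv2sr)
        num[dst] += w * shifted
        den[dst] += w
    out = num / den
    out = np.moveaxis(out, 0, vol.axial_axis)
    return vol.with_values(out.astype(vol.values.dtype))


def _polygon_area(points_xy: np.ndarray) -> float:
    x, y = points_xy[:, 0], points_xy[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def detect_lumen_edge(
    slice2d: np.ndarray,
    wall_threshold: float,
    centre_hint: tuple[float, float] | None = None,
) -> np.ndarray:
    """Trace the lumen edge of one trans-axial slice.

    Returns the inner wall boundary as an ordered, counter-clockwise (in the
    (x=col, y=row) frame) sequence of sub-voxel points ``(x, y)`` obtained by
    marching-squares contouring at ``wall_threshold``.  The lumen contour is
    the smallest closed contour enclosing ``centre_hint`` (default: centroid
    of the below-threshold interior).
    """
    slice2d = np.asarray(slice2d, dtype=float)
    if centre_hint is None:
        below = slice2d < wall_threshold
        if not below.any():
            raise LumenNotFoundError("no below-threshold interior in slice")
        cy, cx = center_of_mass(below)
        centre_hint = (cx, cy)
    cx, cy = float(centre_hint[0]), float(centre_hint[1])
    iy = min(max(int(round(cy)), 0), slice2d.shape[0] - 1)
    ix = min(max(int(round(cx)), 0), slice2d.shape[1] - 1)
    if slice2d[iy, ix] >= wall_threshold:
        raise LumenNotFoundError("centre hint does not sit in a below-threshold interior")
    pt = Point(cx, cy)

    best = None
    best_area = np.inf
    for cont in find_contours(slice2d, wall_threshold):
        if not np.allclose(cont[0], cont[-1]):
            continue  # open contour touching the image border
        xy = cont[:, ::-1]  # (row,col) -> (x,y)
        if len(xy) < 8:
            continue
        poly = Polygon(xy)
        if not poly.is_valid or not poly.contains(pt):
            continue
        if poly.area < best_area:
            best_area = poly.area
            best = xy
    if best is None:
        raise LumenNotFoundError("lumen not found: no closed contour encloses the centre hint")
    pts = best[:-1]  # drop duplicated closing point
    if _polygon_area(pts) < 0:
        pts = pts[::-1]
    return np.ascontiguousarray(pts)


@dataclass
class LumenSpline:
    """Closed periodic smoothing spline of the lumen edge of one slice.

    Arc positions ``s`` (in voxels along the curve) are measured from the
    point where the curve crosses angle 0 seen from its centroid, so rows of
    unwrapped images are angularly aligned across slices.
    """

    tck: tuple
    perimeter: float
    centroid: tuple[float, float]
    smoothing_parameter: float
    _u_grid: np.ndarray
    _arclen: np.ndarray
    _s0: float

    def _u_of_s(self, s: np.ndarray) -> np.ndarray:
        s = np.mod(np.asarray(s, dtype=float) + self._s0, self.perimeter)
        return np.interp(s, self._arclen, self._u_grid)

    def point(self, s: np.ndarray) -> np.ndarray:
        """Evaluate (x, y) at arc position(s) s."""
        u = self._u_of_s(s)
        x, y = interpolate.splev(u, self.tck)
        return np.stack([np.atleast_1d(x), np.atleast_1d(y)], axis=-1)

    def tangent(self, s: np.ndarray) -> np.ndarray:
        u = self._u_of_s(s)
        dx, dy = interpolate.splev(u, self.tck, der=1)
        t = np.stack([np.atleast_1d(dx), np.atleast_1d(dy)], axis=-1)
        return t / np.linalg.norm(t, axis=-1, keepdims=True)

    def normal(self, s: np.ndarray) -> np.ndarray:
        """Outward unit normal; for the CCW parameterisation this is (t_y, -t_x)."""
        t = self.tangent(s)
        return np.stack([t[..., 1], -t[..., 0]], axis=-1)

    def curvature(self, s: np.ndarray) -> np.ndarray:
        u = self._u_of_s(s)
        dx, dy = interpolate.splev(u, self.tck, der=1)
        ddx, ddy = interpolate.splev(u, self.tck, der=2)
        num = np.abs(np.asarray(dx) * ddy - np.asarray(dy) * ddx)
        den = (np.asarray(dx) ** 2 + np.asarray(dy) ** 2) ** 1.5
        return num / np.maximum(den, 1e-12)


def fit_lumen_spline(points: np.ndarray, smoothing_parameter: float = 0.0) -> LumenSpline:
    """Fit a closed periodic smoothing spline to ordered lumen-edge points.

    ``smoothing_parameter`` is the total squared-residual budget ``s`` of the
    underlying FITPACK fit; 0 interpolates the points exactly.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array of (x, y)")
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 8:
        raise SplineFitError(f"need >= 8 points to fit a closed spline, got {len(pts)}")
    if smoothing_parameter < 0:
        raise ValueError("smoothing_parameter must be >= 0")
    if _polygon_area(pts) < 0:
        pts = pts[::-1]
    closed = np.vstack([pts, pts[:1]])
    tck, _ = interpolate.splprep(
        [closed[:, 0], closed[:, 1]], s=smoothing_parameter, per=1, quiet=2
    )
    u_grid = np.linspace(0.0, 1.0, 4097)
    x, y = interpolate.splev(u_grid, tck)
    dense = np.stack([x, y], axis=-1)
    if not LineString(dense).is_simple:
        raise SplineFitError("fitted spline self-intersects")
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = float(arclen[-1])
    centroid = (float(np.mean(x[:-1])), float(np.mean(y[:-1])))
    # anchor arc origin at the crossing of angle 0 from the centroid
    ang = np.arctan2(y[:-1] - centroid[1], x[:-1] - centroid[0])
    i0 = int(np.argmin(np.abs(ang)))
    s0 = float(arclen[i0])
    return LumenSpline(
        tck=tck,
        perimeter=perimeter,
        centroid=centroid,
        smoothing_parameter=smoothing_parameter,
        _u_grid=u_grid,
        _arclen=arclen,
        _s0=s0,
    )


@dataclass
class UnwrapTransform:
    """Invertible mapping between the unwrapped frame and a trans-axial slice.

    Row ``r`` corresponds to arc position ``r * perimeter / n_rows``; column
    ``c`` to radial offset ``c - inner_margin`` voxels along the outward
    normal.  ``to_plane`` is the closed-form inverse used for re-wrapping.
    """

    spline: LumenSpline
    n_rows: int
    n_cols: int
    inner_margin: float
    points: np.ndarray        # (n_rows, 2) spline points at the row arc samples
    normals: np.ndarray       # (n_rows, 2) outward unit normals
    flagged_rows: np.ndarray  # rows whose normals cross before outer depth

    @property
    def row_spacing(self) -> float:
        return self.spline.perimeter / self.n_rows

    def to_plane(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Map (row, col) unwrapped coordinates to trans-axial (x, y)."""
        rows = np.asarray(rows, dtype=float)
        cols = np.asarray(cols, dtype=float)
        if np.any(rows < 0):
            bad = np.flatnonzero(np.atleast_1d(rows) < 0)
            raise ValueError(f"negative row indices at positions {bad.tolist()}")
        if np.any(rows >= self.n_rows) or np.any(cols < 0) or np.any(cols >= self.n_cols):
            bad = np.flatnonzero(
                (np.atleast_1d(rows) >= self.n_rows)
                | (np.atleast_1d(cols) < 0)
                | (np.atleast_1d(cols) >= self.n_cols)
            )
            raise ValueError(f"points outside the unwrapped frame at positions {bad.tolist()}")
        s = rows * self.row_spacing
        p = self.spline.point(s)
        n = self.spline.normal(s)
        off = (cols - self.inner_margin)[..., None]
        return p + off * n

    def to_unwrapped(self, points_xy: np.ndarray) -> np.ndarray:
        """Numerically invert: trans-axial (x, y) -> fractional (row, col).

        Coarse nearest-arc-sample search followed by a fine local foot-point
        search, so the inversion stays accurate at large radial offsets even
        when the spline wobbles.
        """
        q = np.atleast_2d(np.asarray(points_xy, dtype=float))
        d = q[:, None, :] - self.points[None, :, :]
        dist2 = np.einsum("ijk,ijk->ij", d, d)
        i0 = np.argmin(dist2, axis=1)
        # refine the arc position on a fine grid around the coarse match
        offsets = np.linspace(-1.5, 1.5, 61)
        s_grid = (i0[:, None] + offsets[None, :]) * self.row_spacing
        p_grid = self.spline.point(np.mod(s_grid.ravel(), self.spline.perimeter))
        p_grid = p_grid.reshape(len(q), len(offsets), 2)
        dist2f = np.sum((q[:, None, :] - p_grid) ** 2, axis=-1)
        jbest = np.argmin(dist2f, axis=1)
        s_best = np.mod(s_grid[np.arange(len(q)), jbest], self.spline.perimeter)
        p_best = self.spline.point(s_best)
        n_best = self.spline.normal(s_best)
        dq = q - p_best
        col = np.einsum("ij,ij->i", dq, n_best) + self.inner_margin
        row = np.mod(s_best / self.row_spacing, self.n_rows)
        return np.stack([row, col], axis=-1)


@dataclass
class UnwrappedImage:
    """Resampled wall image: rows = arc positions, cols = radial offsets."""

    values: np.ndarray
    transform: UnwrapTransform


def unwrap_slice(
    slice2d: np.ndarray,
    spline: LumenSpline,
    n_arc_samples: int | None = None,
    inner_margin_vox: float = 8.0,
    outer_depth_vox: float = 64.0,
) -> tuple[UnwrappedImage, UnwrapTransform]:
    """Unwrap one trans-axial slice around its lumen spline.

    ``n_arc_samples`` defaults to ``ceil(perimeter)`` (about 1-voxel row
    spacing along the curve).  Intensities are sampled bilinearly.  Rows
    where the outward normals cross before ``outer_depth_vox`` (concave
    regions with small radius of curvature) are reported in
    ``transform.flagged_rows``.
    """
    if n_arc_samples is None:
        n_arc_samples = int(math.ceil(spline.perimeter))
    if n_arc_samples < 4:
        raise ValueError("n_arc_samples must be >= 4")
    if inner_margin_vox < 0 or outer_depth_vox <= 0:
        raise ValueError("inner_margin_vox must be >= 0 and outer_depth_vox > 0")
    n_cols = int(round(inner_margin_vox + outer_depth_vox))
    s = np.arange(n_arc_samples) * spline.perimeter / n_arc_samples
    pts = spline.point(s)
    nrm = spline.normal(s)
    # normals converge at the centre of curvature when the curve bends away
    # from the outward direction within the sampled depth
    kappa = spline.curvature(s)
    second = (np.roll(pts, -1, axis=0) + np.roll(pts, 1, axis=0) - 2 * pts)
    bends_outward = np.einsum("ij,ij->i", second, nrm) > 0
    with np.errstate(divide="ignore"):
        radius_of_curv = 1.0 / np.maximum(kappa, 1e-12)
    flagged = np.flatnonzero(bends_outward & (radius_of_curv < outer_depth_vox))

    offsets = np.arange(n_cols) - inner_margin_vox
    x = pts[:, 0:1] + offsets[None, :] * nrm[:, 0:1]
    y = pts[:, 1:2] + offsets[None, :] * nrm[:, 1:2]
    vals = map_coordinates(
        np.asarray(slice2d, dtype=float), [y, x], order=1, mode="nearest"
    )
    transform = UnwrapTransform(
        spline=spline,
        n_rows=n_arc_samples,
        n_cols=n_cols,
        inner_margin=float(inner_margin_vox),
        points=pts,
        normals=nrm,
        flagged_rows=flagged,
    )
    return UnwrappedImage(values=vals, transform=transform), transform


def rewrap_points(points_unwrapped: np.ndarray, transform: UnwrapTransform) -> np.ndarray:
    """Map unwrapped (row, col) points back onto the trans-axial slice.

    This is the exact closed-form inverse of the unwrap mapping (arc position
    plus normal offset), not a numeric inversion.
    """
    pts = np.atleast_2d(np.asarray(points_unwrapped, dtype=float))
    return transform.to_plane(pts[:, 0], pts[:, 1])
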