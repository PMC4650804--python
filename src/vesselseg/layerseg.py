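"""Media-adventitia boundary extraction in the unwrapped frame.

The wall is first segmented from the paraffin background by a grey-level
threshold.  Because the medial elastic lamellae unwrap to near-vertical
(constant-column) bands while adventitial collagen texture is disordered, a
1D morphological opening across rows plus island removal keeps mostly the
lamellae.  The outermost retained pixel per row (column ``xe``) marks the
outer elastic lamina; a Gaussian mixture fitted to the candidate boundary
positions ``xe + 1`` gives the dominant mean edge position, and the boundary
itself is extracted as the exact minimal-cost (geodesic) path through a
weighted image, one column per row, with a per-row step bound and a penalty
on deviations from a vertical path.  Finally the boundary surface is
smoothed across rows and slices and re-wrapped onto the trans-axial slices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import (
    binary_dilation,
    binary_erosion,
    gaussian_filter,
    gaussian_filter1d,
    maximum_filter,
)
from scipy.ndimage import label as ndi_label
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_otsu
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .phantom import LABEL_ADVENTITIA, LABEL_LUMEN, LABEL_MEDIA
from .unwrap import (
    LumenNotFoundError,
    SplineFitError,
    UnwrappedImage,
    bilateral_filter_axial,
    detect_lumen_edge,
    fit_lumen_spline,
    unwrap_slice,
)
from .volume import Tomogram


@dataclass
class WallMask:
    """Binary wall mask in the unwrapped frame, with its threshold recorded."""

    mask: np.ndarray
    threshold: float


@dataclass
class EdgeProfile:
    """Per-row column of the outermost segmented wall pixel (coordinate xe)."""

    xe: np.ndarray        # int columns; undefined where missing
    missing: np.ndarray   # bool per row

    @property
    def defined_rows(self) -> np.ndarray:
        return np.flatnonzero(~self.missing)


@dataclass
class EdgeModel:
    """Gaussian-mixture summary of the candidate boundary positions xe + 1."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    dominant_mean: float        # mean edge position of the largest-weight component
    closeness_tolerance: float


@dataclass
class WeightParams:
    base_weight: float = 1.0
    edge_bonus: float = 2.0
    mask_penalty: float = 0.5
    deviation_penalty: float | None = None  # lambda; default 0.5 * edge_bonus / max_step
    max_step: int = 2

    def resolved_penalty(self) -> float:
        if self.deviation_penalty is not None:
            return self.deviation_penalty
        return 0.5 * self.edge_bonus / self.max_step

    def validate(self) -> None:
        if not self.base_weight > 0 or not self.edge_bonus > 0:
            raise ValueError("base_weight and edge_bonus must be > 0")
        if not 0 < self.mask_penalty <= self.base_weight:
            raise ValueError("mask_penalty must be in (0, base_weight]")
        if self.deviation_penalty is not None and self.deviation_penalty < 0:
            raise ValueError("deviation_penalty must be >= 0")
        if self.max_step < 1:
            raise ValueError("max_step must be >= 1")


@dataclass
class WeightImage:
    """Non-negative per-pixel weights steering the geodesic boundary path."""

    values: np.ndarray
    params: WeightParams

    @property
    def deviation_penalty(self) -> float:
        return self.params.resolved_penalty()

    @property
    def max_step(self) -> int:
        return self.params.max_step


@dataclass
class BoundaryContour:
    """One column per row: the traced media-adventitia boundary of a slice."""

    columns: np.ndarray
    cost: float


def threshold_wall(
    unwrapped: UnwrappedImage | np.ndarray,
    method: str = "otsu",
    manual_value: float | None = None,
) -> WallMask:
    """Segment the wall from the paraffin background by a grey threshold."""
    img = unwrapped.values if isinstance(unwrapped, UnwrappedImage) else np.asarray(unwrapped)
    if not np.all(np.isfinite(img)):
        raise ValueError("unwrapped image contains non-finite values")
    if method == "fixed":
        if manual_value is None:
            raise ValueError("fixed thresholding requires manual_value")
        thr = float(manual_value)
    elif method == "otsu":
        if np.ptp(img) == 0:
            raise ValueError("no bimodality: image is constant")
        thr = float(threshold_otsu(img))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return WallMask(mask=img >= thr, threshold=thr)


def open_vertical(mask: WallMask | np.ndarray, length_vox: int) -> WallMask:
    """1D morphological opening with a vertical (across-rows) line element.

    Rows sample a closed curve, so the opening wraps periodically across the
    top/bottom row boundary.  Equal to erosion followed by dilation.
    """
    if length_vox < 3 or length_vox % 2 == 0:
        raise ValueError("length_vox must be odd and >= 3")
    m, thr = _as_mask(mask)
    pad = length_vox
    wrapped = np.pad(m, ((pad, pad), (0, 0)), mode="wrap")
    struct = np.ones((length_vox, 1), dtype=bool)
    opened = binary_dilation(binary_erosion(wrapped, struct), struct)
    return WallMask(mask=opened[pad:-pad], threshold=thr)


def remove_islands(mask: WallMask | np.ndarray, min_size_px: int) -> WallMask:
    """Remove 8-connected components smaller than ``min_size_px`` pixels.

    Components of exactly ``min_size_px`` pixels are retained.
    """
    if min_size_px < 1:
        raise ValueError("min_size_px must be >= 1")
    m, thr = _as_mask(mask)
    comp, n = ndi_label(m, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return WallMask(mask=m.copy(), threshold=thr)
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    keep = sizes >= min_size_px
    return WallMask(mask=keep[comp], threshold=thr)


def _as_mask(mask) -> tuple[np.ndarray, float]:
    if isinstance(mask, WallMask):
        return mask.mask.astype(bool), mask.threshold
    return np.asarray(mask, dtype=bool), float("nan")


def edge_profile(mask: WallMask | np.ndarray) -> EdgeProfile:
    """Per row, the column of the outermost (largest-column) set pixel."""
    m, _ = _as_mask(mask)
    any_set = m.any(axis=1)
    if not any_set.any():
        raise ValueError("wall lost: no segmented pixels in any row")
    xe = m.shape[1] - 1 - np.argmax(m[:, ::-1], axis=1)
    xe = np.where(any_set, xe, -1)
    return EdgeProfile(xe=xe, missing=~any_set)


def fit_edge_model(
    profile: EdgeProfile, n_components: int = 2, tolerance: float | None = None
) -> EdgeModel:
    """Fit a Gaussian mixture to the distribution of xe + 1.

    Initialisation is deterministic (k-quantile means, uniform weights); the
    dominant mean is the mean of the largest-weight component.  The default
    closeness tolerance is twice the dominant component's SD.
    """
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    vals = profile.xe[~profile.missing].astype(float) + 1.0
    if len(vals) < 10:
        raise ValueError(f"need >= 10 defined rows, got {len(vals)}")
    if len(vals) < n_components:
        raise ValueError("fewer defined rows than mixture components")
    X = vals[:, None]
    q = np.quantile(vals, (np.arange(n_components) + 0.5) / n_components)
    var = max(float(np.var(vals)), 1e-6)
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        max_iter=200,
        tol=1e-8,
        reg_covar=1e-6,
        n_init=1,
        weights_init=np.full(n_components, 1.0 / n_components),
        means_init=q[:, None],
        precisions_init=np.full((n_components, 1, 1), 1.0 / var),
        random_state=0,
    )
    with warnings.catch_warnings():
        # a strict 1e-8 tolerance may not be reached in 200 iterations on
        # heavy-tailed edge profiles; the fit is still deterministic and usable
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm.fit(X)
    weights = gm.weights_.copy()
    means = gm.means_[:, 0].copy()
    sds = np.sqrt(gm.covariances_[:, 0, 0])
    k = int(np.argmax(weights))
    dom_mean = float(means[k])
    tol = float(tolerance) if tolerance is not None else 2.0 * float(sds[k])
    return EdgeModel(
        weights=weights, means=means, sds=sds, dominant_mean=dom_mean, closeness_tolerance=tol
    )


def build_weight_image(
    mask: WallMask,
    model: EdgeModel,
    profile: EdgeProfile,
    params: WeightParams | None = None,
) -> WeightImage:
    """Construct the weighted image the geodesic path is traced through.

    Every pixel starts at ``base_weight``; pixels inside the initial
    thresholded mask are penalised to ``base_weight - mask_penalty``; then
    candidate boundary pixels ``(row, xe+1)`` whose position is within the
    closeness tolerance of the dominant mean edge position receive
    ``edge_bonus`` on top (penalty-then-bonus precedence).  Weights are
    clipped at zero.
    """
    params = params or WeightParams()
    params.validate()
    m = mask.mask
    W = np.full(m.shape, params.base_weight, dtype=float)
    W[m] = params.base_weight - params.mask_penalty
    rows = profile.defined_rows
    cand = profile.xe[rows] + 1
    ok = (
        (cand < m.shape[1])
        & (np.abs(cand - model.dominant_mean) <= model.closeness_tolerance)
    )
    W[rows[ok], cand[ok]] += params.edge_bonus
    np.clip(W, 0.0, None, out=W)
    return WeightImage(values=W, params=params)


def trace_geodesic_boundary(weights: WeightImage) -> BoundaryContour:
    """Exact minimal-cost vertical path through the weighted image.

    Minimises ``sum_r [(W_max - W[r, c_r]) + lam*|c_r - c_{r-1}|]`` over all
    column sequences with ``|c_r - c_{r-1}| <= d_max``, with free endpoints
    and periodic closure penalised by ``lam*|c_last - c_first|``.  Solved
    exactly by dynamic programming on the row-layered graph (the discrete
    analogue of a fast-marching minimal path); ties break toward the smaller
    column.
    """
    W = np.asarray(weights.values, dtype=float)
    if not np.all(np.isfinite(W)) or np.any(W < 0):
        raise ValueError("weights must be finite and >= 0")
    n_rows, n_cols = W.shape
    if n_rows < 2:
        raise ValueError("need at least 2 rows to trace a path")
    lam = weights.deviation_penalty
    dmax = weights.max_step
    cost = W.max() - W

    # D[s, c]: best cost of a path starting in column s and currently in
    # column c.  back[r, s, c]: step taken into (r, c).
    D = np.full((n_cols, n_cols), np.inf)
    idx = np.arange(n_cols)
    D[idx, idx] = cost[0]
    back = np.zeros((n_rows, n_cols, n_cols), dtype=np.int8)
    deltas = sorted(range(-dmax, dmax + 1), key=lambda d: -d)  # smaller source col first
    for r in range(1, n_rows):
        best = np.full_like(D, np.inf)
        bestd = np.zeros((n_cols, n_cols), dtype=np.int8)
        for d in deltas:
            cand = np.full_like(D, np.inf)
            if d > 0:
                cand[:, d:] = D[:, :-d]
            elif d < 0:
                cand[:, :d] = D[:, -d:]
            else:
                cand[:, :] = D
            cand = cand + lam * abs(d)
            better = cand < best
            best[better] = cand[better]
            bestd[better] = d
        D = best + cost[r][None, :]
        back[r] = bestd

    total = D + lam * np.abs(idx[None, :] - idx[:, None])
    # tie-break: smallest final column, then smallest start column
    flat = np.argmin(total.T)
    c_last, s_best = np.unravel_index(flat, (n_cols, n_cols))
    path = np.empty(n_rows, dtype=int)
    path[-1] = c_last
    for r in range(n_rows - 1, 0, -1):
        path[r - 1] = path[r] - back[r, s_best, path[r]]
    assert path[0] == s_best
    return BoundaryContour(columns=path, cost=float(total[s_best, c_last]))


def smooth_boundary_surface(
    contours: np.ndarray, sigma_rows: float = 3.0, sigma_slices: float = 2.0
) -> np.ndarray:
    """Gaussian smoothing of a boundary-radius surface over (slice, row).

    ``contours`` is (n_slices, n_rows); the row direction is periodic (the
    rows sample a closed curve), the slice direction uses edge replication.
    """
    arr = np.asarray(contours, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[0] < 1:
        raise ValueError("need at least one slice of contours")
    return gaussian_filter(arr, sigma=(sigma_slices, sigma_rows), mode=("nearest", "wrap"))


@dataclass
class SegmentConfig:
    """Tunable parameters of the per-slice segmentation pipeline."""

    apply_bilateral: bool = True
    bilateral_window_vox: int = 7
    bilateral_sigma_spatial: float = 1.5
    bilateral_sigma_range: float | None = None
    n_arc_samples: int = 256
    inner_margin_vox: float = 8.0
    outer_depth_vox: float = 64.0
    spline_smoothing_per_point: float = 0.5
    threshold_method: str = "otsu"
    wall_threshold: float | None = None
    opening_length_vox: int = 13
    island_min_size_px: int = 4
    gmm_components: int = 2
    gmm_tolerance: float | None = None
    base_weight: float = 1.0
    edge_bonus: float = 2.0
    mask_penalty: float = 0.5
    deviation_penalty: float | None = None
    max_step: int = 2
    surface_sigma_rows: float = 3.0
    surface_sigma_slices: float = 2.0
    subvoxel_refine: bool = True

    def weight_params(self) -> WeightParams:
        return WeightParams(
            base_weight=self.base_weight,
            edge_bonus=self.edge_bonus,
            mask_penalty=self.mask_penalty,
            deviation_penalty=self.deviation_penalty,
            max_step=self.max_step,
        )

    def validate(self) -> None:
        self.weight_params().validate()
        if self.opening_length_vox < 3 or self.opening_length_vox % 2 == 0:
            raise ValueError("opening_length_vox must be odd and >= 3")
        if self.island_min_size_px < 1:
            raise ValueError("island_min_size_px must be >= 1")
        if self.gmm_components not in (1, 2, 3):
            raise ValueError("gmm_components must be 1, 2 or 3")
        if self.n_arc_samples < 4:
            raise ValueError("n_arc_samples must be >= 4")
        if self.spline_smoothing_per_point < 0:
            raise ValueError("spline_smoothing_per_point must be >= 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.wall_threshold is None:
            raise ValueError("fixed thresholding requires wall_threshold")


def _refine_boundary(
    img: np.ndarray, path_cols: np.ndarray, reach: int = 3, last: bool = False
) -> np.ndarray:
    """Sub-voxel boundary: local mid-level intensity crossing near the path.

    The traced path sits at the first pixel outside the wall; the physical
    boundary is where the intensity falls through the midpoint between the
    local wall and background levels.  ``last=True`` selects the outermost
    falling crossing (used for the wall/paraffin edge, where interior texture
    dips would otherwise trigger early).  Rows without a falling crossing
    fall back to the half-voxel face convention.
    """
    n_rows, n_cols = img.shape
    out = np.empty(n_rows)
    for r in range(n_rows):
        c0 = int(path_cols[r])
        lo = max(c0 - reach, 0)
        hi = min(c0 + reach - 1, n_cols - 1)
        inner = img[r, lo]
        outer_i = img[r, hi]
        mid = 0.5 * (inner + outer_i)
        seg = img[r, lo : hi + 1]
        out[r] = path_cols[r] - 0.5
        ks = range(len(seg) - 2, -1, -1) if last else range(len(seg) - 1)
        for k in ks:
            if seg[k] >= mid > seg[k + 1]:
                frac = (seg[k] - mid) / (seg[k] - seg[k + 1])
                out[r] = lo + k + frac
                break
    return out


@dataclass
class SegmentationResult:
    """Output of segment_volume: labels, per-slice contours and diagnostics."""

    labels: np.ndarray                 # uint8 (slice,row,col)
    boundary_cols: np.ndarray          # (n_slices, n_rows) sub-voxel boundary columns
    outer_cols: np.ndarray             # (n_slices, n_rows) outer wall-edge columns
    lumen_cols: np.ndarray             # (n_slices, n_rows) sub-voxel lumen-edge columns
    inner_margin: float
    transforms: list                   # UnwrapTransform per slice (None where failed)
    records: list                      # per-slice diagnostic dicts
    config: SegmentConfig
    voxel_size_um: float

    @property
    def n_slices(self) -> int:
        return self.labels.shape[0]

    @property
    def flagged_slices(self) -> list[int]:
        return [r["slice"] for r in self.records if r["flagged"]]

    def lumen_radius_map(self) -> np.ndarray:
        """Luminal radius (vox) per (slice, arc sample), sub-voxel refined."""
        out = np.full((self.n_slices, self.config.n_arc_samples), np.nan)
        for z, tr in enumerate(self.transforms):
            if tr is None:
                continue
            c = tr.spline.centroid
            spline_r = np.hypot(tr.points[:, 0] - c[0], tr.points[:, 1] - c[1])
            out[z] = spline_r + (self.lumen_cols[z] - self.inner_margin)
        return out

    def boundary_radius_map(self) -> np.ndarray:
        """Media-adventitia boundary radius (vox) per (slice, arc sample)."""
        return self.lumen_radius_map() + (self.boundary_cols - self.inner_margin)


def segment_volume(
    vol: Tomogram, config: SegmentConfig | None = None
) -> SegmentationResult:
    """Run the full per-slice segmentation protocol on a tomogram.

    Stages: axial bilateral filter -> lumen edge + periodic spline -> unwrap
    -> wall threshold -> vertical opening + island removal -> edge profile
    -> Gaussian-mixture edge model -> weighted geodesic boundary -> 3D
    surface smoothing -> re-wrap to labels (background 0, lumen 1, media 2,
    adventitia 3).  Slices failing lumen detection or spline fitting are
    flagged for manual review and left unlabelled.
    """
    cfg = config or SegmentConfig()
    cfg.validate()
    tom = vol
    if cfg.apply_bilateral and vol.n_slices > 1:
        tom = bilateral_filter_axial(
            vol, cfg.bilateral_sigma_spatial, cfg.bilateral_sigma_range, cfg.bilateral_window_vox
        )
    slices = tom.slices()
    ns = slices.shape[0]
    n_rows = cfg.n_arc_samples
    boundary = np.full((ns, n_rows), np.nan)
    outer = np.full((ns, n_rows), np.nan)
    lumen_cols = np.full((ns, n_rows), cfg.inner_margin_vox)
    transforms: list = [None] * ns
    unwrapped_values: list = [None] * ns
    records: list[dict] = []

    for z in range(ns):
        sl = slices[z]
        rec = {
            "slice": z,
            "flagged": False,
            "reason": "",
            "threshold": np.nan,
            "dominant_mean": np.nan,
            "path_cost": np.nan,
            "n_flagged_rows": 0,
        }
        try:
            if cfg.threshold_method == "fixed":
                thr_slice = float(cfg.wall_threshold)
            else:
                thr_slice = float(threshold_otsu(sl))
            pts = detect_lumen_edge(sl, thr_slice)
            spline = fit_lumen_spline(pts, cfg.spline_smoothing_per_point * len(pts))
            unw, tr = unwrap_slice(
                sl, spline, cfg.n_arc_samples, cfg.inner_margin_vox, cfg.outer_depth_vox
            )
            wmask = threshold_wall(unw, cfg.threshold_method, cfg.wall_threshold)
            opened = remove_islands(
                open_vertical(wmask, cfg.opening_length_vox), cfg.island_min_size_px
            )
            prof = edge_profile(opened)
            model = fit_edge_model(prof, cfg.gmm_components, cfg.gmm_tolerance)
            wi = build_weight_image(wmask, model, prof, cfg.weight_params())
            path = trace_geodesic_boundary(wi)
            outer_prof = edge_profile(remove_islands(wmask, cfg.island_min_size_px))
            # sub-voxel convention: the boundary sits on the face between the
            # outermost wall pixel and the first outside pixel; optionally
            # refined to the local mid-level intensity crossing, which removes
            # the threshold-dependent placement bias
            if cfg.subvoxel_refine:
                boundary[z] = _refine_boundary(unw.values, path.columns)
                # the lumen edge gets the same treatment: rising mid-level
                # crossing around the spline column (negated image)
                lumen_cols[z] = _refine_boundary(
                    -unw.values, np.full(n_rows, cfg.inner_margin_vox + 0.5)
                )
            else:
                boundary[z] = path.columns.astype(float) - 0.5
            oc = outer_prof.xe.astype(float) + 0.5
            if outer_prof.missing.any():
                oc[outer_prof.missing] = np.median(oc[~outer_prof.missing])
            outer[z] = oc
            transforms[z] = tr
            unwrapped_values[z] = unw.values
            rec.update(
                threshold=wmask.threshold,
                dominant_mean=model.dominant_mean,
                path_cost=path.cost,
                n_flagged_rows=int(len(tr.flagged_rows)),
            )
        except (LumenNotFoundError, SplineFitError, ValueError) as exc:
            rec["flagged"] = True
            rec["reason"] = f"{type(exc).__name__}: {exc}"
        records.append(rec)

    good = [z for z in range(ns) if transforms[z] is not None]
    if not good:
        raise RuntimeError("segmentation failed on every slice")
    # fill failed slices from the nearest successful neighbour so the 3D
    # smoother sees a complete surface; those slices stay unlabelled
    for z in range(ns):
        if transforms[z] is None:
            nearest = min(good, key=lambda g: abs(g - z))
            boundary[z] = boundary[nearest]
            outer[z] = outer[nearest]
            lumen_cols[z] = lumen_cols[nearest]
    boundary = smooth_boundary_surface(boundary, cfg.surface_sigma_rows, cfg.surface_sigma_slices)
    lumen_cols = smooth_boundary_surface(lumen_cols, cfg.surface_sigma_rows, cfg.surface_sigma_slices)
    # The outermost-fibre-per-row signal is a sparse point process that can
    # only under-reach the true outer edge: take its local upper envelope
    # over a small (row, slice) window, then refine each row to the
    # mid-level crossing of the tangentially averaged intensity profile
    # (averaging turns the sparse fibre texture into a smooth radial
    # falloff from wall to paraffin).
    outer = maximum_filter(outer, size=(5, 9), mode=("nearest", "wrap"))
    if cfg.subvoxel_refine:
        for z in good:
            smoothed = gaussian_filter1d(unwrapped_values[z], 4.0, axis=0, mode="wrap")
            # gaps in the fibre texture bias the envelope only inward, so
            # anchor the search no deeper than the slice's median estimate
            anchor = np.maximum(outer[z], np.median(outer[z]))
            outer[z] = _refine_boundary(smoothed, anchor + 0.5, reach=7, last=True)
    outer = smooth_boundary_surface(outer, cfg.surface_sigma_rows, cfg.surface_sigma_slices)
    # the outer edge cannot sit inside the media-adventitia boundary
    outer = np.maximum(outer, boundary + 1.0)

    labels = np.zeros(slices.shape, dtype=np.uint8)
    rows = np.arange(n_rows, dtype=float)
    shape2d = slices.shape[1:]
    max_col = None
    for z in good:
        tr = transforms[z]
        max_col = tr.n_cols - 1e-6
        b_cols = np.clip(boundary[z], 0.0, max_col)
        o_cols = np.clip(outer[z], 0.0, max_col)
        l_cols = np.clip(lumen_cols[z], 0.0, max_col)
        lumen_poly = tr.to_plane(rows, l_cols)
        bound_poly = tr.to_plane(rows, b_cols)
        outer_poly = tr.to_plane(rows, o_cols)
        for poly, code in (
            (outer_poly, LABEL_ADVENTITIA),
            (bound_poly, LABEL_MEDIA),
            (lumen_poly, LABEL_LUMEN),
        ):
            rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=shape2d)
            labels[z, rr, cc] = code

    return SegmentationResult(
        labels=labels,
        boundary_cols=boundary,
        outer_cols=outer,
        lumen_cols=lumen_cols,
        inner_margin=cfg.inner_margin_vox,
        transforms=transforms,
        records=records,
        config=cfg,
        voxel_size_um=vol.voxel_size_um,
    )
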