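"""Synthetic vessel phantoms with voxel-exact ground truth.

The phantom emulates a paraffin-embedded artery as it appears in absorption
microCT: a dark (air-filled) lumen, a medial layer of bright concentric
elastic lamellae separated by cell-rich interlamellar tissue, and an outer
adventitia whose collagen fibres show up as bright, disordered short
segments in a paraffin-infiltrated matrix.  Low-density spherical pores are
embedded in the adventitia.  The geometric truth (labels, boundary radii,
analytic per-slice morphometry) is computed from the pre-blur geometry; PSF
blur and additive Gaussian noise are applied afterwards as measurement
effects.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter
from skimage.draw import line as draw_line

from .volume import Tomogram

# Label codes used throughout the package.
LABEL_BACKGROUND = 0
LABEL_LUMEN = 1
LABEL_MEDIA = 2
LABEL_ADVENTITIA = 3
LABEL_PORE = 4

INTENSITY_KEYS = ("air", "pore", "paraffin", "interlamellar", "lamella", "adventitia_fibre")

DEFAULT_INTENSITIES = {
    "air": 10.0,
    "pore": 25.0,
    "paraffin": 60.0,
    "interlamellar": 100.0,
    "adventitia_fibre": 160.0,
    "lamella": 180.0,
}


@dataclass
class PhantomSpec:
    """Parameters of a synthetic vessel tomogram.

    Lengths are in voxels unless suffixed ``_um``.  ``centre_offset`` is the
    per-slice drift (d_row, d_col) of the vessel centre, modelling a vessel
    axis not perfectly aligned with the scan axis.
    """

    image_shape: tuple[int, int, int] = (64, 256, 256)
    voxel_size_um: float = 0.75
    centre_offset: tuple[float, float] = (0.0, 0.0)
    lumen_radius_vox: float = 40.0
    ripple_amplitude_vox: float = 3.0
    ripple_wavelength_vox: float = 60.0
    n_lamellae: int = 5
    lamella_thickness_vox: float = 3.0
    interlamellar_gap_vox: float = 3.0
    waviness_amplitude_vox: float = 2.0
    waviness_period_rad: float = math.pi / 3
    adventitia_thickness_vox: float = 25.0
    fibre_density: float = 0.3
    fibre_length_range_vox: tuple[int, int] = (5, 15)
    fibre_thickness_vox: int = 2
    pore_count: int = 12
    pore_radius_range_vox: tuple[float, float] = (3.0, 5.0)
    intensity_levels: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    psf_sigma_vox: float = 0.8
    noise_sd: float = 8.0
    seed: int = 0

    @property
    def media_thickness_vox(self) -> float:
        n = self.n_lamellae
        return n * self.lamella_thickness_vox + max(n - 1, 0) * self.interlamellar_gap_vox

    @property
    def outer_radius_vox(self) -> float:
        return self.lumen_radius_vox + self.media_thickness_vox + self.adventitia_thickness_vox

    def validate(self) -> None:
        ns, nr, nc = self.image_shape
        if ns < 1 or nr < 8 or nc < 8:
            raise ValueError(f"image_shape {self.image_shape} too small")
        if not self.lumen_radius_vox > 0:
            raise ValueError("lumen_radius_vox must be > 0")
        if self.n_lamellae < 1:
            raise ValueError("n_lamellae must be >= 1")
        for name in ("lamella_thickness_vox", "interlamellar_gap_vox", "adventitia_thickness_vox"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.fibre_density <= 1.0:
            raise ValueError("fibre_density must be in [0, 1]")
        if self.ripple_amplitude_vox < 0 or self.waviness_amplitude_vox < 0:
            raise ValueError("ripple/waviness amplitudes must be >= 0")
        if self.pore_count < 0:
            raise ValueError("pore_count must be >= 0")
        lo, hi = self.pore_radius_range_vox
        if self.pore_count > 0:
            if not 0 < lo <= hi:
                raise ValueError("pore_radius_range_vox must satisfy 0 < lo <= hi")
            if 2 * hi + 3 > self.adventitia_thickness_vox:
                raise ValueError(
                    "pores do not fit: adventitia_thickness_vox must exceed "
                    "2*max pore radius + 3"
                )
        missing = [k for k in INTENSITY_KEYS if k not in self.intensity_levels]
        if missing:
            raise ValueError(f"intensity_levels missing keys {missing}")
        g = self.intensity_levels
        if not (g["pore"] < g["paraffin"] < g["interlamellar"]):
            raise ValueError("intensity ordering pore < paraffin < interlamellar is required")
        # geometry must fit with >= 5-voxel paraffin margin, including drift
        drift = math.hypot(*self.centre_offset) * max(ns - 1, 0)
        reach = self.outer_radius_vox + self.ripple_amplitude_vox + drift
        half = min(nr, nc) / 2.0
        if reach > half - 5:
            raise ValueError(
                f"vessel geometry (radius {reach:.1f} vox incl. ripple and drift) exceeds "
                f"image bounds: needs <= {half - 5:.1f} vox; enlarge image_shape or shrink radii"
            )


@dataclass
class PressureEffectSpec:
    """Multiplicative remodelling factors applied to build a pressurised twin.

    Directions follow intra-luminal pressurisation: the lumen dilates, both
    wall layers thin, lamellae straighten, the luminal ripple flattens and
    adventitial pores collapse.
    """

    lumen_radius_factor: float = 1.22
    media_thickness_factor: float = 0.85
    adventitia_thickness_factor: float = 0.66
    ripple_amplitude_factor: float = 0.3
    waviness_amplitude_factor: float = 0.3
    pore_count_factor: float = 0.3

    def validate(self) -> None:
        if not self.lumen_radius_factor > 1:
            raise ValueError("lumen_radius_factor must be > 1 (lumen dilates)")
        for name in (
            "media_thickness_factor",
            "adventitia_thickness_factor",
            "ripple_amplitude_factor",
            "waviness_amplitude_factor",
            "pore_count_factor",
        ):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1) (pressurisation reduces it)")


@dataclass
class GroundTruth:
    """Voxel-exact truth for a phantom: labels, boundary radii, analytic metrics."""

    labels: np.ndarray                      # uint8 (slice,row,col), codes above
    boundary_radius: np.ndarray             # (n_slices, n_theta) media-adventitia radius, vox
    theta_samples: np.ndarray               # (n_theta,) angles of boundary_radius columns
    true_metrics: pd.DataFrame              # per-slice analytic morphometry (um units)
    centres: np.ndarray                     # (n_slices, 2) vessel centre (row, col) per slice
    pores: list                             # [(z, y, x, r_vox), ...]
    spec: PhantomSpec

    # ripple parameters frozen for analytic queries
    _ripple_k: int = 0

    def lumen_radius_at(self, theta: np.ndarray) -> np.ndarray:
        """True lumen radius (vox) at angle theta (same for every slice)."""
        s = self.spec
        if self._ripple_k == 0 or s.ripple_amplitude_vox == 0:
            return np.full_like(np.asarray(theta, dtype=float), s.lumen_radius_vox)
        return s.lumen_radius_vox + s.ripple_amplitude_vox * np.sin(self._ripple_k * np.asarray(theta))

    def boundary_radius_at(self, theta: np.ndarray) -> np.ndarray:
        """True media-adventitia boundary radius (vox) at angle theta."""
        return self.lumen_radius_at(theta) + self.spec.media_thickness_vox

    def outer_radius_at(self, theta: np.ndarray) -> np.ndarray:
        return self.boundary_radius_at(theta) + self.spec.adventitia_thickness_vox

    @property
    def total_pore_volume_um3(self) -> float:
        v = self.spec.voxel_size_um
        return sum(4.0 / 3.0 * math.pi * r**3 for (_, _, _, r) in self.pores) * v**3


def _ripple_wavenumber(spec: PhantomSpec) -> int:
    if spec.ripple_amplitude_vox <= 0:
        return 0
    k = round(2 * math.pi * spec.lumen_radius_vox / spec.ripple_wavelength_vox)
    return max(int(k), 1)


def _waviness_wavenumber(spec: PhantomSpec) -> int:
    if spec.waviness_amplitude_vox <= 0:
        return 0
    return max(int(round(2 * math.pi / spec.waviness_period_rad)), 1)


def make_vessel_phantom(spec: PhantomSpec) -> tuple[Tomogram, GroundTruth]:
    """Render a synthetic vessel tomogram and its ground truth.

    Deterministic for a fixed ``spec.seed``.  The returned volume has had
    intensity assignment, PSF blur, then additive noise applied, in that
    order; the GroundTruth reflects the pre-blur geometry.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ns, nr, nc = spec.image_shape
    g = spec.intensity_levels
    t_media = spec.media_thickness_vox
    t_adv = spec.adventitia_thickness_vox
    k_rip = _ripple_wavenumber(spec)
    m_wav = _waviness_wavenumber(spec)
    phases = rng.uniform(0.0, 2 * math.pi, size=spec.n_lamellae)

    labels = np.zeros(spec.image_shape, dtype=np.uint8)
    vol = np.full(spec.image_shape, g["paraffin"], dtype=np.float32)
    centres = np.empty((ns, 2))
    yy, xx = np.indices((nr, nc), dtype=np.float64)
    f_lo, f_hi = spec.fibre_length_range_vox

    for z in range(ns):
        cy = (nr - 1) / 2.0 + spec.centre_offset[0] * z
        cx = (nc - 1) / 2.0 + spec.centre_offset[1] * z
        centres[z] = (cy, cx)
        dy, dx = yy - cy, xx - cx
        r = np.hypot(dy, dx)
        th = np.arctan2(dy, dx)
        r_lum = spec.lumen_radius_vox + (
            spec.ripple_amplitude_vox * np.sin(k_rip * th) if k_rip else 0.0
        )
        rb = r_lum + t_media
        rout = rb + t_adv
        lum = r < r_lum
        med = (r >= r_lum) & (r < rb)
        adv = (r >= rb) & (r < rout)
        labels[z][lum] = LABEL_LUMEN
        labels[z][med] = LABEL_MEDIA
        labels[z][adv] = LABEL_ADVENTITIA
        sl = vol[z]
        sl[lum] = g["air"]
        sl[med] = g["interlamellar"]
        # lamellae: innermost pinned to the lumen edge, outermost to the
        # media-adventitia boundary; interior ones carry the waviness
        for i in range(spec.n_lamellae):
            off = i * (spec.lamella_thickness_vox + spec.interlamellar_gap_vox)
            if 0 < i < spec.n_lamellae - 1 and m_wav:
                w = spec.waviness_amplitude_vox * np.sin(m_wav * th + phases[i])
            else:
                w = 0.0
            a = r_lum + off + w
            band = med & (r >= a) & (r < a + spec.lamella_thickness_vox)
            sl[band] = g["lamella"]
        del sl  # fibre texture and pores are applied in 3D after the loop

    _draw_fibres(spec, rng, labels, vol)
    pores = _place_pores(spec, rng, centres, k_rip)
    for (zc, ycc, xcc, pr) in pores:
        z0, z1 = max(int(math.floor(zc - pr)), 0), min(int(math.ceil(zc + pr)), ns - 1)
        y0, y1 = int(math.floor(ycc - pr)), int(math.ceil(ycc + pr))
        x0, x1 = int(math.floor(xcc - pr)), int(math.ceil(xcc + pr))
        zz, yy2, xx2 = np.mgrid[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1]
        inside = (zz - zc) ** 2 + (yy2 - ycc) ** 2 + (xx2 - xcc) ** 2 < pr**2
        sub = labels[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1]
        carve = inside & (sub == LABEL_ADVENTITIA)  # stay inside the wall
        sub[carve] = LABEL_PORE
        vol[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1][carve] = g["pore"]

    # measurement effects
    if spec.psf_sigma_vox > 0:
        vol = gaussian_filter(vol, spec.psf_sigma_vox, mode="nearest")
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape).astype(np.float32)

    gt = _ground_truth(spec, labels, centres, pores, k_rip)
    return Tomogram(vol, spec.voxel_size_um), gt


def _draw_fibres(spec, rng, labels, vol) -> None:
    """Scatter short fibre segments with random 3D orientation in the adventitia.

    Collagen bundles in the vessel wall run predominantly out of the
    trans-axial plane, so each slice shows short disordered marks rather
    than long in-plane lines; drawing the segments in 3D reproduces that.
    Segments are rasterised at sub-voxel steps, thickened to
    ``fibre_thickness_vox`` and clipped to the adventitia annulus.
    """
    if spec.fibre_density <= 0:
        return
    adv = labels == LABEL_ADVENTITIA
    if not adv.any():
        return
    ns, nr, nc = spec.image_shape
    f_lo, f_hi = spec.fibre_length_range_vox
    fw = max(int(spec.fibre_thickness_vox), 1)
    mean_len = (f_lo + f_hi) / 2.0
    # segments originate in a slightly dilated annulus and are clipped back,
    # so the texture coverage stays uniform right up to the layer boundaries
    # (collagen bundles terminate at the fascia, they do not fade out)
    region = binary_dilation(adv, iterations=int(mean_len // 2))
    region_flat = np.flatnonzero(region)
    # ~mean_len * fw voxels per rasterised segment
    n_seg = int(round(spec.fibre_density * region_flat.size / (mean_len * fw)))
    picks = region_flat[rng.integers(0, region_flat.size, size=n_seg)]
    # isotropic 3D orientations
    u = rng.uniform(-1.0, 1.0, size=n_seg)
    az = rng.uniform(0.0, 2 * math.pi, size=n_seg)
    s = np.sqrt(1 - u**2)
    dirs = np.stack([u, s * np.sin(az), s * np.cos(az)], axis=1)  # (dz, dy, dx)
    lens = rng.integers(f_lo, f_hi + 1, size=n_seg)
    fibre = np.zeros(labels.shape, dtype=bool)
    steps_cache: dict[int, np.ndarray] = {}
    for p, d, ln in zip(picks, dirs, lens):
        t = steps_cache.setdefault(int(ln), np.arange(0.0, float(ln), 0.5))
        z0, rem = divmod(int(p), nr * nc)
        y0, x0 = divmod(rem, nc)
        pts = np.array([z0, y0, x0], dtype=float) + t[:, None] * d
        if fw > 1:
            # one perpendicular stroke thickens the bundle to ~2 voxels
            perp = np.array([-d[1], d[0], 0.0])
            nrm = np.linalg.norm(perp)
            if nrm > 1e-6:
                pts = np.vstack([pts, pts + perp / nrm])
        vox = np.round(pts).astype(int)
        np.clip(vox[:, 0], 0, ns - 1, out=vox[:, 0])
        np.clip(vox[:, 1], 0, nr - 1, out=vox[:, 1])
        np.clip(vox[:, 2], 0, nc - 1, out=vox[:, 2])
        fibre[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    fibre &= adv
    vol[fibre] = spec.intensity_levels["adventitia_fibre"]


def _place_pores(spec, rng, centres, k_rip):
    """Sample sphere centres inside the adventitia annulus.

    Uses light rejection sampling (min separation r1+r2+1) so the requested
    count survives; on exhaustion an overlapping placement is accepted and
    the spheres merge.
    """
    ns = spec.image_shape[0]
    t_media = spec.media_thickness_vox
    pores: list[tuple[float, float, float, float]] = []
    for _ in range(spec.pore_count):
        placed = None
        for _attempt in range(200):
            pr = rng.uniform(*spec.pore_radius_range_vox)
            if ns - 1 - pr <= pr:
                zc = (ns - 1) / 2.0
            else:
                zc = rng.uniform(pr, ns - 1 - pr)
            th_c = rng.uniform(-math.pi, math.pi)
            r_lum = spec.lumen_radius_vox + (
                spec.ripple_amplitude_vox * math.sin(k_rip * th_c) if k_rip else 0.0
            )
            rb = r_lum + t_media
            rc = rng.uniform(rb + pr + 1.5, rb + spec.adventitia_thickness_vox - pr - 1.5)
            cy, cx = centres[int(round(zc))]
            ycc = cy + rc * math.sin(th_c)
            xcc = cx + rc * math.cos(th_c)
            cand = (zc, ycc, xcc, pr)
            ok = all(
                math.dist(cand[:3], q[:3]) > pr + q[3] + 1.0 for q in pores
            )
            if ok:
                placed = cand
                break
        pores.append(placed if placed is not None else cand)
    return pores


def _ground_truth(spec, labels, centres, pores, k_rip) -> GroundTruth:
    ns = spec.image_shape[0]
    v = spec.voxel_size_um
    t_media = spec.media_thickness_vox
    t_adv = spec.adventitia_thickness_vox
    theta = np.linspace(0.0, 2 * math.pi, 720, endpoint=False)
    th_fine = np.linspace(0.0, 2 * math.pi, 4096, endpoint=False)
    r_lum = spec.lumen_radius_vox + (
        spec.ripple_amplitude_vox * np.sin(k_rip * th_fine) if k_rip else 0.0
    )
    rb = r_lum + t_media
    rout = rb + t_adv
    lumen_csa = 0.5 * np.mean(r_lum**2) * 2 * math.pi
    media_csa = 0.5 * np.mean(rb**2 - r_lum**2) * 2 * math.pi
    adv_csa_full = 0.5 * np.mean(rout**2 - rb**2) * 2 * math.pi

    rows = []
    for z in range(ns):
        pore_csa = 0.0
        for (zc, _, _, pr) in pores:
            dz = z - zc
            if abs(dz) < pr:
                pore_csa += math.pi * (pr**2 - dz**2)
        rows.append(
            {
                "slice": z,
                "lumen_csa_um2": lumen_csa * v**2,
                "media_csa_um2": media_csa * v**2,
                "adventitia_csa_um2": (adv_csa_full - pore_csa) * v**2,
                "pore_csa_um2": pore_csa * v**2,
                "media_thickness_um": t_media * v,
                "adventitia_thickness_um": t_adv * v,
            }
        )
    metrics = pd.DataFrame(rows)

    r_lum_t = spec.lumen_radius_vox + (
        spec.ripple_amplitude_vox * np.sin(k_rip * theta) if k_rip else 0.0
    )
    boundary = np.tile(r_lum_t + t_media, (ns, 1))
    return GroundTruth(
        labels=labels,
        boundary_radius=boundary,
        theta_samples=theta,
        true_metrics=metrics,
        centres=centres,
        pores=pores,
        spec=spec,
        _ripple_k=k_rip,
    )


def make_pressurised_pair(
    base_spec: PhantomSpec, pressurisation: PressureEffectSpec
) -> tuple[tuple[Tomogram, GroundTruth], tuple[Tomogram, GroundTruth]]:
    """Build an (unpressurised, pressurised) phantom pair.

    The pressurised member has, by construction, a larger lumen CSA, thinner
    media and adventitia, straighter lamellae, a flatter luminal surface and
    fewer pores.  The two members use seeds ``seed`` and ``seed + 1``.
    """
    pressurisation.validate()
    p = pressurisation
    press_spec = replace(
        base_spec,
        lumen_radius_vox=base_spec.lumen_radius_vox * p.lumen_radius_factor,
        lamella_thickness_vox=base_spec.lamella_thickness_vox * p.media_thickness_factor,
        interlamellar_gap_vox=base_spec.interlamellar_gap_vox * p.media_thickness_factor,
        adventitia_thickness_vox=base_spec.adventitia_thickness_vox
        * p.adventitia_thickness_factor,
        ripple_amplitude_vox=base_spec.ripple_amplitude_vox * p.ripple_amplitude_factor,
        waviness_amplitude_vox=base_spec.waviness_amplitude_vox * p.waviness_amplitude_factor,
        pore_count=int(round(base_spec.pore_count * p.pore_count_factor)),
        seed=base_spec.seed + 1,
    )
    unpress = make_vessel_phantom(base_spec)
    press = make_vessel_phantom(press_spec)
    return unpress, press


def perturb_with_noise(volume: Tomogram, noise_sd: float, seed: int) -> Tomogram:
    """Add i.i.d. Gaussian noise; ``noise_sd = 0`` is the identity."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return volume.with_values(volume.values.copy())
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=volume.values.shape).astype(volume.values.dtype)
    return volume.with_values(volume.values + noise)
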