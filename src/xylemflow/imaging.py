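"""Synthetic cross-section imaging and re-measurement.

Closes the measurement loop with a ground-truth oracle: a ConduitSet is
rendered as an anti-aliased grayscale wedge image (dark lumina on a light
background, one ellipse per conduit, aspect ratio ≤ 1.3, non-overlapping),
then re-measured by global thresholding + connected components — the same
operations an analyst performs on a digitised micrograph.  Conduits whose
centroid falls inside the sector polygon are counted (centroid inclusion
keeps the density estimator unbiased under random sector placement).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from skimage import filters, measure

from .anatomy import ConduitSet

__all__ = ["SectorImage", "render_sector", "segment_conduits", "save_png"]

log = logging.getLogger(__name__)


@dataclass
class SectorImage:
    """Grayscale raster plus the sector geometry in image coordinates.

    ``image`` is float in [0, 1] (1 = background).  The wedge has its apex
    at ``apex`` (pixels), spans ``(theta_min, theta_max)`` radians and the
    annulus between ``r_inner`` and ``r_outer`` (pixels).
    """

    image: np.ndarray
    pixel_size: float  # µm per pixel
    apex: Tuple[float, float]  # (row, col)
    r_inner: float
    r_outer: float
    theta_min: float
    theta_max: float
    ground_truth: Optional[np.ndarray] = None  # (n, 5): row, col, a, b, angle (px)

    def sector_mask(self, shape: Optional[Tuple[int, int]] = None) -> np.ndarray:
        shape = shape or self.image.shape
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        dy = rr - self.apex[0]
        dx = cc - self.apex[1]
        r = np.hypot(dx, dy)
        th = np.arctan2(dy, dx)
        return (
            (r >= self.r_inner)
            & (r <= self.r_outer)
            & (th >= self.theta_min)
            & (th <= self.theta_max)
        )

    def point_in_sector(self, row: float, col: float) -> bool:
        dy, dx = row - self.apex[0], col - self.apex[1]
        r = math.hypot(dx, dy)
        th = math.atan2(dy, dx)
        return (
            self.r_inner <= r <= self.r_outer
            and self.theta_min <= th <= self.theta_max
        )


def _wedge_radii(sector_area_um2: float, angle_deg: float, inner_frac: float = 0.15):
    """Outer/inner radius (µm) of a wedge with the given area and angle."""
    theta = math.radians(angle_deg)
    r_out = math.sqrt(2.0 * sector_area_um2 / (theta * (1.0 - inner_frac**2)))
    return r_out, inner_frac * r_out


def render_sector(
    conduits: ConduitSet,
    pixel_size: float = 0.5,
    seed: int = 0,
    supersample: int = 2,
    max_attempts: int = 2000,
) -> SectorImage:
    """Rasterise a ConduitSet into a wedge image with known placements.

    Ellipse areas equal the conduit lumen areas; aspect ratios are drawn in
    [1, 1.3]; placement is dart-throwing with rejection on bounding-circle
    overlap.  Rendering is done on a ``supersample``× grid and
    block-averaged, which anti-aliases the edges.
    """
    areas = np.sort(conduits.lumen_areas)[::-1]  # large first packs better
    if areas.sum() > 0.6 * conduits.sector_area:
        raise ValueError("lumen packing above 60% of sector area is infeasible")
    rng = np.random.default_rng(seed)
    r_out_um, r_in_um = _wedge_radii(conduits.sector_area, conduits.sector_angle)
    theta = math.radians(conduits.sector_angle)
    th_min, th_max = -theta / 2.0, theta / 2.0

    margin_um = 2.0 * pixel_size
    placed = []  # (x_um, y_um, bound_r_um)
    params = []  # (x, y, a, b, angle) in µm
    for area in areas:
        aspect = rng.uniform(1.0, 1.3)
        # ellipse semi-axes with a·b = area/π
        a = math.sqrt(area / math.pi * aspect)
        b = area / math.pi / a
        bound = a + margin_um
        ok = False
        for _ in range(max_attempts):
            r = math.sqrt(rng.uniform(r_in_um**2, r_out_um**2))
            th = rng.uniform(th_min, th_max)
            x, y = r * math.cos(th), r * math.sin(th)
            if all(
                math.hypot(x - px, y - py) > bound + pb for px, py, pb in placed
            ):
                ok = True
                break
        if not ok:
            raise ValueError(
                f"placement failed for conduit area {area:.0f} µm² after "
                f"{max_attempts} attempts"
            )
        placed.append((x, y, bound))
        params.append((x, y, a, b, rng.uniform(0.0, math.pi)))

    # raster frame: apex sits at a margin inside the image
    pad_um = 4.0 * pixel_size
    half_h = r_out_um * math.sin(theta / 2.0) + pad_um
    n_cols = int(math.ceil((r_out_um + 2 * pad_um) / pixel_size))
    n_rows = int(math.ceil(2 * half_h / pixel_size))
    apex = (n_rows / 2.0, pad_um / pixel_size)

    ss = supersample
    fine = np.zeros((n_rows * ss, n_cols * ss), dtype=bool)
    truth = []
    for x, y, a, b, ang in params:
        row = apex[0] + y / pixel_size
        col = apex[1] + x / pixel_size
        truth.append((row, col, a / pixel_size, b / pixel_size, ang))
        # local patch on the fine grid
        a_px, b_px = a / pixel_size * ss, b / pixel_size * ss
        r0, c0 = row * ss, col * ss
        half = int(math.ceil(a_px)) + 2
        rlo, rhi = int(r0) - half, int(r0) + half + 1
        clo, chi = int(c0) - half, int(c0) + half + 1
        rlo, clo = max(rlo, 0), max(clo, 0)
        rhi, chi = min(rhi, fine.shape[0]), min(chi, fine.shape[1])
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        dr, dc = rr - r0, cc - c0
        ca, sa = math.cos(ang), math.sin(ang)
        u = dc * ca + dr * sa
        v = -dc * sa + dr * ca
        fine[rlo:rhi, clo:chi] |= (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0

    coarse = fine.reshape(n_rows, ss, n_cols, ss).mean(axis=(1, 3))
    image = 1.0 - coarse  # dark lumina on light background
    return SectorImage(
        image=image,
        pixel_size=pixel_size,
        apex=apex,
        r_inner=r_in_um / pixel_size,
        r_outer=r_out_um / pixel_size,
        theta_min=th_min,
        theta_max=th_max,
        ground_truth=np.array(truth) if truth else np.empty((0, 5)),
    )


def segment_conduits(
    sector_image: SectorImage,
    threshold: float | str = "otsu",
    min_area: float = 4.0,
    sample_id: str = "segmented",
    organ: str = "root",
) -> Optional[ConduitSet]:
    """Re-measure a rendered (or real) wedge image.

    Global threshold (Otsu's bimodal-histogram method by default) →
    connected components → area filter ≥ ``min_area`` (µm²) → keep
    components whose centroid lies inside the sector → lumen areas in µm².
    Returns ``None`` (with a warning) when nothing is found.
    """
    img = sector_image.image
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        if img.min() == img.max():
            log.warning("flat image; no conduits found")
            return None
        thr = filters.threshold_otsu(img)
    else:
        thr = float(threshold)
    mask = img < thr  # lumina are dark
    labels = measure.label(mask, connectivity=2)
    px_area = sector_image.pixel_size**2
    areas, kept = [], 0
    for region in measure.regionprops(labels):
        area_um2 = region.area * px_area
        if area_um2 < min_area:
            continue
        row, col = region.centroid
        if not sector_image.point_in_sector(row, col):
            continue
        kept += 1
        areas.append(area_um2)
    if not kept:
        log.warning("segmentation found no conduits above %.1f µm²", min_area)
        return None
    theta = math.degrees(sector_image.theta_max - sector_image.theta_min)
    sector_area = (
        0.5
        * math.radians(theta)
        * (sector_image.r_outer**2 - sector_image.r_inner**2)
        * px_area
    )
    return ConduitSet(
        sample_id=sample_id,
        organ=organ,
        sector_angle=theta,
        sector_area=sector_area,
        lumen_areas=np.array(areas),
    )


def save_png(sector_image: SectorImage, path) -> None:
    """Write the raster as an 8-bit grayscale PNG."""
    import imageio.v3 as iio

    img8 = np.clip(sector_image.image * 255.0, 0, 255).astype(np.uint8)
    iio.imwrite(path, img8)
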