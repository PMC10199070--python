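"""Foveal avascular zone extraction and shape morphometrics.

The FAZ is taken as the 4-connected background component containing the
raster center, after a morphological closing of the vessel mask (disc of
radius ``max_bridge_px``) seals small capillary gaps.  Shape metrics are
measured on the hole-filled region using a sub-pixel marching-squares
boundary contour (raw boundary-pixel counting overestimates perimeter and
would bias the acircularity index upward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from skimage import measure
from skimage.morphology import closing, disk

from .morphometrics import VesselMask


class FazExtractionError(RuntimeError):
    """Raised when no avascular region can be found at the raster center."""


@dataclass(frozen=True)
class FazRegion:
    pixels: np.ndarray  # boolean mask of the region
    touches_border: bool

    @property
    def area_px(self) -> int:
        return int(np.count_nonzero(self.pixels))


@dataclass(frozen=True)
class FazMetrics:
    """The seven FAZ shape descriptors, in physical units (mm / mm²)."""

    area_mm2: float
    perimeter_mm: float
    diameter_max_mm: float
    diameter_min_mm: float
    axis_ratio: float
    eccentricity: float
    acircularity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "faz_area_mm2": self.area_mm2,
            "faz_perimeter_mm": self.perimeter_mm,
            "faz_dmax_mm": self.diameter_max_mm,
            "faz_dmin_mm": self.diameter_min_mm,
            "faz_axis_ratio": self.axis_ratio,
            "faz_eccentricity": self.eccentricity,
            "faz_acircularity": self.acircularity,
        }


def extract_faz(m: VesselMask, max_bridge_px: int = 2) -> FazRegion:
    """Central avascular background component of a vessel mask.

    Raises :class:`FazExtractionError` if the center is vascular even after
    closing.  A region reaching the raster border is returned but flagged
    ``touches_border`` (unreliable: the component may extend off-field).
    """
    vessels = m.pixels
    if max_bridge_px > 0:
        vessels = closing(vessels, disk(max_bridge_px))
    background = ~vessels
    labels, _ = ndi.label(background, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))  # 4-connectivity
    center = (vessels.shape[0] // 2, vessels.shape[1] // 2)
    lab = labels[center]
    if lab == 0:
        raise FazExtractionError("raster center is vascular after closing")
    region = labels == lab
    touches = bool(
        region[0, :].any() or region[-1, :].any()
        or region[:, 0].any() or region[:, -1].any()
    )
    return FazRegion(pixels=region, touches_border=touches)


def _boundary_contour(region: np.ndarray) -> np.ndarray:
    """Longest marching-squares contour of a padded binary region."""
    padded = np.pad(region.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise FazExtractionError("region has no boundary contour")
    return max(contours, key=lambda c: c.shape[0])


def _contour_length(contour: np.ndarray, smooth: int = 5) -> float:
    """Length of a closed contour after light circular smoothing.

    The raw marching-squares polygon overestimates the length of smooth
    boundaries by ~5% (staircase excess); a short circular moving average
    of the vertex coordinates removes that bias to within ~0.3% for discs
    of radius >= 30 px.
    """
    if smooth > 1 and contour.shape[0] > 2 * smooth:
        open_c = contour[:-1]
        sm = np.column_stack([
            ndi.uniform_filter1d(open_c[:, i], smooth, mode="wrap") for i in (0, 1)
        ])
        contour = np.vstack([sm, sm[:1]])
    diffs = np.diff(contour, axis=0)
    return float(np.sqrt((diffs**2).sum(axis=1)).sum())


def _feret_diameters(contour: np.ndarray) -> tuple[float, float]:
    """(max, min) Feret diameters of the convex hull of the contour points."""
    pts = contour
    if len(pts) >= 4:
        try:
            pts = contour[ConvexHull(contour).vertices]
        except Exception:  # degenerate (collinear) input
            pass
    # max Feret: largest pairwise distance over hull vertices
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    dmax = float(np.sqrt(d2.max()))
    # min Feret: smallest width over hull-edge support directions
    edges = np.roll(pts, -1, axis=0) - pts
    norms = np.hypot(edges[:, 0], edges[:, 1])
    keep = norms > 1e-12
    if not keep.any():
        return dmax, 0.0
    normals = np.stack([-edges[keep, 1], edges[keep, 0]], axis=1) / norms[keep, None]
    proj = pts @ normals.T  # (n_pts, n_edges)
    widths = proj.max(axis=0) - proj.min(axis=0)
    return dmax, float(widths.min())


def faz_shape_metrics(region: FazRegion | np.ndarray, scale_um_per_px: float) -> FazMetrics:
    """Measure area, perimeter, Feret diameters, moment-ellipse shape and
    acircularity of a (hole-filled) region at the given physical scale."""
    mask = region.pixels if isinstance(region, FazRegion) else np.asarray(region, bool)
    if not mask.any():
        raise ValueError("empty region")
    if scale_um_per_px <= 0:
        raise ValueError("scale must be positive")
    filled = ndi.binary_fill_holes(mask)

    scale_mm = scale_um_per_px / 1000.0
    area_mm2 = float(np.count_nonzero(filled)) * scale_mm**2

    contour = _boundary_contour(filled)
    perimeter_mm = _contour_length(contour) * scale_mm
    dmax_px, dmin_px = _feret_diameters(contour)

    props = measure.regionprops(filled.astype(np.uint8))[0]
    minor = props.axis_minor_length
    axis_ratio = float(props.axis_major_length / minor) if minor > 0 else float("inf")
    eccentricity = float(props.eccentricity)

    acircularity = perimeter_mm / (2.0 * np.sqrt(np.pi * area_mm2))
    return FazMetrics(
        area_mm2=area_mm2,
        perimeter_mm=perimeter_mm,
        diameter_max_mm=dmax_px * scale_mm,
        diameter_min_mm=dmin_px * scale_mm,
        axis_ratio=axis_ratio,
        eccentricity=eccentricity,
        acircularity=float(acircularity),
    )
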