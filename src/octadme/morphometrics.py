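"""En-face angiogram morphometrics: frame averaging, binarization,
perfusion/vessel density and the per-eye measurement pipeline.

Conventions pinned here (they affect downstream numbers and are therefore
explicit):

* binarization uses the ``>=`` rule: a pixel exactly at threshold is vessel;
* the quality gate is strict: signal strength must exceed ``min_signal``;
* skeletonization is topology-preserving 2-D thinning (Zhang-Suen style, as
  implemented by :func:`skimage.morphology.skeletonize`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage.registration import phase_cross_correlation

from .magnification import MagnificationModel

log = logging.getLogger(__name__)

DEFAULT_BINARIZE_THRESHOLD = 0.5
DEFAULT_MIN_SIGNAL = 50.0


@dataclass(frozen=True)
class EnFaceAngiogram:
    """A vessel-probability raster plus the per-eye scan metadata."""

    pixels: np.ndarray  # 2-D float array, values in [0, 1]
    nominal_scan_width_mm: float = 3.0
    signal_strength: float | None = None
    axial_length_mm: float | None = None
    refraction_D: float | None = None
    keratometry_mm: float | None = None
    eye_id: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixel grid must be a non-empty 2-D array")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.nominal_scan_width_mm <= 0:
            raise ValueError("nominal_scan_width_mm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def nominal_scale_um_per_px(self) -> float:
        """Lateral scale implied by the nominal scan width (pre-correction)."""
        return self.nominal_scan_width_mm * 1000.0 / self.pixels.shape[1]


@dataclass(frozen=True)
class VesselMask:
    """Binary vessel raster with its physical pixel scale (µm/px)."""

    pixels: np.ndarray
    scale_um_per_px: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("mask must be a non-empty 2-D array")
        if self.scale_um_per_px <= 0:
            raise ValueError("scale_um_per_px must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class SkeletonMask:
    """1-px-wide skeleton; foreground is a subset of the source mask."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=bool))


@dataclass(frozen=True)
class DensityMetrics:
    perfusion_density: float
    vessel_density: float

    def __post_init__(self) -> None:
        if self.vessel_density > self.perfusion_density + 1e-12:
            raise ValueError("vessel_density cannot exceed perfusion_density")


def average_frames(
    frames: Sequence[EnFaceAngiogram], *, align: bool = False
) -> EnFaceAngiogram:
    """Pixel-wise mean of repeated scans of the same eye.

    With ``align=True`` each frame is first shifted by the integer
    translation maximizing its cross-correlation with the first frame
    (frames are otherwise assumed pre-registered).  Metadata is taken from
    the first frame; a single frame is returned unchanged.
    """
    if len(frames) == 0:
        raise ValueError("average_frames requires at least one frame")
    shape = frames[0].shape
    for f in frames[1:]:
        if f.shape != shape:
            raise ValueError(f"frame shape mismatch: {f.shape} != {shape}")
    if len(frames) == 1:
        return frames[0]
    stack = []
    ref = frames[0].pixels
    for f in frames:
        px = f.pixels
        if align and f is not frames[0]:
            shift, _, _ = phase_cross_correlation(ref, px, upsample_factor=1)
            px = np.roll(px, tuple(int(s) for s in shift), axis=(0, 1))
        stack.append(px)
    mean = np.clip(np.mean(stack, axis=0), 0.0, 1.0)
    return replace(frames[0], pixels=mean)


def passes_quality(a: EnFaceAngiogram, min_signal: float = DEFAULT_MIN_SIGNAL) -> bool:
    """Strict signal-strength gate; absent signal strength fails (logged)."""
    if a.signal_strength is None:
        log.warning("eye %s: no signal strength recorded; failing quality gate", a.eye_id)
        return False
    return a.signal_strength > min_signal


def binarize(
    a: EnFaceAngiogram,
    threshold: float = DEFAULT_BINARIZE_THRESHOLD,
    *,
    scale_um_per_px: float | None = None,
) -> VesselMask:
    """Threshold the probability raster into a vessel mask (``>=`` rule)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    scale = a.nominal_scale_um_per_px if scale_um_per_px is None else scale_um_per_px
    return VesselMask(pixels=a.pixels >= threshold, scale_um_per_px=scale)


def perfusion_density(m: VesselMask) -> float:
    """Fraction of all pixels segmented as vasculature."""
    return float(np.count_nonzero(m.pixels)) / m.pixels.size


def _zhang_suen(img: np.ndarray) -> np.ndarray:
    """Parallel Zhang-Suen thinning (vectorized textbook formulation).

    Both sub-iterations delete all flagged pixels simultaneously; the loop
    runs until a full pass deletes nothing.
    """
    img = img.astype(bool).copy()
    idx = np.arange(8)
    changed = True
    while changed:
        changed = False
        for phase in (0, 1):
            a = np.pad(img, 1)
            # p2..p9: clockwise neighbours starting north
            P = np.stack([
                a[:-2, 1:-1], a[:-2, 2:], a[1:-1, 2:], a[2:, 2:],
                a[2:, 1:-1], a[2:, :-2], a[1:-1, :-2], a[:-2, :-2],
            ])
            B = P.sum(axis=0)
            A = ((~P[idx]) & P[(idx + 1) % 8]).sum(axis=0)
            if phase == 0:
                keep = (P[0] & P[2] & P[4]) | (P[2] & P[4] & P[6])
            else:
                keep = (P[0] & P[2] & P[6]) | (P[0] & P[4] & P[6])
            delete = img & (B >= 2) & (B <= 6) & (A == 1) & ~keep
            if delete.any():
                img &= ~delete
                changed = True
    return img


def _prune_corners(img: np.ndarray) -> np.ndarray:
    """Delete one simple pixel from any residual 2x2 block.

    Zhang-Suen can leave 2x2 blocks at junctions; a pixel is removed
    (deterministic row-major order) only when it has exactly one 0->1
    transition around its neighbourhood, which preserves connectivity.
    """
    from scipy import ndimage as _ndi

    img = np.pad(img.copy(), 1)

    def simple(r: int, c: int) -> bool:
        patch = img[r - 1:r + 2, c - 1:c + 2].copy()
        patch[1, 1] = False
        _, n = _ndi.label(patch, structure=np.ones((3, 3)))
        return n == 1

    while True:
        blocks = img[:-1, :-1] & img[1:, :-1] & img[:-1, 1:] & img[1:, 1:]
        if not blocks.any():
            return img[1:-1, 1:-1]
        progressed = False
        for br, bc in zip(*np.nonzero(blocks)):
            for r, c in ((br, bc), (br, bc + 1), (br + 1, bc), (br + 1, bc + 1)):
                if img[r, c] and simple(r, c):
                    img[r, c] = False
                    progressed = True
                    break
            if progressed:
                break
        if not progressed:  # pathological tie: leave as-is rather than loop
            return img[1:-1, 1:-1]


def skeletonize(m: VesselMask) -> SkeletonMask:
    """Topological thinning of the vessel mask to a 1-px skeleton
    (parallel Zhang-Suen plus corner pruning of residual 2x2 blocks)."""
    return SkeletonMask(pixels=_prune_corners(_zhang_suen(m.pixels)))


def vessel_density(m: VesselMask) -> DensityMetrics:
    """Perfusion density plus its width-independent skeletonized counterpart."""
    pd = perfusion_density(m)
    skel = skeletonize(m)
    vd = float(np.count_nonzero(skel.pixels)) / skel.pixels.size
    return DensityMetrics(perfusion_density=pd, vessel_density=vd)


@dataclass
class EyeMeasurement:
    """Result bundle from :func:`measure_eye`."""

    density: DensityMetrics | None
    faz: "object | None"  # FazMetrics; avoid import cycle in annotations
    qc_pass: bool
    qc_reasons: list[str] = field(default_factory=list)
    scale_um_per_px: float | None = None
    intermediates: dict = field(default_factory=dict)


def measure_eye(
    frames: Sequence[EnFaceAngiogram],
    *,
    magnification: MagnificationModel | None = None,
    threshold: float = DEFAULT_BINARIZE_THRESHOLD,
    min_signal: float = DEFAULT_MIN_SIGNAL,
    max_bridge_px: int = 2,
    align: bool = False,
    keep_intermediates: bool = False,
) -> EyeMeasurement:
    """Quality-gate, average, binarize, magnification-correct and measure.

    Eyes whose every frame fails the quality gate are excluded: the result
    carries ``qc_pass=False`` with reason codes and no metrics.  FAZ
    extraction failure is recorded as a QC reason but does not void the
    density metrics.
    """
    from .faz import FazExtractionError, extract_faz, faz_shape_metrics

    if len(frames) == 0:
        raise ValueError("measure_eye requires at least one frame")
    reasons: list[str] = []
    usable = [f for f in frames if passes_quality(f, min_signal)]
    if not usable:
        return EyeMeasurement(
            density=None, faz=None, qc_pass=False,
            qc_reasons=["poor_quality_imaging"],
        )
    if len(usable) < len(frames):
        reasons.append(f"dropped_low_signal_frames:{len(frames) - len(usable)}")

    avg = average_frames(usable, align=align)
    scale = avg.nominal_scale_um_per_px
    if magnification is not None:
        if avg.axial_length_mm is not None:
            model = replace(magnification, subject_axial_length_mm=avg.axial_length_mm)
        else:
            model = magnification
            reasons.append("no_axial_length:using_model_default")
        scale *= model.factor()
    mask = binarize(avg, threshold, scale_um_per_px=scale)
    density = vessel_density(mask)

    faz_metrics = None
    intermediates: dict = {}
    try:
        region = extract_faz(mask, max_bridge_px=max_bridge_px)
        faz_metrics = faz_shape_metrics(region, mask.scale_um_per_px)
        if region.touches_border:
            reasons.append("faz_touches_border")
        if keep_intermediates:
            intermediates["faz_region"] = region.pixels
    except FazExtractionError as exc:
        reasons.append(f"no_faz_found:{exc}")

    if keep_intermediates:
        intermediates["averaged"] = avg.pixels
        intermediates["mask"] = mask.pixels
        intermediates["skeleton"] = skeletonize(mask).pixels

    return EyeMeasurement(
        density=density,
        faz=faz_metrics,
        qc_pass=True,
        qc_reasons=reasons,
        scale_um_per_px=scale,
        intermediates=intermediates,
    )
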