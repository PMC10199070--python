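"""Synthetic en-face angiograms with exact centerline ground truth.

Capillary networks are grown as biased random walks entering from the raster
border and drifting toward the center, branching occasionally, and stopping
at a central avascular ellipse.  Growth halts the moment the rasterized
centerline reaches the requested pixel count, so the recorded ground-truth
skeleton density equals the target exactly.  Centerlines are then dilated to
the requested vessel width and bounded Gaussian noise is added to produce a
vessel-probability raster.

Every stochastic draw comes from a named substream of one integer seed, so
adding new generators never perturbs existing outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse_perimeter
from skimage.morphology import dilation, disk

from ..morphometrics import EnFaceAngiogram

_ANGIO_STREAM = 101  # substream tag: default_rng([seed, tag])

#: growth refuses to pack centerlines denser than this fraction of the
#: pixels available outside the avascular ellipse
_MAX_FILL = 0.30


class DensityUnreachableError(ValueError):
    """Target centerline density cannot be realized for these parameters."""


@dataclass(frozen=True)
class AngiogramParams:
    shape: tuple[int, int] = (256, 256)
    target_density: float = 0.098
    vessel_width_px: int = 2
    faz_center_px: tuple[float, float] | None = None  # default: raster center
    faz_semi_axes_px: tuple[float, float] = (28.0, 22.0)
    faz_rotation_rad: float = 0.0
    draw_faz_ring: bool = True
    noise_sd: float = 0.0
    turn_sd: float = 0.12
    branch_prob: float = 0.012
    seed: int = 0
    # scan metadata carried onto the emitted angiogram
    nominal_scan_width_mm: float = 3.0
    signal_strength: float = 62.0
    axial_length_mm: float = 23.95


@dataclass
class AngiogramTruth:
    centerline_set: list[np.ndarray]
    centerline_mask: np.ndarray
    true_skeleton_density: float
    faz_ellipse: tuple[tuple[float, float], tuple[float, float], float]
    vessel_width_px: int
    noise_sd: float
    seed: int
    metadata: dict = field(default_factory=dict)


def _inside_ellipse(r, c, center, axes, rot) -> bool:
    dr, dc = r - center[0], c - center[1]
    cr, sr = math.cos(rot), math.sin(rot)
    u = dr * cr + dc * sr
    v = -dr * sr + dc * cr
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 < 1.0 - 1e-9


def _validate(p: AngiogramParams) -> None:
    h, w = p.shape
    if h <= 0 or w <= 0:
        raise ValueError("raster shape must be positive")
    a, b = p.faz_semi_axes_px
    if a <= 0 or b <= 0:
        raise ValueError("FAZ semi-axes must be positive")
    if a >= min(h, w) / 2 or b >= min(h, w) / 2:
        raise ValueError("FAZ semi-axes must be smaller than half the raster")
    if not 0.0 <= p.target_density < 1.0:
        raise ValueError("target_density must lie in [0, 1)")
    if p.vessel_width_px < 1:
        raise ValueError("vessel_width_px must be a positive integer")
    if p.noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")


def simulate_angiogram(params: AngiogramParams) -> tuple[EnFaceAngiogram, AngiogramTruth]:
    """Generate one angiogram and its exact centerline truth.

    Raises :class:`DensityUnreachableError` when the requested density
    cannot be packed (too high for the available area at the requested
    width) rather than silently clipping.
    """
    _validate(params)
    h, w = params.shape
    total = h * w
    center = params.faz_center_px or ((h - 1) / 2.0, (w - 1) / 2.0)
    axes = params.faz_semi_axes_px
    rot = params.faz_rotation_rad
    rng = np.random.default_rng([params.seed, _ANGIO_STREAM])

    target_count = int(round(params.target_density * total))
    #: centerlines keep a chebyshev clearance of `margin` from foreign
    #: vessels so that tubes dilated to the requested width never merge
    margin = max(1, 2 * (params.vessel_width_px // 2) + 1)
    # pixels strictly inside the ellipse are off-limits to centerlines, and
    # the clearance rule caps how densely lines can pack outside it
    inside_area = math.pi * axes[0] * axes[1]
    available = total - inside_area
    if target_count > min(_MAX_FILL, 0.8 / (margin + 1)) * available:
        raise DensityUnreachableError(
            f"target density {params.target_density} unreachable at width "
            f"{params.vessel_width_px} on a {h}x{w} raster"
        )

    mask = np.zeros((h, w), dtype=bool)
    polylines: list[np.ndarray] = []
    pixlist: list[tuple[int, int]] = []
    count = 0

    def mark(r: int, c: int) -> bool:
        """Mark a pixel; return True when the target count is reached."""
        nonlocal count
        if not mask[r, c]:
            mask[r, c] = True
            pixlist.append((r, c))
            count += 1
        return count >= target_count

    done = False
    if params.draw_faz_ring and target_count > 0:
        # terminal capillary ring traced just outside the avascular ellipse
        rr, cc = ellipse_perimeter(
            int(round(center[0])), int(round(center[1])),
            int(round(axes[0] + 1.0)), int(round(axes[1] + 1.0)),
            orientation=rot, shape=(h, w),
        )
        ring_pts = []
        for r, c in zip(rr, cc):
            if _inside_ellipse(r, c, center, axes, rot):
                continue
            ring_pts.append((r, c))
            if mark(r, c):
                done = True
                break
        if ring_pts:
            polylines.append(np.asarray(ring_pts, dtype=float))

    center_angle_bias = 0.04  # pull of the walk heading toward the center
    max_steps = int(2.0 * max(h, w))
    spawned = 0
    max_spawn = 20000
    pending: list[tuple[int, int, float]] = []
    # 8-connected chain moves indexed by quantized heading; the rasterized
    # centerline is then a minimal digital path, matching what topological
    # thinning of the dilated tube recovers
    chain = [(int(round(math.sin(k * math.pi / 4))), int(round(math.cos(k * math.pi / 4))))
             for k in range(8)]

    while not done and count < target_count:
        if pending:
            r, c, ang = pending.pop()
        else:
            spawned += 1
            if spawned > max_spawn:
                raise DensityUnreachableError(
                    "growth stalled before reaching target density"
                )
            if count == 0 or rng.random() < 0.25:
                side = rng.integers(4)
                if side == 0:
                    r, c = 0, int(rng.integers(0, w))
                elif side == 1:
                    r, c = h - 1, int(rng.integers(0, w))
                elif side == 2:
                    r, c = int(rng.integers(0, h)), 0
                else:
                    r, c = int(rng.integers(0, h)), w - 1
                ang = math.atan2(center[0] - r, center[1] - c) + rng.normal(0, 0.5)
            else:
                # sprout from the existing network at a random angle
                r, c = pixlist[int(rng.integers(len(pixlist)))]
                ang = rng.uniform(-math.pi, math.pi)

        origin = (r, c)
        pts: list[tuple[int, int]] = []
        recent: set[tuple[int, int]] = set()
        retain = 4 * margin + 2  # own trailing pixels exempt from the join check
        walk_start = len(pixlist)
        for _ in range(max_steps):
            if not (0 <= r < h and 0 <= c < w):
                break
            if _inside_ellipse(r, c, center, axes, rot):
                break
            # anastomose: coming within `margin` of a foreign vessel joins
            # it and ends the walk, so dilated tubes never run merged in
            # parallel (clumps would shorten the thinned skeleton)
            joined = False
            for dr in range(-margin, margin + 1):
                for dc in range(-margin, margin + 1):
                    nb = (r + dr, c + dc)
                    if (dr or dc) and nb not in recent \
                            and 0 <= nb[0] < h and 0 <= nb[1] < w and mask[nb] \
                            and max(abs(nb[0] - origin[0]), abs(nb[1] - origin[1])) > margin + 1:
                        # foreign vessel within clearance (origin's own
                        # neighborhood exempt so sprouts can leave their parent)
                        joined = True
            pts.append((r, c))
            recent.add((r, c))
            if len(pts) >= retain + 1:
                recent.discard(pts[-retain - 1])
            if mark(r, c):
                done = True
                break
            if joined:
                break
            if rng.random() < params.branch_prob:
                pending.append((r, c, ang + rng.choice([-1.0, 1.0]) * rng.normal(0.7, 0.2)))
            to_center = math.atan2(center[0] - r, center[1] - c)
            delta = (to_center - ang + math.pi) % (2 * math.pi) - math.pi
            ang += center_angle_bias * delta + rng.normal(0, params.turn_sd)
            dr, dc = chain[int(round(ang / (math.pi / 4))) % 8]
            r, c = r + dr, c + dc
        if not done and len(pts) < 12:
            # roll back stub walks: 1-2 px spurs vanish under dilation +
            # thinning and would silently inflate the recorded truth
            for p_ in pixlist[walk_start:]:
                mask[p_] = False
            count -= len(pixlist) - walk_start
            del pixlist[walk_start:]
        elif pts:
            polylines.append(np.asarray(pts, dtype=float))

    density = count / total

    if params.vessel_width_px == 1:
        clean = mask.astype(float)
    else:
        wd = params.vessel_width_px
        footprint = disk((wd - 1) // 2) if wd % 2 == 1 else np.ones((wd, wd), bool)
        clean = dilation(mask, footprint).astype(float)

    if params.noise_sd > 0:
        clean = clean + rng.normal(0.0, params.noise_sd, size=clean.shape)
    pixels = np.clip(clean, 0.0, 1.0)

    angiogram = EnFaceAngiogram(
        pixels=pixels,
        nominal_scan_width_mm=params.nominal_scan_width_mm,
        signal_strength=params.signal_strength,
        axial_length_mm=params.axial_length_mm,
    )
    truth = AngiogramTruth(
        centerline_set=polylines,
        centerline_mask=mask,
        true_skeleton_density=density,
        faz_ellipse=(center, axes, rot),
        vessel_width_px=params.vessel_width_px,
        noise_sd=params.noise_sd,
        seed=params.seed,
        metadata={"shape": (h, w), "target_density": params.target_density},
    )
    return angiogram, truth
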