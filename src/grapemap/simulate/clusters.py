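"""Synthetic grape-cluster masks with analytic ground truth.

Berries are ellipses packed inside an elliptical cluster envelope.  Each of
the two camera angles (front 0 deg / side 90 deg) is rendered by the
painter's algorithm with its own random depth order: a berry's visible mask
is its ellipse minus every berry drawn nearer to the camera.  Berries whose
visible fraction falls below a threshold are considered missed by the
segmenter, which reproduces the occlusion-driven undercounting that the
linear count correction exists to fix.  Rachis-like elongated artifacts are
added as labelled non-berry shapes so the filtering stages have something to
reject.

Ground truth (berry count, total projected berry area, compactness) is
computed from the un-occluded geometry, so estimator error can be measured
exactly.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely import affinity
from shapely.geometry import Polygon
from shapely.ops import unary_union

from grapemap._geometry import convex_hull_of
from grapemap.masks import BerryMask

__all__ = ["ClusterSimConfig", "ClusterTruth", "PlacementError", "simulate_cluster"]

_ELLIPSE_SEGMENTS = 48  # boundary resolution of each berry polygon


class PlacementError(RuntimeError):
    """Envelope too small to place the requested berries at the requested tightness."""


@dataclass
class ClusterSimConfig:
    """Study-like defaults: ~46 berries of ~222 mm^2 projected area
    (radius ~8.4 mm), moderately tight packing, two angles, a few rachis
    fragments, 0.25 mm/px imaging scale."""

    n_berries: int = 46
    n_berries_sd: float = 8.78  # cluster-to-cluster spread used by the pipeline
    berry_radius_mean: float = 8.4  # mm
    berry_radius_sd: float = 0.8  # mm
    berry_eccentricity_range: tuple[float, float] = (1.0, 1.25)  # major/minor axis ratio
    envelope: tuple[float, float] = (110.0, 220.0)  # semi-axes mm (x, y); clusters are elongated
    packing_tightness: float = 0.65  # in (0, 1]; higher = closer centres = more occlusion
    berries_per_clump: float = 4.0  # average clump (shoulder) size
    clump_spread: float = 1.4  # clump SD in units of mean berry radius
    n_artifacts: int = 3
    boundary_noise: float = 0.03  # fractional radial irregularity of berry outlines
    mm_per_px: float = 0.25
    visible_min_fraction: float = 0.30  # berries more occluded than this are missed
    allow_overlap: bool = True
    compute_truth_areas: bool = True  # union area / compactness truth (skippable for speed)
    n_angles: int = 2
    seed: int = 0
    max_placement_attempts: int = 400  # per berry

    def __post_init__(self) -> None:
        if self.n_berries < 1:
            raise ValueError("n_berries must be >= 1")
        if not self.mm_per_px > 0:
            raise ValueError("mm_per_px must be positive")
        if not (0.0 < self.packing_tightness <= 1.0):
            raise ValueError("packing_tightness must be in (0, 1]")
        lo, hi = self.berry_eccentricity_range
        if not (1.0 <= lo <= hi):
            raise ValueError("eccentricity range must satisfy 1 <= lo <= hi")


@dataclass
class ClusterTruth:
    true_berry_count: int
    true_total_berry_area: float  # mm^2, area of the union of berry ellipses
    true_compactness: float
    visible_counts_per_angle: list[int]
    berry_areas: np.ndarray = field(repr=False, default=None)  # per-berry un-occluded mm^2


def _ellipse(
    center: np.ndarray,
    a: float,
    b: float,
    angle_deg: float,
    rng: np.random.Generator | None = None,
    noise: float = 0.0,
) -> Polygon:
    """Ellipse polygon, optionally with smooth low-order radial irregularity
    (berries in images are not perfect ellipses)."""
    theta = np.linspace(0.0, 2.0 * np.pi, _ELLIPSE_SEGMENTS, endpoint=False)
    radial = np.ones_like(theta)
    if noise > 0 and rng is not None:
        for k in range(2, 7):
            amp = noise / np.sqrt(5.0)
            radial += rng.normal(0, amp) * np.cos(k * theta) + rng.normal(0, amp) * np.sin(k * theta)
    pts = np.column_stack([a * radial * np.cos(theta), b * radial * np.sin(theta)])
    ell = Polygon(pts)
    ell = affinity.rotate(ell, angle_deg)
    return affinity.translate(ell, center[0], center[1])


def _place_centers(cfg: ClusterSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample berry centres inside the envelope with a minimum
    centre spacing controlled by packing_tightness (1 -> heavy contact)."""
    A, B = cfg.envelope
    r = cfg.berry_radius_mean
    # tightness -> 0: centres at least a diameter apart (no contact);
    # tightness -> 1: centres may coincide (heavy projected overlap).
    # A projection of a 3D cluster shows exactly this mix of local overlap
    # and large empty hull regions.
    d_min = 2.0 * r * (1.0 - cfg.packing_tightness)
    if cfg.allow_overlap is False:
        d_min = 2.0 * r * np.sqrt(cfg.berry_eccentricity_range[1]) + 3.0 * cfg.berry_radius_sd
    inner_a, inner_b = max(A - r, 1e-6), max(B - r, 1e-6)
    # berries hang in local clumps (shoulders) around attachment points on
    # the rachis; clumping creates the local overlap that drives occlusion
    # while the envelope keeps the hull large
    n_clumps = max(1, int(round(cfg.n_berries / cfg.berries_per_clump)))
    # attachment points fill the envelope evenly (berries attach along the
    # whole rachis): sunflower-spiral layout with jitter, so the occupied
    # region — and hence the hull — is stable across renders
    k = np.arange(1, n_clumps + 1)
    rad = np.sqrt((k - 0.5) / n_clumps)
    ang = k * np.pi * (3.0 - np.sqrt(5.0)) + rng.uniform(0, 2 * np.pi)
    jit = 0.15 / max(np.sqrt(n_clumps), 1.0)
    u = rad * np.cos(ang) + rng.normal(0, jit, n_clumps)
    v = rad * np.sin(ang) + rng.normal(0, jit, n_clumps)
    scale = np.maximum(np.hypot(u, v), 1e-9)
    shrink = np.where(scale > 1.0, 1.0 / scale, 1.0)
    clumps = [np.array([u[i] * shrink[i] * inner_a, v[i] * shrink[i] * inner_b]) for i in range(n_clumps)]
    clump_sd = cfg.clump_spread * r
    centers: list[np.ndarray] = []
    for _ in range(cfg.n_berries):
        for _attempt in range(cfg.max_placement_attempts):
            c = clumps[rng.integers(n_clumps)] + rng.normal(0.0, clump_sd, size=2)
            if (c[0] / inner_a) ** 2 + (c[1] / inner_b) ** 2 > 1.0:
                continue
            if all(np.hypot(*(c - o)) >= d_min for o in centers):
                centers.append(c)
                break
        else:
            raise PlacementError(
                f"could not place berry {len(centers) + 1}/{cfg.n_berries} "
                f"in envelope {cfg.envelope} at tightness {cfg.packing_tightness}"
            )
    return np.array(centers)


def simulate_cluster(cfg: ClusterSimConfig) -> tuple[list[list[BerryMask]], ClusterTruth]:
    """Render one cluster.

    Returns
    -------
    masks_per_angle : list (length ``cfg.n_angles``) of lists of
        :class:`BerryMask` in pixel coordinates.  Berry masks carry
        ``label={'is_berry': True, 'berry_id': i}``; artifacts carry
        ``is_berry: False``.
    truth : :class:`ClusterTruth` from the un-occluded geometry (mm units).
    """
    rng = np.random.default_rng(cfg.seed)
    centers = _place_centers(cfg, rng)
    radii = np.clip(
        rng.normal(cfg.berry_radius_mean, cfg.berry_radius_sd, size=cfg.n_berries),
        0.2 * cfg.berry_radius_mean,
        None,
    )
    ecc = rng.uniform(*cfg.berry_eccentricity_range, size=cfg.n_berries)
    angles = rng.uniform(0.0, 180.0, size=cfg.n_berries)
    # a*b = r^2 keeps the area at pi r^2 regardless of eccentricity
    berries = [
        _ellipse(
            centers[i],
            radii[i] * np.sqrt(ecc[i]),
            radii[i] / np.sqrt(ecc[i]),
            angles[i],
            rng,
            cfg.boundary_noise,
        )
        for i in range(cfg.n_berries)
    ]
    berry_areas = np.array([b.area for b in berries])
    if cfg.compute_truth_areas:
        union_area = float(unary_union(berries).area)
        hull = convex_hull_of(berries)
        true_compactness = union_area / hull.area
    else:
        union_area = float("nan")
        true_compactness = float("nan")
    truth = ClusterTruth(
        true_berry_count=cfg.n_berries,
        true_total_berry_area=union_area,
        true_compactness=true_compactness,
        visible_counts_per_angle=[],
        berry_areas=berry_areas,
    )

    # rachis-like artifacts: long thin capsules crossing the cluster
    artifacts: list[Polygon] = []
    for _ in range(cfg.n_artifacts):
        c = centers[rng.integers(cfg.n_berries)] + rng.normal(0, cfg.berry_radius_mean, 2)
        length = rng.uniform(4.0, 8.0) * cfg.berry_radius_mean
        width = rng.uniform(0.15, 0.3) * cfg.berry_radius_mean
        art = _ellipse(c, length / 2.0, width / 2.0, rng.uniform(0, 180))
        artifacts.append(art)

    s = 1.0 / cfg.mm_per_px  # mm -> px
    # shift so everything is in the positive pixel quadrant
    all_geoms = berries + artifacts
    minx = min(g.bounds[0] for g in all_geoms)
    miny = min(g.bounds[1] for g in all_geoms)
    pad = 4.0 * cfg.berry_radius_mean

    def to_px(geom: Polygon) -> Polygon:
        g = affinity.translate(geom, -minx + pad, -miny + pad)
        return affinity.scale(g, s, s, origin=(0, 0))

    masks_per_angle: list[list[BerryMask]] = []
    for angle_idx in range(cfg.n_angles):
        # painter's order: iterate near-to-far, clipping by nearer berries
        # (only bbox-overlapping ones can occlude)
        order = rng.permutation(cfg.n_berries)
        bnds = [berries[i].bounds for i in range(cfg.n_berries)]
        view: list[BerryMask] = []
        visible = 0
        drawn: list[int] = []
        for i in order:
            bi = bnds[i]
            occl = [
                berries[j]
                for j in drawn
                if not (
                    bnds[j][2] < bi[0]
                    or bi[2] < bnds[j][0]
                    or bnds[j][3] < bi[1]
                    or bi[3] < bnds[j][1]
                )
            ]
            drawn.append(i)
            vis = berries[i] if not occl else berries[i].difference(unary_union(occl))
            if vis.is_empty:
                continue
            if vis.geom_type != "Polygon":
                pieces = [g for g in vis.geoms if g.geom_type == "Polygon"]
                if not pieces:
                    continue
                vis = max(pieces, key=lambda g: g.area)
            if vis.area / berry_areas[i] < cfg.visible_min_fraction:
                continue
            visible += 1
            view.append(
                BerryMask(
                    mask_id=f"a{angle_idx}_b{i:03d}",
                    polygon=to_px(vis),
                    label={"is_berry": True, "berry_id": int(i), "angle": angle_idx},
                    validate=False,
                )
            )
        view.sort(key=lambda m: m.mask_id)
        for k, art in enumerate(artifacts):
            view.append(
                BerryMask(
                    mask_id=f"a{angle_idx}_art{k:02d}",
                    polygon=to_px(art),
                    label={"is_berry": False, "artifact_id": k, "angle": angle_idx},
                )
            )
        truth.visible_counts_per_angle.append(visible)
        masks_per_angle.append(view)
    return masks_per_angle, truth
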