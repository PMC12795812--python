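"""Calibrated berry- and cluster-level traits.

Given a clean set of berry masks (pixel polygons) and a mm-per-pixel scale,
computes the digital traits used for genetic analysis: per-berry projected
area, length and width; per-cluster berry count (with an occlusion
correction fitted on calibration clusters of known count), the cluster
compactness index, and the cluster aspect ratio.

The compactness index is the ratio of the total berry mask area to the area
of the convex hull enclosing all berry masks: 1 for a single convex berry,
small for loose clusters with much empty hull space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from sklearn.base import BaseEstimator, RegressorMixin

from grapemap._geometry import convex_hull_of, principal_extent_ratio, second_moment_axes
from grapemap.masks import BerryMask

__all__ = [
    "ScaleCalibration",
    "ClusterPhenotype",
    "calibrate_scale",
    "berry_traits",
    "compactness_index",
    "cluster_aspect_ratio",
    "CountCorrection",
    "aggregate_views",
]


@dataclass
class ScaleCalibration:
    mm_per_px: float
    source: str = "metadata"

    def __post_init__(self) -> None:
        if not self.mm_per_px > 0:
            raise ValueError("mm_per_px must be positive")


@dataclass
class ClusterPhenotype:
    """Digital traits of one cluster (possibly aggregated over views)."""

    cluster_id: str
    berry_count_observed: tuple[int, ...]  # one entry per imaged angle
    berry_count_corrected: float | None
    mean_berry_area: float  # mm^2
    mean_berry_length: float  # mm
    mean_berry_width: float  # mm
    compactness: float
    cluster_aspect_ratio: float
    n_views: int = 1
    flags: list[str] = field(default_factory=list)


def calibrate_scale(
    reference_mask: BerryMask | None = None,
    known_size_mm: float | None = None,
    mm_per_px: float | None = None,
    min_reference_area_px: float = 100.0,
) -> ScaleCalibration:
    """Derive the mm-per-pixel scale from a reference object or metadata.

    A reference object of known linear size photographed in-frame corrects
    for camera-to-cluster distance: mm_per_px = known size / measured pixel
    extent (mean of the reference's second-moment axes, robust to slight
    rotation).  Metadata-provided scales pass through unchanged.
    """
    if mm_per_px is not None:
        return ScaleCalibration(mm_per_px, source="metadata")
    if reference_mask is None or known_size_mm is None:
        raise ValueError("need either mm_per_px metadata or a reference mask with its known size")
    if reference_mask.area < min_reference_area_px:
        raise ValueError(
            f"reference mask area {reference_mask.area:.1f} px^2 below floor "
            f"{min_reference_area_px} px^2 (occluded or mis-segmented?)"
        )
    major, minor, _ = second_moment_axes(reference_mask.polygon)
    extent_px = 0.5 * (major + minor)
    return ScaleCalibration(known_size_mm / extent_px, source="reference_object")


def berry_traits(masks: list[BerryMask], scale: ScaleCalibration) -> np.ndarray:
    """Per-berry (area mm^2, length mm, width mm) as an (n, 3) array.

    Length/width are the major/minor full axes of the second-moment
    equivalent ellipse, so they are rotation-invariant and equal the true
    axes for elliptical berries.
    """
    if not masks:
        raise ValueError("no berry masks")
    s = scale.mm_per_px
    out = np.empty((len(masks), 3))
    for i, m in enumerate(masks):
        out[i, 0] = m.area * s * s
        out[i, 1] = m.major_axis * s
        out[i, 2] = m.minor_axis * s
    return out


def compactness_index(masks: list[BerryMask] | list[Polygon]) -> float:
    """Total berry mask area over the area of their convex hull.

    Scale-invariant and unit-free.  Expects essentially disjoint masks
    (after IoU dedup); a single convex mask gives exactly 1.
    """
    if not masks:
        raise ValueError("compactness undefined for an empty mask set")
    polys = [m.polygon if isinstance(m, BerryMask) else m for m in masks]
    total = sum(p.area for p in polys)
    hull = convex_hull_of(polys)
    return float(total / hull.area)


def cluster_aspect_ratio(masks: list[BerryMask] | list[Polygon]) -> float:
    """Elongation of the whole cluster: hull extent along the first
    principal axis over the orthogonal extent (>= 1).

    Uses the convex-hull boundary points of all berry masks; for degenerate
    (collinear) inputs the ratio still comes from the extents, with a warn
    upstream if infinite.
    """
    if len(masks) < 2:
        raise ValueError("cluster aspect ratio needs >= 2 masks")
    polys = [m.polygon if isinstance(m, BerryMask) else m for m in masks]
    try:
        hull = convex_hull_of(polys)
        pts = np.asarray(hull.exterior.coords)[:-1]
    except ValueError:  # collinear: fall back to all boundary points
        pts = np.vstack([np.asarray(p.exterior.coords)[:-1] for p in polys])
    return principal_extent_ratio(pts)


class CountCorrection(RegressorMixin, BaseEstimator):
    """Linear occlusion correction for berry counts.

    A single image under-counts berries because occluded berries are
    invisible.  On calibration clusters with hand-verified true counts, an
    ordinary least-squares line ``true = intercept + slope * observed`` is
    fitted, with the observed regressor being the count from the angle that
    saw the most berries.  Applying the line to new clusters de-biases their
    counts.  The raw prediction is reported without clamping.

    Attributes (after ``fit``): ``slope_``, ``intercept_``, ``r2_``, ``n_``.
    """

    def fit(self, observed, true) -> "CountCorrection":
        x = np.asarray(observed, dtype=float).ravel()
        y = np.asarray(true, dtype=float).ravel()
        if len(x) < 3:
            raise ValueError("need >= 3 calibration pairs")
        if np.ptp(x) == 0:
            raise ValueError("zero variance in observed counts: cannot calibrate")
        A = np.column_stack([np.ones_like(x), x])
        (b0, b1), *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - (b0 + b1 * x)
        sst = ((y - y.mean()) ** 2).sum()
        self.intercept_ = float(b0)
        self.slope_ = float(b1)
        self.r2_ = float(1.0 - resid @ resid / sst) if sst > 0 else 1.0
        self.n_ = len(x)
        return self

    def predict(self, observed) -> np.ndarray:
        x = np.asarray(observed, dtype=float)
        return self.intercept_ + self.slope_ * x

    def correct(self, per_angle_counts) -> float:
        """Corrected count from per-angle observed counts (max-angle rule)."""
        return float(self.predict([max(per_angle_counts)])[0])

    def to_dict(self) -> dict:
        return {"slope": self.slope_, "intercept": self.intercept_, "r2": self.r2_, "n_calibration": self.n_}

    @classmethod
    def from_dict(cls, d: dict) -> "CountCorrection":
        m = cls()
        m.slope_ = float(d["slope"])
        m.intercept_ = float(d["intercept"])
        m.r2_ = float(d.get("r2", float("nan")))
        m.n_ = int(d.get("n_calibration", 0))
        return m


def view_phenotype(
    cluster_id: str,
    masks: list[BerryMask],
    scale: ScaleCalibration,
) -> ClusterPhenotype:
    """Traits of a single view (no count correction yet)."""
    traits = berry_traits(masks, scale)
    return ClusterPhenotype(
        cluster_id=cluster_id,
        berry_count_observed=(len(masks),),
        berry_count_corrected=None,
        mean_berry_area=float(traits[:, 0].mean()),
        mean_berry_length=float(traits[:, 1].mean()),
        mean_berry_width=float(traits[:, 2].mean()),
        compactness=compactness_index(masks),
        cluster_aspect_ratio=cluster_aspect_ratio(masks) if len(masks) >= 2 else 1.0,
        n_views=1,
    )


def aggregate_views(
    views: list[ClusterPhenotype],
    correction: CountCorrection | None = None,
) -> ClusterPhenotype:
    """Combine the (up to two) per-angle views of one cluster.

    Berry size traits, compactness and aspect ratio are averaged with equal
    weight; the berry count uses the max-of-angles rule followed by the
    occlusion correction when a fitted model is supplied.
    """
    if not 1 <= len(views) <= 2:
        raise ValueError(f"expected 1-2 views per cluster, got {len(views)}")
    ids = {v.cluster_id for v in views}
    if len(ids) != 1:
        raise ValueError(f"views from different clusters: {ids}")
    counts = tuple(c for v in views for c in v.berry_count_observed)
    corrected = correction.correct(counts) if correction is not None else float(max(counts))
    flags = ["one-view"] if len(views) == 1 else []
    mean = lambda attr: float(np.mean([getattr(v, attr) for v in views]))
    return ClusterPhenotype(
        cluster_id=views[0].cluster_id,
        berry_count_observed=counts,
        berry_count_corrected=corrected,
        mean_berry_area=mean("mean_berry_area"),
        mean_berry_length=mean("mean_berry_length"),
        mean_berry_width=mean("mean_berry_width"),
        compactness=mean("compactness"),
        cluster_aspect_ratio=mean("cluster_aspect_ratio"),
        n_views=len(views),
        flags=flags,
    )
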