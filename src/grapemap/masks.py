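"""Berry-mask post-processing.

Raw instance-segmentation output for a grape-cluster image contains, besides
true berries, rachis fragments, reference objects, background blobs and
duplicated segmentations of the same berry.  This module turns the raw
candidate set into a clean set of berry masks in four stages:

1. :func:`define_roi` — restrict to the region around the cluster;
2. :func:`geometric_filter` — area / perimeter / aspect-ratio rules;
3. :func:`iou_dedup` — greedy removal of overlapping duplicates;
4. :class:`ShapeScreen` — elliptical-Fourier + PCA outlier screen that
   separates near-elliptical berries from elongated or irregular artifacts.

Coordinates are pixels, origin top-left, y down, 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from shapely.geometry import Polygon, box
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.decomposition import PCA

from grapemap._geometry import iou as _iou
from grapemap._geometry import polygon_moments
from grapemap.efd import efd_descriptor

__all__ = [
    "BerryMask",
    "FilterConfig",
    "define_roi",
    "geometric_filter",
    "iou_dedup",
    "resample_contour",
    "ShapeScreen",
    "process_masks",
]


@dataclass(eq=False)  # identity semantics: a mask is one physical segment
class BerryMask:
    """One candidate segment with its geometric features.

    Features are derived from the (hole-filled) polygon: ``area`` and
    ``perimeter`` in pixels, ``major_axis``/``minor_axis`` as the full axis
    lengths of the second-moment equivalent ellipse, ``aspect_ratio`` =
    major/minor (>= 1).
    """

    mask_id: str
    polygon: Polygon
    label: dict = field(default_factory=dict)  # free-form metadata (truth tags, image ids)
    validate: bool = True  # skip for polygons known simple (e.g. simulator output)

    def __post_init__(self) -> None:
        poly = self.polygon
        if self.validate:
            if not poly.is_valid:
                poly = poly.buffer(0)
                if poly.geom_type == "MultiPolygon":
                    poly = max(poly.geoms, key=lambda g: g.area)
            # fill holes: berries are convex-ish, holes come from specular highlights
            if poly.interiors:
                poly = Polygon(poly.exterior)
        self.polygon = poly
        # all features from one numpy pass over the exterior ring
        try:
            area, centroid, cov = polygon_moments(poly)
        except ValueError as exc:
            raise ValueError(f"mask {self.mask_id}: {exc}") from exc
        xy = np.asarray(poly.exterior.coords)
        self.area = area
        self.perimeter = float(np.hypot(*np.diff(xy, axis=0).T).sum())
        evals = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
        self.major_axis = 4.0 * float(np.sqrt(evals[1]))
        self.minor_axis = 4.0 * float(np.sqrt(evals[0]))
        self.aspect_ratio = self.major_axis / self.minor_axis if self.minor_axis > 0 else float("inf")
        self.centroid = (float(centroid[0]), float(centroid[1]))


@dataclass
class FilterConfig:
    """Thresholds for geometric filtering and the shape screen.

    Area and perimeter bounds are *relative* to the per-image median
    candidate value, so they adapt to image scale.  Defaults reflect that
    berries are near-circular while rachis fragments are elongated; all are
    deliberately configurable because the right values depend on the camera
    setup.
    """

    area_min: float = 0.2  # x median candidate area
    area_max: float = 3.0
    perimeter_min: float = 0.2  # x median candidate perimeter
    perimeter_max: float = 3.0
    aspect_ratio_max: float = 2.5
    iou_threshold: float = 0.4
    roi_margin_px: float = 10.0
    efd_harmonics: int = 10
    pca_variance_kept: float = 0.90
    mahalanobis_quantile: float = 0.99

    def __post_init__(self) -> None:
        if not (0.0 < self.iou_threshold < 1.0):
            raise ValueError("iou_threshold must be in (0, 1)")
        for name in ("area_min", "area_max", "perimeter_min", "perimeter_max", "aspect_ratio_max"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def define_roi(
    masks: list[BerryMask],
    image_extent: tuple[int, int],
    margin: float = 10.0,
    connect_factor: float = 12.0,
) -> tuple[tuple[float, float, float, float], list[BerryMask]]:
    """Bounding box of the largest connected mass of candidate masks.

    Masks within ``connect_factor`` median equivalent diameters of each
    other (boundary-to-boundary) are grouped into connected components — a
    grape cluster is one such mass even though neighbouring berries need not
    touch; the component with the largest total area defines the ROI, padded
    by ``margin`` and clipped to ``image_extent`` (width, height).  Masks
    fully outside the ROI are dropped.

    Returns ``((xmin, ymin, xmax, ymax), kept_masks)``.
    """
    if not masks:
        raise ValueError("cannot define ROI from an empty candidate set")
    areas = np.array([m.area for m in masks])
    med_diam = float(np.median(2.0 * np.sqrt(areas / np.pi)))
    gap = connect_factor * med_diam
    # bounding-box gap is a cheap lower bound on boundary distance and is
    # accurate enough for grouping at this coarse scale
    b = np.array([m.polygon.bounds for m in masks])  # (n, 4) x0 y0 x1 y1
    sep = (
        (b[:, None, 2] + gap < b[None, :, 0])
        | (b[None, :, 2] + gap < b[:, None, 0])
        | (b[:, None, 3] + gap < b[None, :, 1])
        | (b[None, :, 3] + gap < b[:, None, 1])
    )
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    _, labels = connected_components(csr_matrix(~sep), directed=False)
    comp_area = np.bincount(labels, weights=areas)
    best = int(np.argmax(comp_area))
    sel = labels == best
    xs0, ys0, xs1, ys1 = b[sel, 0], b[sel, 1], b[sel, 2], b[sel, 3]
    w, h = image_extent
    roi = (
        max(min(xs0) - margin, 0.0),
        max(min(ys0) - margin, 0.0),
        min(max(xs1) + margin, float(w)),
        min(max(ys1) + margin, float(h)),
    )
    roi_box = box(*roi)
    kept = [m for m in masks if m.polygon.intersects(roi_box)]
    return roi, kept


def geometric_filter(
    masks: list[BerryMask], cfg: FilterConfig | None = None
) -> tuple[list[BerryMask], list[dict]]:
    """Keep masks whose area, perimeter and aspect ratio are all in bounds.

    Bounds are relative to the median candidate area/perimeter of the input
    set.  The rejection log records, per rejected mask, the *first* rule that
    fired (rules are checked in the order area-low, area-high, perimeter-low,
    perimeter-high, aspect-ratio) and the offending value.
    """
    cfg = cfg or FilterConfig()
    if not masks:
        return [], [{"mask_id": None, "rule": "empty_input", "value": 0}]
    med_area = float(np.median([m.area for m in masks]))
    med_perim = float(np.median([m.perimeter for m in masks]))
    kept: list[BerryMask] = []
    log: list[dict] = []
    for m in masks:
        rule = None
        value = None
        if m.area < cfg.area_min * med_area:
            rule, value = "area_min", m.area
        elif m.area > cfg.area_max * med_area:
            rule, value = "area_max", m.area
        elif m.perimeter < cfg.perimeter_min * med_perim:
            rule, value = "perimeter_min", m.perimeter
        elif m.perimeter > cfg.perimeter_max * med_perim:
            rule, value = "perimeter_max", m.perimeter
        elif m.aspect_ratio > cfg.aspect_ratio_max:
            rule, value = "aspect_ratio_max", m.aspect_ratio
        if rule is None:
            kept.append(m)
        else:
            log.append({"mask_id": m.mask_id, "rule": rule, "value": value})
    if not kept:
        log.append({"mask_id": None, "rule": "empty_output", "value": 0})
    return kept, log


def iou_dedup(masks: list[BerryMask], iou_threshold: float = 0.4) -> list[BerryMask]:
    """Remove overlapping duplicates: for any pair with IoU above the
    threshold only the larger mask survives.

    Greedy in descending area (ties broken by mask_id) so the outcome is
    deterministic: each candidate is kept iff it does not exceed the IoU
    threshold against any already-kept (larger) mask.
    """
    order = sorted(masks, key=lambda m: (-m.area, m.mask_id))
    survivors: list[BerryMask] = []
    sbounds: list[tuple[float, float, float, float]] = []

    def overlaps(b1, b2) -> bool:
        return not (b1[2] < b2[0] or b2[2] < b1[0] or b1[3] < b2[1] or b2[3] < b1[1])

    for m in order:
        b = m.polygon.bounds
        if all(
            not overlaps(b, sb) or _iou(m.polygon, s.polygon) <= iou_threshold
            for s, sb in zip(survivors, sbounds)
        ):
            survivors.append(m)
            sbounds.append(b)
    return survivors


def resample_contour(poly: Polygon, n_points: int = 256) -> np.ndarray:
    """Resample a polygon exterior to ``n_points`` equally spaced (by arc
    length) boundary points, counter-clockwise in the raster frame."""
    from shapely import ops

    xy = np.asarray(ops.orient(poly, sign=1.0).exterior.coords)
    seg = np.hypot(*np.diff(xy, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate polygon boundary")
    t = np.linspace(0.0, total, n_points, endpoint=False)
    return np.column_stack([np.interp(t, s, xy[:, 0]), np.interp(t, s, xy[:, 1])])


class ShapeScreen(OutlierMixin, BaseEstimator):
    """PCA + Mahalanobis screen separating berries from non-berry shapes.

    Each mask contributes a normalized elliptical-Fourier descriptor; PCA is
    fit on all descriptors and enough components are kept to reach
    ``variance_kept`` of the variance.  A mask is flagged as non-berry when
    its squared Mahalanobis distance in the kept subspace exceeds the
    chi-square quantile ``quantile`` (distances of points from an elliptical
    population are approximately chi-square with one df per kept component).
    Because most candidates in a cluster image *are* berries, the PCA centre
    tracks berry shape and artifacts land far out.

    PCA runs on phase-invariant features of the descriptor, not on the raw
    coefficients: for near-circular shapes the first harmonic that anchors
    the rotation/start-point normalization is close to degenerate, so raw
    normalized coefficients of such shapes carry an arbitrary residual phase
    that scrambles their coordinates and wrecks the chi-square calibration.
    The singular values of each harmonic's 2x2 coefficient matrix (plus the
    sign of its determinant) are invariant to that residual phase while
    retaining the harmonic energy profile that separates elongated or
    irregular artifacts from berries.

    Attributes (after ``fit``)
    --------------------------
    pca_ : fitted :class:`sklearn.decomposition.PCA`
    n_components_ : kept components
    cutoff_ : squared-distance cutoff (chi-square quantile)
    """

    def __init__(
        self,
        harmonics: int = 10,
        variance_kept: float = 0.90,
        quantile: float = 0.99,
        n_boundary_points: int = 128,
    ) -> None:
        self.harmonics = harmonics
        self.variance_kept = variance_kept
        self.quantile = quantile
        self.n_boundary_points = n_boundary_points

    def descriptors(self, masks: list[BerryMask]) -> np.ndarray:
        from grapemap.efd import elliptic_fourier_coefficients_batch, normalize_coefficients

        contours = np.stack(
            [resample_contour(m.polygon, self.n_boundary_points) for m in masks]
        )
        raw = elliptic_fourier_coefficients_batch(contours, self.harmonics)
        return np.stack([normalize_coefficients(co).ravel() for co in raw])

    @staticmethod
    def phase_invariant_features(X: np.ndarray) -> np.ndarray:
        """Per-harmonic singular values + signed determinant of the
        normalized coefficient matrices; invariant to the residual
        first-harmonic phase ambiguity of near-circular shapes.  The signed
        determinant (rather than its bare sign) keeps chirality information
        continuous, so harmonics with negligible energy contribute nothing."""
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        co = X.reshape(n, d // 4, 2, 2)
        sv = np.linalg.svd(co, compute_uv=False)
        det = np.linalg.det(co)
        return np.concatenate([sv.reshape(n, -1), det], axis=1)

    def fit(self, X: np.ndarray, y=None) -> "ShapeScreen":
        X = self.phase_invariant_features(X)
        if len(X) < 10:
            raise ValueError("need >= 10 descriptors to fit the shape screen")
        self.degenerate_ = bool(np.allclose(X.std(axis=0), 0.0))
        if self.degenerate_:
            warnings.warn("all shape descriptors identical: screen keeps everything")
            self.n_components_ = 0
            self.cutoff_ = float("inf")
            self.pca_ = None
            return self
        pca = PCA()
        pca.fit(X)
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, self.variance_kept) + 1)
        k = min(k, len(X) - 1)
        if k < 1:
            raise ValueError("fewer descriptors than kept components")
        self.pca_ = pca
        self.n_components_ = k
        if self.quantile >= 1.0:
            self.cutoff_ = float("inf")
        else:
            self.cutoff_ = float(stats.chi2.ppf(self.quantile, df=k))
        return self

    def mahalanobis(self, X: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance in the kept PC subspace."""
        if self.degenerate_:
            return np.zeros(len(X))
        scores = self.pca_.transform(self.phase_invariant_features(X))[:, : self.n_components_]
        lam = self.pca_.explained_variance_[: self.n_components_]
        return (scores**2 / lam).sum(axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """+1 for berry-like (inlier), -1 for flagged non-berry."""
        d2 = self.mahalanobis(X)
        return np.where(d2 <= self.cutoff_, 1, -1)

    def is_berry(self, X: np.ndarray) -> np.ndarray:
        return self.predict(X) == 1

    def to_dict(self) -> dict:
        """JSON-serializable snapshot of the fitted screen."""
        out = {
            "harmonics": self.harmonics,
            "variance_kept": self.variance_kept,
            "quantile": self.quantile,
            "n_boundary_points": self.n_boundary_points,
            "degenerate": self.degenerate_,
            "n_components": self.n_components_,
            "cutoff": None if np.isinf(self.cutoff_) else self.cutoff_,
        }
        if not self.degenerate_:
            out["pca_mean"] = self.pca_.mean_.tolist()
            out["pca_components"] = self.pca_.components_.tolist()
            out["pca_explained_variance"] = self.pca_.explained_variance_.tolist()
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ShapeScreen":
        screen = cls(d["harmonics"], d["variance_kept"], d["quantile"], d["n_boundary_points"])
        screen.degenerate_ = bool(d["degenerate"])
        screen.n_components_ = int(d["n_components"])
        screen.cutoff_ = float("inf") if d["cutoff"] is None else float(d["cutoff"])
        if screen.degenerate_:
            screen.pca_ = None
        else:
            pca = PCA()
            pca.mean_ = np.asarray(d["pca_mean"])
            pca.components_ = np.asarray(d["pca_components"])
            pca.explained_variance_ = np.asarray(d["pca_explained_variance"])
            pca.n_components_ = pca.components_.shape[0]
            screen.pca_ = pca
        return screen


def process_masks(
    masks: list[BerryMask],
    image_extent: tuple[int, int],
    cfg: FilterConfig | None = None,
) -> tuple[list[BerryMask], list[dict]]:
    """Full post-processing chain: ROI -> geometric filter -> IoU dedup ->
    shape screen.  Returns (berry masks, rejection log)."""
    cfg = cfg or FilterConfig()
    _, in_roi = define_roi(masks, image_extent, cfg.roi_margin_px)
    log = [
        {"mask_id": m.mask_id, "rule": "outside_roi", "value": 0.0}
        for m in masks
        if m not in in_roi
    ]
    kept, geo_log = geometric_filter(in_roi, cfg)
    log.extend(geo_log)
    deduped = iou_dedup(kept, cfg.iou_threshold)
    log.extend(
        {"mask_id": m.mask_id, "rule": "iou_duplicate", "value": cfg.iou_threshold}
        for m in kept
        if m not in deduped
    )
    if len(deduped) >= 10:
        screen = ShapeScreen(cfg.efd_harmonics, cfg.pca_variance_kept, cfg.mahalanobis_quantile)
        X = screen.descriptors(deduped)
        flags = screen.fit(X).is_berry(X)
        berries = [m for m, f in zip(deduped, flags) if f]
        log.extend(
            {"mask_id": m.mask_id, "rule": "shape_screen", "value": float(d)}
            for m, f, d in zip(deduped, flags, screen.mahalanobis(X))
            if not f
        )
    else:
        berries = deduped
    return berries, log
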