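"""Interchange formats: COCO-style RLE mask JSON, labelled PNG masks,
and the CSV layouts used between pipeline stages.

Tabular interchange is CSV throughout (phenotype records, genotype
matrices in an R/qtl-like layout, maps, scan results, peaks); fitted models
(count correction, shape screen) are JSON.  Every CSV written by the
pipeline carries a provenance header of ``#``-prefixed lines (config hash,
seed, package version) that pandas skips on read via ``comment='#'``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from grapemap.masks import BerryMask

__all__ = [
    "rle_encode",
    "rle_decode",
    "mask_to_polygon",
    "polygon_to_raster",
    "write_masks_json",
    "read_masks_json",
    "read_masks_png",
    "write_masks_png",
    "write_csv",
    "read_csv",
    "write_genotypes_csv",
    "read_genotypes_csv",
    "provenance_hash",
]

_GENO_CODES = {0.0: "A", 1.0: "H"}  # backcross coding; '-' = missing


# ---------------------------------------------------------------- RLE masks
def rle_encode(mask: np.ndarray) -> dict:
    """Uncompressed COCO-style RLE of a boolean mask.

    Counts alternate runs of 0s and 1s in column-major (Fortran) order,
    starting with the number of leading zeros.
    """
    m = np.asarray(mask, dtype=bool)
    flat = m.flatten(order="F").astype(np.int8)
    if flat.size == 0:
        return {"size": list(m.shape), "counts": []}
    change = np.flatnonzero(np.diff(flat)) + 1
    runs = np.diff(np.concatenate([[0], change, [flat.size]]))
    counts = runs.tolist()
    if flat[0] == 1:
        counts = [0] + counts
    return {"size": [int(m.shape[0]), int(m.shape[1])], "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    """Inverse of :func:`rle_encode`."""
    h, w = rle["size"]
    counts = rle["counts"]
    total = sum(counts)
    if total != h * w:
        raise ValueError(f"malformed RLE: counts sum {total} != size {h}x{w}")
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for c in counts:
        if val:
            flat[pos : pos + c] = True
        pos += c
        val = not val
    return flat.reshape((h, w), order="F")


def polygon_to_raster(poly: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a pixel-space polygon onto an (h, w) boolean grid, a pixel
    being set when its centre lies inside the polygon."""
    from skimage.draw import polygon as sk_polygon

    x, y = np.asarray(poly.exterior.coords).T
    rr, cc = sk_polygon(y - 0.5, x - 0.5, shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def mask_to_polygon(mask: np.ndarray) -> Polygon:
    """Boundary polygon of the largest connected region of a boolean mask."""
    from skimage import measure

    contours = measure.find_contours(np.pad(mask, 1).astype(float), 0.5)
    if not contours:
        raise ValueError("empty mask")
    contour = max(contours, key=len)
    # (row, col) -> (x, y), undoing the pad and the half-pixel centre offset
    pts = np.column_stack([contour[:, 1] - 1 + 0.5, contour[:, 0] - 1 + 0.5])
    poly = Polygon(pts)
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
    return poly


def write_masks_json(
    masks: list[BerryMask],
    path: str | Path,
    image_extent: tuple[int, int],
    meta: dict | None = None,
) -> None:
    """Write masks as COCO-style uncompressed-RLE JSON (one file per image)."""
    w, h = image_extent
    items = []
    for m in masks:
        raster = polygon_to_raster(m.polygon, (h, w))
        x0, y0, x1, y1 = m.polygon.bounds
        items.append(
            {
                "mask_id": m.mask_id,
                "segmentation": rle_encode(raster),
                "bbox": [x0, y0, x1 - x0, y1 - y0],
                "label": m.label,
            }
        )
    doc = {"image_extent": [w, h], "meta": meta or {}, "masks": items}
    Path(path).write_text(json.dumps(doc))


def read_masks_json(path: str | Path) -> tuple[list[BerryMask], dict]:
    """Read a mask JSON written by :func:`write_masks_json` (or any
    COCO-style file with uncompressed RLE segmentations)."""
    doc = json.loads(Path(path).read_text())
    masks = []
    for i, item in enumerate(doc.get("masks", doc if isinstance(doc, list) else [])):
        try:
            poly = mask_to_polygon(rle_decode(item["segmentation"]))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: mask #{i} ({item.get('mask_id')}): {exc}") from exc
        masks.append(BerryMask(item.get("mask_id", f"m{i:04d}"), poly, item.get("label", {})))
    ids = [m.mask_id for m in masks]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate mask ids")
    return masks, doc.get("meta", {})


def write_masks_png(
    masks: list[BerryMask],
    png_path: str | Path,
    image_extent: tuple[int, int],
    meta: dict | None = None,
) -> None:
    """Write masks as a 16-bit labelled PNG plus a JSON sidecar mapping
    label values to mask ids."""
    import imageio.v3 as iio

    w, h = image_extent
    lab = np.zeros((h, w), dtype=np.uint16)
    mapping = {}
    for k, m in enumerate(masks, start=1):
        lab[polygon_to_raster(m.polygon, (h, w))] = k
        mapping[str(k)] = {"mask_id": m.mask_id, "label": m.label}
    iio.imwrite(str(png_path), lab)
    sidecar = Path(str(png_path) + ".json")
    sidecar.write_text(json.dumps({"meta": meta or {}, "labels": mapping}))


def read_masks_png(png_path: str | Path) -> tuple[list[BerryMask], dict]:
    """Read a labelled-integer PNG (labels > 0 are masks) + optional sidecar."""
    import imageio.v3 as iio

    lab = np.asarray(iio.imread(str(png_path)))
    sidecar = Path(str(png_path) + ".json")
    info = json.loads(sidecar.read_text()) if sidecar.exists() else {"meta": {}, "labels": {}}
    masks = []
    for v in np.unique(lab):
        if v == 0:
            continue
        entry = info["labels"].get(str(int(v)), {})
        masks.append(
            BerryMask(
                entry.get("mask_id", f"label{int(v)}"),
                mask_to_polygon(lab == v),
                entry.get("label", {}),
            )
        )
    return masks, info.get("meta", {})


# ---------------------------------------------------------------- tabular IO
def provenance_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path: str | Path, provenance: dict | None = None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            for k, v in provenance.items():
                fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=index, lineterminator="\n")


def read_csv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


def write_genotypes_csv(
    genotypes: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> None:
    """Individuals x markers matrix with codes A (0), H (1), - (missing)."""
    coded = genotypes.copy()
    for c in coded.columns:
        coded[c] = coded[c].map(_GENO_CODES).fillna("-")
    coded.index.name = "individual"
    write_csv(coded, path, provenance, index=True)


def read_genotypes_csv(path: str | Path) -> pd.DataFrame:
    coded = read_csv(path, index_col="individual")
    back = {"A": 0.0, "H": 1.0, "-": np.nan}
    out = coded.apply(lambda col: col.map(lambda v: back.get(str(v).strip(), np.nan)))
    return out
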