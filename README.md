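# grapemap

Image-based phenotyping of grape cluster architecture and pseudo-testcross
QTL mapping, in one tested pipeline.

Cluster compactness — how densely berries pack inside a cluster — shapes
disease pressure, ripening uniformity and wine quality, but it is hard to
score objectively at scale.  A practical route is to segment every berry in
2D cluster photographs, clean the resulting instance masks, and compute a
**compactness index**

```
CI = (Σ berry mask areas) / area(convex hull of all berry masks)
```

together with berry count, projected area, length and width.  Aggregated
into per-genotype values by a mixed model, these digital traits can then be
mapped in an F1 cross of two heterozygous parents: markers segregating
lm × ll trace one parent's meiosis and nn × np the other's, so each parent
is analysed as a backcross with its own genetic map (the *pseudo-testcross*
design).

`grapemap` implements every step after segmentation, for breeders and
quantitative geneticists who have berry masks (or want to simulate them):

* **`grapemap.masks` / `grapemap.efd`** — ROI restriction, geometric
  filters, IoU deduplication, and an elliptical-Fourier + PCA screen that
  separates berries from rachis fragments (`ShapeScreen`, a scikit-learn
  style outlier detector).
* **`grapemap.morpho`** — mm-calibrated berry and cluster traits, plus a
  linear occlusion correction for berry counts (`CountCorrection`,
  fit/predict): a single image undercounts berries, so a line
  `true = β₀ + β₁ · max(count over the two camera angles)` is calibrated on
  clusters with known counts.
* **`grapemap.pheno` / `grapemap.reml`** — REML variance components, BLUPs
  and broad-sense heritability `H² = V_g / (V_g + V_e)` for single- and
  multi-season designs.
* **`grapemap.qtl`** — marker QC and binning, conditional genotype
  probabilities, Haley–Knott regression scans with
  `LOD = (n/2)·log₁₀(RSS₀/RSS₁)`, permutation-based genome-wide thresholds
  (95th percentile of the max-LOD null), stepwise multi-QTL selection on
  penalized LOD, 1.5-LOD support intervals and variance-explained reports.
* **`grapemap.simulate`** — synthetic clusters (packed elliptical berries
  with painter's-algorithm occlusion, rachis-like artifacts, exact ground
  truth) and a simulated F1 pseudo-testcross with planted QTLs, so the whole
  chain is testable without any field data.

## Worked example

```python
import numpy as np
from grapemap.simulate import (ClusterSimConfig, CrossSimConfig, PlantedQtl,
                               simulate_cluster, simulate_cross)
from grapemap.masks import process_masks
from grapemap.morpho import ScaleCalibration, view_phenotype, aggregate_views
from grapemap.pheno import fit_single_year
from grapemap.qtl import genotype_probabilities, hk_scan, permutation_threshold

# one synthetic cluster, two camera angles
cfg = ClusterSimConfig(seed=7)
masks_per_angle, truth = simulate_cluster(cfg)
cal = ScaleCalibration(cfg.mm_per_px)
views = []
for masks in masks_per_angle:
    berries, log = process_masks(masks, (3000, 3000))
    views.append(view_phenotype("demo", berries, cal))
pheno = aggregate_views(views)

# a 138-progeny cross with one planted QTL, scanned on BLUPs
cross = CrossSimConfig(n_progeny=138, n_blocks=3, sigma_g=np.sqrt(0.4),
                       sigma_e=1.0, seed=1,
                       planted_qtls=[PlantedQtl("cabsauv", 3, 47.0, 1.0)])
maps, genos, records, _ = simulate_cross(cross)
vc, res = fit_single_year(records, "trait")
probs = genotype_probabilities(maps["cabsauv"], genos["cabsauv"], step_cm=1.0)
scan = hk_scan(probs, res.blups)
thr = permutation_threshold(probs, res.blups, n_perm=1000, alpha=0.05, seed=2)
```

This prints (seeds as above):

```
true berries: 46   visible per angle: [45, 44]   true compactness: 0.161
kept 44 of 48 candidate masks
measured compactness: 0.160   mean berry area: 202.1 mm^2
Vg=0.68  Ve=0.80  H2=0.46
peak: chr3 at 44 cM, LOD 6.5 (5% threshold 2.40)
```

The measured compactness (0.160) matches the generator's analytic truth
(0.161) because the visible masks tile the un-occluded union; two of the 46
berries are hidden deeply enough to be missed, which is what the count
correction exists to fix.  The planted chromosome-3 QTL at 47 cM (it
explains ≈ 19% of the trait variance here) is recovered 3 cM away at
LOD 6.5, far above the permutation threshold.

## Command line

```
grapemap simulate --config cfg.yaml --seed 1 --out runs/sim
grapemap masks process --in image1.json --out masks/
grapemap morpho extract --masks masks/ --scale 0.25 --out clusters.csv
grapemap pheno blup --records records.csv --model single --out blups/
grapemap qtl scan --map map.csv --geno geno.csv --blups blups/blups.csv --out scan/
grapemap run --config cfg.yaml --seed 1 --out runs/full    # full pipeline
```

Tabular interchange is CSV throughout (genotypes in an R/qtl-like A/H/-
coding); masks travel as COCO-style uncompressed-RLE JSON or labelled PNG.

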