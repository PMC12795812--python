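"""Stepwise multi-QTL model selection with a penalized LOD criterion.

Forward selection adds the grid position that most improves the additive
model's LOD; after every addition a backward pass tries dropping each QTL
and a refinement pass rescans each QTL's chromosome with the others held as
covariates.  The objective is the penalized LOD

    pLOD = LOD(model) - penalty * n_qtl

with the penalty conventionally set to the single-scan permutation
threshold (controlling genome-wide false positives per added term).  The
search is additive-only: interaction terms and their separate penalties are
out of scope here, matching a main-effects-only report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from grapemap.qtl.genoprob import GenotypeProbabilities
from grapemap.qtl.scan import _lod_matrix, lod_interval

__all__ = ["QtlPeak", "StepwiseModel", "stepwise_qtl", "variance_explained"]


@dataclass
class QtlPeak:
    trait: str
    parent: str
    chrom: int
    pos_cm: float
    pos_bp: int | None
    lod: float  # drop-one LOD of this QTL in the final model
    marker_variance_pct: float
    model_variance_pct: float
    interval_cm: tuple[float, float]


@dataclass
class StepwiseModel:
    qtl_indices: list[int]  # grid indices into the probability object
    chrom: np.ndarray
    pos_cm: np.ndarray
    lod_model: float
    plod: float
    penalty: float
    n: int
    drop_one_lod: list[float] = field(default_factory=list)

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_indices)

    def positions(self) -> list[tuple[int, float]]:
        return [(int(self.chrom[i]), float(self.pos_cm[i])) for i in self.qtl_indices]


def _model_lod(P: np.ndarray, y: np.ndarray, idx: list[int], n: int) -> float:
    """LOD of the additive model with QTLs at ``idx`` vs the null model."""
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    if not idx:
        return 0.0
    X = np.column_stack([np.ones(n), P[:, idx]])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    rss1 = float(r @ r)
    if rss1 <= 0:
        return float("inf")
    return 0.5 * n * np.log10(rss0 / rss1)


def stepwise_qtl(
    probs: GenotypeProbabilities,
    phenotype: np.ndarray | pd.Series,
    penalty: float,
    max_qtl: int = 6,
    min_distance_cm: float = 10.0,
    refine: bool = True,
) -> StepwiseModel:
    """Forward/backward search for an additive multi-QTL model."""
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(probs.individuals).to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float).ravel()
    keep = ~np.isnan(y)
    y = y[keep]
    P = probs.P[keep]
    n = len(y)
    K = P.shape[1]
    chrom, pos = probs.chrom, probs.pos_cm

    def allowed(idx: list[int], exclude_of: int | None = None) -> np.ndarray:
        ok = np.ones(K, dtype=bool)
        for q in idx:
            if q == exclude_of:
                continue
            ok &= ~((chrom == chrom[q]) & (np.abs(pos - pos[q]) < min_distance_cm))
        return ok

    def best_addition(idx: list[int]) -> tuple[int, float]:
        C = np.column_stack([np.ones(n)] + [P[:, q] for q in idx]) if idx else np.ones((n, 1))
        lod_cond = _lod_matrix(P, y[:, None], C)[:, 0]  # conditional LOD per position
        lod_cur = _model_lod(P, y, idx, n)
        total = lod_cur + lod_cond  # LOD of model + candidate vs null
        total[~allowed(idx)] = -np.inf
        # tie-break: lower cM, then lower chromosome
        j = int(np.lexsort((pos, chrom, -total))[0])
        return j, float(total[j])

    model: list[int] = []
    plod_best = 0.0
    improved = True
    while improved and len(model) < max_qtl:
        improved = False
        j, lod_new = best_addition(model)
        plod_new = lod_new - penalty * (len(model) + 1)
        if plod_new > plod_best + 1e-9:
            model.append(j)
            plod_best = plod_new
            improved = True
            # backward pass
            changed = True
            while changed and len(model) > 1:
                changed = False
                for q in list(model):
                    reduced = [m for m in model if m != q]
                    plod_red = _model_lod(P, y, reduced, n) - penalty * len(reduced)
                    if plod_red > plod_best + 1e-9:
                        model = reduced
                        plod_best = plod_red
                        changed = True
            # refinement: coordinate-wise rescan
            if refine:
                for _ in range(3):
                    moved = False
                    for qi, q in enumerate(model):
                        others = [m for m in model if m != q]
                        C = (
                            np.column_stack([np.ones(n)] + [P[:, m] for m in others])
                            if others
                            else np.ones((n, 1))
                        )
                        lod_cond = _lod_matrix(P, y[:, None], C)[:, 0]
                        cand = (chrom == chrom[q]) & allowed(others)
                        lod_cond[~cand] = -np.inf
                        jbest = int(np.lexsort((pos, chrom, -lod_cond))[0])
                        if jbest != q and lod_cond[jbest] > lod_cond[q] + 1e-9:
                            model[qi] = jbest
                            moved = True
                    if not moved:
                        break
                plod_best = _model_lod(P, y, model, n) - penalty * len(model)

    lod_full = _model_lod(P, y, model, n)
    drop_one = []
    for q in model:
        reduced = [m for m in model if m != q]
        drop_one.append(lod_full - _model_lod(P, y, reduced, n))
    return StepwiseModel(
        qtl_indices=list(model),
        chrom=chrom,
        pos_cm=pos,
        lod_model=lod_full,
        plod=plod_best,
        penalty=penalty,
        n=n,
        drop_one_lod=drop_one,
    )


def variance_explained(model: StepwiseModel) -> tuple[list[float], float]:
    """Per-QTL marker variance % (drop-one) and whole-model variance %.

    Under the regression approximation LOD = (n/2) log10(RSS_0/RSS_1), the
    fraction of phenotypic variance explained by the full model is
    1 - 10^(-2 LOD_full / n); each QTL's marker share is the loss in
    explained variance when it is dropped from the model.
    """
    n = model.n
    r2_full = 1.0 - 10.0 ** (-2.0 * model.lod_model / n)
    marker = []
    for d1 in model.drop_one_lod:
        lod_red = model.lod_model - d1
        r2_red = 1.0 - 10.0 ** (-2.0 * lod_red / n)
        marker.append(100.0 * (r2_full - r2_red))
    return marker, 100.0 * r2_full


def peaks_from_model(
    model: StepwiseModel,
    probs: GenotypeProbabilities,
    phenotype: np.ndarray | pd.Series,
    trait: str,
    parent: str,
    gmap: pd.DataFrame | None = None,
    drop: float = 1.5,
) -> list[QtlPeak]:
    """Package a stepwise model as reportable peaks with 1.5-LOD intervals.

    The interval for each QTL comes from its conditional LOD profile (other
    QTLs as covariates); pos_bp is the nearest mapped marker's position when
    a map with pos_bp is supplied.
    """
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(probs.individuals).to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float).ravel()
    keep = ~np.isnan(y)
    y = y[keep]
    P = probs.P[keep]
    n = len(y)
    marker_pct, model_pct = variance_explained(model)
    out = []
    for qi, q in enumerate(model.qtl_indices):
        others = [m for m in model.qtl_indices if m != q]
        C = np.column_stack([np.ones(n)] + [P[:, m] for m in others]) if others else np.ones((n, 1))
        lod_cond = _lod_matrix(P, y[:, None], C)[:, 0]
        bin_pos = None
        pos_bp = None
        if gmap is not None:
            sub = gmap[gmap["chrom"] == model.chrom[q]]
            bin_pos = sub["pos_cm"].to_numpy(dtype=float)
            if "pos_bp" in sub and len(sub):
                nearest = (sub["pos_cm"] - model.pos_cm[q]).abs().idxmin()
                pos_bp = int(sub.loc[nearest, "pos_bp"])
        interval = lod_interval(
            model.pos_cm,
            lod_cond,
            model.chrom,
            int(model.chrom[q]),
            float(model.pos_cm[q]),
            drop=drop,
            bin_positions=bin_pos,
        )
        out.append(
            QtlPeak(
                trait=trait,
                parent=parent,
                chrom=int(model.chrom[q]),
                pos_cm=float(model.pos_cm[q]),
                pos_bp=pos_bp,
                lod=float(model.drop_one_lod[qi]),
                marker_variance_pct=float(marker_pct[qi]),
                model_variance_pct=float(model_pct),
                interval_cm=interval,
            )
        )
    return out
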