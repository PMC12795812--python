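"""Haley–Knott regression scan, permutation thresholds, LOD intervals.

At every grid position the phenotype is regressed on the conditional
expectation of the QTL genotype (plus any model covariates); the evidence
for a QTL is the regression LOD

    LOD = (n / 2) * log10(RSS_0 / RSS_1)

where RSS_0 / RSS_1 are the residual sums of squares without / with the
position term.  Genome-wide significance comes from permuting the phenotype
vector, recording the genome-wide maximum LOD of each permutation and
taking the (1 - alpha) quantile (numpy's default linear interpolation,
i.e. quantile type 7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from grapemap.qtl.genoprob import GenotypeProbabilities

__all__ = ["QtlScanResult", "hk_scan", "permutation_threshold", "lod_interval"]


@dataclass
class QtlScanResult:
    chrom: np.ndarray
    pos_cm: np.ndarray
    lod: np.ndarray
    n: int
    threshold: float | None = None
    alpha: float | None = None
    perm_max_lods: np.ndarray | None = field(default=None, repr=False)
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "pos_cm": self.pos_cm, "lod": self.lod})

    def peak(self) -> tuple[int, float, float]:
        """(chrom, pos_cm, lod) of the genome-wide maximum; ties broken by
        lower cM then lower chromosome index."""
        best = np.lexsort((self.pos_cm, self.chrom, -self.lod))[0]
        return int(self.chrom[best]), float(self.pos_cm[best]), float(self.lod[best])


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of the columns of M after OLS on covariates C."""
    coef, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coef


def _lod_matrix(P: np.ndarray, Y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """LOD for every (position, phenotype column) pair.

    P: (n, K) genotype probabilities; Y: (n, q) phenotypes; C: (n, c)
    covariates (at least an intercept).  Returns (K, q).
    """
    n = P.shape[0]
    Pr = _residualize(P, C)
    Yr = _residualize(Y, C)
    rss0 = (Yr**2).sum(axis=0)  # (q,)
    spp = (Pr**2).sum(axis=0)  # (K,)
    spy = Pr.T @ Yr  # (K, q)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss1 = rss0[None, :] - spy**2 / np.where(spp > 1e-12, spp, np.inf)[:, None]
        lod = 0.5 * n * np.log10(rss0[None, :] / rss1)
    lod[~np.isfinite(lod)] = 0.0
    return np.clip(lod, 0.0, None)


def hk_scan(
    probs: GenotypeProbabilities,
    phenotype: np.ndarray | pd.Series,
    covariates: np.ndarray | None = None,
) -> QtlScanResult:
    """Single-QTL Haley–Knott scan of one phenotype.

    ``phenotype`` may be a Series indexed by individual id (aligned to the
    probability object, rows with missing phenotype dropped with a warning)
    or a bare vector in the probability object's row order.
    """
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(probs.individuals).to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float).ravel()
    keep = ~np.isnan(y)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} individuals with missing phenotype")
    y = y[keep]
    P = probs.P[keep]
    C = np.ones((len(y), 1))
    if covariates is not None:
        C = np.column_stack([C, np.asarray(covariates)[keep]])
    if np.ptp(y) == 0:
        warnings.warn("constant phenotype: LOD is zero everywhere")
        lod = np.zeros(P.shape[1])
    else:
        lod = _lod_matrix(P, y[:, None], C)[:, 0]
    return QtlScanResult(chrom=probs.chrom, pos_cm=probs.pos_cm, lod=lod, n=len(y))


def permutation_threshold(
    probs: GenotypeProbabilities,
    phenotype: np.ndarray | pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    covariates: np.ndarray | None = None,
    return_distribution: bool = False,
):
    """Genome-wide LOD threshold by phenotype permutation.

    Shuffles the phenotype vector ``n_perm`` times (seeded), records the
    genome-wide maximum LOD of each shuffle, and returns the (1 - alpha)
    quantile of that null distribution.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable tail quantile")
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(probs.individuals).to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float).ravel()
    keep = ~np.isnan(y)
    y = y[keep]
    P = probs.P[keep]
    n = len(y)
    C = np.ones((n, 1))
    if covariates is not None:
        C = np.column_stack([C, np.asarray(covariates)[keep]])
    rng = np.random.default_rng(seed)
    if np.ptp(y) == 0:
        max_lods = np.zeros(n_perm)
    else:
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
        Y = y[perms].T  # (n, n_perm)
        max_lods = _lod_matrix(P, Y, C).max(axis=0)
    thr = float(np.quantile(max_lods, 1.0 - alpha))
    if return_distribution:
        return thr, max_lods
    return thr


def lod_interval(
    pos_cm: np.ndarray,
    lod: np.ndarray,
    chrom: np.ndarray,
    peak_chrom: int,
    peak_pos: float,
    drop: float = 1.5,
    bin_positions: np.ndarray | None = None,
) -> tuple[float, float]:
    """Support interval around a peak: outermost grid positions on each side
    of the peak where LOD >= peak LOD - drop.

    When ``bin_positions`` (the chromosome's marker-bin positions) is given,
    each end is expanded outward to the nearest flanking bin position, the
    convention used when reporting intervals against a binned map.  A peak at
    a chromosome end yields a one-sided interval to the end.
    """
    if drop <= 0:
        raise ValueError("drop must be positive")
    on = chrom == peak_chrom
    p = np.asarray(pos_cm)[on]
    l = np.asarray(lod)[on]
    order = np.argsort(p)
    p, l = p[order], l[order]
    ip = int(np.argmin(np.abs(p - peak_pos)))
    cut = l[ip] - drop
    ok = np.flatnonzero(l >= cut)
    lo = float(p[ok.min()]) if len(ok) else peak_pos
    hi = float(p[ok.max()]) if len(ok) else peak_pos
    if bin_positions is not None and len(bin_positions):
        bp = np.sort(np.asarray(bin_positions, dtype=float))
        below = bp[bp <= lo + 1e-9]
        above = bp[bp >= hi - 1e-9]
        lo = float(below[-1]) if len(below) else lo
        hi = float(above[0]) if len(above) else hi
    return float(lo), float(hi)
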