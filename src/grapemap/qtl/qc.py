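"""Marker and individual quality control, and marker binning.

Genotypes use backcross coding {0, 1, NaN} per parental map (lm x ll or
nn x np markers).  QC mirrors standard GBS practice for a 1:1 segregating
family: markers with minor allele frequency at or below 0.1 or with more
than 10% missing calls are dropped, then individuals with more than 10%
missing calls across the surviving markers are dropped.

Markers mapping to the same genetic position (a *bin*) are collapsed to one
representative: per individual the consensus of the co-binned non-missing
calls, so binning also imputes missing calls wherever the bin's other
markers are unanimous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QcReport", "genotype_qc", "bin_markers"]


@dataclass
class QcReport:
    n_markers_in: int
    n_markers_maf: int  # removed for MAF
    n_markers_missing: int  # removed for missingness
    n_individuals_in: int
    n_individuals_removed: int


def genotype_qc(
    genotypes: pd.DataFrame,
    maf_min: float = 0.1,
    max_missing: float = 0.1,
) -> tuple[pd.DataFrame, QcReport]:
    """Filter a (individuals x markers) 0/1/NaN matrix.

    Keeps markers with MAF > ``maf_min`` and missingness <= ``max_missing``,
    then individuals with missingness <= ``max_missing``.
    """
    G = genotypes.astype(float)
    n_ind, n_mark = G.shape
    freq = G.mean(axis=0, skipna=True)
    maf = np.minimum(freq, 1.0 - freq)
    miss_m = G.isna().mean(axis=0)
    bad_maf = maf <= maf_min
    bad_missing = miss_m > max_missing
    keep_markers = ~(bad_maf | bad_missing)
    if not keep_markers.any():
        raise ValueError("QC removed all markers")
    G = G.loc[:, keep_markers]
    miss_i = G.isna().mean(axis=1)
    keep_ind = miss_i <= max_missing
    G = G.loc[keep_ind]
    report = QcReport(
        n_markers_in=n_mark,
        n_markers_maf=int(bad_maf.sum()),
        n_markers_missing=int((bad_missing & ~bad_maf).sum()),
        n_individuals_in=n_ind,
        n_individuals_removed=int((~keep_ind).sum()),
    )
    return G, report


def bin_markers(
    gmap: pd.DataFrame,
    genotypes: pd.DataFrame,
    conflict_tolerance: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse markers at identical (chrom, pos_cm) into bins.

    Returns (binned map, representative genotypes).  The representative call
    per individual is the unanimous co-binned call (missing filled from the
    other markers in the bin); conflicting calls fall back to the majority
    and the bin is flagged when the conflict fraction exceeds the tolerance.

    The binned map has columns marker (first member), chrom, pos_cm, pos_bp
    (first member), n_markers, conflict_flag.
    """
    gmap = gmap.sort_values(["chrom", "pos_cm"], kind="stable").reset_index(drop=True)
    rows = []
    rep_cols: dict[str, np.ndarray] = {}
    for (chrom, pos), grp in gmap.groupby(["chrom", "pos_cm"], sort=True):
        members = [m for m in grp["marker"] if m in genotypes.columns]
        if not members:
            continue
        block = genotypes[members].to_numpy(dtype=float)  # n x m_bin
        n1 = np.nansum(block == 1, axis=1)
        n0 = np.nansum(block == 0, axis=1)
        rep = np.where(n1 > n0, 1.0, np.where(n0 > n1, 0.0, np.nan))
        typed = (n0 + n1) > 0
        conflicts = ((n0 > 0) & (n1 > 0)).sum()
        frac_conflict = conflicts / max(typed.sum(), 1)
        name = grp["marker"].iloc[0]
        rep_cols[name] = rep
        rows.append(
            {
                "marker": name,
                "chrom": chrom,
                "pos_cm": pos,
                "pos_bp": grp["pos_bp"].iloc[0] if "pos_bp" in grp else np.nan,
                "n_markers": len(members),
                "conflict_flag": bool(frac_conflict > conflict_tolerance),
            }
        )
    binned_map = pd.DataFrame(rows)
    rep_geno = pd.DataFrame(rep_cols, index=genotypes.index)
    return binned_map, rep_geno
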