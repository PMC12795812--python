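"""Conditional QTL-genotype probabilities on a cM grid.

For a backcross-coded chromosome the genotype process along the chromosome
is a two-state Markov chain whose transition probability over distance d is
the recombination fraction r(d) of the map function.  At a grid position
flanked by the nearest informative (non-missing) markers L and R at
distances dL and dR with observed genotypes gL and gR,

    P(g = 1 | gL, gR) = t(gL, 1; rL) t(1, gR; rR) / sum_g' t(gL, g'; rL) t(g', gR; rR)

with t(a, b; r) = r if a != b else 1 - r.  One-sided positions use the
single transition; positions with no informative marker on the chromosome
get 0.5.  At a typed marker the probability collapses to the observed call.
Missing genotypes are therefore handled here, not by dropping individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from grapemap.simulate.cross import recombination_fraction

__all__ = ["GenotypeProbabilities", "genotype_probabilities"]


@dataclass
class GenotypeProbabilities:
    """P(genotype = 1) on a per-chromosome grid for every individual."""

    individuals: list[str]
    chrom: np.ndarray  # (K,) chromosome id per grid position
    pos_cm: np.ndarray  # (K,)
    P: np.ndarray  # (n, K)
    map_function: str = "haldane"

    @property
    def n(self) -> int:
        return self.P.shape[0]

    def positions(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "pos_cm": self.pos_cm})


def _grid(marker_pos: np.ndarray, step: float) -> np.ndarray:
    lo, hi = marker_pos.min(), marker_pos.max()
    grid = np.arange(lo, hi + 1e-9, step) if step > 0 else np.array([])
    return np.unique(np.concatenate([marker_pos, grid]))


def _pair_prob(gL, rL, gR, rR):
    """P(g=1 | both flanks), elementwise."""
    p1 = (gL * (1 - rL) + (1 - gL) * rL) * (gR * (1 - rR) + (1 - gR) * rR)
    p0 = (gL * rL + (1 - gL) * (1 - rL)) * (gR * rR + (1 - gR) * (1 - rR))
    return p1 / (p0 + p1)


def genotype_probabilities(
    gmap: pd.DataFrame,
    genotypes: pd.DataFrame,
    step_cm: float = 1.0,
    map_function: str = "haldane",
) -> GenotypeProbabilities:
    """Compute P(genotype = 1) at grid positions (markers + regular steps).

    ``gmap`` columns: marker, chrom, pos_cm.  ``genotypes``: individuals x
    markers, 0/1/NaN.  Markers absent from either input are ignored.
    """
    gmap = gmap[gmap["marker"].isin(genotypes.columns)].sort_values(
        ["chrom", "pos_cm"], kind="stable"
    )
    n = len(genotypes)
    chrom_out, pos_out, P_out = [], [], []
    for chrom, sub in gmap.groupby("chrom", sort=True):
        pm = sub["pos_cm"].to_numpy(dtype=float)
        G = genotypes[sub["marker"]].to_numpy(dtype=float)  # (n, m)
        grid = _grid(pm, step_cm)
        k = len(grid)
        P = np.full((n, k), 0.5)
        has_missing = np.isnan(G).any()
        if not has_missing:
            P[:] = _interp_chrom(pm, G, grid, map_function)
        else:
            for i in range(n):
                gi = G[i]
                ok = ~np.isnan(gi)
                if not ok.any():
                    continue
                P[i] = _interp_chrom(pm[ok], gi[ok][None, :], grid, map_function)[0]
        chrom_out.append(np.full(k, chrom))
        pos_out.append(grid)
        P_out.append(P)
    return GenotypeProbabilities(
        individuals=list(genotypes.index),
        chrom=np.concatenate(chrom_out),
        pos_cm=np.concatenate(pos_out),
        P=np.hstack(P_out),
        map_function=map_function,
    )


def _interp_chrom(
    pm: np.ndarray, G: np.ndarray, grid: np.ndarray, map_function: str
) -> np.ndarray:
    """Vectorized conditional probabilities for fully informative markers.

    pm: (m,) sorted marker positions; G: (n, m) 0/1; grid: (k,).
    """
    n, m = G.shape
    k = len(grid)
    jR = np.searchsorted(pm, grid, side="left")  # first marker at/right of position
    jL = np.searchsorted(pm, grid, side="right") - 1  # last marker at/left of position
    out = np.empty((n, k))
    at_marker = (jL >= 0) & (jL < m) & (np.abs(pm[np.clip(jL, 0, m - 1)] - grid) < 1e-9)
    both = (~at_marker) & (jL >= 0) & (jR < m)
    left_only = (~at_marker) & (jL >= 0) & (jR >= m)
    right_only = (~at_marker) & (jL < 0) & (jR < m)
    if at_marker.any():
        out[:, at_marker] = G[:, jL[at_marker]]
    if both.any():
        dL = grid[both] - pm[jL[both]]
        dR = pm[jR[both]] - grid[both]
        rL = recombination_fraction(dL, map_function)
        rR = recombination_fraction(dR, map_function)
        out[:, both] = _pair_prob(G[:, jL[both]], rL, G[:, jR[both]], rR)
    if left_only.any():
        d = grid[left_only] - pm[jL[left_only]]
        r = recombination_fraction(d, map_function)
        gL = G[:, jL[left_only]]
        out[:, left_only] = gL * (1 - r) + (1 - gL) * r
    if right_only.any():
        d = pm[jR[right_only]] - grid[right_only]
        r = recombination_fraction(d, map_function)
        gR = G[:, jR[right_only]]
        out[:, right_only] = gR * (1 - r) + (1 - gR) * r
    return out
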