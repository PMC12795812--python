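"""Simulated F1 pseudo-testcross with planted QTLs.

In a pseudo-testcross an F1 family of two heterozygous parents is mapped as
two back-crosses: markers heterozygous in parent A and homozygous in parent
B (lm x ll) segregate 1:1 and trace parent A's meiosis, and vice versa
(nn x np).  Each parent therefore gets its own genetic map and its own 0/1
genotype matrix.

The simulator draws each progeny's parental gametes as Markov chains along
each chromosome with recombination fractions from the chosen map function
(Haldane by default: r = (1 - e^(-2d/100))/2 for d in cM), plants additive
QTLs at arbitrary map positions, and generates phenotypes with the
genotype / genotype-by-year / residual variance structure of a randomized
block trial repeated over years:

    y_ijk = mu + block_jk + sum_q a_q g_iq + G_i + GY_ik + e_ijk

All randomness flows from ``cfg.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CrossSimConfig", "PlantedQtl", "CrossTruth", "simulate_cross", "recombination_fraction"]

_BP_PER_CM = 250_000  # grapevine-like physical:genetic scale for synthetic bp positions


def recombination_fraction(d_cm: np.ndarray | float, map_function: str = "haldane"):
    """Recombination fraction for a map distance in cM."""
    d = np.asarray(d_cm, dtype=float)
    if map_function == "haldane":
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    elif map_function == "kosambi":
        r = 0.5 * np.tanh(2.0 * d / 100.0)
    else:
        raise ValueError(f"unknown map function {map_function!r}")
    return r if np.ndim(d_cm) else float(r)


@dataclass
class PlantedQtl:
    parent: str  # which parental map carries the QTL
    chrom: int
    pos_cm: float
    effect: float  # additive effect of the 0/1 genotype, in trait units


@dataclass
class CrossSimConfig:
    """Defaults mirror the study design: 138 progeny scored in 3 randomized
    blocks over 2 years.  The default genome is five 100-cM chromosomes with
    markers every 5 cM per parent — a scaled genome that keeps repeated
    simulation studies cheap while preserving marker density typical of a
    binned GBS map."""

    n_progeny: int = 138
    parents: tuple[str, str] = ("cabsauv", "riesling")
    chrom_lengths_cm: tuple[float, ...] = (100.0, 100.0, 100.0, 100.0, 100.0)
    marker_spacing_cm: float = 5.0
    planted_qtls: list[PlantedQtl] = field(default_factory=list)
    h2_target: float | None = None  # if set, overrides sigma_g
    n_blocks: int = 3
    n_years: int = 1
    sigma_g: float = 1.0  # genotype SD (non-QTL polygenic)
    sigma_gy: float = 0.0  # genotype-by-year SD
    sigma_e: float = 1.0  # residual SD
    block_effect_sd: float = 0.5
    missing_rate: float = 0.0
    map_function: str = "haldane"
    trait_name: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_progeny < 2:
            raise ValueError("n_progeny must be >= 2")
        for s in (self.sigma_g, self.sigma_gy, self.sigma_e):
            if s < 0:
                raise ValueError("variance components must be >= 0")
        for q in self.planted_qtls:
            if not np.isfinite(q.effect):
                raise ValueError("QTL effects must be finite")
            if q.parent not in self.parents:
                raise ValueError(f"QTL parent {q.parent!r} not in {self.parents}")


@dataclass
class CrossTruth:
    planted_qtls: list[PlantedQtl]
    qtl_genotypes: dict[str, np.ndarray]  # per planted QTL: 0/1 vector over progeny
    genetic_values: np.ndarray
    sigma_g: float
    sigma_gy: float
    sigma_e: float


def _simulate_gametes(
    positions_cm: np.ndarray, n: int, rng: np.random.Generator, map_function: str
) -> np.ndarray:
    """0/1 inherited-allele matrix (n x m) along one chromosome."""
    m = len(positions_cm)
    g = np.empty((n, m), dtype=np.int8)
    g[:, 0] = rng.integers(0, 2, size=n)
    if m > 1:
        r = recombination_fraction(np.diff(positions_cm), map_function)
        flips = rng.random((n, m - 1)) < r
        for j in range(1, m):
            g[:, j] = g[:, j - 1] ^ flips[:, j - 1]
    return g


def _build_map(parent: str, cfg: CrossSimConfig) -> pd.DataFrame:
    rows = []
    for c, length in enumerate(cfg.chrom_lengths_cm, start=1):
        pos = np.arange(0.0, length + 1e-9, cfg.marker_spacing_cm)
        for k, p in enumerate(pos):
            rows.append(
                {
                    "marker": f"{parent[:3]}_c{c:02d}_m{k:03d}",
                    "chrom": c,
                    "pos_cm": float(p),
                    "pos_bp": int(round(p * _BP_PER_CM)),
                }
            )
    return pd.DataFrame(rows)


def simulate_cross(
    cfg: CrossSimConfig,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], pd.DataFrame, CrossTruth]:
    """Simulate maps, genotypes and phenotypes.

    Returns
    -------
    maps : {parent: map DataFrame (marker, chrom, pos_cm, pos_bp)}
    genotypes : {parent: DataFrame individuals x markers, values 0/1/NaN}
    phenotypes : tidy DataFrame (genotype_id, block, year, <trait_name>)
    truth : :class:`CrossTruth`
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_progeny
    ids = [f"P{i:04d}" for i in range(n)]

    maps: dict[str, pd.DataFrame] = {}
    genos: dict[str, pd.DataFrame] = {}
    qtl_geno: dict[str, np.ndarray] = {}
    for parent in cfg.parents:
        gmap = _build_map(parent, cfg)
        cols: dict[str, np.ndarray] = {}
        for c in sorted(gmap["chrom"].unique()):
            sub = gmap[gmap["chrom"] == c]
            marker_pos = sub["pos_cm"].to_numpy()
            qtls_here = [q for q in cfg.planted_qtls if q.parent == parent and q.chrom == c]
            all_pos = np.unique(np.concatenate([marker_pos, [q.pos_cm for q in qtls_here]]))
            g = _simulate_gametes(all_pos, n, rng, cfg.map_function)
            idx = np.searchsorted(all_pos, marker_pos)
            for name, j in zip(sub["marker"], idx):
                cols[name] = g[:, j].astype(float)
            for q in qtls_here:
                jq = int(np.searchsorted(all_pos, q.pos_cm))
                qtl_geno[f"{parent}_c{q.chrom}@{q.pos_cm:g}"] = g[:, jq].copy()
        gdf = pd.DataFrame(cols, index=ids)
        if cfg.missing_rate > 0:
            mask = rng.random(gdf.shape) < cfg.missing_rate
            gdf = gdf.mask(mask)
        maps[parent] = gmap
        genos[parent] = gdf

    qtl_var = sum(q.effect**2 * 0.25 for q in cfg.planted_qtls)
    sigma_g = cfg.sigma_g
    if cfg.h2_target is not None:
        want_vg = cfg.h2_target / (1.0 - cfg.h2_target) * cfg.sigma_e**2
        sigma_g = float(np.sqrt(max(want_vg - qtl_var, 0.0)))

    qtl_part = np.zeros(n)
    for q in cfg.planted_qtls:
        qtl_part += q.effect * qtl_geno[f"{q.parent}_c{q.chrom}@{q.pos_cm:g}"]
    poly = rng.normal(0.0, sigma_g, size=n) if sigma_g > 0 else np.zeros(n)
    genetic = qtl_part + poly

    rows = []
    for year in range(1, cfg.n_years + 1):
        gy = rng.normal(0.0, cfg.sigma_gy, size=n) if cfg.sigma_gy > 0 else np.zeros(n)
        block_eff = (
            rng.normal(0.0, cfg.block_effect_sd, size=cfg.n_blocks)
            if cfg.block_effect_sd > 0
            else np.zeros(cfg.n_blocks)
        )
        for b in range(cfg.n_blocks):
            e = rng.normal(0.0, cfg.sigma_e, size=n) if cfg.sigma_e > 0 else np.zeros(n)
            y = genetic + gy + block_eff[b] + e
            for i in range(n):
                rows.append(
                    {
                        "genotype_id": ids[i],
                        "block": f"B{b + 1}",
                        "year": 2022 + year,
                        cfg.trait_name: y[i],
                    }
                )
    pheno = pd.DataFrame(rows)
    truth = CrossTruth(
        planted_qtls=list(cfg.planted_qtls),
        qtl_genotypes=qtl_geno,
        genetic_values=genetic,
        sigma_g=sigma_g,
        sigma_gy=cfg.sigma_gy,
        sigma_e=cfg.sigma_e,
    )
    return maps, genos, pheno, truth
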