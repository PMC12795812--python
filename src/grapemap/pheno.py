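"""Genotype-level phenotype statistics: aggregation, BLUPs, heritability.

Cluster-level digital traits are first averaged over the (five) imaged
clusters per genotype x block; yield traits arrive already at that level.
Single-year analyses fit

    y_ij = block_j + g_i + e_ij,    g ~ N(0, Vg), e ~ N(0, Ve)

with block fixed and genotype random; multi-year analyses add year and
block-within-year as fixed effects and a genotype-by-year random term.
Broad-sense heritability is reported as H2 = Vg / (Vg + Ve) — the ratio of
the printed variance components, deliberately matching the formula used for
the study rather than an entry-mean variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from grapemap.reml import VarianceComponentModel

__all__ = [
    "VarianceComponents",
    "BlupResult",
    "aggregate_clusters",
    "fit_single_year",
    "fit_multi_year",
    "heritability",
    "trait_correlations",
]


@dataclass
class VarianceComponents:
    V_g: float
    V_e: float
    V_gy: float | None = None
    fixed_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in (self.V_g, self.V_e, self.V_gy):
            if v is not None and v < -1e-12:
                raise ValueError("variance components must be >= 0")


@dataclass
class BlupResult:
    blups: pd.Series  # centered genotype deviations, indexed by genotype_id
    overall_mean: float
    H2: float
    converged: bool
    boundary: list[str] = field(default_factory=list)

    def with_mean(self) -> pd.Series:
        """The 'general mean + BLUP' presentation."""
        return self.blups + self.overall_mean


def aggregate_clusters(
    clusters: pd.DataFrame,
    trait_cols: list[str] | None = None,
    keys: tuple[str, ...] = ("genotype_id", "block", "year"),
) -> pd.DataFrame:
    """Average cluster-level trait values per genotype x block x year.

    Returns one row per key combination with a ``n_clusters`` column; a
    ``flags`` column marks groups with a single cluster or with missing
    trait values averaged over fewer clusters.
    """
    missing = [k for k in keys if k not in clusters.columns]
    if missing:
        raise ValueError(f"cluster table lacks key columns {missing}")
    if trait_cols is None:
        trait_cols = [
            c for c in clusters.columns if c not in keys and pd.api.types.is_numeric_dtype(clusters[c])
        ]
    g = clusters.groupby(list(keys), sort=True)
    out = g[trait_cols].mean().reset_index()
    counts = g.size().rename("n_clusters").reset_index()
    out = out.merge(counts, on=list(keys))
    n_missing = g[trait_cols].apply(lambda d: int(d.isna().any().any())).rename("any_missing").reset_index()
    out = out.merge(n_missing, on=list(keys))
    out["flags"] = ""
    out.loc[out["n_clusters"] == 1, "flags"] += "n=1;"
    out.loc[out["any_missing"] == 1, "flags"] += "missing_trait;"
    return out.drop(columns="any_missing")


def _indicator(values: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(values.unique())
    idx = {v: i for i, v in enumerate(levels)}
    Z = np.zeros((len(values), len(levels)))
    Z[np.arange(len(values)), [idx[v] for v in values]] = 1.0
    return Z, levels


def _fixed_design(df: pd.DataFrame, terms: list[str]) -> np.ndarray:
    """Intercept + treatment-coded factors (first level dropped).

    ``terms`` entries may be single columns or 'a:b' interactions.
    """
    cols = [np.ones(len(df))]
    for term in terms:
        parts = term.split(":")
        combo = df[parts[0]].astype(str)
        for p in parts[1:]:
            combo = combo + "/" + df[p].astype(str)
        levels = sorted(combo.unique())
        for lev in levels[1:]:
            cols.append((combo == lev).to_numpy(dtype=float))
    X = np.column_stack(cols)
    # nested terms (e.g. block within year) overlap their parents; keep a
    # full-rank basis via pivoted QR so REML sees a well-posed fixed design
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    rank = int((np.abs(np.diag(r)) > 1e-9 * abs(r[0, 0])).sum())
    keep = np.sort(piv[:rank])
    return X[:, keep]


def fit_single_year(
    records: pd.DataFrame, trait: str, fixed_variances: dict[str, float] | None = None
) -> tuple[VarianceComponents, BlupResult]:
    """Single-season mixed model: block fixed, genotype random."""
    df = records.dropna(subset=[trait]).copy()
    if df["genotype_id"].nunique() < 2 or df["block"].nunique() < 2:
        raise ValueError("need >= 2 genotypes and >= 2 blocks")
    if "year" in df.columns and df["year"].nunique() > 1:
        raise ValueError("multiple years present: use fit_multi_year")
    y = df[trait].to_numpy(dtype=float)
    X = _fixed_design(df, ["block"])
    Zg, geno_levels = _indicator(df["genotype_id"])
    model = VarianceComponentModel(random_names=("genotype",)).fit(
        y, X, [Zg], fixed_variances=fixed_variances
    )
    vc = VarianceComponents(
        V_g=model.variances_["genotype"],
        V_e=model.variances_["residual"],
        fixed_effects={"coef": model.fixed_effects_},
    )
    blups = pd.Series(model.blups_["genotype"], index=pd.Index(geno_levels, name="genotype_id"))
    res = BlupResult(
        blups=blups,
        overall_mean=float(X.mean(axis=0) @ model.fixed_effects_),
        H2=heritability(vc),
        converged=model.converged_,
        boundary=model.boundary_,
    )
    return vc, res


def fit_multi_year(
    records: pd.DataFrame, trait: str
) -> tuple[VarianceComponents, BlupResult]:
    """Multi-season model: year and block-within-year fixed; genotype and
    genotype-by-year random.  Returns across-year BLUPs."""
    df = records.dropna(subset=[trait]).copy()
    if df["year"].nunique() < 2:
        raise ValueError("single year of data: use fit_single_year")
    y = df[trait].to_numpy(dtype=float)
    X = _fixed_design(df, ["year", "year:block"])
    Zg, geno_levels = _indicator(df["genotype_id"])
    gy = df["genotype_id"].astype(str) + "@" + df["year"].astype(str)
    Zgy, _ = _indicator(gy)
    model = VarianceComponentModel(random_names=("genotype", "genotype_year")).fit(
        y, X, [Zg, Zgy]
    )
    vc = VarianceComponents(
        V_g=model.variances_["genotype"],
        V_e=model.variances_["residual"],
        V_gy=model.variances_["genotype_year"],
        fixed_effects={"coef": model.fixed_effects_},
    )
    blups = pd.Series(model.blups_["genotype"], index=pd.Index(geno_levels, name="genotype_id"))
    res = BlupResult(
        blups=blups,
        overall_mean=float(X.mean(axis=0) @ model.fixed_effects_),
        H2=heritability(vc),
        converged=model.converged_,
        boundary=model.boundary_,
    )
    return vc, res


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability H2 = Vg / (Vg + Ve)."""
    tot = vc.V_g + vc.V_e
    if tot <= 0:
        raise ValueError("Vg + Ve must be positive")
    return float(vc.V_g / tot)


def trait_correlations(blups_by_trait: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """Pearson correlations between per-genotype BLUPs, pairwise-complete.

    ``blups_by_trait`` is genotypes x traits.  Zero-variance traits yield
    NaN entries (off-diagonal), flagged by a warning.
    """
    import warnings

    if len(blups_by_trait) < min_n:
        raise ValueError(f"need >= {min_n} genotypes in common")
    zero_var = blups_by_trait.std() == 0
    if zero_var.any():
        warnings.warn(f"zero-variance traits, correlations undefined: {list(blups_by_trait.columns[zero_var])}")
    with np.errstate(divide="ignore", invalid="ignore"):
        return blups_by_trait.corr(method="pearson", min_periods=min_n)
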