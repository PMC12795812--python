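"""End-to-end orchestration: simulation -> masks -> morphometrics -> BLUPs
-> QTL scan, driven by a single validated configuration and seed.

The pipeline links the imaging strand and the genetics strand: the
simulated cross assigns each genotype a target compactness (its genetic
value on the compactness scale), clusters are rendered to match that
target, traits are re-measured from the rendered masks, measured traits are
aggregated to genotype x block records, BLUPs are fitted and scanned for
QTLs.  Every stage writes CSV artifacts with a provenance header and is
idempotent given (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

import grapemap
from grapemap import io as gio
from grapemap.masks import FilterConfig, process_masks
from grapemap.morpho import CountCorrection, ScaleCalibration, aggregate_views, view_phenotype
from grapemap.pheno import aggregate_clusters, fit_multi_year, fit_single_year
from grapemap.qtl import (
    bin_markers,
    genotype_probabilities,
    genotype_qc,
    hk_scan,
    permutation_threshold,
    stepwise_qtl,
)
from grapemap.qtl.stepwise import peaks_from_model
from grapemap.simulate import ClusterSimConfig, CrossSimConfig, simulate_cluster, simulate_cross

log = logging.getLogger("grapemap")

__all__ = ["PipelineConfig", "ScanConfig", "run_pipeline", "stage_seed", "render_genotype_clusters"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Fan a global seed out to per-stage seeds by stable hashing."""
    h = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class ScanConfig:
    step_cm: float = 1.0
    n_perm: int = 1000
    alpha: float = 0.05
    map_function: str = "haldane"
    stepwise: bool = True
    lod_drop: float = 1.5


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "masks", "morpho", "pheno", "qtl")
    clusters_per_block: int = 5
    compactness_trait_sd: float = 0.009  # genetic spread of target compactness
    compactness_mean: float = 0.18
    cluster_sim: ClusterSimConfig = field(default_factory=ClusterSimConfig)
    cross_sim: CrossSimConfig = field(default_factory=CrossSimConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, sub: dict):
            names = {f.name for f in fields(klass)}
            unknown = set(sub) - names
            if unknown:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            return klass(**sub)

        top = dict(d)
        kw = {}
        for key, klass in [
            ("cluster_sim", ClusterSimConfig),
            ("cross_sim", CrossSimConfig),
            ("filter", FilterConfig),
            ("scan", ScanConfig),
        ]:
            if key in top:
                kw[key] = build(klass, top.pop(key))
        if "stages" in top:
            top["stages"] = tuple(top["stages"])
        names = {f.name for f in fields(cls)}
        unknown = set(top) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**top, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def provenance(self) -> dict:
        return {
            "config_hash": gio.provenance_hash(dataclasses.asdict(self)),
            "seed": self.seed,
            "grapemap_version": grapemap.__version__,
        }


def render_genotype_clusters(
    targets: pd.DataFrame,
    base: ClusterSimConfig,
    filter_cfg: FilterConfig,
    seed: int,
    reference_compactness: float | None = None,
) -> pd.DataFrame:
    """Render and measure one cluster per row of ``targets``.

    ``targets`` columns: genotype_id, block, year, target_compactness.  The
    cluster envelope is scaled so that the expected compactness matches the
    target (compactness scales inversely with hull area, hence with the
    squared envelope scale).  Returns a cluster-level trait table.
    """
    rng = np.random.default_rng(seed)
    if reference_compactness is None:
        _, ref_truth = simulate_cluster(
            dataclasses.replace(
                base, seed=int(rng.integers(2**31 - 1)), compute_truth_areas=True
            )
        )
        reference_compactness = ref_truth.true_compactness
    rows = []
    for _, t in targets.iterrows():
        n_berries = max(5, int(rng.normal(base.n_berries, base.n_berries_sd)))
        # bigger clusters get a proportionally bigger envelope so compactness
        # tracks the target rather than the berry-count draw
        scale = float(
            np.sqrt(reference_compactness / t["target_compactness"])
            * np.sqrt(n_berries / base.n_berries)
        )
        cfg = dataclasses.replace(
            base,
            envelope=(base.envelope[0] * scale, base.envelope[1] * scale),
            n_berries=n_berries,
            seed=int(rng.integers(2**31 - 1)),
        )
        try:
            masks_per_angle, truth = simulate_cluster(cfg)
        except Exception as exc:  # envelope too small for the drawn berry count
            log.warning("cluster render failed (%s); skipping", exc)
            continue
        scale_cal = ScaleCalibration(cfg.mm_per_px)
        views = []
        for angle, masks in enumerate(masks_per_angle):
            extent_px = int(
                2 * (max(cfg.envelope) + 6 * cfg.berry_radius_mean) / cfg.mm_per_px
            )
            berries, _ = process_masks(masks, (extent_px, extent_px), filter_cfg)
            if not berries:
                continue
            views.append(view_phenotype(str(t["genotype_id"]), berries, scale_cal))
        if not views:
            continue
        agg = aggregate_views(views[:2])
        rows.append(
            {
                "genotype_id": t["genotype_id"],
                "block": t["block"],
                "year": t["year"],
                "berry_count_obs_max": max(agg.berry_count_observed),
                "true_berry_count": truth.true_berry_count,
                "mean_berry_area": agg.mean_berry_area,
                "mean_berry_length": agg.mean_berry_length,
                "mean_berry_width": agg.mean_berry_width,
                "compactness": agg.compactness,
                "cluster_aspect_ratio": agg.cluster_aspect_ratio,
                "true_compactness": truth.true_compactness,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the enabled stages in order; artifacts land in ``outdir``.

    A failing stage halts the run with the stage named; artifacts written by
    earlier stages are retained next to a ``FAILED`` sentinel file.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()
    state: dict = {}
    stage_fns = {
        "simulate": _stage_simulate,
        "masks": _stage_masks,
        "morpho": _stage_morpho,
        "pheno": _stage_pheno,
        "qtl": _stage_qtl,
    }
    unknown = [s for s in config.stages if s not in stage_fns]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    for stage in config.stages:
        log.info("stage %s", stage)
        try:
            stage_fns[stage](config, out, prov, state)
        except Exception as exc:
            (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
            raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    (out / "run.json").write_text(json.dumps({**prov, "counts": state.get("counts", {})}, indent=2))
    return out


def _stage_simulate(cfg: PipelineConfig, out: Path, prov: dict, state: dict) -> None:
    cross = dataclasses.replace(cfg.cross_sim, seed=stage_seed(cfg.seed, "simulate"))
    maps, genos, pheno, truth = simulate_cross(cross)
    for parent in maps:
        gio.write_csv(maps[parent], out / f"map_{parent}.csv", prov)
        gio.write_genotypes_csv(genos[parent], out / f"geno_{parent}.csv", prov)
    gio.write_csv(pheno, out / "phenotypes.csv", prov)
    state.update(maps=maps, genos=genos, pheno=pheno, truth=truth, cross_cfg=cross)
    state.setdefault("counts", {})["progeny"] = cross.n_progeny
    state["counts"]["markers"] = {p: maps[p].shape[0] for p in maps}


def _stage_masks(cfg: PipelineConfig, out: Path, prov: dict, state: dict) -> None:
    """Render clusters whose compactness tracks each genotype's simulated
    trait value, then post-process the raw masks."""
    pheno = state.get("pheno")
    if pheno is None:
        pheno = gio.read_csv(out / "phenotypes.csv")
    trait = cfg.cross_sim.trait_name
    # map the simulated trait (standardized) onto the compactness scale
    z = (pheno[trait] - pheno[trait].mean()) / max(pheno[trait].std(), 1e-12)
    targets = pheno[["genotype_id", "block", "year"]].copy()
    targets["target_compactness"] = np.clip(
        cfg.compactness_mean + z * cfg.compactness_trait_sd, 0.05, 0.6
    )
    targets = targets.loc[targets.index.repeat(cfg.clusters_per_block)].reset_index(drop=True)
    clusters = render_genotype_clusters(
        targets, cfg.cluster_sim, cfg.filter, stage_seed(cfg.seed, "masks")
    )
    state["clusters_raw"] = clusters
    state.setdefault("counts", {})["clusters_rendered"] = len(clusters)


def _stage_morpho(cfg: PipelineConfig, out: Path, prov: dict, state: dict) -> None:
    clusters = state["clusters_raw"]
    corr = CountCorrection().fit(
        clusters["berry_count_obs_max"], clusters["true_berry_count"]
    )
    (out / "count_correction.json").write_text(json.dumps(corr.to_dict()))
    clusters = clusters.copy()
    clusters["berry_count"] = corr.predict(clusters["berry_count_obs_max"])
    gio.write_csv(clusters, out / "clusters.csv", prov)
    state["clusters"] = clusters
    state.setdefault("counts", {})["clusters_measured"] = len(clusters)


def _stage_pheno(cfg: PipelineConfig, out: Path, prov: dict, state: dict) -> None:
    clusters = state.get("clusters")
    trait_cols = ["berry_count", "mean_berry_area", "mean_berry_length", "mean_berry_width", "compactness", "cluster_aspect_ratio"]
    if clusters is None:  # genetics-only run: use simulated phenotypes directly
        records = state["pheno"]
        trait_cols = [cfg.cross_sim.trait_name]
    else:
        records = aggregate_clusters(clusters, trait_cols)
    blup_cols = {}
    vc_rows = []
    for trait in trait_cols:
        for year, sub in records.groupby("year"):
            vc, res = fit_single_year(sub, trait)
            blup_cols[(trait, year)] = res.blups
            vc_rows.append(
                {"trait": trait, "year": year, "V_g": vc.V_g, "V_e": vc.V_e, "H2": res.H2}
            )
        if records["year"].nunique() > 1:
            vc, res = fit_multi_year(records, trait)
            blup_cols[(trait, "all")] = res.blups
            vc_rows.append(
                {"trait": trait, "year": "all", "V_g": vc.V_g, "V_e": vc.V_e, "V_gy": vc.V_gy, "H2": res.H2}
            )
    blups = pd.DataFrame({f"{t}_{y}": s for (t, y), s in blup_cols.items()})
    blups.index.name = "genotype_id"
    gio.write_csv(blups, out / "blups.csv", prov, index=True)
    gio.write_csv(pd.DataFrame(vc_rows), out / "variance_components.csv", prov)
    state["blups"] = blups
    state.setdefault("counts", {})["blup_traits"] = blups.shape[1]


def _stage_qtl(cfg: PipelineConfig, out: Path, prov: dict, state: dict) -> None:
    maps, genos, blups = state["maps"], state["genos"], state["blups"]
    sc = cfg.scan
    seed = stage_seed(cfg.seed, "qtl")
    all_scans, all_peaks = [], []
    for parent in maps:
        geno_qc, _ = genotype_qc(genos[parent])
        bmap, bgeno = bin_markers(maps[parent], geno_qc)
        probs = genotype_probabilities(bmap, bgeno, sc.step_cm, sc.map_function)
        for col in blups.columns:
            y = blups[col].reindex(probs.individuals)
            scan = hk_scan(probs, y)
            thr = permutation_threshold(probs, y, sc.n_perm, sc.alpha, seed=seed)
            sdf = scan.to_frame()
            sdf.insert(0, "parent", parent)
            sdf.insert(1, "trait", col)
            sdf["threshold"] = thr
            all_scans.append(sdf)
            if sc.stepwise:
                model = stepwise_qtl(probs, y, penalty=thr)
                for pk in peaks_from_model(model, probs, y, col, parent, bmap, sc.lod_drop):
                    all_peaks.append(
                        {
                            "trait": pk.trait,
                            "parent": pk.parent,
                            "chrom": pk.chrom,
                            "pos_cm": pk.pos_cm,
                            "pos_bp": pk.pos_bp,
                            "lod": pk.lod,
                            "marker_variance_pct": pk.marker_variance_pct,
                            "model_variance_pct": pk.model_variance_pct,
                            "interval_lo_cm": pk.interval_cm[0],
                            "interval_hi_cm": pk.interval_cm[1],
                            "threshold": thr,
                        }
                    )
    gio.write_csv(pd.concat(all_scans, ignore_index=True), out / "scan.csv", prov)
    peaks_df = pd.DataFrame(
        all_peaks,
        columns=[
            "trait", "parent", "chrom", "pos_cm", "pos_bp", "lod",
            "marker_variance_pct", "model_variance_pct",
            "interval_lo_cm", "interval_hi_cm", "threshold",
        ],
    )
    gio.write_csv(peaks_df, out / "peaks.csv", prov)
    state.setdefault("counts", {})["peaks"] = len(peaks_df)
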