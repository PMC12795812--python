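"""QTL engine: QC, binning, genotype probabilities, scans, intervals,
stepwise selection and variance decomposition."""

import numpy as np
import pandas as pd
import pytest

from grapemap.qtl import (
    GenotypeProbabilities,
    bin_markers,
    genotype_probabilities,
    genotype_qc,
    hk_scan,
    lod_interval,
    permutation_threshold,
    stepwise_qtl,
    variance_explained,
)
from grapemap.simulate import CrossSimConfig, PlantedQtl, recombination_fraction, simulate_cross


class TestQc:
    def test_maf_rule(self):
        rng = np.random.default_rng(0)
        g = pd.DataFrame(
            {
                "ok": rng.integers(0, 2, 100).astype(float),
                "rare": np.r_[np.ones(4), np.zeros(96)],  # MAF 0.04
            }
        )
        kept, report = genotype_qc(g)
        assert list(kept.columns) == ["ok"]
        assert report.n_markers_maf == 1

    def test_missingness_rules(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 2, (100, 3)).astype(float)
        g = pd.DataFrame(base, columns=["a", "b", "c"])
        g.loc[:11, "b"] = np.nan  # 12% missing -> removed
        g.loc[:8, "c"] = np.nan  # 9% missing -> kept
        kept, report = genotype_qc(g)
        assert set(kept.columns) == {"a", "c"}
        assert report.n_markers_missing == 1

    def test_constructed_matrix_shape(self):
        """10 x 6 fixture built so exactly 2 markers and 1 individual fail."""
        rng = np.random.default_rng(3)
        g = pd.DataFrame(
            rng.integers(0, 2, (10, 6)).astype(float),
            columns=[f"m{i}" for i in range(6)],
            index=[f"i{i}" for i in range(10)],
        )
        g["m4"] = np.r_[np.ones(1), np.zeros(9)]  # MAF 0.1 -> removed (rule is > 0.1)
        g.loc[["i0", "i1"], "m5"] = np.nan  # 20% missing -> removed
        # individual i9: missing at 1 of the 4 surviving markers (25%)
        g.loc["i9", "m0"] = np.nan
        kept, report = genotype_qc(g)
        assert kept.shape == (9, 4)
        assert report.n_individuals_removed == 1

    def test_all_removed_raises(self):
        g = pd.DataFrame({"m": np.zeros(50)})
        with pytest.raises(ValueError):
            genotype_qc(g)


class TestBinning:
    def _map(self):
        return pd.DataFrame(
            {
                "marker": ["m1", "m2", "m3", "m4"],
                "chrom": [1, 1, 1, 1],
                "pos_cm": [12.4, 12.4, 12.4, 30.0],
                "pos_bp": [100, 200, 300, 900],
            }
        )

    def test_identical_calls_collapse(self):
        calls = np.array([0, 1, 0, 1, 1.0])
        g = pd.DataFrame({m: calls for m in ["m1", "m2", "m3", "m4"]})
        bmap, rep = bin_markers(self._map(), g)
        assert len(bmap) == 2
        assert bmap["n_markers"].tolist() == [3, 1]
        assert (rep.iloc[:, 0] == calls).all()

    def test_distinct_positions_stay(self):
        gmap = self._map().assign(pos_cm=[1.0, 2.0, 3.0, 4.0])
        g = pd.DataFrame({m: np.zeros(3) + 1 for m in gmap["marker"]})
        bmap, _ = bin_markers(gmap, g)
        assert len(bmap) == 4

    def test_missing_filled_from_cobinned(self):
        g = pd.DataFrame(
            {
                "m1": [0, np.nan, 1, np.nan],
                "m2": [0, 1, np.nan, np.nan],
                "m3": [np.nan, 1, 1, 0.0],
                "m4": [1, 1, 0, 0.0],
            }
        )
        bmap, rep = bin_markers(self._map(), g)
        assert rep["m1"].tolist() == [0, 1, 1, 0]
        assert not bmap["conflict_flag"].iloc[0]

    def test_conflicts_flagged_majority_used(self):
        g = pd.DataFrame(
            {
                "m1": [0.0] * 6,
                "m2": [1.0] * 6,  # disagrees everywhere
                "m3": [0.0] * 6,
                "m4": [1.0] * 6,
            }
        )
        bmap, rep = bin_markers(self._map(), g)
        assert bmap["conflict_flag"].iloc[0]
        assert (rep["m1"] == 0).all()  # majority 0 vs 1 (2 markers to 1)


class TestGenotypeProbabilities:
    def test_typed_marker_probability_is_call(self):
        gmap = pd.DataFrame({"marker": ["a", "b"], "chrom": [1, 1], "pos_cm": [0.0, 20.0]})
        geno = pd.DataFrame({"a": [1.0, 0.0], "b": [1.0, 1.0]}, index=["i1", "i2"])
        probs = genotype_probabilities(gmap, geno, step_cm=5.0)
        assert probs.P[0, 0] == 1.0 and probs.P[1, 0] == 0.0

    def test_interval_interior_against_enumeration(self):
        """Midpoint probabilities from exhaustive enumeration of the
        two-interval Markov chain."""
        gmap = pd.DataFrame({"marker": ["a", "b"], "chrom": [1, 1], "pos_cm": [0.0, 20.0]})
        for gl, gr in [(0, 1), (1, 1), (0, 0), (1, 0)]:
            geno = pd.DataFrame({"a": [float(gl)], "b": [float(gr)]}, index=["i"])
            probs = genotype_probabilities(gmap, geno, step_cm=10.0)
            # enumeration oracle over the hidden state at the midpoint
            r = recombination_fraction(10.0)
            t = lambda a, b: r if a != b else 1 - r
            num = t(gl, 1) * t(1, gr)
            den = num + t(gl, 0) * t(0, gr)
            assert probs.P[0, 1] == pytest.approx(num / den, abs=1e-12)

    def test_empirical_frequency_matches_probability(self):
        """Simulated gametes: empirical P(g=1 | flanks) at an untyped midpoint
        matches the conditional formula."""
        cfg = CrossSimConfig(
            n_progeny=20_000, chrom_lengths_cm=(20.0,), marker_spacing_cm=20.0,
            parents=("p1", "p2"), seed=0,
        )
        maps, genos, _, _ = simulate_cross(cfg)
        gmap, g = maps["p1"], genos["p1"]
        # simulate the midpoint by rebuilding with 10 cM spacing
        cfg2 = CrossSimConfig(
            n_progeny=20_000, chrom_lengths_cm=(20.0,), marker_spacing_cm=10.0,
            parents=("p1", "p2"), seed=0,
        )
        maps2, genos2, _, _ = simulate_cross(cfg2)
        g2 = genos2["p1"]
        flank = g2.iloc[:, [0, 2]]
        mid = g2.iloc[:, 1]
        sel = (flank.iloc[:, 0] == 1) & (flank.iloc[:, 1] == 1)
        emp = mid[sel].mean()
        probs = genotype_probabilities(maps2["p1"].iloc[[0, 2]], flank, step_cm=10.0)
        j = int(np.where(probs.pos_cm == 10.0)[0][0])
        r = recombination_fraction(10.0)
        expected = (1 - r) ** 2 / ((1 - r) ** 2 + r**2)
        assert probs.P[sel.to_numpy(), j][0] == pytest.approx(expected, abs=1e-12)
        assert emp == pytest.approx(expected, abs=0.01)

    def test_missing_handled_by_flanking_informative(self):
        gmap = pd.DataFrame(
            {"marker": ["a", "b", "c"], "chrom": [1, 1, 1], "pos_cm": [0.0, 10.0, 20.0]}
        )
        geno = pd.DataFrame({"a": [1.0], "b": [np.nan], "c": [1.0]}, index=["i"])
        probs = genotype_probabilities(gmap, geno, step_cm=10.0)
        # at the missing marker, both informative flanks say 1
        j = np.where(probs.pos_cm == 10.0)[0][0]
        assert probs.P[0, j] > 0.95

    def test_no_informative_markers_gives_half(self):
        gmap = pd.DataFrame({"marker": ["a"], "chrom": [1], "pos_cm": [0.0]})
        geno = pd.DataFrame({"a": [np.nan]}, index=["i"])
        probs = genotype_probabilities(gmap, geno, step_cm=0.0)
        assert probs.P[0, 0] == 0.5


class TestScan:
    def _probs_and_y(self, seed=2, n=100, qtl=None):
        cfg = CrossSimConfig(
            n_progeny=n, n_blocks=1, sigma_g=0.0, sigma_e=1.0, seed=seed,
            planted_qtls=qtl or [],
        )
        maps, genos, pheno, truth = simulate_cross(cfg)
        probs = genotype_probabilities(maps["cabsauv"], genos["cabsauv"], 1.0)
        y = pheno.set_index("genotype_id")["trait"]
        return probs, y, truth

    def test_lod_formula(self):
        """n = 100, RSS0/RSS1 = 10 -> LOD = 50."""
        n = 100
        assert 0.5 * n * np.log10(10.0) == pytest.approx(50.0)

    def test_marker_regression_oracle(self):
        probs, y, _ = self._probs_and_y()
        scan = hk_scan(probs, y)
        yv = y.reindex(probs.individuals).to_numpy()
        n = len(yv)
        rss0 = ((yv - yv.mean()) ** 2).sum()
        for j in [0, 17, 101, 400]:
            X = np.column_stack([np.ones(n), probs.P[:, j]])
            beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
            rss1 = ((yv - X @ beta) ** 2).sum()
            assert scan.lod[j] == pytest.approx(0.5 * n * np.log10(rss0 / rss1), abs=1e-8)

    def test_constant_phenotype_zero_lod(self):
        probs, y, _ = self._probs_and_y()
        with pytest.warns(UserWarning, match="constant"):
            scan = hk_scan(probs, np.full(probs.n, 3.0))
        assert (scan.lod == 0).all()

    def test_affine_invariance(self):
        probs, y, _ = self._probs_and_y(seed=5)
        l1 = hk_scan(probs, y).lod
        l2 = hk_scan(probs, 3.0 * y - 7.0).lod
        assert np.allclose(l1, l2, atol=1e-9)


class TestPermutations:
    def test_seed_reproducibility(self):
        cfg = CrossSimConfig(n_progeny=80, n_blocks=1, seed=3)
        maps, genos, pheno, _ = simulate_cross(cfg)
        probs = genotype_probabilities(maps["cabsauv"], genos["cabsauv"], 2.0)
        y = pheno.set_index("genotype_id")["trait"]
        assert permutation_threshold(probs, y, 200, 0.05, seed=7) == permutation_threshold(
            probs, y, 200, 0.05, seed=7
        )

    def test_constant_phenotype_zero_threshold(self):
        cfg = CrossSimConfig(n_progeny=50, n_blocks=1, seed=3)
        maps, genos, pheno, _ = simulate_cross(cfg)
        probs = genotype_probabilities(maps["cabsauv"], genos["cabsauv"], 2.0)
        assert permutation_threshold(probs, np.ones(50), 100, 0.05, seed=1) == 0.0

    def test_monotone_in_alpha(self):
        cfg = CrossSimConfig(n_progeny=80, n_blocks=1, seed=3)
        maps, genos, pheno, _ = simulate_cross(cfg)
        probs = genotype_probabilities(maps["cabsauv"], genos["cabsauv"], 2.0)
        y = pheno.set_index("genotype_id")["trait"]
        thrs = [permutation_threshold(probs, y, 300, a, seed=5) for a in (0.01, 0.05, 0.10, 0.25)]
        assert all(a >= b for a, b in zip(thrs, thrs[1:]))

    def test_too_few_permutations_rejected(self):
        cfg = CrossSimConfig(n_progeny=50, n_blocks=1, seed=3)
        maps, genos, pheno, _ = simulate_cross(cfg)
        probs = genotype_probabilities(maps["cabsauv"], genos["cabsauv"], 2.0)
        with pytest.raises(ValueError):
            permutation_threshold(probs, pheno.set_index("genotype_id")["trait"], 50)


class TestLodInterval:
    def test_triangular_peak_halfwidth(self):
        """Slope 0.3 LOD/cM around a peak of 6: the 1.5-drop points are 5 cM out."""
        pos = np.arange(0.0, 41.0)
        lod = np.maximum(0.0, 6.0 - 0.3 * np.abs(pos - 20.0))
        lo, hi = lod_interval(pos, lod, np.ones_like(pos), 1, 20.0, drop=1.5)
        assert lo == 15.0 and hi == 25.0

    def test_flat_profile_full_chromosome(self):
        pos = np.arange(0.0, 51.0)
        lod = np.full_like(pos, 4.0)
        lod[25] = 4.5
        lo, hi = lod_interval(pos, lod, np.ones_like(pos), 1, 25.0, drop=1.5)
        assert lo == 0.0 and hi == 50.0

    def test_peak_at_chromosome_end_one_sided(self):
        pos = np.arange(0.0, 31.0)
        lod = np.maximum(0.0, 5.0 - 0.4 * pos)
        lo, hi = lod_interval(pos, lod, np.ones_like(pos), 1, 0.0, drop=1.5)
        assert lo == 0.0
        assert hi == pytest.approx(3.0, abs=1.0)

    def test_expansion_to_bin_positions(self):
        pos = np.arange(0.0, 41.0)
        lod = np.maximum(0.0, 6.0 - 0.3 * np.abs(pos - 20.0))
        lo, hi = lod_interval(
            pos, lod, np.ones_like(pos), 1, 20.0, 1.5, bin_positions=np.array([0.0, 13.0, 27.0, 40.0])
        )
        assert lo == 13.0 and hi == 27.0

    def test_drop_must_be_positive(self):
        with pytest.raises(ValueError):
            lod_interval(np.arange(3.0), np.ones(3), np.ones(3), 1, 0.0, drop=0.0)


class TestStepwise:
    def test_single_qtl_recovered(self):
        cfg = CrossSimConfig(
            n_progeny=138, n_blocks=1, sigma_g=0.0, sigma_e=1.0, seed=21,
            planted_qtls=[PlantedQtl("cabsauv", 3, 47.0, 1.5)],
        )
        maps, genos, pheno, _ = simulate_cross(cfg)
        probs = genotype_probabilities(maps["cabsauv"], genos["cabsauv"], 1.0)
        y = pheno.set_index("genotype_id")["trait"]
        thr = permutation_threshold(probs, y, 200, 0.05, seed=21)
        model = stepwise_qtl(probs, y, penalty=thr)
        assert model.n_qtl == 1
        chrom, pos = model.positions()[0]
        assert chrom == 3 and abs(pos - 47.0) <= 10.0

    def test_variance_explained_matches_ols_oracle(self):
        cfg = CrossSimConfig(
            n_progeny=138, n_blocks=1, sigma_g=0.0, sigma_e=1.0, seed=22,
            planted_qtls=[
                PlantedQtl("cabsauv", 1, 30.0, 0.9),
                PlantedQtl("cabsauv", 4, 60.0, 0.9),
            ],
        )
        maps, genos, pheno, _ = simulate_cross(cfg)
        probs = genotype_probabilities(maps["cabsauv"], genos["cabsauv"], 1.0)
        y = pheno.set_index("genotype_id")["trait"]
        model = stepwise_qtl(probs, y, penalty=2.5)
        marker_pct, model_pct = variance_explained(model)
        yv = y.reindex(probs.individuals).to_numpy()
        n = len(yv)
        X_full = np.column_stack([np.ones(n)] + [probs.P[:, q] for q in model.qtl_indices])
        beta, *_ = np.linalg.lstsq(X_full, yv, rcond=None)
        r2_full = 1 - ((yv - X_full @ beta) ** 2).sum() / ((yv - yv.mean()) ** 2).sum()
        assert model_pct == pytest.approx(100 * r2_full, abs=1e-8)
        for k, q in enumerate(model.qtl_indices):
            reduced = [m for m in model.qtl_indices if m != q]
            X_red = np.column_stack([np.ones(n)] + [probs.P[:, m] for m in reduced])
            b_red, *_ = np.linalg.lstsq(X_red, yv, rcond=None)
            r2_red = 1 - ((yv - X_red @ b_red) ** 2).sum() / ((yv - yv.mean()) ** 2).sum()
            assert marker_pct[k] == pytest.approx(100 * (r2_full - r2_red), abs=1e-8)

    def test_single_qtl_marker_equals_model_pct(self):
        cfg = CrossSimConfig(
            n_progeny=100, n_blocks=1, sigma_g=0.0, seed=23,
            planted_qtls=[PlantedQtl("cabsauv", 2, 50.0, 1.2)],
        )
        maps, genos, pheno, _ = simulate_cross(cfg)
        probs = genotype_probabilities(maps["cabsauv"], genos["cabsauv"], 1.0)
        y = pheno.set_index("genotype_id")["trait"]
        model = stepwise_qtl(probs, y, penalty=3.0)
        if model.n_qtl == 1:
            marker_pct, model_pct = variance_explained(model)
            assert marker_pct[0] == pytest.approx(model_pct, abs=1e-9)

    def test_zero_lod_zero_model_pct(self):
        from grapemap.qtl.stepwise import StepwiseModel

        m = StepwiseModel([], np.array([1]), np.array([0.0]), 0.0, 0.0, 3.0, 100)
        _, pct = variance_explained(m)
        assert pct == 0.0
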