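"""Interval mapping, ridge BLUP and cross-validation properties."""

import numpy as np
import pandas as pd
import pytest

from uavheight import (
    QtlLocus,
    QtlSpec,
    RidgeBLUP,
    SimulationConfig,
    cross_validate,
    fit_gblup,
    icim_scan,
    line_means,
    marker_exclusion_experiment,
    qtl_peaks,
    select_cofactors,
    simulate_dh_population,
    simulate_phenotypes,
)
from uavheight.synthetic_field import make_linkage_map


@pytest.fixture(scope="module")
def dh_population():
    lmap = make_linkage_map(3, 100.0, 5.0)
    geno = simulate_dh_population(lmap, 150, seed=42)
    return lmap, geno


def planted_phenotype(geno, marker_idx, effect, noise_sd, seed):
    rng = np.random.default_rng(seed)
    s = geno.signed()
    return s[:, marker_idx] * effect + rng.normal(0, noise_sd, geno.n_lines)


class TestLineMeans:
    def test_single_observation_passthrough(self):
        t = pd.DataFrame(
            {"genotype_id": ["a", "b"], "value_cm": [80.0, 90.0]}
        )
        m = line_means(t)
        assert m["a"] == 80.0 and m["b"] == 90.0

    def test_linearity_over_balanced_design(self):
        rng = np.random.default_rng(0)
        delta = rng.normal(0, 1, 6)
        t = pd.DataFrame(
            {
                "genotype_id": ["a"] * 6,
                "value_cm": 75.0 + delta,
            }
        )
        assert line_means(t)["a"] == pytest.approx(75.0 + delta.mean())

    def test_zero_noise_means_equal_genetic_values(self):
        cfg = SimulationConfig(
            n_lines=20, n_sites=2, n_reps=2, include_parents=False,
            sigma_ge2=0.0, sigma_e2=0.0, sigma_site2=0.0, seed=5,
        )
        lmap = make_linkage_map(cfg.n_chromosomes, 150.0, 5.0)
        geno = simulate_dh_population(lmap, 20, seed=5)
        table, gv = simulate_phenotypes(geno, lmap, QtlSpec(), cfg)
        means = line_means(table)
        merged = gv.set_index("genotype_id")["genetic_value_cm"]
        np.testing.assert_allclose(
            means.loc[merged.index] - cfg.mean_height_cm, merged, atol=1e-9
        )


class TestSelectCofactors:
    def test_collinear_marker_selected_first(self, dh_population):
        lmap, geno = dh_population
        y = geno.signed()[:, 7] * 3.0
        selected = select_cofactors(geno, y)
        assert selected[0] == 7

    def test_planted_qtl_marker_found(self, dh_population):
        lmap, geno = dh_population
        y = planted_phenotype(geno, 30, 1.0, 1.5, seed=1)  # PVE ~ 30%
        selected = select_cofactors(geno, y)
        pos = lmap.positions_cm
        chroms = np.asarray(lmap.chromosomes)
        assert any(
            chroms[j] == chroms[30] and abs(pos[j] - pos[30]) <= 5.0
            for j in selected
        )

    def test_pure_noise_rarely_selects(self, dh_population):
        lmap, geno = dh_population
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, geno.n_lines)
        assert len(select_cofactors(geno, y)) <= 3


class TestIcimScan:
    def test_scan_at_marker_equals_single_marker_regression(self, dh_population):
        lmap, geno = dh_population
        y = planted_phenotype(geno, 10, 0.8, 1.0, seed=2)
        scan = icim_scan(geno, lmap, y, cofactors=[], step_cm=5.0)
        # independent oracle: explicit single-marker regression LOD
        s = geno.signed()[:, 10]
        yc = y - y.mean()
        sc = s - s.mean()
        b = (sc @ yc) / (sc @ sc)
        rss1 = float(((yc - b * sc) ** 2).sum())
        rss0 = float((yc**2).sum())
        lod_oracle = (len(y) / 2) * np.log10(rss0 / rss1)
        chrom = lmap.chromosomes[10]
        pos = lmap.positions_cm[10]
        row = scan.table[
            (scan.table.chromosome == chrom) & (scan.table.position_cm == pos)
        ]
        assert row["lod"].iloc[0] == pytest.approx(lod_oracle, rel=1e-9)
        assert row["effect_cm"].iloc[0] == pytest.approx(b, rel=1e-9)

    def test_lod_invariant_to_affine_phenotype(self, dh_population):
        lmap, geno = dh_population
        y = planted_phenotype(geno, 25, 0.7, 1.0, seed=3)
        a = icim_scan(geno, lmap, y, step_cm=10.0)
        b = icim_scan(geno, lmap, 3.0 * y + 100.0, step_cm=10.0)
        np.testing.assert_allclose(
            a.table["lod"].to_numpy(), b.table["lod"].to_numpy(), atol=1e-8
        )

    def test_no_cofactors_equals_simple_interval_mapping(self, dh_population):
        lmap, geno = dh_population
        y = planted_phenotype(geno, 25, 0.7, 1.0, seed=4)
        a = icim_scan(geno, lmap, y, cofactors=None, step_cm=10.0)
        b = icim_scan(geno, lmap, y, cofactors=[], step_cm=10.0)
        assert a.table.equals(b.table)

    def test_null_genome_wide_lod_rarely_exceeds_threshold(self):
        lmap = make_linkage_map(3, 150.0, 2.0)
        geno = simulate_dh_population(lmap, 198, seed=11)
        rng = np.random.default_rng(12)
        exceed = 0
        n_sims = 40
        for _ in range(n_sims):
            y = rng.normal(0, 1, 198)
            scan = icim_scan(geno, lmap, y, cofactors=[], step_cm=2.0)
            exceed += scan.max_lod() > 2.5
        assert exceed < 0.5 * n_sims

    def test_misaligned_genotypes_rejected(self, dh_population):
        lmap, geno = dh_population
        other = make_linkage_map(2, 50.0, 25.0)
        with pytest.raises(ValueError, match="aligned"):
            icim_scan(geno, other, np.zeros(geno.n_lines))


class TestQtlPeaks:
    def test_flat_scan_no_peaks(self, dh_population):
        lmap, geno = dh_population
        rng = np.random.default_rng(5)
        scan = icim_scan(geno, lmap, rng.normal(0, 1, geno.n_lines), step_cm=5.0)
        scan.table["lod"] = 0.5
        assert qtl_peaks(scan) == []

    def test_two_distant_qtl_give_two_peaks(self):
        lmap = make_linkage_map(1, 150.0, 5.0, ("1A",))
        geno = simulate_dh_population(lmap, 250, seed=21)
        s = geno.signed()
        j1 = lmap.nearest_marker("1A", 30.0)
        j2 = lmap.nearest_marker("1A", 110.0)
        rng = np.random.default_rng(22)
        y = 1.0 * s[:, j1] + 1.0 * s[:, j2] + rng.normal(0, 1.0, 250)
        # full two-stage procedure: cofactors absorb the linked QTL and kill
        # the inter-peak "ghost" ridge a cofactor-free scan would show
        cof = select_cofactors(geno, y)
        scan = icim_scan(geno, lmap, y, cofactors=cof, step_cm=2.0)
        peaks = qtl_peaks(scan, min_separation_cm=20.0)
        assert len(peaks) == 2
        assert abs(peaks[0].position_cm - 30.0) <= 10
        assert abs(peaks[1].position_cm - 110.0) <= 10

    def test_tie_breaks_leftmost(self, dh_population):
        lmap, geno = dh_population
        rng = np.random.default_rng(6)
        scan = icim_scan(geno, lmap, rng.normal(0, 1, geno.n_lines), step_cm=5.0)
        scan.table["lod"] = 0.0
        # plant a two-point plateau above threshold on one chromosome
        mask = scan.table.chromosome == "1A"
        idx = scan.table[mask].index[4:6]
        scan.table.loc[idx, "lod"] = 5.0
        peaks = qtl_peaks(scan)
        assert len(peaks) == 1
        assert peaks[0].position_cm == scan.table.loc[idx[0], "position_cm"]


class TestRidgeBLUP:
    def test_fixed_lambda_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 2, size=(20, 50)).astype(float)
        y = rng.normal(80, 10, 20)
        model = RidgeBLUP(shrinkage=10.0).fit(X, y)
        # independent oracle: dense normal-equations solve on signed coding
        Z = X * 2 - 1
        Zc = Z - Z.mean(axis=0)
        g = np.linalg.solve(Zc.T @ Zc + 10.0 * np.eye(50), Zc.T @ (y - y.mean()))
        pred_oracle = y.mean() + Zc @ g
        np.testing.assert_allclose(model.predict(X), pred_oracle, atol=1e-8)

    def test_infinite_shrinkage_returns_training_mean(self):
        rng = np.random.default_rng(8)
        X = rng.integers(0, 2, size=(30, 40)).astype(float)
        y = rng.normal(75, 8, 30)
        model = RidgeBLUP(shrinkage=1e12).fit(X, y)
        np.testing.assert_allclose(model.predict(X), y.mean(), atol=1e-6)

    def test_zero_shrinkage_equals_ols(self):
        rng = np.random.default_rng(9)
        X = rng.integers(0, 2, size=(60, 10)).astype(float)
        beta = rng.normal(0, 1, 10)
        y = (X * 2 - 1) @ beta + rng.normal(0, 0.5, 60)
        model = RidgeBLUP(shrinkage=0.0).fit(X, y)
        Z = X * 2 - 1
        Zc = Z - Z.mean(axis=0)
        ols = np.linalg.lstsq(Zc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(model.coef_, ols, atol=1e-8)

    def test_coding_flip_invariance(self):
        rng = np.random.default_rng(10)
        X = rng.integers(0, 2, size=(40, 30)).astype(float)
        y = rng.normal(80, 6, 40)
        a = RidgeBLUP(shrinkage=5.0).fit(X, y).predict(X)
        b = RidgeBLUP(shrinkage=5.0).fit(1 - X, y).predict(1 - X)
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_reml_recovers_variance_ratio_regime(self, dh_population):
        _, geno = dh_population
        rng = np.random.default_rng(13)
        p = geno.values.shape[1]
        u = rng.normal(0, np.sqrt(2.0 / p), p)
        y = geno.signed() @ u + rng.normal(0, 1.0, geno.n_lines)
        model = fit_gblup(geno, y, shrinkage="reml")
        # true ratio sigma_e2/sigma_u2 = 1 / (2/p) = p/2
        assert 0.1 * p / 2 < model.lambda_ < 10 * p / 2

    def test_sklearn_params_roundtrip(self):
        model = RidgeBLUP(shrinkage=3.0)
        assert model.get_params() == {"shrinkage": 3.0}
        model.set_params(shrinkage="reml")
        assert model.shrinkage == "reml"


class TestCrossValidation:
    def test_null_phenotype_centers_on_zero(self, dh_population):
        _, geno = dh_population
        rng = np.random.default_rng(14)
        y = rng.normal(0, 1, geno.n_lines)
        res = cross_validate(geno, y, k=5, repeats=30, seed=3, shrinkage=50.0)
        se = res.accuracies.std(ddof=1) / np.sqrt(len(res.accuracies))
        assert abs(res.r_mean) < 4 * se + 0.1

    def test_leave_one_out_runs(self, dh_population):
        lmap, geno = dh_population
        s = geno.signed()
        rng = np.random.default_rng(15)
        y = s[:, 5] + rng.normal(0, 1, geno.n_lines)
        res = cross_validate(geno, y, k=geno.n_lines, repeats=1, seed=1)
        assert np.isfinite(res.r_mean)

    def test_deterministic_given_seed(self, dh_population):
        _, geno = dh_population
        rng = np.random.default_rng(16)
        y = rng.normal(0, 1, geno.n_lines)
        a = cross_validate(geno, y, repeats=3, seed=9, shrinkage=20.0)
        b = cross_validate(geno, y, repeats=3, seed=9, shrinkage=20.0)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)

    def test_every_line_predicted_once_per_repeat(self, dh_population):
        _, geno = dh_population
        rng = np.random.default_rng(17)
        y = rng.normal(0, 1, geno.n_lines)
        res = cross_validate(geno, y, k=5, repeats=1, seed=2, shrinkage=10.0)
        assert len(res.predictions) == geno.n_lines
        assert res.predictions["line_id"].is_unique


class TestMarkerExclusion:
    def test_excluding_nothing_is_identity(self, dh_population):
        lmap, geno = dh_population
        rng = np.random.default_rng(18)
        y = geno.signed()[:, 8] + rng.normal(0, 1, geno.n_lines)
        res = marker_exclusion_experiment(
            geno, lmap, y, excluded_regions=[], k=5, repeats=3, seed=4,
            shrinkage=20.0,
        )
        assert res["r_full"] == res["r_excluded"]
        assert np.all(res["paired_diffs"] == 0.0)

    def test_excluding_qtl_chromosome_reduces_accuracy(self, dh_population):
        lmap, geno = dh_population
        rng = np.random.default_rng(19)
        j = lmap.nearest_marker("1A", 50.0)
        y = 1.5 * geno.signed()[:, j] + rng.normal(0, 1, geno.n_lines)
        res = marker_exclusion_experiment(
            geno, lmap, y, excluded_chromosomes=["1A"], k=5, repeats=5, seed=5,
        )
        assert res["r_excluded"] < res["r_full"]
        assert res["frac_repeats_reduced"] == 1.0

    def test_excluding_everything_rejected(self, dh_population):
        lmap, geno = dh_population
        y = np.zeros(geno.n_lines)
        with pytest.raises(ValueError, match="at least 10"):
            marker_exclusion_experiment(
                geno, lmap, y,
                excluded_chromosomes=list(lmap.chromosome_names),
            )
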