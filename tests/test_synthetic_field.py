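"""Generator checks: meiosis against Haldane, phenotype model, rendering."""

import numpy as np
import pandas as pd
import pytest

from uavheight import (
    QtlLocus,
    QtlSpec,
    SimulationConfig,
    haldane_r,
    make_field_layout,
    render_field_dsm,
    simulate_dh_population,
    simulate_phenotypes,
)
from uavheight.synthetic_field import make_linkage_map


def two_marker_map(d_cm: float):
    return make_linkage_map(
        n_chromosomes=1, chromosome_length_cm=d_cm if d_cm > 0 else 0.0,
        marker_spacing_cm=d_cm if d_cm > 0 else 1.0, chromosome_names=("1A",),
    )


def observed_recombinant_fraction(geno) -> float:
    v = geno.values
    return float(np.mean(v[:, 0] != v[:, 1]))


class TestMeiosis:
    def test_zero_distance_forces_coinheritance(self):
        lmap = make_linkage_map(1, 0.0, 1.0, ("1A",))
        assert lmap.n_markers == 1  # degenerate grid: colocated = same marker
        # explicit two-marker map at distance 0
        from uavheight.synthetic_field import LinkageMap

        lmap = LinkageMap(("m1", "m2"), ("1A", "1A"), np.array([5.0, 5.0]))
        geno = simulate_dh_population(lmap, 1000, seed=1)
        assert observed_recombinant_fraction(geno) == 0.0

    def test_infinite_distance_approaches_half(self):
        from uavheight.synthetic_field import LinkageMap

        lmap = LinkageMap(("m1", "m2"), ("1A", "1A"), np.array([0.0, 1e9]))
        geno = simulate_dh_population(lmap, 4000, seed=2)
        r = observed_recombinant_fraction(geno)
        se = np.sqrt(0.25 / 4000)
        assert abs(r - 0.5) < 3 * se

    def test_haldane_10cm(self):
        # r = (1 - e^{-0.2})/2 = 0.090635
        from uavheight.synthetic_field import LinkageMap

        expected = (1 - np.exp(-0.2)) / 2
        assert haldane_r(10.0) == pytest.approx(expected)
        lmap = LinkageMap(("m1", "m2"), ("1A", "1A"), np.array([0.0, 10.0]))
        geno = simulate_dh_population(lmap, 5000, seed=3)
        r = observed_recombinant_fraction(geno)
        se = np.sqrt(expected * (1 - expected) / 5000)
        assert abs(r - expected) < 3 * se

    def test_adjacent_fractions_match_haldane_across_map(self):
        lmap = make_linkage_map(3, 60.0, 15.0)
        geno = simulate_dh_population(lmap, 8000, seed=4)
        expected = haldane_r(15.0)
        se = np.sqrt(expected * (1 - expected) / 8000)
        for chrom in lmap.chromosome_names:
            idx = lmap.indices_on(chrom)
            for a, b in zip(idx[:-1], idx[1:]):
                obs = np.mean(geno.values[:, a] != geno.values[:, b])
                assert abs(obs - expected) < 3 * se

    def test_genotypes_binary_and_balanced(self):
        lmap = make_linkage_map(6, 150.0, 5.0)
        geno = simulate_dh_population(lmap, 198, seed=5)
        assert set(np.unique(geno.values)) <= {0, 1}
        freq = geno.values.mean(axis=0)
        se = np.sqrt(0.25 / 198)
        assert np.all(np.abs(freq - 0.5) < 4.5 * se)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            from uavheight.synthetic_field import LinkageMap

            LinkageMap((), (), np.array([]))

    def test_deterministic_given_seed(self):
        lmap = make_linkage_map(2, 50.0, 10.0)
        a = simulate_dh_population(lmap, 50, seed=9)
        b = simulate_dh_population(lmap, 50, seed=9)
        np.testing.assert_array_equal(a.values, b.values)


class TestPhenotypes:
    def test_degenerate_noise_two_values(self):
        cfg = SimulationConfig(
            n_lines=30, n_sites=1, n_reps=2, include_parents=False,
            sigma_ge2=0.0, sigma_e2=0.0, sigma_site2=0.0, seed=1,
        )
        lmap = make_linkage_map(cfg.n_chromosomes, 150.0, 5.0)
        geno = simulate_dh_population(lmap, 30, seed=1)
        qtl = QtlSpec(loci=(QtlLocus("4B", 60.0, 5.0),), polygenic_variance=0.0)
        table, _ = simulate_phenotypes(geno, lmap, qtl, cfg)
        values = np.unique(np.round(table["value_cm"], 9))
        assert len(values) == 2
        # signed +/-1 allele contrast: the two classes differ by twice the effect
        assert np.ptp(values) == pytest.approx(10.0)

    def test_balanced_table(self, small_config, small_field):
        t = small_field.phenotypes
        n_geno = small_config.n_lines + 2  # parents included
        assert len(t) == n_geno * small_config.n_sites * small_config.n_reps
        counts = t.groupby(["genotype_id", "site"]).size()
        assert (counts == small_config.n_reps).all()

    def test_residual_variance_recovered(self):
        cfg = SimulationConfig(
            n_lines=100, n_sites=2, n_reps=3, include_parents=False,
            sigma_ge2=0.0, sigma_e2=36.0, sigma_site2=0.0, seed=2,
        )
        lmap = make_linkage_map(cfg.n_chromosomes, 150.0, 5.0)
        geno = simulate_dh_population(lmap, 100, seed=2)
        qtl = QtlSpec(loci=(), polygenic_variance=0.0)
        table, _ = simulate_phenotypes(geno, lmap, qtl, cfg)
        within = table.groupby(["genotype_id", "site"])["value_cm"].var(ddof=1)
        assert within.mean() == pytest.approx(36.0, rel=0.15)

    def test_population_sd_matches_configured_scale(self):
        cfg = SimulationConfig(n_lines=198, include_parents=False, seed=3)
        lmap = make_linkage_map(cfg.n_chromosomes, 150.0, 5.0)
        geno = simulate_dh_population(lmap, 198, seed=3)
        qtl = QtlSpec()
        table, _ = simulate_phenotypes(geno, lmap, qtl, cfg)
        target_var = (
            sum(q.effect_cm**2 for q in qtl.loci)
            + qtl.polygenic_variance + cfg.sigma_ge2 + cfg.sigma_e2
        )
        site1 = table[table["site"] == "site1"]
        assert site1["value_cm"].std() == pytest.approx(
            np.sqrt(target_var), rel=0.15
        )

    def test_qtl_off_map_rejected(self):
        cfg = SimulationConfig(n_lines=10, include_parents=False)
        lmap = make_linkage_map(2, 50.0, 10.0)
        geno = simulate_dh_population(lmap, 10, seed=1)
        qtl = QtlSpec(loci=(QtlLocus("7D", 10.0, 3.0),), polygenic_variance=0.0)
        with pytest.raises(ValueError, match="absent"):
            simulate_phenotypes(geno, lmap, qtl, cfg)


class TestRendering:
    @staticmethod
    def _layout_and_heights(cfg, n=6, seed=0):
        gids = [f"DH{i:03d}" for i in range(1, n + 1)]
        layout = make_field_layout(gids, cfg, "site1", seed=seed)
        heights = pd.DataFrame(
            {
                "plot_id": [p.plot_id for p in layout.plots],
                "height_cm": np.linspace(60, 110, len(layout.plots)),
            }
        )
        return layout, heights

    def test_degenerate_texture_exact(self):
        cfg = SimulationConfig(
            n_lines=6, n_sites=1, n_reps=1, n_plot_columns=3,
            sensor_noise_sd_m=0.0, spike_fraction=1.0, spike_height_sd_m=0.0,
            canopy_deficit_frac=0.0, terrain_amplitude_m=0.0,
        )
        layout, heights = self._layout_and_heights(cfg)
        dsm, dtm = render_field_dsm(layout, heights, cfg, seed=1)
        for plot in layout.plots:
            h = heights.set_index("plot_id").loc[plot.plot_id, "height_cm"] / 100
            vals, _, _ = dsm.polygon_values(plot.polygon)
            tvals, _, _ = dtm.polygon_values(plot.polygon)
            np.testing.assert_allclose(vals - tvals, h, atol=1e-12)

    def test_bare_ground_noise_statistics(self):
        cfg = SimulationConfig(n_lines=6, n_sites=1, n_reps=1, n_plot_columns=3)
        layout, heights = self._layout_and_heights(cfg)
        dsm, dtm = render_field_dsm(layout, heights, cfg, seed=2)
        diffs = []
        for bg in layout.bare_ground:
            v, _, _ = dsm.polygon_values(bg.polygon)
            t, _, _ = dtm.polygon_values(bg.polygon)
            diffs.append(v - t)
        diffs = np.concatenate(diffs)
        assert abs(diffs.mean()) < 3 * cfg.sensor_noise_sd_m / np.sqrt(len(diffs))
        assert diffs.std() == pytest.approx(cfg.sensor_noise_sd_m, rel=0.1)

    def test_plot_maxima_reach_canopy_top(self):
        cfg = SimulationConfig(n_lines=40, n_sites=1, n_reps=2, n_plot_columns=10)
        layout, heights = self._layout_and_heights(cfg, n=40)
        dsm, dtm = render_field_dsm(layout, heights, cfg, seed=3)
        idx = heights.set_index("plot_id")["height_cm"]
        hits = 0
        for plot in layout.plots:
            top = (idx.loc[plot.plot_id] / 100) * (1 - cfg.canopy_deficit_frac)
            v, _, _ = dsm.polygon_values(plot.polygon)
            t, _, _ = dtm.polygon_values(plot.polygon)
            if (v - t).max() >= top - 2 * cfg.sensor_noise_sd_m:
                hits += 1
        assert hits >= 0.99 * len(layout.plots)

    def test_rendering_reproducible(self):
        cfg = SimulationConfig(n_lines=4, n_sites=1, n_reps=1, n_plot_columns=2)
        layout, heights = self._layout_and_heights(cfg, n=4)
        a, ta = render_field_dsm(layout, heights, cfg, seed=5)
        b, tb = render_field_dsm(layout, heights, cfg, seed=5)
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(ta.data, tb.data)

    def test_gsd_larger_than_plot_rejected(self):
        cfg = SimulationConfig(n_lines=4, n_sites=1, n_reps=1, gsd_m=2.0)
        layout, heights = self._layout_and_heights(cfg, n=4)
        with pytest.raises(ValueError, match="sampling distance"):
            render_field_dsm(layout, heights, cfg, seed=1)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(spike_fraction=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(gsd_m=-0.1)
    with pytest.raises(ValueError):
        SimulationConfig(sigma_e2=-1.0)
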