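"""Generator contracts: segregation, map fidelity, weather structure,
planted-signal bookkeeping, and the end-to-end growth link."""

import numpy as np
import pandas as pd
import pytest

from dendroqtl.climate import find_dry_spells, monthly_dry_index
from dendroqtl.rings import bai_from_widths, process_ring_table
from dendroqtl.simulate import (DatasetConfig, MapSpec, QTLEffect, TruthModel,
                                WeatherParams, build_truth_for_pve,
                                default_map_pair, simulate_daily_climate,
                                simulate_dataset, simulate_genotypes,
                                simulate_ring_widths, simulate_sensitivities)

META = ["marker", "linkage_group", "map_label", "position_cM"]


def geno_codes(frame):
    """Clones x markers 0/1 matrix from the markers-by-rows table."""
    clones = [c for c in frame.columns if c not in META]
    return (frame[clones].to_numpy() == "hom").astype(float).T, clones


class TestGenotypes:
    def test_zero_distance_markers_identical(self):
        spec = MapSpec("P1", [("LG01", 10.0, np.array([5.0, 5.0 + 1e-12]))])
        g, _ = geno_codes(simulate_genotypes(spec, 500, seed=1))
        np.testing.assert_array_equal(g[:, 0], g[:, 1])

    def test_deterministic(self):
        spec = default_map_pair(2, 20.0, 2.0)[0]
        a = simulate_genotypes(spec, 50, seed=9)
        b = simulate_genotypes(spec, 50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_haldane_recombinant_fraction(self):
        spec = MapSpec("P1", [("LG01", 10.0, np.array([0.0, 10.0]))])
        g, _ = geno_codes(simulate_genotypes(spec, 2000, seed=5))
        rec = np.mean(g[:, 0] != g[:, 1])
        expected = 0.5 * (1 - np.exp(-0.2))          # ~0.0906
        sd = np.sqrt(expected * (1 - expected) / 2000)
        assert abs(rec - expected) < 3 * sd

    def test_segregation_one_to_one(self):
        spec = default_map_pair(2, 30.0, 3.0)[0]
        g, _ = geno_codes(simulate_genotypes(spec, 400, seed=2))
        frac = g.mean(axis=0)
        sd = np.sqrt(0.25 / 400)
        assert np.all(np.abs(frac - 0.5) < 3 * sd + 1e-9)

    def test_recombination_monotone_in_distance(self):
        spec = MapSpec("P1", [("LG01", 40.0, np.arange(0.0, 41.0, 5.0))])
        g, _ = geno_codes(simulate_genotypes(spec, 3000, seed=3))
        rec = [np.mean(g[:, 0] != g[:, j]) for j in range(1, g.shape[1])]
        assert all(b >= a - 0.02 for a, b in zip(rec, rec[1:]))

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            MapSpec("P1", [])
        with pytest.raises(ValueError):
            simulate_genotypes(default_map_pair()[0], 1, seed=0)


class TestDailyClimate:
    def test_absorbing_wet_state(self):
        params = WeatherParams(p_wet_given_wet=np.ones(12), p_wet_given_dry=np.ones(12))
        clim = simulate_daily_climate(range(2000, 2002), params, seed=0)
        assert (clim["precip_mm"].iloc[1:] > 0).all()
        spells = find_dry_spells(clim)
        assert sum(s.length for s in spells) <= 1
        for k in range(1, 8):
            mat = monthly_dry_index(spells, k, [2000, 2001])
            assert mat.to_numpy().sum() <= 1

    def test_all_dry_when_wet_unreachable(self):
        params = WeatherParams(p_wet_given_wet=np.zeros(12), p_wet_given_dry=np.zeros(12))
        clim = simulate_daily_climate(range(2000, 2002), params, seed=0)
        assert (clim["precip_mm"] == 0).all()

    def test_every_day_present_once(self):
        clim = simulate_daily_climate(range(2003, 2006), seed=4)   # 2004 is leap
        assert len(clim) == 365 + 366 + 365
        assert clim["date"].is_unique
        assert (clim["precip_mm"] >= 0).all()

    def test_stationary_wet_fraction(self):
        params = WeatherParams(p_wet_given_wet=np.full(12, 0.5),
                               p_wet_given_dry=np.full(12, 0.5))
        clim = simulate_daily_climate(range(2000, 2010), params, seed=8)
        frac = (clim["precip_mm"] > 0).mean()
        sd = np.sqrt(0.25 / len(clim))   # conservative: ignores tiny serial dependence
        assert abs(frac - 0.5) < 5 * sd

    def test_single_year_rejected(self):
        with pytest.raises(ValueError):
            simulate_daily_climate([2000], seed=0)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            WeatherParams(p_wet_given_wet=np.full(12, 1.5))


class TestSensitivities:
    def test_zero_effects_zero_noise(self):
        spec = default_map_pair(2, 20.0, 5.0)[0]
        geno = simulate_genotypes(spec, 30, seed=0)
        truth = TruthModel(qtl_effects=[], clone_noise_sd=0.0)
        s, assign = simulate_sensitivities(geno, truth, seed=1)
        np.testing.assert_allclose(s.to_numpy(), 0.0)
        assert assign.empty

    def test_single_qtl_equals_marker_column(self):
        spec = default_map_pair(1, 20.0, 5.0)[0]
        geno = simulate_genotypes(spec, 40, seed=0)
        truth = TruthModel(qtl_effects=[QTLEffect("P1", "LG01", 10.0, 1.0)],
                           clone_noise_sd=0.0)
        s, assign = simulate_sensitivities(geno, truth, seed=1)
        g, clones = geno_codes(geno)
        j = geno.index[geno["marker"] == assign.iloc[0]["marker"]][0]
        np.testing.assert_allclose(s.to_numpy(), g[:, j])

    def test_planted_pve_arithmetic(self):
        """Mean realised PVE over replicate draws matches the planted 12%."""
        spec = default_map_pair(4, 30.0, 3.0)[0]
        pves = []
        for rep in range(200):
            geno = simulate_genotypes(spec, 139, seed=rep)
            truth = build_truth_for_pve([("P1", "LG01", 15.0, 0.12)])
            _, assign = simulate_sensitivities(geno, truth, seed=10_000 + rep)
            pves.append(assign["realized_pve_pct"].iloc[0])
        assert abs(np.mean(pves) - 12.0) < 2.0


class TestRingWidths:
    def _setup(self, noise_sd=0.0, link=1.0, s_values=(0.0,), years=range(2005, 2015)):
        clim = simulate_daily_climate(range(2004, 2015), seed=3)
        sens = pd.Series(list(s_values),
                         index=[f"cl{i:04d}" for i in range(len(s_values))])
        truth = TruthModel(qtl_effects=[], noise_sd=noise_sd, link_scale=link,
                           ar1_phi=0.3)
        return clim, sens, truth, list(years)

    def test_zero_noise_zero_sensitivity_follows_age_trend(self):
        clim, sens, truth, years = self._setup()
        rings = simulate_ring_widths(sens, clim, truth, years, n_replicates=1, seed=0)
        widths = rings["width_mm"].to_numpy()
        from dendroqtl.rings import RingSeries
        bai = bai_from_widths(RingSeries("t", "c", "S", years[0], widths))
        A, b, c, d = truth.growth_curve
        t = np.arange(1, len(years) + 1, dtype=float)
        np.testing.assert_allclose(bai.bai, A * t**b * np.exp(-c * t) + d, rtol=1e-9)

    def test_deterministic(self):
        clim, sens, truth, years = self._setup(noise_sd=0.1, s_values=(0.5, -0.5))
        a = simulate_ring_widths(sens, clim, truth, years, seed=7)
        b = simulate_ring_widths(sens, clim, truth, years, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_climate_year_rejected(self):
        clim, sens, truth, years = self._setup()
        with pytest.raises(ValueError):
            simulate_ring_widths(sens, clim[clim["date"].dt.year > 2004],
                                 truth, years, seed=0)

    def test_planted_sign_recovered_through_ring_pipeline(self):
        """Clones planted with s = +1 / -1 correlate with the driving index
        with the planted sign after full ring processing, in >= 90% of clones."""
        clim = simulate_daily_climate(range(2004, 2015), seed=13)
        n_half = 20
        sens = pd.Series([1.0] * n_half + [-1.0] * n_half,
                         index=[f"cl{i:04d}" for i in range(2 * n_half)])
        truth = TruthModel(qtl_effects=[], noise_sd=0.05, link_scale=1.0, ar1_phi=0.2)
        years = list(range(2005, 2015))
        rings = simulate_ring_widths(sens, clim, truth, years, n_replicates=1, seed=21)
        chronologies = process_ring_table(rings)
        from dendroqtl.simulate import _march_index_z
        z = _march_index_z(clim, truth, years)
        correct = 0
        for ch in chronologies:
            r = np.corrcoef(ch.values, z.loc[ch.years].to_numpy())[0, 1]
            correct += (r > 0) == (sens[ch.clone_id] > 0)
        assert correct >= 0.9 * len(chronologies)


class TestDataset:
    def test_truth_bookkeeping_and_shapes(self):
        cfg = DatasetConfig(n_clones=25, n_replicates=2, n_groups=3,
                            group_length_cm=30.0, spacing_cm=3.0,
                            ring_years=(2008, 2015),
                            pve_minor=(0.03, 0.02))
        data = simulate_dataset(cfg, seed=11)
        assert data["sensitivities"].size == 25
        assert len(data["truth_assignments"]) == 3     # major + two minors
        assert data["rings"]["tree_id"].nunique() == 50
        n_days = data["climate"]["date"].nunique()
        assert n_days == len(data["climate"])
        # genotype table covers both maps
        assert set(data["genotypes"]["map_label"]) == {"P1", "P2"}

    def test_dataset_deterministic(self):
        cfg = DatasetConfig(n_clones=12, n_replicates=1, n_groups=2,
                            ring_years=(2010, 2014), pve_minor=(0.03,))
        a = simulate_dataset(cfg, seed=5)
        b = simulate_dataset(cfg, seed=5)
        pd.testing.assert_frame_equal(a["rings"], b["rings"])
        pd.testing.assert_frame_equal(a["genotypes"], b["genotypes"])
        pd.testing.assert_frame_equal(a["climate"], b["climate"])
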