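import json

import numpy as np
import pytest
from scipy.stats import spearmanr

from memscale import (
    SyntheticConfig,
    build_gabriel_graph,
    connected_components,
    gen_abundance,
    gen_coordinates,
    gen_environment,
    idw_interpolate,
    make_dataset,
    morans_i,
)


class TestGenCoordinates:
    def test_seed_reproducible(self):
        a = gen_coordinates(50, (100, 100), seed=3)
        b = gen_coordinates(50, (100, 100), seed=3)
        assert np.array_equal(a.xy, b.xy)

    def test_all_points_inside_extent(self):
        c = gen_coordinates(100, (30, 60), seed=1)
        assert np.all(c.xy[:, 0] >= 0) and np.all(c.xy[:, 0] <= 30)
        assert np.all(c.xy[:, 1] >= 0) and np.all(c.xy[:, 1] <= 60)

    @pytest.mark.parametrize("seed", range(20))
    def test_default_density_gives_connected_gabriel_graph(self, seed):
        c = gen_coordinates(329, (300, 350), seed=seed)
        W = build_gabriel_graph(c)
        assert connected_components(W).max() == 0

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            gen_coordinates(20, (0, 100), seed=0)


class TestIdw:
    def test_target_at_station_exact(self):
        stations = [(0, 0), (10, 0)]
        vals = [5.0, 9.0]
        out = idw_interpolate(stations, vals, [(10, 0)], power=2)
        assert out[0] == 9.0

    def test_equidistant_two_stations_average(self):
        out = idw_interpolate([(0, 0), (10, 0)], [20.0, 24.0], [(5, 0)], power=2)
        assert out[0] == pytest.approx(22.0)

    def test_high_power_approaches_nearest_neighbor(self):
        # spread design: each target is unambiguously closest to one
        # station, so a high power should hand over that station's value
        r = np.random.default_rng(0)
        gx, gy = np.meshgrid(np.arange(5) * 25.0, np.arange(4) * 25.0)
        stations = np.column_stack([gx.ravel(), gy.ravel()])
        vals = r.uniform(10, 30, len(stations))
        targets = stations + r.uniform(-2, 2, stations.shape)
        out = idw_interpolate(stations, vals, targets, power=8)
        assert np.max(np.abs(out - vals)) < 0.01

    def test_no_stations_rejected(self):
        with pytest.raises(ValueError, match="station"):
            idw_interpolate(np.zeros((0, 2)), [], [(0, 0)])


class TestGenEnvironment:
    def test_zero_gradient_zero_noise_constant_temperature(self):
        cfg = SyntheticConfig(n_sites=40, seed=0, temp_noise_sd=0.0,
                              temp_slope={m: 0.0 for m in ("mayT", "junT", "julT", "augT")},
                              cutoff_junT=20.5)
        coords = gen_coordinates(cfg.n_sites, cfg.extent, rng=cfg.rng(0))
        env = gen_environment(coords, cfg)
        for month in ("mayT", "junT", "julT", "augT"):
            assert np.allclose(env[month], env[month].iloc[0], atol=1e-9)

    def test_distance_zero_at_source(self):
        cfg = SyntheticConfig(n_sites=40, seed=1)
        coords = gen_coordinates(cfg.n_sites, cfg.extent, rng=cfg.rng(0))
        xy = coords.xy.copy()
        xy[0] = cfg.source
        from memscale import Coordinates
        env = gen_environment(Coordinates(xy=xy), cfg)
        assert env["dist_km"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_june_temperature_spatially_structured(self, seed):
        cfg = SyntheticConfig(n_sites=100, seed=seed)
        coords = gen_coordinates(cfg.n_sites, cfg.extent, rng=cfg.rng(0))
        env = gen_environment(coords, cfg, rng=cfg.rng(1))
        W = build_gabriel_graph(coords)
        assert morans_i(env["junT"].to_numpy(), W) > 0

    def test_landuse_proportions_valid_composition(self):
        cfg = SyntheticConfig(n_sites=80, seed=5)
        coords = gen_coordinates(cfg.n_sites, cfg.extent, rng=cfg.rng(0))
        env = gen_environment(coords, cfg, rng=cfg.rng(1))
        from memscale.synthetic import BUFFER_SCALES, LANDUSE_CLASSES
        for scale in BUFFER_SCALES:
            cols = [f"{c}{scale}" for c in LANDUSE_CLASSES]
            block = env[cols].to_numpy()
            assert np.all(block >= 0) and np.all(block <= 1)
            assert np.all(block.sum(axis=1) <= 1 + 1e-12)


class TestGenAbundance:
    def test_invasive_zero_above_cutoff(self):
        for seed in range(5):
            cfg = SyntheticConfig(seed=seed)
            table, _ = make_dataset(cfg)
            jun = table.env["junT"].to_numpy()
            inv = table.counts["hhalys"].to_numpy()
            assert np.any(jun > cfg.cutoff_junT)  # the cutoff actually bites
            assert np.all(inv[jun > cfg.cutoff_junT] == 0)

    def test_negative_rank_correlation_below_cutoff(self):
        for seed in range(5):
            cfg = SyntheticConfig(seed=seed)
            table, _ = make_dataset(cfg)
            jun = table.env["junT"].to_numpy()
            inv = table.counts["hhalys"].to_numpy()
            below = jun <= cfg.cutoff_junT
            rho, _ = spearmanr(jun[below], inv[below])
            assert rho < 0

    def test_null_coefficients_make_species_exchangeable(self):
        from scipy.stats import ks_2samp
        species = {
            k: {"intercept": np.log(5.0), "coefficients": {}, "invasive": False}
            for k in ("a", "b", "c")
        }
        cfg = SyntheticConfig(n_sites=300, seed=9, species=species)
        coords = gen_coordinates(cfg.n_sites, cfg.extent, rng=cfg.rng(0))
        env = gen_environment(coords, cfg, rng=cfg.rng(1))
        Y, _ = gen_abundance(env, coords, cfg, rng=cfg.rng(2))
        _, p = ks_2samp(Y.counts[:, 0], Y.counts[:, 1])
        assert p > 0.01

    def test_loglinear_fit_recovers_temperature_coefficient(self):
        # independent GLM fit with the generating family closes the loop
        import statsmodels.api as sm
        hits_sign, within = 0, 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SyntheticConfig(seed=seed)
            table, truth = make_dataset(cfg)
            jun = table.env["junT"].to_numpy()
            below = jun <= cfg.cutoff_junT
            covs = ["junT", "dist_km", "developopen250", "forestdeci250"]
            X = sm.add_constant(table.env.loc[below, covs].to_numpy())
            y = table.counts["hhalys"].to_numpy()[below]
            fit = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=1 / cfg.dispersion)).fit()
            beta = fit.params[1]
            true_beta = truth.species["hhalys"]["coefficients"]["junT"]
            hits_sign += np.sign(beta) == np.sign(true_beta)
            within += abs(beta - true_beta) <= 0.25 * abs(true_beta)
        assert hits_sign == n_seeds
        assert within >= 0.8 * n_seeds


class TestMakeDataset:
    def test_default_config_shape(self):
        table, truth = make_dataset(SyntheticConfig(seed=2))
        assert table.n == 329
        assert table.counts.shape[1] == 3
        assert truth.true_scale == "very_broad"

    def test_same_seed_byte_identical_csv(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        make_dataset(SyntheticConfig(seed=4), out_csv=p1)
        make_dataset(SyntheticConfig(seed=4), out_csv=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_truth_bundle_serialized(self, tmp_path):
        p = tmp_path / "truth.json"
        _, truth = make_dataset(SyntheticConfig(n_sites=30, seed=6), out_truth=p)
        loaded = json.loads(p.read_text())
        assert loaded["cutoff_junT"] == truth.cutoff_junT
        assert loaded["seed"] == 6
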