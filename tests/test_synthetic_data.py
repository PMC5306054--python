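import numpy as np
import pandas as pd
import pytest

from asmpipe.data_io import read_dataset
from asmpipe.synthetic_data import (
    SynthConfig,
    generate_dataset,
    generate_environment,
    generate_pool,
    generate_transect_community,
    read_truth,
    simulate_to_dir,
)


class TestGeneratePool:
    def test_identity_correlation_gives_small_sample_r(self):
        cfg = SynthConfig(n_species_pool=500, n_traits=4, trait_correlation=0.0)
        pool = generate_pool(cfg, np.random.default_rng(0))
        corr = pool.values.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() < 0.15

    def test_single_trait(self):
        cfg = SynthConfig(n_traits=1)
        pool = generate_pool(cfg, np.random.default_rng(0))
        assert pool.values.shape == (49, 1)
        assert pool.values.iloc[:, 0].std(ddof=1) == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        cfg = SynthConfig()
        a = generate_pool(cfg, np.random.default_rng(5)).values
        b = generate_pool(cfg, np.random.default_rng(5)).values
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_correlation_rejected(self):
        cfg = SynthConfig(n_traits=3, trait_correlation=-0.9)
        with pytest.raises(ValueError, match="positive definite"):
            generate_pool(cfg, np.random.default_rng(0))


class TestGenerateEnvironment:
    def test_cluster_structure(self):
        cfg = SynthConfig()
        env = generate_environment(cfg, np.random.default_rng(0))
        assert len(env) == 36
        assert env["cluster_id"].nunique() == 12
        assert (env["cluster_id"].value_counts() == 3).all()

    def test_complexity_floor(self):
        env = generate_environment(SynthConfig(), np.random.default_rng(1))
        assert (env["complexity"] >= 1.0).all()
        assert env["sand"].between(0, 1).all()

    def test_zero_cluster_variance_flattens_depth(self):
        import statsmodels.api as sm

        cfg = SynthConfig(depth_cluster_sd=0.0, depth_within_sd=0.5)
        env = generate_environment(cfg, np.random.default_rng(2))
        res = sm.MixedLM(
            env["depth"].to_numpy(),
            np.ones((len(env), 1)),
            groups=env["cluster_id"].to_numpy(),
        ).fit(reml=True)
        total = np.asarray(res.cov_re)[0, 0] + res.scale
        assert np.asarray(res.cov_re)[0, 0] / total < 0.25


class TestGenerateTransectCommunity:
    def test_boundary_single_step(self, rng):
        cfg = SynthConfig(n_species_pool=10, n_traits=2, richness_range=(5, 9))
        pool = generate_pool(cfg, rng)
        abund, comp = generate_transect_community(
            pool,
            commonness=np.ones(10),
            sand=0.5,
            true_mix=(0, 100, 0),
            richness=9,
            optimum=np.zeros(2),
            rng=rng,
            config=cfg,
        )
        assert comp.as_tuple() == (0, 1, 0)
        assert len(abund) == 9

    def test_stochastic_inclusion_tracks_commonness(self, rng):
        from scipy.stats import spearmanr

        cfg = SynthConfig(n_species_pool=25, n_traits=3, richness_range=(10, 15))
        pool = generate_pool(cfg, rng)
        commonness = np.exp(rng.standard_normal(25))
        freq = pd.Series(0.0, index=pool.species)
        for _ in range(200):
            abund, _ = generate_transect_community(
                pool, commonness, 0.5, (100, 0, 0), 12, np.zeros(3), rng, cfg
            )
            freq[abund.index] += 1
        rho, p = spearmanr(commonness, freq.to_numpy())
        assert rho > 0 and p < 0.01

    def test_filtering_concentrates_near_optimum(self, rng):
        cfg = SynthConfig(n_species_pool=25, n_traits=3, richness_range=(10, 15))
        pool = generate_pool(cfg, rng)
        commonness = np.ones(25)
        optimum = np.zeros(3)
        d = np.linalg.norm(pool.matrix - optimum, axis=1)
        ids = list(pool.species)

        def mean_dist(mix, n=100):
            out = []
            for _ in range(n):
                abund, _ = generate_transect_community(
                    pool, commonness, 0.5, mix, 10, optimum, rng, cfg
                )
                rows = [ids.index(s) for s in abund.index]
                out.append(d[rows].mean())
            return np.mean(out)

        assert mean_dist((0, 100, 0)) < mean_dist((100, 0, 0))


class TestGenerateDataset:
    def test_structure_and_invariants(self, small_synthetic):
        dataset, truth, cfg = small_synthetic
        assert len(dataset.transects) == cfg.n_transects
        assert dataset.pool.size <= cfg.n_species_pool
        assert (dataset.pool.occupancy >= 1).all()
        env = dataset.environment()
        assert env["cluster_id"].nunique() == cfg.n_clusters

    def test_mean_richness_near_target(self):
        mids = []
        for seed in range(1, 11):
            cfg = SynthConfig(n_transects=12, n_clusters=4, seed=seed)
            ds, _ = generate_dataset(cfg)
            mids.append(np.mean([t.richness for t in ds.transects]))
        target = np.mean(SynthConfig().richness_range)
        assert abs(np.mean(mids) - target) / target < 0.15

    def test_truth_round_trips(self, tmp_path):
        cfg = SynthConfig(
            n_transects=6, n_clusters=2, n_species_pool=20,
            richness_range=(8, 14), seed=3,
        )
        paths = simulate_to_dir(cfg, tmp_path)
        truth = read_truth(paths["truth"])
        assert truth["seed"] == 3
        assert len(truth["transects"]) == 6
        ds = read_dataset(paths["abundance"], paths["traits"], paths["environment"])
        assert len(ds.transects) == 6

    def test_mean_abundance_tracks_sand(self, small_synthetic):
        dataset, _, cfg = small_synthetic
        totals = np.array([t.total_abundance for t in dataset.transects])
        sand = np.array([t.sand for t in dataset.transects])
        expected = cfg.abundance_base * (1 - sand)
        assert np.corrcoef(totals, expected)[0, 1] > 0.99


class TestOptimumLink:
    def test_zero_slope_gives_null_coefficients(self):
        """With an environment-independent optimum the trait-environment
        coefficients average to ~0 across datasets."""
        from asmpipe.trait_env_stats import ctm_table, refit_formula

        coefs = []
        for seed in range(30):
            cfg = SynthConfig(
                n_species_pool=30, n_transects=12, n_clusters=4,
                richness_range=(12, 18), depth_slope=0.0,
                true_mix=(70.0, 30.0, 0.0), seed=300 + seed,
            )
            ds, _ = generate_dataset(cfg)
            env = ds.environment()
            res = refit_formula(
                ctm_table(ds).iloc[:, 0], env[["depth"]], env["cluster_id"],
                predictors=["depth"],
            )
            coefs.append(res.coefficients["depth"])
        assert abs(np.mean(coefs)) < 0.1

    def test_depth_slope_detected_with_filtering(self):
        from asmpipe.trait_env_stats import ctm_table, refit_formula

        hits = 0
        rounds = 25
        for seed in range(rounds):
            cfg = SynthConfig(
                n_species_pool=30, n_transects=36, n_clusters=12,
                richness_range=(12, 18), depth_slope=1.0,
                true_mix=(60.0, 30.0, 10.0), seed=600 + seed,
            )
            ds, _ = generate_dataset(cfg)
            env = ds.environment()
            res = refit_formula(
                ctm_table(ds).iloc[:, 0], env[["depth"]], env["cluster_id"],
                predictors=["depth"],
            )
            hits += (res.coefficients["depth"] > 0) and (res.pvalues["depth"] < 0.05)
        assert hits >= 0.8 * rounds
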