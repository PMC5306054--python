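import itertools

import numpy as np
import pandas as pd
import pytest

from asmpipe.community_dissimilarity import (
    abundance_richness_regressions,
    bray_curtis,
    bray_curtis_matrix,
    env_distance_matrix,
    mantel,
    slope_contrast,
)


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3), (1, 2, 3), 0.0),
            ((1, 0, 2), (0, 3, 0), 1.0),  # disjoint supports
            ((1, 0, 2), (1, 1, 0), 0.6),  # |0|+|1|+|2| over 5
        ],
    )
    def test_hand_computed_values(self, x, y, expected):
        assert bray_curtis(x, y) == pytest.approx(expected)

    def test_both_empty_errors(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    def test_matrix_matches_pairwise_calls(self, toy_dataset):
        mat = toy_dataset.abundance_matrix()
        bc = bray_curtis_matrix(mat)
        for i, j in itertools.combinations(range(len(mat)), 2):
            assert bc.iloc[i, j] == pytest.approx(
                bray_curtis(mat.iloc[i], mat.iloc[j])
            )
        assert np.allclose(bc, bc.T) and np.all(np.diag(bc) == 0)

    def test_well_defined_on_frequencies(self, rng):
        freq = rng.random((6, 10))
        bc = bray_curtis_matrix(pd.DataFrame(freq))
        assert ((bc.to_numpy() >= 0) & (bc.to_numpy() <= 1)).all()


class TestEnvDistance:
    def test_hand_computed_depth_only(self):
        # constant sand/complexity are dropped; depth diffs 5,10,5 over max 10
        env = pd.DataFrame(
            {
                "depth": [0.0, 5.0, 10.0],
                "sand": [0.3, 0.3, 0.3],
                "complexity": [1.2, 1.2, 1.2],
            },
            index=["t1", "t2", "t3"],
        )
        d = env_distance_matrix(env)
        assert d.loc["t1", "t2"] == pytest.approx(0.5)
        assert d.loc["t1", "t3"] == pytest.approx(1.0)
        assert d.loc["t2", "t3"] == pytest.approx(0.5)

    def test_identical_environments_zero(self):
        env = pd.DataFrame(
            {"depth": [1.0, 1.0], "sand": [0.1, 0.1], "complexity": [1.0, 1.0]}
        )
        with pytest.raises(ValueError):
            env_distance_matrix(env)

    def test_max_pair_attains_sqrt3(self, toy_tables):
        _, _, env = toy_tables
        d = env_distance_matrix(env)
        # t1 and t3 attain the max difference on all three variables
        assert d.loc["t1", "t3"] == pytest.approx(np.sqrt(3.0))
        assert d.to_numpy().max() <= np.sqrt(3.0) + 1e-12


class TestMantel:
    def _random_distance(self, rng, n):
        pts = rng.random((n, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        return d

    def test_self_correlation_is_one(self, rng):
        a = self._random_distance(rng, 6)
        res = mantel(a, a, n_perm=99, rng=rng)
        assert res.r == pytest.approx(1.0)

    def test_exhaustive_enumeration_at_n4(self, rng):
        """p at n=4 matches brute-force enumeration of all 24 relabelings."""
        a = self._random_distance(rng, 4)
        b = self._random_distance(rng, 4)
        res = mantel(a, b, n_perm=100_000, rng=rng)
        assert res.exact and res.n_permutations == 24

        iu = np.triu_indices(4, 1)
        r_obs = np.corrcoef(a[iu], b[iu])[0, 1]
        count = 0
        for perm in itertools.permutations(range(4)):
            bp = b[np.ix_(perm, perm)]
            if np.corrcoef(a[iu], bp[iu])[0, 1] >= r_obs - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / 24)

    def test_matches_reference_implementation(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel

        a = self._random_distance(rng, 12)
        b = 0.5 * a + 0.5 * self._random_distance(rng, 12)
        res = mantel(a, b, n_perm=999, rng=rng)
        r_ref, p_ref, _ = skbio_mantel(
            DistanceMatrix(a), DistanceMatrix(b), permutations=999,
            alternative="greater",
        )
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, abs=0.05)

    def test_joint_relabeling_invariance(self, rng):
        a = self._random_distance(rng, 8)
        b = self._random_distance(rng, 8)
        perm = rng.permutation(8)
        r1 = mantel(a, b, n_perm=49, rng=np.random.default_rng(0)).r
        r2 = mantel(
            a[np.ix_(perm, perm)], b[np.ix_(perm, perm)],
            n_perm=49, rng=np.random.default_rng(0),
        ).r
        assert r1 == pytest.approx(r2)

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            mantel(np.zeros((2, 2)), np.zeros((2, 2)))


class TestSlopeContrast:
    def _sym(self, vals, n):
        m = np.zeros((n, n))
        m[np.triu_indices(n, 1)] = vals
        return m + m.T

    def test_identical_groups_no_interaction(self, rng):
        n = 8
        npairs = n * (n - 1) // 2
        env = self._sym(rng.random(npairs), n)
        bc = self._sym(rng.random(npairs), n)
        out = slope_contrast(bc, bc, env)
        assert out["interaction_coef"] == pytest.approx(0.0, abs=1e-10)
        assert out["slope_observed"] == pytest.approx(out["slope_null"])

    def test_group_slopes_equal_per_group_ols(self, rng):
        from scipy.stats import linregress

        n = 10
        npairs = n * (n - 1) // 2
        env = self._sym(rng.random(npairs), n)
        iu = np.triu_indices(n, 1)
        bc1 = self._sym(0.5 * env[iu] + 0.05 * rng.standard_normal(npairs), n)
        bc2 = self._sym(0.1 * env[iu] + 0.05 * rng.standard_normal(npairs), n)
        out = slope_contrast(bc1, bc2, env)
        assert out["slope_observed"] == pytest.approx(
            linregress(env[iu], bc1[iu]).slope
        )
        assert out["slope_null"] == pytest.approx(
            linregress(env[iu], bc2[iu]).slope
        )

    def test_detects_slope_difference(self, rng):
        # observed slope 0.5 vs null slope 0, n_pairs ~ 630, noise sd 0.1
        n = 36
        npairs = n * (n - 1) // 2
        env = self._sym(rng.random(npairs), n)
        iu = np.triu_indices(n, 1)
        hits = 0
        rounds = 20
        for _ in range(rounds):
            bc_obs = self._sym(0.5 * env[iu] + 0.1 * rng.standard_normal(npairs), n)
            bc_null = self._sym(0.3 + 0.1 * rng.standard_normal(npairs), n)
            out = slope_contrast(bc_obs, bc_null, env)
            hits += out["interaction_p"] < 0.001
        assert hits >= 0.95 * rounds


class TestAbundanceRichness:
    def test_counts_match_bruteforce(self, toy_dataset):
        mat = toy_dataset.abundance_matrix()
        assert (mat.sum(axis=1) > 0).all()
        out = abundance_richness_regressions(toy_dataset)
        assert set(out["response"]) == {"abundance", "richness"}

    def test_sand_abundance_gradient_detected(self):
        """Sandier transects hold fewer individuals by construction."""
        from asmpipe.synthetic_data import SynthConfig, generate_dataset

        hits = 0
        rounds = 20
        for seed in range(rounds):
            cfg = SynthConfig(
                n_species_pool=30, n_transects=36, n_clusters=12,
                richness_range=(12, 18), seed=100 + seed,
            )
            ds, _ = generate_dataset(cfg)
            out = abundance_richness_regressions(ds)
            row = out[(out.response == "abundance") & (out.variable == "sand")]
            hits += (row.coefficient.iloc[0] < 0) and (row.p.iloc[0] < 0.05)
        assert hits >= 0.9 * rounds
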