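import numpy as np
import pandas as pd
import pytest

from asmpipe.fd_metrics import SummaryEngine
from asmpipe.stepcam_forward import (
    Assembler,
    StepComposition,
    assemble,
    remove_filter,
    remove_limiting,
    remove_random,
)


@pytest.fixture
def line_traits():
    return pd.DataFrame(
        {"x": [0.0, 1.0, 10.0]}, index=pd.Index(["a", "b", "c"], name="species_id")
    )


class TestStepComposition:
    def test_percentages_sum_to_100(self):
        comp = StepComposition(7, 1, 2)
        assert sum(comp.percentages) == pytest.approx(100.0)

    def test_largest_remainder_sums_exactly(self):
        for total in range(1, 40):
            comp = StepComposition.from_fractions((70, 10, 20), total)
            assert comp.total == total

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            StepComposition(-1, 0, 1)


class TestRemoveRandom:
    def test_inverse_occupancy_probabilities(self, rng):
        # f = (1, 9): removal probabilities (0.9, 0.1)
        occupancy = {"a": 1, "b": 9}
        removed = [
            remove_random(["a", "b"], occupancy, rng) for _ in range(10_000)
        ]
        frac_a = np.mean([r == "a" for r in removed])
        assert frac_a == pytest.approx(0.9, abs=0.01)

    def test_equal_occupancy_uniform(self, rng):
        occupancy = {"a": 3, "b": 3, "c": 3}
        removed = [remove_random(list("abc"), occupancy, rng) for _ in range(6000)]
        counts = pd.Series(removed).value_counts(normalize=True)
        assert np.allclose(counts, 1 / 3, atol=0.03)


class TestRemoveFilter:
    def test_farthest_from_optimum_removed(self):
        traits = pd.DataFrame(
            {"x": [0.5, 2.0, 1.1]}, index=pd.Index(["a", "b", "c"])
        )
        assert remove_filter(["a", "b", "c"], traits, optimum=[0.0]) == "b"

    def test_tie_breaks_to_smaller_id(self):
        traits = pd.DataFrame({"x": [1.0, -1.0]}, index=pd.Index(["a", "b"]))
        assert remove_filter(["a", "b"], traits, optimum=[0.0]) == "a"

    def test_repeated_filtering_contracts_distances(self, rng):
        traits = pd.DataFrame(
            rng.standard_normal((12, 3)),
            index=pd.Index([f"s{i:02d}" for i in range(12)]),
        )
        optimum = np.zeros(3)
        current = list(traits.index)
        prev = np.inf
        while len(current) > 2:
            current.remove(remove_filter(current, traits, optimum))
            mean_d = np.linalg.norm(
                traits.loc[current].to_numpy() - optimum, axis=1
            ).mean()
            assert mean_d <= prev + 1e-12
            prev = mean_d


class TestRemoveLimiting:
    def test_hand_worked_collinear_case(self, line_traits):
        # closest pair (a, b); second-nearest: a->c is 10, b->c is 9
        assert remove_limiting(["a", "b", "c"], line_traits) == "b"

    def test_exact_tie_removes_smallest_id(self):
        # unit square: closest pair (a, b) found first; both members'
        # second-nearest neighbours are exactly 1 away -> smaller id goes
        traits = pd.DataFrame(
            {"x": [0.0, 1.0, 0.0, 1.0], "y": [0.0, 0.0, 1.0, 1.0]},
            index=pd.Index(["a", "b", "c", "d"]),
        )
        assert remove_limiting(["a", "b", "c", "d"], traits) == "a"

    def test_min_pairwise_distance_never_decreases(self, rng):
        traits = pd.DataFrame(
            rng.standard_normal((10, 2)),
            index=pd.Index([f"s{i}" for i in range(10)]),
        )
        current = list(traits.index)
        prev = 0.0
        while len(current) > 3:
            current.remove(remove_limiting(current, traits))
            pts = traits.loc[current].to_numpy()
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            assert d.min() >= prev - 1e-12
            prev = d.min()


class TestAssemble:
    def test_empty_composition_returns_pool(self, small_synthetic, rng):
        dataset, _, _ = small_synthetic
        out = assemble(dataset.pool, StepComposition(0, 0, 0), rng=rng)
        assert sorted(out) == list(dataset.pool.species)

    def test_richness_exact_for_any_step_count(self, small_synthetic, rng):
        dataset, _, _ = small_synthetic
        n = dataset.pool.size
        for k in range(1, n - 1, 3):
            out = assemble(dataset.pool, StepComposition(k, 0, 0), rng=rng)
            assert len(out) == n - k
            assert set(out) <= set(dataset.pool.species)

    def test_pure_filtering_is_deterministic(self, small_synthetic, rng):
        dataset, _, _ = small_synthetic
        optimum = np.zeros(dataset.pool.matrix.shape[1])
        comp = StepComposition(0, 10, 0)
        a = assemble(dataset.pool, comp, optimum=optimum, rng=np.random.default_rng(1))
        b = assemble(dataset.pool, comp, optimum=optimum, rng=np.random.default_rng(2))
        assert a == b

    def test_kernel_matches_single_step_rules(self, small_synthetic):
        """The compiled removal loop agrees with the reference single-step
        operators for the two deterministic operators, applied in fixed
        order."""
        dataset, _, _ = small_synthetic
        traits = dataset.pool.traits.values
        optimum = traits.mean().to_numpy()
        comp = StepComposition(0, 4, 3)
        fast = assemble(
            dataset.pool,
            comp,
            optimum=optimum,
            rng=np.random.default_rng(0),
            order_policy="fixed",
        )
        current = list(dataset.pool.species)
        for _ in range(4):
            current.remove(remove_filter(current, traits, optimum))
        for _ in range(3):
            current.remove(remove_limiting(current, traits))
        assert fast == sorted(current)

    def test_occupancy_weighted_inclusion(self, small_synthetic, rng):
        """Widespread species survive stochastic removal more often."""
        from scipy.stats import spearmanr

        dataset, _, _ = small_synthetic
        pool = dataset.pool
        total = pool.size - 15
        freq = np.zeros(pool.size)
        asm = Assembler(pool.matrix, pool.occupancy_array)
        for _ in range(200):
            freq[asm.run(StepComposition(total, 0, 0), rng)] += 1
        rho, p = spearmanr(pool.occupancy_array, freq)
        assert rho > 0 and p < 0.01

    def test_filtering_beats_random_at_reaching_optimum(self, small_synthetic, rng):
        dataset, _, _ = small_synthetic
        pool = dataset.pool
        optimum = pool.matrix[dataset.community_indices("t01")].mean(axis=0)
        asm = Assembler(pool.matrix, pool.occupancy_array, optimum=optimum)
        total = pool.size - 12
        d_opt = np.linalg.norm(pool.matrix - optimum, axis=1)

        def mean_dist(comp):
            vals = [
                d_opt[asm.run(comp, rng)].mean()
                for _ in range(100)
            ]
            return np.mean(vals)

        assert mean_dist(StepComposition(0, total, 0)) < mean_dist(
            StepComposition(total, 0, 0)
        )


class TestEnsembleContrasts:
    """Distributional signatures of the three operators (the logic behind
    contrasting observed communities with process-specific ensembles)."""

    def test_process_signatures(self, small_synthetic, rng):
        from scipy.stats import mannwhitneyu

        dataset, _, _ = small_synthetic
        pool = dataset.pool
        engine = SummaryEngine(pool.matrix, m=3)
        optimum = pool.matrix[dataset.community_indices("t01")].mean(axis=0)
        asm = Assembler(pool.matrix, pool.occupancy_array, optimum=optimum)
        total = pool.size - 12
        d_opt = np.linalg.norm(pool.matrix - optimum, axis=1)
        dist = asm.dist

        def batch(comp, n=100):
            fric, dopt, mind = [], [], []
            for _ in range(n):
                idx = asm.run(comp, rng)
                fric.append(engine.stats_vector(idx)[0])
                dopt.append(d_opt[idx].mean())
                sub = dist[np.ix_(idx, idx)]
                mind.append(sub.min())
            return np.array(fric), np.array(dopt), np.array(mind)

        f_rand, d_rand, m_rand = batch(StepComposition(total, 0, 0))
        f_filt, d_filt, _ = batch(StepComposition(0, total, 0))
        _, _, m_lim = batch(StepComposition(0, 0, total))

        # filtering contracts the hull and the spread around the optimum
        assert mannwhitneyu(f_filt, f_rand, alternative="less").pvalue < 0.01
        assert mannwhitneyu(d_filt, d_rand, alternative="less").pvalue < 0.01
        # limiting similarity spreads species out
        assert mannwhitneyu(m_lim, m_rand, alternative="greater").pvalue < 0.01
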