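import itertools
import math

import numpy as np
import pytest
from scipy import stats

import netchrono as nc
from netchrono.theory import CorruptionSpec, corrupt_and_rank


class TestOverallError:
    def test_identity_sequence_has_zero_error(self):
        rep = nc.overall_error([1, 2, 3, 4], [1, 2, 3, 4])
        assert rep.overall_error == 0.0
        assert rep.kendall_tau == 1.0
        assert rep.spearman_rho == 1.0

    def test_reversed_three_elements(self):
        # D = (-2, 0, 2); error = sqrt(8/27)
        rep = nc.overall_error([1, 2, 3], [3, 2, 1])
        assert rep.overall_error == pytest.approx(math.sqrt(8 / 27))
        assert rep.kendall_tau == -1.0
        assert list(rep.displacements) == [-2, 0, 2]

    def test_matches_independent_formula(self):
        # independently coded oracle: plain python loop over the definition
        rng = np.random.default_rng(3)
        truth = np.arange(1, 101)
        restored = rng.permutation(100) + 1
        rep = nc.overall_error(truth, restored)
        e = 100
        acc = 0.0
        for a, b in zip(truth, restored):
            acc += ((a - b) / e) ** 2
        assert rep.overall_error == pytest.approx(math.sqrt(acc / e), abs=1e-12)

    def test_rejects_non_permutations(self):
        with pytest.raises(ValueError):
            nc.overall_error([1, 2, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            nc.overall_error([1, 2], [1, 2, 3])

    def test_displacements_sum_to_zero(self):
        rng = np.random.default_rng(0)
        restored = rng.permutation(50) + 1
        rep = nc.overall_error(np.arange(1, 51), restored)
        assert rep.displacements.sum() == 0


class TestTheoreticalError:
    def test_formula_value(self):
        # sqrt(0.75*0.25)/0.5/100
        assert nc.theoretical_error(0.75, 10_000) == pytest.approx(
            math.sqrt(0.1875) / 0.5 / 100)

    def test_perfect_accuracy_limit(self):
        assert nc.theoretical_error(1.0, 100) == 0.0

    def test_singular_point_rejected(self):
        with pytest.raises(ValueError):
            nc.theoretical_error(0.5, 1000)
        with pytest.raises(ValueError):
            nc.theoretical_error(0.5 + 1 / (4 * math.sqrt(100)), 100)

    def test_decreasing_in_x_and_E(self):
        assert nc.theoretical_error(0.9, 1000) < nc.theoretical_error(0.7, 1000)
        assert nc.theoretical_error(0.8, 2000) < nc.theoretical_error(0.8, 500)


def _brute_force_borda(decisions, n):
    """Independent oracle: count wins with plain loops, rank by (count, idx)."""
    wins = [0] * n
    for (i, j), i_newer in decisions.items():
        wins[i if i_newer else j] += 1
    order = sorted(range(n), key=lambda k: (wins[k], k))
    pos = [0] * n
    for rank, k in enumerate(order, start=1):
        pos[k] = rank
    return pos, wins


class TestBordaAggregation:
    def test_all_correct_counts(self):
        decisions = {(0, 1): False, (0, 2): False, (1, 2): False}
        u = nc.borda_counts(decisions, 3)
        assert list(u) == [0, 1, 2]

    def test_single_flip_produces_full_tie(self):
        decisions = {(0, 1): False, (0, 2): True, (1, 2): False}
        u = nc.borda_counts(decisions, 3)
        assert list(u) == [1, 1, 1]
        seq = nc.restore_sequence(u, [(0, 1), (1, 2), (2, 3)])
        assert list(seq.positions) == [1, 2, 3]  # stable tie-break

    def test_missing_pair_rejected(self):
        with pytest.raises(ValueError):
            nc.borda_counts({(0, 1): True}, 3)

    def test_counts_sum_to_pair_total(self):
        rng = np.random.default_rng(1)
        n = 9
        decisions = {(i, j): bool(rng.random() < 0.5)
                     for i in range(n) for j in range(i + 1, n)}
        u = nc.borda_counts(decisions, n)
        assert u.sum() == n * (n - 1) // 2

    def test_restore_matches_sort_oracle(self):
        rng = np.random.default_rng(5)
        u = rng.integers(0, 10, size=50)
        seq = nc.restore_sequence(u, [(i, i + 1) for i in range(50)])
        oracle = sorted(range(50), key=lambda k: (u[k], k))
        pos = [0] * 50
        for rank, k in enumerate(oracle, start=1):
            pos[k] = rank
        assert list(seq.positions) == pos

    def test_matches_exhaustive_oracle_small_E(self):
        """Restored sequences equal brute-force rank aggregation, E <= 8."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(3, 9))
            decisions = {(i, j): bool(rng.random() < 0.5)
                         for i in range(n) for j in range(i + 1, n)}
            u = nc.borda_counts(decisions, n)
            seq = nc.restore_sequence(u, [(i, i + 1) for i in range(n)])
            pos, wins = _brute_force_borda(decisions, n)
            assert list(seq.borda) == wins
            assert list(seq.positions) == pos


class TestCorruptedRanking:
    def test_no_corruption_restores_exactly(self):
        res = nc.simulate_corrupted_ranking(CorruptionSpec(E=50, x=1.0, R=3, seed=0))
        assert np.all(res["displacements"] == 0)

    def test_mean_error_tracks_theory(self):
        res = nc.simulate_corrupted_ranking(CorruptionSpec(E=1000, x=0.8, R=20, seed=2))
        theory = nc.theoretical_error(0.8, 1000)
        assert abs(res["errors"].mean() - theory) / theory < 0.15

    def test_displacement_distribution_symmetric(self):
        res = nc.simulate_corrupted_ranking(CorruptionSpec(E=500, x=0.8, R=20, seed=4))
        d = res["displacements"].ravel() / 500
        se = d.std(ddof=1) / math.sqrt(d.size)
        assert abs(d.mean()) < 3 * se

    def test_spread_decreases_with_x_and_E(self):
        s_x = {}
        for x in (0.7, 0.9):
            res = nc.simulate_corrupted_ranking(CorruptionSpec(E=400, x=x, R=10, seed=6))
            s_x[x] = (res["displacements"] / 400).std()
        assert s_x[0.9] < s_x[0.7]
        s_e = {}
        for e in (200, 2000):
            res = nc.simulate_corrupted_ranking(CorruptionSpec(E=e, x=0.8, R=5, seed=8))
            s_e[e] = (res["displacements"] / e).std()
        assert s_e[2000] < s_e[200]

    def test_metrics_co_monotone_across_accuracies(self):
        # overall error, Kendall tau and Spearman rho order a batch of
        # corrupted sequences identically
        errs, taus, rhos = [], [], []
        truth = np.arange(1, 301)
        for x in (0.6, 0.7, 0.8, 0.9, 0.99):
            spec = CorruptionSpec(E=300, x=x, R=1, seed=10)
            res = nc.simulate_corrupted_ranking(spec)
            rep = nc.overall_error(truth, res["restored_last"])
            errs.append(rep.overall_error)
            taus.append(rep.kendall_tau)
            rhos.append(rep.spearman_rho)
        assert stats.spearmanr(errs, taus).statistic == pytest.approx(-1.0)
        assert stats.spearmanr(taus, rhos).statistic == pytest.approx(1.0)

    def test_one_over_sqrt_E_scaling(self):
        errs = []
        es = [250, 500, 1000, 2000]
        for e in es:
            res = nc.simulate_corrupted_ranking(CorruptionSpec(E=e, x=0.8, R=10, seed=3))
            errs.append(res["errors"].mean())
        slope = np.polyfit(np.log(es), np.log(errs), 1)[0]
        assert -0.6 <= slope <= -0.4


class TestCoarseDisplacements:
    def test_every_edge_own_snapshot_reduces_to_plain(self):
        restored = np.array([2, 1, 3, 4, 5])
        disp = nc.displacement_vs_coarse_truth([1] * 5, restored, R=4, seed=0)
        expected = np.arange(1, 6) - restored
        assert np.all(disp == expected)

    def test_single_snapshot_gives_uniform_intermediate(self):
        # alpha* is a uniform random permutation; D/E approaches the
        # triangular distribution of a difference of two uniform ranks
        e = 200
        restored = np.arange(1, e + 1)
        disp = nc.displacement_vs_coarse_truth([e], restored, R=400, seed=1)
        d = disp.ravel() / e
        # triangular density on (-1, 1): variance = 1/6
        assert abs(d.var() - 1 / 6) < 0.02
        assert abs(d.mean()) < 0.01

    def test_sim_coarse_perfect_accuracy_no_displacement(self):
        disp = nc.displacement_sim_coarse([1] * 30, x=1.0, R=5, seed=2)
        assert np.all(disp == 0)

    def test_real_vs_sim_distributions_overlap(self):
        """Coarse-truth displacements of an actually-corrupted restoration
        match the pure-simulation counterpart at the same accuracy."""
        e, x = 300, 0.8
        sizes = [60] * 5
        rng = np.random.default_rng(9)
        spec = CorruptionSpec(E=e, x=x, R=1, seed=11)
        restored = nc.simulate_corrupted_ranking(spec)["restored_last"]
        real = nc.displacement_vs_coarse_truth(sizes, restored, R=100, seed=3).ravel() / e
        sim = nc.displacement_sim_coarse(sizes, x=x, R=100, seed=4).ravel() / e
        ks = stats.ks_2samp(real, sim).statistic
        assert ks < 0.1

    def test_spread_shrinks_with_x_in_coarse_sim(self):
        s = {}
        for x in (0.7, 0.9):
            d = nc.displacement_sim_coarse([50] * 6, x=x, R=20, seed=5)
            s[x] = (d / 300).std()
        assert s[0.9] < s[0.7]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nc.displacement_sim_coarse([10, 10], x=0.4, R=1, seed=0)
        with pytest.raises(ValueError):
            nc.displacement_vs_coarse_truth([], np.array([]), R=1, seed=0)


class TestMeanFieldProperties:
    def test_variance_law_interior(self):
        e, x, r = 300, 0.8, 200
        res = nc.simulate_corrupted_ranking(CorruptionSpec(E=e, x=x, R=r, seed=11))
        alpha_hat = np.arange(1, e + 1)[None, :] - res["displacements"]
        interior = slice(int(0.2 * e), int(0.8 * e))
        emp = (alpha_hat[:, interior] / e).var(axis=0, ddof=1).mean()
        pred = x * (1 - x) / (e * (2 * x - 1) ** 2)
        assert abs(emp - pred) / pred < 0.2

    def test_interior_positions_unbiased(self):
        e, x, r = 300, 0.8, 200
        res = nc.simulate_corrupted_ranking(CorruptionSpec(E=e, x=x, R=r, seed=11))
        alpha_hat = np.arange(1, e + 1)[None, :] - res["displacements"]
        mean = alpha_hat.mean(axis=0)
        se = alpha_hat.std(axis=0, ddof=1) / math.sqrt(r)
        interior = slice(int(0.2 * e), int(0.8 * e))
        ok = np.abs(mean - np.arange(1, e + 1))[interior] <= 3 * se[interior]
        assert ok.mean() >= 0.95
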