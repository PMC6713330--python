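"""Spiral-count series statistics against generator ground truth."""

import numpy as np
import pytest

from spiralchaos.markov import (
    SpiralMarkovEstimator,
    occupancy_distribution,
    single_spiral_dwell_statistics,
    termination_aligned_average,
    time_average_spiral_number,
    transition_probabilities,
)
from spiralchaos.synthetic import (
    markov_preset,
    stationary_distribution,
    synthetic_markov_series,
)


def series(counts, dt=0.01):
    c = np.asarray(counts, dtype=int)
    return (np.arange(len(c)) * dt, c)


class TestTimeAverage:
    def test_constant_series(self):
        s = series([7] * 1000)
        mean, sd = time_average_spiral_number([s], T_obs=5.0,
                                              settle_exclude=0.0)
        assert mean == 7.0 and sd == 0.0

    def test_alternating_series(self):
        s = series([4, 6] * 600)
        mean, sd = time_average_spiral_number([s], T_obs=10.0,
                                              settle_exclude=0.0)
        assert mean == pytest.approx(5.0)
        assert sd == pytest.approx(1.0)

    def test_insufficient_time_is_explicit(self):
        with pytest.raises(ValueError, match="insufficient"):
            time_average_spiral_number([series([3] * 50)], T_obs=80.0)

    def test_matches_stationary_mean_of_generating_chain(self):
        spec = markov_preset("tnnp_like")
        eps = synthetic_markov_series(spec, 100, start_state=20, seed=9,
                                      step_cap=3000)
        long_eps = [e for e in eps if len(e[1]) > 500]
        mean, sd = time_average_spiral_number(long_eps, T_obs=10.0,
                                              settle_exclude=0.5)
        pi = stationary_distribution(spec)
        target = np.sum(np.arange(1, len(pi) + 1) * pi)
        n_samples = int(10.0 / 0.01)
        se = sd / np.sqrt(n_samples / 20)   # crude autocorrelation discount
        assert abs(mean - target) < max(3 * se, 0.15 * target)


class TestOccupancy:
    def test_direct_frequencies(self):
        occ = occupancy_distribution([series([1, 1, 2, 2])])
        assert occ == {1: 0.5, 2: 0.5}

    def test_sums_to_one(self, rng):
        occ = occupancy_distribution([series(rng.integers(0, 9, 500))])
        assert sum(occ.values()) == pytest.approx(1.0)

    def test_matches_generator_stationary_law(self):
        # total-variation distance to the planted chain's stationary law;
        # the chain is mean-reverting (up-biased low, down-biased high) so
        # it mixes quickly and the empirical occupancy is comparable to
        # the stationary law within a few hundred steps
        from spiralchaos.synthetic import MarkovChainSpec
        spec = MarkovChainSpec(jumps={
            1: {-2: 0.0, -1: 0.0, 0: 0.3, 1: 0.5, 2: 0.2},
            4: {-2: 0.05, -1: 0.25, 0: 0.4, 1: 0.25, 2: 0.05},
            8: {-2: 0.2, -1: 0.5, 0: 0.25, 1: 0.05, 2: 0.0},
        }, n_max=25)
        eps = synthetic_markov_series(spec, 150, start_state=6, seed=21,
                                      step_cap=1000)
        counts = np.concatenate([c[c > 0] for _, c in eps])
        assert len(counts) > 1e5
        vals, freq = np.unique(counts, return_counts=True)
        emp = np.zeros(spec.n_max)
        emp[vals - 1] = freq / freq.sum()
        pi = stationary_distribution(spec)
        tv = 0.5 * np.abs(emp - pi).sum()
        assert tv < 0.05


class TestTransitions:
    def test_constant_series_is_pure_stay(self):
        stats = transition_probabilities([series([5] * 100)])
        assert stats.probs[5][0] == 1.0
        assert all(stats.probs[5][d] == 0.0 for d in (-2, -1, 1, 2))

    def test_hand_counted_series(self):
        # transitions of [3,4,4,2,3]: +1, 0, -2, +1
        stats = transition_probabilities([series([3, 4, 4, 2, 3])])
        pooled = stats.pooled()
        assert pooled[1] == pytest.approx(0.5)
        assert pooled[0] == pytest.approx(0.25)
        assert pooled[-2] == pytest.approx(0.25)

    def test_per_state_rows_sum_to_one(self):
        spec = markov_preset("bocf_like")
        eps = synthetic_markov_series(spec, 50, start_state=10, seed=2,
                                      step_cap=1000)
        stats = transition_probabilities(eps)
        for n, row in stats.probs.items():
            assert sum(row.values()) == pytest.approx(1.0)
            assert all(p >= 0 for p in row.values())

    def test_planted_probabilities_recovered(self):
        spec = markov_preset("tnnp_like")
        eps = synthetic_markov_series(spec, 200, start_state=15, seed=5,
                                      step_cap=2000)
        stats = transition_probabilities(eps)
        n_tr = sum(stats.counts[8].values())
        assert n_tr > 1000
        for d, p in spec.row(8).items():
            sigma = np.sqrt(p * (1 - p) / n_tr)
            assert abs(stats.probs[8][d] - p) <= 3 * sigma + 1e-9

    def test_oversize_jumps_reported_not_folded(self):
        stats = transition_probabilities([series([5, 1, 1])])
        assert stats.oversize_jumps == 1
        assert 5 not in stats.probs     # its only transition was oversize

    def test_absorbing_state_emits_no_transitions(self):
        stats = transition_probabilities([series([1, 0, 0, 0])])
        assert 0 not in stats.probs


class TestAlignedAverage:
    def test_single_series_is_itself(self):
        t, mean, sd, cnt = termination_aligned_average([series([3, 2, 1, 0])])
        np.testing.assert_array_equal(mean, [3, 2, 1, 0])
        assert t[-1] == 0.0

    def test_two_series_direct_average(self):
        a = series([3, 1, 0])
        b = series([5, 3, 0])
        t, mean, sd, cnt = termination_aligned_average([a, b])
        np.testing.assert_allclose(mean, [4.0, 2.0, 0.0])
        np.testing.assert_array_equal(cnt, [2, 2, 2])

    def test_aligned_mean_is_zero_at_termination(self):
        spec = markov_preset("tnnp_like")
        eps = synthetic_markov_series(spec, 50, start_state=5, seed=13,
                                      step_cap=5000)
        term = [e for e in eps if e[1][-1] == 0]
        assert len(term) > 10
        t, mean, sd, cnt = termination_aligned_average(term)
        assert mean[-1] == 0.0

    def test_unterminated_series_rejected(self):
        with pytest.raises(ValueError, match="terminated"):
            termination_aligned_average([series([3, 2, 1])])

    def test_breakup_contrast_shapes_final_phase(self):
        # the rare-breakup chain departs from its plateau earlier (long
        # single-spiral tail) than the frequent-breakup chain
        drop = {}
        for kind in ("bocf_like", "tnnp_like"):
            spec = markov_preset(kind)
            eps = synthetic_markov_series(spec, 150, start_state=12,
                                          seed=17, step_cap=20_000)
            term = [e for e in eps if e[1][-1] == 0]
            assert len(term) > 50
            t, mean, sd, cnt = termination_aligned_average(term)
            good = cnt >= len(term) // 2
            plateau = mean[good][:max(1, good.sum() // 4)].mean()
            below = t[good][mean[good] < 0.5 * plateau]
            drop[kind] = below.min()      # most negative aligned time
        assert drop["bocf_like"] < drop["tnnp_like"]


class TestDwellStatistics:
    def test_hand_series_with_terminating_dwell(self):
        d = single_spiral_dwell_statistics([series([1, 1, 1, 0])])
        assert d["ending_in_termination"] == [3]
        assert d["ending_in_breakup"] == []

    def test_hand_series_with_breakup_dwell(self):
        d = single_spiral_dwell_statistics([series([2, 1, 1, 3, 1, 0])])
        assert d["ending_in_breakup"] == [2]
        assert d["ending_in_termination"] == [1]

    def test_exit_split_matches_generator(self):
        # from state 1 the preset exits down with p_down/(p_down+p_up)
        spec = markov_preset("tnnp_like")
        eps = synthetic_markov_series(spec, 400, start_state=1, seed=23,
                                      step_cap=500)
        d = single_spiral_dwell_statistics(eps)
        n_term = len(d["ending_in_termination"])
        n_break = len(d["ending_in_breakup"])
        row = spec.row(1)
        p_down = row[-1] / (row[-1] + row[1] + row[2])
        n = n_term + n_break
        phat = n_term / n
        assert abs(phat - p_down) <= 3 * np.sqrt(p_down * (1 - p_down) / n)


class TestEstimatorSurface:
    def test_fitted_attributes(self):
        est = SpiralMarkovEstimator(lag=1)
        eps = synthetic_markov_series(markov_preset("bocf_like"), 20,
                                      start_state=5, seed=1, step_cap=500)
        est.fit(eps)
        assert hasattr(est, "transition_stats_")
        assert hasattr(est, "occupancy_")
        assert est.n_series_ == 20
        assert est.get_params()["lag"] == 1
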