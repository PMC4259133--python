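"""Survival prediction metrics: censoring KM, Brier/IBS, concordance,
recovery rate."""

import numpy as np
import pytest
from lifelines.utils import concordance_index as ll_concordance

from harmcox import (SurvivalDataset, breslow_baseline, brier_score,
                     concordance_index, ibs, km_censoring, predict_survival,
                     recovery_rate)
from harmcox.metrics import PredictedSurvival, StepSurvival


def constant_prediction(n, value, times=(1e9,)):
    """S(t|x) == value for every subject and every t > 0."""
    return PredictedSurvival(times=np.array([0.0]),
                             curves=np.full((n, 1), float(value)))


def graf_bs_oracle(data, pred, t, G):
    """Straight-line evaluation of the IPC-weighted Brier score."""
    total, n_inc = 0.0, 0
    for i in range(data.n):
        S = pred.at(t)[i]
        if data.time[i] <= t and data.event[i] == 1:
            w = G.at_minus(data.time[i])
            if w > 0:
                total += S ** 2 / w
                n_inc += 1
        elif data.time[i] > t:
            w = G.at(t)
            if w > 0:
                total += (1 - S) ** 2 / w
                n_inc += 1
        else:
            n_inc += 1  # censored before t: contributes zero
    return total / n_inc


class TestKmCensoring:
    def test_no_censoring_gives_unit_weight(self):
        d = SurvivalDataset(np.zeros((4, 1)), [1, 2, 3, 4], [1, 1, 1, 1])
        G = km_censoring(d)
        assert G.at(0.5) == 1.0
        assert G.at(3.5) == 1.0

    def test_all_censored_textbook_steps(self):
        d = SurvivalDataset(np.zeros((4, 1)), [1, 2, 3, 4], [1, 0, 0, 0])
        # censorings at 2, 3, 4 are "events" for G; at-risk 3, 2, 1
        G = km_censoring(d)
        assert G.at(2.5) == pytest.approx(2 / 3)
        assert G.at(3.5) == pytest.approx(1 / 3)
        assert G.at(4.0) == pytest.approx(0.0)

    def test_drops_only_at_censoring_times(self):
        d = SurvivalDataset(np.zeros((4, 1)), [1, 2, 3, 4], [1, 0, 1, 0])
        G = km_censoring(d)
        assert G.at(1.5) == 1.0                      # event at 1: no drop
        assert G.at(2.5) == pytest.approx(2 / 3)     # at-risk 3 at t=2
        assert G.at(3.9) == pytest.approx(2 / 3)
        assert G.at(4.0) == pytest.approx(0.0)

    def test_left_limit(self):
        d = SurvivalDataset(np.zeros((3, 1)), [1, 2, 3], [0, 1, 1])
        G = km_censoring(d)
        assert G.at_minus(1.0) == 1.0
        assert G.at(1.0) == pytest.approx(2 / 3)


class TestBrierScore:
    def test_constant_half_prediction(self):
        d = SurvivalDataset(np.zeros((6, 1)), [1, 2, 3, 4, 5, 6], np.ones(6))
        pred = constant_prediction(6, 0.5)
        for t in (0.5, 2.5, 5.5):
            assert brier_score(d, pred, t) == pytest.approx(0.25)

    def test_oracle_predictor_scores_zero(self):
        d = SurvivalDataset(np.zeros((3, 1)), [1.0, 2.0, 3.0], [1, 1, 1])
        times = np.array([1.0, 2.0, 3.0])
        curves = (times[None, :] < d.time[:, None]).astype(float)
        pred = PredictedSurvival(times=times, curves=curves)
        for t in (0.5, 1.5, 2.5):
            assert brier_score(d, pred, t) == pytest.approx(0.0)

    def test_matches_brute_force_with_censoring(self, rng):
        d = SurvivalDataset(rng.standard_normal((8, 2)),
                            [0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0],
                            [1, 0, 1, 1, 0, 1, 0, 1])
        base = breslow_baseline(d, [0.3, -0.2])
        pred = predict_survival(base, d.X, [0.3, -0.2])
        G = km_censoring(d)
        for t in (0.7, 1.7, 2.7, 3.7):
            assert brier_score(d, pred, t) == \
                pytest.approx(graf_bs_oracle(d, pred, t, G), rel=1e-12)

    def test_matches_scikit_survival(self, rng):
        from sksurv.metrics import brier_score as sks_brier
        d = SurvivalDataset(rng.standard_normal((20, 2)),
                            np.arange(1, 21, dtype=float),
                            rng.integers(0, 2, 20) | (np.arange(20) == 0))
        beta = np.array([0.4, -0.3])
        pred = predict_survival(breslow_baseline(d, beta), d.X, beta)
        y = np.array([(bool(e), t) for e, t in zip(d.event, d.time)],
                     dtype=[("event", "?"), ("time", "<f8")])
        times = np.array([5.5, 10.5, 15.5])
        est = np.column_stack([pred.at(t) for t in times])
        _, ref = sks_brier(y, y, est, times)
        ours = [brier_score(d, pred, t) for t in times]
        assert np.allclose(ours, ref, atol=1e-10)

    def test_bounds(self, rng):
        d = SurvivalDataset(rng.standard_normal((15, 1)),
                            rng.exponential(size=15) + 0.1,
                            rng.integers(0, 2, 15) | (np.arange(15) == 0))
        pred = constant_prediction(15, 0.9)
        for t in np.linspace(0.05, d.time.max() * 0.95, 7):
            assert 0.0 <= brier_score(d, pred, t) <= 1.0


class TestIntegratedBrierScore:
    def test_constant_prediction_integrates_exactly(self):
        d = SurvivalDataset(np.zeros((6, 1)), [1, 2, 3, 4, 5, 6], np.ones(6))
        assert ibs(d, constant_prediction(6, 0.5)) == pytest.approx(0.25)

    def test_oracle_predictor_zero(self):
        d = SurvivalDataset(np.zeros((3, 1)), [1.0, 2.0, 3.0], [1, 1, 1])
        times = np.array([1.0, 2.0, 3.0])
        curves = (times[None, :] < d.time[:, None]).astype(float)
        assert ibs(d, PredictedSurvival(times, curves)) == pytest.approx(0.0)

    def test_matches_independent_step_integrator(self, rng):
        d = SurvivalDataset(rng.standard_normal((5, 1)),
                            [0.8, 1.6, 2.4, 3.2, 4.0], [1, 0, 1, 1, 0])
        beta = np.array([0.5])
        pred = predict_survival(breslow_baseline(d, beta), d.X, beta)
        G = km_censoring(d)
        tau = d.time.max()
        jumps = np.unique(np.concatenate([[0.0], d.time, pred.times,
                                          G.times, [tau]]))
        jumps = jumps[jumps <= tau]
        total = 0.0
        for lo, hi in zip(jumps[:-1], jumps[1:]):
            mid = 0.5 * (lo + hi)  # BS constant on (lo, hi)
            total += graf_bs_oracle(d, pred, mid, G) * (hi - lo)
        assert ibs(d, pred) == pytest.approx(total / tau, abs=1e-12)

    def test_grid_refinement_invariance(self):
        # prediction jump times interleaved between observed times must not
        # change the exact step integral
        d = SurvivalDataset(np.zeros((4, 1)), [1, 2, 3, 4], [1, 1, 1, 1])
        coarse = constant_prediction(4, 0.5)
        fine = PredictedSurvival(times=np.array([0.0, 1.5, 2.5]),
                                 curves=np.full((4, 3), 0.5))
        assert ibs(d, coarse) == pytest.approx(ibs(d, fine))


class TestConcordance:
    def test_hand_enumerated_case(self):
        d = SurvivalDataset(np.zeros((3, 1)), [1.0, 2.0, 3.0], [1, 1, 1])
        survival_scores = np.array([0.1, 0.9, 0.5])
        assert concordance_index(d, -survival_scores) == pytest.approx(2 / 3)

    def test_perfect_ordering(self):
        d = SurvivalDataset(np.zeros((5, 1)), [1, 2, 3, 4, 5], np.ones(5))
        assert concordance_index(d, -np.arange(5.0)) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(77)
        d = SurvivalDataset(np.zeros((400, 1)),
                            rng.exponential(size=400) + 0.01, np.ones(400))
        ci = concordance_index(d, rng.standard_normal(400))
        assert ci == pytest.approx(0.5, abs=0.05)

    def test_all_tied_scores_give_half(self):
        d = SurvivalDataset(np.zeros((4, 1)), [1, 2, 3, 4], [1, 1, 0, 1])
        assert concordance_index(d, np.zeros(4)) == 0.5

    def test_censored_pairs_excluded(self):
        # subject 0 censored: pairs with t_0 < t_j cannot be ordered
        d = SurvivalDataset(np.zeros((3, 1)), [1.0, 2.0, 3.0], [0, 1, 1])
        # only the (1, 2) pair is comparable
        assert concordance_index(d, [0.0, 5.0, 1.0]) == 1.0

    def test_matches_lifelines(self, rng):
        d = SurvivalDataset(rng.standard_normal((30, 2)),
                            rng.exponential(size=30) + 0.05,
                            rng.integers(0, 2, 30) | (np.arange(30) == 0))
        risk = rng.standard_normal(30)
        ours = concordance_index(d, risk)
        ref = ll_concordance(d.time, -risk, d.event)
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_no_comparable_pairs_signaled(self):
        d = SurvivalDataset(np.zeros((2, 1)), [1.0, 2.0], [0, 1])
        with pytest.raises(ValueError):
            concordance_index(d, [1.0, 0.0])


class TestRecoveryRate:
    def test_exact_support_recovery(self):
        assert recovery_rate([5, 5, 5], [5, 5, 5]) == 1.0

    def test_half_noise(self):
        assert recovery_rate([5, 5], [10, 10]) == 0.5

    def test_ratio_of_means_not_mean_of_ratios(self):
        assert recovery_rate([4.8], [6.6]) == pytest.approx(4.8 / 6.6)
        # means first: (4+5)/2 over (5+9)/2, not mean(4/5, 5/9)
        assert recovery_rate([4, 5], [5, 9]) == pytest.approx(4.5 / 7.0)

    def test_undefined_cases(self):
        with pytest.raises(ValueError):
            recovery_rate([0, 0], [0, 0])
        with pytest.raises(ValueError):
            recovery_rate([6], [5])


def test_step_survival_evaluation():
    s = StepSurvival(times=np.array([1.0, 2.0]), values=np.array([0.6, 0.2]))
    assert s.at(0.5) == 1.0
    assert s.at(1.0) == 0.6
    assert s.at_minus(1.0) == 1.0
    assert s.at(2.7) == 0.2
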