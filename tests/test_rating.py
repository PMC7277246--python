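"""Skill-rating updates, convergence, and the consistency statistic."""

import math

import numpy as np
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import ndtr

from conftest import run_recovery_study
from viscomp.design import ComparisonRecord
from viscomp.errors import LookupRatingError, ValidationError
from viscomp.rating import (
    RatingBelief,
    RatingConfig,
    TrueSkillRater,
    consistency_score,
    gaussian_moments,
    rate_comparisons,
    update_pair,
)


def integrate_posterior_moments(mu_w, sigma_w, mu_l, sigma_l, beta, n_nodes=120):
    """Winner's posterior mean/sd by 2-D Gauss-Hermite integration.

    Independent oracle for the closed-form update: integrates
    N(s_w) N(s_l) Phi((s_w - s_l)/(sqrt(2) beta)) on a probabilists'
    Hermite grid.
    """
    x, wx = hermegauss(n_nodes)
    s_w = mu_w + sigma_w * x
    s_l = mu_l + sigma_l * x
    lik = ndtr((s_w[:, None] - s_l[None, :]) / (math.sqrt(2.0) * beta))
    weight = wx[:, None] * wx[None, :] * lik
    z = weight.sum()
    mean = (weight * s_w[:, None]).sum() / z
    second = (weight * s_w[:, None] ** 2).sum() / z
    return mean, math.sqrt(second - mean**2)


class TestGaussianMoments:
    def test_values_at_zero(self):
        v, w = gaussian_moments(0.0)
        assert v == pytest.approx(math.sqrt(2.0 / math.pi), abs=1e-6)  # 0.797885
        assert w == pytest.approx(2.0 / math.pi, abs=1e-6)  # 0.636620

    def test_value_at_minus_two(self):
        # phi(-2)/Phi(-2) = 2.3732155328... (sympy 20-digit evaluation)
        v, _ = gaussian_moments(-2.0)
        assert v == pytest.approx(2.3732155328228409, abs=1e-9)

    @pytest.mark.parametrize("t", [-50.0, -12.0, -8.0, -3.0, 0.0, 3.0, 12.0])
    def test_total_and_bounded(self, t):
        v, w = gaussian_moments(t)
        assert v > 0
        assert 0 <= w <= 1
        assert math.isfinite(v) and math.isfinite(w)

    def test_deep_tail_matches_asymptotics(self):
        # v(t) ~ -t for t -> -inf
        v, w = gaussian_moments(-30.0)
        assert v == pytest.approx(30.0, rel=1e-2)
        assert w == pytest.approx(1.0, abs=1e-2)


class TestUpdatePair:
    def test_equal_priors_closed_form(self):
        cfg = RatingConfig(tau=0.0)
        winner, loser = update_pair(RatingBelief(), RatingBelief(), cfg)
        assert winner.mu == pytest.approx(29.205, abs=1e-3)
        assert loser.mu == pytest.approx(20.795, abs=1e-3)
        assert winner.sigma == pytest.approx(7.195, abs=1e-3)
        assert loser.sigma == pytest.approx(7.195, abs=1e-3)

    def test_antisymmetry_at_equal_priors(self):
        cfg = RatingConfig(tau=0.0)
        winner, loser = update_pair(RatingBelief(), RatingBelief(), cfg)
        assert winner.mu - cfg.mu0 == pytest.approx(cfg.mu0 - loser.mu, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_winner_up_loser_down_sigmas_shrink(self, seed):
        rng = np.random.default_rng(seed)
        a = RatingBelief(mu=rng.uniform(10, 40), sigma=rng.uniform(1, 10))
        b = RatingBelief(mu=rng.uniform(10, 40), sigma=rng.uniform(1, 10))
        cfg = RatingConfig(beta=rng.uniform(1, 6), tau=0.0)
        winner, loser = update_pair(a, b, cfg)
        assert winner.mu > a.mu
        assert loser.mu < b.mu
        assert winner.sigma <= a.sigma
        assert loser.sigma <= b.sigma

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValidationError):
            update_pair(RatingBelief(mu=float("nan")), RatingBelief())

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_numerical_posterior_moments(self, seed):
        """Closed-form update equals exact posterior moments to <= 1e-5."""
        rng = np.random.default_rng(1000 + seed)
        w = RatingBelief(mu=rng.uniform(15, 35), sigma=rng.uniform(2, 10))
        l = RatingBelief(mu=rng.uniform(15, 35), sigma=rng.uniform(2, 10))
        beta = rng.uniform(1.5, 8)
        cfg = RatingConfig(beta=beta, tau=0.0)
        new_w, new_l = update_pair(w, l, cfg)
        mean_w, sd_w = integrate_posterior_moments(w.mu, w.sigma, l.mu, l.sigma, beta)
        assert new_w.mu == pytest.approx(mean_w, abs=1e-5)
        assert new_w.sigma == pytest.approx(sd_w, abs=1e-5)
        # the loser is the winner of the mirrored game
        mean_l, sd_l = integrate_posterior_moments(-l.mu, l.sigma, -w.mu, w.sigma, beta)
        assert new_l.mu == pytest.approx(-mean_l, abs=1e-5)
        assert new_l.sigma == pytest.approx(sd_l, abs=1e-5)


class TestRateComparisons:
    def test_no_comparisons_keeps_priors(self):
        table = rate_comparisons([], items=["A", "B", "C"])
        for item in "ABC":
            assert table[item].mu == pytest.approx(25.0)
            assert table[item].sigma == pytest.approx(25.0 / 3.0, abs=1e-3)

    def test_transitive_wins_force_ordering(self):
        records = []
        for _ in range(20):
            records += [
                ComparisonRecord("o", "A", "B", "A"),
                ComparisonRecord("o", "B", "C", "B"),
                ComparisonRecord("o", "A", "C", "A"),
            ]
        table = rate_comparisons(records)
        assert table["A"].mu > table["B"].mu > table["C"].mu

    def test_missing_choice_rejected(self):
        with pytest.raises(ValidationError):
            rate_comparisons([ComparisonRecord("o", "A", "B")])

    def test_relabeling_invariance(self):
        records = [
            ComparisonRecord("o", "A", "B", "A"),
            ComparisonRecord("o", "B", "C", "B"),
            ComparisonRecord("o", "C", "A", "A"),
        ] * 5
        mapping = {"A": "X", "B": "Y", "C": "Z"}
        renamed = [
            ComparisonRecord(r.observer_id, mapping[r.item_a], mapping[r.item_b],
                             mapping[r.chosen])
            for r in records
        ]
        t1 = rate_comparisons(records)
        t2 = rate_comparisons(renamed)
        for old, new in mapping.items():
            assert t1[old].mu == t2[new].mu
            assert t1[old].sigma == t2[new].sigma

    def test_epoch_trace_roughly_decreasing(self):
        _, _, table = run_recovery_study(60, 30, noise_sd=2.0, seed=4)
        trace = table.epoch_trace
        assert len(trace) >= 1
        assert trace[-1] < trace[0]

    @pytest.mark.parametrize("seed", range(5))
    def test_balanced_design_mean_drift_small(self, seed):
        world, _, table = run_recovery_study(100, 20, noise_sd=2.0, seed=seed)
        mus = [table[i].mu for i in world.items()]
        assert abs(float(np.mean(mus)) - 25.0) <= 0.5


class TestConsistencyScore:
    def test_perfect_agreement_is_one(self):
        records = [ComparisonRecord("o", "A", "B", "A")] * 4
        table = rate_comparisons(records)
        assert consistency_score(records, table) == 1.0

    def test_mu_ties_count_half(self):
        table = rate_comparisons([], items=["A", "B"])  # equal priors
        records = [ComparisonRecord("o", "A", "B", "A"),
                   ComparisonRecord("o", "A", "B", "B")]
        assert consistency_score(records, table) == 0.5

    def test_missing_item_names_it(self):
        table = rate_comparisons([], items=["A", "B"])
        with pytest.raises(LookupRatingError, match="ghost"):
            consistency_score([ComparisonRecord("o", "A", "ghost", "A")], table)

    def test_equal_latents_fair_coin_near_half(self):
        """Two equal-latent items under a pure-noise observer: expectation 0.5."""
        rng = np.random.default_rng(9)
        choices = rng.random(100_000) < 0.5
        records = [
            ComparisonRecord("o", "A", "B", "A" if c else "B") for c in choices
        ]
        table = rate_comparisons(records, RatingConfig(epochs_max=2))
        assert consistency_score(records, table) == pytest.approx(0.5, abs=0.01)

    def test_monotone_in_observer_noise(self):
        """More perceptual noise can only reduce choice-rating consistency."""
        means = []
        for noise in (0.0, 2.0, 5.0, 10.0):
            scores = []
            for seed in range(5):
                world, records, table = run_recovery_study(60, 20, noise, seed=seed)
                scores.append(consistency_score(records, table))
            means.append(float(np.mean(scores)))
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))


class TestTrueSkillRater:
    def test_estimator_round_trip(self):
        records = [ComparisonRecord("o", "A", "B", "A")] * 10
        rater = TrueSkillRater(epochs_max=3).fit(records)
        assert rater.ratings_["A"] > rater.ratings_["B"]
        assert rater.score(records) == 1.0
        assert rater.get_params()["epochs_max"] == 3
        clone = TrueSkillRater(**rater.get_params()).fit(records)
        assert clone.ratings_ == rater.ratings_
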