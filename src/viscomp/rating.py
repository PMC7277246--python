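"""Bayesian two-player skill rating of 2AFC comparisons.

Each item carries a Gaussian belief N(mu, sigma^2) over its latent perceived
complexity.  Every comparison is treated as a game won by the chosen item;
the winner/loser beliefs are moment-matched against the exact posterior

    p(s_w, s_l | win)  propto  N(s_w; mu_w, sigma_w^2) N(s_l; mu_l, sigma_l^2)
                               * Phi((s_w - s_l) / (sqrt(2) * beta)),

which for the no-draw two-player case has closed-form first and second
moments in terms of v(t) = phi(t)/Phi(t) and w(t) = v(t) (v(t) + t).  The
final mu is the item's complexity score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr

from .design import ComparisonRecord
from .errors import LookupRatingError, ValidationError

__all__ = [
    "RatingBelief",
    "RatingConfig",
    "RatingTable",
    "gaussian_moments",
    "update_pair",
    "rate_comparisons",
    "consistency_score",
    "TrueSkillRater",
]

logger = logging.getLogger(__name__)

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

DEFAULT_MU0 = 25.0
DEFAULT_SIGMA0 = 25.0 / 3.0


@dataclass(frozen=True)
class RatingBelief:
    """Gaussian belief over one item's latent complexity score."""

    mu: float = DEFAULT_MU0
    sigma: float = DEFAULT_SIGMA0

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class RatingConfig:
    """Engine parameters.

    beta is the performance noise of a single game (half the prior sd by
    default); tau is a small dynamics variance added to each belief before
    every update so ratings never freeze entirely.  The comparison list is
    replayed in shuffled order for up to ``epochs_max`` epochs, stopping once
    the mean per-item |delta mu| of an epoch falls below
    ``epsilon_converge``.
    """

    mu0: float = DEFAULT_MU0
    sigma0: float = DEFAULT_SIGMA0
    beta: float = DEFAULT_SIGMA0 / 2.0
    tau: float = DEFAULT_SIGMA0 / 100.0
    epochs_max: int = 10
    epsilon_converge: float = 0.01
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.beta > 0):
            raise ValidationError("beta must be > 0")
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")
        if not (self.epsilon_converge > 0):
            raise ValidationError("epsilon_converge must be > 0")
        if self.epochs_max < 1:
            raise ValidationError("epochs_max must be >= 1")


@dataclass
class RatingTable:
    """Final beliefs for every item plus the per-epoch convergence trace."""

    beliefs: dict[str, RatingBelief]
    epoch_trace: list[float] = field(default_factory=list)

    def __getitem__(self, item_id: str) -> RatingBelief:
        try:
            return self.beliefs[item_id]
        except KeyError:
            raise LookupRatingError(f"item {item_id!r} has no rating") from None

    def __contains__(self, item_id: str) -> bool:
        return item_id in self.beliefs

    def __len__(self) -> int:
        return len(self.beliefs)

    def mus(self) -> dict[str, float]:
        return {k: b.mu for k, b in self.beliefs.items()}

    def as_tuples(self) -> dict[str, tuple[float, float]]:
        return {k: (b.mu, b.sigma) for k, b in self.beliefs.items()}


def gaussian_moments(t: float) -> tuple[float, float]:
    """Truncated-Gaussian correction terms v(t) = phi(t)/Phi(t), w(t) = v(v+t).

    Computed in log space (via the log normal CDF) so the ratio stays finite
    and accurate far into the left tail (t << -8), where naive pdf/cdf
    division underflows.
    """
    t = float(t)
    if not math.isfinite(t):
        raise ValidationError(f"non-finite margin t={t}")
    log_v = -0.5 * t * t - _LOG_SQRT_2PI - float(log_ndtr(t))
    v = math.exp(log_v)
    w = v * (v + t)
    # clamp fp noise: w is analytically in (0, 1)
    return v, min(max(w, 0.0), 1.0)


def update_pair(
    winner: RatingBelief, loser: RatingBelief, cfg: RatingConfig | None = None
) -> tuple[RatingBelief, RatingBelief]:
    """Posterior beliefs after one game in which ``winner`` beat ``loser``.

    With c^2 = 2 beta^2 + sigma_w^2 + sigma_l^2 and t = (mu_w - mu_l)/c:

        mu_w    += (sigma_w^2 / c) * v(t)
        mu_l    -= (sigma_l^2 / c) * v(t)
        sigma^2 *= 1 - (sigma^2 / c^2) * w(t)    (each side)

    tau^2 is added to both variances before the update.
    """
    cfg = cfg or RatingConfig()
    for b in (winner, loser):
        if not (math.isfinite(b.mu) and math.isfinite(b.sigma)):
            raise ValidationError("non-finite rating belief")
    var_w = winner.sigma**2 + cfg.tau**2
    var_l = loser.sigma**2 + cfg.tau**2
    c2 = 2.0 * cfg.beta**2 + var_w + var_l
    c = math.sqrt(c2)
    v, w = gaussian_moments((winner.mu - loser.mu) / c)
    new_w = RatingBelief(
        mu=winner.mu + var_w / c * v,
        sigma=math.sqrt(var_w * (1.0 - var_w / c2 * w)),
    )
    new_l = RatingBelief(
        mu=loser.mu - var_l / c * v,
        sigma=math.sqrt(var_l * (1.0 - var_l / c2 * w)),
    )
    return new_w, new_l


def _items_of(records: list[ComparisonRecord], extra: list[str] | None) -> list[str]:
    seen: dict[str, None] = {}
    for rec in records:
        seen.setdefault(rec.item_a)
        seen.setdefault(rec.item_b)
    for item in extra or []:
        seen.setdefault(item)
    return list(seen)


def rate_comparisons(
    records: list[ComparisonRecord],
    cfg: RatingConfig | None = None,
    items: list[str] | None = None,
) -> RatingTable:
    """Run sequential skill updates over the comparison list until convergence.

    Every item appearing in any comparison (plus any in ``items``) gets a
    belief; items with no comparisons keep the prior.  Updates are strictly
    online; each epoch replays the full list in a freshly shuffled order.
    An empty record list returns a table of priors.
    """
    cfg = cfg or RatingConfig()
    all_items = _items_of(records, items)
    mu = {k: cfg.mu0 for k in all_items}
    var = {k: cfg.sigma0**2 for k in all_items}
    trace: list[float] = []

    for rec in records:
        if rec.chosen is None:
            raise ValidationError("every comparison must have its chosen field set")

    if records:
        rng = np.random.default_rng(cfg.shuffle_seed)
        order = np.arange(len(records))
        tau2 = cfg.tau**2
        two_beta2 = 2.0 * cfg.beta**2
        log_sqrt_2pi = _LOG_SQRT_2PI
        for epoch in range(cfg.epochs_max):
            rng.shuffle(order)
            start = dict(mu)
            for idx in order:
                rec = records[idx]
                w_id = rec.chosen
                l_id = rec.item_b if rec.chosen == rec.item_a else rec.item_a
                vw = var[w_id] + tau2
                vl = var[l_id] + tau2
                c2 = two_beta2 + vw + vl
                c = math.sqrt(c2)
                t = (mu[w_id] - mu[l_id]) / c
                v = math.exp(-0.5 * t * t - log_sqrt_2pi - float(log_ndtr(t)))
                w = v * (v + t)
                if w > 1.0:
                    w = 1.0
                mu[w_id] += vw / c * v
                mu[l_id] -= vl / c * v
                var[w_id] = vw * (1.0 - vw / c2 * w)
                var[l_id] = vl * (1.0 - vl / c2 * w)
            delta = sum(abs(mu[k] - start[k]) for k in all_items) / len(all_items)
            trace.append(delta)
            logger.info("rating epoch %d: mean |delta mu| = %.5f", epoch + 1, delta)
            if delta < cfg.epsilon_converge:
                break

    beliefs = {k: RatingBelief(mu=mu[k], sigma=math.sqrt(var[k])) for k in all_items}
    return RatingTable(beliefs=beliefs, epoch_trace=trace)


def consistency_score(records: list[ComparisonRecord], table: RatingTable) -> float:
    """Fraction of comparisons whose chosen item has the strictly greater mu.

    Ties in mu count 0.5.  This is the internal-consistency statistic of a
    one-dimensional representation of the judgements: a high value means the
    scalar scores explain most individual choices.
    """
    if not records:
        raise ValidationError("consistency_score needs at least one comparison")
    total = 0.0
    for rec in records:
        if rec.chosen is None:
            raise ValidationError("every comparison must have its chosen field set")
        mu_a = table[rec.item_a].mu
        mu_b = table[rec.item_b].mu
        mu_chosen = mu_a if rec.chosen == rec.item_a else mu_b
        mu_other = mu_b if rec.chosen == rec.item_a else mu_a
        if mu_chosen > mu_other:
            total += 1.0
        elif mu_chosen == mu_other:
            total += 0.5
    return total / len(records)


class TrueSkillRater:
    """sklearn-style estimator wrapping :func:`rate_comparisons`.

    Parameters mirror :class:`RatingConfig`.  After ``fit`` the instance
    exposes ``table_`` (a :class:`RatingTable`), ``ratings_`` (item -> mu)
    and ``epoch_trace_``; ``score`` returns the consistency statistic of a
    comparison list against the fitted ratings.
    """

    def __init__(
        self,
        mu0: float = DEFAULT_MU0,
        sigma0: float = DEFAULT_SIGMA0,
        beta: float = DEFAULT_SIGMA0 / 2.0,
        tau: float = DEFAULT_SIGMA0 / 100.0,
        epochs_max: int = 10,
        epsilon_converge: float = 0.01,
        shuffle_seed: int = 0,
    ):
        self.mu0 = mu0
        self.sigma0 = sigma0
        self.beta = beta
        self.tau = tau
        self.epochs_max = epochs_max
        self.epsilon_converge = epsilon_converge
        self.shuffle_seed = shuffle_seed

    def get_params(self, deep: bool = True) -> dict:
        return {
            "mu0": self.mu0,
            "sigma0": self.sigma0,
            "beta": self.beta,
            "tau": self.tau,
            "epochs_max": self.epochs_max,
            "epsilon_converge": self.epsilon_converge,
            "shuffle_seed": self.shuffle_seed,
        }

    def set_params(self, **params) -> "TrueSkillRater":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValidationError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def _config(self) -> RatingConfig:
        return RatingConfig(
            mu0=self.mu0,
            sigma0=self.sigma0,
            beta=self.beta,
            tau=self.tau,
            epochs_max=self.epochs_max,
            epsilon_converge=self.epsilon_converge,
            shuffle_seed=self.shuffle_seed,
        )

    def fit(
        self, X: list[ComparisonRecord], y=None, items: list[str] | None = None
    ) -> "TrueSkillRater":
        self.table_ = rate_comparisons(list(X), self._config(), items=items)
        self.ratings_ = self.table_.mus()
        self.epoch_trace_ = list(self.table_.epoch_trace)
        return self

    def score(self, X: list[ComparisonRecord], y=None) -> float:
        return consistency_score(list(X), self.table_)
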