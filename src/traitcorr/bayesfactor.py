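"""Marginal-likelihood estimates and Bayes factors.

Marginal likelihoods are harmonic means of the sampled likelihoods
(computed in log space); Bayes factors are ``2 x (lnL1 - lnL0)`` with
the conventional evidence bands (>2 positive, >5 strong).  The second
route to a Bayes factor compares how often the reversible-jump chain
visits independent-model partitions against the exact prior odds of the
enumerated partition space.  The harmonic-mean estimator is known to be
unstable (infinite variance in general); it is retained here because
the reported quantities are defined on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .mcmc import PosteriorSample
from .partitions import count_model_space

__all__ = [
    "BayesFactorResult", "RjVisitSummary", "harmonic_mean_loglik",
    "log_bayes_factor", "bf_band", "best_of_replicates",
    "prior_odds_model_space", "bf_from_odds_ratio", "visit_odds_bf",
]

POSITIVE_THRESHOLD = 2.0
STRONG_THRESHOLD = 5.0


def bf_band(bf: float) -> str:
    """Evidence band: 'none' (<=2), 'positive' (2-5), 'strong' (>5)."""
    if bf > STRONG_THRESHOLD:
        return "strong"
    if bf > POSITIVE_THRESHOLD:
        return "positive"
    return "none"


@dataclass(frozen=True)
class BayesFactorResult:
    lnl_model1: float
    lnl_model0: float
    bf: float
    band: str


@dataclass(frozen=True)
class RjVisitSummary:
    """Visit-count evidence from one reversible-jump run.

    All odds fields are None (not applicable) when the chain never
    visited an independent partition — the strongest possible support
    for the dependent model, but an undefined ratio.
    """
    visits_independent: int
    visits_total: int
    prior_odds: float
    posterior_odds: float | None
    odds_ratio: float | None
    bf: float | None

    @property
    def not_applicable(self) -> bool:
        return self.posterior_odds is None


def harmonic_mean_loglik(sample: PosteriorSample | Sequence[float]) -> float:
    """log of the harmonic mean of sampled likelihoods.

    For retained log-likelihoods lnL_i this is
    ``ln N - logsumexp(-lnL_i)``, evaluated entirely in log space.
    """
    lnl = sample.lnl if isinstance(sample, PosteriorSample) else np.asarray(sample, float)
    if lnl.size == 0:
        raise ValueError("harmonic mean of an empty sample")
    return float(np.log(lnl.size) - logsumexp(-lnl))


def log_bayes_factor(lnl1: float, lnl0: float) -> BayesFactorResult:
    """BF = 2 x (lnL1 - lnL0) from two log marginal likelihoods."""
    if not (np.isfinite(lnl1) and np.isfinite(lnl0)):
        raise ValueError("log marginal likelihoods must be finite")
    bf = 2.0 * (lnl1 - lnl0)
    return BayesFactorResult(lnl_model1=float(lnl1), lnl_model0=float(lnl0),
                             bf=bf, band=bf_band(bf))


def best_of_replicates(samples: Sequence[PosteriorSample]) -> PosteriorSample:
    """The replicate with the highest harmonic-mean log likelihood.

    Ties are broken by the lowest seed so the choice is deterministic.
    """
    if not samples:
        raise ValueError("no replicate runs supplied")
    keyed = [(-harmonic_mean_loglik(s), s.seed, i) for i, s in enumerate(samples)]
    keyed.sort()
    return samples[keyed[0][2]]


def prior_odds_model_space(zero_class_enabled: bool = False) -> float:
    """Prior odds of dependent vs independent partitions under the
    uniform-partition prior, by exact enumeration of the model space."""
    total, indep = count_model_space(zero_class_enabled)
    return (total - indep) / indep


def bf_from_odds_ratio(odds_ratio: float) -> float:
    """BF = 2 ln(posterior odds / prior odds)."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    return 2.0 * float(np.log(odds_ratio))


def visit_odds_bf(sample: PosteriorSample, prior_odds: float) -> RjVisitSummary:
    """Visit-count Bayes factor for dependent vs independent models.

    ``posterior_odds = (visits_total - visits_independent) /
    visits_independent``; dividing by the prior odds and taking
    ``2 ln`` gives the BF.  Zero independent visits propagate as NA.
    """
    vi = sample.visits_independent
    vt = sample.n_samples
    if vt == 0:
        raise ValueError("empty reversible-jump sample")
    if vi == 0:
        return RjVisitSummary(visits_independent=0, visits_total=vt,
                              prior_odds=float(prior_odds), posterior_odds=None,
                              odds_ratio=None, bf=None)
    post = (vt - vi) / vi
    ratio = post / prior_odds
    return RjVisitSummary(visits_independent=vi, visits_total=vt,
                          prior_odds=float(prior_odds),
                          posterior_odds=post, odds_ratio=ratio,
                          bf=bf_from_odds_ratio(ratio))
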