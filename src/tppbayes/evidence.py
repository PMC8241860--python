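"""Marginal likelihoods, posterior model probabilities and hit calling.

The marginal likelihood (evidence) of each model is approximated with the
Laplace-Metropolis estimator

    log p(y|M) ~= (P/2) log(2 pi) + (1/2) log |H| + log p(theta*|M) + log p(y|theta*),

where theta* is the posterior draw maximizing the recorded log posterior and
H is the sample covariance of the (unconstrained-scale) posterior draws.
Everything is evaluated on the unconstrained scale with the Jacobian folded
into the prior density, which makes the estimate parameterization-invariant.

Treatment effects are then scored by the posterior probability of the
condition-dependent model M1 under multiplicity-controlling prior model
probabilities p(M0) = 0.99, p(M1) = 0.01; a protein is a hit when that
probability strictly exceeds 0.99.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .sampling import ModelFit

DEFAULT_PRIOR_PROB_M0 = 0.99
DEFAULT_HIT_THRESHOLD = 0.99


class EvidenceError(RuntimeError):
    pass


def laplace_metropolis_from_draws(draws_unconstrained: np.ndarray,
                                  log_post: np.ndarray,
                                  min_draws: int = 200,
                                  ridge: float = 1e-10) -> float:
    """Laplace-Metropolis log evidence from unconstrained draws and their log posterior."""
    X = np.asarray(draws_unconstrained, dtype=float)
    lp = np.asarray(log_post, dtype=float)
    if X.ndim != 2 or X.shape[0] < min_draws:
        raise EvidenceError(f"need at least {min_draws} draws, got {X.shape[0]}")
    P = X.shape[1]
    cov = np.cov(X, rowvar=False).reshape(P, P) + ridge * np.eye(P)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0 or not np.isfinite(logdet):
        raise EvidenceError("rank-deficient posterior covariance after ridge guard")
    i_best = int(np.argmax(lp))
    return float(0.5 * P * np.log(2.0 * np.pi) + 0.5 * logdet + lp[i_best])


def laplace_metropolis_logml(fit: ModelFit) -> float:
    """Evidence of a model fit; under M1 the per-condition evidences add."""
    total = 0.0
    for s in fit.samples:
        if s.n_draws == 0:
            raise EvidenceError("no draws available (flagged fit)")
        total += laplace_metropolis_from_draws(s.draws_unconstrained, s.log_post)
    return total


@dataclass
class ModelEvidence:
    logml_M0: float
    logml_M1: float
    P0: int
    P1: int
    prior_prob_M0: float
    posterior_prob_M1: float
    log_bayes_factor_10: float


def posterior_model_prob(logml0: float, logml1: float,
                         prior_prob_M0: float = DEFAULT_PRIOR_PROB_M0,
                         P0: int = 0, P1: int = 0) -> ModelEvidence:
    """Posterior probability of M1 from the two log evidences.

    prob(M1|y) = 1 / (1 + exp(logml0 - logml1 + log(prior0/prior1))), computed
    with a logistic so that infinitely separated evidences map to {0, 1}
    without overflow.
    """
    if not 0 < prior_prob_M0 < 1:
        raise ValueError("prior_prob_M0 must be in (0, 1)")
    log_prior_odds_10 = np.log1p(-prior_prob_M0) - np.log(prior_prob_M0)
    log_bf = logml1 - logml0
    prob1 = float(expit(log_bf + log_prior_odds_10))
    return ModelEvidence(logml_M0=float(logml0), logml_M1=float(logml1),
                         P0=P0, P1=P1, prior_prob_M0=prior_prob_M0,
                         posterior_prob_M1=prob1, log_bayes_factor_10=float(log_bf))


def classify_hits(probs: dict[str, float], threshold: float = DEFAULT_HIT_THRESHOLD,
                  flagged: set[str] | None = None) -> tuple[set[str], set[str]]:
    """(hits, flagged-and-excluded) at a strict probability threshold.

    Proteins whose sampler was flagged unreliable are reported separately,
    never silently dropped.
    """
    flagged = flagged or set()
    hits = {pid for pid, pr in probs.items()
            if pid not in flagged and np.isfinite(pr) and pr > threshold}
    return hits, {pid for pid in probs if pid in flagged}


def sensitivity(hits: set[str], positive_set: set[str]) -> float:
    """Proportion of the positive set that was called a hit."""
    if not positive_set:
        raise ValueError("positive set is empty")
    return len(set(hits) & set(positive_set)) / len(positive_set)
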