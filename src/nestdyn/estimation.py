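"""Empirical parameter estimation from behavioral observations.

Places a nest on the model's phase diagram from video-annotated behavior:
the per-capita fighting-interaction rate (alpha after rescaling by the
molecular degradation time), the queen's dominance error rate, and the
resulting lower bound on the discrimination steepness lambda.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import worker_attractor

__all__ = [
    "BehaviorCounts",
    "estimate_interaction_rate",
    "estimate_error_rate",
    "estimate_lambda_bound",
    "queen_worker_gap",
]


@dataclass(frozen=True)
class BehaviorCounts:
    """Summary counts entering the parameter estimates.

    fighting_events_per_individual: subdominant (fight) events per
    individual over the observation window.  observation_time: hours.
    census_N: insects counted in the night-time census.
    queen_interactions_total / queen_subdominant: fights involving the
    queen and those she lost.
    """

    fighting_events_per_individual: np.ndarray
    observation_time: float
    census_N: int
    queen_interactions_total: int = 0
    queen_subdominant: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "fighting_events_per_individual",
            np.asarray(self.fighting_events_per_individual, dtype=float),
        )
        if self.observation_time <= 0:
            raise ValueError("observation_time must be > 0")
        if self.census_N < 1:
            raise ValueError("census_N must be >= 1")
        if np.any(self.fighting_events_per_individual < 0):
            raise ValueError("event counts must be non-negative")
        if not 0 <= self.queen_subdominant <= self.queen_interactions_total:
            raise ValueError("queen_subdominant must be <= queen_interactions_total")


def estimate_interaction_rate(counts: BehaviorCounts):
    """Per-capita fighting interactions per day, with SEM across individuals.

    rate = total fighting events / (census_N * observation days).  The SEM
    is taken over per-individual daily rates; individuals present without
    any events contribute zeros (the census defines the denominator).
    """
    days = counts.observation_time / 24.0
    per_ind = np.zeros(counts.census_N)
    k = counts.fighting_events_per_individual
    per_ind[: min(len(k), counts.census_N)] = k[: counts.census_N] / days
    rate = float(per_ind.mean())
    sem = float(per_ind.std(ddof=1) / np.sqrt(counts.census_N)) if counts.census_N > 1 else 0.0
    return rate, sem


def estimate_error_rate(queen_subdominant: int, queen_interactions: int) -> float:
    """Dominance error rate of the queen from fight outcomes.

    With ``k`` losses in ``n`` fights the point estimate is ``k/n``; at
    ``k = 0`` a single pseudo-observed loss is added, giving ``1/n`` (so 0
    losses out of 17 queen fights yields 1/17), keeping the estimate
    strictly positive so it can be inverted for the asymmetry bound.
    """
    if queen_interactions < 1:
        raise ValueError("need at least one queen interaction")
    if not 0 <= queen_subdominant <= queen_interactions:
        raise ValueError("queen_subdominant must be in [0, n]")
    if queen_subdominant == 0:
        return 1.0 / queen_interactions
    return queen_subdominant / queen_interactions


def estimate_lambda_bound(error_rate: float, expression_gap: float) -> float:
    """Lower bound on the discrimination steepness from the error rate.

    Inverts the logistic discrimination function: an error rate
    ``eps = sigma(gap)`` observed across a steady queen-worker expression
    gap implies ``lambda = ln((1-eps)/eps) / gap``.  With eps = 1/17 and
    the mean-field gap ~0.116 this reproduces lambda ~ 24.
    """
    if not 0.0 < error_rate < 1.0:
        raise ValueError("error_rate must be in (0, 1)")
    if expression_gap <= 0:
        raise ValueError("expression_gap must be > 0")
    return float(np.log((1.0 - error_rate) / error_rate) / expression_gap)


def queen_worker_gap(alpha_tilde: float) -> float:
    """Steady queen-worker expression gap 1 - r2 at a given alpha_tilde.

    Default gap for :func:`estimate_lambda_bound` when no supplementary
    mapping is supplied.
    """
    return 1.0 - worker_attractor(alpha_tilde)
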