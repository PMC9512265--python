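"""Queen-persistence-time statistics under stochastic interaction timing.

A worker's queen genes are reset every time the queen dominates it; if too
long a time passes without such an interaction, its molecular state drifts
up and the worker challenges the queen.  With ``N`` workers each receiving
queen interactions at mean intervals ``T_int``, and molecular states stable
for a time ``R * T_int`` after an interaction, the expected time until the
first chance challenge is

    T = T_int * ( R + 1 / (1 - (1 - exp(-R))**N) ).

The formula is the expectation of a window model: in each interaction
window of length ``T_int`` every worker independently escapes reset with
probability ``exp(-R)``; the number of windows until some worker escapes is
geometric, and the escaping worker needs a further ``R * T_int`` of
unperturbed drift to complete the challenge.

Reduced gene-expression noise (e.g. through gene-body DNA methylation)
enters through the same template with the per-window activation probability
replaced by the upper-tail probability of the expression distribution,
``exp(-1/sigma)`` for exponential tails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PersistenceParams",
    "persistence_time_R",
    "persistence_time_sigma",
    "simulate_replacement",
]


@dataclass(frozen=True)
class PersistenceParams:
    """Parameters of the queen-persistence estimate.

    T_int: mean time between consecutive subdominant interactions of a
    worker (hours).  R: ratio of the molecular-stability time to T_int.
    N: number of workers.  sigma_expr: queen-gene expression noise scale
    across insects.  tail: expression-distribution family used for the
    noise variant.
    """

    T_int: float
    R: float
    N: int
    sigma_expr: float = 1.0
    tail: str = "exponential"

    def __post_init__(self):
        if self.T_int <= 0:
            raise ValueError("T_int must be > 0")
        if self.R < 0:
            raise ValueError("R must be >= 0")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.sigma_expr <= 0:
            raise ValueError("sigma_expr must be > 0")
        if self.tail not in ("exponential", "normal"):
            raise ValueError(f"unknown tail family {self.tail!r}")


def _window_persistence(p_act: float, R: float, N: int, T_int: float) -> float:
    # shared template: geometric number of windows at per-worker
    # activation probability p_act, plus the R*T_int excursion itself
    if p_act <= 0.0:
        return float("inf")
    denom = 1.0 - (1.0 - p_act) ** N
    if denom <= 0.0:
        return float("inf")
    return T_int * (R + 1.0 / denom)


def persistence_time_R(R: float, N: int, T_int: float) -> float:
    """Expected queen persistence time T_int*(R + 1/[1-(1-e^-R)^N]).

    Monotone increasing in R and N.  At R = 0 every window activates and
    T = T_int; as R grows without bound the activation probability
    vanishes and T diverges — a +inf flag is returned (never an
    exception) once the geometric denominator underflows to zero.
    """
    if R < 0:
        raise ValueError("R must be >= 0")
    if N < 1:
        raise ValueError("N must be >= 1")
    if T_int <= 0:
        raise ValueError("T_int must be > 0")
    return _window_persistence(np.exp(-R), R, int(N), T_int)


def persistence_time_sigma(
    sigma_expr: float,
    N: int,
    T_int: float,
    R: float,
    tail: str = "exponential",
) -> float:
    """Persistence time under expression noise of scale ``sigma_expr``.

    The per-window chance-activation probability is the upper-tail mass of
    the worker expression distribution beyond the (unit) activation
    threshold: ``exp(-1/sigma)`` for exponential tails, the Gaussian upper
    tail ``sf(1/sigma)`` for normal tails.  Strictly decreasing in
    ``sigma_expr``; diverges as ``sigma_expr -> 0``.
    """
    if sigma_expr <= 0:
        raise ValueError("sigma_expr must be > 0")
    if tail == "exponential":
        p_act = float(np.exp(-1.0 / sigma_expr))
    elif tail == "normal":
        p_act = float(stats.norm.sf(1.0 / sigma_expr))
    else:
        raise ValueError(f"unknown tail family {tail!r}")
    return _window_persistence(p_act, R, int(N), T_int)


def simulate_replacement(
    params: PersistenceParams,
    replicates: int,
    seed: int,
    mode: str = "window",
    horizon_windows: int = 10_000_000,
):
    """Monte-Carlo estimate of the queen persistence time.

    Modes
    -----
    ``"window"`` (default)
        The statistical model behind the closed form: synchronous
        interaction windows of length ``T_int``; each window every worker
        independently escapes its reset with probability ``exp(-R)``
        (or the tail probability under the noise variant); the first
        window with an escape is followed by the ``R*T_int`` excursion.
    ``"poisson"`` / ``"deterministic"``
        Continuous renewal process: each worker receives queen
        interactions at gaps that are exponential (mean ``T_int``) or
        deterministic; a worker whose current gap exceeds ``R*T_int``
        becomes a challenger.  The poisson variant deviates from the
        closed form by a few percent (gap-inspection bias); the
        deterministic variant never produces a challenge for R >= 1.

    Returns
    -------
    dict with keys ``mean``, ``ci95`` (half-width of the normal 95% CI of
    the mean), ``times`` (replicate first-challenge times), ``censored``
    (replicates that hit the horizon without a challenge).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    N, R, T_int = params.N, params.R, params.T_int

    if params.tail == "exponential" and params.sigma_expr == 1.0:
        p_act = float(np.exp(-R))
    else:
        p_act = (
            float(np.exp(-1.0 / params.sigma_expr))
            if params.tail == "exponential"
            else float(stats.norm.sf(1.0 / params.sigma_expr))
        )

    times = np.empty(replicates)
    censored = 0
    if mode == "window":
        # geometric number of windows with success prob 1-(1-p)^N
        p_any = 1.0 - (1.0 - p_act) ** N
        if p_any <= 0.0:
            return {"mean": float("inf"), "ci95": float("nan"),
                    "times": np.full(replicates, np.inf), "censored": replicates}
        k = rng.geometric(p_any, size=replicates)
        over = k > horizon_windows
        censored = int(over.sum())
        k = np.minimum(k, horizon_windows)
        times = (k + R) * T_int
    elif mode in ("poisson", "deterministic"):
        c = R * T_int
        for rep in range(replicates):
            t_first = np.inf
            for _ in range(N):
                t = 0.0
                for _ in range(horizon_windows):
                    gap = rng.exponential(T_int) if mode == "poisson" else T_int
                    if gap > c:
                        t_first = min(t_first, t + c)
                        break
                    t += gap
                    if t >= t_first:
                        break
            if np.isinf(t_first):
                censored += 1
                t_first = horizon_windows * T_int
            times[rep] = t_first
    else:
        raise ValueError(f"unknown mode {mode!r}")

    mean = float(np.mean(times))
    sem = float(np.std(times, ddof=1) / np.sqrt(replicates)) if replicates > 1 else float("nan")
    return {"mean": mean, "ci95": 1.96 * sem, "times": times, "censored": censored}
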