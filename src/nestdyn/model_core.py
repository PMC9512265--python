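"""Core model of queen-gene dynamics coupled to dominance interactions.

A *Polistes* nest is modelled as ``N`` insects, each carrying a single
coarse-grained molecular state ``r`` — the concentration of queen-gene
products scaled so that the unrepressed production/degradation balance sits
at ``r = 1``.  Insects meet in dominance contests whose rate and outcome
depend on their molecular states through the interaction kernel

    K(r_i, r_j) = r_i * r_j * sigma(r_i - r_j),

the rate at which insect *i* is subject to a subdominant interaction with
insect *j*.  ``sigma`` is the dominance-discrimination function: a monotone
decreasing weight on the expression difference with steepness ``lambda``
(insects with clearly lower queen-gene expression almost always lose).

This module houses the parameter record, ``sigma``, the kernel, the
nondimensionalization of physical rates, and the derived mean-field
constants used throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "sigma_dom",
    "interaction_kernel",
    "nondimensionalize",
    "steady_mean",
    "worker_attractor",
    "queen_threshold",
    "load_params",
    "save_params",
]


@dataclass(frozen=True)
class ModelParams:
    """All kinetic and interaction parameters of the nest model.

    Scaled-units convention (the default): time is measured in units of the
    degradation time of queen-gene products (``delta = 1``) and
    concentrations are scaled by the steady-state expression level, so the
    unrepressed attractor is ``r = 1``.

    Parameters
    ----------
    N : int
        Number of insects in the nest.
    mu : float
        Production rate of queen-gene products (per unit time; equals
        ``delta`` at the scaled balance point).
    delta : float
        Degradation rate (per unit time); 1 in scaled mode.
    Gamma : float
        Decay rate of the repressed state ``q = 1 -> 0`` (full model only).
    omega : float
        Interaction rate constant in front of the kernel for repression
        flips (full model only).
    m : int
        Mean number of queen-gene products removed per subdominant
        interaction (reduced model), in molecule counts.
    alpha : float
        Per-individual interaction rate (dimensionless once time is scaled).
    lambda_asym : float
        Dominance-discrimination steepness; outcomes discriminate
        expression differences on the scale ``1/lambda_asym``.
    alpha_tilde : float
        Rescaled interaction rate of the mean-field limit.  Defaults to
        ``alpha * m / n_ss`` (the decrement expressed in concentration
        units); treated as a free parameter where ``m`` is unknown.
    n_ss : int
        Steady-state molecule count that sets the Monte-Carlo granularity
        (``r = n / n_ss``).
    """

    N: int = 16
    mu: float = 1.0
    delta: float = 1.0
    Gamma: float = 1.0
    omega: float = 10.0
    m: int = 5
    alpha: float = 4.625
    lambda_asym: float = 24.0
    alpha_tilde: float = field(default=None)  # type: ignore[assignment]
    n_ss: int = 50

    def __post_init__(self):
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        for name in ("mu", "delta", "Gamma", "omega", "alpha"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative rate, got {v}")
        if self.lambda_asym < 0:
            raise ValueError(f"lambda_asym must be >= 0, got {self.lambda_asym}")
        if self.m < 0:
            raise ValueError(f"m must be >= 0, got {self.m}")
        if self.n_ss < 1:
            raise ValueError(f"n_ss must be >= 1, got {self.n_ss}")
        if self.alpha_tilde is None:
            object.__setattr__(self, "alpha_tilde", self.alpha * self.m / self.n_ss)
        elif self.alpha_tilde < 0:
            raise ValueError(f"alpha_tilde must be >= 0, got {self.alpha_tilde}")

    @property
    def scaled(self) -> bool:
        """True when the record follows the scaled-units convention."""
        return self.delta == 1.0

    def replace(self, **kw) -> "ModelParams":
        if "alpha_tilde" not in kw and ("alpha" in kw or "m" in kw or "n_ss" in kw):
            kw["alpha_tilde"] = None
        return replace(self, **kw)


def sigma_dom(x, lambda_asym):
    """Dominance-discrimination weight ``1 / (1 + exp(lambda * x))``.

    ``x`` is the expression difference ``r_i - r_j`` of the focal
    (potentially subdominant) insect relative to its opponent.  The weight
    decreases monotonically on a scale ``1/lambda_asym`` and satisfies the
    complement identity ``sigma(x) + sigma(-x) = 1``; at ``lambda_asym = 0``
    contests are coin flips.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("expression difference must be finite")
    if lambda_asym < 0 or not np.isfinite(lambda_asym):
        raise ValueError(f"lambda_asym must be finite and >= 0, got {lambda_asym}")
    # overflow-safe logistic
    out = np.empty_like(x, dtype=float)
    z = lambda_asym * x
    pos = z >= 0
    out[pos] = np.exp(-z[pos]) / (1.0 + np.exp(-z[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(z[~pos]))
    return out if out.ndim else float(out)


def interaction_kernel(r_i, r_j, lambda_asym):
    """Rate weight ``K(r_i, r_j) = r_i * r_j * sigma(r_i - r_j)``.

    This is the rate at which insect *i* is subject to subdominant
    interactions with insect *j*; summing both directions of a pair gives
    ``r_i * r_j`` by the complement identity.
    """
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    if np.any(r_i < 0) or np.any(r_j < 0):
        raise ValueError("expression levels must be non-negative")
    out = r_i * r_j * sigma_dom(r_i - r_j, lambda_asym)
    return out if np.ndim(out) else float(out)


def nondimensionalize(
    N: int,
    mu: float,
    delta: float,
    interactions_per_day: float,
    degradation_time_hours: float | None = None,
    m: int = 5,
    n_ss: int = 50,
    lambda_asym: float = 24.0,
    Gamma: float = 10.0,
    omega: float = 1.0,
) -> ModelParams:
    """Convert physical-unit rates to the scaled parameter record.

    Time is rescaled by the degradation time ``1/delta`` and concentrations
    by the steady-state level ``mu/delta``, so the returned record has
    ``delta = 1`` and the unrepressed attractor at ``r = 1``.  The
    dimensionless per-individual interaction rate is the physical
    per-capita rate times the degradation time::

        alpha = interactions_per_day * (degradation_time / 24 h)

    e.g. 3.7 fighting interactions per day with a 30 h molecular
    degradation time gives ``alpha = 3.7 * 30/24 = 4.625``.

    Parameters in per-unit-time form (``mu``, ``delta``) must share one
    time unit; ``interactions_per_day`` is per day and
    ``degradation_time_hours`` (default ``24/delta`` treating ``delta`` as
    per-day) expresses the degradation time in hours.
    """
    if delta <= 0:
        raise ValueError(f"degradation rate must be > 0, got {delta}")
    if mu <= 0:
        raise ValueError(f"production rate must be > 0, got {mu}")
    if degradation_time_hours is None:
        degradation_time_hours = 24.0 / delta
    alpha = interactions_per_day * degradation_time_hours / 24.0
    return ModelParams(
        N=N,
        mu=1.0,
        delta=1.0,
        Gamma=Gamma / delta,
        omega=omega / delta,
        m=m,
        alpha=alpha,
        lambda_asym=lambda_asym,
        n_ss=n_ss,
    )


def steady_mean(alpha_tilde: float) -> float:
    """Mean queen-gene expression of the steady colony, (sqrt(2a+1)-1)/a.

    Fixed point of the coherent-population reduction
    ``d rbar/d tau = 1 - rbar - alpha_tilde * rbar**2 / 2`` (each colony
    member suppresses the others with the tie weight sigma(0)=1/2).
    Continuous at 0 with limit 1.
    """
    if alpha_tilde < 0:
        raise ValueError("alpha_tilde must be >= 0")
    if alpha_tilde < 1e-12:
        return 1.0
    return (math.sqrt(2.0 * alpha_tilde + 1.0) - 1.0) / alpha_tilde


def worker_attractor(alpha_tilde: float, rbar: float | None = None) -> float:
    """Worker attractor r2 = 1/(1 + alpha_tilde * rbar).

    ``rbar`` defaults to the steady colony mean.  This is the stable
    molecular state of an individual fully subdominant to the rest of the
    colony; the queen attractor is r0 = 1.
    """
    if rbar is None:
        rbar = steady_mean(alpha_tilde)
    return 1.0 / (1.0 + alpha_tilde * rbar)


def queen_threshold(alpha_tilde: float) -> float:
    """Midpoint of the queen and worker attractors, (1 + r2)/2.

    Parameter-free separatrix proxy used to call an insect "queen-like".
    Degenerates to 1 as ``alpha_tilde -> 0`` where the two attractors
    merge; callers classifying uncoupled colonies should fall back to an
    absolute threshold (half the unrepressed steady state, 0.5).
    """
    return 0.5 * (1.0 + worker_attractor(alpha_tilde))


# ---------------------------------------------------------------------------
# config round-trip

_PARAM_KEYS = {
    "N", "mu", "delta", "Gamma", "omega", "m",
    "alpha", "lambda_asym", "alpha_tilde", "n_ss",
}


def save_params(params: ModelParams, path) -> None:
    """Write a parameter record to a YAML key-value file."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(params), fh, sort_keys=True)


def load_params(path) -> ModelParams:
    """Read a parameter record from YAML; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a key-value mapping")
    unknown = set(data) - _PARAM_KEYS
    if unknown:
        raise ValueError(f"{Path(path).name}: unknown parameter keys {sorted(unknown)}")
    return ModelParams(**data)
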