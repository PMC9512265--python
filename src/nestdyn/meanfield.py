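"""Deterministic mean-field dynamics of the colony expression density.

In the limit of many insects and time scales long compared to single
interactions, the number density f(r, tau) of insects with scaled
queen-gene expression r obeys a conservative advection equation

    d_tau f + d_r [ v(r, [f]) f ] = 0,
    v(r, [f]) = (1 - r) - alpha_tilde * r * Int r' sigma(r - r') fhat(r') dr',

where fhat is f normalized to unit mass (per-capita form) and
``alpha_tilde`` is the rescaled interaction rate.  The first term is the
molecular production/degradation drift toward r = 1; the second is
colony-level repression, strongest on insects below the bulk of the
colony.

Two complementary descriptions are provided:

* :func:`evolve_density` — a first-order upwind finite-volume solver for
  the full transport equation (mass-conserving, positivity-preserving);

* the **coherent-population reduction**: when the colony remains a
  coherent peak at position rbar, its mean obeys
  ``d rbar/d tau = 1 - rbar - alpha_tilde*rbar^2/2`` (each member
  suppresses the others with the tie weight sigma(0) = 1/2), with steady
  state rbar* = (sqrt(2*alpha_tilde + 1) - 1)/alpha_tilde, while a tracer
  individual at r in this colony drifts with
  ``dr/d tau = 1 - r - alpha_tilde*r*rbar*sigma(r - rbar)``.  The tracer
  is bistable: a worker attractor r2 = 1/(1 + alpha_tilde*rbar), the
  queen attractor r0 = 1, and an unstable plastic state between them —
  the population structure acts as the bifurcation parameter of a
  saddle-node bifurcation.

At strong discrimination (large lambda) the coherent peak of the full PDE
is linearly unstable to rank-ordered spreading (insects above the peak
escape suppression); the reduction is then the faithful description of
the paper-wasp phase-space structure, while the PDE develops a spread
worker band.  See docs/methods.md for the stability analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model_core import ModelParams, sigma_dom, steady_mean

__all__ = [
    "PopulationDensity",
    "gaussian_density",
    "drift_velocity",
    "evolve_density",
    "tracer_velocity",
    "colony_mean_velocity",
    "phase_portrait",
    "find_separatrix",
    "perturb_and_classify",
    "bifurcation_diagram",
]


@dataclass
class PopulationDensity:
    """Density of insects on the expression axis.

    ``edges``: strictly increasing cell edges on [0, r_max];
    ``f``: non-negative density per cell (individuals per unit r);
    ``tau``: current scaled time.
    """

    edges: np.ndarray
    f: np.ndarray
    tau: float = 0.0

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("grid edges must be strictly increasing")
        if self.f.shape != (self.edges.size - 1,):
            raise ValueError("f must have one value per grid cell")
        if np.any(self.f < 0):
            raise ValueError("density must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def mass(self) -> float:
        return float(np.sum(self.f * self.widths))

    @property
    def mean_r(self) -> float:
        """Mass-weighted mean expression rbar."""
        m = self.mass
        if m == 0:
            return float("nan")
        return float(np.sum(self.centers * self.f * self.widths) / m)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"r": self.centers, "f": self.f})


def gaussian_density(
    center: float, mass: float = 1.0, r_max: float = 1.5, n_cells: int = 400,
    width_cells: float = 2.0,
) -> PopulationDensity:
    """Narrow Gaussian peak standing in for a delta-like colony."""
    edges = np.linspace(0.0, r_max, n_cells + 1)
    c = 0.5 * (edges[:-1] + edges[1:])
    w = width_cells * (r_max / n_cells)
    f = np.exp(-0.5 * ((c - center) / w) ** 2)
    f *= mass / np.sum(f * np.diff(edges))
    return PopulationDensity(edges=edges, f=f)


def drift_velocity(r, density: PopulationDensity, alpha_tilde: float, lambda_asym: float):
    """Per-capita drift v(r) = (1-r) - alpha_tilde * r * <r' sigma(r-r')>.

    The angle bracket is the mass-normalized integral over ``density``;
    an empty colony leaves only the molecular drift 1 - r.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    if np.any(density.f < 0):
        raise ValueError("density must be non-negative")
    m = density.mass
    if m == 0:
        out = 1.0 - r
    else:
        c = density.centers
        wts = density.f * density.widths / m
        # suppression integral for every query point
        sig = sigma_dom(r[:, None] - c[None, :], lambda_asym)
        supp = (sig * (c * wts)[None, :]).sum(axis=1)
        out = (1.0 - r) - alpha_tilde * r * supp
    return out if out.size > 1 else float(out[0])


def evolve_density(
    density: PopulationDensity,
    params: ModelParams | float,
    duration: float,
    lambda_asym: float | None = None,
    cfl: float = 0.5,
    n_snapshots: int = 10,
    refresh_every: int = 8,
):
    """Advect the density under its own drift field (upwind finite volume).

    ``params`` may be a ModelParams record (using its alpha_tilde and
    lambda_asym) or a bare alpha_tilde float with ``lambda_asym`` given
    separately.  Mass is conserved to round-off (zero-flux boundaries; the
    drift points inward at both ends of [0, r_max] for r_max > 1).
    Returns a list of PopulationDensity snapshots (including initial and
    final states).
    """
    if isinstance(params, ModelParams):
        at, lam = params.alpha_tilde, params.lambda_asym
    else:
        at = float(params)
        if lambda_asym is None:
            raise ValueError("lambda_asym required when passing bare alpha_tilde")
        lam = float(lambda_asym)
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if density.mass <= 0:
        raise ValueError("initial mass must be > 0")

    edges = density.edges
    c = density.centers
    dx = density.widths
    f = density.f.copy()
    m_tot = density.mass

    # suppression weight matrix: faces x cells
    faces = edges
    sig_fc = sigma_dom(faces[:, None] - c[None, :], lam)
    cw = c * dx  # cell weight for the integral (times f)

    snap_times = np.linspace(0.0, duration, max(2, n_snapshots))
    snaps = [PopulationDensity(edges=edges.copy(), f=f.copy(), tau=density.tau)]
    t = 0.0
    dx_min = dx.min()
    next_snap = 1
    step = 0
    v = None
    while t < duration - 1e-12:
        if step % refresh_every == 0 or v is None:
            # the interaction integral varies on the advective time scale,
            # far slower than a CFL step; refresh it every few steps
            supp = sig_fc @ (cw * f) / m_tot
            v = (1.0 - faces) - at * faces * supp  # velocity at faces
            vp = np.maximum(v[1:-1], 0.0)
            vm = np.minimum(v[1:-1], 0.0)
            vmax = np.max(np.abs(v)) + 1e-12
        dt = min(cfl * dx_min / vmax, duration - t)
        # upwind flux at interior faces; boundary fluxes stay zero
        flux = np.zeros_like(faces)
        flux[1:-1] = vp * f[:-1] + vm * f[1:]
        f = f - dt * np.diff(flux) / dx
        np.maximum(f, 0.0, out=f)
        step += 1
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(
                f"density solver produced non-finite values at tau={t:.4f} "
                f"(alpha_tilde={at}, lambda={lam})"
            )
        t += dt
        while next_snap < len(snap_times) and t >= snap_times[next_snap] - 1e-12:
            snaps.append(PopulationDensity(edges=edges.copy(), f=f.copy(),
                                           tau=density.tau + snap_times[next_snap]))
            next_snap += 1
    while next_snap < len(snap_times):
        snaps.append(PopulationDensity(edges=edges.copy(), f=f.copy(),
                                       tau=density.tau + snap_times[next_snap]))
        next_snap += 1
    return snaps


# ---------------------------------------------------------------------------
# coherent-population reduction: (rbar, r) dynamics


def colony_mean_velocity(rbar, alpha_tilde: float):
    """d rbar/d tau = 1 - rbar - alpha_tilde * rbar^2 / 2 for a coherent colony."""
    rbar = np.asarray(rbar, dtype=float)
    return 1.0 - rbar - 0.5 * alpha_tilde * rbar**2


def tracer_velocity(r, rbar, alpha_tilde: float, lambda_asym: float):
    """Drift of a single tracer insect in a coherent colony at rbar."""
    r = np.asarray(r, dtype=float)
    return (1.0 - r) - alpha_tilde * r * np.asarray(rbar) * sigma_dom(
        np.asarray(r) - np.asarray(rbar), lambda_asym
    )


def tracer_fixed_points(rbar: float, alpha_tilde: float, lambda_asym: float,
                        r_max: float = 1.5, n_scan: int = 3000):
    """All tracer fixed points in a frozen colony, with stability labels.

    Scans ``v(r)`` for sign changes and polishes each root by bisection.
    Returns a list of (r_root, stable) sorted by r.
    """
    rs = np.linspace(1e-9, r_max, n_scan)
    v = tracer_velocity(rs, rbar, alpha_tilde, lambda_asym)
    roots = []
    for k in range(n_scan - 1):
        if v[k] == 0.0:
            roots.append(rs[k])
        elif v[k] * v[k + 1] < 0:
            roots.append(brentq(
                lambda x: tracer_velocity(x, rbar, alpha_tilde, lambda_asym),
                rs[k], rs[k + 1], xtol=1e-12,
            ))
    out = []
    eps = 1e-6
    for root in roots:
        vm = tracer_velocity(max(root - eps, 0.0), rbar, alpha_tilde, lambda_asym)
        vp = tracer_velocity(root + eps, rbar, alpha_tilde, lambda_asym)
        out.append((float(root), bool(vm > 0 > vp)))
    return sorted(out)


def find_separatrix(rbar: float, alpha_tilde: float, lambda_asym: float,
                    horizon: float = 60.0, tol: float = 1e-6):
    """Tracer-fate separatrix in a frozen colony, located by bisection.

    Returns the boundary r* between convergence to the worker and the
    queen attractor, or a dict flagging failure when the tracer dynamics
    are monostable (no fold for this colony structure).
    """
    fps = tracer_fixed_points(rbar, alpha_tilde, lambda_asym)
    stable = [r for r, s in fps if s]
    unstable = [r for r, s in fps if not s]
    if len(stable) < 2 or not unstable:
        return {"converged": False, "separatrix": None, "fixed_points": fps}

    lo, hi = stable[0], stable[-1]

    def fate(r0: float) -> bool:  # True -> queen branch
        sol = solve_ivp(
            lambda _, y: tracer_velocity(y, rbar, alpha_tilde, lambda_asym),
            (0.0, horizon), [r0], rtol=1e-8, atol=1e-10,
        )
        rf = sol.y[0, -1]
        return abs(rf - hi) < abs(rf - lo)

    a, b = lo, hi
    while b - a > tol:
        mid = 0.5 * (a + b)
        if fate(mid):
            b = mid
        else:
            a = mid
    return {"converged": True, "separatrix": 0.5 * (a + b), "fixed_points": fps}


def phase_portrait(
    alpha_tilde: float,
    lambda_asym: float,
    rbar_grid=None,
    r_grid=None,
    tracers=(),
    horizon: float = 30.0,
):
    """Joint (rbar, r) vector field with tracer trajectories and separatrix.

    Arrows are (d rbar/d tau, d r/d tau) on a grid; ``tracers`` is an
    iterable of (r0, rbar0) initial conditions integrated under the
    coupled reduction.  The separatrix is computed in the steady colony.
    """
    if rbar_grid is None:
        rbar_grid = np.linspace(0.05, 1.2, 24)
    if r_grid is None:
        r_grid = np.linspace(0.0, 1.2, 25)
    RB, R = np.meshgrid(np.asarray(rbar_grid), np.asarray(r_grid))
    U = colony_mean_velocity(RB, alpha_tilde)
    V = tracer_velocity(R, RB, alpha_tilde, lambda_asym)

    trajs = []
    for r0, rb0 in tracers:
        sol = solve_ivp(
            lambda _, y: [
                float(tracer_velocity(y[0], y[1], alpha_tilde, lambda_asym)),
                float(colony_mean_velocity(y[1], alpha_tilde)),
            ],
            (0.0, horizon), [r0, rb0], rtol=1e-8, atol=1e-10, dense_output=True,
        )
        ts = np.linspace(0.0, horizon, 400)
        ys = sol.sol(ts)
        trajs.append({"t": ts, "r": ys[0], "rbar": ys[1]})

    rbar_star = steady_mean(alpha_tilde)
    sep = find_separatrix(rbar_star, alpha_tilde, lambda_asym)
    return {
        "rbar_grid": RB,
        "r_grid": R,
        "drbar": U,
        "dr": V,
        "tracers": trajs,
        "rbar_steady": rbar_star,
        "separatrix": sep,
    }


def perturb_and_classify(
    alpha_tilde: float,
    lambda_asym: float,
    mode: str,
    magnitude: float,
    branch: str = "worker",
    horizon: float = 80.0,
):
    """Response of a steady colony to an intrinsic or extrinsic perturbation.

    intrinsic
        One tracer insect is displaced by ``magnitude`` along r with the
        colony structure frozen at its steady state; classified
        ``suppressed`` if it relaxes back to its original branch,
        ``reprogrammed`` if it crosses to the other one.
    extrinsic
        The colony as a whole (and the tracer with it) is displaced
        coherently by ``-magnitude`` (queen-removal analogue: the
        population structure drops); colony and tracer then co-evolve.
        Classified ``reprogrammed`` if the tracer ends on the queen
        branch after passing near the plastic (separatrix) state.

    Returns a dict with ``outcome`` in {"suppressed", "reprogrammed"},
    the trajectory, and the relevant fixed points.
    """
    if mode not in ("intrinsic", "extrinsic"):
        raise ValueError(f"unknown perturbation mode {mode!r}")
    rbar_star = steady_mean(alpha_tilde)
    fps = tracer_fixed_points(rbar_star, alpha_tilde, lambda_asym)
    stable = [r for r, s in fps if s]
    r_worker = stable[0]
    r_queen = stable[-1]
    r0 = r_worker if branch == "worker" else r_queen

    if mode == "intrinsic":
        start = r0 + magnitude
        if start < 0:
            raise ValueError("perturbation would produce negative expression")
        sol = solve_ivp(
            lambda _, y: tracer_velocity(y, rbar_star, alpha_tilde, lambda_asym),
            (0.0, horizon), [start], rtol=1e-8, atol=1e-10, dense_output=True,
        )
        rf = float(sol.y[0, -1])
        same = abs(rf - r0) < abs(rf - (r_queen if r0 == r_worker else r_worker))
        outcome = "suppressed" if same else "reprogrammed"
        traj = {"t": sol.t, "r": sol.y[0], "rbar": np.full_like(sol.t, rbar_star)}
    else:
        # diagonal displacement: the population structure drops by
        # `magnitude` (queen-mode mass removed) and the tracer is carried
        # with it — once the structure falls to the tracer's own level the
        # tracer is part of the coherent queenless colony
        start_rb = max(rbar_star - magnitude, 1e-6)
        start_r = min(r0, start_rb)
        sol = solve_ivp(
            lambda _, y: [
                float(tracer_velocity(y[0], y[1], alpha_tilde, lambda_asym)),
                float(colony_mean_velocity(y[1], alpha_tilde)),
            ],
            (0.0, horizon), [start_r, start_rb], rtol=1e-8, atol=1e-10,
        )
        rf = float(sol.y[0, -1])
        # after a coherent drop the colony re-converges to rbar*; a tracer
        # that rides it up to the plastic state (rather than falling back
        # to the worker attractor) has regained queen potential
        outcome = "reprogrammed" if rf > 0.5 * (r_worker + rbar_star) else "suppressed"
        traj = {"t": sol.t, "r": sol.y[0], "rbar": sol.y[1]}
    return {
        "outcome": outcome,
        "trajectory": traj,
        "fixed_points": fps,
        "rbar_steady": rbar_star,
        "final_r": rf,
    }


def bifurcation_diagram(
    alpha_tilde: float,
    lambda_asym: float,
    rbar_grid=None,
    r_max: float = 1.5,
):
    """Tracer fixed points versus the frozen population structure rbar.

    Sweeps the colony mean rbar (the functional bifurcation parameter),
    root-tracking all tracer fixed points; returns tidy arrays of
    (rbar, r, stable) plus the located fold (saddle-node) point where the
    worker and plastic branches annihilate, or ``fold=None`` when no fold
    lies in range.
    """
    if rbar_grid is None:
        rbar_grid = np.linspace(0.01, 1.2, 240)
    rbar_grid = np.asarray(rbar_grid, dtype=float)
    rows = []
    counts = []
    for rb in rbar_grid:
        fps = tracer_fixed_points(rb, alpha_tilde, lambda_asym, r_max=r_max)
        counts.append(len(fps))
        for r, s in fps:
            rows.append((rb, r, s))
    rows = np.array(rows, dtype=object)
    counts = np.asarray(counts)

    fold = None
    jumps = np.where(np.diff(counts) != 0)[0]
    if jumps.size:
        k = jumps[0]
        lo, hi = rbar_grid[k], rbar_grid[k + 1]
        n_lo = counts[k]
        for _ in range(60):  # bisect the root-count change
            mid = 0.5 * (lo + hi)
            n_mid = len(tracer_fixed_points(mid, alpha_tilde, lambda_asym, r_max=r_max))
            if n_mid == n_lo:
                lo = mid
            else:
                hi = mid
        fold_rbar = 0.5 * (lo + hi)
        fps = tracer_fixed_points(hi, alpha_tilde, lambda_asym, r_max=r_max)
        # the colliding pair are the two lowest roots on the 3-root side
        if len(fps) >= 3:
            fold_r = 0.5 * (fps[0][0] + fps[1][0])
        else:
            fold_r = fps[0][0]
        fold = {"rbar": float(fold_rbar), "r": float(fold_r)}

    return {
        "rbar": np.array([x[0] for x in rows], dtype=float),
        "r": np.array([x[1] for x in rows], dtype=float),
        "stable": np.array([x[2] for x in rows], dtype=bool),
        "fold": fold,
    }
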