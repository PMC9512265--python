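"""Event-driven stochastic simulation of the whole nest.

Two levels of description are simulated exactly with Gillespie's algorithm:

* the **reduced model**: each insect carries a molecule count ``n_i``
  (``r_i = n_i / n_ss``); production at rate ``n_ss`` and degradation at
  rate ``n_i`` (scaled time) realize the molecular birth-death balance at
  ``r = 1``, and a subdominant interaction of ``i`` with ``j`` — at rate
  ``alpha * K(r_i, r_j)`` — removes ``m`` molecules from the loser;

* the **full model**: insects additionally carry a repression flag
  ``q_i``; production runs at ``mu * (1 - q_i)``, degradation at
  ``delta * n_i``, repression decays ``1 -> 0`` at rate ``Gamma``, and an
  interaction flips ``q_i: 0 -> 1`` at rate ``omega * sum_j K_ij``.  In
  the limit of fast repression cycles (large ``Gamma``) the full model
  reduces to the reduced one with ``m ~ mu/Gamma``.

Pairwise interaction channels are sampled via the complement identity
``K(i,j) + K(j,i) = r_i r_j``: an unordered pair is drawn with probability
proportional to ``r_i r_j`` (total rate ``alpha*(S^2 - Q)/2`` with
``S = sum r``, ``Q = sum r^2``) and the subdominant member is then chosen
with probability ``sigma(r_i - r_j)`` — an exact decomposition, not an
approximation.

On top of the simulators sit the social-structure classifier, the
(alpha, lambda) phase diagram, and the queen-removal experiment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from numba import njit

from .model_core import ModelParams, queen_threshold

__all__ = [
    "NestTrajectory",
    "simulate_reduced",
    "simulate_full",
    "classify_social_structure",
    "phase_diagram",
    "queen_removal_experiment",
    "effective_alpha_tilde",
]


@dataclass
class NestTrajectory:
    """Sampled per-insect states and interaction events of one realization.

    ``times`` are the regular sample times; ``n`` (and ``q`` for the full
    model) are (time, insect) arrays of molecule counts; ``r = n/n_ss``.
    ``events`` is an (n_events, 3) float array of
    (time, dominant id, subdominant id).
    """

    times: np.ndarray
    n: np.ndarray
    params: ModelParams
    seed: int
    events: np.ndarray
    q: np.ndarray | None = None

    @property
    def r(self) -> np.ndarray:
        return self.n / self.params.n_ss

    def mean_r(self, window: float = 5.0) -> np.ndarray:
        """Per-insect time-average of r over the trailing ``window``."""
        t_end = self.times[-1]
        sel = self.times >= t_end - window
        return self.r[sel].mean(axis=0)

    def to_frame(self):
        """Long-format table (time, insect, n, q, r)."""
        import pandas as pd

        T, N = self.n.shape
        q = self.q if self.q is not None else np.zeros_like(self.n)
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, N),
                "insect": np.tile(np.arange(N), T),
                "n": self.n.ravel(),
                "q": q.ravel(),
                "r": self.r.ravel(),
            }
        )

    def events_frame(self):
        import pandas as pd

        return pd.DataFrame(self.events, columns=["time", "dominant", "subdominant"]).astype(
            {"dominant": int, "subdominant": int}
        )


def effective_alpha_tilde(params: ModelParams) -> float:
    """Mean-field coupling matched to a finite nest.

    A focal insect is suppressed by its N-1 nest mates, so the coupling
    appearing in the one-body description is alpha * m * (N-1) / n_ss.
    """
    return params.alpha * params.m * (params.N - 1) / params.n_ss


# ---------------------------------------------------------------------------
# numba cores


@njit(cache=True)
def _pick_weighted(w, total, u):
    # linear scan; N is small
    acc = 0.0
    target = u * total
    for i in range(w.shape[0]):
        acc += w[i]
        if acc >= target:
            return i
    return w.shape[0] - 1


@njit(cache=True)
def _sigma(x, lam):
    z = lam * x
    if z > 50.0:
        return 0.0
    if z < -50.0:
        return 1.0
    return 1.0 / (1.0 + np.exp(z))


@njit(cache=True)
def _core_reduced(n0, n_ss, alpha, lam, m, horizon, sample_dt, seed, max_events):
    np.random.seed(seed)
    N = n0.shape[0]
    n = n0.astype(np.float64).copy()
    r = n / n_ss
    S = r.sum()
    Q = (r * r).sum()

    n_samp = int(np.floor(horizon / sample_dt)) + 1
    samples = np.zeros((n_samp, N))
    ev_t = np.empty(max_events)
    ev_dom = np.empty(max_events, dtype=np.int64)
    ev_sub = np.empty(max_events, dtype=np.int64)
    n_ev = 0

    t = 0.0
    isamp = 0
    samples[0] = n
    isamp = 1
    steps = 0
    while True:
        a_prod = N * n_ss
        a_deg = n.sum()
        pair_sum = 0.5 * (S * S - Q)
        a_int = alpha * pair_sum if pair_sum > 0.0 else 0.0
        a_tot = a_prod + a_deg + a_int
        dt = np.random.exponential(1.0 / a_tot)
        t_new = t + dt
        while isamp < n_samp and isamp * sample_dt <= t_new:
            samples[isamp] = n
            isamp += 1
        if t_new >= horizon:
            break
        t = t_new
        u = np.random.random() * a_tot
        if u < a_prod:
            i = int(np.random.random() * N)
            if i == N:
                i = N - 1
            n[i] += 1.0
        elif u < a_prod + a_deg:
            i = _pick_weighted(n, a_deg, np.random.random())
            n[i] -= 1.0
        else:
            # unordered pair ~ r_i r_j via two independent draws, reject i==j
            while True:
                i = _pick_weighted(r, S, np.random.random())
                j = _pick_weighted(r, S, np.random.random())
                if i != j:
                    break
            if np.random.random() < _sigma(r[i] - r[j], lam):
                sub, dom = i, j
            else:
                sub, dom = j, i
            n[sub] = max(0.0, n[sub] - m)
            i = sub
            if n_ev < max_events:
                ev_t[n_ev] = t
                ev_dom[n_ev] = dom
                ev_sub[n_ev] = sub
                n_ev += 1
        # incremental update of S, Q with periodic refresh against drift
        r_i_old = r[i]
        r[i] = n[i] / n_ss
        S += r[i] - r_i_old
        Q += r[i] * r[i] - r_i_old * r_i_old
        steps += 1
        if steps % 16384 == 0:
            S = r.sum()
            Q = (r * r).sum()
    while isamp < n_samp:
        samples[isamp] = n
        isamp += 1
    return samples, ev_t[:n_ev], ev_dom[:n_ev], ev_sub[:n_ev]


@njit(cache=True)
def _core_full(n0, q0, n_ss, mu, delta, Gamma, omega, lam, horizon, sample_dt, seed, max_events):
    np.random.seed(seed)
    N = n0.shape[0]
    n = n0.astype(np.float64).copy()
    q = q0.astype(np.float64).copy()
    r = n / n_ss
    S = r.sum()
    Q2 = (r * r).sum()

    n_samp = int(np.floor(horizon / sample_dt)) + 1
    samples_n = np.zeros((n_samp, N))
    samples_q = np.zeros((n_samp, N))
    ev_t = np.empty(max_events)
    ev_dom = np.empty(max_events, dtype=np.int64)
    ev_sub = np.empty(max_events, dtype=np.int64)
    n_ev = 0

    t = 0.0
    samples_n[0] = n
    samples_q[0] = q
    isamp = 1
    steps = 0
    while True:
        n_active = N - q.sum()
        a_prod = mu * n_active
        a_deg = delta * n.sum()
        a_gam = Gamma * q.sum()
        pair_sum = 0.5 * (S * S - Q2)
        a_int = omega * pair_sum if pair_sum > 0.0 else 0.0  # thinning bound
        a_tot = a_prod + a_deg + a_gam + a_int
        if a_tot <= 0.0:
            t = horizon
            break
        dt = np.random.exponential(1.0 / a_tot)
        t_new = t + dt
        while isamp < n_samp and isamp * sample_dt <= t_new:
            samples_n[isamp] = n
            samples_q[isamp] = q
            isamp += 1
        if t_new >= horizon:
            break
        t = t_new
        u = np.random.random() * a_tot
        i = -1
        if u < a_prod:
            w = (1.0 - q)
            i = _pick_weighted(w, n_active, np.random.random())
            n[i] += 1.0
        elif u < a_prod + a_deg:
            i = _pick_weighted(n, n.sum(), np.random.random())
            n[i] -= 1.0
        elif u < a_prod + a_deg + a_gam:
            i = _pick_weighted(q, q.sum(), np.random.random())
            q[i] = 0.0
        else:
            while True:
                a = _pick_weighted(r, S, np.random.random())
                b = _pick_weighted(r, S, np.random.random())
                if a != b:
                    break
            if np.random.random() < _sigma(r[a] - r[b], lam):
                sub, dom = a, b
            else:
                sub, dom = b, a
            # every pair encounter is a fight and is logged; the repression
            # flip applies only to unrepressed losers (exact thinning of
            # the state update, not of the encounter process)
            if q[sub] == 0.0:
                q[sub] = 1.0
            if n_ev < max_events:
                ev_t[n_ev] = t
                ev_dom[n_ev] = dom
                ev_sub[n_ev] = sub
                n_ev += 1
        if i >= 0:
            r_old = r[i]
            r[i] = n[i] / n_ss
            S += r[i] - r_old
            Q2 += r[i] * r[i] - r_old * r_old
        steps += 1
        if steps % 16384 == 0:
            S = r.sum()
            Q2 = (r * r).sum()
    while isamp < n_samp:
        samples_n[isamp] = n
        samples_q[isamp] = q
        isamp += 1
    return samples_n, samples_q, ev_t[:n_ev], ev_dom[:n_ev], ev_sub[:n_ev]


# ---------------------------------------------------------------------------
# public simulators


def _check_sim_args(params: ModelParams, horizon: float):
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if params.N < 1:
        raise ValueError("N must be >= 1")


def simulate_reduced(
    params: ModelParams,
    r0,
    horizon: float,
    seed: int,
    sample_dt: float = 0.1,
    max_events: int = 2_000_000,
) -> NestTrajectory:
    """Exact Gillespie simulation of the reduced (molecule-count) model.

    ``r0`` gives initial scaled expression per insect (scalar or length-N);
    counts start at ``round(r0 * n_ss)``.  Reproducible: identical
    (params, seed) give identical trajectories.
    """
    _check_sim_args(params, horizon)
    if not params.scaled:
        raise ValueError("simulate_reduced expects scaled parameters (delta == 1)")
    r0 = np.broadcast_to(np.asarray(r0, dtype=float), (params.N,))
    if np.any(r0 < 0):
        raise ValueError("initial expression must be non-negative")
    n0 = np.rint(r0 * params.n_ss).astype(np.int64)
    samples, ev_t, ev_dom, ev_sub = _core_reduced(
        n0, float(params.n_ss), params.alpha, params.lambda_asym,
        float(params.m), float(horizon), float(sample_dt), int(seed) & 0x7FFFFFFF,
        int(max_events),
    )
    times = np.arange(samples.shape[0]) * sample_dt
    events = np.column_stack([ev_t, ev_dom, ev_sub]) if len(ev_t) else np.empty((0, 3))
    return NestTrajectory(times=times, n=samples, params=params, seed=seed, events=events)


def simulate_full(
    params: ModelParams,
    r0,
    horizon: float,
    seed: int,
    q0=None,
    sample_dt: float = 0.1,
    max_events: int = 2_000_000,
) -> NestTrajectory:
    """Exact Gillespie simulation of the full (n, q) master-equation model.

    Channels: production ``mu*(1-q_i)``, degradation ``delta*n_i``,
    repression decay ``Gamma`` per repressed insect, and repression flips
    ``q_i: 0 -> 1`` at rate ``omega * sum_j K_ij`` (implemented by exact
    thinning of the pair process).
    """
    _check_sim_args(params, horizon)
    r0 = np.broadcast_to(np.asarray(r0, dtype=float), (params.N,))
    if np.any(r0 < 0):
        raise ValueError("initial expression must be non-negative")
    n0 = np.rint(r0 * params.n_ss).astype(np.int64)
    if q0 is None:
        q0 = np.zeros(params.N, dtype=np.int64)
    else:
        q0 = np.asarray(q0, dtype=np.int64)
        if q0.shape != (params.N,) or np.any((q0 != 0) & (q0 != 1)):
            raise ValueError("q0 must be a length-N 0/1 vector")
    mu_counts = params.mu * params.n_ss if params.scaled else params.mu
    samples_n, samples_q, ev_t, ev_dom, ev_sub = _core_full(
        n0, q0, float(params.n_ss), float(mu_counts), float(params.delta),
        float(params.Gamma), float(params.omega), params.lambda_asym,
        float(horizon), float(sample_dt), int(seed) & 0x7FFFFFFF, int(max_events),
    )
    times = np.arange(samples_n.shape[0]) * sample_dt
    events = np.column_stack([ev_t, ev_dom, ev_sub]) if len(ev_t) else np.empty((0, 3))
    return NestTrajectory(
        times=times, n=samples_n, params=params, seed=seed, events=events, q=samples_q
    )


# ---------------------------------------------------------------------------
# social structure


def classify_social_structure(snapshot, threshold: float) -> str:
    """Classify a per-insect expression snapshot into a social structure.

    Counts insects with ``r`` above ``threshold``: none -> ``no-queen``;
    one -> ``single-queen``; several but not all -> ``multiple-queen``;
    all -> ``all-queen``.
    """
    snapshot = np.asarray(snapshot, dtype=float)
    if snapshot.size == 0:
        raise ValueError("snapshot must be non-empty")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    k = int(np.sum(snapshot > threshold))
    if k == 0:
        return "no-queen"
    if k == snapshot.size:
        return "all-queen"
    if k == 1:
        return "single-queen"
    return "multiple-queen"


def _cell_threshold(params: ModelParams) -> float:
    """Per-cell queen threshold: attractor midpoint, absolute floor 0.5.

    The midpoint degenerates to 1 as the coupling vanishes; uncoupled
    colonies are classified against half the unrepressed steady state.
    """
    at = effective_alpha_tilde(params)
    thr = queen_threshold(at)
    return min(thr, 0.95) if at > 0 else 0.5


def phase_diagram(
    alpha_grid,
    lambda_grid,
    replicates: int,
    params: ModelParams,
    seed: int,
    horizon: float = 60.0,
    r_start: float = 0.2,
    avg_window: float = 10.0,
    threshold: float | None = None,
):
    """Modal social structure over an (alpha, lambda) grid.

    Each cell runs ``replicates`` reduced-model simulations from a
    worker-like start and classifies the trailing time-averaged expression
    profile.  Returns a dict with the modal class per cell and the
    per-class frequencies.  ``threshold`` of None uses the per-cell
    attractor midpoint (floored at 0.5 for vanishing coupling).
    """
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if alpha_grid.size == 0 or lambda_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(alpha_grid.size * lambda_grid.size * replicates) & 0x7FFFFFFF
    modal = np.empty((lambda_grid.size, alpha_grid.size), dtype=object)
    freqs = np.empty_like(modal)
    idx = 0
    for il, lam in enumerate(lambda_grid):
        for ia, alpha in enumerate(alpha_grid):
            p = params.replace(alpha=float(alpha), lambda_asym=float(lam))
            thr = threshold if threshold is not None else _cell_threshold(p)
            labels = []
            for _ in range(replicates):
                traj = simulate_reduced(p, r_start, horizon, int(child[idx]),
                                        sample_dt=0.5, max_events=500_000)
                labels.append(classify_social_structure(traj.mean_r(avg_window), thr))
                idx += 1
            counts = Counter(labels)
            modal[il, ia] = counts.most_common(1)[0][0]
            freqs[il, ia] = {k: v / replicates for k, v in counts.items()}
    return {
        "alpha": alpha_grid,
        "lambda": lambda_grid,
        "modal": modal,
        "frequencies": freqs,
    }


# ---------------------------------------------------------------------------
# queen removal


def queen_removal_experiment(
    params: ModelParams,
    seed: int,
    settle_horizon: float = 40.0,
    post_horizon: float = 40.0,
    window: float = 5.0,
    threshold: float | None = None,
    initial_r=None,
    model: str = "full",
    release_repression: bool = True,
):
    """Remove the top individual from a settled nest and track the response.

    A nest is first simulated from a worker-like start (or ``initial_r``)
    until it settles; at t=0 the insect with the highest trailing-average
    expression is removed, and the remaining N-1 insects are simulated on.

    ``model="full"`` (default) runs the (n, q) master-equation model.
    With ``release_repression=True`` the workers' repression states are
    cleared at the removal: the queen's dominance is what maintains the
    repressed state of her nest mates, so her loss releases the colony
    from repression and the nest relaxes from a queenless, unrepressed,
    low-expression configuration — the collective upregulation transient,
    during which fighting activity surges before dominance re-establishes
    order.  With ``release_repression=False`` (or ``model="reduced"``,
    where suppression is instantaneous) workers keep policing each other
    through the removal and only the structural reorganization (a new
    queen) is seen, without the surge.

    Returns a dict with the pre/post trajectories, windowed interaction
    rates per capita (activity proxy), the egg-layer count series (insects
    above the queen threshold), the replacement time (first time a unique
    insect is above threshold and stays there to the end), and a
    ``reprogrammed`` flag.
    """
    if params.N < 2:
        raise ValueError("queen removal needs at least 2 insects")
    if model not in ("full", "reduced"):
        raise ValueError(f"unknown model {model!r}")
    thr = threshold if threshold is not None else _cell_threshold(params)
    ss = np.random.SeedSequence(seed)
    s_pre, s_post = (int(x) & 0x7FFFFFFF for x in ss.generate_state(2))
    start = 0.2 if initial_r is None else initial_r
    simulate = simulate_full if model == "full" else simulate_reduced
    pre = simulate(params, start, settle_horizon, s_pre, sample_dt=0.1)
    mean_pre = pre.mean_r(window)
    queen = int(np.argmax(mean_pre))
    keep = np.arange(params.N) != queen
    r_after = pre.r[-1][keep]
    p_post = params.replace(N=params.N - 1)
    if model == "full":
        if release_repression:
            q_after = np.zeros(params.N - 1, dtype=np.int64)
        else:
            q_after = (pre.q[-1][keep]).astype(np.int64)
        post = simulate_full(p_post, r_after, post_horizon, s_post,
                             q0=q_after, sample_dt=0.1)
    else:
        post = simulate_reduced(p_post, r_after, post_horizon, s_post, sample_dt=0.1)

    def _windowed_rate(traj, t0, t1):
        edges = np.arange(t0, t1 + 1e-9, window)
        counts, _ = np.histogram(traj.events[:, 0], bins=edges)
        return counts / window / traj.params.N

    # activity proxy: interaction events per unit time per insect
    act_pre = _windowed_rate(pre, max(0.0, settle_horizon - 4 * window), settle_horizon)
    act_post = _windowed_rate(post, 0.0, min(4 * window, post_horizon))

    # egg-layer counts on window-averaged expression: the molecular state
    # relevant for oogenesis integrates over many production/degradation
    # events, so instantaneous shot noise is smoothed out
    from scipy.ndimage import uniform_filter1d

    dt = float(post.times[1] - post.times[0]) if len(post.times) > 1 else 1.0
    k = max(1, int(round(window / dt)))
    smoothed = uniform_filter1d(post.r, size=k, axis=0, mode="nearest")
    egg_layers = (smoothed > thr).sum(axis=1)
    stable = egg_layers == 1
    replacement_time = np.nan
    run = np.where(~stable)[0]
    first = 0 if run.size == 0 else run[-1] + 1
    if first < stable.size and post.times[-1] - post.times[first] >= window:
        replacement_time = float(post.times[first])
    reprogrammed = bool(np.isfinite(replacement_time)) or bool(stable[-1])
    return {
        "pre": pre,
        "post": post,
        "queen": queen,
        "threshold": thr,
        "activity_pre": act_pre,
        "activity_post": act_post,
        "egg_layers": egg_layers,
        "egg_layer_times": post.times,
        "replacement_time": replacement_time,
        "reprogrammed": reprogrammed,
    }
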