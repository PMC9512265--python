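"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the queen-removal study design: a nest of ~16
insects observed through five phases (an unmanipulated control, a
queenless eggless phase after queen removal, and D1/D4/D14 anchored on
the reappearance of egg laying), with

* dominance asymmetry concentrated on the single queen in control nests
  (she wins fights at 1 - epsilon, epsilon set by the discrimination
  steepness across the queen-worker expression gap),
* elevated, symmetric fighting in the queenless eggless phase,
* collective queen-gene upregulation at D4 in all individuals,
* per-gene expression noise decreasing with gene-body methylation,
* ovary size increasing with an individual's queen-gene score.

Every generator exposes its ground-truth parameters so downstream
estimators can be tested as parameter-recovery problems, and a fixed
seed yields byte-identical outputs (one global seed fans out to
independent per-generator substreams).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import sigma_dom
from .observables import ExpressionTable, PHASES

__all__ = ["NestScenario", "generate_events", "generate_expression", "generate_frames"]


@dataclass(frozen=True)
class NestScenario:
    """Ground-truth description of one synthetic nest.

    Durations are observation-window lengths in hours per phase (video
    recordings of ~45 min per phase in the study; lengthen for
    estimator-recovery work).  ``fight_rate_per_day`` is the per-capita
    daily subdominant-interaction rate in control nests;
    ``eggless_fight_factor`` multiplies it during the queenless phase.
    ``queen_lfc`` is the queen-gene log-fold upregulation of queens over
    workers (control) and of everyone at D4;
    ``methylation_noise_slope`` sets how strongly per-gene noise decays
    with methylation (sd = noise_sd * exp(-slope * methylation)).
    """

    N: int = 16
    phases: tuple = PHASES
    phase_hours: tuple = (0.75, 0.75, 0.75, 0.75, 0.75)
    fight_rate_per_day: float = 3.7
    eggless_fight_factor: float = 3.0
    neutral_rate_per_day: float = 12.0
    foraging_rate_per_day: float = 6.0
    dominance_asymmetry: bool = True
    lambda_asym: float = 24.0
    expression_gap: float = 0.1155
    queen_id: int = 0
    queen_fight_share: float = 0.4
    n_genes: int = 10_000
    n_queen_genes: int = 200
    queen_lfc: float = 1.5
    d4_lfc_factor: float = 0.8
    noise_sd: float = 0.6
    methylation_noise_slope: float = 1.5
    ovary_base_mm: float = 0.3
    ovary_span_mm: float = 1.6
    seed: int = 0

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if len(self.phases) != len(self.phase_hours):
            raise ValueError("one duration per phase required")
        if any(h <= 0 for h in self.phase_hours):
            raise ValueError("phase durations must be > 0")
        for name in ("fight_rate_per_day", "neutral_rate_per_day",
                     "foraging_rate_per_day", "eggless_fight_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_queen_genes < 2 or self.n_queen_genes > self.n_genes:
            raise ValueError("need 2 <= n_queen_genes <= n_genes")

    @property
    def error_rate(self) -> float:
        """Probability that the queen loses a control-phase fight."""
        if not self.dominance_asymmetry:
            return 0.5
        return float(sigma_dom(self.expression_gap, self.lambda_asym))

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible substream for one generator."""
        key = int.from_bytes(stream.encode(), "little") % (2**32)
        return np.random.default_rng(np.random.SeedSequence((self.seed, key)))


def _poisson_times(rng, rate_per_hour: float, hours: float) -> np.ndarray:
    n = rng.poisson(rate_per_hour * hours)
    return np.sort(rng.uniform(0.0, hours, size=n))


def generate_events(scenario: NestScenario) -> pd.DataFrame:
    """Synthetic interaction event log across all phases.

    Fights are a Poisson stream at the per-capita subdominant rate times
    N; in the control (and D-phases) a fraction ``queen_fight_share`` of
    fights involve the queen, who wins with probability 1 - error_rate;
    worker-worker fights are coin flips.  In the eggless phase the queen
    is absent, everyone fights symmetrically at the elevated rate.  Each
    fight is written as a DOM row (winner) plus a SUB row (loser);
    foraging events as DEC/REC pairs; neutral ANT/TR as one row per
    participant.
    """
    rng = scenario.rng("events")
    rows = []
    t0 = 0.0
    eps = scenario.error_rate
    for phase, hours in zip(scenario.phases, scenario.phase_hours):
        queenless = phase == "eggless"
        members = [i for i in range(scenario.N)
                   if not (queenless and i == scenario.queen_id)]
        n_here = len(members)
        factor = scenario.eggless_fight_factor if queenless else 1.0
        fight_rate = scenario.fight_rate_per_day / 24.0 * factor * n_here
        for t in _poisson_times(rng, fight_rate, hours):
            if (not queenless and scenario.dominance_asymmetry
                    and rng.random() < scenario.queen_fight_share):
                w = scenario.queen_id
                others = [i for i in members if i != w]
                o = others[rng.integers(len(others))]
                if rng.random() < eps:
                    winner, loser = o, w
                else:
                    winner, loser = w, o
            else:
                # symmetric fight among the (other) colony members; when
                # dominance asymmetry is on, queen fights are exactly the
                # branch above
                pool = members
                if not queenless and scenario.dominance_asymmetry:
                    pool = [i for i in members if i != scenario.queen_id]
                a, b = rng.choice(len(pool), size=2, replace=False)
                winner, loser = pool[a], pool[b]
            rows.append((t0 + t, winner, loser, "DOM", phase))
            rows.append((t0 + t, loser, winner, "SUB", phase))
        forage_rate = scenario.foraging_rate_per_day / 24.0 * n_here / 2.0
        for t in _poisson_times(rng, forage_rate, hours):
            a, b = rng.choice(n_here, size=2, replace=False)
            rows.append((t0 + t, members[a], members[b], "DEC", phase))
            rows.append((t0 + t, members[b], members[a], "REC", phase))
        neutral_rate = scenario.neutral_rate_per_day / 24.0 * n_here / 2.0
        for t in _poisson_times(rng, neutral_rate, hours):
            a, b = rng.choice(n_here, size=2, replace=False)
            kind = "ANT" if rng.random() < 0.5 else "TR"
            rows.append((t0 + t, members[a], members[b], kind, phase))
            rows.append((t0 + t, members[b], members[a], kind, phase))
        t0 += hours
    log = pd.DataFrame(rows, columns=["time", "actor", "partner", "type", "phase"])
    return log.sort_values("time", kind="stable").reset_index(drop=True)


def generate_expression(scenario: NestScenario) -> ExpressionTable:
    """Synthetic expression table with queen genes, methylation, ovaries.

    Log-scale expression: per-gene baseline ~ N(2, 1); queen genes gain
    ``queen_lfc`` in control queens and ``queen_lfc * d4_lfc_factor`` in
    every D4 individual; per-gene noise sd is
    ``noise_sd * exp(-methylation_noise_slope * methylation)`` with
    methylation ~ Beta(2, 2).  One cohort of N individuals per phase in
    {control, D4}; ovary size grows linearly with an individual's
    realized queen-gene score (queens exceed the 1.5 mm maturity size by
    construction).
    """
    rng = scenario.rng("expression")
    G = scenario.n_genes
    baseline = rng.normal(2.0, 1.0, size=G)
    methylation = rng.beta(2.0, 2.0, size=G)
    noise_sd = scenario.noise_sd * np.exp(
        -scenario.methylation_noise_slope * methylation
    )
    queen_flag = np.zeros(G, dtype=bool)
    queen_flag[rng.choice(G, size=scenario.n_queen_genes, replace=False)] = True
    # heterogeneous per-gene fold changes: the queen *profile* (which
    # queen genes go up by how much) is what reference correlations
    # detect; a uniform shift would leave Pearson r unchanged
    lfc_pattern = rng.gamma(2.0, 0.5, size=G) * queen_flag

    cohorts = [p for p in ("control", "D4") if p in scenario.phases] or ["control"]
    cols, phases_col, values = [], [], []
    for phase in cohorts:
        for i in range(scenario.N):
            if phase == "control" and i == scenario.queen_id:
                shift = scenario.queen_lfc * lfc_pattern
            elif phase == "D4":
                shift = scenario.queen_lfc * scenario.d4_lfc_factor * lfc_pattern
            else:
                shift = 0.0
            expr = baseline + shift + rng.normal(0.0, 1.0, size=G) * noise_sd
            values.append(expr)
            cols.append(f"{phase}_w{i:02d}")
            phases_col.append(phase)
    values = np.column_stack(values)

    gene_index = pd.Index([f"g{k:05d}" for k in range(G)], name="gene")
    table = pd.DataFrame(values, index=gene_index, columns=cols)
    genes = pd.DataFrame(
        {"queen_gene": queen_flag, "methylation": methylation}, index=gene_index
    )
    # ovary size tracks each individual's realized queen-gene score in the
    # control cohort; at D4 only the newly established queen has matured
    # ovaries even though everyone's expression is still elevated
    qscore = values[queen_flag].mean(axis=0) - baseline[queen_flag].mean()
    qnorm = np.clip(qscore / max(scenario.queen_lfc, 1e-9), 0, None)
    is_d4 = np.array([p == "D4" for p in phases_col])
    new_queen = np.array([c.endswith(f"w{scenario.queen_id:02d}") for c in cols])
    qnorm[is_d4] = np.where(new_queen[is_d4], 1.0, 0.0)
    ovary = scenario.ovary_base_mm + scenario.ovary_span_mm * qnorm \
        + rng.normal(0.0, 0.05, size=len(cols))
    individuals = pd.DataFrame(
        {"phase": phases_col, "ovary_mm": np.clip(ovary, 0.0, None)},
        index=pd.Index(cols, name="individual"),
    )
    return ExpressionTable(values=table, genes=genes, individuals=individuals)


def generate_frames(
    scenario: NestScenario,
    n_frames: int = 20,
    height: int = 96,
    width: int = 128,
    radius: int = 4,
    speeds: dict | None = None,
    phase: str = "control",
) -> np.ndarray:
    """Grayscale frame stack of N bright disks walking on a dark comb.

    ``speeds`` maps phase name to per-frame step size in pixels
    (defaults: control 1.0, eggless 3.0, others 1.5).  Returns a uint8
    array (n_frames, height, width); ground-truth displacement per frame
    is the chosen speed, so activity scales monotonically with it.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if speeds is None:
        speeds = {"control": 1.0, "eggless": 3.0}
    speed = speeds.get(phase, 1.5)
    rng = scenario.rng(f"frames-{phase}")
    yy, xx = np.mgrid[0:height, 0:width]
    pos = np.column_stack([
        rng.uniform(radius, height - radius, scenario.N),
        rng.uniform(radius, width - radius, scenario.N),
    ])
    frames = np.zeros((n_frames, height, width), dtype=np.uint8)
    for k in range(n_frames):
        img = np.full((height, width), 30, dtype=np.uint8)
        for cy, cx in pos:
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
            img[disk] = 200
        frames[k] = img
        if speed > 0:
            ang = rng.uniform(0, 2 * np.pi, scenario.N)
            pos[:, 0] = np.clip(pos[:, 0] + speed * np.sin(ang), radius, height - radius)
            pos[:, 1] = np.clip(pos[:, 1] + speed * np.cos(ang), radius, width - radius)
    return frames
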