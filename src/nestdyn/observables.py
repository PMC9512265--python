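"""Behavioral, imaging, and omics observables of the nest.

The quantities computed by the field study, re-implemented on tabular
inputs: per-individual behavior indices from annotated interaction logs,
nest-level activity from frame differencing, ovary maturity calls,
queen-profile expression correlations, the methylation/expression-noise
relationship, and phase comparisons with multiple-testing correction.

Interaction logs use the six-type ethogram: DOM (domination), SUB
(subordination), DEC (donor of foraging material), REC (receiver), TR
(trophallaxis), ANT (antennation).  Each dyadic fight appears as two rows
— a DOM row for the winner and a SUB row for the loser — so the indices
are direct row counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

INTERACTION_TYPES = ("DOM", "SUB", "DEC", "REC", "TR", "ANT")
PHASES = ("control", "eggless", "D1", "D4", "D14")
FIGHT_TYPES = ("DOM", "SUB")

OVARY_MATURE_MM = 1.5  # smallest egg size associated with egg laying

__all__ = [
    "INTERACTION_TYPES",
    "PHASES",
    "ExpressionTable",
    "validate_event_log",
    "behavior_indices",
    "subdominant_rate",
    "global_activity",
    "queen_profile_correlation",
    "variable_fraction_by_methylation",
    "compare_phases",
    "classify_ovary",
]


@dataclass
class ExpressionTable:
    """Genes x individuals expression with gene and individual annotations.

    ``values``: DataFrame (rows = genes, columns = individual ids) of
    normalized log-scale expression.  ``genes``: DataFrame indexed by gene
    with boolean ``queen_gene`` and float ``methylation`` in [0, 1].
    ``individuals``: DataFrame indexed by individual id with ``phase`` and
    ``ovary_mm`` columns.
    """

    values: pd.DataFrame
    genes: pd.DataFrame
    individuals: pd.DataFrame

    def __post_init__(self):
        if not self.values.index.equals(self.genes.index):
            raise ValueError("gene annotation index must match expression rows")
        if not self.values.columns.equals(self.individuals.index):
            raise ValueError("individual annotation index must match expression columns")
        meth = self.genes["methylation"]
        if (meth < 0).any() or (meth > 1).any():
            raise ValueError("methylation levels must lie in [0, 1]")
        if self.genes["queen_gene"].dtype != bool:
            raise ValueError("queen_gene flags must be boolean")


def validate_event_log(log: pd.DataFrame) -> pd.DataFrame:
    """Check an interaction event log against the schema.

    Required columns: ``time`` (hours, >= 0), ``actor``, ``partner``,
    ``type`` (six-type vocabulary), ``phase``.  Returns the validated
    frame; raises ValueError naming the first offending row otherwise.
    """
    required = {"time", "actor", "partner", "type", "phase"}
    missing = required - set(log.columns)
    if missing:
        raise ValueError(f"event log missing columns {sorted(missing)}")
    bad = ~log["type"].isin(INTERACTION_TYPES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unknown interaction type {log['type'].iloc[row]!r} in row {row}"
        )
    if (log["time"] < 0).any():
        row = int(np.flatnonzero((log["time"] < 0).to_numpy())[0])
        raise ValueError(f"negative time in row {row}")
    return log


def behavior_indices(log: pd.DataFrame, observed_hours: pd.Series | dict) -> pd.DataFrame:
    """Per-individual interaction rate, fight index, and dominance index.

    interaction rate = all interactions per hour observed on the nest;
    fight index = (DOM + SUB) / all interactions; dominance index =
    DOM / (DOM + SUB), missing (NaN) for individuals without fights.
    Individuals present (in ``observed_hours``) but without interactions
    are included with zero rate.
    """
    log = validate_event_log(log)
    observed = pd.Series(observed_hours, dtype=float)
    if (observed <= 0).any():
        raise ValueError("observed time must be > 0 for present individuals")
    counts = (
        log.pivot_table(index="actor", columns="type", aggfunc="size", fill_value=0)
        .reindex(observed.index, fill_value=0)
        .reindex(columns=list(INTERACTION_TYPES), fill_value=0)
    )
    total = counts.sum(axis=1)
    fights = counts["DOM"] + counts["SUB"]
    out = pd.DataFrame(index=observed.index)
    out["interaction_rate"] = total / observed
    out["fight_index"] = np.where(total > 0, fights / total, 0.0)
    out["dominance_index"] = np.where(fights > 0, counts["DOM"] / fights, np.nan)
    return out


def subdominant_rate(log: pd.DataFrame, census_N: int,
                     observation_hours: float | None = None) -> float:
    """SUB events per census individual per day (passive interaction rate).

    Normalized by the night-time census count rather than the individuals
    seen on video, to stay unbiased for insects off-nest during recording.
    ``observation_hours`` defaults to the time span of the log.
    """
    if census_N < 1:
        raise ValueError("census_N must be >= 1")
    if len(log) == 0:
        return 0.0
    log = validate_event_log(log)
    n_sub = int((log["type"] == "SUB").sum())
    if observation_hours is None:
        observation_hours = float(log["time"].max())
    if observation_hours <= 0:
        raise ValueError("observation time must be > 0")
    return n_sub / census_N / (observation_hours / 24.0)


def global_activity(frames, n_wasps: int, spatial_scale: float = 1.0) -> np.ndarray:
    """Frame-differencing activity per frame transition.

    Mean absolute per-pixel intensity change between consecutive frames,
    normalized by the number of wasps present and by the squared spatial
    scale (pixels per label diameter, the camera-distance calibration).
    Only relative comparisons between phases of one recording setup are
    meaningful.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (frames, height, width) stack with >= 2 frames")
    if n_wasps < 1:
        raise ValueError("n_wasps must be >= 1")
    if spatial_scale <= 0:
        raise ValueError("spatial_scale must be > 0")
    diffs = np.abs(np.diff(frames, axis=0)).mean(axis=(1, 2))
    return diffs / n_wasps / spatial_scale**2


def queen_profile_correlation(
    table: ExpressionTable,
    queen_genes=None,
    reference_queens=None,
) -> pd.Series:
    """Per-individual mean Pearson correlation with reference queen profiles.

    For each individual, the Pearson correlation of its queen-gene
    expression vector with each reference queen's vector is computed and
    averaged.  Queen genes default to the flagged set; reference queens
    default to control-phase individuals with mature ovaries.  Zero
    variance vectors yield a missing value.
    """
    if queen_genes is None:
        queen_genes = table.genes.index[table.genes["queen_gene"]]
    queen_genes = pd.Index(queen_genes)
    if len(queen_genes) < 2:
        raise ValueError("need at least 2 queen genes")
    if reference_queens is None:
        ind = table.individuals
        reference_queens = ind.index[
            (ind["phase"] == "control") & (ind["ovary_mm"] >= OVARY_MATURE_MM)
        ]
    reference_queens = list(reference_queens)
    if not reference_queens:
        raise ValueError("no reference queens supplied or found")
    sub = table.values.loc[queen_genes]
    out = {}
    for ind_id in sub.columns:
        x = sub[ind_id].to_numpy()
        cors = []
        for q in reference_queens:
            y = sub[q].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                cors.append(np.nan)
            else:
                cors.append(stats.pearsonr(x, y)[0])
        out[ind_id] = float(np.nanmean(cors)) if not np.all(np.isnan(cors)) else np.nan
    return pd.Series(out, name="queen_profile_correlation")


def _overdispersion(values: np.ndarray):
    """Per-gene over-dispersion relative to a mean-variance trend.

    Fits log variance as a quadratic function of mean expression across
    genes and scores each gene by the chi-square upper tail of
    (n-1) * s^2 / trend(s^2).  Returns (log-ratio statistic, p-values).
    A simplified stand-in for a full technical-noise decomposition: it
    asks which genes vary across individuals more than genes of similar
    expression level do.
    """
    n = values.shape[1]
    mean = values.mean(axis=1)
    var = values.var(axis=1, ddof=1)
    ok = var > 0
    coef = np.polyfit(mean[ok], np.log(var[ok]), 2)
    trend = np.exp(np.polyval(coef, mean))
    ratio = var / trend
    pvals = stats.chi2.sf((n - 1) * ratio, df=n - 1)
    return np.log(ratio), pvals


def variable_fraction_by_methylation(
    table: ExpressionTable,
    bins: int = 5,
    alpha: float = 0.05,
    phase: str = "control",
    workers_only: bool = True,
):
    """Fraction of significantly variable genes per methylation bin.

    Tests each gene for excess expression variability across workers (an
    over-dispersion test against the genome-wide mean-variance trend,
    BH-corrected at ``alpha``), bins genes by methylation level, and also
    runs an unbinned Pearson test of methylation against the per-gene
    variability statistic.

    Returns a dict with ``bin_edges``, ``fraction`` (NaN for empty bins),
    ``n_per_bin``, and ``pearson`` = (r, p) on the unbinned pairs.
    """
    if bins < 2:
        raise ValueError("need at least 2 methylation bins")
    ind = table.individuals
    cols = ind.index[ind["phase"] == phase]
    if workers_only:
        cols = [c for c in cols if ind.loc[c, "ovary_mm"] < OVARY_MATURE_MM]
    if len(cols) < 2:
        raise ValueError("need at least 2 workers to assess variability")
    values = table.values[list(cols)].to_numpy()
    log_ratio, pvals = _overdispersion(values)
    significant = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]

    meth = table.genes["methylation"].to_numpy()
    edges = np.linspace(meth.min(), meth.max() + 1e-12, bins + 1)
    which = np.digitize(meth, edges[1:-1])
    fraction = np.full(bins, np.nan)
    n_per_bin = np.zeros(bins, dtype=int)
    for b in range(bins):
        sel = which == b
        n_per_bin[b] = sel.sum()
        if n_per_bin[b] > 0:
            fraction[b] = significant[sel].mean()
    r, p = stats.pearsonr(meth, log_ratio)
    return {
        "bin_edges": edges,
        "fraction": fraction,
        "n_per_bin": n_per_bin,
        "significant": significant,
        "statistic": log_ratio,
        "pearson": (float(r), float(p)),
    }


def compare_phases(
    stat: pd.DataFrame,
    value: str = "value",
    phase: str = "phase",
    pair_id: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise phase comparisons with Benjamini-Hochberg correction.

    ``stat`` holds one row per observation with a phase label and a
    statistic value.  Phases are compared pairwise with the Wilcoxon
    signed-rank test when ``pair_id`` links observations across phases,
    and the Mann-Whitney rank-sum test otherwise.  Pairs with fewer than
    2 observations on either side get a missing result.  Returns a frame
    of (phase_a, phase_b, statistic, p, p_adjusted, significant).
    """
    phases = [p for p in PHASES if p in set(stat[phase])]
    phases += [p for p in pd.unique(stat[phase]) if p not in phases]
    rows = []
    for i, a in enumerate(phases):
        for b in phases[i + 1:]:
            xa = stat.loc[stat[phase] == a]
            xb = stat.loc[stat[phase] == b]
            if len(xa) < 2 or len(xb) < 2:
                rows.append((a, b, np.nan, np.nan))
                continue
            if pair_id is not None:
                merged = xa.merge(xb, on=pair_id, suffixes=("_a", "_b"))
                if len(merged) < 2:
                    rows.append((a, b, np.nan, np.nan))
                    continue
                d = merged[f"{value}_a"] - merged[f"{value}_b"]
                if np.allclose(d, 0):
                    rows.append((a, b, 0.0, 1.0))
                    continue
                s, p = stats.wilcoxon(merged[f"{value}_a"], merged[f"{value}_b"])
            else:
                va, vb = xa[value].to_numpy(), xb[value].to_numpy()
                if np.all(va[:, None] == vb[None, :]):
                    rows.append((a, b, np.nan, 1.0))
                    continue
                s, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
            rows.append((a, b, float(s), float(p)))
    out = pd.DataFrame(rows, columns=["phase_a", "phase_b", "statistic", "p"])
    mask = out["p"].notna()
    out["p_adjusted"] = np.nan
    if mask.any():
        out.loc[mask, "p_adjusted"] = multipletests(
            out.loc[mask, "p"], alpha=alpha, method="fdr_bh"
        )[1]
    out["significant"] = out["p_adjusted"] < alpha
    return out


def classify_ovary(egg_length_mm: float) -> str:
    """Ovary maturity call: mature iff the largest egg is >= 1.5 mm."""
    if egg_length_mm < 0:
        raise ValueError("egg length must be non-negative")
    return "mature" if egg_length_mm >= OVARY_MATURE_MM else "immature"
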