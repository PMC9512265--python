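import numpy as np
import pandas as pd
import pytest

from nestdyn import (
    behavior_indices,
    classify_ovary,
    compare_phases,
    global_activity,
    queen_profile_correlation,
    subdominant_rate,
    variable_fraction_by_methylation,
)
from nestdyn.observables import ExpressionTable, validate_event_log


def _log(rows):
    return pd.DataFrame(rows, columns=["time", "actor", "partner", "type", "phase"])


class TestBehaviorIndices:
    def test_direct_formula(self):
        rows = [(0.1, "a", "b", "DOM", "control")] * 3
        rows += [(0.2, "a", "b", "SUB", "control")]
        rows += [(0.3, "a", "b", "ANT", "control")] * 4
        idx = behavior_indices(_log(rows), {"a": 2.0, "b": 2.0})
        assert idx.loc["a", "interaction_rate"] == pytest.approx(4.0)
        assert idx.loc["a", "fight_index"] == pytest.approx(0.5)
        assert idx.loc["a", "dominance_index"] == pytest.approx(0.75)

    def test_no_fights_gives_missing_dominance(self):
        idx = behavior_indices(
            _log([(0.1, "a", "b", "ANT", "control")]), {"a": 1.0, "b": 1.0}
        )
        assert idx.loc["a", "fight_index"] == 0.0
        assert np.isnan(idx.loc["a", "dominance_index"])

    def test_present_but_silent_individual_counted(self):
        idx = behavior_indices(
            _log([(0.1, "a", "b", "TR", "control")]), {"a": 1.0, "b": 1.0, "c": 2.0}
        )
        assert idx.loc["c", "interaction_rate"] == 0.0

    def test_row_order_invariance(self):
        rows = [(0.1, "a", "b", "DOM", "control"),
                (0.2, "b", "a", "SUB", "control"),
                (0.5, "b", "a", "DOM", "control"),
                (0.5, "a", "b", "SUB", "control")]
        hours = {"a": 1.0, "b": 1.0}
        fwd = behavior_indices(_log(rows), hours)
        rev = behavior_indices(_log(rows[::-1]), hours)
        pd.testing.assert_frame_equal(fwd, rev)

    def test_unknown_type_is_schema_error(self):
        with pytest.raises(ValueError, match="GROOM"):
            behavior_indices(_log([(0.1, "a", "b", "GROOM", "control")]), {"a": 1.0})

    def test_indices_bounded(self, scenario_long):
        from nestdyn import generate_events

        log = generate_events(scenario_long)
        idx = behavior_indices(log, {i: 120.0 for i in range(scenario_long.N)})
        assert (idx["interaction_rate"] >= 0).all()
        assert idx["fight_index"].between(0, 1).all()
        assert idx["dominance_index"].dropna().between(0, 1).all()


class TestDomSubPairing:
    def test_colony_dom_equals_sub(self, scenario_long):
        from nestdyn import generate_events

        log = generate_events(scenario_long)
        assert (log["type"] == "DOM").sum() == (log["type"] == "SUB").sum()


class TestSubdominantRate:
    def test_printed_arithmetic(self):
        rows = [(float(i % 24), i % 5, (i + 1) % 5, "SUB", "control") for i in range(74)]
        log = _log(rows)
        assert subdominant_rate(log, 20, observation_hours=24.0) == pytest.approx(3.7)

    def test_empty_log(self):
        assert subdominant_rate(_log([]), 10) == 0.0

    def test_zero_census_rejected(self):
        with pytest.raises(ValueError):
            subdominant_rate(_log([]), 0)


class TestGlobalActivity:
    def test_identical_frames_zero(self):
        frames = np.full((3, 8, 8), 7, dtype=np.uint8)
        assert np.all(global_activity(frames, 4) == 0.0)

    def test_displaced_disk_pixel_count(self):
        # one bright square moved to a non-overlapping spot changes
        # exactly twice its area
        f0 = np.zeros((20, 20))
        f1 = np.zeros((20, 20))
        f0[2:6, 2:6] = 10.0
        f1[10:14, 10:14] = 10.0
        act = global_activity(np.stack([f0, f1]), 1)
        assert act[0] == pytest.approx(2 * 16 * 10.0 / 400)

    def test_wasp_normalization(self):
        f = np.zeros((2, 10, 10))
        f[1, 0, 0] = 8.0
        assert global_activity(f, 2)[0] == pytest.approx(global_activity(f, 1)[0] / 2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            global_activity(np.zeros((1, 5, 5)), 1)
        with pytest.raises(ValueError):
            global_activity(np.zeros((5, 5)), 1)


class TestQueenProfileCorrelation:
    @staticmethod
    def _tiny_table(values, phases, ovaries):
        genes = pd.Index([f"g{i}" for i in range(values.shape[0])], name="gene")
        cols = pd.Index([f"w{i}" for i in range(values.shape[1])], name="individual")
        return ExpressionTable(
            values=pd.DataFrame(values, index=genes, columns=cols),
            genes=pd.DataFrame(
                {"queen_gene": np.ones(len(genes), dtype=bool),
                 "methylation": np.zeros(len(genes))}, index=genes),
            individuals=pd.DataFrame(
                {"phase": phases, "ovary_mm": ovaries}, index=cols),
        )

    def test_identical_to_reference_scores_one(self):
        v = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        t = self._tiny_table(v, ["control", "control"], [2.0, 0.2])
        cors = queen_profile_correlation(t)
        assert cors["w1"] == pytest.approx(1.0)

    def test_negated_centered_profile_scores_minus_one(self):
        ref = np.array([1.0, 2.0, 5.0])
        neg = 2 * ref.mean() - ref
        t = self._tiny_table(np.column_stack([ref, neg]),
                             ["control", "control"], [2.0, 0.2])
        cors = queen_profile_correlation(t)
        assert cors["w1"] == pytest.approx(-1.0)

    def test_d4_individuals_score_above_control_workers(self, expression_table):
        cors = queen_profile_correlation(expression_table)
        ind = expression_table.individuals
        ctrl_workers = [c for c in cors.index
                        if ind.loc[c, "phase"] == "control"
                        and ind.loc[c, "ovary_mm"] < 1.5]
        d4 = [c for c in cors.index if ind.loc[c, "phase"] == "D4"]
        assert cors[d4].mean() > cors[ctrl_workers].mean() + 0.1


class TestVariableFraction:
    def test_noise_decreasing_with_methylation_detected(self, expression_table):
        res = variable_fraction_by_methylation(expression_table, bins=5)
        r, p = res["pearson"]
        assert r < 0 and p < 0.05
        frac = res["fraction"]
        assert np.nanmean(frac[:2]) > np.nanmean(frac[-2:])

    def test_single_bin_rejected(self, expression_table):
        with pytest.raises(ValueError):
            variable_fraction_by_methylation(expression_table, bins=1)


class TestComparePhases:
    def test_identical_samples_adjusted_p_one(self):
        stat = pd.DataFrame({
            "phase": ["control"] * 4 + ["eggless"] * 4,
            "value": [1.0] * 8,
        })
        out = compare_phases(stat)
        assert out["p_adjusted"].iloc[0] == 1.0

    def test_large_shift_detected(self):
        rng = np.random.default_rng(3)
        stat = pd.DataFrame({
            "phase": ["control"] * 12 + ["eggless"] * 12,
            "value": np.concatenate([rng.normal(0, 1, 12), rng.normal(5, 1, 12)]),
        })
        out = compare_phases(stat)
        assert bool(out["significant"].iloc[0])

    def test_bh_never_below_raw_p(self):
        rng = np.random.default_rng(4)
        stat = pd.DataFrame({
            "phase": (["control"] * 6 + ["eggless"] * 6 + ["D1"] * 6
                      + ["D4"] * 6),
            "value": rng.normal(0, 1, 24),
        })
        out = compare_phases(stat)
        ok = out["p"].notna()
        assert np.all(out.loc[ok, "p_adjusted"] >= out.loc[ok, "p"] - 1e-12)

    def test_paired_mode_uses_signed_rank(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 10)
        stat = pd.DataFrame({
            "phase": ["control"] * 10 + ["eggless"] * 10,
            "value": np.concatenate([base, base + 2.0 + rng.normal(0, 0.1, 10)]),
            "wasp": list(range(10)) * 2,
        })
        out = compare_phases(stat, pair_id="wasp")
        assert bool(out["significant"].iloc[0])

    def test_insufficient_observations_missing(self):
        stat = pd.DataFrame({"phase": ["control", "eggless", "eggless"],
                             "value": [1.0, 2.0, 3.0]})
        out = compare_phases(stat)
        assert np.isnan(out["p"].iloc[0])


class TestOvary:
    @pytest.mark.parametrize("mm,expect", [
        (1.5, "mature"), (2.1, "mature"), (1.4999, "immature"), (0.4, "immature"),
    ])
    def test_threshold(self, mm, expect):
        assert classify_ovary(mm) == expect

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_ovary(-0.1)


def test_validate_event_log_missing_columns():
    with pytest.raises(ValueError, match="missing"):
        validate_event_log(pd.DataFrame({"time": [0.0]}))
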