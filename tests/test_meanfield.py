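import numpy as np
import pytest

from nestdyn import (
    PopulationDensity,
    bifurcation_diagram,
    colony_mean_velocity,
    drift_velocity,
    evolve_density,
    find_separatrix,
    gaussian_density,
    perturb_and_classify,
    phase_portrait,
    steady_mean,
    tracer_velocity,
    worker_attractor,
)
from nestdyn.meanfield import tracer_fixed_points


class TestDrift:
    def test_empty_colony_is_pure_molecular_drift(self):
        d = gaussian_density(0.5)
        d.f[:] = 0.0
        r = np.linspace(0, 1.4, 10)
        assert np.allclose(drift_velocity(r, d, 2.0, 24.0), 1 - r)

    def test_queen_above_distant_colony_feels_no_repression(self):
        d = gaussian_density(0.2)  # all mass far below r=1
        v1 = drift_velocity(1.0, d, 1.0, 50.0)
        assert abs(v1) < 1e-3

    def test_worker_fixed_point_identity(self):
        # a tracer below a coherent colony at rbar sits at 1/(1+at*rbar)
        at = 1.5
        rbar = steady_mean(at)
        r2 = worker_attractor(at, rbar)
        assert tracer_velocity(r2, rbar, at, 1e4) == pytest.approx(0.0, abs=1e-6)

    def test_negative_density_rejected(self):
        d = gaussian_density(0.5)
        d.f[3] = 1.0
        d.f *= -1
        with pytest.raises(ValueError):
            drift_velocity(0.5, d, 1.0, 1.0)


class TestEvolveDensity:
    def test_uncoupled_mass_collects_at_unity(self):
        end = evolve_density(gaussian_density(0.3), 0.0, 12.0,
                             lambda_asym=0.0, n_snapshots=2)[-1]
        assert end.mean_r == pytest.approx(1.0, abs=0.01)
        peak = end.centers[np.argmax(end.f)]
        assert peak == pytest.approx(1.0, abs=0.02)

    def test_mass_conservation_and_positivity(self):
        d0 = gaussian_density(0.4, mass=3.0)
        snaps = evolve_density(d0, 1.0, 10.0, lambda_asym=24.0, n_snapshots=4)
        for s in snaps:
            assert s.mass == pytest.approx(3.0, rel=1e-10)
            assert np.all(s.f >= 0)

    @pytest.mark.parametrize("at", [0.5, 1.0, 2.0])
    def test_steady_mean_matches_closed_form(self, at):
        # symmetric interactions keep the colony coherent; its steady
        # mean is (sqrt(2a+1)-1)/a
        end = evolve_density(gaussian_density(0.3), at, 25.0,
                             lambda_asym=0.0, n_snapshots=2)[-1]
        assert end.mean_r == pytest.approx(steady_mean(at), abs=0.01)

    def test_grid_refinement_converges(self):
        # steady mean lands within two cell widths of the closed form at
        # every resolution (the steady peak aliases within one cell), and
        # refining 4x tightens the spread
        at = 1.0
        means = {}
        for n_cells in (200, 800):
            end = evolve_density(gaussian_density(0.3, n_cells=n_cells), at,
                                 25.0, lambda_asym=0.0, n_snapshots=2)[-1]
            means[n_cells] = end.mean_r
            assert abs(end.mean_r - steady_mean(at)) < 2 * 1.5 / n_cells
        assert abs(means[800] - means[200]) < 2e-3

    def test_invalid_inputs(self):
        d = gaussian_density(0.3)
        with pytest.raises(ValueError):
            evolve_density(d, 1.0, -1.0, lambda_asym=0.0)
        d.f[:] = 0.0
        with pytest.raises(ValueError):
            evolve_density(d, 1.0, 1.0, lambda_asym=0.0)


class TestDensityRecord:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            PopulationDensity(edges=np.array([0.0, 1.0, 0.5]), f=np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            PopulationDensity(edges=np.array([0.0, 0.5, 1.0]), f=np.array([1.0, -1.0]))


class TestAttractorsAndSeparatrix:
    @pytest.mark.parametrize("at", [0.5, 1.0, 2.0])
    def test_bistable_tracer_in_steady_colony(self, at):
        rbar = steady_mean(at)
        fps = tracer_fixed_points(rbar, at, 24.0)
        stable = [r for r, s in fps if s]
        assert len(stable) == 2
        assert stable[0] == pytest.approx(worker_attractor(at, rbar), abs=0.03)
        assert stable[1] == pytest.approx(1.0, abs=0.02)

    def test_separatrix_is_the_unstable_point(self):
        at = 1.0
        rbar = steady_mean(at)
        res = find_separatrix(rbar, at, 24.0)
        assert res["converged"]
        unstable = [r for r, s in res["fixed_points"] if not s][0]
        assert res["separatrix"] == pytest.approx(unstable, abs=1e-3)

    def test_tracer_fates_bracket_separatrix(self):
        at = 1.0
        rbar = steady_mean(at)
        sep = find_separatrix(rbar, at, 24.0)["separatrix"]
        fps = tracer_fixed_points(rbar, at, 24.0)
        stable = [r for r, s in fps if s]
        from scipy.integrate import solve_ivp

        for r0, target in ((sep - 0.02, stable[0]), (sep + 0.02, stable[1])):
            sol = solve_ivp(lambda _, y: tracer_velocity(y, rbar, at, 24.0),
                            (0, 200.0), [r0], rtol=1e-8)
            assert sol.y[0, -1] == pytest.approx(target, abs=0.01)

    def test_monostable_colony_reports_no_separatrix(self):
        res = find_separatrix(0.05, 0.2, 24.0)
        assert not res["converged"]


class TestPhasePortrait:
    def test_queen_tracer_stays_at_queen_attractor(self):
        pp = phase_portrait(1.0, 24.0, tracers=[(1.0, steady_mean(1.0))])
        tr = pp["tracers"][0]
        assert abs(tr["r"][-1] - 1.0) < 0.01

    def test_queenless_colony_transient(self):
        # a queenless low colony rises collectively: the tracer rides the
        # colony mean to the plastic state
        at = 1.0
        pp = phase_portrait(at, 24.0, tracers=[(0.3, 0.3)])
        tr = pp["tracers"][0]
        assert tr["rbar"][-1] == pytest.approx(steady_mean(at), abs=1e-3)
        assert tr["r"][-1] == pytest.approx(steady_mean(at), abs=0.02)
        assert tr["r"].max() > 0.5  # transient rise


class TestPerturbations:
    def test_intrinsic_below_gap_suppressed(self):
        res = perturb_and_classify(1.0, 24.0, "intrinsic", 0.05)
        assert res["outcome"] == "suppressed"

    def test_intrinsic_beyond_separatrix_reprograms(self):
        res = perturb_and_classify(1.0, 24.0, "intrinsic", 0.4)
        assert res["outcome"] == "reprogrammed"

    def test_zero_magnitude_is_suppressed(self):
        res = perturb_and_classify(1.0, 24.0, "intrinsic", 0.0)
        assert res["outcome"] == "suppressed"
        assert res["final_r"] == pytest.approx(res["fixed_points"][0][0], abs=1e-6)

    def test_extrinsic_queen_removal_reaches_plastic_state(self):
        at = 1.0
        gap = steady_mean(at) - worker_attractor(at)
        res = perturb_and_classify(at, 24.0, "extrinsic", gap * 1.05)
        assert res["outcome"] == "reprogrammed"
        assert res["final_r"] == pytest.approx(steady_mean(at), abs=0.02)

    def test_small_extrinsic_displacement_is_suppressed(self):
        res = perturb_and_classify(1.0, 24.0, "extrinsic", 0.02)
        assert res["outcome"] == "suppressed"

    def test_invalid_mode_and_magnitude(self):
        with pytest.raises(ValueError):
            perturb_and_classify(1.0, 24.0, "ambient", 0.1)
        with pytest.raises(ValueError):
            perturb_and_classify(1.0, 24.0, "intrinsic", -2.0)


class TestBifurcation:
    def test_low_population_structure_leaves_only_queen_state(self):
        bd = bifurcation_diagram(1.0, 24.0, rbar_grid=np.linspace(0.01, 0.2, 30))
        assert bd["fold"] is None
        assert np.allclose(bd["r"], 1.0, atol=0.05)

    def test_saddle_node_fold_located(self):
        bd = bifurcation_diagram(1.0, 24.0)
        assert bd["fold"] is not None
        rb_fold = bd["fold"]["rbar"]
        below = tracer_fixed_points(rb_fold - 0.05, 1.0, 24.0)
        above = tracer_fixed_points(rb_fold + 0.05, 1.0, 24.0)
        assert len(above) - len(below) == 2  # two roots born at the fold

    def test_worker_branch_follows_identity_at_large_rbar(self):
        bd = bifurcation_diagram(2.0, 24.0)
        sel = (bd["rbar"] > 0.8) & bd["stable"] & (bd["r"] < 0.6)
        expect = 1.0 / (1.0 + 2.0 * bd["rbar"][sel])
        assert np.allclose(bd["r"][sel], expect, atol=0.03)


def test_colony_mean_velocity_fixed_point():
    at = 1.7
    assert colony_mean_velocity(steady_mean(at), at) == pytest.approx(0.0, abs=1e-12)
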