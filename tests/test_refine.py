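"""Annealing schedule, restraint potentials, Langevin dynamics, drivers."""

import numpy as np
import pytest

from ucrefine.refine import (
    KB_KCAL,
    HarmonicRestraints,
    LangevinIntegrator,
    PositionalRestraint,
    Schedule,
    XrayEngine,
    heavy_atom_rmsd,
    refine_b_factors,
    run_refinement,
    scramble_model,
    select_final,
)
from ucrefine.toys import ToySpec, make_toy_crystal, perturb_model, simulate_f_obs


class TestSchedule:
    def test_phase_boundary_values(self):
        s = Schedule()
        assert s.total_ps == 40.0
        assert [s.w_xray(t) for t in (0.0, 20.0, 30.0, 40.0)] == [0, 0, 1, 1]
        assert s.temperature(0.0) == 0.0
        assert s.temperature(20.0) == 298.0
        assert s.temperature(30.0) == 298.0
        assert s.temperature(40.0) == 0.0
        assert s.gamma_ps == 2.0
        assert s.update_interval == 100
        assert s.n_steps == 20000

    def test_ramp_is_linear(self):
        s = Schedule()
        assert s.w_xray(25.0) == pytest.approx(0.5)
        assert s.temperature(10.0) == pytest.approx(149.0)
        assert s.temperature(35.0) == pytest.approx(149.0)

    def test_positional_restraints_only_during_heat(self):
        s = Schedule()
        assert s.restraints_active(5.0)
        assert not s.restraints_active(21.0)

    def test_scaled_preserves_shape(self):
        s = Schedule().scaled(0.1)
        assert s.total_ps == pytest.approx(4.0)
        assert s.w_xray(s.heat_ps) == 0.0
        assert s.w_xray(s.heat_ps + s.ramp_ps) == 1.0


class TestRestraints:
    def test_gradient_matches_finite_differences(self, small_toy, rng):
        _, model, _ = small_toy
        restr = HarmonicRestraints(model)
        cart = model.cartesian() + rng.normal(0, 0.05, (model.n_atoms, 3))
        e0, g = restr(cart)
        h = 1e-5
        for j in rng.choice(model.n_atoms, 5, replace=False):
            for ax in range(3):
                up, dn = cart.copy(), cart.copy()
                up[j, ax] += h
                dn[j, ax] -= h
                fd = (restr(up)[0] - restr(dn)[0]) / (2 * h)
                assert g[j, ax] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_translation_invariance(self, small_toy):
        _, model, _ = small_toy
        restr = HarmonicRestraints(model)
        cart = model.cartesian()
        e0, _ = restr(cart)
        e1, _ = restr(cart + np.array([1.3, -0.7, 2.1]))
        assert e1 == pytest.approx(e0, abs=1e-9)

    def test_rotation_invariance(self):
        # an isolated cluster in a large cell: rotation preserves all
        # interatomic geometry and no periodic image comes within range
        from ucrefine.model import UnitCellGeometry

        spec = ToySpec(seed=4, space_group="P1", n_atoms=6, chain_len=6,
                       cell=UnitCellGeometry(40.0, 40.0, 40.0))
        model = make_toy_crystal(spec)
        restr = HarmonicRestraints(model)
        # unwrap the chain into contiguous Cartesian coordinates: rotation
        # and periodic wrapping do not commute
        raw = model.cell.orthogonalize(model.frac)
        cart = raw.copy()
        for i in range(1, len(cart)):
            step = restr._min_image((raw[i] - raw[i - 1])[None])[0]
            cart[i] = cart[i - 1] + step
        cart = cart - cart.mean(axis=0) + np.array([20.0, 20.0, 20.0])
        theta = 0.3
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        center = cart.mean(axis=0)
        e0, _ = restr(cart)
        e1, _ = restr((cart - center) @ R.T + center)
        assert e1 == pytest.approx(e0, rel=1e-6, abs=1e-6)

    def test_reference_geometry_is_minimum(self, small_toy):
        _, model, _ = small_toy
        restr = HarmonicRestraints(model)
        e0, g0 = restr(model.cartesian())
        assert abs(e0) < 1e-18 or e0 >= 0
        assert np.abs(g0).max() < 1e-8 or e0 > 0  # repulsion-free reference

    def test_positional_restraint_quadratic(self, small_toy):
        _, model, _ = small_toy
        pos = PositionalRestraint(model, k=10.0)
        cart = model.cartesian()
        d = np.zeros_like(cart)
        d[0] = (0.2, 0, 0)
        e, g = pos(cart + d)
        assert e == pytest.approx(10.0 * 0.04)
        assert g[0, 0] == pytest.approx(2 * 10.0 * 0.2)


class TestLangevin:
    def test_rest_state_stays_at_rest(self):
        integ = LangevinIntegrator(np.array([12.0, 16.0]), 0.002, 2.0, seed=0)
        cart = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        vel = np.zeros_like(cart)
        force = np.zeros_like(cart)
        c, v, f = integ.step(cart, vel, force, 0.0, lambda x: np.zeros_like(x))
        assert np.array_equal(c, cart) and not v.any()

    def test_identical_seeds_identical_trajectories(self):
        def run(seed):
            integ = LangevinIntegrator(np.array([12.0]), 0.002, 2.0, seed=seed,
                                       remove_com=False)
            x = np.zeros((1, 3))
            v = np.zeros_like(x)
            f = np.zeros_like(x)
            for _ in range(200):
                x, v, f = integ.step(x, v, f, 150.0, lambda c: -5.0 * c)
            return x
        assert np.array_equal(run(7), run(7))
        assert not np.array_equal(run(7), run(8))

    def test_harmonic_equipartition(self):
        """Long Langevin run on a 3-D oscillator: <E_pot> = 3/2 kT within 20%."""
        k = 10.0
        integ = LangevinIntegrator(np.array([12.0]), 0.002, 2.0, seed=4,
                                   remove_com=False)
        x = np.zeros((1, 3))
        v = np.zeros_like(x)
        f = -2 * k * x
        samples = []
        for i in range(40000):
            x, v, f = integ.step(x, v, f, 298.0, lambda c: -2 * k * c)
            if i > 5000:
                samples.append(k * float((x**2).sum()))
        expected = 1.5 * KB_KCAL * 298.0
        assert np.mean(samples) == pytest.approx(expected, rel=0.2)

    def test_bad_timestep_rejected(self):
        with pytest.raises(ValueError):
            LangevinIntegrator(np.array([12.0]), 0.0, 2.0)


class TestRunRefinement:
    def test_heat_only_restraints_hold_model(self, p21_toy):
        _, model, _ = p21_toy
        scrambled, rmsd = scramble_model(model, heat_ps=0.5, run_ps=0.0, seed=1)
        assert rmsd < 0.5

    def test_energy_bookkeeping_identity(self, small_toy):
        _, model, rset = small_toy
        sched = Schedule(heat_ps=0.1, ramp_ps=0.1, cool_ps=0.2, seed=2)
        _, trace = run_refinement(model, rset, sched)
        for et, er, w, ex in zip(trace.e_total, trace.e_restraints,
                                 trace.w_xray, trace.e_xray):
            assert et == pytest.approx(er + w * ex, rel=1e-9, abs=1e-9)
        assert np.isfinite(trace.e_total).all()

    def test_trace_w_xray_at_phase_boundaries(self, small_toy):
        _, model, rset = small_toy
        sched = Schedule(heat_ps=0.2, ramp_ps=0.2, cool_ps=0.2, seed=2)
        _, trace = run_refinement(model, rset, sched)
        assert trace.w_xray[0] == 0.0
        assert trace.w_xray[-1] == 1.0
        assert trace.time_ps[-1] == pytest.approx(sched.total_ps)

    def test_bit_reproducible_given_seed(self, small_toy):
        _, model, rset = small_toy
        sched = Schedule(heat_ps=0.1, ramp_ps=0.1, cool_ps=0.1, seed=5)
        a, _ = run_refinement(model, rset, sched)
        b, _ = run_refinement(model, rset, sched)
        assert np.array_equal(a.frac, b.frac)

    def test_requires_expanded_model(self, small_toy):
        _, model, rset = small_toy
        asu = model.copy()
        asu.is_p1_expanded = False
        with pytest.raises(ValueError, match="P1-expanded"):
            run_refinement(asu, rset)

    def test_zero_temperature_descent_keeps_perfect_model(self, p21_toy):
        """A damped (0 K) run started from the generating model stays at it."""
        _, model, rset = p21_toy
        sched = Schedule(heat_ps=0.05, ramp_ps=0.15, cool_ps=1.2, t_high=0.0,
                         dt_fs=0.5, seed=3)
        restr = HarmonicRestraints(model)
        refined, trace = run_refinement(model, rset, sched, restraints=restr)
        assert trace.r_work[-1] < 0.02
        assert heavy_atom_rmsd(refined, model) < 0.05


class TestScramble:
    def test_seed_reproducible(self, p21_toy):
        _, model, _ = p21_toy
        a, ra = scramble_model(model, heat_ps=0.2, run_ps=0.3, seed=9)
        b, rb = scramble_model(model, heat_ps=0.2, run_ps=0.3, seed=9)
        assert np.array_equal(a.frac, b.frac)
        assert ra == rb

    def test_longer_runs_drift_further_on_average(self, p21_toy):
        _, model, _ = p21_toy
        means = []
        for run_ps in (0.5, 2.0):
            rmsds = [scramble_model(model, heat_ps=0.5, run_ps=run_ps, seed=s)[1]
                     for s in (1, 2, 3)]
            means.append(np.mean(rmsds))
        assert means[1] >= means[0]


class TestBFactorRefinement:
    def test_uniform_b_recovered(self):
        spec = ToySpec(seed=3, b_range=(20.0, 20.0))
        model = make_toy_crystal(spec)
        rset = simulate_f_obs(model, spec)
        start = model.copy()
        start.set_b_iso(np.full(model.n_atoms, 40.0))
        refined = refine_b_factors(start, rset)
        assert refined.b_iso.mean() == pytest.approx(20.0, rel=0.2)
        assert np.allclose(refined.frac, start.frac)  # coordinates untouched

    def test_r_work_does_not_increase_from_truth(self, p21_toy):
        _, model, rset = p21_toy
        engine = XrayEngine(rset)
        engine.refresh(model)
        r_before = engine.target(model, with_forces=False)[0].r_work
        refined = refine_b_factors(model, rset)
        engine2 = XrayEngine(rset)
        engine2.refresh(refined)
        r_after = engine2.target(refined, with_forces=False)[0].r_work
        assert r_after <= r_before + 1e-4  # numerically zero on both sides

    def test_clamp_respected(self, p21_toy):
        _, model, rset = p21_toy
        start = model.copy()
        start.set_b_iso(np.full(model.n_atoms, 190.0))
        refined = refine_b_factors(start, rset)
        assert refined.b_iso.min() >= 1.0
        assert refined.b_iso.max() <= 200.0


class TestSelectFinal:
    def test_lowest_r_free_wins(self):
        assert select_final([("A", 0.30), ("B", 0.28)]) == "B"

    def test_single_candidate(self):
        assert select_final([("A", 0.5)]) == "A"

    def test_tie_keeps_earlier_stage(self):
        assert select_final([("early", 0.30), ("late", 0.30)]) == "early"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_final([])


class TestRmsd:
    def test_origin_shift_mode_ignores_uniform_translation(self, small_toy):
        _, model, _ = small_toy
        moved = model.copy()
        moved.set_frac(model.frac + np.array([0.05, 0.02, 0.07]))
        assert heavy_atom_rmsd(moved, model) > 0.5
        assert heavy_atom_rmsd(moved, model, allow_origin_shift=True) < 1e-9

    def test_atom_matching_ignores_equal_element_swap(self, small_toy):
        _, model, _ = small_toy
        els = np.array(model.elements)
        i, j = np.nonzero(els == "C")[0][:2]
        swapped = model.copy()
        frac = swapped.frac.copy()
        frac[[i, j]] = frac[[j, i]]
        swapped.set_frac(frac)
        assert heavy_atom_rmsd(swapped, model) > 0.1
        assert heavy_atom_rmsd(swapped, model, match_atoms=True) < 1e-9
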