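"""Direct-summation structure factors, solvent mask, scaling."""

import numpy as np
import pytest

from ucrefine.model import AtomicModel, AtomRecord, UnitCellGeometry, operators_for
from ucrefine.mltarget import r_factors
from ucrefine.reflections import full_hemisphere
from ucrefine.scattering import (
    ScaleModel,
    build_solvent_mask,
    f_calc,
    f_calc_gradients,
    f_mask,
    fit_scales,
    form_factor,
)
from ucrefine.toys import ToySpec, make_toy_crystal, simulate_f_obs


def sf_bruteforce(model, hkl):
    """Independent double-loop direct summation (the oracle)."""
    out = np.zeros(len(hkl), dtype=complex)
    for i, h in enumerate(hkl):
        d = model.cell.d_spacing(h)
        s = 1.0 / (2.0 * d)
        acc = 0.0 + 0.0j
        for j in range(model.n_atoms):
            f = form_factor(model.elements[j], s)
            dw = np.exp(-model.b_iso[j] * s * s)
            phase = np.exp(2j * np.pi * float(np.dot(h, model.frac[j])))
            acc += model.occupancy[j] * f * dw * phase
        out[i] = acc
    return out


ELECTRONS = {"C": 6, "N": 7, "O": 8, "S": 16}


class TestFormFactor:
    @pytest.mark.parametrize("el,z", sorted(ELECTRONS.items()))
    def test_forward_scattering_equals_electron_count(self, el, z):
        assert form_factor(el, 0.0) == pytest.approx(z, abs=0.05)

    @pytest.mark.parametrize("el", ["C", "N", "O", "S"])
    def test_strictly_decreasing_on_unit_interval(self, el):
        s = np.linspace(0, 1, 101)
        f = form_factor(el, s)
        assert np.all(np.diff(f) < 0)

    def test_unknown_element_rejected(self):
        with pytest.raises(KeyError, match="Xx"):
            form_factor("Xx", 0.1)


class TestFCalc:
    def test_single_carbon_at_origin(self, cubic_cell):
        model = AtomicModel(
            cubic_cell, operators_for("P1"),
            [AtomRecord("C", "A", 1, "X", (0.0, 0.0, 0.0), 0.0)],
            is_p1_expanded=True,
        )
        hkl = np.array([(1, 0, 0), (1, 1, 0), (2, 1, 3)])
        F = f_calc(model, hkl)
        assert np.allclose(F.imag, 0, atol=1e-12)
        for h, val in zip(hkl, F.real):
            s = 1.0 / (2.0 * cubic_cell.d_spacing(h))
            assert val == pytest.approx(form_factor("C", s), rel=1e-12)

    def test_shift_theorem(self, small_toy):
        _, model, _ = small_toy
        hkl = full_hemisphere(model.cell, 2.8)
        F0 = f_calc(model, hkl)
        t = np.array([0.13, 0.27, 0.41])
        shifted = model.copy()
        shifted.set_frac(model.frac + t)
        F1 = f_calc(shifted, hkl)
        expected = F0 * np.exp(2j * np.pi * (hkl @ t))
        assert np.allclose(F1, expected, rtol=1e-10, atol=1e-9)
        assert np.allclose(np.abs(F1), np.abs(F0), rtol=1e-10)

    def test_friedel_symmetry(self, small_toy):
        _, model, _ = small_toy
        hkl = np.array([(1, 2, 3), (2, -1, 0), (0, 3, -2)])
        assert np.allclose(f_calc(model, -hkl), np.conj(f_calc(model, hkl)), rtol=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        spec = ToySpec(seed=17, n_atoms=25, space_group="P21")  # 50-atom cell
        model = make_toy_crystal(spec)
        hkl = full_hemisphere(model.cell, 2.0)
        hkl = hkl[rng.choice(len(hkl), 200, replace=False)]
        fast = f_calc(model, hkl)
        oracle = sf_bruteforce(model, hkl)
        assert np.allclose(fast, oracle, rtol=1e-10)

    def test_requires_expanded_model(self, cubic_cell):
        asu = AtomicModel(cubic_cell, operators_for("P21"),
                          [AtomRecord("C", "A", 1, "X", (0.1, 0.2, 0.3), 10.0)])
        with pytest.raises(ValueError, match="P1-expanded"):
            f_calc(asu, np.array([(1, 0, 0)]))

    def test_origin_index_rejected(self, small_toy):
        _, model, _ = small_toy
        with pytest.raises(ValueError):
            f_calc(model, np.array([(0, 0, 0)]))


class TestGradients:
    def test_zero_weights_zero_gradient(self, small_toy):
        _, model, _ = small_toy
        hkl = full_hemisphere(model.cell, 3.0)
        gx, gb = f_calc_gradients(model, hkl, np.zeros(len(hkl), dtype=complex))
        assert not gx.any() and not gb.any()

    def test_weight_length_checked(self, small_toy):
        _, model, _ = small_toy
        with pytest.raises(ValueError, match="length"):
            f_calc_gradients(model, np.array([(1, 0, 0)]), np.zeros(3, dtype=complex))

    def test_gradient_matches_finite_differences(self, small_toy, rng):
        """d/dx and d/dB of a quadratic functional of F_calc vs central FD."""
        _, model, _ = small_toy
        hkl = full_hemisphere(model.cell, 2.6)
        target_f = np.abs(f_calc(model, hkl)) * rng.uniform(0.8, 1.2, len(hkl))

        def target(m):
            return float(np.sum((np.abs(f_calc(m, hkl)) - target_f) ** 2))

        F = f_calc(model, hkl)
        w = 2.0 * (np.abs(F) - target_f) * F / np.abs(F)
        gx, gb = f_calc_gradients(model, hkl, w)

        h = 1e-5
        cart = model.cartesian()
        for j in rng.choice(model.n_atoms, 4, replace=False):
            for ax in range(3):
                up, dn = model.copy(), model.copy()
                cu, cd = cart.copy(), cart.copy()
                cu[j, ax] += h
                cd[j, ax] -= h
                up.set_frac(model.cell.fractionalize(cu))
                dn.set_frac(model.cell.fractionalize(cd))
                fd = (target(up) - target(dn)) / (2 * h)
                assert gx[j, ax] == pytest.approx(fd, rel=1e-4, abs=1e-8)
        hb = 1e-3
        for j in rng.choice(model.n_atoms, 4, replace=False):
            up, dn = model.copy(), model.copy()
            bu, bd = model.b_iso.copy(), model.b_iso.copy()
            bu[j] += hb
            bd[j] -= hb
            up.set_b_iso(bu)
            dn.set_b_iso(bd)
            fd = (target(up) - target(dn)) / (2 * hb)
            assert gb[j] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_solvent_atoms_feel_no_force(self, small_toy):
        _, model, _ = small_toy
        from ucrefine.model import place_solvent

        wet = place_solvent(model, n_water=3, seed=2)
        hkl = full_hemisphere(wet.cell, 3.0)
        w = np.ones(len(hkl), dtype=complex)
        gx, gb = f_calc_gradients(wet, hkl, w)
        assert not gx[~wet.is_protein].any()
        assert gx[wet.is_protein].any()


class TestSolventMask:
    def test_empty_model_is_all_solvent(self, cubic_cell):
        empty = AtomicModel(cubic_cell, operators_for("P1"), [], is_p1_expanded=True)
        mask = build_solvent_mask(empty, 2.0)
        assert mask.solvent_fraction == 1.0
        hkl = np.array([(1, 0, 0), (0, 2, 1)])
        assert np.allclose(f_mask(mask, hkl), 0, atol=1e-10)

    def test_single_atom_excluded_volume(self):
        cell = UnitCellGeometry(30.0, 30.0, 30.0)
        model = AtomicModel(
            cell, operators_for("P1"),
            [AtomRecord("C", "A", 1, "X", (0.5, 0.5, 0.5), 10.0)],
            is_p1_expanded=True,
        )
        mask = build_solvent_mask(model, 1.6)  # fine grid for the volume check
        excluded = (1.0 - mask.solvent_fraction) * cell.volume
        # sphere of r_vdw + r_probe, grown back by r_shrink from outside
        r_eff = 1.70 + 1.11 - 0.9
        expected = 4.0 / 3.0 * np.pi * r_eff**3
        assert excluded == pytest.approx(expected, rel=0.15)

    def test_fraction_monotone_in_atoms(self, p21_toy):
        _, model, _ = p21_toy
        fractions = []
        for n in (4, 16, model.n_atoms):
            sub = AtomicModel(model.cell, model.operators, model.atoms[:n],
                              is_p1_expanded=True)
            fractions.append(build_solvent_mask(sub, 2.0).solvent_fraction)
        assert fractions[0] >= fractions[1] >= fractions[2]

    def test_toy_solvent_fraction_physical(self, p21_toy):
        _, model, _ = p21_toy
        frac = build_solvent_mask(model, 2.0).solvent_fraction
        assert 0.2 <= frac <= 0.9

    def test_babinet_complement(self, p21_toy):
        _, model, _ = p21_toy
        mask = build_solvent_mask(model, 2.0)
        comp = type(mask)(1.0 - mask.grid, mask.cell, mask.d_min)
        hkl = full_hemisphere(model.cell, 3.0)
        assert np.allclose(f_mask(comp, hkl), -f_mask(mask, hkl), atol=1e-9)

    def test_fmask_matches_direct_sum_on_small_grid(self, rng):
        from ucrefine.scattering import SolventMaskGrid

        cell = UnitCellGeometry(12.0, 12.0, 12.0)
        grid = (rng.random((12, 12, 12)) > 0.5).astype(float)
        mask = SolventMaskGrid(grid, cell, 2.0)
        hkl = np.array([(1, 0, 0), (2, 3, 1), (-4, 2, 5), (0, 0, 5)])
        got = f_mask(mask, hkl)
        # brute-force transform oracle
        n = 12
        idx = np.indices((n, n, n)).reshape(3, -1).T / n
        for h, val in zip(hkl, got):
            phases = np.exp(2j * np.pi * (idx @ h))
            oracle = cell.volume / n**3 * (grid.ravel() * phases).sum()
            assert val == pytest.approx(oracle, rel=1e-10, abs=1e-9)

    def test_nyquist_guard(self, p21_toy):
        _, model, _ = p21_toy
        mask = build_solvent_mask(model, 2.0)
        big = np.array([(mask.shape[0], 0, 0)])
        with pytest.raises(ValueError, match="Nyquist"):
            f_mask(mask, big)


class TestFitScales:
    def test_recovers_exact_global_factor(self, p21_toy):
        _, model, rset = p21_toy
        hkl = rset.hkl
        fc = f_calc(model, hkl)
        f_obs = 2.0 * np.abs(fc)
        sm, fm_abs = fit_scales(f_obs, fc, np.zeros_like(fc), hkl, rset.shell_id,
                                cell=model.cell)
        assert np.allclose(sm.k_overall * sm.k_iso, 2.0, atol=1e-6)
        assert r_factors(f_obs, fm_abs)[0] < 1e-6

    def test_recovers_known_k_mask(self, p21_toy):
        spec, model, rset = p21_toy  # data generated with k_mask = 0.35
        fc = f_calc(model, rset.hkl)
        fmask = f_mask(build_solvent_mask(model, spec.d_min), rset.hkl)
        sm, fm_abs = fit_scales(rset.f_obs, fc, fmask, rset.hkl, rset.shell_id,
                                ~rset.is_free, cell=model.cell)
        assert np.abs(sm.k_mask - spec.k_mask_true).max() <= 0.05
        assert r_factors(rset.f_obs, fm_abs)[0] < 1e-4

    def test_scaling_never_worse_than_unit_scales(self, p21_toy, rng):
        _, model, rset = p21_toy
        noisy = model.copy()
        cart = noisy.cartesian() + rng.normal(0, 0.15, (model.n_atoms, 3))
        noisy.set_frac(model.cell.fractionalize(cart))
        fc = f_calc(noisy, rset.hkl)
        fmask = f_mask(build_solvent_mask(noisy, rset.d_min), rset.hkl)
        r_unit = r_factors(rset.f_obs, np.abs(fc + 0.0 * fmask))[0]
        _, fm_abs = fit_scales(rset.f_obs, fc, fmask, rset.hkl, rset.shell_id,
                               cell=model.cell)
        assert r_factors(rset.f_obs, fm_abs)[0] <= r_unit

    def test_empty_shell_inherits_neighbor(self, p21_toy):
        _, model, rset = p21_toy
        fc = f_calc(model, rset.hkl)
        shells = rset.shell_id.copy()
        work = ~rset.is_free & (shells != 3)  # empty one shell of work data
        with pytest.warns(UserWarning, match="shell 3"):
            sm, _ = fit_scales(rset.f_obs, fc, np.zeros_like(fc), rset.hkl,
                               shells, work, cell=model.cell)
        assert sm.k_mask[3] == sm.k_mask[2]
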