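"""Annealed restrained-dynamics refinement of a P1 unit-cell model.

The refinement is a short Langevin-dynamics run in which every atom feels
the sum of a restraint (force-field stand-in) force and the X-ray force,

    E_total = E_restraints + w_xray(t) * E_xray,

following a three-phase annealing program: heating (temperature ramped
from 0 K to 298 K with harmonic positional restraints of
10 kcal/mol/A^2 holding the protein atoms, w_xray = 0), a ramp phase
(298 K, restraints released, w_xray raised linearly from 0 to 1), and
cooling (298 K down to 0 K at the plateau weight w_xray = 1, steering the
system into the energy minimum).  At the defaults the program is
20 ps + 10 ps + 10 ps = 40 ps; the Langevin thermostat uses collision
frequency gamma = 2/ps.  The solvent mask, scale model and the
shell-wise likelihood parameters alpha/beta are refreshed every 100
integrator steps (0.2 ps at a 2 fs timestep) and treated as constants in
between, so the atomic forces are the analytic derivatives of E_xray at
frozen scaling/likelihood parameters.

The molecular-mechanics force field itself is deliberately pluggable: any
callable mapping Cartesian coordinates to ``(energy, gradient)`` fits the
``RestraintModel`` contract.  The built-in :class:`HarmonicRestraints` is
a simple geometry regularizer (harmonic bonds and angles referenced to
the starting topology plus a soft-sphere repulsion with an 8 A cutoff)
sufficient to keep toy models stereochemically sane during annealing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Protocol

import numpy as np

from ._tables import element_mass
from .model import AtomicModel
from .mltarget import (
    TargetResult,
    estimate_alpha_beta,
    expand_shell_params,
    ml_target_acentric,
)
from .reflections import ReflectionSet, assign_shells
from .scattering import (
    ScaleModel,
    build_solvent_mask,
    f_calc,
    f_calc_gradients,
    f_mask,
    fit_scales,
)

__all__ = [
    "Schedule",
    "RestraintModel",
    "HarmonicRestraints",
    "PositionalRestraint",
    "XrayEngine",
    "LangevinIntegrator",
    "RefinementTrace",
    "run_refinement",
    "scramble_model",
    "refine_b_factors",
    "select_final",
    "heavy_atom_rmsd",
]

KB_KCAL = 0.0019872041          # kcal/mol/K
ACC_UNIT = 418.4                # (kcal/mol/A)/(g/mol) -> A/ps^2
KB_EFF = KB_KCAL * ACC_UNIT     # amu A^2 ps^-2 K^-1
FORCE_LIMIT = 1e5               # kcal/mol/A divergence guard


# --------------------------------------------------------------------------
# schedule


@dataclass(frozen=True)
class Schedule:
    """The heat / ramp / cool annealing program.

    Times are picoseconds; ``dt_fs`` is the integrator step in
    femtoseconds.  ``scaled(f)`` shortens (or lengthens) all three phases
    by a common factor for desk-scale runs.
    """

    heat_ps: float = 20.0
    ramp_ps: float = 10.0
    cool_ps: float = 10.0
    t_high: float = 298.0
    dt_fs: float = 2.0
    gamma_ps: float = 2.0
    update_interval: int = 100
    k_pos_restraint: float = 10.0   # kcal/mol/A^2, heat phase only
    w_plateau: float = 1.0
    seed: int = 0

    @property
    def total_ps(self) -> float:
        return self.heat_ps + self.ramp_ps + self.cool_ps

    @property
    def dt_ps(self) -> float:
        return self.dt_fs * 1e-3

    @property
    def n_steps(self) -> int:
        return int(round(self.total_ps / self.dt_ps))

    def temperature(self, t_ps: float) -> float:
        """Target temperature (K) at time t."""
        if t_ps <= self.heat_ps:
            return self.t_high * (t_ps / self.heat_ps if self.heat_ps > 0 else 1.0)
        if t_ps <= self.heat_ps + self.ramp_ps:
            return self.t_high
        rem = self.total_ps - t_ps
        return self.t_high * max(rem, 0.0) / self.cool_ps if self.cool_ps > 0 else 0.0

    def w_xray(self, t_ps: float) -> float:
        """X-ray weight at time t (0 in heat, linear ramp, plateau in cool)."""
        if t_ps <= self.heat_ps:
            return 0.0
        if t_ps <= self.heat_ps + self.ramp_ps:
            frac = (t_ps - self.heat_ps) / self.ramp_ps if self.ramp_ps > 0 else 1.0
            return self.w_plateau * frac
        return self.w_plateau

    def restraints_active(self, t_ps: float) -> bool:
        """Positional restraints hold the atoms only during heating."""
        return t_ps < self.heat_ps

    def scaled(self, factor: float) -> "Schedule":
        return replace(
            self,
            heat_ps=self.heat_ps * factor,
            ramp_ps=self.ramp_ps * factor,
            cool_ps=self.cool_ps * factor,
        )


# --------------------------------------------------------------------------
# restraint potentials


class RestraintModel(Protocol):
    """Contract for the force-field term: cart (N,3) -> (energy, gradient)."""

    def __call__(self, cart: np.ndarray) -> tuple[float, np.ndarray]: ...


class HarmonicRestraints:
    """Geometry regularizer referenced to the starting topology.

    Bonds are all heavy-atom pairs closer than ``bond_cutoff`` in the
    reference model (periodic minimum image); each keeps its reference
    length with force constant ``k_bond``.  Angles between pairs of bonds
    sharing an atom keep their reference value with ``k_angle``.  All
    non-bonded pairs feel a soft-sphere quadratic repulsion below
    ``rep_r0``, with each pair's onset capped at its reference separation
    so the reference geometry itself is penalty-free (the restraint
    minimum coincides with the reference, as a force field's does with
    ideal geometry).  The energy depends only on interatomic distances
    and angles, so it is exactly translation- and rotation-invariant.
    """

    def __init__(
        self,
        model: AtomicModel,
        k_bond: float = 200.0,
        bond_cutoff: float = 1.85,
        k_angle: float = 40.0,
        k_rep: float = 20.0,
        rep_r0: float = 2.4,
        rep_cutoff: float = 8.0,
    ) -> None:
        self.cell = model.cell
        self.k_bond = k_bond
        self.k_angle = k_angle
        self.k_rep = k_rep
        self.rep_r0 = rep_r0
        self.rep_cutoff = rep_cutoff
        cart = model.cartesian()
        n = len(cart)
        d = self._pair_distances(cart)
        iu = np.triu_indices(n, k=1)
        bonded = d[iu] < bond_cutoff
        self.bonds = np.column_stack([iu[0][bonded], iu[1][bonded]])
        self.bond_r0 = d[self.bonds[:, 0], self.bonds[:, 1]] if len(self.bonds) else np.empty(0)
        self._bond_set = {tuple(b) for b in self.bonds}
        # per-pair repulsion onset: never beyond the reference separation,
        # zero for bonded pairs
        self._rep_r0 = np.minimum(rep_r0, d - 1e-9)
        np.fill_diagonal(self._rep_r0, 0.0)
        for i, j in self.bonds:
            self._rep_r0[i, j] = self._rep_r0[j, i] = 0.0
        # angles: j is the apex for every pair of its bonded partners
        partners: dict[int, list[int]] = {}
        for i, j in self.bonds:
            partners.setdefault(int(i), []).append(int(j))
            partners.setdefault(int(j), []).append(int(i))
        angles = []
        for apex, nbrs in partners.items():
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    angles.append((nbrs[a], apex, nbrs[b]))
        self.angles = np.array(angles, dtype=int).reshape(-1, 3)
        self.angle_theta0 = np.array(
            [self._angle(cart, *ijk) for ijk in self.angles]
        ) if len(self.angles) else np.empty(0)

    # -- geometry helpers (periodic minimum image) --

    def _min_image(self, dcart: np.ndarray) -> np.ndarray:
        frac = dcart @ self.cell.frac_matrix.T
        frac -= np.round(frac)
        return frac @ self.cell.orth_matrix.T

    def _pair_distances(self, cart: np.ndarray) -> np.ndarray:
        d = cart[:, None, :] - cart[None, :, :]
        shape = d.shape
        d = self._min_image(d.reshape(-1, 3)).reshape(shape)
        return np.linalg.norm(d, axis=-1)

    def _angle(self, cart, i, j, k) -> float:
        u = self._min_image((cart[i] - cart[j])[None])[0]
        v = self._min_image((cart[k] - cart[j])[None])[0]
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return math.acos(min(1.0, max(-1.0, c)))

    def __call__(self, cart: np.ndarray) -> tuple[float, np.ndarray]:
        cart = np.asarray(cart, dtype=float)
        energy = 0.0
        grad = np.zeros_like(cart)

        if len(self.bonds):
            dv = self._min_image(cart[self.bonds[:, 0]] - cart[self.bonds[:, 1]])
            r = np.linalg.norm(dv, axis=1)
            dr = r - self.bond_r0
            energy += float(self.k_bond * (dr**2).sum())
            g = (2.0 * self.k_bond * dr / r)[:, None] * dv
            np.add.at(grad, self.bonds[:, 0], g)
            np.add.at(grad, self.bonds[:, 1], -g)

        for (i, j, k), th0 in zip(self.angles, self.angle_theta0):
            u = self._min_image((cart[i] - cart[j])[None])[0]
            v = self._min_image((cart[k] - cart[j])[None])[0]
            ru, rv = np.linalg.norm(u), np.linalg.norm(v)
            c = np.dot(u, v) / (ru * rv)
            c = min(1.0, max(-1.0, c))
            th = math.acos(c)
            s = math.sqrt(max(1.0 - c * c, 1e-12))
            dEdth = 2.0 * self.k_angle * (th - th0)
            energy += float(self.k_angle * (th - th0) ** 2)
            dth_du = -(v / (ru * rv) - c * u / (ru * ru)) / s
            dth_dv = -(u / (ru * rv) - c * v / (rv * rv)) / s
            grad[i] += dEdth * dth_du
            grad[k] += dEdth * dth_dv
            grad[j] -= dEdth * (dth_du + dth_dv)

        # soft-sphere repulsion on non-bonded pairs (pairwise onset radii)
        n = len(cart)
        d = cart[:, None, :] - cart[None, :, :]
        shape = d.shape
        dv = self._min_image(d.reshape(-1, 3)).reshape(shape)
        r = np.linalg.norm(dv, axis=-1)
        iu = np.triu_indices(n, k=1)
        close = (r[iu] < self._rep_r0[iu]) & (r[iu] > 1e-9)
        for p in np.nonzero(close)[0]:
            i, j = int(iu[0][p]), int(iu[1][p])
            rij = r[i, j]
            dr = self._rep_r0[i, j] - rij
            energy += float(self.k_rep * dr * dr)
            g = (-2.0 * self.k_rep * dr / rij) * dv[i, j]
            grad[i] += g
            grad[j] -= g
        return energy, grad


class PositionalRestraint:
    """Harmonic tether to reference Cartesian coordinates (minimum image)."""

    def __init__(self, model: AtomicModel, k: float = 10.0, protein_only: bool = True):
        self.cell = model.cell
        self.ref = model.cartesian()
        self.k = k
        self.mask = model.is_protein if protein_only else np.ones(model.n_atoms, bool)

    def __call__(self, cart: np.ndarray) -> tuple[float, np.ndarray]:
        d = cart - self.ref
        frac = d @ self.cell.frac_matrix.T
        frac -= np.round(frac)
        d = frac @ self.cell.orth_matrix.T
        d[~self.mask] = 0.0
        energy = float(self.k * (d**2).sum())
        return energy, 2.0 * self.k * d


# --------------------------------------------------------------------------
# the X-ray engine: E_xray, forces, periodic parameter refresh


class XrayEngine:
    """Evaluates E_xray and its atomic forces against one reflection set.

    ``refresh(model)`` rebuilds the solvent mask, refits the scale model
    and re-estimates alpha/beta from the current coordinates; in between,
    ``target(model)`` treats those parameters as constants (their
    dependence on the coordinates is deliberately ignored, as is standard
    in refinement), so forces are the exact analytic gradient of the
    frozen-parameter E_xray.
    """

    def __init__(
        self, reflections: ReflectionSet, n_shells: int = 10,
        beta_floor_rel: float = 1e-6,
    ):
        if reflections.shell_id.max() < 0:
            reflections = assign_shells(
                reflections, min(n_shells, max(1, len(reflections) // 50) or 1)
            )
        self.rset = reflections
        self.beta_floor_rel = beta_floor_rel
        self.hkl = reflections.hkl
        self.f_obs = reflections.f_obs
        self.work = ~reflections.is_free
        self.shell_id = reflections.shell_id
        self.scale: ScaleModel | None = None
        self._fmask: np.ndarray | None = None
        self.alpha: np.ndarray | None = None
        self.beta: np.ndarray | None = None

    def refresh(self, model: AtomicModel) -> None:
        fc = f_calc(model, self.hkl)
        mask = build_solvent_mask(model, self.rset.d_min)
        self._fmask = f_mask(mask, self.hkl)
        self.scale, fm_abs = fit_scales(
            self.f_obs, fc, self._fmask, self.hkl, self.shell_id, self.work,
            cell=self.rset.cell,
        )
        params = estimate_alpha_beta(
            self.f_obs, fm_abs, self.shell_id, self.work,
            beta_floor_rel=self.beta_floor_rel,
        )
        self.alpha, self.beta = expand_shell_params(params, self.shell_id)

    def target(self, model: AtomicModel, with_forces: bool = True):
        """Returns ``(TargetResult, force (N,3) or None, dE/dB or None)``."""
        if self.scale is None:
            self.refresh(model)
        fc = f_calc(model, self.hkl)
        fsum = fc + self.scale.k_mask[self.shell_id] * self._fmask
        k_tot = self.scale.k_total(self.hkl, self.shell_id)
        fm_abs = k_tot * np.abs(fsum)
        res = ml_target_acentric(self.f_obs, fm_abs, self.alpha, self.beta, self.work)
        if not with_forces:
            return res, None, None
        abs_fsum = np.abs(fsum)
        phase = np.where(abs_fsum > 0, fsum / np.where(abs_fsum > 0, abs_fsum, 1.0), 1.0)
        w = res.de_dfm * k_tot * phase
        grad_xyz, grad_b = f_calc_gradients(model, self.hkl, w)
        return res, -grad_xyz, grad_b

    def f_model_complex(self, model: AtomicModel) -> np.ndarray:
        if self.scale is None:
            self.refresh(model)
        fc = f_calc(model, self.hkl)
        return self.scale.f_model(self.hkl, self.shell_id, fc, self._fmask)


# --------------------------------------------------------------------------
# Langevin dynamics (BAOAB)


class LangevinIntegrator:
    """BAOAB splitting of Langevin dynamics; deterministic for a seed.

    Units: coordinates A, time ps, masses g/mol, forces kcal/mol/A.  At
    T = 0 the noise vanishes and the scheme reduces to damped
    gradient-following dynamics.
    """

    def __init__(
        self, masses: np.ndarray, dt_ps: float, gamma_ps: float, seed: int = 0,
        remove_com: bool = True, max_shift: float = 0.05,
    ):
        if dt_ps <= 0:
            raise ValueError("timestep must be positive")
        self.m = np.asarray(masses, dtype=float)[:, None]
        self.dt = dt_ps
        self.gamma = gamma_ps
        self.rng = np.random.default_rng(seed)
        self._c1 = math.exp(-gamma_ps * dt_ps)
        # an amplitude-only X-ray target leaves the cell origin unrestrained,
        # so centre-of-mass drift is removed by default (as MD engines do)
        self.remove_com = remove_com
        # per-step atomic shift cap (A): the ML target stiffens sharply as
        # the fit improves, and capping the step keeps the fixed-dt
        # integrator stable there (the usual practice in SA refinement);
        # 0.05 A sits well above thermal step sizes at 298 K yet bounds
        # the residual amplitude of unresolvable stiff modes
        self.max_shift = max_shift

    def _clamp(self, vel: np.ndarray) -> np.ndarray:
        if not self.max_shift:
            return vel
        vmax = self.max_shift / self.dt
        speed = np.linalg.norm(vel, axis=1, keepdims=True)
        factor = np.minimum(1.0, vmax / np.maximum(speed, 1e-30))
        return vel * factor

    def step(
        self, cart: np.ndarray, vel: np.ndarray, force: np.ndarray,
        temperature: float, force_fn: Callable[[np.ndarray], np.ndarray],
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """One BAOAB step; returns (cart, vel, force-at-new-positions)."""
        dt, m = self.dt, self.m
        vel = self._clamp(vel + 0.5 * dt * ACC_UNIT * force / m)
        cart = cart + 0.5 * dt * vel
        sigma = np.sqrt(KB_EFF * max(temperature, 0.0) / m * (1.0 - self._c1**2))
        vel = self._c1 * vel + sigma * self.rng.standard_normal(vel.shape)
        if self.remove_com:
            vel = vel - (self.m * vel).sum(axis=0) / self.m.sum()
        cart = cart + 0.5 * dt * vel
        force = force_fn(cart)
        if np.abs(force).max() > FORCE_LIMIT:
            j = int(np.abs(force).max(axis=1).argmax())
            raise RuntimeError(
                f"dynamics diverged: |force| = {np.abs(force).max():.3g} kcal/mol/A "
                f"on atom {j}; reduce the timestep or check the data"
            )
        vel = self._clamp(vel + 0.5 * dt * ACC_UNIT * force / m)
        return cart, vel, force


# --------------------------------------------------------------------------
# driver operations


@dataclass
class RefinementTrace:
    """Per-update-step bookkeeping of the annealing run."""

    time_ps: list[float] = field(default_factory=list)
    temperature: list[float] = field(default_factory=list)
    w_xray: list[float] = field(default_factory=list)
    e_restraints: list[float] = field(default_factory=list)
    e_xray: list[float] = field(default_factory=list)
    e_total: list[float] = field(default_factory=list)
    r_work: list[float] = field(default_factory=list)
    r_free: list[float | None] = field(default_factory=list)

    def record(self, t, T, w, er, ex, rw, rf):
        self.time_ps.append(float(t))
        self.temperature.append(float(T))
        self.w_xray.append(float(w))
        self.e_restraints.append(float(er))
        self.e_xray.append(float(ex))
        self.e_total.append(float(er) + float(w) * float(ex))
        self.r_work.append(float(rw))
        self.r_free.append(None if rf is None else float(rf))


def _masses(model: AtomicModel) -> np.ndarray:
    return np.array([element_mass(el) for el in model.elements])


def run_refinement(
    model: AtomicModel,
    reflections: ReflectionSet,
    schedule: Schedule | None = None,
    restraints: RestraintModel | None = None,
    beta_floor_rel: float = 1e-4,
) -> tuple[AtomicModel, RefinementTrace]:
    """Anneal the unit-cell model against the data; returns the final frame.

    The model must be P1-expanded and the reflection set expanded with
    free flags.  At every step the total force is the restraint force plus
    ``w_xray(t)`` times the ML force (the latter acting only on protein
    atoms); scale model, solvent mask and alpha/beta are refreshed every
    ``schedule.update_interval`` steps.  Positional restraints tether the
    protein atoms to the starting coordinates during the heat phase only.
    """
    if not model.is_p1_expanded:
        raise ValueError("run_refinement requires a P1-expanded model")
    schedule = schedule or Schedule()
    work = model.copy()
    if restraints is None:
        restraints = HarmonicRestraints(work)
    posres = PositionalRestraint(work, k=schedule.k_pos_restraint)
    # dynamics stability floor: with noiseless or near-perfect data the
    # estimated beta collapses and the target curvature outruns any fixed
    # timestep; flooring beta at a 1% amplitude-noise equivalent keeps the
    # forces integrable without moving the target's minimum
    engine = XrayEngine(reflections, beta_floor_rel=beta_floor_rel)
    integrator = LangevinIntegrator(
        _masses(work), schedule.dt_ps, schedule.gamma_ps, seed=schedule.seed
    )
    trace = RefinementTrace()

    cart = work.cartesian()
    vel = np.zeros_like(cart)
    state = {"w": 0.0, "t": 0.0, "er": 0.0, "ml": None}

    def force_fn(c: np.ndarray) -> np.ndarray:
        er, gr = restraints(c)
        f = -gr
        if schedule.restraints_active(state["t"]):
            ep, gp = posres(c)
            er += ep
            f -= gp
        state["er"] = er
        if state["w"] > 0.0:
            work.set_frac(work.cell.fractionalize(c))
            res, fx, _ = engine.target(work)
            state["ml"] = res
            f = f + state["w"] * fx
        return f

    force = force_fn(cart)
    n_steps = schedule.n_steps
    for step in range(n_steps):
        t_now = step * schedule.dt_ps
        t_next = (step + 1) * schedule.dt_ps
        state["t"] = t_next
        state["w"] = schedule.w_xray(t_next)
        if step % schedule.update_interval == 0:
            work.set_frac(work.cell.fractionalize(cart))
            engine.refresh(work)
            res, _, _ = engine.target(work, with_forces=False)
            trace.record(
                t_now, schedule.temperature(t_now), schedule.w_xray(t_now),
                state["er"], res.e_xray, res.r_work, res.r_free,
            )
            force = force_fn(cart)  # forces at the refreshed parameters
        T = schedule.temperature(t_next)
        cart, vel, force = integrator.step(cart, vel, force, T, force_fn)

    work.set_frac(work.cell.fractionalize(cart))
    engine.refresh(work)
    res, _, _ = engine.target(work, with_forces=False)
    trace.record(
        schedule.total_ps, schedule.temperature(schedule.total_ps),
        schedule.w_xray(schedule.total_ps), state["er"],
        res.e_xray, res.r_work, res.r_free,
    )
    return work, trace


def scramble_model(
    model: AtomicModel,
    heat_ps: float = 20.0,
    run_ps: float = 100.0,
    dt_fs: float = 2.0,
    gamma_ps: float = 2.0,
    k_pos_restraint: float = 10.0,
    t_high: float = 298.0,
    seed: int = 0,
    restraints: RestraintModel | None = None,
) -> tuple[AtomicModel, float]:
    """Manufacture an imperfect starting model by restrained-then-free MD.

    The model is heated from 0 to ``t_high`` over ``heat_ps`` with
    harmonic positional restraints on the protein atoms, then evolved
    unrestrained for ``run_ps`` (no X-ray term anywhere).  Returns the
    final frame and its heavy-atom r.m.s.d. to the input — an imitation of
    an imperfect model in need of refinement.  Longer free runs drift
    further on average.
    """
    if not model.is_p1_expanded:
        raise ValueError("scramble_model requires a P1-expanded model")
    work = model.copy()
    if restraints is None:
        restraints = HarmonicRestraints(work)
    posres = PositionalRestraint(work, k=k_pos_restraint)
    dt_ps = dt_fs * 1e-3
    integrator = LangevinIntegrator(_masses(work), dt_ps, gamma_ps, seed=seed)
    cart = work.cartesian()
    vel = np.zeros_like(cart)
    heating = {"on": True}

    def force_fn(c):
        _, gr = restraints(c)
        f = -gr
        if heating["on"]:
            _, gp = posres(c)
            f -= gp
        return f

    force = force_fn(cart)
    n_heat = int(round(heat_ps / dt_ps))
    for step in range(n_heat):
        T = t_high * (step + 1) / n_heat
        cart, vel, force = integrator.step(cart, vel, force, T, force_fn)
    heating["on"] = False
    force = force_fn(cart)
    for _ in range(int(round(run_ps / dt_ps))):
        cart, vel, force = integrator.step(cart, vel, force, t_high, force_fn)
    work.set_frac(work.cell.fractionalize(cart))
    return work, heavy_atom_rmsd(work, model)


def refine_b_factors(
    model: AtomicModel,
    reflections: ReflectionSet,
    n_steps: int = 25,
    b_bounds: tuple[float, float] = (1.0, 200.0),
    n_scale_shells: int = 1,
) -> AtomicModel:
    """Optimize per-atom isotropic B factors by bounded quasi-Newton.

    Runs ``n_steps`` L-BFGS iterations on the protein atoms' B factors
    minimizing E_xray at fixed coordinates, with B clamped to
    ``b_bounds``.  Scales, mask and alpha/beta are fitted once up front
    and held fixed during the minimization.  The scale model is refitted
    on ``n_scale_shells`` resolution shells (default one): a multi-shell
    k_iso absorbs exactly the smooth exp(dB s^2) signature that
    distinguishes B factors, leaving the B gradient blind to any overall
    offset, so B refinement uses a resolution-flat scale.  Before the
    per-atom step, the overall B offset between data and model is
    determined by a Wilson-style log-linear fit and moved onto the atoms
    (the usual ADP scale partitioning) — a scalar scale would otherwise
    pin the mean B at its starting value.
    """
    from scipy import optimize

    work = model.copy()
    rset1 = assign_shells(reflections, n_scale_shells)
    engine = XrayEngine(rset1)
    engine.refresh(work)

    # partition the overall B onto the atoms: against the full, flat-scaled
    # F_model the residual resolution trend is exp(-B_ov s^2); fit
    # ln(F_obs/|F_model|) ~ ln k - B_ov s^2 and move B_ov onto the atoms.
    # The scale refit partially re-absorbs each shift, so iterate to a
    # fixed point before the per-atom step.
    sel0 = np.nonzero(work.is_protein)[0]
    s2 = 0.25 / rset1.d**2
    for _ in range(10):
        fm_abs = np.abs(engine.f_model_complex(work))
        ok = (fm_abs > 0) & (rset1.f_obs > 0) & ~rset1.is_free
        y = np.log(rset1.f_obs[ok] / fm_abs[ok])
        X = np.column_stack([np.ones(int(ok.sum())), -s2[ok]])
        wts = np.sqrt(rset1.f_obs[ok] * fm_abs[ok])
        coef, *_ = np.linalg.lstsq(X * wts[:, None], y * wts, rcond=None)
        b_shift = float(coef[1])
        if abs(b_shift) < 0.25:
            break
        b0 = work.b_iso.copy()
        b0[sel0] = np.clip(b0[sel0] + b_shift, *b_bounds)
        work.set_b_iso(b0)
        engine.refresh(work)
    sel = np.nonzero(work.is_protein)[0]
    b_full = work.b_iso.copy()

    def objective(bvec):
        b_full[sel] = bvec
        work.set_b_iso(b_full)
        res, _, grad_b = engine.target(work)
        return res.e_xray, grad_b[sel]

    res = optimize.minimize(
        objective,
        x0=np.clip(work.b_iso[sel], *b_bounds),
        jac=True,
        method="L-BFGS-B",
        bounds=[b_bounds] * len(sel),
        options={"maxiter": n_steps, "maxfun": 10 * n_steps},
    )
    b_full[sel] = np.clip(res.x, *b_bounds)
    work.set_b_iso(b_full)
    return work


def select_final(candidates: list[tuple[AtomicModel, float]]) -> AtomicModel:
    """Pick the candidate with the lowest R_free; ties keep the earlier stage."""
    if not candidates:
        raise ValueError("no candidate models")
    best_i = 0
    for i, (_, rf) in enumerate(candidates):
        if rf < candidates[best_i][1]:
            best_i = i
    return candidates[best_i][0]


def heavy_atom_rmsd(
    a: AtomicModel, b: AtomicModel, protein_only: bool = True,
    allow_origin_shift: bool = False, match_atoms: bool = False,
) -> float:
    """R.m.s.d. over heavy atoms, periodic minimum-image, no rotation fit.

    With ``allow_origin_shift`` the mean displacement is subtracted first:
    in a P1 cell restrained only by amplitudes the absolute origin is
    unobservable (a rigid translation of the whole cell leaves every
    |F(h)| unchanged), so two models differing by a uniform shift are the
    same crystal structure.  With ``match_atoms`` atoms are paired by
    optimal assignment within each element class before measuring: atoms
    of one element are physically indistinguishable, so a permutation of
    equal-element labels is also the same structure.
    """
    sel = np.array([el != "H" for el in a.elements])
    if protein_only:
        sel &= a.is_protein
    fa, fb = a.frac[sel], b.frac[sel]
    if match_atoms:
        from scipy.optimize import linear_sum_assignment

        els = np.array(a.elements)[sel]
        order = np.arange(len(fa))
        for el in np.unique(els):
            idx = np.nonzero(els == el)[0]
            dfm = fa[idx][:, None, :] - fb[idx][None, :, :]
            dfm -= np.round(dfm)
            D = np.linalg.norm(np.einsum("mk,ijk->ijm", a.cell.orth_matrix, dfm), axis=2)
            ri, ci = linear_sum_assignment(D**2)
            order[idx[ri]] = idx[ci]
        fb = fb[order]
    df = fa - fb
    df -= np.round(df)
    d = df @ a.cell.orth_matrix.T
    if allow_origin_shift:
        d = d - d.mean(axis=0)
    return float(np.sqrt((d**2).sum(axis=1).mean()))
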