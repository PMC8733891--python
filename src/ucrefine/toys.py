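"""Synthetic toy crystals and simulated diffraction data.

Every stage of the engine is testable at desk scale against crystals
generated here: a handful of light atoms placed in a small cell of one of
the fixture space groups (P1, P21, P212121, C2), with complete simulated
amplitude data to a chosen resolution.  Simulated F_obs are the model
amplitudes of the generating structure under known true scales and bulk
solvent, optionally with multiplicative Gaussian noise, so parameter-
recovery tests know the ground truth exactly.

Toys are deliberately small (<= 200 atoms per cell, d_min >= 1.5 A,
<= 5000 reflections) so that brute-force oracles — double-loop structure
factors, orbit enumeration, finite differences — stay affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    AtomicModel,
    AtomRecord,
    UnitCellGeometry,
    build_unit_cell,
    operators_for,
)
from .reflections import ReflectionSet, assign_shells, full_hemisphere, generate_free_flags
from .scattering import ScaleModel, build_solvent_mask, f_calc, f_mask

__all__ = ["ToySpec", "make_toy_crystal", "simulate_f_obs", "perturb_model"]

_TOY_ELEMENTS = ("C", "C", "C", "N", "O")  # roughly protein-like composition


@dataclass
class ToySpec:
    """Recipe for a synthetic crystal and its simulated data."""

    space_group: str = "P21"
    cell: UnitCellGeometry = field(
        default_factory=lambda: UnitCellGeometry(16.0, 18.0, 17.0, 90.0, 95.0, 90.0)
    )
    n_atoms: int = 24            # atoms in the asymmetric unit
    chain_len: int = 8           # atoms per bonded chain fragment
    bond_length: float = 1.5     # A between consecutive chain atoms
    b_range: tuple[float, float] = (10.0, 30.0)
    d_min: float = 2.0
    noise: float = 0.0           # relative sigma of multiplicative amplitude noise
    k_mask_true: float = 0.35
    u_aniso_true: tuple[float, ...] = (0.0,) * 6
    free_fraction: float = 0.10
    n_shells: int = 8
    min_separation: float = 1.2
    seed: int = 0


def make_toy_crystal(spec: ToySpec, expand: bool = True) -> AtomicModel:
    """Generate a random toy crystal satisfying its own symmetry exactly.

    Atoms are placed in the asymmetric unit as short bonded chains
    (consecutive atoms ``spec.bond_length`` apart, mimicking a covalently
    connected protein fragment) by rejection sampling, so that every atom
    keeps at least ``spec.min_separation`` Angstrom (periodic metric) from
    all non-adjacent atoms *and all symmetry mates*; the expanded cell
    therefore obeys the same separation rule.  Deterministic for a given
    seed.  The chain topology keeps the built-in harmonic restraint model
    connected, as a real molecule's bond network would be.
    """
    rng = np.random.default_rng(spec.seed)
    ops = operators_for(spec.space_group)
    cell = spec.cell
    A = cell.orth_matrix
    Ainv = cell.frac_matrix
    placed_frac: list[np.ndarray] = []   # all symmetry copies, one row per mate
    asu_frac: list[np.ndarray] = []
    records: list[AtomRecord] = []

    def clears(cand: np.ndarray) -> bool:
        """cand's symmetry mates clear all placed atoms and each other."""
        mates = np.array([op.apply(cand) for op in ops])
        old = np.vstack(placed_frac) if placed_frac else np.empty((0, 3))
        for a, m in enumerate(mates):
            others = np.vstack([old, mates[a + 1:]])
            if len(others):
                df = others - m
                df -= np.round(df)
                if np.linalg.norm(df @ A.T, axis=1).min() < spec.min_separation:
                    return False
        return True

    for i in range(spec.n_atoms):
        chain_pos = i % spec.chain_len
        for attempt in range(10_000):
            if chain_pos == 0 or not asu_frac:
                cand = rng.random(3)
            else:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                cart_prev = A @ asu_frac[-1]
                cand = (Ainv @ (cart_prev + spec.bond_length * direction)) % 1.0
            if clears(cand):
                break
        else:
            raise RuntimeError(
                f"could not place atom {i + 1}/{spec.n_atoms} after 10000 attempts; "
                "cell too crowded"
            )
        asu_frac.append(cand)
        placed_frac.append(np.array([op.apply(cand) for op in ops]))
        records.append(
            AtomRecord(
                element=_TOY_ELEMENTS[rng.integers(len(_TOY_ELEMENTS))],
                chain="A",
                residue_id=i + 1,
                atom_name="X",
                frac=tuple(cand),
                b_iso=float(rng.uniform(*spec.b_range)),
                residue_name="TOY",
            )
        )
    asu = AtomicModel(cell, ops, records, is_p1_expanded=False)
    return build_unit_cell(asu) if expand else asu


def simulate_f_obs(model: AtomicModel, spec: ToySpec) -> ReflectionSet:
    """Complete simulated amplitudes to d_min from the generating model.

    F_obs = |F_model| under the true scales (k_overall = 1, per-shell
    k_iso = 1, k_mask = ``spec.k_mask_true``, anisotropic coefficients
    ``spec.u_aniso_true``), with optional multiplicative Gaussian noise
    N(1, noise^2) truncated at zero.  The set covers every hemisphere
    index with d >= d_min exactly once, binned into ``spec.n_shells``
    shells with free flags at ``spec.free_fraction``.
    """
    if spec.noise < 0:
        raise ValueError("noise level must be non-negative")
    if not model.is_p1_expanded:
        raise ValueError("simulate_f_obs needs the expanded unit-cell model")
    hkl = full_hemisphere(model.cell, spec.d_min)
    fc = f_calc(model, hkl)
    mask = build_solvent_mask(model, spec.d_min)
    fm = f_mask(mask, hkl)
    f_true = np.abs(fc + spec.k_mask_true * fm)
    sm = ScaleModel(1.0, np.asarray(spec.u_aniso_true, dtype=float),
                    np.ones(1), np.array([spec.k_mask_true]))
    f_true = f_true * sm.k_aniso(hkl)
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed + 1)
        factor = np.maximum(rng.normal(1.0, spec.noise, len(f_true)), 0.0)
        f_obs = f_true * factor
        sig = spec.noise * f_true
    else:
        f_obs = f_true
        sig = np.full(len(f_true), np.nan)
    df = pd.DataFrame(
        {"h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2], "f_obs": f_obs, "sig_f": sig}
    )
    rset = ReflectionSet(model.cell, df, provenance="p1-expanded",
                         operators=list(model.operators))
    rset = assign_shells(rset, spec.n_shells)
    if spec.free_fraction > 0:
        rset = generate_free_flags(rset, spec.free_fraction, seed=spec.seed + 2)
    return rset


def perturb_model(
    model: AtomicModel,
    rmsd: float,
    seed: int = 0,
    mode: str = "fragment",
    fragment_len: int = 8,
    jitter_fraction: float = 0.25,
) -> AtomicModel:
    """Displace the protein atoms to a prescribed heavy-atom r.m.s.d.

    ``mode="fragment"`` (default) displaces each run of ``fragment_len``
    consecutive atoms by a common random translation plus a small per-atom
    jitter (``jitter_fraction`` of the total displacement budget).  This
    mimics how real imperfect models err — fragments and domains shifted
    collectively with local geometry largely intact — rather than
    uncorrelated atomic noise.  ``mode="atomic"`` applies independent
    isotropic Gaussian noise to every atom.  The realized displacement is
    rescaled so the heavy-atom r.m.s.d. equals ``rmsd`` exactly.
    """
    rng = np.random.default_rng(seed)
    out = model.copy()
    cart = out.cartesian()
    n = out.n_atoms
    if mode == "atomic":
        disp = rng.normal(0.0, rmsd / np.sqrt(3.0), cart.shape)
    elif mode == "fragment":
        disp = np.zeros_like(cart)
        for start in range(0, n, fragment_len):
            shift = rng.normal(0.0, rmsd / np.sqrt(3.0), 3)
            disp[start:start + fragment_len] = shift
        disp += rng.normal(0.0, jitter_fraction * rmsd / np.sqrt(3.0), cart.shape)
    else:
        raise ValueError(f"unknown perturbation mode {mode!r}")
    disp[~out.is_protein] = 0.0
    sel = out.is_protein
    actual = np.sqrt((disp[sel] ** 2).sum(axis=1).mean())
    if actual > 0:
        disp *= rmsd / actual
    out.set_frac(out.cell.fractionalize(cart + disp))
    return out
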