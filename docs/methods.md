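# Methods

`ucrefine` refines an atomic model of a whole crystal unit cell, treated as a
P1 (symmetry-free) cell, against merged structure-factor amplitudes expanded
onto the full symmetry orbit. This note records the model, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## The target function

The refinement energy is

    E_total = E_restraints + w_xray(t) · E_xray ,

where `E_restraints` is a molecular-mechanics-style geometry term (pluggable;
see below) and `E_xray` is the maximum-likelihood amplitude target. Because
the cell is treated as P1, every reflection is acentric and the likelihood of
an observed amplitude F_o given the model amplitude F_m is the Rice
distribution with per-resolution-shell parameters α (model correlation) and
β (variance of the unexplained signal):

    p(F_o | F_m) = (2 F_o / β) exp(−(F_o² + α² F_m²)/β) I₀(2 α F_o F_m / β)

`E_xray` is the plain sum of the negative log-likelihood over work
reflections; free (cross-validation) reflections never enter the target, its
gradient, α/β estimation or scaling — they exist only for R_free. The
amplitude derivative

    dE/dF_m = 2 α² F_m / β − (2 α F_o / β) · (I₁/I₀)(2 α F_o F_m / β)

is chained through the scale model and the direct summation to per-atom
Cartesian forces and B-factor derivatives. Bessel ratios use exponentially
scaled forms (`i0e`, `i1e`), so arbitrarily large arguments are safe. The
plateau weight is w_xray = 1; E_xray is treated as being in the same units as
the restraint energy (kcal/mol).

## Model structure factors

    F_model(h) = k_overall · k_aniso(h) · k_iso(shell) · [F_calc(h) + k_mask(shell) · F_mask(h)]

* **F_calc** — direct summation over all ordered atoms with four-Gaussian
  IT1992 form factors (coefficients from gemmi's table) and isotropic
  Debye–Waller attenuation exp(−B s²), s = sinθ/λ = 1/(2d). No FFT
  approximation: the forces are the exact analytic derivative of the sum.
* **F_mask** — the flat bulk-solvent model: a binary grid (spacing ≈ d_min/4,
  dimensions padded to 2·3·5-smooth numbers) marks solvent voxels; a voxel is
  non-solvent within r_vdW + r_probe (r_probe = 1.11 Å) of a protein atom, and
  the solvent region is then grown back by r_shrink = 0.9 Å. F_mask is the
  FFT of this grid scaled by V_cell/N_voxels. These mask parameters are the
  conventional defaults for the flat-mask model.
* **Scales** — fitted per pass: (k_mask, k_iso) per shell by a coarse k_mask
  grid {0, 0.05, …, 1} refined by golden section with the closed-form
  least-squares k_iso at each candidate; then the six anisotropic
  coefficients by *amplitude-weighted* linear least squares in log space
  (weights √(F_obs·F_pred) — unweighted log-space fitting is dominated by
  weak reflections whose log ratios are unbounded, and measurably worsens the
  amplitude residual); then a closing global k_overall. Two passes. The
  anisotropic scale is constrained to be traceless in the reciprocal metric:
  its isotropic component is exactly a uniform B shift, which belongs to the
  atoms (or to per-shell k_iso), not to the scale. Shells in which |F_mask|
  carries no measurable signal inherit the previous shell's k_mask — the
  parameter is unidentifiable there; empty shells inherit their neighbor's
  parameters with a warning.

α/β are estimated per resolution shell by quasi-Newton maximization of the
Rice likelihood over the work set, initialized from the moment estimators
α₀ = ΣF_oF_m/ΣF_m², β₀ = mean((F_o − α₀F_m)²). β is floored at
10⁻⁶ × mean F_obs² of the shell for estimation; shells with fewer than 10
work reflections are merged with a neighbor.

## The annealing program

Refinement is Langevin dynamics (BAOAB splitting) under a three-phase
program: heating 0→298 K over 20 ps with 10 kcal/mol/Å² positional restraints
on the protein atoms and w_xray = 0; a 10 ps ramp at 298 K with the
positional restraints released and w_xray raised linearly 0→1; and 10 ps of
cooling 298→0 K at w_xray = 1, which dissipates thermal fluctuations and
steers the system into the energy minimum. The collision frequency is
γ = 2 ps⁻¹; the default timestep is 2 fs (configurable down to 0.5 fs; the
toy models carry no hydrogens, so no bond constraints are needed). The
solvent mask, scale model and α/β are refreshed every 100 steps and treated
as constants in between — their dependence on the coordinates is deliberately
ignored in the forces, as is standard. X-ray forces act only on protein
atoms; explicit solvent sites and ions, if present, feel only the restraint
term. The final MD frame is the refined model; running two replicas that
differ only in the thermostat's random stream and keeping the lower-R_free
product is the default protocol.

Three integrator details matter and are deliberate:

* **Centre-of-mass motion removal.** An amplitude-only target in P1 leaves
  the cell origin completely unrestrained — a rigid translation of all atoms
  changes no |F(h)|. Without correction the model executes a random walk of
  its origin. The mass-weighted mean velocity is therefore removed each step,
  as MD engines routinely do. (Consequently, comparisons between refined and
  reference models should allow a uniform origin shift; `heavy_atom_rmsd`
  exposes this as an option.)
* **Per-step shift cap.** As the fit approaches perfection on clean data the
  estimated β collapses and the curvature of E_xray grows without bound; no
  fixed timestep can resolve the stiffest modes. Each atom's per-step
  displacement is capped (default 0.05 Å, implemented as a speed clamp),
  which converts would-be integration blow-ups into a bounded, damped
  residual. The cap sits far above thermal step sizes at 298 K, so ordinary
  dynamics (checked against equipartition) is unaffected.
* **Dynamics β floor.** For force evaluation during dynamics, β is floored
  at 10⁻⁴ × mean F_obs² per shell (a 1% amplitude-noise equivalent), keeping
  the force stiffness integrable on noiseless synthetic data. The floor does
  not move the target's minimum — verified directly: quasi-Newton
  minimization of the frozen-parameter target from the generating model stays
  at it to 10⁻⁴ Å. Real data's noise keeps β above this floor anyway.

A residual of the finite timestep remains visible on noiseless data: the
unresolvable stiff modes ring at an amplitude set by the shift cap and the
refresh cadence, so annealed runs bottom out near r ≈ 0.02–0.04 rather than
0. This floor is an integration artifact, not a bias (the underlying minimum
is at the generating coordinates), and it shrinks with the timestep.

## Restraint model

The molecular-mechanics force field is a contract: any callable mapping
Cartesian coordinates to (energy, gradient) can drive the dynamics, so a real
force-field engine can be plugged in. The built-in `HarmonicRestraints` is a
geometry regularizer referenced to a topology: harmonic bonds (pairs within
1.85 Å of the reference, k = 200 kcal/mol/Å²), harmonic angles between bonds
sharing an atom (k = 40 kcal/mol/rad²), and a soft-sphere repulsion below
2.4 Å whose onset is capped per pair at the reference separation, so the
reference geometry itself is penalty-free and the restraint minimum coincides
with the reference — the analogue of a force field being consistent with
ideal geometry. The gradient is analytic and FD-checked; the energy depends
only on internal distances and angles (translation- and rotation-invariant up
to periodic imaging). In recovery experiments the restraints are referenced
to the generating geometry, mirroring reality: restraint targets encode
chemical knowledge that is exact for the true structure, not the distorted
starting model.

## Supporting machinery

* **P1 expansion** emits h→hᵀR for every operator, reduces to a fixed Friedel
  hemisphere ((h>0) ∨ (h=0 ∧ k>0) ∨ (h=k=0 ∧ l≥0)) and de-duplicates; free
  flags (10% by default) are regenerated on the expanded set, accepting that
  symmetry mates may straddle the work/test split.
* **Systematic absences** are enumerated from the phase condition
  (hᵀR = h with non-integral h·t) and can be appended to the work set as
  F_obs = 0 restraints; for a P1-treated cell they are genuine information.
* **Solvent-content accounting** converts the model's mass to volume with the
  generic protein partial specific volume 0.74 ml/g, fills the remainder with
  water at 29.9 ų/molecule and neutralizes the residue-table formal charge
  with Na⁺/Cl⁻. Placement (needed only for the toy restraint world) is
  rejection sampling ≥ 2.4 Å from any atom.
* **B-factor refinement** is 25 bounded L-BFGS steps on per-atom B in
  [1, 200] Ų at fixed coordinates. Beforehand the overall B offset between
  data and model is fitted Wilson-style (weighted log-linear in s²) and moved
  onto the atoms, and the scale model is refitted on a single shell — a
  resolution-dependent k_iso would absorb exactly the exp(ΔB s²) signature
  that identifies B, pinning the atoms at their starting values.
* **Water picking** synthesizes the acentric difference map with coefficients
  2(m F_o − D |F_m|) e^{iφ_model}, m = (I₁/I₀)(2αF_oF_m/β), D = α (the
  overall scale being already folded into F_model), then keeps local maxima
  ≥ 3σ, ≥ 2.2 Å apart and 2.2–3.5 Å from a protein N/O acceptor, ranked by
  height with parabolic sub-voxel interpolation.

## Synthetic crystals

The toy generator places short bonded chains (default 8 atoms, 1.5 Å bonds,
C/N/O composition, B ∈ [10, 30] Ų) in a small cell of one of P1, P2₁,
P2₁2₁2₁ or C2, by rejection sampling so that all symmetry copies keep
≥ 1.2 Å separation; chains give the restraint model a connected topology, as
a real molecule's bond network would. Simulated data are the generating
model's |F_model| under known true scales (k_mask = 0.35 by default, optional
anisotropy), complete to d_min on the hemisphere, with optional multiplicative
Gaussian amplitude noise; the default experiments use noiseless data so that
recovery has an exact target. The default perturbation for recovery
experiments displaces bonded fragments collectively with a small per-atom
jitter — the error structure of real imperfect models (shifted domains,
MR models, MD-scrambled frames) — rather than independent atomic noise, which
destroys local geometry in a way no realistic starting model does.

What the toys do **not** emulate: measurement noise statistics of real
intensities, incompleteness and anisotropic completeness, twinning, ice
rings, radiation damage, alternate conformations, hydrogens, and a realistic
chemical force field. Passing recovery tests therefore demonstrates the
correctness and convergence of the machinery — forces, scaling, likelihood,
annealing — under controlled conditions, not performance on deposited data.

## Problem sizes

The bundled experiments use a 48-atom P2₁ cell (24-atom asymmetric unit) at
d_min = 2.0 Å (~1270 reflections) for end-to-end work, 20–50-atom cells for
oracle comparisons, and a 4 ps annealing program (0.75/0.75/2.5 ps at 1 fs)
with two replicas for coordinate recovery — chosen so every brute-force
oracle (double-loop summation, orbit enumeration, finite differences) runs
comfortably on one CPU.
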