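"""Structure factors by direct summation, bulk-solvent mask, and scaling.

The model structure-factor hierarchy is the standard one:

    F_model(h) = k_overall * k_aniso(h) * k_iso(shell) *
                 [ F_calc(h) + k_mask(shell) * F_mask(h) ]

F_calc comes from direct summation over all ordered atoms with the
four-Gaussian IT1992 form factors,

    F_calc(h) = sum_j occ_j f_j(s) exp(-B_j s^2) exp(2 pi i h . x_j),

with s = sin(theta)/lambda = 1/(2d) and isotropic Debye-Waller attenuation
exp(-B s^2).  F_mask is the Fourier transform of a flat binary
solvent-mask grid (voxels beyond the atoms' solvent-excluded region), the
classic flat bulk-solvent model for the disordered interstitial water.
Scale parameters are fitted per resolution shell against |F_obs| on the
work set; everything is analytic so the gradient of any target built on
F_model reaches the atoms by the chain rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._tables import vdw_radius
from .model import AtomicModel, UnitCellGeometry

__all__ = [
    "form_factor",
    "f_calc",
    "f_calc_gradients",
    "SolventMaskGrid",
    "build_solvent_mask",
    "f_mask",
    "ScaleModel",
    "fit_scales",
]

# cached 4-Gaussian IT1992 coefficients per element, via gemmi's table
_IT92_CACHE: dict[str, tuple[np.ndarray, np.ndarray, float]] = {}


def _it92_coeffs(element: str) -> tuple[np.ndarray, np.ndarray, float]:
    key = element.strip().capitalize()
    if key not in _IT92_CACHE:
        import gemmi

        el = gemmi.Element(key)
        if el.atomic_number == 0:
            raise KeyError(
                f"unknown element {element!r}; use standard symbols such as C, N, O, S"
            )
        coef = el.it92
        if coef is None:
            raise KeyError(f"no IT1992 coefficients for element {element!r}")
        _IT92_CACHE[key] = (np.array(coef.a), np.array(coef.b), float(coef.c))
    return _IT92_CACHE[key]


def form_factor(element: str, s) -> np.ndarray | float:
    """IT1992 X-ray form factor f(s) = sum_i a_i exp(-b_i s^2) + c (electrons).

    ``s`` is sin(theta)/lambda in 1/Angstrom; at s = 0 the value equals the
    element's electron count to within the tabulation error.
    """
    a, b, c = _it92_coeffs(element)
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("s must be non-negative")
    out = (a * np.exp(-b * s[..., None] ** 2)).sum(axis=-1) + c
    return float(out) if out.ndim == 0 else out


def _atom_amplitudes(model: AtomicModel, s2: np.ndarray) -> np.ndarray:
    """(n_refl, n_atoms) real amplitude occ_j f_j(s) exp(-B_j s^2)."""
    n_refl = len(s2)
    amp = np.empty((n_refl, model.n_atoms))
    elements = np.array(model.elements)
    for el in np.unique(elements):
        a, b, c = _it92_coeffs(el)
        f = (a * np.exp(-b * s2[:, None])).sum(axis=1) + c
        amp[:, elements == el] = f[:, None]
    amp *= np.exp(-np.outer(s2, model.b_iso))
    amp *= model.occupancy
    return amp


def _check_indices(hkl: np.ndarray) -> np.ndarray:
    hkl = np.atleast_2d(np.asarray(hkl))
    if np.any(np.all(hkl == 0, axis=1)):
        raise ValueError("(0,0,0) is not a valid reflection")
    return hkl


def f_calc(model: AtomicModel, hkl) -> np.ndarray:
    """Direct-summation structure factors of the P1-expanded model.

    Returns complex F_calc for each index.  The result is invariant to the
    [0,1) wrapping of fractional coordinates since phases are periodic.
    """
    if not model.is_p1_expanded:
        raise ValueError(
            "model must be P1-expanded (whole unit cell) before computing "
            "structure factors; call build_unit_cell first"
        )
    hkl = _check_indices(hkl)
    Gstar = model.cell.reciprocal_metric
    s2 = 0.25 * np.einsum("ij,jk,ik->i", hkl.astype(float), Gstar, hkl.astype(float))
    amp = _atom_amplitudes(model, s2)
    phase = np.exp(2j * np.pi * (hkl.astype(float) @ model.frac.T))
    return (amp * phase).sum(axis=1)


def f_calc_gradients(
    model: AtomicModel, hkl, dtarget_dF: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Chain-rule gradients of a scalar target through the direct sum.

    ``dtarget_dF`` holds one complex weight per reflection, defined as
    w = dT/dRe(F) + i dT/dIm(F), so that dT/dp = sum_h Re(conj(w_h) dF_h/dp).

    Returns ``(grad_xyz, grad_b)``: the Cartesian coordinate gradient
    (n_atoms, 3) in target-units per Angstrom and the per-atom B-factor
    gradient (n_atoms,).  Rows for non-protein atoms (bulk solvent sites,
    ions) are zero: X-ray forces act only on the ordered protein atoms.
    """
    if not model.is_p1_expanded:
        raise ValueError("model must be P1-expanded")
    hkl = _check_indices(hkl)
    w = np.asarray(dtarget_dF, dtype=complex)
    if w.shape != (hkl.shape[0],):
        raise ValueError(
            f"weight length {w.shape} does not match {hkl.shape[0]} reflections"
        )
    H = hkl.astype(float)
    Gstar = model.cell.reciprocal_metric
    s2 = 0.25 * np.einsum("ij,jk,ik->i", H, Gstar, H)
    amp = _atom_amplitudes(model, s2)
    phase = np.exp(2j * np.pi * (H @ model.frac.T))
    z = np.conj(w)[:, None] * amp * phase  # (n_refl, n_atoms)
    # dT/dfrac_jk = -2 pi sum_h h_k Im(z_hj)
    grad_frac = -2.0 * np.pi * np.einsum("hj,hk->jk", z.imag, H)
    grad_xyz = grad_frac @ model.cell.frac_matrix
    grad_b = -np.einsum("hj,h->j", z.real, s2)
    mask = ~model.is_protein
    if mask.any():
        grad_xyz[mask] = 0.0
        grad_b[mask] = 0.0
    return grad_xyz, grad_b


# --------------------------------------------------------------------------
# flat bulk-solvent mask


def _fft_friendly(n: int) -> int:
    """Smallest integer >= n whose prime factors are all in {2, 3, 5}."""
    while True:
        m = n
        for p in (2, 3, 5):
            while m % p == 0:
                m //= p
        if m == 1:
            return n
        n += 1


@dataclass
class SolventMaskGrid:
    """Binary solvent occupancy on a cell-spanning grid (1 = solvent)."""

    grid: np.ndarray  # float 0/1, shape (na, nb, nc)
    cell: UnitCellGeometry
    d_min: float

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def solvent_fraction(self) -> float:
        return float(self.grid.mean())


def build_solvent_mask(
    model: AtomicModel,
    d_min: float,
    r_probe: float = 1.11,
    r_shrink: float = 0.9,
    grid_divisor: float = 4.0,
) -> SolventMaskGrid:
    """Flat bulk-solvent mask on a grid of spacing ~ d_min/4.

    A voxel is marked non-solvent when it lies within r_vdw + r_probe of
    any ordered protein atom (periodic metric); the solvent region is then
    grown back by r_shrink (voxels within r_shrink of solvent are
    reclaimed), the standard probe-and-shrink construction for the flat
    mask model.  Solvent and ion records do not carve the mask.
    """
    from scipy import ndimage

    cell = model.cell
    spacing = d_min / grid_divisor
    dims = tuple(
        _fft_friendly(max(int(math.ceil(L / spacing)), 8))
        for L in (cell.a, cell.b, cell.c)
    )
    if min(dims) < 8:
        raise ValueError("solvent-mask grid must have at least 8 points per axis")
    mask = np.ones(dims)
    A = cell.orth_matrix
    Ainv = cell.frac_matrix
    # fractional half-extent of a Cartesian radius along each axis
    frac_per_A = np.linalg.norm(Ainv, axis=1)

    protein = np.nonzero(model.is_protein)[0]
    for j in protein:
        radius = vdw_radius(model.elements[j]) + r_probe
        _carve_sphere(mask, model.frac[j], radius, A, frac_per_A)

    # shrink: reclaim non-solvent voxels within r_shrink of the solvent region
    foot = _ball_footprint(r_shrink, cell, dims)
    if foot is not None and mask.min() == 0.0:
        dilated = ndimage.grey_dilation(mask, footprint=foot, mode="wrap")
        mask = np.maximum(mask, np.minimum(dilated, 1.0))
    return SolventMaskGrid(mask, cell, d_min)


def _carve_sphere(mask, frac_center, radius, A, frac_per_A) -> None:
    dims = np.array(mask.shape)
    lo = np.floor((frac_center - radius * frac_per_A) * dims).astype(int)
    hi = np.ceil((frac_center + radius * frac_per_A) * dims).astype(int)
    axes = [np.arange(lo[i], hi[i] + 1) for i in range(3)]
    gi, gj, gk = np.meshgrid(*axes, indexing="ij")
    fr = np.stack([gi, gj, gk], axis=-1) / dims - frac_center
    fr -= np.round(fr)
    cart = fr @ A.T
    inside = (cart**2).sum(axis=-1) <= radius * radius
    ii, jj, kk = gi[inside] % dims[0], gj[inside] % dims[1], gk[inside] % dims[2]
    mask[ii, jj, kk] = 0.0


def _ball_footprint(radius: float, cell: UnitCellGeometry, dims) -> np.ndarray | None:
    """Voxel footprint of a Cartesian ball of the given radius (or None if trivial)."""
    A = cell.orth_matrix
    step = A / np.asarray(dims)  # cart displacement per voxel along each axis
    nmax = [int(math.floor(radius / np.linalg.norm(step[:, i]))) + 1 for i in range(3)]
    if max(nmax) == 0:
        return None
    rng = [np.arange(-n, n + 1) for n in nmax]
    gi, gj, gk = np.meshgrid(*rng, indexing="ij")
    off = np.stack([gi, gj, gk], axis=-1).astype(float)
    cart = off @ step.T
    foot = (cart**2).sum(axis=-1) <= radius * radius
    return foot if foot.any() else None


def f_mask(mask: SolventMaskGrid, hkl) -> np.ndarray:
    """Fourier coefficients of the binary mask, scaled by V_cell/N_voxels.

    F_mask(h) = (V/N) sum_voxels m(x) exp(2 pi i h.x); evaluated with a
    single inverse FFT.  Indices beyond the grid Nyquist limit are refused.
    """
    hkl = _check_indices(hkl)
    dims = np.array(mask.shape)
    if np.any(np.abs(hkl) >= dims // 2):
        raise ValueError("Miller index beyond the solvent-mask grid Nyquist limit")
    coeffs = np.fft.ifftn(mask.grid) * mask.cell.volume
    return coeffs[hkl[:, 0] % dims[0], hkl[:, 1] % dims[1], hkl[:, 2] % dims[2]]


# --------------------------------------------------------------------------
# scaling


@dataclass
class ScaleModel:
    """Fitted scales mapping F_calc + F_mask to F_model.

    ``u_aniso`` holds the six coefficients (b11, b22, b33, b12, b13, b23)
    of the reciprocal-space exponential anisotropic factor
    k_aniso(h) = exp(-1/4 (h^2 b11 + k^2 b22 + l^2 b33
                           + 2hk b12 + 2hl b13 + 2kl b23)).
    """

    k_overall: float
    u_aniso: np.ndarray  # (6,)
    k_iso: np.ndarray    # (n_shells,)
    k_mask: np.ndarray   # (n_shells,)

    def k_aniso(self, hkl) -> np.ndarray:
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        h, k, l = hkl[:, 0], hkl[:, 1], hkl[:, 2]
        b11, b22, b33, b12, b13, b23 = self.u_aniso
        q = h * h * b11 + k * k * b22 + l * l * b33 + 2 * (
            h * k * b12 + h * l * b13 + k * l * b23
        )
        return np.exp(-0.25 * q)

    def k_total(self, hkl, shell_id) -> np.ndarray:
        """Overall multiplicative scale per reflection (everything except k_mask)."""
        return self.k_overall * self.k_aniso(hkl) * self.k_iso[np.asarray(shell_id)]

    def f_model(self, hkl, shell_id, fc: np.ndarray, fm: np.ndarray) -> np.ndarray:
        """Complex F_model per reflection."""
        shell_id = np.asarray(shell_id)
        return self.k_total(hkl, shell_id) * (fc + self.k_mask[shell_id] * fm)


def _golden_section(fun, lo, hi, tol=1e-4):
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc_, fd_ = fun(c), fun(d)
    while b - a > tol:
        if fc_ < fd_:
            b, d, fd_ = d, c, fc_
            c = b - invphi * (b - a)
            fc_ = fun(c)
        else:
            a, c, fc_ = c, d, fd_
            d = a + invphi * (b - a)
            fd_ = fun(d)
    return 0.5 * (a + b)


def fit_scales(
    f_obs: np.ndarray,
    fc: np.ndarray,
    fm: np.ndarray,
    hkl: np.ndarray,
    shell_id: np.ndarray,
    work: np.ndarray | None = None,
    n_passes: int = 2,
    mask_signal_floor: float = 1e-8,
    cell: UnitCellGeometry | None = None,
    aniso_traceless: bool = True,
) -> tuple[ScaleModel, np.ndarray]:
    """Fit the scale hierarchy against |F_obs| on the work set.

    Per shell, (k_mask, k_iso) minimize sum (|F_obs| - |F_model|)^2 with
    k_mask searched on a coarse grid {0, 0.05, ..., 1} and refined by
    golden section (k_iso is the closed-form least-squares scale at each
    k_mask); the six anisotropic coefficients are then fitted by linear
    least squares in log space on shell-normalized ratios, and k_overall
    closes the global least-squares scale.  The pass is repeated
    ``n_passes`` times.  Shells where the mask contributes no measurable
    amplitude inherit the previous shell's k_mask (the parameter is
    unidentifiable there); empty shells inherit the neighbor's parameters
    with a warning.

    Returns ``(ScaleModel, |F_model|)`` over all reflections.
    """
    f_obs = np.asarray(f_obs, dtype=float)
    fc = np.asarray(fc, dtype=complex)
    fm = np.asarray(fm, dtype=complex)
    shell_id = np.asarray(shell_id)
    hkl = np.atleast_2d(np.asarray(hkl))
    if work is None:
        work = np.ones(len(f_obs), dtype=bool)
    n_shells = int(shell_id.max()) + 1

    k_iso = np.ones(n_shells)
    k_mask = np.zeros(n_shells)
    u_aniso = np.zeros(6)
    k_overall = 1.0
    sm = ScaleModel(k_overall, u_aniso, k_iso, k_mask)

    grid = np.arange(0.0, 1.0001, 0.05)
    for _ in range(n_passes):
        ka = sm.k_overall * sm.k_aniso(hkl)
        prev_mask = 0.0
        prev_iso = 1.0
        for s in range(n_shells):
            sel = work & (shell_id == s)
            if not sel.any():
                warnings.warn(f"resolution shell {s} has no work reflections; "
                              "inheriting neighbor scales")
                k_mask[s], k_iso[s] = prev_mask, prev_iso
                continue
            t = f_obs[sel] / ka[sel]
            fcs, fms = fc[sel], fm[sel]

            def rss(km, t=t, fcs=fcs, fms=fms):
                p = np.abs(fcs + km * fms)
                denom = (p * p).sum()
                ki = (t * p).sum() / denom if denom > 0 else 1.0
                r = t - ki * p
                return (r * r).sum()

            mask_signal = (np.abs(fms) ** 2).sum()
            if mask_signal <= mask_signal_floor * max((np.abs(fcs) ** 2).sum(), 1e-30):
                km_best = prev_mask
            else:
                km_best = grid[np.argmin([rss(g) for g in grid])]
                lo = max(0.0, km_best - 0.05)
                hi = min(1.0, km_best + 0.05)
                km_best = _golden_section(rss, lo, hi)
            p = np.abs(fcs + km_best * fms)
            ki = (t * p).sum() / (p * p).sum()
            k_mask[s] = km_best
            k_iso[s] = max(ki, 1e-12)
            prev_mask, prev_iso = k_mask[s], k_iso[s]

        # anisotropic factor: weighted linear LS in log space on work ratios;
        # weights ~ amplitude^2 so weak reflections with wild log ratios do
        # not dominate (log-space LS then approximates the amplitude residual)
        fsum_abs = np.abs(fc + k_mask[shell_id] * fm)
        pred_iso = sm.k_overall * sm.k_aniso(hkl) * k_iso[shell_id] * fsum_abs
        ok = work & (pred_iso > 0) & (f_obs > 0)
        ratio = np.log(f_obs[ok] / pred_iso[ok])
        wts = np.sqrt(f_obs[ok] * pred_iso[ok])
        h, k, l = (hkl[ok, i].astype(float) for i in range(3))
        X = -0.25 * np.column_stack([h * h, k * k, l * l, 2 * h * k, 2 * h * l, 2 * k * l])
        coef, *_ = np.linalg.lstsq(X * wts[:, None], ratio * wts, rcond=None)
        u_aniso += coef
        if cell is not None and aniso_traceless:
            # remove the isotropic component (proportional to the reciprocal
            # metric, i.e. a uniform B shift) so the anisotropic scale cannot
            # absorb what belongs to atomic B factors / per-shell scales
            b11, b22, b33, b12, b13, b23 = u_aniso
            B = np.array([[b11, b12, b13], [b12, b22, b23], [b13, b23, b33]])
            G = cell.reciprocal_metric
            lam = float((B * G).sum() / (G * G).sum())
            B = B - lam * G
            u_aniso = np.array(
                [B[0, 0], B[1, 1], B[2, 2], B[0, 1], B[0, 2], B[1, 2]]
            )
        sm = ScaleModel(sm.k_overall, u_aniso, k_iso, k_mask)

        # close the global scale
        pred = sm.k_total(hkl, shell_id) * fsum_abs
        denom = (pred[work] ** 2).sum()
        if denom > 0:
            k_overall = sm.k_overall * float((f_obs[work] * pred[work]).sum() / denom)
        sm = ScaleModel(k_overall, u_aniso, k_iso, k_mask)

    f_model_abs = np.abs(sm.f_model(hkl, shell_id, fc, fm))
    return sm, f_model_abs
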