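"""Maximum-likelihood amplitude target, alpha/beta estimation, R factors, maps.

For a symmetry-free (P1) cell every reflection is acentric, so the
likelihood of an observed amplitude F_o given the model amplitude F_m is
the Rice distribution

    p(F_o | F_m) = (2 F_o / beta) exp(-(F_o^2 + alpha^2 F_m^2)/beta)
                   I0(2 alpha F_o F_m / beta),

with per-resolution-shell parameters alpha (model quality / correlation)
and beta (variance of the unexplained signal).  The refinement
pseudo-energy is the negative log-likelihood summed over work reflections:

    E_xray = sum_work [ (F_o^2 + alpha^2 F_m^2)/beta - ln(2 F_o/beta)
                        - ln I0(2 alpha F_o F_m / beta) ],

whose derivative with respect to F_m,

    dE/dF_m = 2 alpha^2 F_m / beta
              - (2 alpha F_o / beta) * (I1/I0)(2 alpha F_o F_m / beta),

feeds the chain rule down to atomic forces.  Bessel terms use the
exponentially scaled forms so large arguments never overflow.  Free
(cross-validation) reflections contribute nothing to the target, its
gradient, alpha/beta estimation or scaling; they exist only for R_free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, special

__all__ = [
    "MLShellParams",
    "TargetResult",
    "ml_target_acentric",
    "estimate_alpha_beta",
    "expand_shell_params",
    "r_factors",
    "difference_map",
    "find_map_peaks",
    "pick_waters",
]

BETA_FLOOR_REL = 1e-6  # beta floor as a fraction of the shell's mean F_obs^2


@dataclass
class MLShellParams:
    """Rice-likelihood parameters of one resolution shell."""

    shell_id: int
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


@dataclass
class TargetResult:
    """The ML pseudo-energy, its amplitude gradient, and R factors."""

    e_xray: float
    de_dfm: np.ndarray  # per reflection; zero on free reflections
    r_work: float
    r_free: float | None


def _log_i0(x: np.ndarray) -> np.ndarray:
    # ln I0(x) = x + ln(i0e(x)); i0e is exp(-|x|) I0(x), stable for all x
    return x + np.log(special.i0e(x))


def _i1_over_i0(x: np.ndarray) -> np.ndarray:
    return special.i1e(x) / special.i0e(x)


def ml_target_acentric(
    f_obs: np.ndarray,
    f_model: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    work: np.ndarray,
) -> TargetResult:
    """Acentric Rice negative log-likelihood and its dE/d|F_model|.

    ``alpha``/``beta`` are per-reflection arrays (already expanded from
    their shells).  R factors are computed on the same call for reporting:
    work reflections feed r_work, the complement feeds r_free.
    """
    f_obs = np.asarray(f_obs, dtype=float)
    f_model = np.asarray(f_model, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    work = np.asarray(work, dtype=bool)
    for name, arr in (("f_obs", f_obs), ("f_model", f_model)):
        bad = ~np.isfinite(arr)
        if bad.any():
            raise ValueError(f"non-finite {name} at reflection index {int(np.argmax(bad))}")

    x = 2.0 * alpha * f_obs * f_model / beta
    nll = (
        (f_obs**2 + alpha**2 * f_model**2) / beta
        - np.log(2.0 * f_obs / beta)
        - _log_i0(x)
    )
    e_xray = float(nll[work].sum())
    de = 2.0 * alpha**2 * f_model / beta - (2.0 * alpha * f_obs / beta) * _i1_over_i0(x)
    de = np.where(work, de, 0.0)
    free = ~work
    if work.any():
        r_work, r_free = r_factors(f_obs, f_model, free)
    else:
        r_work, r_free = float("nan"), None
    return TargetResult(e_xray, de, r_work, r_free)


def _shell_nll(params, fo, fm, floor):
    alpha, logbeta = params
    beta = np.exp(logbeta) + floor
    x = 2.0 * alpha * fo * fm / beta
    return float(
        ((fo**2 + alpha**2 * fm**2) / beta - np.log(2.0 * fo / beta) - _log_i0(x)).sum()
    )


def estimate_alpha_beta(
    f_obs: np.ndarray,
    f_model: np.ndarray,
    shell_id: np.ndarray,
    work: np.ndarray | None = None,
    min_per_shell: int = 10,
    max_iter: int = 200,
    beta_floor_rel: float = BETA_FLOOR_REL,
) -> list[MLShellParams]:
    """Per-shell (alpha, beta) by maximizing the acentric Rice likelihood.

    Each shell is optimized by quasi-Newton (L-BFGS-B over alpha and
    ln beta) from the moment initializer

        alpha0 = sum F_o F_m / sum F_m^2,
        beta0  = mean((F_o - alpha0 F_m)^2) + floor.

    Shells with fewer than ``min_per_shell`` work reflections are merged
    with their lower-resolution neighbor for estimation (both shells then
    share the fitted values).  Non-convergence falls back to the
    initializer with a warning.
    """
    f_obs = np.asarray(f_obs, dtype=float)
    f_model = np.asarray(f_model, dtype=float)
    shell_id = np.asarray(shell_id)
    if work is None:
        work = np.ones(len(f_obs), dtype=bool)
    n_shells = int(shell_id.max()) + 1

    # merge under-populated shells with their predecessor
    groups: list[list[int]] = []
    for s in range(n_shells):
        count = int((work & (shell_id == s)).sum())
        if groups and count < min_per_shell:
            groups[-1].append(s)
        else:
            groups.append([s])
    # a leading under-populated group merges forward
    if groups and int(np.isin(shell_id[work], groups[0]).sum()) < min_per_shell and len(groups) > 1:
        groups[1] = groups[0] + groups[1]
        groups.pop(0)

    out: dict[int, MLShellParams] = {}
    for group in groups:
        sel = work & np.isin(shell_id, group)
        fo, fm = f_obs[sel], f_model[sel]
        floor = beta_floor_rel * float((fo**2).mean()) if sel.any() else 1e-12
        denom = float((fm**2).sum())
        a0 = float((fo * fm).sum() / denom) if denom > 0 else 1.0
        a0 = min(max(a0, 1e-3), 1.5)
        b0 = float(((fo - a0 * fm) ** 2).mean()) + floor
        res = optimize.minimize(
            _shell_nll,
            x0=np.array([a0, np.log(b0)]),
            args=(fo, fm, floor),
            method="L-BFGS-B",
            bounds=[(1e-4, 1.5), (np.log(floor), None)],
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-10},
        )
        if res.success or res.fun <= _shell_nll([a0, np.log(b0)], fo, fm, floor):
            alpha, beta = float(res.x[0]), float(np.exp(res.x[1]) + floor)
        else:
            warnings.warn(f"alpha/beta optimizer did not converge in shells {group}; "
                          "using moment initializer")
            alpha, beta = a0, b0
        for s in group:
            out[s] = MLShellParams(s, alpha, beta)
    return [out[s] for s in range(n_shells)]


def expand_shell_params(
    params: list[MLShellParams], shell_id: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-reflection (alpha, beta) arrays from per-shell parameters."""
    alpha = np.array([p.alpha for p in params])
    beta = np.array([p.beta for p in params])
    shell_id = np.asarray(shell_id)
    return alpha[shell_id], beta[shell_id]


def r_factors(
    f_obs: np.ndarray, f_model: np.ndarray, free: np.ndarray | None = None
) -> tuple[float, float | None]:
    """Standard amplitude residuals sum||F_o|-|F_m|| / sum|F_o| per set.

    Returns ``(r_work, r_free)``; r_free is None without free reflections.
    """
    f_obs = np.asarray(f_obs, dtype=float)
    f_model = np.asarray(f_model, dtype=float)
    if free is None:
        free = np.zeros(len(f_obs), dtype=bool)
    free = np.asarray(free, dtype=bool)
    work = ~free
    if not work.any() or f_obs[work].sum() == 0:
        raise ValueError("work set is empty or has zero total amplitude")
    r_work = float(np.abs(f_obs[work] - f_model[work]).sum() / f_obs[work].sum())
    r_free = None
    if free.any() and f_obs[free].sum() > 0:
        r_free = float(np.abs(f_obs[free] - f_model[free]).sum() / f_obs[free].sum())
    return r_work, r_free


# --------------------------------------------------------------------------
# difference maps and water picking


def difference_map(
    hkl: np.ndarray,
    f_obs: np.ndarray,
    f_model: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    work: np.ndarray,
    grid_shape: tuple[int, int, int],
    cell,
) -> np.ndarray:
    """Real-space mF_obs - DF_model difference density on a grid.

    Coefficients are the acentric difference synthesis
    2 (m F_o - D |F_m|) exp(i phi_model) over the work set, with figure of
    merit m = (I1/I0)(2 alpha F_o F_m / beta) and D = alpha.  ``f_model``
    is the fully scaled complex model structure factor (the same quantity
    alpha/beta were estimated against), so the overall scale is already
    applied consistently; for a perfect model the coefficients vanish and
    the map is flat.  The map is synthesized by placing each coefficient
    and its Friedel mate on the FFT grid.
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    f_model = np.asarray(f_model, dtype=complex)
    work = np.asarray(work, dtype=bool)
    if not work.any():
        raise ValueError("cannot synthesize a difference map from an empty work set")
    fm_abs = np.abs(f_model)
    phase = np.where(fm_abs > 0, f_model / np.where(fm_abs > 0, fm_abs, 1.0), 1.0)
    x = 2.0 * np.asarray(alpha) * np.asarray(f_obs) * fm_abs / np.asarray(beta)
    m = _i1_over_i0(x)
    coeff = 2.0 * (m * np.asarray(f_obs) - np.asarray(alpha) * fm_abs) * phase
    coeff = np.where(work, coeff, 0.0)

    grid = np.zeros(grid_shape, dtype=complex)
    dims = np.array(grid_shape)
    ok = np.all(np.abs(hkl) < dims // 2, axis=1)
    for (h, k, l), c in zip(hkl[ok], coeff[ok]):
        grid[h % dims[0], k % dims[1], l % dims[2]] += c
        grid[-h % dims[0], -k % dims[1], -l % dims[2]] += np.conj(c)
    rho = np.fft.fftn(grid).real / cell.volume
    return rho


def find_map_peaks(
    rho: np.ndarray,
    cell,
    sigma_cutoff: float = 3.0,
) -> list[tuple[np.ndarray, float]]:
    """Local maxima above ``sigma_cutoff`` map sigmas, strictly sorted by height.

    Returns ``[(fractional position, height in sigma), ...]``; positions
    carry a parabolic sub-voxel correction along each axis.
    """
    sig = float(rho.std())
    if sig == 0:
        return []
    dims = np.array(rho.shape)
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = rho >= ndimage.maximum_filter(rho, footprint=footprint, mode="wrap")
    cand = np.argwhere(local_max & (rho >= sigma_cutoff * sig))
    peaks = []
    for idx in cand:
        frac = idx.astype(float)
        for ax in range(3):
            m = idx.copy(); p = idx.copy()
            m[ax] = (m[ax] - 1) % dims[ax]
            p[ax] = (p[ax] + 1) % dims[ax]
            y0, y1, y2 = rho[tuple(m)], rho[tuple(idx)], rho[tuple(p)]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                frac[ax] += 0.5 * (y0 - y2) / denom
        peaks.append(((frac / dims) % 1.0, rho[tuple(idx)] / sig))
    peaks.sort(key=lambda t: -t[1])
    return peaks


def pick_waters(
    peaks: list[tuple[np.ndarray, float]],
    model,
    min_peak_sep: float = 2.2,
    contact_range: tuple[float, float] = (2.2, 3.5),
) -> list[tuple[np.ndarray, float]]:
    """Filter difference-map peaks down to plausible ordered-water sites.

    Keeps peaks at least ``min_peak_sep`` Angstrom from previously accepted
    (higher) peaks and within ``contact_range`` of a protein N or O
    acceptor; ranking by height is preserved.
    """
    A = model.cell.orth_matrix
    acceptors = model.frac[
        model.is_protein & np.isin(np.array(model.elements), ("N", "O"))
    ]
    accepted: list[tuple[np.ndarray, float]] = []
    lo, hi = contact_range
    for frac, height in peaks:
        if accepted:
            df = np.array([a[0] for a in accepted]) - frac
            df -= np.round(df)
            if np.linalg.norm(df @ A.T, axis=1).min() < min_peak_sep:
                continue
        if len(acceptors):
            df = acceptors - frac
            df -= np.round(df)
            dist = np.linalg.norm(df @ A.T, axis=1)
            if not np.any((dist >= lo) & (dist <= hi)):
                continue
        accepted.append((frac, height))
    return accepted
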