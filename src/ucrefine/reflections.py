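"""Reflection tables: I/O, P1 expansion, free flags, shells, absences.

Merged amplitude data |F_obs(hkl)| is stored one row per unique Miller
index on a fixed Friedel hemisphere; the convention kept everywhere is

    (h > 0) or (h == 0 and k > 0) or (h == 0 and k == 0 and l >= 0).

Because merged amplitude data carries no anomalous signal in this setting,
one hemisphere representative per Friedel pair suffices.  Expansion to P1
replicates each amplitude onto the symmetry orbit of its index so that a
symmetry-free unit-cell model can be restrained by the full data set; free
(cross-validation) flags are regenerated after expansion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SymmetryOperator, UnitCellGeometry, parse_symop_triplet

__all__ = [
    "ReflectionSet",
    "hemisphere_reduce",
    "full_hemisphere",
    "expand_to_p1",
    "generate_free_flags",
    "assign_shells",
    "systematic_absences",
    "read_reflections",
    "write_reflections",
]

_COLUMNS = ["h", "k", "l", "f_obs", "sig_f", "is_free", "d", "shell_id"]


def hemisphere_reduce(hkl: np.ndarray) -> np.ndarray:
    """Map Miller indices onto the package's Friedel hemisphere."""
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    flip = (hkl[:, 0] < 0) | (
        (hkl[:, 0] == 0) & ((hkl[:, 1] < 0) | ((hkl[:, 1] == 0) & (hkl[:, 2] < 0)))
    )
    out = hkl.copy()
    out[flip] *= -1
    return out


def full_hemisphere(cell: UnitCellGeometry, d_min: float) -> np.ndarray:
    """All hemisphere indices (excluding (0,0,0)) with d >= d_min."""
    astar = np.sqrt(np.diag(cell.reciprocal_metric))
    hmax = np.floor(1.0 / (d_min * astar)).astype(int) + 1
    rng = [np.arange(-m, m + 1) for m in hmax]
    H = np.array(np.meshgrid(*rng, indexing="ij")).reshape(3, -1).T
    H = H[np.any(H != 0, axis=1)]
    keep = (H[:, 0] > 0) | (
        (H[:, 0] == 0) & ((H[:, 1] > 0) | ((H[:, 1] == 0) & (H[:, 2] >= 0)))
    )
    H = H[keep]
    d = cell.d_spacing(H)
    return H[d >= d_min - 1e-9]


@dataclass
class ReflectionSet:
    """A table of unique reflections with cell and provenance metadata.

    ``data`` columns: h, k, l, f_obs, sig_f (NaN when absent), is_free,
    d (Angstrom), shell_id (-1 before binning).  ``provenance`` is
    ``"merged"`` for symmetry-merged input and ``"p1-expanded"`` after
    expansion.
    """

    cell: UnitCellGeometry
    data: pd.DataFrame
    n_shells: int = 0
    provenance: str = "merged"
    operators: list[SymmetryOperator] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True).copy()
        for col in ("h", "k", "l"):
            df[col] = df[col].astype(int)
        if "sig_f" not in df:
            df["sig_f"] = np.nan
        if "is_free" not in df:
            df["is_free"] = False
        df["is_free"] = df["is_free"].astype(bool)
        if np.any(df["f_obs"].to_numpy() < 0):
            raise ValueError("amplitudes must be non-negative")
        dup = df.duplicated(subset=["h", "k", "l"])
        if dup.any():
            bad = tuple(int(x) for x in df.loc[dup.idxmax(), ["h", "k", "l"]])
            raise ValueError(f"duplicate Miller index {bad}")
        df["d"] = self.cell.d_spacing(df[["h", "k", "l"]].to_numpy())
        if "shell_id" not in df:
            df["shell_id"] = -1
        self.data = df[_COLUMNS]

    @property
    def hkl(self) -> np.ndarray:
        return self.data[["h", "k", "l"]].to_numpy()

    @property
    def f_obs(self) -> np.ndarray:
        return self.data["f_obs"].to_numpy()

    @property
    def is_free(self) -> np.ndarray:
        return self.data["is_free"].to_numpy()

    @property
    def d(self) -> np.ndarray:
        return self.data["d"].to_numpy()

    @property
    def shell_id(self) -> np.ndarray:
        return self.data["shell_id"].to_numpy()

    @property
    def d_min(self) -> float:
        return float(self.data["d"].min())

    @property
    def d_max(self) -> float:
        return float(self.data["d"].max())

    def __len__(self) -> int:
        return len(self.data)


# --------------------------------------------------------------------------
# expansion to P1


def expand_to_p1(rset: ReflectionSet, operators: list[SymmetryOperator] | None = None) -> ReflectionSet:
    """Expand a merged set onto the full symmetry orbit (hemisphere-reduced).

    For each reflection h and each operator with rotation R, the index
    h^T R belongs to the orbit and carries the same amplitude.  Orbit
    members are mapped to the Friedel hemisphere and de-duplicated, so the
    output holds exactly the distinct hemisphere orbit members.  Applying
    the expansion twice is a no-op.
    """
    ops = operators if operators is not None else rset.operators
    if not ops:
        raise ValueError("no symmetry operators supplied for expansion")
    hkl = rset.hkl
    rows = []
    for op in ops:
        ht = hkl @ op.R  # h^T R, exact integer arithmetic
        rows.append(ht)
    seen: dict[tuple[int, int, int], int] = {}
    out_rows = []
    df = rset.data
    for i_op, ht in enumerate(rows):
        red = hemisphere_reduce(ht)
        for i in range(len(df)):
            key = (int(red[i, 0]), int(red[i, 1]), int(red[i, 2]))
            if key not in seen:
                seen[key] = i
                out_rows.append(
                    (key[0], key[1], key[2], df["f_obs"].iat[i], df["sig_f"].iat[i])
                )
    new = pd.DataFrame(out_rows, columns=["h", "k", "l", "f_obs", "sig_f"])
    return ReflectionSet(
        rset.cell, new, provenance="p1-expanded", operators=list(ops)
    )


def generate_free_flags(rset: ReflectionSet, fraction: float = 0.10, seed: int = 0) -> ReflectionSet:
    """Flag round(fraction*N) reflections as the free (test) set.

    Selection is uniform without replacement and deterministic for a given
    seed.  When applied after P1 expansion the flags are drawn fresh on the
    expanded set, so symmetry mates of one merged observation may straddle
    the work/test split; that mirrors the pipeline this package follows.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    n = len(rset)
    n_free = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_free, replace=False)
    flags = np.zeros(n, dtype=bool)
    flags[idx] = True
    df = rset.data.copy()
    df["is_free"] = flags
    return ReflectionSet(rset.cell, df, rset.n_shells, rset.provenance, rset.operators)


def assign_shells(rset: ReflectionSet, n_shells: int, scheme: str = "equal-count") -> ReflectionSet:
    """Bin reflections into resolution shells, low resolution first.

    ``equal-count`` balances shell populations to within one reflection;
    ``equal-log-d`` uses uniform bins in log d.
    """
    n = len(rset)
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    if n_shells > n:
        raise ValueError(f"n_shells={n_shells} exceeds reflection count {n}")
    d = rset.d
    order = np.argsort(-d, kind="stable")  # descending d = low res first
    shell = np.empty(n, dtype=int)
    if scheme == "equal-count":
        bounds = np.linspace(0, n, n_shells + 1).round().astype(int)
        for s in range(n_shells):
            shell[order[bounds[s]:bounds[s + 1]]] = s
    elif scheme == "equal-log-d":
        logd = np.log(d)
        span = logd.max() - logd.min()
        if span == 0:
            shell[:] = 0
        else:
            shell = np.clip(
                ((logd.max() - logd) / span * n_shells).astype(int), 0, n_shells - 1
            )
    else:
        raise ValueError(f"unknown binning scheme {scheme!r}")
    df = rset.data.copy()
    df["shell_id"] = shell
    return ReflectionSet(rset.cell, df, n_shells, rset.provenance, rset.operators)


def systematic_absences(
    operators: list[SymmetryOperator], cell: UnitCellGeometry, d_min: float
) -> list[tuple[int, int, int]]:
    """Enumerate systematically absent indices to resolution d_min.

    An index h is absent when some operator (R, t) satisfies h^T R = h with
    exp(2 pi i h.t) != 1: the phase condition then forces F(h) = 0.  These
    indices can be appended to the work set as F_obs = 0 restraints for a
    symmetry-free unit-cell model, where the condition is no longer
    automatic.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    H = full_hemisphere(cell, d_min)
    absent = []
    for h in H:
        for op in operators:
            if np.array_equal(h @ op.R, h):
                phase = float(h @ op.t)
                if abs(phase - round(phase)) > 1e-9:
                    absent.append((int(h[0]), int(h[1]), int(h[2])))
                    break
    return absent


def add_absence_restraints(rset: ReflectionSet) -> ReflectionSet:
    """Append systematic absences as F_obs = 0 work-set rows."""
    absent = systematic_absences(rset.operators, rset.cell, rset.d_min)
    have = {tuple(row) for row in rset.hkl}
    rows = [(h, k, l, 0.0, np.nan) for (h, k, l) in absent if (h, k, l) not in have]
    if not rows:
        return rset
    extra = pd.DataFrame(rows, columns=["h", "k", "l", "f_obs", "sig_f"])
    extra["is_free"] = False
    df = pd.concat([rset.data[["h", "k", "l", "f_obs", "sig_f", "is_free"]], extra],
                   ignore_index=True)
    return ReflectionSet(rset.cell, df, rset.n_shells, rset.provenance, rset.operators)


# --------------------------------------------------------------------------
# I/O: CSV golden dialect and MTZ


def write_reflections(rset: ReflectionSet, path: str) -> None:
    """Write CSV (bit-exact golden dialect) or MTZ, chosen by extension.

    The CSV dialect is ``h,k,l,f_obs,sig_f,is_free`` with '#'-comment
    header lines carrying the cell parameters and operator triplets.
    """
    path = str(path)
    if path.endswith(".mtz"):
        _write_mtz(rset, path)
        return
    c = rset.cell
    with open(path, "w") as fh:
        fh.write(f"# cell {c.a!r} {c.b!r} {c.c!r} {c.alpha!r} {c.beta!r} {c.gamma!r}\n")
        for op in rset.operators:
            fh.write(f"# symop {op.triplet()}\n")
        fh.write(f"# provenance {rset.provenance}\n")
        fh.write("h,k,l,f_obs,sig_f,is_free\n")
        for row in rset.data.itertuples(index=False):
            sig = "" if np.isnan(row.sig_f) else repr(float(row.sig_f))
            fh.write(
                f"{row.h},{row.k},{row.l},{float(row.f_obs)!r},{sig},{int(row.is_free)}\n"
            )


def read_reflections(path: str, cell: UnitCellGeometry | None = None) -> ReflectionSet:
    """Read the CSV dialect or an MTZ file (columns F, SIGF, FreeR_flag)."""
    path = str(path)
    if path.endswith(".mtz"):
        return _read_mtz(path)
    operators: list[SymmetryOperator] = []
    provenance = "merged"
    header_cell = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "cell":
                    vals = [float(x) for x in parts[1:7]]
                    header_cell = UnitCellGeometry(*vals)
                elif parts and parts[0] == "symop":
                    operators.append(parse_symop_triplet("".join(parts[1:])))
                elif parts and parts[0] == "provenance":
                    provenance = parts[1]
                continue
            if line.startswith("h,"):
                continue
            f = line.split(",")
            rows.append(
                (
                    int(f[0]), int(f[1]), int(f[2]), float(f[3]),
                    float(f[4]) if f[4] != "" else np.nan,
                    bool(int(f[5])) if len(f) > 5 and f[5] != "" else False,
                )
            )
    use_cell = cell or header_cell
    if use_cell is None:
        raise ValueError(f"{path}: no cell parameters in header and none supplied")
    df = pd.DataFrame(rows, columns=["h", "k", "l", "f_obs", "sig_f", "is_free"])
    return ReflectionSet(use_cell, df, provenance=provenance, operators=operators)


def _write_mtz(rset: ReflectionSet, path: str) -> None:
    import gemmi

    mtz = gemmi.Mtz(with_base=True)
    c = rset.cell
    mtz.set_cell_for_all(gemmi.UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma))
    mtz.spacegroup = gemmi.SpaceGroup("P1")
    mtz.add_dataset("ucrefine")
    mtz.add_column("F", "F")
    mtz.add_column("SIGF", "Q")
    mtz.add_column("FreeR_flag", "I")
    arr = np.column_stack(
        [
            rset.hkl.astype(float),
            rset.f_obs,
            rset.data["sig_f"].to_numpy(),
            rset.is_free.astype(float),
        ]
    )
    mtz.set_data(arr)
    mtz.write_to_file(path)


def _read_mtz(path: str) -> ReflectionSet:
    import gemmi

    mtz = gemmi.read_mtz_file(path)
    labels = [col.label for col in mtz.columns]
    fcol = next((l for l in labels if l in ("F", "FP", "FOBS", "F-obs")), None)
    if fcol is None:
        icols = [l for l in labels if l.upper() in ("I", "IOBS", "IMEAN")]
        if icols:
            raise ValueError(
                f"{path}: intensity columns only ({icols}); convert intensities "
                "to amplitudes before loading"
            )
        raise ValueError(f"{path}: no amplitude column among {labels}")
    arr = np.array(mtz, copy=True)
    col = {l: i for i, l in enumerate(labels)}
    df = pd.DataFrame(
        {
            "h": arr[:, col["H"]].astype(int),
            "k": arr[:, col["K"]].astype(int),
            "l": arr[:, col["L"]].astype(int),
            "f_obs": arr[:, col[fcol]],
        }
    )
    sig = next((l for l in labels if l in ("SIGF", "SIGFP", "SIGFOBS")), None)
    df["sig_f"] = arr[:, col[sig]] if sig else np.nan
    free = next((l for l in labels if "free" in l.lower()), None)
    df["is_free"] = arr[:, col[free]].astype(int).astype(bool) if free else False
    cell = UnitCellGeometry(
        mtz.cell.a, mtz.cell.b, mtz.cell.c, mtz.cell.alpha, mtz.cell.beta, mtz.cell.gamma
    )
    return ReflectionSet(cell, df)
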