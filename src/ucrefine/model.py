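"""Crystal geometry, symmetry operators and the refinable atomic model.

The refinement engine works on a whole crystal unit cell treated as a P1
(symmetry-free) cell: the asymmetric unit is expanded by the space-group
operators once, up front, and from then on every atom is an independent
degree of freedom.  This module provides the unit-cell metric, fractional
<-> Cartesian conversion under the standard PDB orthogonalization
convention (a along x, b in the xy plane), symmetry-operator parsing from
triplet strings such as ``-x, y+1/2, -z``, unit-cell assembly, and the
solvent-content bookkeeping used to decide how many waters and counterions
a hydrated cell should hold.

Coordinates are fractional internally, wrapped to [0, 1); Cartesian
coordinates appear only at the force/integrator boundary.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np

from ._tables import (
    DA_ML_PER_G_TO_A3,
    PROTEIN_SPECIFIC_VOLUME,
    RESIDUE_CHARGE,
    WATER_VOLUME_A3,
    element_mass,
)

__all__ = [
    "UnitCellGeometry",
    "SymmetryOperator",
    "AtomRecord",
    "AtomicModel",
    "parse_symop_triplet",
    "SPACE_GROUP_OPERATORS",
    "operators_for",
    "build_unit_cell",
    "estimate_water_and_ions",
    "place_solvent",
    "read_model",
    "write_model",
]


# --------------------------------------------------------------------------
# unit cell


@dataclass(frozen=True)
class UnitCellGeometry:
    """Triclinic cell parameters with cached metric machinery.

    Attributes
    ----------
    a, b, c : float
        Edge lengths in Angstrom.
    alpha, beta, gamma : float
        Angles in degrees.
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0.0:
            raise ValueError("cell angles do not define a positive-definite metric")

    @property
    def volume(self) -> float:
        """Cell volume in Angstrom^3 (closed-form triclinic expression)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def orth_matrix(self) -> np.ndarray:
        """3x3 matrix A with cart = A @ frac (PDB convention)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = self.volume
        return np.array(
            [
                [a, b * cg, c * cb],
                [0.0, b * sg, c * (ca - cb * cg) / sg],
                [0.0, 0.0, v / (a * b * sg)],
            ]
        )

    @property
    def frac_matrix(self) -> np.ndarray:
        """Inverse of :attr:`orth_matrix`: frac = frac_matrix @ cart."""
        return np.linalg.inv(self.orth_matrix)

    @property
    def metric_tensor(self) -> np.ndarray:
        """Real-space metric G = A^T A; squared distances are df^T G df."""
        A = self.orth_matrix
        return A.T @ A

    @property
    def reciprocal_metric(self) -> np.ndarray:
        """Reciprocal metric G* = G^-1; 1/d^2 = h^T G* h."""
        return np.linalg.inv(self.metric_tensor)

    def orthogonalize(self, frac) -> np.ndarray:
        """Fractional -> Cartesian (Angstrom)."""
        frac = np.asarray(frac, dtype=float)
        return frac @ self.orth_matrix.T

    def fractionalize(self, cart) -> np.ndarray:
        """Cartesian (Angstrom) -> fractional."""
        cart = np.asarray(cart, dtype=float)
        return cart @ self.frac_matrix.T

    def d_spacing(self, hkl) -> np.ndarray | float:
        """Resolution d (Angstrom) of one or many Miller indices.

        1/d^2 = h^T G* h with G* the reciprocal metric tensor; the
        scattering-vector magnitude used by form factors is s = 1/(2d).
        """
        h = np.asarray(hkl, dtype=float)
        single = h.ndim == 1
        h = np.atleast_2d(h)
        if np.any(np.all(h == 0, axis=1)):
            raise ValueError("d-spacing undefined for (0,0,0)")
        inv_d2 = np.einsum("ij,jk,ik->i", h, self.reciprocal_metric, h)
        d = 1.0 / np.sqrt(inv_d2)
        return float(d[0]) if single else d


# --------------------------------------------------------------------------
# symmetry operators

_TERM_RE = re.compile(r"([+-]?)\s*(\d+(?:/\d+)?|[xyz])")
_ALLOWED_DENOMS = {1, 2, 3, 4, 6, 12}


@dataclass(frozen=True)
class SymmetryOperator:
    """A crystallographic symmetry operation acting on fractional coordinates.

    ``frac' = rotation @ frac + translation``.  Rotation entries are in
    {-1, 0, 1}; translation components are rationals with denominator
    dividing 12 (stored as floats, exact for these values).
    """

    rotation: tuple[tuple[int, int, int], ...]
    translation: tuple[float, float, float]

    def __post_init__(self) -> None:
        R = np.array(self.rotation)
        if R.shape != (3, 3) or not np.all(np.isin(R, (-1, 0, 1))):
            raise ValueError("rotation must be 3x3 with entries in {-1,0,1}")
        if round(abs(np.linalg.det(R))) != 1:
            raise ValueError("rotation is not unimodular")

    @property
    def R(self) -> np.ndarray:
        return np.array(self.rotation, dtype=int)

    @property
    def t(self) -> np.ndarray:
        return np.array(self.translation, dtype=float)

    def apply(self, frac) -> np.ndarray:
        """Apply to fractional coordinates, wrapped to [0, 1)."""
        frac = np.asarray(frac, dtype=float)
        out = frac @ self.R.T.astype(float) + self.t
        return out % 1.0

    def compose(self, other: "SymmetryOperator") -> "SymmetryOperator":
        """self after other, translation reduced mod 1."""
        R = self.R @ other.R
        t = (self.R @ other.t + self.t) % 1.0
        return SymmetryOperator(tuple(map(tuple, R.tolist())), tuple(t.tolist()))

    def triplet(self) -> str:
        """Format back to ``x,y,z``-style text (round-trips with the parser)."""
        names = "xyz"
        parts = []
        for i in range(3):
            term = ""
            for j in range(3):
                r = self.rotation[i][j]
                if r == 1:
                    term += ("+" if term else "") + names[j]
                elif r == -1:
                    term += "-" + names[j]
            tfrac = Fraction(self.translation[i]).limit_denominator(12)
            if tfrac != 0:
                sign = "+" if tfrac > 0 else "-"
                term += f"{sign}{abs(tfrac)}"
            parts.append(term or "0")
        return ",".join(parts)

    def is_identity(self) -> bool:
        return np.array_equal(self.R, np.eye(3, dtype=int)) and np.allclose(self.t, 0)


def parse_symop_triplet(triplet: str) -> SymmetryOperator:
    """Parse a symmetry-operator triplet such as ``"-x, y+1/2, -z"``.

    Each of the three comma-separated terms is a signed combination of the
    variables x, y, z plus an optional rational offset with denominator in
    {2, 3, 4, 6, 12}.
    """
    terms = [t.strip() for t in triplet.split(",")]
    if len(terms) != 3:
        raise ValueError(f"expected 3 comma-separated terms, got {triplet!r}")
    rotation = np.zeros((3, 3), dtype=int)
    translation = np.zeros(3)
    for i, term in enumerate(terms):
        consumed = 0
        compact = term.replace(" ", "")
        if not compact:
            raise ValueError(f"empty term in {triplet!r}")
        for m in _TERM_RE.finditer(compact):
            if m.start() != consumed:
                raise ValueError(f"malformed term {term!r} in {triplet!r}")
            if consumed > 0 and m.group(1) == "":
                # tokens after the first need an explicit sign ("2x" is not
                # a unimodular coefficient, it is a parse error)
                raise ValueError(f"malformed term {term!r} in {triplet!r}")
            consumed = m.end()
            sign = -1 if m.group(1) == "-" else 1
            tok = m.group(2)
            if tok in "xyz":
                rotation[i, "xyz".index(tok)] += sign
            else:
                frac = Fraction(tok)
                if frac.denominator not in _ALLOWED_DENOMS:
                    raise ValueError(f"unsupported denominator in term {term!r}")
                translation[i] += sign * float(frac)
        if consumed != len(compact):
            raise ValueError(f"malformed term {term!r} in {triplet!r}")
    translation %= 1.0
    if not np.all(np.isin(rotation, (-1, 0, 1))):
        raise ValueError(f"rotation entries outside {{-1,0,1}} in {triplet!r}")
    if round(abs(np.linalg.det(rotation))) != 1:
        raise ValueError(f"non-unimodular rotation in {triplet!r}")
    return SymmetryOperator(tuple(map(tuple, rotation.tolist())), tuple(translation.tolist()))


#: Convenience operator lists for the space groups used by the toy fixtures.
SPACE_GROUP_OPERATORS: dict[str, tuple[str, ...]] = {
    "P1": ("x,y,z",),
    "P21": ("x,y,z", "-x,y+1/2,-z"),
    "P212121": (
        "x,y,z",
        "-x+1/2,-y,z+1/2",
        "-x,y+1/2,-z+1/2",
        "x+1/2,-y+1/2,-z",
    ),
    "C2": ("x,y,z", "-x,y,-z", "x+1/2,y+1/2,z", "-x+1/2,y+1/2,-z"),
}


def operators_for(space_group: str) -> list[SymmetryOperator]:
    """Operators for one of the convenience space groups (P1, P21, P212121, C2)."""
    key = space_group.replace(" ", "").replace("(", "").replace(")", "")
    if key not in SPACE_GROUP_OPERATORS:
        raise KeyError(
            f"no built-in operators for {space_group!r}; supply triplets explicitly "
            f"(built-ins: {sorted(SPACE_GROUP_OPERATORS)})"
        )
    return [parse_symop_triplet(t) for t in SPACE_GROUP_OPERATORS[key]]


def check_operator_closure(operators: list[SymmetryOperator], tol: float = 1e-9) -> bool:
    """True if the operator set is closed under composition modulo unit translations."""
    def key(op: SymmetryOperator):
        t = np.round(np.asarray(op.t) * 12) % 12
        return (tuple(op.R.ravel()), tuple(int(x) for x in t))

    have = {key(op) for op in operators}
    for p in operators:
        for q in operators:
            if key(p.compose(q)) not in have:
                return False
    return True


# --------------------------------------------------------------------------
# atoms and models


@dataclass
class AtomRecord:
    """One atom: element, identifiers, fractional position, isotropic B."""

    element: str
    chain: str
    residue_id: int
    atom_name: str
    frac: tuple[float, float, float]
    b_iso: float
    occupancy: float = 1.0
    residue_name: str = "UNK"
    is_protein: bool = True

    def __post_init__(self) -> None:
        if self.b_iso < 0:
            raise ValueError("b_iso must be non-negative")
        if self.occupancy != 1.0:
            raise ValueError("occupancies must all equal 1.0")


class AtomicModel:
    """A crystal model: cell, symmetry operators and atom records.

    Atom data is held in numpy arrays (``frac`` (N,3), ``b_iso`` (N,),
    ``occupancy`` (N,), boolean ``is_protein`` (N,)) with parallel lists of
    element symbols and identifiers, so the scattering code can vectorize
    over atoms.  ``is_p1_expanded`` records whether the model is the full
    unit cell (all operators applied) as opposed to an asymmetric unit.
    """

    def __init__(
        self,
        cell: UnitCellGeometry,
        operators: list[SymmetryOperator],
        atoms: list[AtomRecord],
        is_p1_expanded: bool = False,
    ) -> None:
        self.cell = cell
        self.operators = list(operators)
        if not self.operators:
            self.operators = [parse_symop_triplet("x,y,z")]
        self._records = list(atoms)
        self.is_p1_expanded = is_p1_expanded
        self._sync_arrays()

    def _sync_arrays(self) -> None:
        n = len(self._records)
        self.frac = np.array([r.frac for r in self._records], dtype=float).reshape(n, 3) % 1.0
        self.b_iso = np.array([r.b_iso for r in self._records], dtype=float)
        self.occupancy = np.array([r.occupancy for r in self._records], dtype=float)
        self.elements = [r.element.strip().upper() for r in self._records]
        self.is_protein = np.array([r.is_protein for r in self._records], dtype=bool)

    @property
    def atoms(self) -> list[AtomRecord]:
        return self._records

    @property
    def n_atoms(self) -> int:
        return len(self._records)

    def set_frac(self, frac: np.ndarray) -> None:
        """Replace fractional coordinates (wrapped to [0,1))."""
        frac = np.asarray(frac, dtype=float)
        if frac.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        self.frac = frac % 1.0
        for r, f in zip(self._records, self.frac):
            r.frac = tuple(f)

    def set_b_iso(self, b: np.ndarray) -> None:
        b = np.asarray(b, dtype=float)
        if b.shape != (self.n_atoms,):
            raise ValueError("B-factor array shape mismatch")
        if np.any(b < 0):
            raise ValueError("b_iso must be non-negative")
        self.b_iso = b.copy()
        for r, bi in zip(self._records, self.b_iso):
            r.b_iso = float(bi)

    def cartesian(self) -> np.ndarray:
        return self.cell.orthogonalize(self.frac)

    def copy(self) -> "AtomicModel":
        return AtomicModel(
            self.cell,
            list(self.operators),
            [replace(r) for r in self._records],
            self.is_p1_expanded,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<AtomicModel {self.n_atoms} atoms, {len(self.operators)} ops, "
            f"{'P1-expanded' if self.is_p1_expanded else 'ASU'}>"
        )


def build_unit_cell(asu: AtomicModel) -> AtomicModel:
    """Assemble the full unit cell from the asymmetric unit.

    Every symmetry operator is applied to every atom (``frac' = R frac + t``
    wrapped to [0, 1)); B factors, occupancies and elements are copied, and
    chain identifiers of symmetry copies beyond the first are suffixed with
    the operator index so the copies remain distinguishable.  Near-duplicate
    positions (< 0.1 Angstrom apart, periodic metric) are reported as
    special-position candidates but not merged.
    """
    if asu.is_p1_expanded:
        raise ValueError("model is already P1-expanded")
    records: list[AtomRecord] = []
    for i_op, op in enumerate(asu.operators):
        for rec in asu.atoms:
            new = replace(rec)
            new.frac = tuple(op.apply(np.asarray(rec.frac)))
            if i_op > 0:
                new.chain = f"{rec.chain}{i_op}"
            records.append(new)
    out = AtomicModel(asu.cell, asu.operators, records, is_p1_expanded=True)
    _warn_special_positions(out)
    return out


def _warn_special_positions(model: AtomicModel, cutoff: float = 0.1) -> None:
    df = model.frac[:, None, :] - model.frac[None, :, :]
    df -= np.round(df)
    dist = np.linalg.norm(np.einsum("mk,ijk->mij", model.cell.orth_matrix, df), axis=0)
    iu = np.triu_indices(model.n_atoms, k=1)
    close = dist[iu] < cutoff
    if np.any(close):
        pairs = [(int(iu[0][k]), int(iu[1][k])) for k in np.nonzero(close)[0]]
        warnings.warn(
            f"special-position candidates (pairs closer than {cutoff} A): {pairs[:20]}",
            stacklevel=3,
        )


# --------------------------------------------------------------------------
# solvent-content accounting


def estimate_water_and_ions(model: AtomicModel) -> tuple[int, int, int]:
    """Estimate how many waters and counterions a hydrated cell should hold.

    The protein volume follows from the total atomic mass and the generic
    protein partial specific volume 0.74 ml/g; the remaining cell volume is
    filled with water at 29.9 A^3 per molecule.  The net formal charge from
    the residue-type table (Asp/Glu -1, Lys/Arg +1, His 0) is neutralized
    with Na+ or Cl-, each ion displacing one water site.

    Returns ``(n_water, n_na, n_cl)``.
    """
    mass = sum(element_mass(el) for el in model.elements)
    v_protein = mass * PROTEIN_SPECIFIC_VOLUME * DA_ML_PER_G_TO_A3
    v_cell = model.cell.volume
    if v_protein >= v_cell:
        warnings.warn("protein volume exceeds the cell volume; no room for water")
        return 0, 0, 0
    n_water = int(math.floor((v_cell - v_protein) / WATER_VOLUME_A3))

    seen: set[tuple[str, int]] = set()
    charge = 0
    for rec in model.atoms:
        key = (rec.chain, rec.residue_id)
        if rec.is_protein and key not in seen:
            seen.add(key)
            charge += RESIDUE_CHARGE.get(rec.residue_name.upper(), 0)
    n_na = max(0, -charge)
    n_cl = max(0, charge)
    n_water = max(0, n_water - n_na - n_cl)
    return n_water, n_na, n_cl


def place_solvent(
    model: AtomicModel,
    n_water: int,
    n_na: int = 0,
    n_cl: int = 0,
    seed: int = 0,
    min_dist: float = 2.4,
    max_attempts: int = 10_000,
) -> AtomicModel:
    """Add water oxygens and ions by rejection sampling.

    Sites are drawn uniformly in the cell and accepted when at least
    ``min_dist`` (default 2.4 A, periodic metric) from every existing atom.
    This placement is a simple geometric heuristic sufficient for the toy
    restraint potential; solvent atoms are flagged ``is_protein=False`` so
    the X-ray forces never act on them.
    """
    rng = np.random.default_rng(seed)
    out = model.copy()
    species = [("O", "HOH", False)] * n_water + [("NA", "NA", False)] * n_na + [
        ("CL", "CL", False)
    ] * n_cl
    A = model.cell.orth_matrix
    existing = out.frac.copy()
    records = list(out.atoms)
    resid = max((r.residue_id for r in records), default=0)
    for k, (element, resname, _) in enumerate(species):
        for attempt in range(max_attempts):
            cand = rng.random(3)
            if existing.size:
                df = existing - cand
                df -= np.round(df)
                d = np.linalg.norm(df @ A.T, axis=1)
                if d.min() < min_dist:
                    continue
            resid += 1
            records.append(
                AtomRecord(
                    element=element,
                    chain="W",
                    residue_id=resid,
                    atom_name=element if element != "O" else "O",
                    frac=tuple(cand),
                    b_iso=30.0,
                    residue_name=resname,
                    is_protein=False,
                )
            )
            existing = np.vstack([existing, cand]) if existing.size else cand[None]
            break
        else:
            raise RuntimeError(
                f"could not place solvent site {k + 1}/{len(species)} "
                f"after {max_attempts} attempts"
            )
    return AtomicModel(out.cell, out.operators, records, out.is_p1_expanded)


# --------------------------------------------------------------------------
# model I/O (PDB / mmCIF via gemmi)

_WATER_NAMES = {"HOH", "WAT", "NA", "CL"}


def read_model(path: str, space_group: str | None = None) -> AtomicModel:
    """Read a PDB or mmCIF file into an :class:`AtomicModel`.

    The cell comes from CRYST1 / the cell category; symmetry operators come
    from the file's space-group name when it is one of the built-in groups,
    from ``space_group`` when given, and default to identity otherwise.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    cell = UnitCellGeometry(
        st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma
    )
    sg_name = space_group or (st.spacegroup_hm or "P1")
    try:
        operators = operators_for(sg_name)
    except KeyError:
        ops = gemmi.find_spacegroup_by_name(sg_name)
        if ops is None:
            raise
        operators = [parse_symop_triplet(op.triplet()) for op in ops.operations()]
    records: list[AtomRecord] = []
    fm = cell.frac_matrix
    for chain in st[0]:
        for res in chain:
            for atom in res:
                frac = fm @ np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                records.append(
                    AtomRecord(
                        element=atom.element.name.upper(),
                        chain=chain.name,
                        residue_id=res.seqid.num,
                        atom_name=atom.name,
                        frac=tuple(frac % 1.0),
                        b_iso=float(atom.b_iso),
                        occupancy=1.0,
                        residue_name=res.name,
                        is_protein=res.name.upper() not in _WATER_NAMES,
                    )
                )
    return AtomicModel(cell, operators, records, is_p1_expanded=False)


def write_model(model: AtomicModel, path: str) -> None:
    """Write the model as PDB or mmCIF (by extension), CRYST1 set to P1 when expanded."""
    import gemmi

    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(
        model.cell.a, model.cell.b, model.cell.c,
        model.cell.alpha, model.cell.beta, model.cell.gamma,
    )
    st.spacegroup_hm = "P 1"
    gmodel = gemmi.Model("1")
    chains: dict[str, "gemmi.Chain"] = {}
    A = model.cell.orth_matrix
    for rec in model.atoms:
        ch = chains.get(rec.chain)
        if ch is None:
            gmodel.add_chain(gemmi.Chain(rec.chain[:2]))
            ch = gmodel[-1]
            chains[rec.chain] = ch
        res = gemmi.Residue()
        res.name = rec.residue_name
        res.seqid = gemmi.SeqId(rec.residue_id, " ")
        atom = gemmi.Atom()
        atom.name = rec.atom_name
        atom.element = gemmi.Element(rec.element.capitalize())
        cart = A @ np.asarray(rec.frac)
        atom.pos = gemmi.Position(*cart)
        atom.b_iso = rec.b_iso
        atom.occ = rec.occupancy
        res.add_atom(atom)
        ch.add_residue(res)
    st.add_model(gmodel)
    path = str(path)
    if path.endswith(".cif") or path.endswith(".mmcif"):
        st.make_mmcif_document().write_file(path)
    else:
        st.write_pdb(path)
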