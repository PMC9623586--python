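"""Torsional geometry: dihedral angles, periodic arithmetic, and the
torsional-space metric.

All angles are in degrees, normalized to the half-open interval (-180, 180]
with the IUPAC sign convention for dihedrals.  The distance between two
side-chain conformations is the Euclidean norm, over chi dihedrals, of the
shortest-arc angular differences::

    d(p, q) = sqrt( sum_i  min(|p_i - q_i|, 360 - |p_i - q_i|)^2 )

This metric preserves the rotational energy barriers of each chi bond and is
the coordinate in which side-chain conformations are clustered into rotamers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "normalize_angle",
    "periodic_angle_distance",
    "TorsionVector",
    "torsion_distance",
    "AtomQuadruple",
    "dihedral_angle",
    "chi_definitions",
    "chi_count",
    "extract_sidechain_torsions",
    "place_atom",
    "SYMMETRIC_TERMINAL_CHI",
]

# Boltzmann constant in kcal mol^-1 K^-1; shared by the whole package.
KB_KCAL_MOL_K = 1.987204259e-3

#: Terminal chi dihedrals that are two-fold symmetric in the underlying
#: chemistry (ring flips / carboxylate oxygen exchange).  Folding them into a
#: half-range is optional and off by default.
SYMMETRIC_TERMINAL_CHI = {"PHE": 2, "TYR": 2, "ASP": 2, "GLU": 3}


def normalize_angle(raw: float | np.ndarray) -> float | np.ndarray:
    """Normalize an angle in degrees to the interval (-180, 180].

    Idempotent; adding any multiple of 360 deg does not change the result.
    Accepts scalars or arrays.  Raises ``ValueError`` on non-finite input.
    """
    arr = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("angle must be finite")
    out = -((-arr + 180.0) % 360.0) + 180.0
    if np.ndim(raw) == 0:
        return float(out)
    return out


def periodic_angle_distance(a: float, b: float) -> float | np.ndarray:
    """Shortest arc between two angles on the circle, in [0, 180] degrees.

    E.g. the distance between -179 deg and 180 deg is 1 deg.
    """
    d = normalize_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    return np.abs(d) if np.ndim(d) else abs(d)


@dataclass(frozen=True)
class TorsionVector:
    """Ordered chi dihedral angles (degrees) of one side chain.

    The angles are normalized to (-180, 180] on construction.  ``n`` is the
    number of chi dihedrals (>= 1).
    """

    angles: tuple

    def __init__(self, angles: Iterable[float]):
        arr = tuple(float(normalize_angle(a)) for a in angles)
        if len(arr) == 0:
            raise ValueError("TorsionVector needs at least one chi angle")
        object.__setattr__(self, "angles", arr)

    @property
    def n(self) -> int:
        return len(self.angles)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.angles, dtype=float)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.angles)


def _coerce(v) -> np.ndarray:
    if isinstance(v, TorsionVector):
        return v.as_array()
    return np.atleast_1d(normalize_angle(np.asarray(v, dtype=float)))


def torsion_distance(p, q) -> float:
    """Euclidean distance between two torsion vectors under periodic wrap.

    The per-component differences use the shortest arc, so the distance
    between (-179,) and (180,) is 1 deg.  This is a true metric; note that
    d(p, q) < c implies every per-chi distance < c, so a cutoff on d is
    stricter than the same cutoff applied per dihedral.
    """
    pa, qa = _coerce(p), _coerce(q)
    if pa.shape != qa.shape:
        raise ValueError(
            f"torsion dimension mismatch: {pa.shape[0]} vs {qa.shape[0]}"
        )
    d = periodic_angle_distance(pa, qa)
    return float(np.sqrt(np.sum(np.square(d))))


@dataclass(frozen=True)
class AtomQuadruple:
    """Four atom indices (i, j, k, l) defining a dihedral about the j-k bond."""

    i: int
    j: int
    k: int
    l: int

    def __post_init__(self):
        if len({self.i, self.j, self.k, self.l}) != 4:
            raise ValueError("dihedral atom indices must be distinct")

    def as_tuple(self) -> tuple:
        return (self.i, self.j, self.k, self.l)


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees) of four points, IUPAC convention.

    Looking along the p2->p3 bond, a clockwise rotation of the far bond
    relative to the near bond is positive.  Returns a value in (-180, 180].
    Raises ``ValueError`` for degenerate (collinear or coincident) geometry.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12:
        raise ValueError("central bond has zero length")
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate dihedral: collinear atom triple")
    m1 = np.cross(n1, b2 / b2n)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return normalize_angle(math.degrees(math.atan2(y, x)))


# ---------------------------------------------------------------------------
# Canonical chi definitions
# ---------------------------------------------------------------------------

def _load_chi_table() -> dict:
    table: dict = {}
    text = (
        resources.files("rotamerbh").joinpath("data/chi_definitions.tsv").read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, chi, *atoms = line.split("\t")
        table.setdefault(res, {})[int(chi)] = tuple(atoms)
    return {
        res: tuple(chis[i] for i in sorted(chis)) for res, chis in table.items()
    }


_CHI_TABLE = _load_chi_table()


def chi_definitions(residue_name: str) -> tuple:
    """Ordered (chi1, chi2, ...) atom-name quadruples for a residue type.

    Raises ``ValueError`` for residue types without rotameric side chains
    (ALA, GLY, PRO, capping groups, unknown names).
    """
    res = residue_name.upper()
    if res not in _CHI_TABLE:
        raise ValueError(
            f"residue {residue_name!r} has no rotameric chi dihedrals"
        )
    return _CHI_TABLE[res]


def chi_count(residue_name: str) -> int:
    return len(chi_definitions(residue_name))


def extract_sidechain_torsions(
    residue_atoms: Mapping[str, Sequence[float]],
    residue_name: str,
    fold_symmetric: bool = False,
) -> TorsionVector:
    """Compute the chi dihedrals of one residue from its atom coordinates.

    Parameters
    ----------
    residue_atoms
        Mapping of atom name to 3-D coordinate for the residue (backbone N
        and CA are required in addition to the side-chain heavy atoms).
    residue_name
        Three-letter residue code (HID/HIE/HIP accepted for histidine).
    fold_symmetric
        If True, two-fold symmetric terminal dihedrals (PHE/TYR chi2,
        ASP chi2, GLU chi3) are folded into (-90, 90].

    Raises ``KeyError`` naming the residue and atom if a required atom is
    missing, and ``ValueError`` if the residue type has no chi dihedrals.
    """
    quads = chi_definitions(residue_name)
    angles = []
    for chi_idx, names in enumerate(quads, start=1):
        coords = []
        for name in names:
            if name not in residue_atoms:
                raise KeyError(
                    f"residue {residue_name}: missing atom {name} "
                    f"(needed for chi{chi_idx})"
                )
            coords.append(residue_atoms[name])
        ang = dihedral_angle(*coords)
        if (
            fold_symmetric
            and SYMMETRIC_TERMINAL_CHI.get(residue_name.upper()) == chi_idx
        ):
            ang = normalize_angle(ang + 180.0) if abs(ang) > 90.0 else ang
            if ang == -90.0:
                ang = 90.0
        angles.append(ang)
    return TorsionVector(angles)


def place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place a new atom D given three reference atoms and internal coordinates.

    ``bond`` is |C-D| in the coordinate units, ``angle`` the B-C-D angle in
    degrees, ``dihedral`` the A-B-C-D dihedral in degrees (IUPAC sign).
    Standard natural-extension (NeRF) construction.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    th = math.radians(angle)
    ph = math.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("reference atoms are collinear")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(th),
            bond * math.sin(th) * math.cos(ph),
            -bond * math.sin(th) * math.sin(ph),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
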