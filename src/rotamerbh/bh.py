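"""Basin-hopping global optimization with rotamer and group-rotation moves.

Basin-hopping explores a potential energy surface transformed so that every
point maps to the energy of its local minimum,

    E~(r) = min V(r),

by perturbing the current structure, locally minimizing, and accepting or
rejecting the new minimum with a Metropolis criterion at a sampling
temperature expressed in energy units.  The free-energy variant (FEBH)
applies the same criterion to local free energies estimated with the
harmonic superposition approximation.

Move types:

* group rotation — rotate all atoms downstream of a chosen rotatable bond by
  a random amount (applied to backbone phi/psi and, in the group-rotation
  schemes, to side-chain chi dihedrals);
* rotamer move — set all chi dihedrals of a uniformly chosen residue to a
  library rotamer drawn with its occupation probability;
* Cartesian displacement — independent uniform atomic displacements.

Schemes are parameterized by (n_SC, f_SC, n_BB, f_BB): the number of
side-chain moves (residues for rotamer moves, chi dihedrals for group
rotation) applied every f_SC steps, and the number of backbone dihedrals
rotated every f_BB steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.transform import Rotation as _Rotation

from .torsion import KB_KCAL_MOL_K, AtomQuadruple, dihedral_angle, normalize_angle
from .library import Context, RotamerLibrary

__all__ = [
    "ResidueTopology",
    "Topology",
    "Potential",
    "BHScheme",
    "MinimumRecord",
    "BHTrajectory",
    "rotate_dihedral",
    "set_dihedral",
    "local_minimize",
    "harmonic_free_energy",
    "metropolis_accept",
    "group_rotation_move",
    "cartesian_displacement_move",
    "rotamer_move",
    "run_basin_hopping",
    "markov_diagnostics",
    "scheme_presets",
    "superposition_rmsd",
]


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass
class ResidueTopology:
    """One chi-bearing residue: name, atom-name -> index map, chi quadruples."""

    name: str
    chain_pos: int
    atoms: Dict[str, int]
    chi_quads: List[AtomQuadruple]


@dataclass
class Topology:
    """Bond graph plus residue and dihedral bookkeeping for a structure."""

    n_atoms: int
    bonds: List[Tuple[int, int]]
    chain_names: List[str]
    residues: List[ResidueTopology]
    backbone_quads: List[AtomQuadruple]

    def __post_init__(self):
        self._adj: List[List[int]] = [[] for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            self._adj[i].append(j)
            self._adj[j].append(i)
        self._downstream_cache: Dict[Tuple[int, int], np.ndarray] = {}

    def context(self, residue: ResidueTopology) -> Context:
        pos = residue.chain_pos
        return (
            self.chain_names[pos - 1],
            self.chain_names[pos],
            self.chain_names[pos + 1],
        )

    def sidechain_quads(self) -> List[AtomQuadruple]:
        return [q for r in self.residues for q in r.chi_quads]

    def downstream_atoms(self, j: int, k: int) -> np.ndarray:
        """Atoms on the k side of the j-k bond (moved when rotating it)."""
        key = (j, k)
        if key not in self._downstream_cache:
            seen = {j, k}
            stack = [k]
            out = []
            while stack:
                a = stack.pop()
                for b in self._adj[a]:
                    if b not in seen:
                        if b == j:
                            raise ValueError("bond is part of a ring")
                        seen.add(b)
                        out.append(b)
                        stack.append(b)
            self._downstream_cache[key] = np.asarray(sorted(out), dtype=int)
        return self._downstream_cache[key]


# ---------------------------------------------------------------------------
# Potential interface
# ---------------------------------------------------------------------------

class Potential:
    """Energy function with gradient (and optionally Hessian) and topology.

    Subclasses implement ``energy`` and ``gradient`` over flat (3N,) or
    (N, 3) coordinate arrays; ``hessian`` defaults to central finite
    differences of the gradient.
    """

    topology: Optional[Topology] = None

    def energy(self, coords: np.ndarray) -> float:  # pragma: no cover
        raise NotImplementedError

    def gradient(self, coords: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def energy_gradient(self, coords: np.ndarray) -> Tuple[float, np.ndarray]:
        return self.energy(coords), self.gradient(coords)

    def hessian(self, coords: np.ndarray, step: float = 1e-4) -> np.ndarray:
        x = np.asarray(coords, dtype=float).ravel()
        n = x.size
        H = np.empty((n, n))
        for i in range(n):
            xp = x.copy()
            xm = x.copy()
            xp[i] += step
            xm[i] -= step
            H[:, i] = (
                np.asarray(self.gradient(xp)).ravel()
                - np.asarray(self.gradient(xm)).ravel()
            ) / (2.0 * step)
        return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# Dihedral manipulation
# ---------------------------------------------------------------------------

def _measure(coords: np.ndarray, quad: AtomQuadruple) -> float:
    c = coords.reshape(-1, 3)
    return dihedral_angle(c[quad.i], c[quad.j], c[quad.k], c[quad.l])


def rotate_dihedral(
    coords: np.ndarray, topology: Topology, quad: AtomQuadruple, delta: float
) -> np.ndarray:
    """Rotate all atoms downstream of the j-k bond by ``delta`` degrees.

    The rotation increases the dihedral defined by ``quad`` by ``delta``
    (mod 360); bond lengths and angles are untouched.
    """
    c = coords.reshape(-1, 3).copy()
    axis = c[quad.k] - c[quad.j]
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("zero-length rotation axis")
    axis /= norm
    moving = topology.downstream_atoms(quad.j, quad.k)
    rot = _Rotation.from_rotvec(np.radians(-delta) * axis)
    c[moving] = rot.apply(c[moving] - c[quad.k]) + c[quad.k]
    return c.reshape(np.asarray(coords).shape)


def set_dihedral(
    coords: np.ndarray, topology: Topology, quad: AtomQuadruple, target: float
) -> np.ndarray:
    """Rotate the j-k bond so the dihedral equals ``target`` degrees."""
    current = _measure(np.asarray(coords, dtype=float), quad)
    return rotate_dihedral(coords, topology, quad, normalize_angle(target - current))


# ---------------------------------------------------------------------------
# Local minimization and free energies
# ---------------------------------------------------------------------------

@dataclass
class MinimumRecord:
    """One locally minimized structure in a basin-hopping run."""

    step: int
    coordinates: np.ndarray
    potential_energy: float
    free_energy: Optional[float] = None
    accepted: Optional[bool] = None
    converged: bool = True
    rms_gradient: float = 0.0
    minimizer_iterations: int = 0
    function_evaluations: int = 0
    move_type: str = "start"


def local_minimize(
    potential: Potential,
    start_coordinates: np.ndarray,
    rms_force_tol: float = 1e-6,
    max_iter: int = 5000,
) -> MinimumRecord:
    """L-BFGS local minimization to an RMS-force tolerance (kcal/mol/A).

    Non-convergence within ``max_iter`` iterations is flagged on the record
    (``converged = False``) rather than raised.
    """
    x0 = np.asarray(start_coordinates, dtype=float)
    shape = x0.shape
    if not np.all(np.isfinite(x0)):
        raise ValueError("non-finite starting coordinates")

    def fun(x):
        e, g = potential.energy_gradient(x.reshape(shape))
        return e, np.asarray(g, dtype=float).ravel()

    res = _scipy_minimize(
        fun,
        x0.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={
            # pgtol bounds the max |g_i|, which bounds the RMS gradient.
            "gtol": rms_force_tol,
            "ftol": 0.0,
            "maxiter": max_iter,
            "maxcor": 20,
        },
    )
    g = np.asarray(potential.gradient(res.x.reshape(shape))).ravel()
    rms = float(np.sqrt(np.mean(np.square(g))))
    return MinimumRecord(
        step=0,
        coordinates=res.x.reshape(shape),
        potential_energy=float(res.fun),
        converged=bool(rms <= rms_force_tol),
        rms_gradient=rms,
        minimizer_iterations=int(res.nit),
        function_evaluations=int(res.nfev),
    )


def harmonic_free_energy(
    potential: Potential,
    minimum: MinimumRecord | np.ndarray,
    temperature: float = 298.0,
    eigenvalue_floor: float = 1e-8,
    fd_step: float = 1e-4,
) -> float:
    """Local free energy of a minimum in the harmonic superposition
    approximation (classical, unit masses):

        F = V + k_B T * sum_j ln(omega_j),   omega_j = sqrt(lambda_j),

    over normal modes with Hessian eigenvalue lambda_j above
    ``eigenvalue_floor`` (zero modes from overall translation/rotation are
    skipped).  ``temperature`` in kelvin.  F is defined up to an additive
    constant shared by all minima of the same system; only differences enter
    acceptance.  An eigenvalue below ``-eigenvalue_floor`` means the input is
    not a minimum and raises ``ValueError``.
    """
    coords = (
        minimum.coordinates if isinstance(minimum, MinimumRecord) else np.asarray(minimum)
    )
    V = (
        minimum.potential_energy
        if isinstance(minimum, MinimumRecord)
        else potential.energy(coords)
    )
    H = potential.hessian(coords, step=fd_step) if _hessian_takes_step(potential) else potential.hessian(coords)
    evals = np.linalg.eigvalsh(H)
    if np.any(evals < -eigenvalue_floor):
        raise ValueError(
            f"negative Hessian eigenvalue {evals.min():.3e}: not a minimum"
        )
    pos = evals[evals > eigenvalue_floor]
    kT = KB_KCAL_MOL_K * temperature
    return float(V + kT * 0.5 * np.sum(np.log(pos)))


def _hessian_takes_step(potential: Potential) -> bool:
    import inspect

    try:
        sig = inspect.signature(potential.hessian)
    except (TypeError, ValueError):  # pragma: no cover
        return False
    return "step" in sig.parameters


def metropolis_accept(delta: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion on an energy difference (kcal/mol).

    ``temperature`` is the sampling temperature in energy units (kcal/mol).
    delta <= 0 always accepts; otherwise accept with probability
    exp(-delta/temperature).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta <= 0:
        return True
    return bool(rng.random() < math.exp(-delta / temperature))


# ---------------------------------------------------------------------------
# Moves
# ---------------------------------------------------------------------------

def cartesian_displacement_move(
    coords: np.ndarray, rng: np.random.Generator, max_displacement: float = 1.0
) -> np.ndarray:
    """Displace every atom by an independent uniform vector with per-coordinate
    magnitude <= ``max_displacement`` (angstrom)."""
    if max_displacement < 0:
        raise ValueError("max_displacement must be >= 0")
    c = np.asarray(coords, dtype=float)
    return c + rng.uniform(-max_displacement, max_displacement, size=c.shape)


def group_rotation_move(
    coords: np.ndarray,
    topology: Topology,
    rng: np.random.Generator,
    dihedral_selection_prob: float = 0.025,
    max_amplitude: float = 180.0,
    dihedrals: Optional[Sequence[AtomQuadruple]] = None,
    n_select: Optional[int] = None,
) -> np.ndarray:
    """Group rotation: rotate randomly chosen dihedrals by random amounts.

    By default every eligible dihedral (backbone plus side chain) is selected
    independently with ``dihedral_selection_prob``; if ``n_select`` is given,
    exactly that many distinct dihedrals are drawn uniformly instead.  Each
    selected dihedral is rotated by a uniform draw in [-max_amplitude,
    +max_amplitude] degrees; only atoms downstream of the rotated bond move.
    """
    pool = list(dihedrals) if dihedrals is not None else (
        list(topology.backbone_quads) + topology.sidechain_quads()
    )
    if not pool:
        raise ValueError("no rotatable dihedrals")
    if n_select is not None:
        n_select = min(n_select, len(pool))
        chosen = rng.choice(len(pool), size=n_select, replace=False)
        selected = [pool[int(i)] for i in chosen]
    else:
        mask = rng.random(len(pool)) < dihedral_selection_prob
        selected = [q for q, m in zip(pool, mask) if m]
    out = np.asarray(coords, dtype=float)
    for quad in selected:
        delta = rng.uniform(-max_amplitude, max_amplitude)
        out = rotate_dihedral(out, topology, quad, delta)
    return out


def rotamer_move(
    coords: np.ndarray,
    topology: Topology,
    library: RotamerLibrary,
    n_SC: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Impose library rotamers on ``n_SC`` uniformly chosen residues.

    Residues are chosen uniformly without replacement among chi-bearing
    residues; for each, a rotamer is drawn with probability proportional to
    its library probability (renormalized over the context's entries) and
    every chi dihedral is set to the rotamer mean by rotating downstream
    atoms.  The backbone is untouched.
    """
    residues = topology.residues
    if not residues:
        raise ValueError("no chi-bearing residues")
    n_SC = min(n_SC, len(residues))
    chosen = rng.choice(len(residues), size=n_SC, replace=False)
    out = np.asarray(coords, dtype=float)
    for ri in sorted(int(i) for i in chosen):
        res = residues[ri]
        context = topology.context(res)
        try:
            rots = library.get(context)
        except KeyError:
            raise KeyError(f"context {context} absent from rotamer library")
        if not rots:
            raise KeyError(f"context {context} has no rotamers in library")
        probs = np.array([r.probability for r in rots], dtype=float)
        probs /= probs.sum()
        rot = rots[int(rng.choice(len(rots), p=probs))]
        if len(rot.chi_mean) != len(res.chi_quads):
            raise ValueError(
                f"context {context}: rotamer has {len(rot.chi_mean)} chi, "
                f"topology has {len(res.chi_quads)}"
            )
        for quad, target in zip(res.chi_quads, rot.chi_mean):
            out = set_dihedral(out, topology, quad, target)
    return out


# ---------------------------------------------------------------------------
# Schemes and the BH driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BHScheme:
    """Move cadence for a basin-hopping run.

    ``n_SC`` side-chain moves (residues for rotamer moves, chi dihedrals for
    group rotation) are applied every ``f_SC`` steps; ``n_BB`` backbone
    dihedrals are rotated every ``f_BB`` steps.  ``temperature`` is the
    Metropolis sampling temperature in kcal/mol.
    """

    name: str
    side_move: str  # "rotamer" | "group_rotation"
    n_SC: int
    f_SC: int
    n_BB: int
    f_BB: int
    temperature: float = 1.3
    displacement_amplitude: float = 0.0
    use_free_energy: bool = False
    backbone_amplitude: float = 180.0
    sidechain_amplitude: float = 180.0

    def __post_init__(self):
        if self.side_move not in ("rotamer", "group_rotation"):
            raise ValueError(f"unknown side move {self.side_move!r}")
        if self.n_SC < 0 or self.n_BB < 0:
            raise ValueError("move counts must be >= 0")
        if self.f_SC < 1 or self.f_BB < 1:
            raise ValueError("move frequencies must be >= 1")
        if self.temperature <= 0:
            raise ValueError("sampling temperature must be positive")


@dataclass
class BHTrajectory:
    """The record of one basin-hopping run."""

    records: List[MinimumRecord] = field(default_factory=list)
    best_energy: float = math.inf
    best_coordinates: Optional[np.ndarray] = None
    success_step: Optional[int] = None
    scheme_name: str = ""
    seed: Optional[int] = None

    @property
    def accepted(self) -> List[MinimumRecord]:
        return [r for r in self.records if r.accepted]


def run_basin_hopping(
    potential: Potential,
    start: np.ndarray,
    scheme: BHScheme,
    n_steps: int,
    rng_seed: int | np.random.Generator,
    library: Optional[RotamerLibrary] = None,
    reference_energy: Optional[float] = None,
    success_window: float = 1.0,
    rms_force_tol: float = 1e-6,
    free_energy_temperature: float = 298.0,
    stop_at_success: bool = False,
) -> BHTrajectory:
    """Run basin-hopping (or FEBH) under a move scheme.

    At step s (1-based) a backbone group rotation of ``n_BB`` distinct
    phi/psi dihedrals is applied iff s % f_BB == 0, then a side-chain move
    (rotamer or group rotation) iff s % f_SC == 0; both may fire in one
    step.  The candidate is locally minimized and accepted against the
    current Markov-chain minimum on the potential-energy (or, for FEBH,
    harmonic free-energy) difference.  Every proposal is recorded.
    ``success_step`` is set when a minimized structure within
    ``success_window`` kcal/mol of ``reference_energy`` is first
    encountered.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if scheme.side_move == "rotamer" and scheme.n_SC > 0 and library is None:
        raise ValueError("rotamer scheme requires a rotamer library")
    topo = potential.topology

    def finalize(rec: MinimumRecord) -> MinimumRecord:
        if scheme.use_free_energy:
            rec.free_energy = harmonic_free_energy(
                potential, rec, temperature=free_energy_temperature
            )
        return rec

    traj = BHTrajectory(scheme_name=scheme.name,
                        seed=rng_seed if isinstance(rng_seed, int) else None)
    current = finalize(local_minimize(potential, start, rms_force_tol))
    current.accepted = True
    current.move_type = "start"
    traj.records.append(current)
    traj.best_energy = current.potential_energy
    traj.best_coordinates = current.coordinates.copy()

    def check_success(rec: MinimumRecord, step: int):
        if (
            traj.success_step is None
            and reference_energy is not None
            and rec.potential_energy <= reference_energy + success_window
        ):
            traj.success_step = step

    check_success(current, 0)
    acceptance_key = "free_energy" if scheme.use_free_energy else "potential_energy"

    for s in range(1, n_steps + 1):
        if stop_at_success and traj.success_step is not None:
            break
        x = current.coordinates.copy()
        moves = []
        if scheme.n_BB > 0 and s % scheme.f_BB == 0:
            x = group_rotation_move(
                x, topo, rng,
                max_amplitude=scheme.backbone_amplitude,
                dihedrals=topo.backbone_quads,
                n_select=scheme.n_BB,
            )
            moves.append("BB")
        if scheme.n_SC > 0 and s % scheme.f_SC == 0:
            if scheme.side_move == "rotamer":
                x = rotamer_move(x, topo, library, scheme.n_SC, rng)
            else:
                x = group_rotation_move(
                    x, topo, rng,
                    max_amplitude=scheme.sidechain_amplitude,
                    dihedrals=topo.sidechain_quads(),
                    n_select=scheme.n_SC,
                )
            moves.append("SC")
        if scheme.displacement_amplitude > 0:
            x = cartesian_displacement_move(x, rng, scheme.displacement_amplitude)
            moves.append("CART")
        candidate = finalize(local_minimize(potential, x, rms_force_tol))
        candidate.step = s
        candidate.move_type = "+".join(moves) if moves else "none"
        delta = getattr(candidate, acceptance_key) - getattr(current, acceptance_key)
        candidate.accepted = metropolis_accept(delta, scheme.temperature, rng)
        traj.records.append(candidate)
        if candidate.potential_energy < traj.best_energy:
            traj.best_energy = candidate.potential_energy
            traj.best_coordinates = candidate.coordinates.copy()
        check_success(candidate, s)
        if candidate.accepted:
            current = candidate
    return traj


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def superposition_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Least RMSD (angstrom) between two structures after optimal rigid
    superposition (translation + proper rotation)."""
    A = np.asarray(a, dtype=float).reshape(-1, 3)
    B = np.asarray(b, dtype=float).reshape(-1, 3)
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    _, rssd = _Rotation.align_vectors(A, B)
    return float(rssd / math.sqrt(A.shape[0]))


def markov_diagnostics(trajectory: BHTrajectory) -> Dict[str, object]:
    """Per-step energy differences and accepted-chain displacement series.

    Returns ``delta_e`` — for every proposal, the energy relative to the
    Markov-chain minimum current at proposal time — and ``delta_d`` — the
    least-RMSD between adjacent accepted minima — with their medians.
    """
    if not trajectory.records:
        raise ValueError("empty trajectory")
    delta_e: List[float] = []
    current = trajectory.records[0]
    for rec in trajectory.records[1:]:
        delta_e.append(rec.potential_energy - current.potential_energy)
        if rec.accepted:
            current = rec
    accepted = trajectory.accepted
    delta_d = [
        superposition_rmsd(a.coordinates, b.coordinates)
        for a, b in zip(accepted, accepted[1:])
    ]
    return {
        "delta_e": np.asarray(delta_e),
        "delta_d": np.asarray(delta_d),
        "median_delta_e": float(np.median(delta_e)) if delta_e else 0.0,
        "median_delta_d": float(np.median(delta_d)) if delta_d else 0.0,
    }


# ---------------------------------------------------------------------------
# Scheme presets
# ---------------------------------------------------------------------------

_PRESET_ROWS = [
    # name, side_move, n_SC, f_SC, n_BB, f_BB
    ("rotamer 1", "rotamer", 2, 1, 1, 1),
    ("rotamer 2", "rotamer", 2, 1, 2, 2),
    ("rotamer 3", "rotamer", 3, 1, 1, 1),
    ("rotamer 4", "rotamer", 2, 1, 3, 3),
    ("rotamer 5", "rotamer", 2, 2, 2, 2),
    ("rotamer 6", "rotamer", 2, 1, 3, 4),
    ("rotamer 7", "rotamer", 3, 1, 3, 3),
    ("rotamer 8", "rotamer", 3, 2, 2, 2),
    ("group rotation 1", "group_rotation", 4, 1, 1, 1),
    ("group rotation 2", "group_rotation", 4, 1, 2, 2),
    ("group rotation 3", "group_rotation", 6, 1, 1, 1),
    ("group rotation 4", "group_rotation", 6, 1, 2, 1),
]


def scheme_presets() -> Dict[str, BHScheme]:
    """The benchmark move schemes: rotamer 1-8 and group rotation 1-4.

    All presets sample at 1.3 kcal/mol with no Cartesian displacements.
    """
    return {
        name: BHScheme(
            name=name, side_move=side, n_SC=n_sc, f_SC=f_sc, n_BB=n_bb, f_BB=f_bb,
            temperature=1.3, displacement_amplitude=0.0,
        )
        for name, side, n_sc, f_sc, n_bb, f_bb in _PRESET_ROWS
    }
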