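"""Synthetic data and desk-scale benchmark systems.

Two generators live here:

* :func:`sample_planted_ensemble` draws side-chain conformational ensembles
  around planted rotamer centers with wrapped Gaussian angular noise and
  prescribed free energies, emulating the basin-hopping tripeptide ensembles
  the library pipeline consumes.  Recovery of the planted centers and
  Boltzmann populations by the real pipeline is the core end-to-end check.

* :func:`make_rotamer_chain` builds a bead-chain potential whose "residues"
  carry multi-well torsional side-chain terms, double-well backbone
  dihedrals, and soft inter-bead repulsion.  The full set of well
  combinations is enumerable, so the global minimum is known exactly and
  basin-hopping benchmarks on it are self-validating.

All energies in kcal/mol, lengths in angstrom, angles in degrees.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .torsion import (
    KB_KCAL_MOL_K,
    AtomQuadruple,
    TorsionVector,
    normalize_angle,
    place_atom,
    torsion_distance,
)
from .library import (
    ConformationRecord,
    Context,
    RotamerLibrary,
    build_library,
    equilibrium_populations,
)
from .bh import (
    MinimumRecord,
    Potential,
    ResidueTopology,
    Topology,
    local_minimize,
)

__all__ = [
    "PlantedRotamerSpec",
    "sample_planted_ensemble",
    "RotamerChainPotential",
    "make_rotamer_chain",
    "toy_library",
]


# ---------------------------------------------------------------------------
# Planted rotamer ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedRotamerSpec:
    """Specification of a synthetic ensemble around planted rotamer centers.

    ``centers`` must be pairwise separated by more than twice the clustering
    cutoff (else recovery is not identifiable) and ``noise_sd`` must stay
    below a quarter of the cutoff.
    """

    context: Context
    centers: Tuple[TorsionVector, ...]
    free_energies: Tuple[float, ...]
    noise_sd: float = 5.0
    n_draws: int = 200
    seed: int = 0
    cutoff: float = 40.0

    def __post_init__(self):
        if len(self.centers) != len(self.free_energies):
            raise ValueError("need one free energy per center")
        if len(self.centers) == 0:
            raise ValueError("need at least one center")
        for a, b in itertools.combinations(self.centers, 2):
            if torsion_distance(a, b) <= 2 * self.cutoff:
                raise ValueError(
                    "planted centers must be pairwise farther than "
                    f"{2 * self.cutoff} deg apart"
                )
        if not self.noise_sd < self.cutoff / 4:
            raise ValueError("noise_sd must be below cutoff/4")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


def _wrapped_truncated_normal(
    rng: np.random.Generator, sd: float, size
) -> np.ndarray:
    """Gaussian angular noise truncated at +-4 sd, applied on the circle."""
    if sd == 0:
        return np.zeros(size)
    out = rng.normal(0.0, sd, size=size)
    bad = np.abs(out) > 4 * sd
    while np.any(bad):
        out[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(out) > 4 * sd
    return out


def sample_planted_ensemble(spec: PlantedRotamerSpec) -> List[ConformationRecord]:
    """Draw a conformational ensemble from a planted-rotamer specification.

    Draw counts per center follow a seeded multinomial over the Boltzmann
    weights of the planted free energies at 298 K.  Each draw perturbs its
    center by wrapped truncated-Gaussian noise.  Free energies are assigned
    so that the summed equilibrium population of a center's draws equals the
    center's planted Boltzmann population: every draw in a center with
    ``n_c`` draws carries F_c + k_B T ln(n_c) plus a +-0.05 kcal/mol jitter
    (distinct minima within one basin are never exactly degenerate).
    """
    rng = np.random.default_rng(spec.seed)
    kT = KB_KCAL_MOL_K * 298.0
    weights = equilibrium_populations(spec.free_energies, 298.0)
    counts = rng.multinomial(spec.n_draws, weights)
    # Guarantee every center is represented so recovery is well-posed.
    for c in range(len(counts)):
        if counts[c] == 0:
            counts[np.argmax(counts)] -= 1
            counts[c] += 1
    records = []
    for c, (center, F_c) in enumerate(zip(spec.centers, spec.free_energies)):
        n_c = int(counts[c])
        base = center.as_array()
        noise = _wrapped_truncated_normal(rng, spec.noise_sd, (n_c, center.n))
        jitter = rng.uniform(-0.05, 0.05, size=n_c)
        for d in range(n_c):
            torsions = TorsionVector(normalize_angle(base + noise[d]))
            F = F_c + kT * math.log(n_c) + float(jitter[d])
            records.append(
                ConformationRecord(
                    id=f"{'-'.join(spec.context)}:c{c}:d{d}",
                    torsions=torsions,
                    potential_energy=F,
                    free_energy=F,
                )
            )
    return records


# ---------------------------------------------------------------------------
# The rotamer-chain toy potential
# ---------------------------------------------------------------------------

THETA0 = 109.47  # tetrahedral reference angle, degrees
BOND_R0 = 1.5
K_BOND = 30.0    # kcal/mol/A^2
K_ANGLE = 15.0   # kcal/mol/rad^2
BB_H2 = 2.0      # two-fold backbone barrier height
BB_H1 = 1.5      # tilt making the second backbone well shallower
BB_REF = 180.0   # favored (trans) backbone dihedral
CHI_KAPPA = 8.0  # side-chain well concentration (~20 deg width)
NB_EPS = 1.0     # soft repulsion strength
NB_SIGMA = 2.2   # soft repulsion range
NB_DELTA = 0.5   # softening of the repulsion core, A^2


try:  # compiled kernel for the hot path; the numpy path remains as fallback
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco


@_njit(cache=False)
def _chain_energy_grad(
    x,
    bond_idx,
    angle_idx,
    bb_quads,
    chi_quads,
    chi_centers,
    chi_depths,
    nb_idx,
    k_bond,
    r0,
    k_angle,
    theta0,
    bb_h2,
    bb_h1,
    bb_ref,
    kappa,
    nb_eps,
    nb_sig2,
    nb_delta,
):
    n = x.shape[0]
    g = np.zeros((n, 3))
    e = 0.0
    for t in range(bond_idx.shape[0]):
        i = bond_idx[t, 0]
        j = bond_idx[t, 1]
        dx = x[j] - x[i]
        r = math.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        dr = r - r0
        e += k_bond * dr * dr
        pre = 2.0 * k_bond * dr / r
        for c in range(3):
            g[j, c] += pre * dx[c]
            g[i, c] -= pre * dx[c]
    for t in range(angle_idx.shape[0]):
        a = angle_idx[t, 0]
        b = angle_idx[t, 1]
        cc = angle_idx[t, 2]
        u = x[a] - x[b]
        v = x[cc] - x[b]
        nu = math.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
        nv = math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
        cth = (u[0] * v[0] + u[1] * v[1] + u[2] * v[2]) / (nu * nv)
        if cth > 1.0:
            cth = 1.0
        elif cth < -1.0:
            cth = -1.0
        th = math.acos(cth)
        dth = th - theta0
        e += k_angle * dth * dth
        sth = math.sqrt(max(1.0 - cth * cth, 1e-12))
        pref = 2.0 * k_angle * dth * (-1.0 / sth)
        for c in range(3):
            du = v[c] / (nu * nv) - cth * u[c] / (nu * nu)
            dv = u[c] / (nu * nv) - cth * v[c] / (nv * nv)
            g[a, c] += pref * du
            g[cc, c] += pref * dv
            g[b, c] -= pref * (du + dv)
    n_bb = bb_quads.shape[0]
    n_chi = chi_quads.shape[0]
    for t in range(n_bb + n_chi):
        if t < n_bb:
            q = bb_quads[t]
        else:
            q = chi_quads[t - n_bb]
        b1 = x[q[1]] - x[q[0]]
        b2 = x[q[2]] - x[q[1]]
        b3 = x[q[3]] - x[q[2]]
        n1 = np.empty(3)
        n2 = np.empty(3)
        n1[0] = b1[1] * b2[2] - b1[2] * b2[1]
        n1[1] = b1[2] * b2[0] - b1[0] * b2[2]
        n1[2] = b1[0] * b2[1] - b1[1] * b2[0]
        n2[0] = b2[1] * b3[2] - b2[2] * b3[1]
        n2[1] = b2[2] * b3[0] - b2[0] * b3[2]
        n2[2] = b2[0] * b3[1] - b2[1] * b3[0]
        nb2 = math.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
        m1x = n1[1] * b2[2] - n1[2] * b2[1]
        m1y = n1[2] * b2[0] - n1[0] * b2[2]
        m1z = n1[0] * b2[1] - n1[1] * b2[0]
        xx = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
        yy = (m1x * n2[0] + m1y * n2[1] + m1z * n2[2]) / nb2
        phi = math.atan2(yy, xx)
        if t < n_bb:
            dphi = phi - bb_ref
            e += 0.5 * bb_h2 * (1.0 - math.cos(2.0 * dphi)) + 0.5 * bb_h1 * (
                1.0 - math.cos(dphi)
            )
            dV = bb_h2 * math.sin(2.0 * dphi) + 0.5 * bb_h1 * math.sin(dphi)
        else:
            ri = t - n_bb
            dV = 0.0
            for w in range(chi_centers.shape[1]):
                d = phi - chi_centers[ri, w]
                wexp = math.exp(kappa * (math.cos(d) - 1.0))
                e += -chi_depths[ri, w] * wexp
                dV += chi_depths[ri, w] * wexp * kappa * math.sin(d)
        sq1 = n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2
        sq2 = n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2
        c12 = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / (nb2 * nb2)
        c32 = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / (nb2 * nb2)
        for c in range(3):
            d1 = (nb2 / sq1) * n1[c]
            d4 = -(nb2 / sq2) * n2[c]
            d2 = -(1.0 + c12) * d1 + c32 * d4
            d3 = -(d1 + d2 + d4)
            g[q[0], c] += dV * d1
            g[q[1], c] += dV * d2
            g[q[2], c] += dV * d3
            g[q[3], c] += dV * d4
    for t in range(nb_idx.shape[0]):
        i = nb_idx[t, 0]
        j = nb_idx[t, 1]
        dx = x[j] - x[i]
        r2 = dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2 + nb_delta
        s = nb_sig2 / r2
        s6 = s ** 6
        e += nb_eps * s6
        pre = -12.0 * nb_eps * s6 / r2
        for c in range(3):
            g[j, c] += pre * dx[c]
            g[i, c] -= pre * dx[c]
    return e, g


class RotamerChainPotential(Potential):
    """Bead-chain potential with multi-well side-chain torsions.

    Each of ``n_residues`` residues is a backbone bead carrying a two-bead
    side chain whose single chi dihedral feels a seeded multi-well torsional
    term.  Backbone dihedrals are double wells (trans favored); beads
    separated by four or more bonds repel softly, which frustrates some
    side-chain well combinations.  The catalogued global minimum is found by
    enumerating every well combination and minimizing each.
    """

    def __init__(
        self,
        n_residues: int,
        chi_centers: np.ndarray,   # (n_residues, wells)
        chi_depths: np.ndarray,    # (n_residues, wells)
        seed: int,
    ):
        self.n_residues = int(n_residues)
        self.chi_centers = np.asarray(chi_centers, dtype=float)
        self.chi_depths = np.asarray(chi_depths, dtype=float)
        self.seed = int(seed)
        self.wells_per_residue = self.chi_centers.shape[1]
        self.topology = self._build_topology()
        self._setup_terms()
        # Filled in by make_rotamer_chain after enumeration:
        self.minima: List[MinimumRecord] = []
        self.global_minimum_energy: Optional[float] = None
        self.global_minimum_coords: Optional[np.ndarray] = None
        self.global_minimum_torsions: Optional[Tuple[float, ...]] = None

    # -- topology ----------------------------------------------------------

    def _build_topology(self) -> Topology:
        n = self.n_residues
        n_bb = n + 2                       # cap, residues, cap
        self.bb_index = list(range(n_bb))
        self.s1_index = [n_bb + 2 * i for i in range(n)]
        self.s2_index = [n_bb + 2 * i + 1 for i in range(n)]
        n_atoms = n_bb + 2 * n
        bonds = [(i, i + 1) for i in range(n_bb - 1)]
        for i in range(n):
            b = self.bb_index[i + 1]
            bonds += [(b, self.s1_index[i]), (self.s1_index[i], self.s2_index[i])]
        chain_names = ["CAP"] + [f"RS{i + 1}" for i in range(n)] + ["CAP"]
        residues = []
        for i in range(n):
            b_prev, b = self.bb_index[i], self.bb_index[i + 1]
            quad = AtomQuadruple(b_prev, b, self.s1_index[i], self.s2_index[i])
            residues.append(
                ResidueTopology(
                    name=f"RS{i + 1}",
                    chain_pos=i + 1,
                    atoms={"B": b, "S1": self.s1_index[i], "S2": self.s2_index[i]},
                    chi_quads=[quad],
                )
            )
        backbone_quads = [
            AtomQuadruple(i, i + 1, i + 2, i + 3) for i in range(n_bb - 3)
        ]
        return Topology(
            n_atoms=n_atoms,
            bonds=bonds,
            chain_names=chain_names,
            residues=residues,
            backbone_quads=backbone_quads,
        )

    def _setup_terms(self):
        topo = self.topology
        adj = [[] for _ in range(topo.n_atoms)]
        for i, j in topo.bonds:
            adj[i].append(j)
            adj[j].append(i)
        self._bond_idx = np.asarray(topo.bonds, dtype=int)
        angles = []
        for b in range(topo.n_atoms):
            nb = sorted(adj[b])
            for x in range(len(nb)):
                for y in range(x + 1, len(nb)):
                    angles.append((nb[x], b, nb[y]))
        self._angle_idx = np.asarray(angles, dtype=int)
        self._bb_quads = np.asarray(
            [q.as_tuple() for q in topo.backbone_quads], dtype=int
        ).reshape(-1, 4)
        self._chi_quads = np.asarray(
            [r.chi_quads[0].as_tuple() for r in topo.residues], dtype=int
        )
        # Bond-graph distances for the non-bonded pair list (>= 4 bonds apart).
        n = topo.n_atoms
        dist = np.full((n, n), 99, dtype=int)
        for i in range(n):
            dist[i, i] = 0
            frontier = [i]
            d = 0
            while frontier:
                d += 1
                nxt = []
                for a in frontier:
                    for b in adj[a]:
                        if dist[i, b] > d:
                            dist[i, b] = d
                            nxt.append(b)
                frontier = nxt
        iu, ju = np.triu_indices(n, k=1)
        mask = dist[iu, ju] >= 4
        self._nb_idx = np.ascontiguousarray(
            np.stack([iu[mask], ju[mask]], axis=1).astype(np.int64)
        )
        self._bond_idx = np.ascontiguousarray(self._bond_idx.astype(np.int64))
        self._angle_idx = np.ascontiguousarray(self._angle_idx.astype(np.int64))
        self._bb_quads = np.ascontiguousarray(self._bb_quads.astype(np.int64))
        self._chi_quads = np.ascontiguousarray(self._chi_quads.astype(np.int64))
        self._chi_centers_rad = np.ascontiguousarray(np.radians(self.chi_centers))

    # -- geometry ----------------------------------------------------------

    def build_coordinates(
        self,
        backbone_dihedrals: Sequence[float],
        chi: Sequence[float],
    ) -> np.ndarray:
        """Idealized coordinates with the requested dihedrals (degrees)."""
        n = self.n_residues
        bb = list(backbone_dihedrals)
        if len(bb) != len(self.topology.backbone_quads):
            raise ValueError("wrong number of backbone dihedrals")
        if len(chi) != n:
            raise ValueError("wrong number of chi angles")
        coords = np.zeros((self.topology.n_atoms, 3))
        coords[0] = (0.0, 0.0, 0.0)
        coords[1] = (BOND_R0, 0.0, 0.0)
        th = math.radians(THETA0)
        coords[2] = coords[1] + BOND_R0 * np.array(
            (-math.cos(th), math.sin(th), 0.0)
        )
        for m in range(3, len(self.bb_index)):
            coords[m] = place_atom(
                coords[m - 3], coords[m - 2], coords[m - 1],
                BOND_R0, THETA0, bb[m - 3],
            )
        for i in range(n):
            b_prev, b, b_next = (
                self.bb_index[i], self.bb_index[i + 1], self.bb_index[i + 2]
            )
            coords[self.s1_index[i]] = place_atom(
                coords[b_next], coords[b_prev], coords[b], BOND_R0, THETA0, 120.0
            )
            coords[self.s2_index[i]] = place_atom(
                coords[b_prev], coords[b], coords[self.s1_index[i]],
                BOND_R0, THETA0, chi[i],
            )
        return coords

    def measure_chi(self, coords: np.ndarray) -> np.ndarray:
        from .torsion import dihedral_angle

        c = np.asarray(coords, dtype=float).reshape(-1, 3)
        return np.array(
            [dihedral_angle(*(c[k] for k in q)) for q in self._chi_quads]
        )

    def measure_backbone(self, coords: np.ndarray) -> np.ndarray:
        from .torsion import dihedral_angle

        c = np.asarray(coords, dtype=float).reshape(-1, 3)
        return np.array(
            [dihedral_angle(*(c[k] for k in q)) for q in self._bb_quads]
        )

    def start_coordinates(self) -> np.ndarray:
        """A deliberately unfavorable start: extended backbone, every chi on
        the plateau opposite its first well."""
        bb = [BB_REF] * len(self.topology.backbone_quads)
        chi = [normalize_angle(c + 180.0) for c in self.chi_centers[:, 0]]
        return self.build_coordinates(bb, chi)

    # -- energy / gradient -------------------------------------------------

    def energy(self, coords: np.ndarray) -> float:
        return self.energy_gradient(coords)[0]

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        return self.energy_gradient(coords)[1]

    def energy_gradient(self, coords: np.ndarray) -> Tuple[float, np.ndarray]:
        if _HAVE_NUMBA:
            x = np.ascontiguousarray(
                np.asarray(coords, dtype=float).reshape(-1, 3)
            )
            e, g = _chain_energy_grad(
                x,
                self._bond_idx,
                self._angle_idx,
                self._bb_quads,
                self._chi_quads,
                self._chi_centers_rad,
                self.chi_depths,
                self._nb_idx,
                K_BOND,
                BOND_R0,
                K_ANGLE,
                math.radians(THETA0),
                BB_H2,
                BB_H1,
                math.radians(BB_REF),
                CHI_KAPPA,
                NB_EPS,
                NB_SIGMA * NB_SIGMA,
                NB_DELTA,
            )
            return e, g.reshape(np.asarray(coords).shape)
        return self._energy_gradient_numpy(coords)

    def _energy_gradient_numpy(self, coords: np.ndarray) -> Tuple[float, np.ndarray]:
        x = np.asarray(coords, dtype=float).reshape(-1, 3)
        g = np.zeros_like(x)
        e = 0.0

        # bonds
        bi, bj = self._bond_idx[:, 0], self._bond_idx[:, 1]
        dv = x[bj] - x[bi]
        r = np.linalg.norm(dv, axis=1)
        dr = r - BOND_R0
        e += K_BOND * float(np.sum(dr * dr))
        f = (2.0 * K_BOND * dr / r)[:, None] * dv
        np.add.at(g, bj, f)
        np.add.at(g, bi, -f)

        # angles
        ai, aj, ak = (self._angle_idx[:, c] for c in range(3))
        u = x[ai] - x[aj]
        v = x[ak] - x[aj]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cos = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
        theta = np.arccos(cos)
        dtheta = theta - math.radians(THETA0)
        e += K_ANGLE * float(np.sum(dtheta * dtheta))
        sin = np.sqrt(np.clip(1.0 - cos * cos, 1e-12, None))
        pref = 2.0 * K_ANGLE * dtheta * (-1.0 / sin)
        du = (v / (nu * nv)[:, None]) - (cos / (nu * nu))[:, None] * u
        dv_ = (u / (nu * nv)[:, None]) - (cos / (nv * nv))[:, None] * v
        np.add.at(g, ai, pref[:, None] * du)
        np.add.at(g, ak, pref[:, None] * dv_)
        np.add.at(g, aj, -pref[:, None] * (du + dv_))

        # dihedrals: backbone double wells + side-chain multi-well terms
        for quads, kind in ((self._bb_quads, "bb"), (self._chi_quads, "chi")):
            if quads.size == 0:
                continue
            p1, p2, p3, p4 = (x[quads[:, c]] for c in range(4))
            b1 = p2 - p1
            b2 = p3 - p2
            b3 = p4 - p3
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=1)
            m1 = np.cross(n1, b2 / nb2[:, None])
            xx = np.sum(n1 * n2, axis=1)
            yy = np.sum(m1 * n2, axis=1)
            phi = np.arctan2(yy, xx)  # radians, IUPAC sign
            if kind == "bb":
                dphi = phi - math.radians(BB_REF)
                e += float(
                    np.sum(
                        0.5 * BB_H2 * (1.0 - np.cos(2.0 * dphi))
                        + 0.5 * BB_H1 * (1.0 - np.cos(dphi))
                    )
                )
                dV = BB_H2 * np.sin(2.0 * dphi) + 0.5 * BB_H1 * np.sin(dphi)
            else:
                dphi = phi[:, None] - np.radians(self.chi_centers)
                wexp = np.exp(CHI_KAPPA * (np.cos(dphi) - 1.0))
                e += float(np.sum(-self.chi_depths * wexp))
                dV = np.sum(
                    self.chi_depths * wexp * CHI_KAPPA * np.sin(dphi), axis=1
                )
            # Cartesian derivatives of the dihedral angle.
            sq1 = np.sum(n1 * n1, axis=1)
            sq2 = np.sum(n2 * n2, axis=1)
            dphi_d1 = (nb2 / sq1)[:, None] * n1
            dphi_d4 = -(nb2 / sq2)[:, None] * n2
            c12 = np.sum(b1 * b2, axis=1) / (nb2 * nb2)
            c32 = np.sum(b3 * b2, axis=1) / (nb2 * nb2)
            dphi_d2 = -(1.0 + c12)[:, None] * dphi_d1 + c32[:, None] * dphi_d4
            dphi_d3 = -(dphi_d1 + dphi_d2 + dphi_d4)
            for col, dd in zip(range(4), (dphi_d1, dphi_d2, dphi_d3, dphi_d4)):
                np.add.at(g, quads[:, col], dV[:, None] * dd)

        # soft repulsion
        if self._nb_idx.size:
            pi, pj = self._nb_idx[:, 0], self._nb_idx[:, 1]
            dvn = x[pj] - x[pi]
            r2 = np.sum(dvn * dvn, axis=1) + NB_DELTA
            s = (NB_SIGMA * NB_SIGMA) / r2
            s6 = s ** 6
            e += NB_EPS * float(np.sum(s6))
            fpre = (-12.0 * NB_EPS * s6 / r2)[:, None] * dvn
            np.add.at(g, pj, fpre)
            np.add.at(g, pi, -fpre)

        return e, g.reshape(np.asarray(coords).shape)


def make_rotamer_chain(
    n_residues: int, wells_per_residue: int, seed: int
) -> RotamerChainPotential:
    """Build a rotamer-chain potential and catalogue its minima.

    Well centers are evenly spaced around the circle with a seeded +-10 deg
    per-residue jitter; depths are seeded uniform in [1, 3] kcal/mol.  All
    side-chain well combinations, crossed with both backbone wells of every
    backbone dihedral, are built and locally minimized; the catalogued global
    minimum is the deepest minimum found.  Raises if the number of
    combinations exceeds 1e5.
    """
    if wells_per_residue < 2:
        raise ValueError("need at least two wells per residue")
    rng = np.random.default_rng(seed)
    base = np.linspace(-180.0, 180.0, wells_per_residue, endpoint=False) + 180.0 / wells_per_residue
    centers = normalize_angle(
        base[None, :] + rng.uniform(-10.0, 10.0, size=(n_residues, wells_per_residue))
    )
    depths = rng.uniform(1.0, 3.0, size=(n_residues, wells_per_residue))
    pot = RotamerChainPotential(n_residues, centers, depths, seed)

    n_bb = len(pot.topology.backbone_quads)
    n_combos = (wells_per_residue ** n_residues) * (2 ** n_bb)
    if n_combos > 1e5:
        raise ValueError(
            f"{n_combos} well combinations exceed the enumerability bound"
        )
    seen: Dict[Tuple, MinimumRecord] = {}
    bb_wells = (BB_REF, normalize_angle(BB_REF + 180.0))
    for bb_combo in itertools.product(range(2), repeat=n_bb):
        bb = [bb_wells[w] for w in bb_combo]
        for chi_combo in itertools.product(range(wells_per_residue), repeat=n_residues):
            chi = [centers[i, w] for i, w in enumerate(chi_combo)]
            start = pot.build_coordinates(bb, chi)
            rec = local_minimize(pot, start, rms_force_tol=1e-6)
            if not rec.converged:
                continue
            key = tuple(np.round(pot.measure_chi(rec.coordinates), 0)) + tuple(
                np.round(pot.measure_backbone(rec.coordinates), 0)
            )
            if key not in seen or rec.potential_energy < seen[key].potential_energy:
                seen[key] = rec
    minima = sorted(seen.values(), key=lambda r: r.potential_energy)
    pot.minima = minima
    best = minima[0]
    pot.global_minimum_energy = best.potential_energy
    pot.global_minimum_coords = best.coordinates
    pot.global_minimum_torsions = tuple(pot.measure_chi(best.coordinates))
    return pot


_CHAIN_CACHE: Dict[Tuple[int, int, int], RotamerChainPotential] = {}


def cached_rotamer_chain(
    n_residues: int, wells_per_residue: int, seed: int
) -> RotamerChainPotential:
    """Memoized :func:`make_rotamer_chain` (enumeration is the costly part)."""
    key = (n_residues, wells_per_residue, seed)
    if key not in _CHAIN_CACHE:
        _CHAIN_CACHE[key] = make_rotamer_chain(*key)
    return _CHAIN_CACHE[key]


def toy_library(
    potential: RotamerChainPotential, temperature: float = 298.0
) -> RotamerLibrary:
    """Rotamer library for a rotamer chain via the real clustering pipeline.

    The enumerated minima serve as the conformational ensemble: for each
    residue context the chi angle of every catalogued minimum, weighted by
    the minimum's Boltzmann population (the minimum's potential energy
    stands in for its free energy), is clustered exactly as in library
    construction.  This closes the loop: rotamer moves on the toy system use
    a library produced by the same code path as for peptides.
    """
    if not potential.minima:
        raise ValueError("potential has no catalogued minima; use make_rotamer_chain")
    ensembles: Dict[Context, List[ConformationRecord]] = {}
    chain = potential.topology.chain_names
    for i, res in enumerate(potential.topology.residues):
        context = potential.topology.context(res)
        records = []
        for m, rec in enumerate(potential.minima):
            chi = potential.measure_chi(rec.coordinates)[i]
            records.append(
                ConformationRecord(
                    id=f"{res.name}:m{m}",
                    torsions=TorsionVector([chi]),
                    potential_energy=rec.potential_energy,
                    free_energy=rec.potential_energy,
                )
            )
        ensembles[context] = records
    return build_library(ensembles, temperature=temperature)
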