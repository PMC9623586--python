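"""Sequence-dependent rotamer libraries.

A rotamer library is built per tripeptide *context* — the three-letter codes
(prev, central, next) of a residue and its neighbours — from an ensemble of
side-chain conformations with associated free energies:

1. each conformation gets its Boltzmann equilibrium population at the library
   temperature (298 K by default),
2. conformations are clustered in torsional space (average linkage, 40 deg
   cut),
3. each cluster becomes a rotamer: per-chi circular mean and circular
   (population) standard deviation, with a 1.0 deg standard deviation
   assigned to singleton clusters, and probability equal to the summed
   member populations,
4. rotamers with probability < 0.005 are pruned (probabilities are *not*
   renormalized afterwards; consumers renormalize at draw time).

Matching an observed side chain against a library uses the per-chi criterion:
a rotamer matches iff the observed conformation is within 40 deg of the
rotamer mean in every chi dihedral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .torsion import (
    KB_KCAL_MOL_K,
    TorsionVector,
    chi_count,
    normalize_angle,
    periodic_angle_distance,
    torsion_distance,
)
from .clustering import average_linkage_cluster, pairwise_torsion_distances

__all__ = [
    "Context",
    "ConformationRecord",
    "Rotamer",
    "RotamerLibrary",
    "equilibrium_populations",
    "circular_mean_sd",
    "cluster_to_rotamer",
    "build_library",
    "match_sidechain",
    "nearest_distance",
    "coverage_report",
    "reference_rotamer_tracking",
]

Context = Tuple[str, str, str]

#: Residue types excluded as central residues: too simple (ALA, GLY) or
#: conformationally restricted (PRO) to support rotameric states.
NON_ROTAMERIC = {"ALA", "GLY", "PRO"}

DEFAULT_CUTOFF = 40.0
DEFAULT_TEMPERATURE = 298.0
DEFAULT_PRUNE = 0.005
SINGLETON_SD = 1.0


@dataclass(frozen=True)
class ConformationRecord:
    """One ensemble member: torsions plus potential and free energy (kcal/mol)."""

    id: str
    torsions: TorsionVector
    potential_energy: float
    free_energy: float
    coordinates: Optional[np.ndarray] = None

    def __post_init__(self):
        if not (math.isfinite(self.potential_energy) and math.isfinite(self.free_energy)):
            raise ValueError(f"conformation {self.id}: non-finite energy")


@dataclass(frozen=True)
class Rotamer:
    """One rotamer: chi means/spreads (degrees) and occupation probability."""

    context: Context
    chi_mean: Tuple
    chi_sd: Tuple
    probability: float
    member_count: int

    def __post_init__(self):
        if len(self.chi_mean) != len(self.chi_sd):
            raise ValueError("chi_mean and chi_sd must have equal length")
        if not 0.0 <= self.probability <= 1.0 + 1e-9:
            raise ValueError(f"probability {self.probability} outside [0, 1]")
        if self.member_count < 1:
            raise ValueError("member_count must be >= 1")

    @property
    def n_chi(self) -> int:
        return len(self.chi_mean)


@dataclass
class RotamerLibrary:
    """Rotamers keyed by tripeptide context, plus build metadata."""

    entries: Dict[Context, List[Rotamer]] = field(default_factory=dict)
    temperature: float = DEFAULT_TEMPERATURE
    cutoff: float = DEFAULT_CUTOFF
    prune: float = DEFAULT_PRUNE
    provenance: str = "rotamerbh"

    def contexts(self) -> List[Context]:
        return sorted(self.entries)

    def get(self, context: Context) -> List[Rotamer]:
        """Rotamers for a context; generic HIS falls back to the HID entry."""
        key = tuple(context)
        if key in self.entries:
            return self.entries[key]
        if key[1].upper() == "HIS":
            delta = (key[0], "HID", key[2])
            if delta in self.entries:
                return self.entries[delta]
        raise KeyError(f"context {key} not in library")

    def __contains__(self, context) -> bool:
        try:
            self.get(context)
            return True
        except KeyError:
            return False


def equilibrium_populations(
    free_energies: Sequence[float], temperature: float = DEFAULT_TEMPERATURE
) -> np.ndarray:
    """Boltzmann populations p_i ∝ exp(-F_i / kT), normalized to sum 1.

    ``temperature`` in kelvin; invariant to adding a constant to all F_i.
    """
    F = np.asarray(free_energies, dtype=float)
    if F.size == 0:
        raise ValueError("empty free-energy list")
    if not np.all(np.isfinite(F)):
        raise ValueError("free energies must be finite")
    beta = 1.0 / (KB_KCAL_MOL_K * temperature)
    w = np.exp(-beta * (F - F.min()))
    return w / w.sum()


def circular_mean_sd(angles: Sequence[float]) -> Tuple[float, float]:
    """Circular mean and population standard deviation of angles in degrees.

    The mean is the direction of the resultant vector; the standard deviation
    is the root mean square of the shortest-arc deviations from that mean, so
    that for tightly clustered angles it coincides with the ordinary
    population standard deviation regardless of wrap-around at +-180 deg.
    """
    a = np.radians(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise ValueError("empty angle list")
    mean = math.degrees(math.atan2(np.mean(np.sin(a)), np.mean(np.cos(a))))
    mean = normalize_angle(mean)
    dev = periodic_angle_distance(np.degrees(a), mean)
    sd = float(np.sqrt(np.mean(np.square(dev))))
    return float(mean), sd


def cluster_to_rotamer(
    members: Sequence[ConformationRecord],
    populations: Sequence[float],
    context: Context,
) -> Rotamer:
    """Collapse one flat cluster into a rotamer.

    ``populations`` are the equilibrium populations of the members within the
    whole ensemble; the rotamer probability is their sum.  Singleton clusters
    get a 1.0 deg standard deviation on every chi to account for variance
    from displacements about the corresponding minimum.
    """
    if len(members) == 0:
        raise ValueError("empty cluster")
    if len(members) != len(populations):
        raise ValueError("members and populations must align")
    n = members[0].torsions.n
    mat = np.vstack([m.torsions.as_array() for m in members])
    if mat.shape[1] != n:
        raise ValueError("mixed chi dimensions in cluster")
    means, sds = [], []
    for j in range(n):
        mu, sd = circular_mean_sd(mat[:, j])
        means.append(mu)
        sds.append(sd if len(members) > 1 else SINGLETON_SD)
    return Rotamer(
        context=tuple(context),
        chi_mean=tuple(means),
        chi_sd=tuple(sds),
        probability=float(np.sum(populations)),
        member_count=len(members),
    )


def build_library(
    ensembles: Dict[Context, Sequence[ConformationRecord]],
    cutoff: float = DEFAULT_CUTOFF,
    temperature: float = DEFAULT_TEMPERATURE,
    prune: float = DEFAULT_PRUNE,
) -> RotamerLibrary:
    """Build a sequence-dependent rotamer library from conformation ensembles.

    Per context: Boltzmann populations from the free energies, average-linkage
    clustering of the torsions at ``cutoff``, one rotamer per cluster, then
    rotamers with probability strictly below ``prune`` are removed (retained
    probabilities are not renormalized).  Entries are sorted by descending
    probability.
    """
    lib = RotamerLibrary(
        temperature=temperature, cutoff=cutoff, prune=prune
    )
    for context, records in ensembles.items():
        context = tuple(context)
        central = context[1].upper()
        if central in NON_ROTAMERIC:
            raise ValueError(
                f"central residue {central} supports no rotameric states"
            )
        records = list(records)
        if not records:
            raise ValueError(f"context {context}: empty ensemble")
        pops = equilibrium_populations(
            [r.free_energy for r in records], temperature
        )
        if len(records) == 1:
            assignment_labels = (0,)
        else:
            dists = pairwise_torsion_distances([r.torsions for r in records])
            _, assignment = average_linkage_cluster(dists, cutoff=cutoff)
            assignment_labels = assignment.labels
        rotamers = []
        for cid in range(max(assignment_labels) + 1):
            idx = [i for i, lab in enumerate(assignment_labels) if lab == cid]
            rot = cluster_to_rotamer(
                [records[i] for i in idx], pops[idx], context
            )
            rotamers.append(rot)
        rotamers = [r for r in rotamers if r.probability >= prune]
        rotamers.sort(key=lambda r: (-r.probability, r.chi_mean))
        lib.entries[context] = rotamers
    return lib


def _per_chi_max_distance(observed: TorsionVector, rotamer: Rotamer) -> float:
    obs = observed.as_array() if isinstance(observed, TorsionVector) else np.atleast_1d(
        np.asarray(observed, float)
    )
    if obs.shape[0] != rotamer.n_chi:
        raise ValueError(
            f"chi dimension mismatch: observed {obs.shape[0]}, "
            f"rotamer {rotamer.n_chi}"
        )
    d = periodic_angle_distance(obs, np.asarray(rotamer.chi_mean))
    return float(np.max(d))


def match_sidechain(
    observed: TorsionVector,
    candidates: Sequence[Rotamer],
    tolerance: float = DEFAULT_CUTOFF,
) -> Optional[Rotamer]:
    """Match an observed side chain against candidate rotamers.

    A rotamer matches iff the observation is strictly within ``tolerance``
    of its mean in every chi dihedral.  Among multiple matches the
    highest-probability one is returned; ``None`` if no candidate qualifies.
    """
    best = None
    for rot in candidates:
        if _per_chi_max_distance(observed, rot) < tolerance:
            if best is None or rot.probability > best.probability:
                best = rot
    return best


def nearest_distance(
    observed: TorsionVector, candidates: Sequence[Rotamer]
) -> float:
    """Distance to the nearest rotamer: min over candidates of the maximum
    per-chi periodic distance (degrees)."""
    if not candidates:
        raise ValueError("no candidate rotamers")
    return min(_per_chi_max_distance(observed, r) for r in candidates)


@dataclass(frozen=True)
class CoverageReport:
    """Per-residue-type match percentages and mean rotamer counts."""

    percent_by_residue: Dict[str, float]
    mean_rotamers_by_residue: Dict[str, float]
    total_percent: float
    n_matched: int
    n_tested: int
    n_unresolvable: int


def coverage_report(
    test_set: Sequence[Tuple[Context, TorsionVector]],
    library: RotamerLibrary,
    tolerance: float = DEFAULT_CUTOFF,
) -> CoverageReport:
    """Fraction of observed side-chain conformations present in the library.

    Observations whose context is absent from the library are counted as
    unresolvable and excluded from the percentages.  For each central residue
    type the report gives the percent matched and the average number of
    rotamers per distinct context encountered, plus the overall total.
    """
    if len(test_set) == 0:
        raise ValueError("empty test set")
    matched: Dict[str, int] = {}
    tested: Dict[str, int] = {}
    contexts_seen: Dict[str, set] = {}
    unresolvable = 0
    for context, observed in test_set:
        context = tuple(context)
        try:
            rots = library.get(context)
        except KeyError:
            unresolvable += 1
            continue
        central = context[1].upper()
        tested[central] = tested.get(central, 0) + 1
        contexts_seen.setdefault(central, set()).add(context)
        if rots and match_sidechain(observed, rots, tolerance) is not None:
            matched[central] = matched.get(central, 0) + 1
    if not tested:
        raise ValueError("no resolvable observations in test set")
    percent = {
        res: 100.0 * matched.get(res, 0) / n for res, n in tested.items()
    }
    mean_counts = {
        res: float(
            np.mean([len(library.get(c)) for c in sorted(contexts_seen[res])])
        )
        for res in tested
    }
    n_matched = sum(matched.values())
    n_tested = sum(tested.values())
    return CoverageReport(
        percent_by_residue=percent,
        mean_rotamers_by_residue=mean_counts,
        total_percent=100.0 * n_matched / n_tested,
        n_matched=n_matched,
        n_tested=n_tested,
        n_unresolvable=unresolvable,
    )


def reference_rotamer_tracking(
    library: RotamerLibrary,
    reference_context: Context,
    tolerance: float = DEFAULT_CUTOFF,
    aggregate_metric: bool = False,
) -> Dict[Context, float]:
    """Track the reference context's top rotamer across all other contexts.

    The most probable rotamer of ``reference_context`` (e.g. GLY-XXX-GLY,
    whose flanking glycines put minimal constraints on the side chain) is
    located in every other context with the same central residue, using the
    per-chi 40 deg criterion (or, if ``aggregate_metric``, the aggregate
    torsional-distance criterion), and its probability there is reported
    (0 if absent).
    """
    reference_context = tuple(reference_context)
    if reference_context not in library.entries:
        raise KeyError(f"reference context {reference_context} not in library")
    ref_rots = library.entries[reference_context]
    if not ref_rots:
        raise ValueError(f"reference context {reference_context} has no rotamers")
    ref = max(ref_rots, key=lambda r: r.probability)
    ref_vec = TorsionVector(ref.chi_mean)
    central = reference_context[1]
    out: Dict[Context, float] = {}
    for context, rots in library.entries.items():
        if context[1] != central:
            continue
        prob = 0.0
        best = None
        for rot in rots:
            if aggregate_metric:
                ok = torsion_distance(ref_vec, TorsionVector(rot.chi_mean)) < tolerance
            else:
                ok = _per_chi_max_distance(ref_vec, rot) < tolerance
            if ok and (best is None or rot.probability > best.probability):
                best = rot
        if best is not None:
            prob = best.probability
        out[context] = prob
    return out
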