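"""Readers and writers: multi-model PDB ensembles, energy sidecars, the
rotamer-library text format, run configuration and logging.

The library file is a tab-separated text format, one rotamer per line::

    prev  central  next  chi1_mean..chi4_mean  chi1_sd..chi4_sd  probability  member_count

with blank fields for unused chi dihedrals and a ``#key=value`` metadata
header (temperature, cutoff, prune threshold, provenance).  The format is
diffable and round-trips losslessly: writing, reading and re-writing a
library reproduces the file byte for byte.

Conformational ensembles travel either as multi-model PDB files with a TSV
energy sidecar (model_id, potential_energy, free_energy) or as a flat TSV of
context + chi angles + energies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .torsion import TorsionVector, chi_definitions, extract_sidechain_torsions, place_atom
from .library import (
    ConformationRecord,
    Context,
    Rotamer,
    RotamerLibrary,
)

__all__ = [
    "EnsembleBundle",
    "RunConfig",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_energy_sidecar",
    "write_energy_sidecar",
    "write_library",
    "read_library",
    "read_conformation_tsv",
    "write_conformation_tsv",
    "read_test_set_tsv",
    "bundle_to_ensembles",
    "synthetic_tripeptide_bundle",
    "get_logger",
]

LIBRARY_FORMAT_VERSION = "1"

_log_configured = False


def get_logger(name: str = "rotamerbh") -> logging.Logger:
    """Structured logger: timestamped lines of stage and key=value pairs."""
    global _log_configured
    logger = logging.getLogger(name)
    if not _log_configured:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        logger.propagate = False
        _log_configured = True
    return logger


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat key-value run configuration; unknown keys are rejected."""

    cutoff: float = 40.0
    temperature: float = 298.0
    prune: float = 0.005
    sampling_temperature: float = 1.3
    rms_force_tol: float = 1e-6
    seed: int = 0
    steps: int = 1000
    scheme: str = "rotamer 2"

    @classmethod
    def from_mapping(cls, mapping: Dict[str, object]) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**mapping)
        for key in ("cutoff", "temperature", "prune", "sampling_temperature", "rms_force_tol"):
            if getattr(cfg, key) <= 0:
                raise ValueError(f"config {key} must be positive")
        return cfg


# ---------------------------------------------------------------------------
# Multi-model PDB
# ---------------------------------------------------------------------------

@dataclass
class EnsembleBundle:
    """A multi-model coordinate ensemble with shared sequence and energies.

    ``models`` is a list of frames; each frame maps residue index (0-based,
    in chain order) to a dict of atom name -> xyz.  ``sequence`` holds the
    residue names in chain order including capping groups.  ``energies``
    maps model id to (potential_energy, free_energy).  Models that could not
    supply all side-chain atoms are listed in ``flagged`` with a reason and
    excluded from analysis.
    """

    sequence: List[str]
    models: List[Dict[int, Dict[str, np.ndarray]]]
    model_ids: List[str]
    energies: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    flagged: List[Tuple[str, str]] = field(default_factory=list)


def _check_pdb_lines(path: Path):
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line) < 54:
                raise ValueError(f"{path}:{lineno}: truncated ATOM record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed coordinates in ATOM record"
                )


def read_multimodel_pdb(path, energies_path=None) -> EnsembleBundle:
    """Read a multi-model PDB file (and optional energy sidecar).

    Models appear in file order.  ACE/NME capping groups are kept in the
    sequence.  Models in which a chi-bearing residue lacks a required
    side-chain atom are flagged (and skipped), not fatal.  Malformed ATOM
    records raise with the offending line number.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty PDB file")
    _check_pdb_lines(path)
    structure = PDBParser(QUIET=True).get_structure("ens", str(path))
    models = []
    model_ids = []
    flagged: List[Tuple[str, str]] = []
    sequence: List[str] = []
    for model in structure:
        frame: Dict[int, Dict[str, np.ndarray]] = {}
        names = []
        for chain in model:
            for res in chain:
                names.append(res.get_resname().strip())
                frame[len(names) - 1] = {
                    atom.get_name().strip(): atom.get_coord().astype(float)
                    for atom in res
                }
        if not names:
            continue
        if not sequence:
            sequence = names
        mid = str(model.id)
        problem = _missing_sidechain_atoms(names, frame)
        if problem:
            flagged.append((mid, problem))
        models.append(frame)
        model_ids.append(mid)
    if not models:
        raise ValueError(f"{path}: no models found")
    bundle = EnsembleBundle(
        sequence=sequence, models=models, model_ids=model_ids, flagged=flagged
    )
    if energies_path is not None:
        bundle.energies = read_energy_sidecar(energies_path)
    return bundle


def _missing_sidechain_atoms(names, frame) -> Optional[str]:
    for i, resname in enumerate(names):
        try:
            quads = chi_definitions(resname)
        except ValueError:
            continue
        needed = {a for quad in quads for a in quad}
        missing = needed - set(frame.get(i, {}))
        if missing:
            return f"residue {i} ({resname}) missing {sorted(missing)}"
    return None


def write_multimodel_pdb(bundle: EnsembleBundle, path):
    """Write an :class:`EnsembleBundle` as a multi-model PDB file."""
    path = Path(path)
    lines = []
    for m, frame in enumerate(bundle.models):
        lines.append(f"MODEL     {m + 1:>4d}")
        serial = 1
        for ri in sorted(frame):
            resname = bundle.sequence[ri]
            for name, xyz in frame[ri].items():
                pad_name = f" {name:<3s}" if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:>5d} {pad_name}{'':1s}{resname:>3s} A"
                    f"{ri + 1:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}"
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_energy_sidecar(path) -> Dict[str, Tuple[float, float]]:
    """TSV sidecar: model_id, potential_energy, free_energy (kcal/mol)."""
    out = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("model_id"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns")
        out[parts[0]] = (float(parts[1]), float(parts[2]))
    return out


def write_energy_sidecar(energies: Dict[str, Tuple[float, float]], path):
    lines = ["model_id\tpotential_energy\tfree_energy"]
    for mid, (pe, fe) in energies.items():
        lines.append(f"{mid}\t{pe!r}\t{fe!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def bundle_to_ensembles(
    bundle: EnsembleBundle, central_index: Optional[int] = None
) -> Dict[Context, List[ConformationRecord]]:
    """Extract per-context conformation records from a PDB ensemble.

    ``central_index`` selects the central residue (default: the single
    chi-bearing residue between the termini).  Flagged models are skipped.
    Requires the bundle to carry energies for every retained model.
    """
    seq = bundle.sequence
    if central_index is None:
        candidates = []
        for i in range(1, len(seq) - 1):
            try:
                chi_definitions(seq[i])
                candidates.append(i)
            except ValueError:
                pass
        if len(candidates) != 1:
            raise ValueError(
                "central_index required: found chi-bearing residues at "
                f"{candidates}"
            )
        central_index = candidates[0]
    context = (seq[central_index - 1], seq[central_index], seq[central_index + 1])
    flagged_ids = {mid for mid, _ in bundle.flagged}
    records = []
    for mid, frame in zip(bundle.model_ids, bundle.models):
        if mid in flagged_ids:
            continue
        if mid not in bundle.energies:
            raise ValueError(f"model {mid}: no energy row in sidecar")
        pe, fe = bundle.energies[mid]
        torsions = extract_sidechain_torsions(frame[central_index], seq[central_index])
        records.append(
            ConformationRecord(
                id=mid, torsions=torsions, potential_energy=pe, free_energy=fe
            )
        )
    if not records:
        raise ValueError("no usable models in bundle")
    return {context: records}


# ---------------------------------------------------------------------------
# Conformation / test-set TSV formats
# ---------------------------------------------------------------------------

def write_conformation_tsv(
    ensembles: Dict[Context, Sequence[ConformationRecord]], path
):
    """Flat TSV of conformations: context, id, chi angles, energies."""
    lines = [
        "prev\tcentral\tnext\tid\tchi1\tchi2\tchi3\tchi4\tpotential_energy\tfree_energy"
    ]
    for context in sorted(ensembles):
        for rec in ensembles[context]:
            chis = list(rec.torsions.angles) + [""] * (4 - rec.torsions.n)
            chi_cols = "\t".join("" if c == "" else repr(float(c)) for c in chis)
            lines.append(
                f"{context[0]}\t{context[1]}\t{context[2]}\t{rec.id}\t"
                f"{chi_cols}\t{rec.potential_energy!r}\t{rec.free_energy!r}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_conformation_tsv(path) -> Dict[Context, List[ConformationRecord]]:
    out: Dict[Context, List[ConformationRecord]] = {}
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("prev\t"):
        raise ValueError(f"{path}: missing conformation TSV header")
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 10:
            raise ValueError(f"{path}:{lineno}: expected 10 columns")
        context = (parts[0], parts[1], parts[2])
        chis = [float(c) for c in parts[4:8] if c != ""]
        rec = ConformationRecord(
            id=parts[3],
            torsions=TorsionVector(chis),
            potential_energy=float(parts[8]),
            free_energy=float(parts[9]),
        )
        out.setdefault(context, []).append(rec)
    return out


def read_test_set_tsv(path) -> List[Tuple[Context, TorsionVector]]:
    """Test set for coverage: prev, central, next, chi1..chi4 (blank unused)."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("#", "prev\t")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: expected context + chi columns")
        context = (parts[0], parts[1], parts[2])
        chis = [float(c) for c in parts[3:7] if c.strip() != ""]
        out.append((context, TorsionVector(chis)))
    return out


# ---------------------------------------------------------------------------
# Rotamer library format
# ---------------------------------------------------------------------------

def write_library(library: RotamerLibrary, path):
    """Serialize a rotamer library to the TSV text format (lossless)."""
    lines = [
        f"#rotamerbh_library_version={LIBRARY_FORMAT_VERSION}",
        f"#temperature={library.temperature!r}",
        f"#cutoff={library.cutoff!r}",
        f"#prune={library.prune!r}",
        f"#provenance={library.provenance}",
        "prev\tcentral\tnext\t"
        "chi1_mean\tchi2_mean\tchi3_mean\tchi4_mean\t"
        "chi1_sd\tchi2_sd\tchi3_sd\tchi4_sd\tprobability\tmember_count",
    ]
    for context in sorted(library.entries):
        rots = sorted(
            library.entries[context], key=lambda r: (-r.probability, r.chi_mean)
        )
        for rot in rots:
            means = list(rot.chi_mean) + [""] * (4 - rot.n_chi)
            sds = list(rot.chi_sd) + [""] * (4 - rot.n_chi)
            cols = (
                list(context)
                + ["" if v == "" else repr(float(v)) for v in means]
                + ["" if v == "" else repr(float(v)) for v in sds]
                + [repr(float(rot.probability)), str(rot.member_count)]
            )
            lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


def read_library(path) -> RotamerLibrary:
    """Read a rotamer library written by :func:`write_library`.

    Malformed rows and bad headers raise with the offending location.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    meta: Dict[str, str] = {}
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key] = value
            body_start = i + 1
        else:
            break
    if meta.get("rotamerbh_library_version") != LIBRARY_FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported or missing library version "
            f"{meta.get('rotamerbh_library_version')!r}"
        )
    for key in ("temperature", "cutoff", "prune"):
        if key not in meta:
            raise ValueError(f"{path}: header missing {key}")
    if body_start >= len(lines) or not lines[body_start].startswith("prev\t"):
        raise ValueError(f"{path}: missing column header")
    lib = RotamerLibrary(
        temperature=float(meta["temperature"]),
        cutoff=float(meta["cutoff"]),
        prune=float(meta["prune"]),
        provenance=meta.get("provenance", ""),
    )
    for lineno, line in enumerate(lines[body_start + 1 :], body_start + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 13:
            raise ValueError(f"{path}:{lineno}: expected 13 columns")
        context = (parts[0], parts[1], parts[2])
        means = [float(v) for v in parts[3:7] if v != ""]
        sds = [float(v) for v in parts[7:11] if v != ""]
        if len(means) != len(sds):
            raise ValueError(f"{path}:{lineno}: chi mean/sd arity mismatch")
        try:
            rot = Rotamer(
                context=context,
                chi_mean=tuple(means),
                chi_sd=tuple(sds),
                probability=float(parts[11]),
                member_count=int(parts[12]),
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        lib.entries.setdefault(context, []).append(rot)
    return lib


# ---------------------------------------------------------------------------
# Synthetic peptide fixture (labelled synthetic: idealized geometry, not a
# force-field structure)
# ---------------------------------------------------------------------------

def synthetic_tripeptide_bundle(
    chi1_values: Sequence[float],
    energies: Optional[Sequence[Tuple[float, float]]] = None,
) -> EnsembleBundle:
    """Build a synthetic ACE-SER-NME ensemble with prescribed chi1 values.

    Geometry is idealized (standard bond lengths/angles via internal-
    coordinate construction); one model per requested chi1.  Useful as a
    fixture for the PDB round trip and torsion extraction.
    """
    models = []
    ids = []
    for m, chi1 in enumerate(chi1_values):
        ace_c = np.array([0.0, 0.0, 0.0])
        ace_o = np.array([0.0, 1.23, 0.0])
        ace_ch3 = np.array([-1.5, -0.5, 0.0])
        n = place_atom(ace_ch3, ace_o, ace_c, 1.33, 115.0, 180.0)
        ca = place_atom(ace_o, ace_c, n, 1.45, 121.0, 180.0)
        c = place_atom(ace_c, n, ca, 1.52, 110.0, -60.0)
        o = place_atom(n, ca, c, 1.23, 120.0, 0.0)
        cb = place_atom(c, n, ca, 1.53, 110.0, 122.0)
        og = place_atom(n, ca, cb, 1.41, 110.5, chi1)
        nme_n = place_atom(n, ca, c, 1.33, 116.0, 180.0)
        nme_ch3 = place_atom(ca, c, nme_n, 1.45, 121.0, 180.0)
        models.append(
            {
                0: {"C": ace_c, "O": ace_o, "CH3": ace_ch3},
                1: {"N": n, "CA": ca, "C": c, "O": o, "CB": cb, "OG": og},
                2: {"N": nme_n, "CH3": nme_ch3},
            }
        )
        ids.append(str(m))
    bundle = EnsembleBundle(
        sequence=["ACE", "SER", "NME"], models=models, model_ids=ids
    )
    if energies is not None:
        bundle.energies = {
            mid: (float(pe), float(fe)) for mid, (pe, fe) in zip(ids, energies)
        }
    return bundle
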