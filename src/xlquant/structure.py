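"""Cross-link mapping onto 3D coordinates as Ca-Ca distance restraints.

A DSS bridge (11.6 A spacer) between two lysines implies a Ca-Ca distance
of roughly <= 24 A in the native structure; on imperfect models distances
up to 35 A are still considered compatible. Boundaries are inclusive.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser

from .seqdigest import ProteinRecord

__all__ = [
    "StructureModel",
    "RestraintThresholds",
    "DistanceRestraint",
    "read_structure",
    "ca_distance",
    "evaluate_restraints",
    "domain_pair_label",
    "write_restraint_report",
    "pymol_distance_script",
]

logger = logging.getLogger(__name__)

STATUSES = ("within_expected", "within_model_max", "violated")


@dataclass
class StructureModel:
    """Ca coordinates keyed by (chain id, residue number)."""

    model_id: str
    ca_coords: dict[tuple[str, int], np.ndarray]

    def __post_init__(self) -> None:
        for key, xyz in self.ca_coords.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (3,) or not np.isfinite(xyz).all():
                raise ValueError(f"bad coordinates for residue {key}")
            self.ca_coords[key] = xyz

    def __len__(self) -> int:
        return len(self.ca_coords)

    def coord(self, residue: int, chain: str | None = None) -> np.ndarray:
        if chain is None:
            hits = [k for k in self.ca_coords if k[1] == residue]
            if not hits:
                raise KeyError(f"residue {residue} has no Ca in model {self.model_id}")
            if len(hits) > 1:
                raise KeyError(f"residue {residue} ambiguous across chains {hits}")
            return self.ca_coords[hits[0]]
        try:
            return self.ca_coords[(chain, residue)]
        except KeyError:
            raise KeyError(
                f"residue {chain}/{residue} has no Ca in model {self.model_id}"
            ) from None

    def has_residue(self, residue: int, chain: str | None = None) -> bool:
        try:
            self.coord(residue, chain)
            return True
        except KeyError:
            return False


@dataclass(frozen=True)
class RestraintThresholds:
    """DSS-specific distance cutoffs (A)."""

    linker_arm: float = 11.6
    expected_max: float = 24.0
    model_max: float = 35.0

    def __post_init__(self) -> None:
        if not self.linker_arm < self.expected_max < self.model_max:
            raise ValueError("thresholds must satisfy linker_arm < expected_max < model_max")

    def status(self, distance: float) -> str:
        if distance < 0:
            raise ValueError("negative distance")
        if distance <= self.expected_max:
            return "within_expected"
        if distance <= self.model_max:
            return "within_model_max"
        return "violated"


@dataclass(frozen=True)
class DistanceRestraint:
    site1: int
    site2: int
    distance: float
    status: str
    domains: tuple[str, str] = ("unassigned", "unassigned")


def read_structure(
    path: str | Path,
    chains: Iterable[str] | None = None,
    allow_insertion_codes: bool = False,
    residue_offset: dict[str, int] | None = None,
) -> StructureModel:
    """Extract Ca records from a PDB file (first model only).

    ``residue_offset`` maps chain id to an integer added to the file's
    residue numbers, for models that renumber relative to the sequence.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))
    models = list(structure.get_models())
    if not models:
        raise ValueError(f"{path}: no models")
    model = models[0]
    selected = set(chains) if chains is not None else None
    offsets = residue_offset or {}
    coords: dict[tuple[str, int], np.ndarray] = {}
    for chain in model:
        if selected is not None and chain.id not in selected:
            continue
        for residue in chain:
            hetflag, resseq, icode = residue.id
            if hetflag.strip():
                continue
            if icode.strip() and not allow_insertion_codes:
                raise ValueError(
                    f"{path}: insertion code {icode!r} at {chain.id}/{resseq} not supported"
                )
            if "CA" not in residue:
                logger.warning(
                    "%s: residue %s/%s lacks a Ca atom; skipped", path, chain.id, resseq
                )
                continue
            coords[(chain.id, resseq + offsets.get(chain.id, 0))] = np.array(
                residue["CA"].coord, dtype=float
            )
    if not coords:
        raise ValueError(f"{path}: no Ca atoms in selection")
    return StructureModel(model_id=path.stem, ca_coords=coords)


def ca_distance(model: StructureModel, res_i: int, res_j: int, chain: str | None = None) -> float:
    """Euclidean Ca-Ca distance (A) between two residues."""
    a = model.coord(res_i, chain)
    b = model.coord(res_j, chain)
    return float(np.linalg.norm(a - b))


def evaluate_restraints(
    model: StructureModel,
    links: Sequence[tuple[int, int]],
    thresholds: RestraintThresholds | None = None,
    protein: ProteinRecord | None = None,
    chain: str | None = None,
) -> tuple[list[DistanceRestraint], dict]:
    """Distance and satisfaction status for each residue-pair link.

    Links whose residues are absent from the model are reported in the
    summary under ``unmapped`` rather than raising.
    """
    thresholds = thresholds or RestraintThresholds()
    restraints: list[DistanceRestraint] = []
    unmapped: list[tuple[int, int]] = []
    for site1, site2 in links:
        if not (model.has_residue(site1, chain) and model.has_residue(site2, chain)):
            unmapped.append((site1, site2))
            continue
        d = ca_distance(model, site1, site2, chain)
        domains = (
            (protein.domain_of(site1), protein.domain_of(site2))
            if protein is not None
            else ("unassigned", "unassigned")
        )
        restraints.append(DistanceRestraint(site1, site2, d, thresholds.status(d), domains))
    status_counts = {s: 0 for s in STATUSES}
    domain_counts: dict[str, int] = {}
    for r in restraints:
        status_counts[r.status] += 1
        key = "-".join(sorted(r.domains))
        domain_counts[key] = domain_counts.get(key, 0) + 1
    summary = {
        "n_links": len(links),
        "n_mapped": len(restraints),
        "unmapped": unmapped,
        "status_counts": status_counts,
        "domain_pair_counts": domain_counts,
        "thresholds": {
            "linker_arm": thresholds.linker_arm,
            "expected_max": thresholds.expected_max,
            "model_max": thresholds.model_max,
        },
    }
    return restraints, summary


def domain_pair_label(
    link: tuple[int, int], protein: ProteinRecord
) -> tuple[str, str]:
    """Ordered pair of domain names containing the two link sites.

    Overlapping annotations resolve to the first matching span in file
    order (logged); unannotated residues label as ``unassigned``.
    """
    labels = []
    for site in link:
        matches = [name for name, s, e in protein.domains if s <= site <= e]
        if len(matches) > 1:
            logger.info(
                "residue %d in overlapping domains %s; using %s", site, matches, matches[0]
            )
        labels.append(matches[0] if matches else "unassigned")
    return (labels[0], labels[1])


def write_restraint_report(
    restraints: Sequence[DistanceRestraint],
    summary: dict,
    tsv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("site1\tsite2\tdistance_A\tstatus\tdomain1\tdomain2\n")
        for r in restraints:
            fh.write(
                f"{r.site1}\t{r.site2}\t{r.distance:.2f}\t{r.status}\t"
                f"{r.domains[0]}\t{r.domains[1]}\n"
            )
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
            fh.write("\n")


def pymol_distance_script(
    restraints: Sequence[DistanceRestraint], chain: str = "A", object_name: str = "xl"
) -> str:
    """Plain-text PyMOL commands drawing one dashed distance per restraint."""
    lines = []
    for i, r in enumerate(restraints, start=1):
        lines.append(
            f"distance {object_name}_{i}_{r.status}, "
            f"chain {chain} and resi {r.site1} and name CA, "
            f"chain {chain} and resi {r.site2} and name CA"
        )
    return "\n".join(lines) + ("\n" if lines else "")
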