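"""Seeded synthetic data: proteins, folds, spectra and intensity matrices.

Every generator is deterministic given (seed, config); independent
sub-streams are derived from the seed so that stages can be regenerated
in isolation. The statistical structure mirrors what the analysis
assumes: lysine-rich random proteins, self-avoiding Ca traces, b/y CID
spectra with mass error and noise peaks, and triplicate lognormal
intensities with a responsive link subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .masses import MassConstants, mz_from_neutral_mass
from .mgf import MsmsSpectrum
from .quant import IntensityMatrix
from .search import CrossLinkCandidate, SearchParameters, theoretical_fragments
from .seqdigest import ProteinRecord
from .structure import StructureModel

__all__ = [
    "SimulationConfig",
    "GroundTruthLink",
    "make_protein",
    "make_structure",
    "sample_ground_truth_links",
    "simulate_spectrum",
    "simulate_intensities",
    "write_fasta",
    "write_pdb",
    "write_truth",
]

AMINO_ACIDS = "ACDEFGHILMNPQRSTVWY"  # K handled via lysine_fraction


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    # protein / fold
    protein_length: int = 120
    lysine_fraction: float = 0.10
    ca_step: float = 3.8
    min_approach: float = 4.0
    # ground-truth links
    link_cutoff: float = 24.0
    n_responsive: int = 2
    responsive_fc: float = 1.9
    # spectra
    coverage: float = 0.7
    noise_fraction: float = 0.3
    mz_error_sd: float = 0.1  # Da; <= ms2 tolerance / 3
    precursor_ppm_max: float = 5.0
    # intensities
    conditions: tuple[str, ...] = ("treated", "control_1", "control_2")
    replicates: int = 3
    cv: float = 0.15
    baseline: float = 1.0e6
    protein_level_baseline: float = 1.0e8
    protein_level_cv: float = 0.10

    def __post_init__(self) -> None:
        if not 0 <= self.lysine_fraction <= 1:
            raise ValueError("lysine_fraction must lie in [0, 1]")
        if self.cv < 0 or self.protein_level_cv < 0:
            raise ValueError("CV must be non-negative")
        if self.responsive_fc <= 0:
            raise ValueError("fold-changes must be positive")
        if self.replicates < 2:
            raise ValueError("need at least two replicates")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass(frozen=True)
class GroundTruthLink:
    site1: int
    site2: int
    responsive: bool
    fold_change: float  # treated vs each control; 1.0 when not responsive

    @property
    def link_id(self) -> str:
        return f"K{self.site1}-K{self.site2}"


def make_protein(config: SimulationConfig, protein_id: str | None = None) -> ProteinRecord:
    """Random protein with the requested lysine fraction; >= 2 lysines."""
    rng = config.rng(1)
    n = config.protein_length
    is_k = rng.random(n) < config.lysine_fraction
    others = rng.choice(list(AMINO_ACIDS), size=n)
    residues = np.where(is_k, "K", others)
    # guarantee at least two lysines (forced positions drawn from the stream)
    deficit = 2 - int(is_k.sum())
    if deficit > 0 and n >= 2:
        free = np.flatnonzero(~is_k)
        for pos in rng.choice(free, size=deficit, replace=False):
            residues[pos] = "K"
    return ProteinRecord(
        id=protein_id or f"synprot_seed{config.seed}",
        sequence="".join(residues),
    )


def make_structure(
    protein: ProteinRecord, config: SimulationConfig, chain: str = "A"
) -> StructureModel:
    """Self-avoiding 3D random walk Ca trace.

    Consecutive residues sit exactly ``ca_step`` apart; non-consecutive
    pairs stay at least ``min_approach`` apart. Dead ends backtrack.
    """
    rng = config.rng(2)
    n = len(protein)
    coords: list[np.ndarray] = [np.zeros(3)]
    tries_at_level = [0]
    while len(coords) < n:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        candidate = coords[-1] + config.ca_step * direction
        prior = np.array(coords[:-1]) if len(coords) > 1 else None
        clash = (
            prior is not None
            and (np.linalg.norm(prior - candidate, axis=1) < config.min_approach).any()
        )
        if not clash:
            coords.append(candidate)
            tries_at_level.append(0)
            continue
        tries_at_level[-1] += 1
        if tries_at_level[-1] > 50 and len(coords) > 1:
            coords.pop()
            tries_at_level.pop()
            tries_at_level[-1] += 1
    ca = {(chain, i + 1): c for i, c in enumerate(coords)}
    return StructureModel(model_id=f"synfold_seed{config.seed}", ca_coords=ca)


def sample_ground_truth_links(
    protein: ProteinRecord,
    structure: StructureModel,
    config: SimulationConfig,
    chain: str = "A",
) -> list[GroundTruthLink]:
    """All K-K pairs within the Ca-Ca cutoff; a random subset is responsive."""
    rng = config.rng(3)
    k_positions = [i + 1 for i, aa in enumerate(protein.sequence) if aa == "K"]
    pairs = []
    for a_idx, site1 in enumerate(k_positions):
        for site2 in k_positions[a_idx + 1 :]:
            d = np.linalg.norm(
                structure.coord(site1, chain) - structure.coord(site2, chain)
            )
            if d <= config.link_cutoff:
                pairs.append((site1, site2))
    n_resp = min(config.n_responsive, len(pairs))
    responsive_idx = set(
        rng.choice(len(pairs), size=n_resp, replace=False).tolist() if n_resp else []
    )
    return [
        GroundTruthLink(
            site1,
            site2,
            responsive=i in responsive_idx,
            fold_change=config.responsive_fc if i in responsive_idx else 1.0,
        )
        for i, (site1, site2) in enumerate(pairs)
    ]


def simulate_spectrum(
    candidate: CrossLinkCandidate,
    config: SimulationConfig,
    params: SearchParameters | None = None,
    constants: MassConstants | None = None,
    rng: np.random.Generator | None = None,
    spectrum_id: str | None = None,
) -> MsmsSpectrum:
    """CID-like b/y spectrum of a candidate with mass error and noise peaks.

    With coverage 1, noise 0 and zero mass error the peak list equals the
    theoretical ion list exactly.
    """
    params = params or SearchParameters()
    constants = constants or MassConstants()
    rng = rng if rng is not None else config.rng(4)

    precursor_charge = 3 if candidate.theoretical_mass < 3000 else 4
    frag_charges = list(
        range(1, max(1, min(params.max_fragment_charge, precursor_charge - 1)) + 1)
    )
    ions = theoretical_fragments(candidate, params, constants, frag_charges)
    keep = rng.random(len(ions)) < config.coverage
    if not keep.any():
        keep[rng.integers(len(ions))] = True
    kept_mz = np.array([ion.mz for ion in ions])[keep]
    kept_mz = kept_mz + rng.normal(0.0, config.mz_error_sd, size=kept_mz.size)
    kept_int = rng.lognormal(mean=np.log(100.0), sigma=0.4, size=kept_mz.size)

    n_noise = int(round(config.noise_fraction * kept_mz.size))
    lo, hi = min(ion.mz for ion in ions), max(ion.mz for ion in ions)
    noise_mz = rng.uniform(max(50.0, 0.8 * lo), 1.1 * hi, size=n_noise)
    noise_int = rng.lognormal(mean=np.log(20.0), sigma=0.4, size=n_noise)

    peaks = np.column_stack(
        [np.concatenate([kept_mz, noise_mz]), np.concatenate([kept_int, noise_int])]
    )
    ppm_error = rng.uniform(-config.precursor_ppm_max, config.precursor_ppm_max)
    neutral = candidate.theoretical_mass * (1.0 + ppm_error * 1e-6)
    return MsmsSpectrum(
        spectrum_id=spectrum_id or f"sim_{candidate.label()}",
        precursor_mz=mz_from_neutral_mass(neutral, precursor_charge, constants.proton),
        precursor_charge=precursor_charge,
        peaks=peaks,
    )


def simulate_intensities(
    links: Sequence[GroundTruthLink], config: SimulationConfig
) -> IntensityMatrix:
    """Triplicate lognormal intensity matrix with a responsive subset.

    Responsive links are scaled by their true fold-change in the first
    (treated) condition only. The protein-level row carries its own
    multiplicative noise, shared by no link (pure run-level quantity).
    """
    rng = config.rng(5)
    columns = pd.MultiIndex.from_tuples(
        [
            (cond, f"r{rep + 1}")
            for cond in config.conditions
            for rep in range(config.replicates)
        ],
        names=["condition", "replicate"],
    )
    sigma = float(np.sqrt(np.log1p(config.cv**2)))
    treated = config.conditions[0]
    rows = {}
    for link in links:
        base = config.baseline * rng.lognormal(0.0, 0.5)
        values = []
        for cond, _rep in columns:
            mean = base * (link.fold_change if cond == treated else 1.0)
            noise = rng.lognormal(-0.5 * sigma**2, sigma) if sigma > 0 else 1.0
            values.append(mean * noise)
        rows[link.link_id] = values
    intensities = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    p_sigma = float(np.sqrt(np.log1p(config.protein_level_cv**2)))
    level = config.protein_level_baseline * (
        rng.lognormal(-0.5 * p_sigma**2, p_sigma, size=len(columns))
        if p_sigma > 0
        else np.ones(len(columns))
    )
    return IntensityMatrix(intensities, pd.Series(level, index=columns))


def write_fasta(protein: ProteinRecord, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(f">{protein.id}\n")
        for i in range(0, len(protein.sequence), width):
            fh.write(protein.sequence[i : i + width] + "\n")


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write Ca-only coordinates in fixed-column PDB format."""
    with open(path, "w") as fh:
        serial = 1
        for (chain, resnum), (x, y, z) in sorted(structure.ca_coords.items()):
            fh.write(
                f"ATOM  {serial:5d}  CA  ALA {chain}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C\n"
            )
            serial += 1
        fh.write("END\n")


def write_truth(
    links: Sequence[GroundTruthLink], config: SimulationConfig, path: str | Path
) -> None:
    payload = {
        "config": asdict(config),
        "links": [
            {
                "link": link.link_id,
                "site1": link.site1,
                "site2": link.site2,
                "responsive": link.responsive,
                "fold_change": link.fold_change,
            }
            for link in links
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
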