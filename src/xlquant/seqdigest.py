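"""Sequence I/O, in-silico tryptic digestion and peptide mass arithmetic.

Residue coordinates are 1-based and inclusive throughout, matching the
usual protein-numbering convention (K783, K852, ...).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .masses import MassConstants

__all__ = [
    "ProteinRecord",
    "Peptide",
    "DigestionRule",
    "read_fasta",
    "read_domains",
    "digest",
    "peptide_mass",
    "with_fixed_cys",
]

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence plus optional 1-based inclusive domain spans."""

    id: str
    sequence: str
    domains: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        names = [d[0] for d in self.domains]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate domain names in {self.id}")
        for name, start, end in self.domains:
            if not (1 <= start <= end <= len(self.sequence)):
                raise ValueError(
                    f"domain {name} span {start}-{end} outside 1-{len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, pos: int) -> str:
        """Residue letter at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.sequence):
            raise IndexError(f"position {pos} outside 1-{len(self.sequence)}")
        return self.sequence[pos - 1]

    def domain_of(self, pos: int) -> str:
        """Name of the first annotated span containing ``pos``, else ``unassigned``."""
        for name, start, end in self.domains:
            if start <= pos <= end:
                return name
        return "unassigned"


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide span of a protein.

    ``mods`` holds (1-based protein position, modification name) pairs; at
    most one modification per position.
    """

    protein_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int
    mods: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"span {self.start}-{self.end} does not match sequence length "
                f"{len(self.sequence)}"
            )
        positions = [p for p, _ in self.mods]
        if len(positions) != len(set(positions)):
            raise ValueError("more than one modification on a single residue")
        for pos, name in self.mods:
            if not self.start <= pos <= self.end:
                raise ValueError(f"mod {name} at {pos} outside span {self.start}-{self.end}")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, pos: int) -> str:
        if not self.start <= pos <= self.end:
            raise IndexError(f"position {pos} outside {self.start}-{self.end}")
        return self.sequence[pos - self.start]

    def with_mods(self, mods: Iterable[tuple[int, str]]) -> "Peptide":
        merged = tuple(sorted(set(self.mods) | set(mods)))
        return Peptide(
            self.protein_id, self.start, self.end, self.sequence,
            self.missed_cleavages, merged,
        )


@dataclass(frozen=True)
class DigestionRule:
    """Cleavage specificity. Default is trypsin: after K/R, not before P."""

    cleave_after: frozenset[str] = frozenset("KR")
    suppress_before: frozenset[str] = frozenset("P")
    max_missed_cleavages: int = 2
    min_length: int = 4
    max_length: int = 60

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.min_length > self.max_length:
            raise ValueError("min_length exceeds max_length")

    def cleavage_sites(self, sequence: str) -> list[int]:
        """1-based positions P such that cleavage occurs after residue P."""
        sites = []
        for i, aa in enumerate(sequence[:-1]):
            if aa in self.cleave_after and sequence[i + 1] not in self.suppress_before:
                sites.append(i + 1)
        return sites


def read_fasta(path: str | Path, allow_x: bool = False) -> list[ProteinRecord]:
    """Read protein records from a FASTA file, preserving entry order.

    Sequences are uppercased. Residues outside the 20 standard letters
    raise unless ``allow_x`` is set (then ``X`` is tolerated).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not seq:
            raise ValueError(f"entry {entry.id!r} in {path} has no sequence")
        allowed = STANDARD_RESIDUES | ({"X"} if allow_x else set())
        for i, aa in enumerate(seq, start=1):
            if aa not in allowed:
                raise ValueError(
                    f"illegal residue {aa!r} at position {i} of {entry.id!r}"
                )
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA entries in {path}")
    return records


def read_domains(path: str | Path) -> tuple[tuple[str, int, int], ...]:
    """Read a 3-column TSV of domain annotations (name, start, end)."""
    spans: list[tuple[str, int, int]] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "name":  # optional header
                continue
            if len(row) < 3:
                raise ValueError(f"domain row {row!r} needs 3 columns")
            spans.append((row[0], int(row[1]), int(row[2])))
    return tuple(spans)


def digest(protein: ProteinRecord, rule: DigestionRule | None = None) -> list[Peptide]:
    """Fully tryptic digestion with missed cleavages.

    Returns every peptide made of 1..max_missed_cleavages+1 consecutive
    minimal fragments whose length falls inside the rule's range, ordered
    by (start, end).
    """
    rule = rule or DigestionRule()
    seq = protein.sequence
    sites = rule.cleavage_sites(seq)
    # fragment boundaries: [b0..b1], (b1..b2], ... as 1-based inclusive spans
    bounds = [0] + sites + [len(seq)]
    peptides: list[Peptide] = []
    nfrag = len(bounds) - 1
    for i in range(nfrag):
        for k in range(rule.max_missed_cleavages + 1):
            j = i + k + 1
            if j >= len(bounds):
                break
            start, end = bounds[i] + 1, bounds[j]
            if not rule.min_length <= end - start + 1 <= rule.max_length:
                continue
            peptides.append(
                Peptide(
                    protein_id=protein.id,
                    start=start,
                    end=end,
                    sequence=seq[start - 1 : end],
                    missed_cleavages=k,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def peptide_mass(peptide: Peptide, constants: MassConstants | None = None) -> float:
    """Neutral monoisotopic mass: residues + water + modification deltas."""
    constants = constants or MassConstants()
    total = constants.water
    for aa in peptide.sequence:
        total += constants.residue(aa)
    for _, name in peptide.mods:
        total += constants.mod(name)
    return total


def with_fixed_cys(peptide: Peptide, mod: str = "carbamidomethyl") -> Peptide:
    """Apply the fixed cysteine modification to every C in the peptide."""
    mods = [
        (pos, mod)
        for pos in range(peptide.start, peptide.end + 1)
        if peptide.residue(pos) == "C" and pos not in {p for p, _ in peptide.mods}
    ]
    return peptide.with_mods(mods) if mods else peptide
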