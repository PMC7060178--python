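from pathlib import Path

import numpy as np
import pytest

from xlquant.masses import MassConstants
from xlquant.seqdigest import DigestionRule, Peptide, ProteinRecord

EXTERNAL_FASTA = Path(__file__).parent / "data" / "external" / "gpr110_NM_153840.fasta"

# Independent monoisotopic atomic masses for oracle computations in tests.
ORACLE_ATOMS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

# Elemental compositions of the 20 amino-acid residues (peptide-bond form).
ORACLE_RESIDUE_FORMULAS = {
    "G": dict(C=2, H=3, N=1, O=1),
    "A": dict(C=3, H=5, N=1, O=1),
    "S": dict(C=3, H=5, N=1, O=2),
    "P": dict(C=5, H=7, N=1, O=1),
    "V": dict(C=5, H=9, N=1, O=1),
    "T": dict(C=4, H=7, N=1, O=2),
    "C": dict(C=3, H=5, N=1, O=1, S=1),
    "L": dict(C=6, H=11, N=1, O=1),
    "I": dict(C=6, H=11, N=1, O=1),
    "N": dict(C=4, H=6, N=2, O=2),
    "D": dict(C=4, H=5, N=1, O=3),
    "Q": dict(C=5, H=8, N=2, O=2),
    "K": dict(C=6, H=12, N=2, O=1),
    "E": dict(C=5, H=7, N=1, O=3),
    "M": dict(C=5, H=9, N=1, O=1, S=1),
    "H": dict(C=6, H=7, N=3, O=1),
    "F": dict(C=9, H=9, N=1, O=1),
    "R": dict(C=6, H=12, N=4, O=1),
    "Y": dict(C=9, H=9, N=1, O=2),
    "W": dict(C=11, H=10, N=2, O=1),
}


def oracle_peptide_mass(sequence: str) -> float:
    """Per-atom summation oracle for an unmodified peptide's neutral mass."""
    atoms = {"H": 2, "O": 1}  # one water
    for aa in sequence:
        for element, count in ORACLE_RESIDUE_FORMULAS[aa].items():
            atoms[element] = atoms.get(element, 0) + count
    return sum(ORACLE_ATOMS[el] * n for el, n in atoms.items())


def oracle_digest(sequence: str, rule: DigestionRule) -> set[tuple[int, int, int]]:
    """Brute-force enumeration of (start, end, missed_cleavages) spans."""
    n = len(sequence)

    def cleaves_after(p: int) -> bool:  # 1-based position p
        return (
            sequence[p - 1] in rule.cleave_after
            and (p == n or sequence[p] not in rule.suppress_before)
        )

    out = set()
    for start in range(1, n + 1):
        for end in range(start, n + 1):
            if start != 1 and not cleaves_after(start - 1):
                continue
            if end != n and not cleaves_after(end):
                continue
            internal = sum(1 for p in range(start, end) if cleaves_after(p))
            if internal > rule.max_missed_cleavages:
                continue
            if not rule.min_length <= end - start + 1 <= rule.max_length:
                continue
            out.add((start, end, internal))
    return out


@pytest.fixture(scope="session")
def constants() -> MassConstants:
    return MassConstants()


@pytest.fixture
def toy_protein() -> ProteinRecord:
    return ProteinRecord("toy", "AKAKAR")


def make_peptide(protein: ProteinRecord, start: int, end: int, mc: int = 0) -> Peptide:
    return Peptide(
        protein_id=protein.id,
        start=start,
        end=end,
        sequence=protein.sequence[start - 1 : end],
        missed_cleavages=mc,
    )
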