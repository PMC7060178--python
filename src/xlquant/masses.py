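"""Monoisotopic mass constants and m/z arithmetic.

All masses are monoisotopic and expressed in daltons (Da). Residue masses
are the standard amino-acid *residue* masses (peptide-bond form, i.e. the
free amino acid minus one water); a peptide's neutral mass is the sum of
its residue masses plus one water.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "ATOMIC_MASSES",
    "WATER",
    "PROTON",
    "MassConstants",
    "formula_mass",
    "neutral_mass_from_mz",
    "mz_from_neutral_mass",
]

#: Monoisotopic atomic masses (Da) of the elements occurring in peptides
#: and amine-reactive linker chemistry.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

WATER = 18.0105646
PROTON = 1.00727646688

#: Elemental compositions of the 20 canonical amino-acid residues
#: (peptide-bond form, i.e. minus one water).
RESIDUE_FORMULAS: dict[str, str] = {
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
}

#: Modification deltas (Da). The DSS bridge is C8H10O2; hydrolysis of one
#: NHS ester adds a water, giving the dead-end (monolink) C8H12O3.
MOD_MASSES: dict[str, float] = {
    "carbamidomethyl": 57.02146,
    "oxidation": 15.994915,
    "dss_crosslink": 138.06808,
    "dss_monolink": 156.07864,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(formula: str, atomic_masses: dict[str, float] | None = None) -> float:
    """Monoisotopic mass of a molecular formula such as ``"C8H10O2"``.

    Parameters
    ----------
    formula:
        Element symbols each optionally followed by a count.
    atomic_masses:
        Override table; defaults to :data:`ATOMIC_MASSES`.
    """
    table = atomic_masses if atomic_masses is not None else ATOMIC_MASSES
    if not formula:
        raise ValueError("empty formula")
    pos = 0
    total = 0.0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos or not match.group(1):
            raise ValueError(f"malformed formula {formula!r} at offset {pos}")
        element, count = match.group(1), match.group(2)
        if element not in table:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        total += table[element] * (int(count) if count else 1)
        pos = match.end()
        if pos == len(formula):
            break
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r} at offset {pos}")
    return total


#: Standard monoisotopic residue masses (Da), derived from the atomic table.
RESIDUE_MASSES: dict[str, float] = {
    aa: formula_mass(formula) for aa, formula in RESIDUE_FORMULAS.items()
}


@dataclass(frozen=True)
class MassConstants:
    """Bundle of residue, water, proton and modification masses.

    The defaults reproduce standard monoisotopic chemistry; individual
    entries can be overridden via :meth:`with_overrides` (e.g. from a
    config file).
    """

    residue_masses: dict[str, float] = field(
        default_factory=lambda: dict(RESIDUE_MASSES)
    )
    water: float = WATER
    proton: float = PROTON
    mod_masses: dict[str, float] = field(default_factory=lambda: dict(MOD_MASSES))

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.residue_masses)
        if missing:
            raise ValueError(f"residue masses missing for {sorted(missing)}")
        bad = [aa for aa, m in self.residue_masses.items() if m <= 0]
        if bad:
            raise ValueError(f"non-positive residue masses for {sorted(bad)}")

    def residue(self, letter: str) -> float:
        try:
            return self.residue_masses[letter]
        except KeyError:
            raise KeyError(f"unknown residue {letter!r}") from None

    def mod(self, name: str) -> float:
        try:
            return self.mod_masses[name]
        except KeyError:
            raise KeyError(f"unknown modification {name!r}") from None

    def with_overrides(
        self,
        residue_masses: dict[str, float] | None = None,
        mod_masses: dict[str, float] | None = None,
    ) -> "MassConstants":
        return replace(
            self,
            residue_masses={**self.residue_masses, **(residue_masses or {})},
            mod_masses={**self.mod_masses, **(mod_masses or {})},
        )


def neutral_mass_from_mz(mz: float, z: int, proton: float = PROTON) -> float:
    """Neutral monoisotopic mass of an ion observed at ``mz`` with charge ``z``.

    M = z * (m/z) - z * m_proton, assuming protonation as the only charge
    carrier (positive-ion ESI).
    """
    if z <= 0:
        raise ValueError(f"charge must be positive, got {z}")
    if mz <= proton:
        raise ValueError(f"m/z {mz} not above the proton mass")
    return z * mz - z * proton


def mz_from_neutral_mass(mass: float, z: int, proton: float = PROTON) -> float:
    """m/z at which a neutral mass appears with ``z`` protons attached."""
    if z <= 0:
        raise ValueError(f"charge must be positive, got {z}")
    return (mass + z * proton) / z
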