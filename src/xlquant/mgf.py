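"""Minimal MGF (Mascot generic format) reader/writer for centroided MS/MS.

Supports the fields this pipeline needs: TITLE, PEPMASS, CHARGE and the
peak list. Charges are assumed positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = ["MsmsSpectrum", "read_mgf", "write_mgf"]


@dataclass
class MsmsSpectrum:
    """One centroided MS/MS spectrum. Peaks are kept sorted by m/z."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    peaks: np.ndarray  # shape (n, 2): [m/z, intensity]

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        order = np.argsort(peaks[:, 0], kind="stable")
        peaks = peaks[order]
        if peaks.size and peaks[:, 1].min() < 0:
            raise ValueError(f"negative intensity in spectrum {self.spectrum_id}")
        self.peaks = peaks

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]


def read_mgf(path: str | Path) -> list[MsmsSpectrum]:
    spectra: list[MsmsSpectrum] = []
    title = ""
    pepmass = charge = None
    peaks: list[tuple[float, float]] = []
    in_ions = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                in_ions, title, pepmass, charge, peaks = True, "", None, None, []
            elif line == "END IONS":
                if pepmass is None or charge is None:
                    raise ValueError(
                        f"{path}: spectrum ending at line {lineno} lacks PEPMASS/CHARGE"
                    )
                spectra.append(
                    MsmsSpectrum(
                        spectrum_id=title or f"spectrum_{len(spectra) + 1}",
                        precursor_mz=pepmass,
                        precursor_charge=charge,
                        peaks=np.array(peaks, dtype=float).reshape(-1, 2),
                    )
                )
                in_ions = False
            elif not in_ions:
                continue
            elif line.startswith("TITLE="):
                title = line[len("TITLE="):]
            elif line.startswith("PEPMASS="):
                pepmass = float(line[len("PEPMASS="):].split()[0])
            elif line.startswith("CHARGE="):
                charge = int(line[len("CHARGE="):].rstrip("+"))
            elif "=" in line:
                continue  # unrecognised header, tolerated
            else:
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: malformed peak line {line!r}")
                peaks.append((float(parts[0]), float(parts[1])))
    return spectra


def write_mgf(spectra: Iterable[MsmsSpectrum], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={sp.spectrum_id}\n")
            fh.write(f"PEPMASS={sp.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={sp.precursor_charge}+\n")
            for mz, inten in sp.peaks:
                fh.write(f"{mz:.5f} {inten:.2f}\n")
            fh.write("END IONS\n")
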