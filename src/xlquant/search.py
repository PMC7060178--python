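"""DSS cross-link candidate enumeration, fragment generation and MS/MS matching.

Candidate species:

* ``through_space`` — DSS bridge between lysines on two distinct tryptic
  peptides (alpha/beta segments).
* ``loop_link`` — bridge between two lysines inside one tryptic peptide.
* ``monolink`` — one reacted, one hydrolyzed NHS ester ("dead end").

A cross-linked lysine blocks tryptic cleavage, so a linked K may not be
the C-terminal cleavage residue of its peptide (unless it is the protein
C-terminus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .masses import MassConstants, mz_from_neutral_mass, neutral_mass_from_mz
from .mgf import MsmsSpectrum
from .seqdigest import DigestionRule, Peptide, ProteinRecord, peptide_mass, with_fixed_cys

__all__ = [
    "KINDS",
    "SearchParameters",
    "CrossLinkCandidate",
    "TheoreticalIon",
    "SpectrumMatch",
    "LinkRecord",
    "valid_link_sites",
    "enumerate_candidates",
    "candidate_mass",
    "theoretical_fragments",
    "match_spectrum",
    "classify_links",
    "classify_pair",
    "links_to_tsv",
]

KINDS = ("through_space", "loop_link", "monolink")


@dataclass(frozen=True)
class SearchParameters:
    """Matching tolerances and linker chemistry settings."""

    ms1_tol_ppm: float = 10.0
    ms2_tol_da: float = 0.3
    reactive_residue: str = "K"
    crosslink_mod: str = "dss_crosslink"
    monolink_mod: str = "dss_monolink"
    min_precursor_charge: int = 2  # singly charged precursors are excluded
    max_precursor_charge: int = 7
    max_fragment_charge: int = 3
    nterm_monolink: bool = True  # protein N-terminus is a valid monolink site
    nterm_crosslink: bool = False
    score_weight_ions: float = 0.7
    score_weight_intensity: float = 0.3

    def __post_init__(self) -> None:
        if self.ms1_tol_ppm <= 0 or self.ms2_tol_da <= 0:
            raise ValueError("tolerances must be positive")
        if self.min_precursor_charge > self.max_precursor_charge:
            raise ValueError("empty precursor charge range")
        if self.max_fragment_charge < 1:
            raise ValueError("empty fragment charge range")
        total = self.score_weight_ions + self.score_weight_intensity
        if abs(total - 1.0) > 1e-9:
            raise ValueError("score weights must sum to 1")


@dataclass(frozen=True)
class CrossLinkCandidate:
    """A candidate linked species with 1-based protein link site(s)."""

    kind: str
    alpha: Peptide
    beta: Peptide | None
    sites: tuple[int, ...]
    theoretical_mass: float

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown candidate kind {self.kind!r}")
        expected = {"through_space": 2, "loop_link": 2, "monolink": 1}[self.kind]
        if len(self.sites) != expected:
            raise ValueError(f"{self.kind} candidate needs {expected} site(s)")
        if (self.beta is not None) != (self.kind == "through_space"):
            raise ValueError("beta peptide present iff through_space")

    @property
    def site_pair(self) -> tuple[int, ...]:
        return tuple(sorted(self.sites))

    def label(self) -> str:
        sites = "-".join(f"K{s}" for s in sorted(self.sites))
        return f"{self.kind}:{sites}"


@dataclass(frozen=True)
class TheoreticalIon:
    segment: str  # "alpha" | "beta"
    series: str  # "b" | "y"
    index: int
    charge: int
    mz: float


@dataclass(frozen=True)
class MatchedIon:
    segment: str
    series: str
    index: int
    charge: int
    observed_mz: float
    error_da: float


@dataclass(frozen=True)
class SpectrumMatch:
    spectrum_id: str
    candidate: CrossLinkCandidate
    matched_ions: tuple[MatchedIon, ...]
    n_theoretical: int
    score: float
    precursor_error_ppm: float


def valid_link_sites(
    peptide: Peptide,
    protein_length: int,
    reactive_residue: str = "K",
) -> list[int]:
    """Reactive positions usable as link sites in this peptide.

    The C-terminal residue is excluded (a linked K cannot have been
    cleaved) unless the peptide ends at the protein C-terminus.
    """
    sites = []
    for pos in range(peptide.start, peptide.end + 1):
        if peptide.residue(pos) != reactive_residue:
            continue
        if pos == peptide.end and pos != protein_length:
            continue
        sites.append(pos)
    return sites


def candidate_mass(
    kind: str,
    alpha: Peptide,
    beta: Peptide | None = None,
    constants: MassConstants | None = None,
    params: SearchParameters | None = None,
    fixed_cys: bool = True,
) -> float:
    """Theoretical neutral mass of a candidate, fixed Cys mods included."""
    constants = constants or MassConstants()
    params = params or SearchParameters()
    prep = (lambda p: with_fixed_cys(p)) if fixed_cys else (lambda p: p)
    mass = peptide_mass(prep(alpha), constants)
    if kind == "through_space":
        if beta is None:
            raise ValueError("through_space needs a beta peptide")
        mass += peptide_mass(prep(beta), constants) + constants.mod(params.crosslink_mod)
    elif kind == "loop_link":
        mass += constants.mod(params.crosslink_mod)
    elif kind == "monolink":
        mass += constants.mod(params.monolink_mod)
    else:
        raise ValueError(f"unknown candidate kind {kind!r}")
    return mass


def enumerate_candidates(
    peptides: Sequence[Peptide],
    params: SearchParameters | None = None,
    kinds: Iterable[str] = KINDS,
    constants: MassConstants | None = None,
    protein_length: int | None = None,
) -> list[CrossLinkCandidate]:
    """All valid candidates of the requested kinds, deterministically ordered.

    Through-space pairs use non-overlapping peptide spans (intra-protein
    links between overlapping tryptic peptides are physically impossible)
    and are deduplicated as unordered pairs.
    """
    params = params or SearchParameters()
    constants = constants or MassConstants()
    kinds = set(kinds)
    unknown = kinds - set(KINDS)
    if unknown:
        raise ValueError(f"unknown kinds {sorted(unknown)}")
    if protein_length is None:
        protein_length = max((p.end for p in peptides), default=0)

    ordered = sorted(peptides, key=lambda p: (p.start, p.end))
    site_map = {
        (p.start, p.end): valid_link_sites(p, protein_length, params.reactive_residue)
        for p in ordered
    }
    out: list[CrossLinkCandidate] = []

    def add(kind: str, alpha: Peptide, beta: Peptide | None, sites: tuple[int, ...]) -> None:
        mass = candidate_mass(kind, alpha, beta, constants, params)
        out.append(CrossLinkCandidate(kind, alpha, beta, sites, mass))

    if "monolink" in kinds:
        for p in ordered:
            sites = list(site_map[(p.start, p.end)])
            if params.nterm_monolink and p.start == 1 and 1 not in sites:
                sites.insert(0, 1)
            for s in sites:
                add("monolink", p, None, (s,))
    if "loop_link" in kinds:
        for p in ordered:
            sites = site_map[(p.start, p.end)]
            for i in range(len(sites)):
                for j in range(i + 1, len(sites)):
                    add("loop_link", p, None, (sites[i], sites[j]))
    if "through_space" in kinds:
        for i, pa in enumerate(ordered):
            for pb in ordered[i + 1 :]:
                if pb.start <= pa.end:  # overlapping spans
                    continue
                for sa in site_map[(pa.start, pa.end)]:
                    for sb in site_map[(pb.start, pb.end)]:
                        add("through_space", pa, pb, (sa, sb))
    return out


def _segment_fragments(
    peptide: Peptide,
    constants: MassConstants,
    link_delta: dict[int, float],
    skip_between: tuple[int, int] | None,
) -> tuple[list[tuple[str, int, float]], float]:
    """Neutral b/y fragment masses for one segment.

    ``link_delta`` maps 1-based protein positions to extra mass carried by
    fragments containing that position. ``skip_between`` suppresses
    fragments containing exactly one of a loop-linked site pair.
    """
    pep = with_fixed_cys(peptide)
    n = len(pep)
    res = np.array([constants.residue(aa) for aa in pep.sequence])
    extra = np.zeros(n)
    for pos, name in pep.mods:
        extra[pos - pep.start] += constants.mod(name)
    neutral = res.sum() + extra.sum() + constants.water + sum(link_delta.values())

    def span_delta(lo: int, hi: int) -> float | None:
        """Extra mass for a fragment covering local residues [lo, hi] (0-based)."""
        covered = [p for p in link_delta if lo <= p - pep.start <= hi]
        if skip_between is not None:
            p1, p2 = skip_between
            has1 = lo <= p1 - pep.start <= hi
            has2 = lo <= p2 - pep.start <= hi
            if has1 != has2:
                return None  # bridge would be severed: fragment not emitted
            bridge = constants.mod("dss_crosslink") if has1 and has2 else 0.0
            return sum(link_delta[p] for p in covered) + bridge
        return sum(link_delta[p] for p in covered)

    prefix = np.cumsum(res + extra)
    frags: list[tuple[str, int, float]] = []
    for i in range(1, n):
        d = span_delta(0, i - 1)
        if d is not None:
            frags.append(("b", i, prefix[i - 1] + d))
        d = span_delta(n - i, n - 1)
        if d is not None:
            frags.append(("y", i, prefix[n - 1] - prefix[n - i - 1] + constants.water + d))
    return frags, neutral


def theoretical_fragments(
    candidate: CrossLinkCandidate,
    params: SearchParameters | None = None,
    constants: MassConstants | None = None,
    charges: Sequence[int] | None = None,
) -> list[TheoreticalIon]:
    """b/y ions for each segment of a candidate, as m/z at the given charges.

    Through-space fragments containing the link site carry the intact
    partner peptide plus the bridge; loop-link fragments between the two
    sites are not emitted; monolink fragments carry the hydrolyzed linker.
    """
    params = params or SearchParameters()
    constants = constants or MassConstants()
    if charges is None:
        charges = list(range(1, params.max_fragment_charge + 1))

    segments: list[tuple[str, Peptide, dict[int, float], tuple[int, int] | None]] = []
    if candidate.kind == "through_space":
        assert candidate.beta is not None
        bridge = constants.mod(params.crosslink_mod)
        mass_a = peptide_mass(with_fixed_cys(candidate.alpha), constants)
        mass_b = peptide_mass(with_fixed_cys(candidate.beta), constants)
        site_a, site_b = candidate.sites
        segments.append(("alpha", candidate.alpha, {site_a: mass_b + bridge}, None))
        segments.append(("beta", candidate.beta, {site_b: mass_a + bridge}, None))
    elif candidate.kind == "loop_link":
        p1, p2 = sorted(candidate.sites)
        segments.append(("alpha", candidate.alpha, {}, (p1, p2)))
    else:  # monolink
        (site,) = candidate.sites
        segments.append(("alpha", candidate.alpha, {site: constants.mod(params.monolink_mod)}, None))

    ions: list[TheoreticalIon] = []
    for name, pep, delta, skip in segments:
        frags, _ = _segment_fragments(pep, constants, delta, skip)
        for series, index, neutral in frags:
            for z in charges:
                ions.append(
                    TheoreticalIon(name, series, index, z, mz_from_neutral_mass(neutral, z, constants.proton))
                )
    return ions


def match_spectrum(
    spectrum: MsmsSpectrum,
    candidates: Sequence[CrossLinkCandidate],
    params: SearchParameters | None = None,
    constants: MassConstants | None = None,
) -> list[SpectrumMatch]:
    """Score candidates against one spectrum, best first.

    Candidates are pre-filtered by precursor mass (ppm window); observed
    peaks are assigned greedily, nearest m/z first, each peak at most once.
    Score = w_ions * (matched / theoretical ions) + w_int * (explained /
    total intensity).
    """
    params = params or SearchParameters()
    constants = constants or MassConstants()
    if spectrum.peaks.shape[0] < 1:
        raise ValueError(f"spectrum {spectrum.spectrum_id} has no peaks")
    if spectrum.precursor_charge < params.min_precursor_charge:
        raise ValueError(
            f"precursor charge {spectrum.precursor_charge} below minimum "
            f"{params.min_precursor_charge}"
        )
    observed_mass = neutral_mass_from_mz(
        spectrum.precursor_mz, spectrum.precursor_charge, constants.proton
    )
    frag_charges = list(
        range(1, max(1, min(params.max_fragment_charge, spectrum.precursor_charge - 1)) + 1)
    )
    mz = spectrum.mz
    intensity = spectrum.intensity
    total_intensity = float(intensity.sum())

    results: list[tuple[float, float, int, SpectrumMatch]] = []
    for order, cand in enumerate(candidates):
        ppm = (observed_mass - cand.theoretical_mass) / cand.theoretical_mass * 1e6
        if abs(ppm) > params.ms1_tol_ppm:
            continue
        ions = theoretical_fragments(cand, params, constants, frag_charges)
        # all (theoretical, peak) pairs within tolerance, nearest first
        pairs: list[tuple[float, int, int]] = []
        for t_idx, ion in enumerate(ions):
            lo = np.searchsorted(mz, ion.mz - params.ms2_tol_da, side="left")
            hi = np.searchsorted(mz, ion.mz + params.ms2_tol_da, side="right")
            for p_idx in range(lo, hi):
                pairs.append((abs(mz[p_idx] - ion.mz), t_idx, p_idx))
        pairs.sort()
        used_peaks: set[int] = set()
        used_ions: set[int] = set()
        matched: list[MatchedIon] = []
        for _, t_idx, p_idx in pairs:
            if t_idx in used_ions or p_idx in used_peaks:
                continue
            used_ions.add(t_idx)
            used_peaks.add(p_idx)
            ion = ions[t_idx]
            matched.append(
                MatchedIon(ion.segment, ion.series, ion.index, ion.charge,
                           float(mz[p_idx]), float(mz[p_idx] - ion.mz))
            )
        if not ions:
            continue
        frac_ions = len(matched) / len(ions)
        frac_int = (
            float(intensity[sorted(used_peaks)].sum()) / total_intensity
            if total_intensity > 0
            else 0.0
        )
        score = params.score_weight_ions * frac_ions + params.score_weight_intensity * frac_int
        match = SpectrumMatch(
            spectrum_id=spectrum.spectrum_id,
            candidate=cand,
            matched_ions=tuple(matched),
            n_theoretical=len(ions),
            score=score,
            precursor_error_ppm=ppm,
        )
        results.append((-score, abs(ppm), order, match))
    results.sort(key=lambda r: (r[0], r[1], r[2]))
    return [r[3] for r in results]


@dataclass(frozen=True)
class LinkRecord:
    """One unique residue-level link aggregated over accepted matches."""

    kind: str
    sites: tuple[int, ...]
    domains: tuple[str, ...]
    best_score: float
    n_spectra: int


def classify_links(
    matches: Sequence[SpectrumMatch],
    protein: ProteinRecord,
) -> tuple[list[LinkRecord], dict[str, int]]:
    """Collapse accepted matches to unique links and tally per kind."""
    by_link: dict[tuple[str, tuple[int, ...]], list[SpectrumMatch]] = {}
    for m in matches:
        for site in m.candidate.sites:
            if not 1 <= site <= len(protein):
                raise ValueError(
                    f"link site {site} outside protein {protein.id} (1-{len(protein)})"
                )
        by_link.setdefault((m.candidate.kind, m.candidate.site_pair), []).append(m)
    records = [
        LinkRecord(
            kind=kind,
            sites=sites,
            domains=tuple(protein.domain_of(s) for s in sites),
            best_score=max(m.score for m in ms),
            n_spectra=len(ms),
        )
        for (kind, sites), ms in sorted(by_link.items())
    ]
    tallies = {kind: 0 for kind in KINDS}
    for rec in records:
        tallies[rec.kind] += 1
    return records, tallies


def classify_pair(
    protein: ProteinRecord,
    site1: int,
    site2: int,
    rule: DigestionRule | None = None,
    reactive_residue: str = "K",
) -> str:
    """Decide whether a residue pair is a loop-link or a through-space link.

    The pair is a loop-link iff both sites fit inside one fully tryptic
    peptide reachable with at most ``rule.max_missed_cleavages`` missed
    cleavages, where the linked residues themselves are blocked (they
    neither terminate the peptide, unless at the protein C-terminus, nor
    count as missed cleavages). Otherwise it is through-space.
    """
    rule = rule or DigestionRule()
    for site in (site1, site2):
        if protein.residue(site) != reactive_residue:
            raise ValueError(
                f"site {site} is {protein.residue(site)!r}, not {reactive_residue!r}"
            )
    if site1 == site2:
        raise ValueError("a link needs two distinct sites")
    p1, p2 = sorted((site1, site2))
    length = len(protein)
    sites = rule.cleavage_sites(protein.sequence)
    bounds = [0] + sites + [length]
    linked = {p1, p2}
    for s_bound in bounds:
        start = s_bound + 1
        if start > p1:
            break
        for e_bound in bounds:
            if e_bound < p2:
                continue
            if e_bound in linked and e_bound != length:
                continue  # cleavage at a blocked (linked) lysine
            if e_bound - s_bound > rule.max_length:
                break
            internal = [x for x in sites if start <= x < e_bound and x not in linked]
            if len(internal) <= rule.max_missed_cleavages:
                return "loop_link"
            break  # larger spans only add missed cleavages
    return "through_space"


def links_to_tsv(records: Sequence[LinkRecord], path: str | Path, protein_id: str) -> None:
    """Write links as a 5-column TSV (protein, site1, site2-or-dash, kind, score)."""
    with open(path, "w") as fh:
        fh.write("protein\tsite1\tsite2\tkind\tscore\n")
        for rec in records:
            site2 = str(rec.sites[1]) if len(rec.sites) == 2 else "-"
            fh.write(
                f"{protein_id}\t{rec.sites[0]}\t{site2}\t{rec.kind}\t{rec.best_score:.4f}\n"
            )
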