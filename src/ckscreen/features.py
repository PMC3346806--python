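"""Chemokine sequence features: masses, isotope envelopes, motifs, cysteines.

Mass spectrometry distinguishes oxidized from reduced cysteines: each formed
disulfide bond removes two hydrogen atoms, lowering the monoisotopic mass by
2 x 1.0078250319 Da. Comparing a measured deconvoluted monoisotopic mass with
the theoretical mass computed for 0..n_Cys/2 bonds therefore counts the
disulfide bonds actually formed. The isotope envelope is obtained by
polynomial convolution of the elemental isotope distributions of the
sequence's molecular formula.

Motif scanning covers features commonly used to support a chemokine
annotation: glycosaminoglycan (GAG) attachment sites (serine-glycine core
with a basic flank), the RGD integrin-binding motif and N-glycosylation
sequons N-[^P]-[ST].
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from pyteomics import mass as pmass

__all__ = [
    "MassResult",
    "IsotopePattern",
    "MotifHit",
    "CysteineStats",
    "DEFAULT_MOTIFS",
    "monoisotopic_mass",
    "isotope_pattern",
    "scan_motifs",
    "cysteine_stats",
]

H_MASS = pmass.nist_mass["H"][1][0]  # 1.00782503207 Da
WATER_MASS = pmass.calculate_mass(formula="H2O")

# Default motif set. The GAG-attachment pattern is a serine-glycine core with
# an optional basic residue on the N-terminal flank; it is an editable
# stand-in for a served linear-motif class and matches e.g. RSGG.
DEFAULT_MOTIFS = {
    "GAG_attachment": r"[RK]?SG[GSA]",
    "RGD": r"RGD",
    "N_glycosylation": r"N[^P][ST]",
}


@dataclass
class MassResult:
    mass: float                  # monoisotopic, Da
    formula: dict                # element -> count (after disulfide correction)
    n_disulfides: int
    delta: Optional[float] = None  # experimental - theoretical, Da

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError("non-positive mass")


@dataclass
class IsotopePattern:
    peaks: list  # [(mass Da, relative abundance)], max abundance = 1

    def __post_init__(self):
        masses = [m for m, _ in self.peaks]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise ValueError("isotope peak masses must be strictly increasing")

    @property
    def monoisotopic(self) -> float:
        return self.peaks[0][0]


class MotifHit(NamedTuple):
    name: str
    pattern: str
    start: int   # 1-based inclusive
    end: int
    matched: str


class CysteineStats(NamedTuple):
    count: int
    positions: tuple       # 1-based
    separations: tuple     # j - i over all position pairs i < j


def _check_sequence(sequence: str, n_disulfides: int):
    bad = [i + 1 for i, aa in enumerate(sequence) if aa == "X"]
    if bad:
        raise ValueError(f"sequence contains X at positions {bad}")
    unknown = set(sequence) - set(pmass.std_aa_comp) - set("ACDEFGHIKLMNPQRSTVWY")
    if unknown:
        raise ValueError(f"non-standard residues {sorted(unknown)}")
    n_cys = sequence.count("C")
    if n_cys < 2 * n_disulfides:
        raise ValueError(
            f"{n_disulfides} disulfides need {2 * n_disulfides} cysteines; "
            f"sequence has {n_cys}"
        )


def _composition(sequence: str, n_disulfides: int) -> pmass.Composition:
    comp = pmass.Composition(sequence=sequence)  # includes terminal H2O
    comp["H"] -= 2 * n_disulfides
    return comp


def monoisotopic_mass(sequence: str, n_disulfides: int = 0,
                      experimental_mass: Optional[float] = None) -> MassResult:
    """Theoretical monoisotopic mass with free, unmodified termini; each
    disulfide bond subtracts two hydrogens."""
    _check_sequence(sequence, n_disulfides)
    comp = _composition(sequence, n_disulfides)
    m = pmass.calculate_mass(composition=comp)
    delta = None if experimental_mass is None else experimental_mass - m
    return MassResult(mass=m, formula=dict(comp), n_disulfides=n_disulfides,
                      delta=delta)


def _element_isotopes(element: str):
    """Sorted (mass, abundance) pairs for an element's stable isotopes."""
    data = pmass.nist_mass[element]
    iso = [(m, ab) for k, (m, ab) in data.items() if k != 0 and ab > 0]
    iso.sort()
    return iso


def isotope_pattern(sequence: str, n_disulfides: int = 0,
                    abundance_floor: float = 1e-6,
                    max_peaks: int = 60) -> IsotopePattern:
    """Aggregated (nucleon-resolved) isotope envelope by iterative polynomial
    convolution of elemental isotope distributions.

    Peaks are indexed by the number of extra neutrons relative to the
    monoisotopic species; each peak mass is the abundance-weighted mean of
    the isotopologues it aggregates. The first peak equals the monoisotopic
    mass and abundances are normalized to a maximum of 1.
    """
    _check_sequence(sequence, n_disulfides)
    comp = _composition(sequence, n_disulfides)

    # distribution as (abundance[k], mass_moment[k]) over extra-neutron count k
    prob = np.array([1.0])
    moment = np.array([0.0])
    mono = 0.0
    for element, count in comp.items():
        if count == 0:
            continue
        iso = _element_isotopes(element)
        m0 = iso[0][0]
        mono += m0 * count
        k_offsets = [int(round(m - m0)) for m, _ in iso]
        size = max(k_offsets) + 1
        e_prob = np.zeros(size)
        e_mom = np.zeros(size)
        for (m, ab), k in zip(iso, k_offsets):
            e_prob[k] += ab
            e_mom[k] += ab * (m - m0)
        # normalize abundances of the element distribution
        tot = e_prob.sum()
        e_prob /= tot
        e_mom /= tot
        # exponentiation by repeated convolution (binary powering)
        p_pow, m_pow = np.array([1.0]), np.array([0.0])
        base_p, base_m = e_prob, e_mom
        n = count
        while n > 0:
            if n & 1:
                m_pow = np.convolve(p_pow, base_m) + np.convolve(m_pow, base_p)
                p_pow = np.convolve(p_pow, base_p)
                m_pow = m_pow[:max_peaks]
                p_pow = p_pow[:max_peaks]
            base_m = 2 * np.convolve(base_p, base_m)
            base_p = np.convolve(base_p, base_p)
            base_m = base_m[:max_peaks]
            base_p = base_p[:max_peaks]
            n >>= 1
        moment = np.convolve(prob, m_pow) + np.convolve(moment, p_pow)
        prob = np.convolve(prob, p_pow)
        moment = moment[:max_peaks]
        prob = prob[:max_peaks]

    peaks = []
    top = prob.max()
    for k in range(len(prob)):
        if prob[k] / top < abundance_floor:
            continue
        mean_offset = moment[k] / prob[k] if prob[k] > 0 else float(k)
        peaks.append((mono + mean_offset, prob[k] / top))
    return IsotopePattern(peaks=peaks)


def scan_motifs(sequence: str, motif_set: dict = None) -> list:
    """All non-overlapping matches per motif, 1-based inclusive spans."""
    motifs = DEFAULT_MOTIFS if motif_set is None else motif_set
    hits = []
    for name, pattern in motifs.items():
        for m in re.finditer(pattern, sequence):
            hits.append(
                MotifHit(name=name, pattern=pattern,
                         start=m.start() + 1, end=m.end(), matched=m.group())
            )
    hits.sort(key=lambda h: (h.start, h.name))
    return hits


def cysteine_stats(sequence: str) -> CysteineStats:
    """Cysteine count, 1-based positions and all pairwise separations."""
    positions = tuple(i + 1 for i, aa in enumerate(sequence) if aa == "C")
    separations = tuple(
        positions[b] - positions[a]
        for a in range(len(positions))
        for b in range(a + 1, len(positions))
    )
    return CysteineStats(count=len(positions), positions=positions,
                         separations=separations)
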