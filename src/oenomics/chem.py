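"""Molecular-formula arithmetic, adduct m/z, isotope envelopes and quality scores.

Every screening decision downstream consumes one of the quantities computed
here: the theoretical m/z of a compound's negative-mode adduct, the signed
mass error in mDa, an isotopic-pattern fit score (an mSigma-like statistic,
0 = perfect agreement) and the chromatographic peak score (area/intensity).

Element monoisotopic masses and isotope abundances are pinned to a bundled
IUPAC/CODATA table (``data/isotopes.tsv``) so results are bit-stable.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from pyteomics.mass import Composition

__all__ = [
    "MolecularFormula",
    "AdductSpec",
    "IsotopePattern",
    "ADDUCTS",
    "PROTON_MASS",
    "FormulaError",
    "InsufficientEnvelopeError",
    "monoisotopic_mass",
    "adduct_mz",
    "mass_error_mda",
    "theoretical_isotope_pattern",
    "isotopic_fit_msigma",
    "peak_score",
]

#: Mass of a proton in Da.  Negative-mode deprotonation deltas are multiples of
#: this constant; electron bookkeeping is folded into it (sub-0.1 mDa effect,
#: below the instrument accuracy modeled here).
PROTON_MASS = 1.00727646688


class FormulaError(ValueError):
    """Raised for malformed formulas or elements without tabulated masses."""


class InsufficientEnvelopeError(ValueError):
    """Raised when an observed isotope envelope has too few peaks to score."""


@functools.lru_cache(maxsize=1)
def _isotope_table() -> dict[str, list[tuple[int, float, float]]]:
    """Bundled table: element -> [(mass number, mass, abundance), ...]."""
    table: dict[str, list[tuple[int, float, float]]] = {}
    text = (resources.files("oenomics") / "data" / "isotopes.tsv").read_text()
    for line in text.strip().splitlines()[1:]:
        element, mass_number, mass, abundance = line.split("\t")
        table.setdefault(element, []).append(
            (int(mass_number), float(mass), float(abundance))
        )
    for isotopes in table.values():
        isotopes.sort()
    return table


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition, e.g. catechin ``C15H14O6``.

    Only elements present in the bundled constants table (CHNOPS) are
    accepted; counts must be positive.
    """

    element_counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.element_counts:
            raise FormulaError("formula must contain at least one element")
        known = _isotope_table()
        for element, count in self.element_counts:
            if element not in known:
                raise FormulaError(f"no tabulated masses for element {element!r}")
            if count <= 0:
                raise FormulaError(f"non-positive count for element {element!r}")

    @classmethod
    def parse(cls, formula: str) -> "MolecularFormula":
        """Parse a Hill-notation formula string such as ``'C30H26O12'``."""
        try:
            composition = Composition(formula=formula)
        except Exception as exc:  # pyteomics raises PyteomicsError
            raise FormulaError(f"cannot parse formula {formula!r}") from exc
        return cls(tuple(sorted(composition.items())))

    @property
    def counts(self) -> dict[str, int]:
        return dict(self.element_counts)

    def __str__(self) -> str:
        order = sorted(self.counts, key=lambda e: (e != "C", e != "H", e))
        return "".join(
            f"{el}{n if n > 1 else ''}" for el, n in ((e, self.counts[e]) for e in order)
        )


@dataclass(frozen=True)
class AdductSpec:
    """A negative-mode adduct: name, neutral-mass offset in Da, and charge."""

    name: str
    mass_delta: float
    charge: int = -1


#: Supported negative-mode adducts.  ``[M-2H]-`` applies to flavylium cations
#: (anthocyanins) which lose two protons to yield a singly charged anion;
#: ``[M+H2O-H]-`` is the hydrated pseudomolecular ion seen for e.g.
#: quercetin dimethyl ether glucoside.
ADDUCTS: dict[str, AdductSpec] = {
    "[M-H]-": AdductSpec("[M-H]-", -PROTON_MASS),
    "[M-2H]-": AdductSpec("[M-2H]-", -2.0 * PROTON_MASS),
    "[M+H2O-H]-": AdductSpec("[M+H2O-H]-", 18.0105646863 - PROTON_MASS),
}


@dataclass(frozen=True)
class IsotopePattern:
    """Isotope envelope: (m/z offset from monoisotopic, intensity rel. to base).

    The first peak is the monoisotopic (A) peak at offset 0 and intensity 1.
    """

    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("empty isotope pattern")
        offset0, intensity0 = self.peaks[0]
        if offset0 != 0.0 or intensity0 != 1.0:
            raise ValueError("first isotope peak must be (0, 1)")
        offsets = [p[0] for p in self.peaks]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("isotope peak offsets must be strictly increasing")
        if any(not (0.0 < p[1] <= 1.0) for p in self.peaks):
            raise ValueError("relative intensities must lie in (0, 1]")

    @property
    def relative_intensities(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Monoisotopic (principal-isotope) mass of ``formula`` in Da."""
    table = _isotope_table()
    return sum(
        table[element][0][1] * count for element, count in formula.element_counts
    )


def adduct_mz(formula: MolecularFormula, adduct: AdductSpec | str) -> float:
    """Theoretical m/z of ``formula`` under ``adduct`` (name or spec)."""
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise KeyError(f"unsupported adduct {adduct!r}") from None
    return (monoisotopic_mass(formula) + adduct.mass_delta) / abs(adduct.charge)


def mass_error_mda(observed_mz: float, theoretical_mz: float) -> float:
    """Signed mass error (observed − theoretical) in mDa."""
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("m/z values must be positive")
    return (observed_mz - theoretical_mz) * 1000.0


@functools.lru_cache(maxsize=4096)
def theoretical_isotope_pattern(
    formula: MolecularFormula, n_peaks: int = 3
) -> IsotopePattern:
    """Aggregated isotope envelope (A, A+1, A+2, ...) for ``formula``.

    Isotopologues are grouped by nominal mass shift — appropriate for QToF
    resolving power, where the fine structure within an A+1 cluster is not
    resolved.  Intensities are computed by convolving per-element shift
    distributions and normalized to the base (monoisotopic) peak.
    """
    if n_peaks < 2:
        raise ValueError("n_peaks must be >= 2")
    table = _isotope_table()
    dist = np.zeros(n_peaks)
    dist[0] = 1.0
    for element, count in formula.element_counts:
        isotopes = table[element]
        base_number = isotopes[0][0]
        atom = np.zeros(n_peaks)
        for mass_number, _mass, abundance in isotopes:
            shift = mass_number - base_number
            if shift < n_peaks:
                atom[shift] += abundance
        for _ in range(count):
            dist = np.convolve(dist, atom)[:n_peaks]
    base = dist[0]
    # nominal bins sit ~1 Da apart; the 13C spacing is used as the nominal
    # offset since carbon dominates A+1/A+2 for CHNOPS metabolites
    peaks = tuple(
        (shift * 1.0033548, float(dist[shift] / base))
        for shift in range(n_peaks)
        if dist[shift] > 0
    )
    return IsotopePattern(peaks)


def isotopic_fit_msigma(
    theoretical: IsotopePattern, observed: IsotopePattern, n_compare: int = 3
) -> float:
    """mSigma-like isotopic fit score: 0 = perfect, larger = worse.

    Defined as 1000 × the root-mean-square deviation between base-peak
    normalized relative intensities over the non-base peaks of the common
    prefix, capped at the first ``n_compare`` isotope peaks.  The scale makes
    the conventional acceptance thresholds (≤50 for targets, <100 for
    suspects) meaningful for realistic envelope noise.
    """
    if len(observed.peaks) < 2:
        raise InsufficientEnvelopeError(
            "observed envelope has a single peak; isotopic fit undefined"
        )
    if len(theoretical.peaks) < 2:
        raise InsufficientEnvelopeError("theoretical envelope has a single peak")
    k = min(len(theoretical.peaks), len(observed.peaks), n_compare)
    theo = theoretical.relative_intensities[1:k]
    obs = observed.relative_intensities[1:k]
    return float(1000.0 * np.sqrt(np.mean((obs - theo) ** 2)))


def peak_score(area: float, intensity: float) -> float:
    """Chromatographic peak score: peak area divided by peak intensity.

    Well-shaped LC peaks give values of roughly 5–20; spikes and noise give
    low values.  Suspect screening requires > 4.
    """
    if intensity <= 0:
        raise ValueError("peak intensity must be positive for a peak score")
    return area / intensity
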