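"""Synthetic two-variety wine study generator.

Emulates the statistical structure of a 46-sample LC-HRMS wine-authentication
study: 27 Agiorgitiko + 19 Xinomavro samples over two vintages, pooled QC
injections, procedural blanks every 10 injections, an ethyl vanillin internal
standard at 2 mg/L, and 7-point calibration series spanning 0.1-20 mg/L in
solvent and in matrix.

The default compound panel carries 22 quantified phenolic targets with
class-conditional concentration means on the published Table-1 scale, the 17
discriminant markers (three of which are targets) with their class
directions, fermentation/terroir-confounded compounds (organic acids,
tyrosol and resveratrol glycosides) and class-neutral suspects.  Decoy
features with isotope envelopes inconsistent with any panel formula exercise
false-positive control.

Within-class concentrations are log-normal (concentration ranges in wine are
right-skewed); the vintage effect is a shared multiplicative shift.  MS
response factors scale as ``5e4 x (10 / mean)^0.9`` so that IS-normalized
peak areas span roughly 1.5 orders of magnitude across the panel - the
compression implied by published OPLS-DA covariances, where |p1| varies only
~3.5x over compounds whose concentrations vary ~100x.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import ADDUCTS, IsotopePattern, MolecularFormula, adduct_mz, theoretical_isotope_pattern
from .screening import CompoundEntry, PeakFeature

__all__ = [
    "StudyDesign",
    "NoiseConfig",
    "CompoundSpec",
    "StudyData",
    "CalibrationData",
    "LOSS_MASSES",
    "DEFAULT_REMOVAL_LIST",
    "default_panel_table",
    "build_compound_panel",
    "default_panel",
    "generate_study",
    "generate_calibration_series",
]

#: Neutral-loss masses (Da) used to derive qualifier MS/MS fragments.
LOSS_MASSES = {
    "H2O": 18.010565,
    "CO": 27.994915,
    "CO2": 43.989829,
    "CH2O": 30.010565,
    "CH3": 15.023475,
    "C2H4": 28.031300,
    "C2H4+CO2": 72.021129,
    "hexose": 162.052824,
    "pentose": 132.042259,
}

#: Variables removed before supervised modeling: organic acids (vintage,
#: vineyard and winemaking driven) and fermentation/defense-induced
#: tyrosol and resveratrol glycosides.
DEFAULT_REMOVAL_LIST = (
    "Malic acid",
    "Tartaric acid",
    "Lactic acid",
    "Citric acid",
    "Tyrosol glucoside",
    "Piceid",
)


@dataclass(frozen=True)
class StudyDesign:
    """Sample-level design of the synthetic study."""

    n_class_a: int = 27
    n_class_b: int = 19
    class_a: str = "Agiorgitiko"
    class_b: str = "Xinomavro"
    vintages: tuple[int, ...] = (2017, 2018)
    n_qc: int = 5
    blank_every: int = 10
    is_concentration: float = 2.0  # mg/L
    is_response_factor: float = 5.0e4  # area per mg/L
    calibration_levels: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0)
    n_decoys_per_sample: int = 15
    n_blank_features: int = 12

    def __post_init__(self) -> None:
        if min(self.n_class_a, self.n_class_b, self.n_qc, self.blank_every) <= 0:
            raise ValueError("design counts must be positive")
        levels = np.asarray(self.calibration_levels)
        if len(levels) < 5 or np.any(np.diff(levels) <= 0):
            raise ValueError("calibration levels must be >= 5 and strictly increasing")


@dataclass(frozen=True)
class NoiseConfig:
    """Noise amplitudes of the simulated measurement process."""

    mz_sd_mda: float = 0.5
    rt_sd_min: float = 0.05
    envelope_rel_sd: float = 0.05
    injection_cv: float = 0.03
    qc_cv: float = 0.02
    calibration_cv: float = 0.02
    fragment_detection: float = 0.95
    fragment_mz_sd_mda: float = 1.0
    effect_multiplier: float = 1.0  # 0 = no class separation, 1 = Table-1 scale

    @classmethod
    def zero(cls) -> "NoiseConfig":
        """Noiseless limit (class effects retained)."""
        return cls(
            mz_sd_mda=0.0, rt_sd_min=0.0, envelope_rel_sd=0.0, injection_cv=0.0,
            qc_cv=0.0, calibration_cv=0.0, fragment_detection=1.0,
            fragment_mz_sd_mda=0.0,
        )


@dataclass(frozen=True)
class CompoundSpec:
    """Generator-side description of one panel compound."""

    entry: CompoundEntry
    mean_a: float  # Agiorgitiko-class mean (mg/L for targets; abundance units)
    mean_b: float
    cv_within: float
    vintage_shift: float
    response_factor: float
    detection_probability: float = 0.95
    is_marker: bool = False
    internal_standard: bool = False

    def __post_init__(self) -> None:
        if self.mean_a < 0 or self.mean_b < 0:
            raise ValueError(f"{self.entry.name}: negative class mean")
        if self.cv_within <= 0 or self.response_factor <= 0:
            raise ValueError(f"{self.entry.name}: cv_within and response_factor must be > 0")


# name, formula, adduct, role, class, rt (min), descriptor (blank = (rt-1)/1.5),
# mean_a, mean_b, cv, vintage_shift, losses, fragments, marker
_PANEL_ROWS = [
    # -- quantified targets (class means in mg/L on the published scale) --
    ("Gallic acid", "C7H6O5", "[M-H]-", "target", "Hydroxybenzoic acids", 1.20, None, 26.4, 43.0, 0.30, 0.15, "CO2;H2O", "", 0),
    ("Protocatechuic acid", "C7H6O4", "[M-H]-", "target", "Hydroxybenzoic acids", 1.80, None, 3.0, 1.3, 0.35, 0.15, "CO2", "108.0217", 0),
    ("4-Hydroxybenzoic acid", "C7H6O3", "[M-H]-", "target", "Hydroxybenzoic acids", 2.40, None, 0.52, 0.34, 0.40, 0.15, "CO2", "65.0397", 0),
    ("Gentisic acid", "C7H6O4", "[M-H]-", "target", "Hydroxybenzoic acids", 2.60, None, 0.481, 0.43, 0.35, 0.15, "CO2", "107.0139", 0),
    ("Hydroxytyrosol", "C8H10O3", "[M-H]-", "target", "Phenylethanoids", 2.20, None, 0.992, 2.7, 0.20, 0.15, "CH2O", "95.0503", 0),
    ("Tyrosol", "C8H10O2", "[M-H]-", "target", "Phenylethanoids", 2.70, None, 28.0, 43.0, 0.30, 0.15, "CH2O", "93.0710", 0),
    ("Caffeic acid", "C9H8O4", "[M-H]-", "target", "Hydroxycinnamic acids", 2.90, None, 2.4, 2.4, 0.40, 0.15, "CO2;H2O", "", 0),
    ("Vanillic acid", "C8H8O4", "[M-H]-", "target", "Hydroxybenzoic acids", 2.75, None, 1.9, 0.99, 0.35, 0.15, "CH3;CO2", "", 0),
    ("Syringic acid", "C9H10O5", "[M-H]-", "target", "Hydroxybenzoic acids", 3.05, None, 4.7, 2.1, 0.30, 0.15, "CH3;CO2", "", 0),
    ("Catechin", "C15H14O6", "[M-H]-", "target", "Flavan-3-ols", 3.00, None, 27.0, 65.0, 0.20, 0.15, "CO2;H2O", "", 1),
    ("Epicatechin", "C15H14O6", "[M-H]-", "target", "Flavan-3-ols", 3.45, None, 15.0, 38.0, 0.25, 0.15, "CO2;H2O", "", 1),
    ("Vanillin", "C8H8O3", "[M-H]-", "target", "Benzaldehydes", 3.20, None, 0.05, 0.05, 0.30, 0.15, "CH3;CO", "", 0),
    ("p-Coumaric acid", "C9H8O3", "[M-H]-", "target", "Hydroxycinnamic acids", 3.35, None, 1.80, 1.02, 0.45, 0.15, "CO2", "117.0346", 0),
    ("Ferulic acid", "C10H10O4", "[M-H]-", "target", "Hydroxycinnamic acids", 3.70, None, 0.22, 0.34, 0.40, 0.15, "CH3;CO2", "", 0),
    ("Salicylic acid", "C7H6O3", "[M-H]-", "target", "Hydroxybenzoic acids", 3.90, None, 0.67, 0.26, 0.30, 0.15, "CO2;H2O", "", 1),
    ("Taxifolin", "C15H12O7", "[M-H]-", "target", "Flavanonols", 4.30, None, 0.10, 0.11, 0.30, 0.15, "H2O", "125.0244", 0),
    ("Myricetin", "C15H10O8", "[M-H]-", "target", "Flavonols", 4.90, None, 2.4, 4.5, 0.40, 0.15, "H2O", "151.0037", 0),
    ("Resveratrol", "C14H12O3", "[M-H]-", "target", "Stilbenes", 5.10, None, 1.4, 0.78, 0.45, 0.15, "CO2;H2O", "", 0),
    ("Quercetin", "C15H10O7", "[M-H]-", "target", "Flavonols", 5.60, None, 2.7, 6.2, 0.35, 0.15, "", "151.0037;178.9986", 0),
    ("Eriodictyol", "C15H12O6", "[M-H]-", "target", "Flavanones", 5.90, None, 0.05, 0.05, 0.30, 0.15, "", "135.0452;151.0037", 0),
    ("Luteolin", "C15H10O6", "[M-H]-", "target", "Flavones", 6.00, None, 0.04, 0.04, 0.30, 0.15, "", "133.0295;151.0037", 0),
    ("Naringenin", "C15H12O5", "[M-H]-", "target", "Flavanones", 6.20, None, 0.10, 0.072, 0.30, 0.15, "", "119.0502;151.0037", 0),
    # -- suspect-list markers (abundance units on the Table-1 scale) --
    ("Ethyl gallate", "C9H10O5", "[M-H]-", "suspect", "Benzoates", 4.10, None, 6.0, 14.0, 0.25, 0.15, "C2H4;C2H4+CO2", "", 1),
    ("Indolelactic acid glucoside", "C17H21NO8", "[M-H]-", "suspect", "Amines", 3.48, 1.80, 4.0, 10.0, 0.25, 0.15, "hexose", "186.0560;142.0635", 1),
    ("Ethyl coumarate", "C11H12O3", "[M-H]-", "suspect", "Cinnamates", 5.95, None, 8.0, 3.2, 0.25, 0.15, "C2H4;C2H4+CO2", "", 1),
    ("L-Proline", "C5H9NO2", "[M-H]-", "suspect", "Amino acids", 1.38, None, 28.0, 72.0, 0.25, 0.15, "", "70.0293;68.0500", 1),
    ("Quercetin 3,3'-dimethyl ether 4'-glucoside", "C23H24O12", "[M+H2O-H]-", "suspect", "Flavonols", 3.30, None, 7.0, 2.8, 0.25, 0.15, "hexose;H2O", "", 1),
    ("Coutaric acid", "C13H12O8", "[M-H]-", "suspect", "Cinnamates", 1.75, 0.50, 9.0, 3.6, 0.25, 0.15, "", "149.0092;163.0401", 1),
    ("(Iso)leucine", "C6H13NO2", "[M-H]-", "suspect", "Amino acids", 1.92, None, 42.0, 16.0, 0.25, 0.15, "", "84.0444;69.0340", 1),
    ("Procyanidin dimer 1", "C30H26O12", "[M-H]-", "suspect", "Flavan-3-ols", 3.31, None, 5.0, 12.0, 0.25, 0.15, "", "289.0718;425.0877", 1),
    ("Quercetin 3-glucuronide", "C21H18O13", "[M-H]-", "suspect", "Flavonols", 5.00, None, 6.0, 2.4, 0.25, 0.15, "", "301.0352;178.9991", 1),
    ("Malvidin 3-O-glucoside", "C23H25O12", "[M-2H]-", "suspect", "Anthocyanins", 4.20, 2.27, 20.0, 8.0, 0.25, 0.15, "hexose", "314.0441", 1),
    ("Benzyl O-[arabinofuranosyl-(1->6)-glucoside]", "C18H26O10", "[M-H]-", "suspect", "Benzyl alcohol derivatives", 4.48, 2.12, 5.0, 2.0, 0.25, 0.15, "pentose", "107.0497", 1),
    ("Protocatechuic acid ethyl ester", "C9H10O4", "[M-H]-", "suspect", "Benzoates", 4.60, None, 6.0, 2.4, 0.25, 0.15, "C2H4;C2H4+CO2", "", 1),
    ("Gallocatechin", "C15H14O7", "[M-H]-", "suspect", "Flavan-3-ols", 2.80, 1.32, 4.0, 9.5, 0.25, 0.15, "H2O", "125.0244;179.0350", 1),
    ("p-Hydroxybenzaldehyde", "C7H6O2", "[M-H]-", "suspect", "Benzaldehydes", 3.10, None, 1.8, 5.0, 0.25, 0.15, "CO", "92.0262", 1),
    # -- confounded compounds (vintage/fermentation driven, class-neutral) --
    ("Malic acid", "C4H6O5", "[M-H]-", "suspect", "Organic acids", 0.80, None, 500.0, 500.0, 0.50, 0.30, "H2O;CO2", "", 0),
    ("Tartaric acid", "C4H6O6", "[M-H]-", "suspect", "Organic acids", 0.75, None, 1500.0, 1500.0, 0.50, 0.30, "H2O;CO2", "", 0),
    ("Lactic acid", "C3H6O3", "[M-H]-", "suspect", "Organic acids", 0.85, None, 800.0, 800.0, 0.50, 0.30, "H2O", "43.0189", 0),
    ("Citric acid", "C6H8O7", "[M-H]-", "suspect", "Organic acids", 0.95, None, 300.0, 300.0, 0.50, 0.30, "H2O;CO2", "", 0),
    ("Tyrosol glucoside", "C14H20O7", "[M-H]-", "suspect", "Phenylethanoids", 2.30, None, 10.0, 10.0, 0.50, 0.30, "hexose", "119.0502", 0),
    ("Piceid", "C20H22O8", "[M-H]-", "suspect", "Stilbenes", 4.70, None, 3.0, 3.0, 0.50, 0.30, "hexose", "185.0608", 0),
    # -- class-neutral suspects --
    ("Caftaric acid", "C13H12O9", "[M-H]-", "suspect", "Cinnamates", 1.60, None, 50.0, 50.0, 0.25, 0.15, "", "179.0350;149.0092", 0),
    ("Tryptophan", "C11H12N2O2", "[M-H]-", "suspect", "Amino acids", 2.00, None, 10.0, 10.0, 0.25, 0.15, "", "116.0506;142.0662", 0),
    ("Phenylalanine", "C9H11NO2", "[M-H]-", "suspect", "Amino acids", 2.15, None, 15.0, 15.0, 0.25, 0.15, "", "147.0446;103.0552", 0),
    ("Isoquercitrin", "C21H20O12", "[M-H]-", "suspect", "Flavonols", 4.95, None, 3.0, 3.0, 0.25, 0.15, "hexose", "271.0248", 0),
    ("Astilbin", "C21H22O11", "[M-H]-", "suspect", "Flavanonols", 4.85, None, 2.0, 2.0, 0.25, 0.15, "", "303.0510;285.0405", 0),
    ("Abscisic acid", "C15H20O4", "[M-H]-", "suspect", "Sesquiterpenoids", 5.30, None, 1.0, 1.0, 0.25, 0.15, "CO2;H2O", "", 0),
    ("Catechin gallate", "C22H18O10", "[M-H]-", "suspect", "Flavan-3-ols", 4.00, None, 2.0, 2.0, 0.25, 0.15, "", "289.0718;169.0142", 0),
    ("Quinic acid", "C7H12O6", "[M-H]-", "suspect", "Organic acids", 0.70, None, 100.0, 100.0, 0.25, 0.15, "H2O", "85.0295", 0),
    # -- internal standard (absent from wine; spiked at 2 mg/L) --
    ("Ethyl vanillin", "C9H10O3", "[M-H]-", "target", "Internal standard", 3.60, None, 0.0, 0.0, 0.25, 0.0, "CH3;C2H4", "", 0),
]

_PANEL_COLUMNS = [
    "name", "formula", "adduct", "role", "compound_class", "rt", "descriptor",
    "mean_a", "mean_b", "cv", "vintage_shift", "losses", "fragments", "marker",
]

#: Name of the spiked internal standard (ethyl vanillin, absent from wine).
IS_NAME = "Ethyl vanillin"


def default_panel_table() -> pd.DataFrame:
    """The shipped compound panel as a data frame (the DB text format)."""
    return pd.DataFrame(_PANEL_ROWS, columns=_PANEL_COLUMNS)


def _clean_cell(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    return str(value)


def _fragments_for(row: pd.Series, precursor_mz: float) -> tuple[float, ...]:
    fragments: list[float] = []
    for loss in filter(None, _clean_cell(row.get("losses")).split(";")):
        if loss not in LOSS_MASSES:
            raise ValueError(f"unknown neutral loss {loss!r}")
        fragments.append(round(precursor_mz - LOSS_MASSES[loss], 4))
    explicit = _clean_cell(row.get("fragments"))
    fragments.extend(float(f) for f in filter(None, explicit.split(";")))
    return tuple(fragments[:5])


def build_compound_panel(source: pd.DataFrame) -> list[CompoundSpec]:
    """Construct the generator panel from a well-formed source table.

    Response factors default to ``5e4 x (10/mean)^0.9`` (ionization
    efficiency anti-correlated with abundance class); malformed rows are
    rejected with their row number.
    """
    if source is None or len(source) == 0:
        raise ValueError("empty compound panel source")
    specs: list[CompoundSpec] = []
    for i, row in source.reset_index(drop=True).iterrows():
        try:
            formula = MolecularFormula.parse(str(row["formula"]))
            adduct = ADDUCTS[str(row["adduct"])]
            mz = adduct_mz(formula, adduct)
            rt = float(row["rt"])
            descriptor = row.get("descriptor")
            if descriptor is None or (isinstance(descriptor, float) and np.isnan(descriptor)):
                descriptor = round((rt - 1.0) / 1.5, 3)
            is_internal = str(row["name"]) == IS_NAME
            entry = CompoundEntry(
                name=str(row["name"]),
                formula=formula,
                adduct=adduct,
                expected_rt=rt if row["role"] == "target" else None,
                qualifier_fragments=_fragments_for(row, mz),
                compound_class=str(row["compound_class"]),
                role=str(row["role"]),
                rt_descriptor=float(descriptor),
            )
            mean_a, mean_b = float(row["mean_a"]), float(row["mean_b"])
            mean_overall = (mean_a + mean_b) / 2.0
            if is_internal:
                rf = 5.0e4
            else:
                rf = 5.0e4 * (10.0 / mean_overall) ** 0.9
            specs.append(
                CompoundSpec(
                    entry=entry,
                    mean_a=mean_a,
                    mean_b=mean_b,
                    cv_within=float(row["cv"]),
                    vintage_shift=float(row["vintage_shift"]),
                    response_factor=rf,
                    is_marker=bool(row["marker"]),
                    internal_standard=is_internal,
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"malformed panel row {i + 1}: {exc}") from exc
    return specs


def default_panel() -> list[CompoundSpec]:
    """The default study panel (targets, markers, confounders, neutrals, IS)."""
    return build_compound_panel(default_panel_table())


@dataclass
class StudyData:
    """Generated study: per-sample features, metadata and the truth record."""

    features: dict[str, list[PeakFeature]]
    metadata: pd.DataFrame
    truth: dict


@dataclass
class CalibrationData:
    """Generated calibration experiment: solvent/matrix series + replicates."""

    solvent: pd.DataFrame  # analyte, concentration, response
    matrix: pd.DataFrame
    precision: pd.DataFrame  # analyte, level, replicate, response
    truth: dict


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    if mean <= 0:
        return 0.0
    if cv <= 0:
        return mean
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _effect_adjusted_means(spec: CompoundSpec, multiplier: float) -> tuple[float, float]:
    """Scale class separation: 0 -> equal means, 1 -> the panel's published scale."""
    if spec.mean_a <= 0 or spec.mean_b <= 0 or multiplier == 1.0:
        return spec.mean_a, spec.mean_b
    g = float(np.sqrt(spec.mean_a * spec.mean_b))
    return (
        g * (spec.mean_a / g) ** multiplier,
        g * (spec.mean_b / g) ** multiplier,
    )


def _observed_envelope(
    rng: np.random.Generator, formula: MolecularFormula, rel_sd: float
) -> IsotopePattern:
    theo = theoretical_isotope_pattern(formula, 3)
    peaks = [(0.0, 1.0)]
    for offset, intensity in theo.peaks[1:]:
        noisy = intensity * (1.0 + rng.normal(0.0, rel_sd)) if rel_sd > 0 else intensity
        peaks.append((offset, float(np.clip(noisy, 1e-6, 1.0))))
    return IsotopePattern(tuple(peaks))


def _decoy_feature(rng: np.random.Generator, sample_id: str, tag: int) -> PeakFeature:
    """A pure-noise feature whose envelope fits no small-molecule formula."""
    mz = float(rng.uniform(50.0, 1000.0))
    envelope = IsotopePattern(
        ((0.0, 1.0), (1.0033548, float(rng.uniform(0.5, 0.9))))
    )
    area = float(rng.lognormal(np.log(2.0e4), 1.0))
    fragments = tuple(
        (float(rng.uniform(50.0, mz - 1.0)), float(rng.uniform(100, 1000)))
        for _ in range(int(rng.integers(0, 3)))
        if mz > 52.0
    )
    return PeakFeature(
        sample_id=sample_id,
        mz=mz,
        rt=float(rng.uniform(0.3, 16.5)),
        area=area,
        intensity=area / float(rng.uniform(6.2, 19.9)),
        isotope_envelope=envelope,
        msms_fragments=fragments,
    )


def _compound_feature(
    rng: np.random.Generator,
    sample_id: str,
    spec: CompoundSpec,
    concentration: float,
    injection_factor: float,
    noise: NoiseConfig,
) -> PeakFeature:
    area = concentration * spec.response_factor * injection_factor
    width = float(rng.uniform(6.2, 19.9))
    mz = spec.entry.theoretical_mz + (
        rng.normal(0.0, noise.mz_sd_mda) / 1000.0 if noise.mz_sd_mda > 0 else 0.0
    )
    rt_true = spec.entry.expected_rt
    if rt_true is None:
        # suspects carry their chromatographic truth in the panel descriptor row
        rt_true = _true_rt(spec)
    rt = rt_true + (rng.normal(0.0, noise.rt_sd_min) if noise.rt_sd_min > 0 else 0.0)
    fragments = []
    intensity = area / width
    for frag in spec.entry.qualifier_fragments:
        if rng.random() < noise.fragment_detection:
            jitter = (
                rng.normal(0.0, noise.fragment_mz_sd_mda) / 1000.0
                if noise.fragment_mz_sd_mda > 0 else 0.0
            )
            fragments.append((frag + jitter, intensity * float(rng.uniform(0.05, 0.3))))
    return PeakFeature(
        sample_id=sample_id,
        mz=float(mz),
        rt=float(max(rt, 0.05)),
        area=float(area),
        intensity=float(intensity),
        isotope_envelope=_observed_envelope(rng, spec.entry.formula, noise.envelope_rel_sd),
        msms_fragments=tuple(fragments),
    )


_TRUE_RT: dict[str, float] = {row[0]: row[5] for row in _PANEL_ROWS}


def _true_rt(spec: CompoundSpec) -> float:
    rt = _TRUE_RT.get(spec.entry.name)
    if rt is None:
        # fall back to the descriptor-implied retention for custom panels
        rt = 1.0 + 1.5 * (spec.entry.rt_descriptor or 1.0)
    return float(rt)


def generate_study(
    design: StudyDesign,
    panel: Sequence[CompoundSpec],
    noise: NoiseConfig | None = None,
    seed: int | None = None,
) -> StudyData:
    """Generate per-sample peak-feature lists, metadata and the truth record.

    Deterministic given ``seed`` (required); QC injections carry the mean
    profile of all class samples with injection-level noise; blanks contain
    only decoy features.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible generation")
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)
    compounds = [s for s in panel if not s.internal_standard]
    is_spec = next((s for s in panel if s.internal_standard), None)
    if is_spec is None:
        raise ValueError("panel lacks an internal-standard compound")

    sample_ids: list[str] = []
    rows = []
    for cls, short, n in (
        (design.class_a, design.class_a[:3], design.n_class_a),
        (design.class_b, design.class_b[:3], design.n_class_b),
    ):
        for i in range(n):
            sid = f"{short}{i + 1:02d}"
            vintage = design.vintages[i % len(design.vintages)]
            sample_ids.append(sid)
            rows.append((sid, cls, vintage, False, False))
    qc_ids = [f"QC{i + 1:02d}" for i in range(design.n_qc)]
    n_blanks = int(np.ceil((len(sample_ids) + design.n_qc) / design.blank_every)) + 1
    blank_ids = [f"Blank{i + 1:02d}" for i in range(n_blanks)]
    rows += [(sid, None, None, True, False) for sid in qc_ids]
    rows += [(sid, None, None, False, True) for sid in blank_ids]
    metadata = pd.DataFrame(
        rows, columns=["sample_id", "class_label", "vintage", "is_qc", "is_blank"]
    ).set_index("sample_id")

    # per-sample true concentrations
    concentrations = pd.DataFrame(
        0.0, index=sample_ids, columns=[s.entry.name for s in compounds]
    )
    features: dict[str, list[PeakFeature]] = {}
    for sid in sample_ids:
        cls = metadata.loc[sid, "class_label"]
        vintage = metadata.loc[sid, "vintage"]
        vintage_sign = 1.0 if vintage == design.vintages[-1] else -1.0
        injection = 1.0 + (rng.normal(0.0, noise.injection_cv) if noise.injection_cv > 0 else 0.0)
        sample_features: list[PeakFeature] = []
        for spec in compounds:
            mean_a, mean_b = _effect_adjusted_means(spec, noise.effect_multiplier)
            mean = mean_a if cls == design.class_a else mean_b
            mean *= 1.0 + vintage_sign * spec.vintage_shift
            conc = _lognormal(rng, mean, spec.cv_within)
            concentrations.loc[sid, spec.entry.name] = conc
            if conc > 0:
                sample_features.append(
                    _compound_feature(rng, sid, spec, conc, injection, noise)
                )
        sample_features.append(
            _compound_feature(rng, sid, is_spec, design.is_concentration, injection, noise)
        )
        for d in range(design.n_decoys_per_sample):
            sample_features.append(_decoy_feature(rng, sid, d))
        features[sid] = sample_features

    mean_profile = concentrations.mean(axis=0)
    for sid in qc_ids:
        injection = 1.0 + (rng.normal(0.0, noise.injection_cv) if noise.injection_cv > 0 else 0.0)
        sample_features = []
        for spec in compounds:
            conc = float(mean_profile[spec.entry.name])
            if noise.qc_cv > 0:
                conc *= 1.0 + rng.normal(0.0, noise.qc_cv)
            if conc > 0:
                sample_features.append(
                    _compound_feature(rng, sid, spec, conc, injection, noise)
                )
        sample_features.append(
            _compound_feature(rng, sid, is_spec, design.is_concentration, injection, noise)
        )
        features[sid] = sample_features

    for sid in blank_ids:
        features[sid] = [
            _decoy_feature(rng, sid, d) for d in range(design.n_blank_features)
        ]

    markers = {
        s.entry.name: (design.class_a if s.mean_a > s.mean_b else design.class_b)
        for s in compounds
        if s.is_marker
    }
    truth = {
        "concentrations": concentrations,
        "markers": markers,
        "seed": seed,
        "is_nominal_area": design.is_concentration * is_spec.response_factor,
        "removal_list": list(DEFAULT_REMOVAL_LIST),
    }
    return StudyData(features=features, metadata=metadata, truth=truth)


def generate_calibration_series(
    panel: Sequence[CompoundSpec],
    design: StudyDesign,
    noise: NoiseConfig | None = None,
    seed: int | None = None,
) -> CalibrationData:
    """Solvent and matrix-matched calibration series plus precision replicates.

    Responses are analyte/IS area ratios; the matrix-matched slope carries a
    per-analyte suppression/enhancement factor drawn uniformly in
    [0.7, 1.2], i.e. matrix effects inside the +/-40% acceptance band.
    Precision replicates (n=5) are generated at 0.5 and 5.0 mg/L.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible generation")
    if len(design.calibration_levels) < 5:
        raise ValueError("calibration design needs at least 5 levels")
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)
    is_spec = next((s for s in panel if s.internal_standard), None)
    if is_spec is None:
        raise ValueError("panel lacks an internal-standard compound")
    is_area = design.is_concentration * is_spec.response_factor

    targets = [s for s in panel if s.entry.role == "target" and not s.internal_standard]
    solvent_rows, matrix_rows, precision_rows = [], [], []
    suppression: dict[str, float] = {}
    slopes: dict[str, float] = {}
    for spec in targets:
        slope = spec.response_factor / is_area
        slopes[spec.entry.name] = slope
        factor = float(rng.uniform(0.7, 1.2))
        suppression[spec.entry.name] = factor
        for level in design.calibration_levels:
            eps = rng.normal(0.0, noise.calibration_cv) if noise.calibration_cv > 0 else 0.0
            solvent_rows.append((spec.entry.name, level, slope * level * (1.0 + eps)))
            eps_m = rng.normal(0.0, noise.calibration_cv) if noise.calibration_cv > 0 else 0.0
            matrix_rows.append(
                (spec.entry.name, level, slope * factor * level * (1.0 + eps_m))
            )
        for level in (0.5, 5.0):
            for rep in range(5):
                eps = rng.normal(0.0, noise.calibration_cv) if noise.calibration_cv > 0 else 0.0
                precision_rows.append(
                    (spec.entry.name, level, rep + 1, slope * level * (1.0 + eps))
                )
    columns = ["analyte", "concentration", "response"]
    return CalibrationData(
        solvent=pd.DataFrame(solvent_rows, columns=columns),
        matrix=pd.DataFrame(matrix_rows, columns=columns),
        precision=pd.DataFrame(
            precision_rows, columns=["analyte", "level", "replicate", "response"]
        ),
        truth={"suppression": suppression, "slopes": slopes, "seed": seed},
    )
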