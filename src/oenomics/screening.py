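"""Target and suspect screening of LC-HRMS peak features against compound databases.

Target screening matches features to compounds for which authentic standards
exist (known experimental retention time); suspect screening matches against
a wider database of compounds expected in wine, with a QSRR-predicted
retention time replacing the experimental one.  Both are conjunctions of
per-criterion checks (mass accuracy, retention time, isotopic fit, peak
area/intensity, peak score, MS/MS qualifier fragments); confidence in an
identification is graded on the Schymanski level ladder (1, 2a, 2b, 3, ...).
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .chem import (
    ADDUCTS,
    AdductSpec,
    InsufficientEnvelopeError,
    IsotopePattern,
    MolecularFormula,
    adduct_mz,
    isotopic_fit_msigma,
    mass_error_mda,
    peak_score,
    theoretical_isotope_pattern,
)

__all__ = [
    "CompoundEntry",
    "PeakFeature",
    "ScreeningCriteria",
    "ScreeningHit",
    "TARGET_CRITERIA",
    "SUSPECT_CRITERIA",
    "RetentionTimeModel",
    "target_screen",
    "suspect_screen",
    "assign_identification_level",
    "predict_retention_time",
    "prevalence_and_blank_filter",
]


@dataclass(frozen=True)
class CompoundEntry:
    """One database record (target panel or suspect list)."""

    name: str
    formula: MolecularFormula
    adduct: AdductSpec
    theoretical_mz: float | None = None
    expected_rt: float | None = None  # min; experimental (targets)
    predicted_rt: float | None = None  # min; QSRR output (suspects)
    in_applicability_domain: bool = False
    qualifier_fragments: tuple[float, ...] = ()
    compound_class: str = ""
    role: str = "suspect"  # "target" | "suspect"
    rt_descriptor: float | None = None  # hydrophobicity-like QSRR descriptor

    def __post_init__(self) -> None:
        if self.role not in ("target", "suspect"):
            raise ValueError(f"unknown role {self.role!r}")
        mz = adduct_mz(self.formula, self.adduct)
        if self.theoretical_mz is None:
            object.__setattr__(self, "theoretical_mz", mz)
        elif abs(self.theoretical_mz - mz) > 1e-4:  # 0.1 mDa consistency
            raise ValueError(
                f"{self.name}: stored m/z {self.theoretical_mz:.4f} inconsistent "
                f"with formula+adduct ({mz:.4f})"
            )
        if len(self.qualifier_fragments) > 5:
            raise ValueError(f"{self.name}: at most 5 qualifier fragments")
        if any(f >= self.theoretical_mz + 1 for f in self.qualifier_fragments):
            raise ValueError(f"{self.name}: qualifier fragment above precursor m/z")


@dataclass(frozen=True)
class PeakFeature:
    """One detected chromatographic feature in one sample."""

    sample_id: str
    mz: float
    rt: float
    area: float
    intensity: float
    isotope_envelope: IsotopePattern | None = None
    msms_fragments: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.mz <= 0 or self.area <= 0 or self.intensity <= 0:
            raise ValueError("m/z, area and intensity must be positive")


@dataclass(frozen=True)
class ScreeningCriteria:
    """Acceptance thresholds for one screening mode.

    Strictness follows the conventional rules: mass error and RT tolerance
    are strict upper bounds, area/intensity/peak score strict lower bounds,
    the isotopic fit an inclusive upper bound, and the suspect RT window an
    inclusive bound on |experimental − predicted|.
    """

    max_mass_error: float  # mDa
    max_msigma: float
    min_area: float
    min_intensity: float
    min_fragments: int = 1
    max_rt_error: float | None = None  # min; targets only
    min_peak_score: float | None = None  # suspects only
    rt_window_predicted: float | None = None  # min; suspects only
    fragment_tolerance_mda: float = 10.0

    def __post_init__(self) -> None:
        for name in ("max_mass_error", "max_msigma", "min_area", "min_intensity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: Target-screening thresholds: <2 mDa, <0.2 min, mSigma <= 50, area > 800,
#: intensity > 200, at least one qualifier fragment.
TARGET_CRITERIA = ScreeningCriteria(
    max_mass_error=2.0, max_msigma=50.0, min_area=800.0, min_intensity=200.0,
    max_rt_error=0.2,
)

#: Suspect-screening thresholds: <5 mDa, area > 2000, intensity > 800,
#: mSigma < 100, peak score > 4, 1.8-min predicted-RT window (in-domain only),
#: at least one base fragment.
SUSPECT_CRITERIA = ScreeningCriteria(
    max_mass_error=5.0, max_msigma=100.0, min_area=2000.0, min_intensity=800.0,
    min_peak_score=4.0, rt_window_predicted=1.8,
)


@dataclass
class ScreeningHit:
    """A compound-feature match with every criterion value recorded."""

    compound: CompoundEntry
    feature: PeakFeature
    mass_error: float
    rt_error: float | None
    msigma: float | None
    peak_score: float
    matched_fragments: tuple[float, ...]
    identification_level: str | None = None

    @property
    def sample_id(self) -> str:
        return self.feature.sample_id


def _matched_fragments(
    feature: PeakFeature, compound: CompoundEntry, tolerance_mda: float
) -> tuple[float, ...]:
    if not feature.msms_fragments or not compound.qualifier_fragments:
        return ()
    observed = np.array([mz for mz, _ in feature.msms_fragments])
    matched = []
    for qualifier in compound.qualifier_fragments:
        if np.any(np.abs(observed - qualifier) * 1000.0 < tolerance_mda):
            matched.append(qualifier)
    return tuple(matched)


def _evaluate(
    feature: PeakFeature,
    compound: CompoundEntry,
    criteria: ScreeningCriteria,
    reference_rt: float | None,
) -> tuple[ScreeningHit | None, str | None]:
    """Evaluate (feature, compound); return (hit, None) on pass, (None, reason) on fail.

    Criteria are conjunctive and checked cheapest-first; the mass-error gate
    rejects almost every candidate pair before the isotope-envelope fit is
    computed.
    """
    error = mass_error_mda(feature.mz, compound.theoretical_mz)
    if abs(error) >= criteria.max_mass_error:
        return None, "mass_error"
    if feature.area <= criteria.min_area:
        return None, "area"
    if feature.intensity <= criteria.min_intensity:
        return None, "intensity"
    score = peak_score(feature.area, feature.intensity)
    if criteria.min_peak_score is not None and score <= criteria.min_peak_score:
        return None, "peak_score"
    rt_error = None if reference_rt is None else feature.rt - reference_rt
    if criteria.max_rt_error is not None:
        if rt_error is None or abs(rt_error) >= criteria.max_rt_error:
            return None, "rt_error"
    matched = _matched_fragments(feature, compound, criteria.fragment_tolerance_mda)
    if len(matched) < criteria.min_fragments:
        return None, "fragments"
    if feature.isotope_envelope is None or len(feature.isotope_envelope.peaks) < 2:
        return None, "isotope_envelope"
    msigma = isotopic_fit_msigma(
        theoretical_isotope_pattern(compound.formula, 3), feature.isotope_envelope
    )
    if msigma > criteria.max_msigma:
        return None, "msigma"
    return ScreeningHit(compound, feature, error, rt_error, msigma, score, matched), None


def _group_features(
    features: Mapping[str, Sequence[PeakFeature]] | Iterable[PeakFeature],
) -> dict[str, list[PeakFeature]]:
    if isinstance(features, Mapping):
        return {sid: list(fs) for sid, fs in features.items()}
    grouped: dict[str, list[PeakFeature]] = {}
    for feature in features:
        grouped.setdefault(feature.sample_id, []).append(feature)
    return grouped


def _best_hit(candidates: list[ScreeningHit]) -> ScreeningHit:
    # smallest |mass error|, then smallest |rt error|, then largest area
    return min(
        candidates,
        key=lambda h: (
            abs(h.mass_error),
            abs(h.rt_error) if h.rt_error is not None else np.inf,
            -h.feature.area,
        ),
    )


def target_screen(
    features: Mapping[str, Sequence[PeakFeature]] | Iterable[PeakFeature],
    db: Sequence[CompoundEntry],
    criteria: ScreeningCriteria = TARGET_CRITERIA,
    audit: dict | None = None,
) -> list[ScreeningHit]:
    """Screen features against the target panel (authentic standards).

    A feature qualifies only if *all* criteria pass, including at least one
    qualifier-fragment match; among multiple qualifying features for one
    compound in one sample, the smallest absolute mass error wins (ties
    broken by RT error, then larger area).  Hits from target screening are
    confirmed by reference standard, i.e. identification level 1.
    """
    if not db:
        warnings.warn("empty target database; no hits", stacklevel=2)
        return []
    if criteria.max_rt_error is None:
        raise ValueError("target screening requires an RT tolerance")
    for entry in db:
        if entry.role != "target" or entry.expected_rt is None:
            raise ValueError(f"{entry.name}: target entries need role=target and expected_rt")
    hits: list[ScreeningHit] = []
    for sample_id, sample_features in sorted(_group_features(features).items()):
        for compound in db:
            passing = []
            for feature in sample_features:
                hit, reason = _evaluate(feature, compound, criteria, compound.expected_rt)
                if hit is not None:
                    passing.append(hit)
                elif audit is not None:
                    audit[reason] = audit.get(reason, 0) + 1
            if passing:
                best = _best_hit(passing)
                best.identification_level = "1"
                hits.append(best)
    return hits


def suspect_screen(
    features: Mapping[str, Sequence[PeakFeature]] | Iterable[PeakFeature],
    db: Sequence[CompoundEntry],
    criteria: ScreeningCriteria = SUSPECT_CRITERIA,
    rt_model: "RetentionTimeModel | None" = None,
    audit: dict | None = None,
) -> list[ScreeningHit]:
    """Screen features against the suspect database.

    The retention-time window applies only to compounds inside the QSRR
    model's applicability domain; out-of-domain entries skip the RT check
    but the RT error is still recorded on the hit.  Hits default to
    identification level 3 (tentative candidate) until stronger evidence is
    supplied via :func:`assign_identification_level`.
    """
    if not db:
        warnings.warn("empty suspect database; no hits", stacklevel=2)
        return []
    resolved: list[CompoundEntry] = []
    for entry in db:
        if entry.role != "suspect":
            raise ValueError(f"{entry.name}: suspect entries need role=suspect")
        if entry.predicted_rt is None:
            if entry.in_applicability_domain and rt_model is None:
                raise ValueError(
                    f"{entry.name}: flagged in-domain but no predicted RT and no RT model"
                )
            if rt_model is not None and entry.rt_descriptor is not None:
                rt, in_domain = rt_model.predict(entry.rt_descriptor)
                entry = replace(entry, predicted_rt=rt, in_applicability_domain=in_domain)
        resolved.append(entry)
    hits: list[ScreeningHit] = []
    for sample_id, sample_features in sorted(_group_features(features).items()):
        for compound in resolved:
            passing = []
            for feature in sample_features:
                hit, reason = _evaluate(feature, compound, criteria, compound.predicted_rt)
                if (
                    hit is not None
                    and compound.in_applicability_domain
                    and criteria.rt_window_predicted is not None
                    and (
                        hit.rt_error is None
                        or abs(hit.rt_error) > criteria.rt_window_predicted
                    )
                ):
                    hit, reason = None, "rt_window"
                if hit is not None:
                    passing.append(hit)
                elif audit is not None:
                    audit[reason] = audit.get(reason, 0) + 1
            if passing:
                best = _best_hit(passing)
                best.identification_level = "3"
                hits.append(best)
    return hits


def assign_identification_level(
    hit: ScreeningHit,
    reference_standard: bool = False,
    library_spectrum_match: bool = False,
    diagnostic_evidence: bool = False,
) -> str:
    """Assign a Schymanski confidence level from the available evidence.

    1 = confirmed by reference standard; 2a = library spectrum match;
    2b = diagnostic evidence (structure supported without spectrum or
    standard, e.g. in-silico fragment rank plus RT plausibility);
    3 = tentative candidate.  Contradictory flags resolve to the strongest
    evidence.
    """
    if reference_standard:
        level = "1"
    elif library_spectrum_match:
        level = "2a"
    elif diagnostic_evidence:
        level = "2b"
    else:
        level = "3"
    hit.identification_level = level
    return level


class RetentionTimeModel:
    """QSRR stand-in: ridge regression of RT on one hydrophobicity-like descriptor.

    The applicability domain is the descriptor range of the training set
    widened by 5% on each side; predictions outside it are flagged so the
    suspect-screening RT window is not enforced for them.
    """

    DOMAIN_MARGIN = 0.05

    def __init__(self, alpha: float = 1.0) -> None:
        self._ridge = Ridge(alpha=alpha)
        self._lo: float | None = None
        self._hi: float | None = None

    def fit(self, descriptors: Sequence[float], rts: Sequence[float]) -> "RetentionTimeModel":
        x = np.asarray(descriptors, dtype=float)
        y = np.asarray(rts, dtype=float)
        if x.size < 2:
            raise ValueError("need at least two (descriptor, rt) training pairs")
        self._ridge.fit(x.reshape(-1, 1), y)
        span = x.max() - x.min()
        self._lo = x.min() - self.DOMAIN_MARGIN * span
        self._hi = x.max() + self.DOMAIN_MARGIN * span
        return self

    def predict(self, descriptor: float | None) -> tuple[float | None, bool]:
        """Return (predicted RT in min, in-applicability-domain flag)."""
        if self._lo is None:
            raise ValueError("model not fitted")
        if descriptor is None or not np.isfinite(descriptor):
            return None, False
        rt = float(self._ridge.predict(np.array([[descriptor]]))[0])
        return rt, bool(self._lo <= descriptor <= self._hi)

    @classmethod
    def from_targets(cls, targets: Sequence[CompoundEntry], alpha: float = 1.0) -> "RetentionTimeModel":
        pairs = [
            (t.rt_descriptor, t.expected_rt)
            for t in targets
            if t.rt_descriptor is not None and t.expected_rt is not None
        ]
        if len(pairs) < 2:
            raise ValueError("need at least two targets with descriptor and RT")
        return cls(alpha=alpha).fit(*zip(*pairs))


def predict_retention_time(
    compound: CompoundEntry, model: RetentionTimeModel
) -> tuple[float | None, bool]:
    """Predict a compound's retention time; missing descriptor -> out of domain."""
    return model.predict(compound.rt_descriptor)


def prevalence_and_blank_filter(
    hits: Sequence[ScreeningHit],
    metadata: pd.DataFrame,
    min_prevalence: float = 0.8,
    blank_area_fraction: float = 0.1,
) -> list[str]:
    """Retain compounds detected in >= ``min_prevalence`` of at least one class
    and not present in procedural blanks.

    ``metadata`` is indexed by sample id with columns ``class_label`` (NaN
    for QC/blank injections), ``is_qc`` and ``is_blank``.  A compound counts
    as present in a blank when its blank peak area reaches
    ``blank_area_fraction`` of the median area across class samples.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    is_blank = metadata["is_blank"].astype(bool)
    is_qc = metadata.get("is_qc", pd.Series(False, index=metadata.index)).astype(bool)
    class_samples = metadata.loc[~is_blank & ~is_qc, "class_label"].dropna()
    class_sizes = class_samples.value_counts()
    if not is_blank.any():
        warnings.warn("no blank injections in batch; blank filter skipped", stacklevel=2)

    by_compound: dict[str, list[ScreeningHit]] = {}
    for hit in hits:
        by_compound.setdefault(hit.compound.name, []).append(hit)

    retained = []
    for name, compound_hits in by_compound.items():
        sample_areas = {
            h.sample_id: h.feature.area
            for h in compound_hits
            if h.sample_id in class_samples.index
        }
        counts = class_samples.loc[list(sample_areas)].value_counts()
        prevalence_ok = any(
            counts.get(cls, 0) / size >= min_prevalence
            for cls, size in class_sizes.items()
        )
        if not prevalence_ok:
            continue
        blank_areas = [
            h.feature.area
            for h in compound_hits
            if h.sample_id in metadata.index and is_blank.get(h.sample_id, False)
        ]
        if blank_areas and sample_areas:
            threshold = blank_area_fraction * float(np.median(list(sample_areas.values())))
            if max(blank_areas) >= threshold:
                continue  # contamination
        retained.append(name)
    return sorted(retained)
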