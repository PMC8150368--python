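"""Calibration-based quantification and method-validation metrics.

Quantification uses external-standard calibration: 7-point curves of the
analyte/IS peak-area ratio against concentration (0.1–20 mg/L design), fit by
ordinary least squares.  Validation covers linearity (R²), matrix effect
(%ME = (matrix factor − 1) × 100), LOD/LOQ at signal-to-noise 3 and 10, and
instrumental precision as %RSD of replicate injections.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "ValidationReport",
    "QuantResult",
    "fit_calibration",
    "quantify",
    "matrix_effect",
    "estimate_lod_loq",
    "precision_rsd",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """An OLS calibration line: response (area ratio) vs concentration (mg/L)."""

    analyte: str
    concentrations: tuple[float, ...]
    responses: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class ValidationReport:
    """Per-analyte method-validation summary."""

    analyte: str
    r_squared: float
    matrix_effect: float  # percent
    lod: float  # mg/L
    loq: float  # mg/L
    rsd_low: float  # % at 0.5 mg/L
    rsd_high: float  # % at 5.0 mg/L


@dataclass(frozen=True)
class QuantResult:
    """A concentration estimate with its reporting flag.

    ``flag`` is ``"ok"`` above LOQ, ``"traces"`` between LOD and LOQ, and
    ``"<LOD"`` below LOD; when no LOD/LOQ are supplied the flag is ``"ok"``.
    """

    concentration: float
    flag: str = "ok"


def fit_calibration(
    points: Sequence[tuple[float, float]], analyte: str = ""
) -> CalibrationCurve:
    """Ordinary least squares of response on concentration.

    Requires at least 5 distinct concentration levels (the study design uses
    7 spanning 0.1–20 mg/L).
    """
    if len(points) < 5:
        raise ValueError("calibration requires at least 5 points")
    conc = np.array([p[0] for p in points], dtype=float)
    resp = np.array([p[1] for p in points], dtype=float)
    if np.ptp(conc) == 0:
        raise ValueError("zero concentration variance: singular design")
    result = stats.linregress(conc, resp)
    return CalibrationCurve(
        analyte=analyte,
        concentrations=tuple(conc),
        responses=tuple(resp),
        slope=float(result.slope),
        intercept=float(result.intercept),
        r_squared=float(result.rvalue**2),
    )


def quantify(
    hit_response: float,
    curve: CalibrationCurve,
    lod: float | None = None,
    loq: float | None = None,
) -> QuantResult:
    """Invert the calibration curve: concentration = (response − intercept)/slope.

    Values between LOD and LOQ are flagged ``"traces"``; below LOD, ``"<LOD"``.
    """
    if curve.slope <= 0:
        raise ValueError("invalid calibration curve: non-positive slope")
    concentration = (hit_response - curve.intercept) / curve.slope
    flag = "ok"
    if lod is not None and concentration < lod:
        flag = "<LOD"
    elif loq is not None and concentration < loq:
        flag = "traces"
    return QuantResult(float(concentration), flag)


def matrix_effect(slope_matrix_matched: float, slope_solvent: float) -> float:
    """%Matrix Effect = (Matrix Factor − 1) × 100, MF = matrix/solvent slope ratio.

    Negative values indicate ionization suppression by the wine matrix,
    positive values enhancement; |%ME| <= 40 is the usual acceptance band.
    """
    if slope_solvent <= 0:
        raise ValueError("solvent slope must be positive")
    return (slope_matrix_matched / slope_solvent - 1.0) * 100.0


def estimate_lod_loq(curve: CalibrationCurve, noise: float) -> tuple[float, float]:
    """LOD and LOQ at signal-to-noise 3 and 10: (3·noise/slope, 10·noise/slope).

    ``noise`` is a response-scale scalar (e.g. the standard deviation of
    blank responses).
    """
    if noise <= 0:
        raise ValueError("noise must be positive")
    if curve.slope <= 0:
        raise ValueError("invalid calibration curve: non-positive slope")
    return 3.0 * noise / curve.slope, 10.0 * noise / curve.slope


def precision_rsd(replicate_responses: Sequence[float]) -> float:
    """Relative standard deviation (%) of replicate injections."""
    resp = np.asarray(replicate_responses, dtype=float)
    if resp.size < 2:
        raise ValueError("precision requires at least 2 replicates")
    mean = resp.mean()
    if mean == 0:
        raise ValueError("zero mean response: RSD undefined")
    return float(100.0 * resp.std(ddof=1) / mean)
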