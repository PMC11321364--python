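"""Ratio-of-ratios calibration analytics for pulse oximetry.

From paired systolic/diastolic transmittances this module computes the
perfusion index AC/DC = (Id - Is)/Is per wavelength, the ratio of ratios
R = (AC/DC)_660 / (AC/DC)_940, least-squares calibration lines
SaO2 = a + b*R per skin phenotype, bias tables of a skin-specific
calibration against the commercial relation SpO2 = 110 - 25*R, and the
skin-tone correction multipliers that re-align the moderate and dark
calibration curves with the light one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "IntensityRecord",
    "CalibrationCurve",
    "BiasReport",
    "CorrectionFactor",
    "COMMERCIAL_INTERCEPT",
    "COMMERCIAL_SLOPE",
    "round_half_away",
    "ac_dc",
    "ratio_of_ratios",
    "fit_calibration",
    "commercial_spo2",
    "invert_calibration",
    "bias_report",
    "cohort_bias_ratio",
    "reference_multiplier",
    "multiplier_profile",
    "apply_multiplier",
]

#: Widely used commercial calibration SpO2 = 110 - 25 R.
COMMERCIAL_INTERCEPT = 110.0
COMMERCIAL_SLOPE = -25.0


def round_half_away(x, decimals: int = 1):
    """Round half away from zero (printed-table convention).

    numpy's default rounds half to even; reproducing one-decimal printed
    tables requires the away-from-zero rule.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class IntensityRecord:
    """Systolic/diastolic transmittance pair for one grid condition."""

    skin: str
    sat_a: float  # percent
    wavelength: int
    transmittance_systolic: float
    transmittance_diastolic: float

    @property
    def pulsatility_violated(self) -> bool:
        """More systolic blood should mean more absorption (Is <= Id).

        Monte Carlo noise can violate this; such records are flagged and
        kept, never dropped.
        """
        return self.transmittance_systolic > self.transmittance_diastolic

    @property
    def ac_dc(self) -> float:
        return ac_dc(self.transmittance_systolic, self.transmittance_diastolic)


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear calibration SaO2(%) = intercept + slope * R."""

    skin: str
    intercept: float
    slope: float
    r_squared: float = float("nan")
    residual_sd: float = float("nan")
    n_points: int = 0

    def predict(self, ratio: float) -> float:
        """SaO2 (%) predicted at a given ratio of ratios."""
        return self.intercept + self.slope * np.asarray(ratio, dtype=float)

    def invert(self, sao2) -> float:
        return invert_calibration(self, sao2)


#: The commercial relation expressed as a curve, for round-trip checks.
COMMERCIAL_CURVE = CalibrationCurve(
    "commercial", COMMERCIAL_INTERCEPT, COMMERCIAL_SLOPE
)


@dataclass(frozen=True)
class BiasReport:
    """Per-SaO2 predicted SpO2 and bias rows, with their mean.

    ``spo2`` and ``bias`` are unrounded; the one-decimal printed-table
    versions are produced on demand by :meth:`to_table`.
    """

    skin: str
    sao2: np.ndarray
    spo2: np.ndarray
    bias: np.ndarray

    @property
    def mean_bias(self) -> float:
        return float(np.mean(self.bias))

    def to_table(self):
        """Rows rounded to one decimal, half away from zero."""
        import pandas as pd

        return pd.DataFrame(
            {
                "sao2": self.sao2,
                "spo2": round_half_away(self.spo2),
                "bias": round_half_away(self.bias),
            }
        )


@dataclass(frozen=True)
class CorrectionFactor:
    """Skin-tone correction multiplier for the ratio of ratios.

    ``kind`` is ``linear_at_reference`` (single multiplier evaluated at a
    reference saturation) or ``mean_of_profile`` (arithmetic mean of the
    per-SaO2 multiplier profile).
    """

    kind: str
    skin: str
    sao2_grid: np.ndarray
    profile: np.ndarray
    applied_factor: float

    def __post_init__(self) -> None:
        if np.any(self.profile <= 0) or self.applied_factor <= 0:
            raise ValueError("correction factors must be positive")


def ac_dc(transmittance_systolic: float, transmittance_diastolic: float) -> float:
    """Perfusion index (Id - Is)/Is from the two cardiac-phase intensities."""
    i_s = transmittance_systolic
    i_d = transmittance_diastolic
    if i_s <= 0:
        raise ValueError("systolic intensity must be positive")
    return (i_d - i_s) / i_s


def ratio_of_ratios(acdc_660: float, acdc_940: float) -> float:
    """R = (AC/DC at 660 nm) / (AC/DC at 940 nm)."""
    if acdc_940 == 0:
        raise ValueError("infrared AC/DC is zero; ratio undefined")
    return acdc_660 / acdc_940


def fit_calibration(points, skin: str = "") -> CalibrationCurve:
    """Ordinary least squares of SaO2 (%) on R.

    ``points`` is a sequence of ``(R, SaO2)`` pairs.  SaO2 is the
    response and R the regressor, matching the conventional form
    SaO2 = a + b*R of oximeter calibration lines.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (R, SaO2) points")
    r, sao2 = pts[:, 0], pts[:, 1]
    if np.allclose(r, r[0]):
        raise ValueError("all R values identical; calibration fit is degenerate")
    fit = stats.linregress(r, sao2)
    resid = sao2 - (fit.intercept + fit.slope * r)
    dof = max(1, len(r) - 2)
    return CalibrationCurve(
        skin=skin,
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        residual_sd=float(math.sqrt(np.sum(resid**2) / dof)),
        n_points=len(r),
    )


def commercial_spo2(ratio) -> float:
    """SpO2 (%) from the commercial relation 110 - 25 R (not clamped)."""
    return COMMERCIAL_INTERCEPT + COMMERCIAL_SLOPE * np.asarray(ratio, dtype=float)


def invert_calibration(curve: CalibrationCurve, sao2):
    """R implied by a calibration curve at a given SaO2 (%)."""
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; cannot invert")
    return (np.asarray(sao2, dtype=float) - curve.intercept) / curve.slope


def bias_report(
    curve: CalibrationCurve,
    sao2_range=np.arange(86, 93),
    commercial=commercial_spo2,
) -> BiasReport:
    """Bias (SpO2 - SaO2) of the commercial relation for one skin type.

    For each true SaO2, the R value a subject of this skin type would
    produce is obtained by inverting the skin-specific curve; feeding
    that R through the commercial relation gives the displayed SpO2.
    """
    sao2 = np.atleast_1d(np.asarray(sao2_range, dtype=float))
    if sao2.size == 0:
        raise ValueError("empty SaO2 range")
    if sao2.min() < 70 or sao2.max() > 100:
        raise ValueError("SaO2 range must lie within [70, 100]%")
    r = invert_calibration(curve, sao2)
    spo2 = np.asarray(commercial(r), dtype=float)
    return BiasReport(skin=curve.skin, sao2=sao2, spo2=spo2, bias=spo2 - sao2)


def _mean_bias(report) -> float:
    return report.mean_bias if hasattr(report, "mean_bias") else float(report)


def cohort_bias_ratio(report_lighter, report_darker) -> float:
    """Ratio of mean biases, darker cohort over lighter cohort.

    Accepts :class:`BiasReport` objects or plain mean-bias numbers (for
    published cohort means).
    """
    lighter = _mean_bias(report_lighter)
    darker = _mean_bias(report_darker)
    if lighter == 0:
        raise ValueError("lighter-cohort mean bias is zero; ratio undefined")
    return darker / lighter


def reference_multiplier(
    curve_ref: CalibrationCurve,
    curve_other: CalibrationCurve,
    sao2_ref: float = 100.0,
) -> float:
    """R_ref / R_other at a single reference saturation (default 100%)."""
    r_ref = invert_calibration(curve_ref, sao2_ref)
    r_other = invert_calibration(curve_other, sao2_ref)
    if r_other == 0:
        raise ValueError("reference R of the target curve is zero")
    return float(r_ref / r_other)


def multiplier_profile(
    curve_ref: CalibrationCurve,
    curve_other: CalibrationCurve,
    sao2_grid=np.arange(70, 101, 5),
) -> CorrectionFactor:
    """Per-SaO2 multipliers R_ref/R_other and their arithmetic mean.

    The profile rises toward low saturation for dark skin (an effectively
    exponential trend), so its mean is the scalar factor applied when a
    single multiplier must cover the whole saturation range.
    """
    grid = np.atleast_1d(np.asarray(sao2_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty SaO2 grid")
    r_ref = invert_calibration(curve_ref, grid)
    r_other = invert_calibration(curve_other, grid)
    if np.any(r_other == 0):
        raise ValueError("target curve has zero R on the grid")
    profile = r_ref / r_other
    return CorrectionFactor(
        kind="mean_of_profile",
        skin=curve_other.skin,
        sao2_grid=grid,
        profile=profile,
        applied_factor=float(np.mean(profile)),
    )


def apply_multiplier(curve_or_points, factor: float):
    """Scale every R by ``factor`` and return the re-fitted calibration.

    For a :class:`CalibrationCurve` the result is exact algebra: scaling
    R by f maps SaO2 = a + b*R to SaO2 = a + (b/f)*R'.  For raw points
    the scaled points are re-fitted by OLS.
    """
    if factor <= 0:
        raise ValueError("multiplier must be positive")
    if isinstance(curve_or_points, CalibrationCurve):
        c = curve_or_points
        return CalibrationCurve(
            skin=c.skin,
            intercept=c.intercept,
            slope=c.slope / factor,
            r_squared=c.r_squared,
            residual_sd=c.residual_sd,
            n_points=c.n_points,
        )
    pts = np.asarray(list(curve_or_points), dtype=float)
    scaled = np.column_stack([pts[:, 0] * factor, pts[:, 1]])
    return fit_calibration(scaled)
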