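"""Gravimetric force-sensor calibration.

A steel ball of known mass loads the sensor tip while the sensor is rotated
through one full revolution; the axial gravity component m·g·cos(θ - φ)
traces a sinusoid in the ADC output. Fitting the recorded sweep recovers the
force-to-signal conversion coefficient (nN/ADU), the phase of the sensitive
axis, the ADC baseline, force-unit error metrics (RMSE, maximum absolute
error) and an operational sensor resolution.

The fit is linear least squares of ADC on {cos θ, sin θ, 1}: the model class
contains the noise-free sweep exactly, so noise-free recovery is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import weight_nN
from .virtual_instrument import CalibrationSweep

__all__ = [
    "expected_axis_force",
    "CalibrationModel",
    "CalibrationResult",
    "fit_calibration",
    "estimate_resolution",
    "convert_trace",
]


def expected_axis_force(ball_mass, angle, phase=0.0, gravity=9.80665):
    """Gravity component along the sensor's sensitive axis, in nN.

    m·g·cos(angle - phase); mass in grams, angles in degrees.
    """
    if ball_mass <= 0:
        raise ValueError("ball_mass must be > 0")
    return weight_nN(ball_mass, gravity) * np.cos(np.deg2rad(np.asarray(angle) - phase))


@dataclass
class CalibrationResult:
    """Fitted calibration of one force sensor.

    coefficient: nN per ADU (> 0); phase: degrees; baseline: ADU;
    rmse / max_error: force-unit residual metrics over the sweep, nN;
    resolution: SD of force-converted fit residuals, nN (the operational
    definition used by this package — see docs/methods.md).
    """

    coefficient: float
    phase: float
    baseline: float
    rmse: float
    max_error: float
    resolution: float
    n_points: int

    def __post_init__(self):
        if self.coefficient <= 0:
            raise ValueError("coefficient must be > 0")

    def summary(self) -> str:
        lines = [
            "Force sensor calibration (gravimetric rotation sweep)",
            "=" * 53,
            f"n angular positions     {self.n_points:>10d}",
            f"coefficient [nN/ADU]    {self.coefficient:>12.6g}",
            f"phase [deg]             {self.phase:>12.4f}",
            f"baseline [ADU]          {self.baseline:>12.4f}",
            f"RMSE [nN]               {self.rmse:>12.6g}",
            f"max error [nN]          {self.max_error:>12.6g}",
            f"resolution [nN]         {self.resolution:>12.6g}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "coefficient_nN_per_ADU": self.coefficient,
            "phase_deg": self.phase,
            "baseline_ADU": self.baseline,
            "rmse_nN": self.rmse,
            "max_error_nN": self.max_error,
            "resolution_nN": self.resolution,
            "n_points": self.n_points,
        }


class CalibrationModel:
    """Least-squares sinusoid fit of a calibration sweep.

    ADC_i = A cosθ_i + B sinθ_i + C is fitted by ordinary least squares;
    the amplitude R = sqrt(A² + B²) equals m·g / coefficient, the phase is
    atan2(B, A), the baseline is C.
    """

    def __init__(self, sweep: CalibrationSweep):
        self.sweep = sweep

    def fit(self) -> CalibrationResult:
        sweep = self.sweep
        theta = np.deg2rad(sweep.angles)
        X = np.column_stack([np.cos(theta), np.sin(theta), np.ones_like(theta)])
        if np.linalg.matrix_rank(X) < 3:
            raise np.linalg.LinAlgError(
                "degenerate sweep design: angles do not span the circle"
            )
        coef, *_ = np.linalg.lstsq(X, sweep.adc_values, rcond=None)
        A, B, C = coef
        R = float(np.hypot(A, B))
        if R <= 0:
            raise np.linalg.LinAlgError("zero sinusoid amplitude: cannot calibrate")
        mg = weight_nN(sweep.ball_mass, sweep.gravity)
        coefficient = mg / R
        phase = float(np.rad2deg(np.arctan2(B, A)))
        predicted_adc = X @ coef
        force_resid = (predicted_adc - sweep.adc_values) * coefficient
        rmse = float(np.sqrt(np.mean(force_resid**2)))
        max_error = float(np.max(np.abs(force_resid)))
        if sweep.angles.size >= 5:
            resolution = float(np.std(force_resid, ddof=1))
        else:
            resolution = float("nan")
        return CalibrationResult(
            coefficient=coefficient,
            phase=phase,
            baseline=float(C),
            rmse=rmse,
            max_error=max_error,
            resolution=resolution,
            n_points=int(sweep.angles.size),
        )


def fit_calibration(sweep: CalibrationSweep) -> CalibrationResult:
    """Fit a rotation sweep; see :class:`CalibrationModel`."""
    return CalibrationModel(sweep).fit()


def estimate_resolution(sweep: CalibrationSweep, result: CalibrationResult) -> float:
    """Sensor resolution: SD of force-converted fit residuals, nN.

    The smallest force change distinguishable from fit scatter, defined
    operationally as the standard deviation of (measured - predicted) forces.
    Requires at least 5 residuals.
    """
    if sweep.angles.size < 5:
        raise ValueError("need at least 5 residuals to estimate resolution")
    theta = np.deg2rad(sweep.angles)
    mg = weight_nN(sweep.ball_mass, sweep.gravity)
    predicted_adc = (
        (mg / result.coefficient) * np.cos(theta - np.deg2rad(result.phase))
        + result.baseline
    )
    force_resid = (predicted_adc - sweep.adc_values) * result.coefficient
    return float(np.std(force_resid, ddof=1))


def convert_trace(adc_values, result: CalibrationResult) -> np.ndarray:
    """Convert a raw ADC trace to force: F_i = (adc_i - baseline) * coefficient."""
    adc_values = np.asarray(adc_values, dtype=float)
    return (adc_values - result.baseline) * result.coefficient
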