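"""Power-law rheology across indentation speeds and depths.

Soft cells are viscoelastic: the apparent modulus depends on how fast they
are probed. The structural damping (power-law) model

    E(t) = E0 * (t / tref)^(-beta),      tref = 1 s

captures this with two parameters: E0, the modulus at the reference time,
and beta, the fluidity exponent (0 = purely elastic solid, 1 = Newtonian
viscous liquid). Varying the plate speed over 2.5-15.0 µm/s changes the
indentation time t at a fixed strain checkpoint by the same 6x factor, which
conditions a log-log regression for (E0, beta).

Probing at a shallow strain checkpoint interrogates mostly the cytoplasm;
a deep checkpoint engages the nucleus as well, so fitting the model per
depth regime separates fluid-like cytoplasmic from solid-like nuclear
behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .mechanics import StressStrainCurve
from .virtual_instrument import CompressionRecord

__all__ = [
    "RheologySample",
    "RheologyFit",
    "PowerLawModel",
    "apparent_modulus_at_checkpoint",
    "fit_power_law",
    "compare_regimes",
]

#: default strain checkpoints for the two depth regimes
LOW_COMPRESSION_CHECKPOINT = 0.15
HIGH_COMPRESSION_CHECKPOINT = 0.45


@dataclass(frozen=True)
class RheologySample:
    """One (indentation time, apparent modulus) observation.

    t: time from contact to the strain checkpoint, s. apparent_E: secant
    modulus σ/ε at the checkpoint, kPa. regime: 'low_compression' (cytoplasm)
    or 'high_compression' (nucleus engaged).
    """

    t: float
    apparent_E: float
    speed: float = np.nan
    regime: str = "low_compression"

    def __post_init__(self):
        if self.t <= 0:
            raise ValueError("t must be > 0")
        if self.apparent_E <= 0:
            raise ValueError("apparent_E must be > 0")


def apparent_modulus_at_checkpoint(
    curve: StressStrainCurve,
    record: CompressionRecord,
    strain_checkpoint: float,
    nucleus_contact_strain: float = 0.4,
) -> RheologySample:
    """Secant modulus σ/ε at a fixed strain checkpoint on the loading branch.

    The stress at the checkpoint is linearly interpolated between the
    bracketing loading points; t is the elapsed time from contact onset to
    the checkpoint. The sample is tagged 'low_compression' if the checkpoint
    is below the nucleus-contact strain, else 'high_compression'.
    """
    if not 0 < strain_checkpoint < 1:
        raise ValueError("strain_checkpoint must be in (0, 1)")
    load = curve.loading
    if load.strain.size < 2 or load.strain.max() < strain_checkpoint:
        raise ValueError("insufficient compression: checkpoint unreached")
    if load.time is None:
        raise ValueError("curve carries no time information")
    # loading strain is non-decreasing; interpolate stress and time
    stress_at = float(np.interp(strain_checkpoint, load.strain, load.stress))
    if np.isfinite(record.speed) and record.speed > 0:
        # exact elapsed time from contact for a constant-speed ramp
        t = strain_checkpoint * record.L0 / record.speed
    else:
        # record time is measured from contact onset
        t = float(np.interp(strain_checkpoint, load.strain, load.time))
    regime = (
        "low_compression"
        if strain_checkpoint < nucleus_contact_strain
        else "high_compression"
    )
    return RheologySample(
        t=t, apparent_E=stress_at / strain_checkpoint,
        speed=record.speed, regime=regime,
    )


@dataclass
class RheologyFit:
    """Fitted power-law parameters for one depth regime."""

    E0: float  # kPa, modulus at t = tref
    beta: float  # dimensionless fluidity exponent
    tref: float = 1.0  # s
    r_squared: float = np.nan
    n_samples: int = 0
    regime: str = ""

    def __post_init__(self):
        if self.E0 <= 0:
            raise ValueError("E0 must be > 0")

    def summary(self) -> str:
        return "\n".join(
            [
                f"Power-law rheology fit{' — ' + self.regime if self.regime else ''}",
                "=" * 40,
                f"E0 [kPa]   {self.E0:>12.4f}   (modulus at t = {self.tref:g} s)",
                f"beta       {self.beta:>12.4f}   (0 elastic solid, 1 viscous liquid)",
                f"n samples  {self.n_samples:>12d}",
                f"R^2        {self.r_squared:>12.6f}",
            ]
        )


class PowerLawModel:
    """Fit E(t) = E0 (t/tref)^(-beta) to apparent-modulus samples.

    Default method is ordinary least squares in log space (the model is an
    exact line there: ln E = ln E0 - beta·ln(t/tref)); nonlinear least
    squares on the original scale is available as a cross-check.
    """

    def __init__(self, samples: list[RheologySample], tref: float = 1.0):
        if tref <= 0:
            raise ValueError("tref must be > 0")
        if len(samples) < 3:
            raise ValueError("need at least 3 samples")
        t = np.array([s.t for s in samples], dtype=float)
        E = np.array([s.apparent_E for s in samples], dtype=float)
        if np.any(E <= 0):
            raise ValueError("invalid sample: non-positive apparent modulus")
        if np.unique(t).size < 2:
            raise np.linalg.LinAlgError("singular fit: all indentation times equal")
        self.t, self.E, self.tref = t, E, tref
        self.regime = samples[0].regime if samples else ""

    def fit(self, method: str = "ols") -> RheologyFit:
        if method == "ols":
            x = np.log(self.t / self.tref)
            y = np.log(self.E)
            res = stats.linregress(x, y)
            beta = -float(res.slope)
            E0 = float(np.exp(res.intercept))
            r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
        elif method == "nls":
            def model(t, E0, beta):
                return E0 * (t / self.tref) ** (-beta)

            p0 = (float(np.median(self.E)), 0.2)
            popt, _ = optimize.curve_fit(model, self.t, self.E, p0=p0, maxfev=10000)
            E0, beta = float(popt[0]), float(popt[1])
            ss_res = float(np.sum((self.E - model(self.t, *popt)) ** 2))
            ss_tot = float(np.sum((self.E - self.E.mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        else:
            raise ValueError("method must be 'ols' or 'nls'")
        return RheologyFit(
            E0=E0, beta=beta, tref=self.tref, r_squared=r2,
            n_samples=self.t.size, regime=self.regime,
        )


def fit_power_law(
    samples: list[RheologySample], tref: float = 1.0, method: str = "ols"
) -> RheologyFit:
    """Fit the power-law model; see :class:`PowerLawModel`."""
    return PowerLawModel(samples, tref=tref).fit(method=method)


def compare_regimes(low: RheologyFit, high: RheologyFit) -> dict:
    """Compare shallow- and deep-indentation fits.

    Reports the E0 ratio (deep/shallow) and the beta difference
    (shallow - deep), and flags whether the ordering matches the expected
    compartment picture: a stiffer, more solid-like response at depth
    (E0_high > E0_low and beta_high < beta_low). The flags describe this
    dataset; the ordering is not an invariant of arbitrary inputs.
    """
    if low is None or high is None:
        raise ValueError("both regimes required")
    ratio = high.E0 / low.E0
    beta_diff = low.beta - high.beta
    return {
        "E0_low_kPa": low.E0,
        "E0_high_kPa": high.E0,
        "E0_ratio_high_over_low": ratio,
        "beta_low": low.beta,
        "beta_high": high.beta,
        "beta_diff_low_minus_high": beta_diff,
        "stiffer_at_depth": bool(ratio > 1),
        "more_solid_at_depth": bool(beta_diff > 0),
    }
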