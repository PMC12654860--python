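"""Stress-strain construction and elastic-modulus extraction.

From a synchronized force/geometry record of one compression run:

* engineering strain   ε_t = (L0 - L_t) / L0
* contact stress       σ_t = F_t / S_t with S_t = π·D_t²/4
  (force in nN, area in µm², so σ is in kPa with no conversion factor)
* the elastic modulus E is the ordinary-least-squares slope of σ on ε over
  the high-strain region of the loading branch (default: the top 30% of the
  achieved strain), where the stress-strain plot is linear.

Points without plate contact (S_t = 0) carry no stress information and are
excluded, not assigned infinite stress.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .image_geometry import contact_area
from .virtual_instrument import CompressionRecord

__all__ = [
    "StressStrainCurve",
    "ModulusEstimate",
    "ElasticModulusModel",
    "compute_stress",
    "compute_strain",
    "build_curve",
    "fit_elastic_modulus",
    "max_force",
]


def compute_stress(Ft, St):
    """Contact stress σ = F/S; nN/µm² reported as kPa (identical units)."""
    Ft = np.asarray(Ft, dtype=float)
    St = np.asarray(St, dtype=float)
    if np.any(St <= 0):
        raise ValueError("no-contact point: St must be > 0 to define stress")
    out = Ft / St
    return out.item() if out.ndim == 0 else out


def compute_strain(Lt, L0):
    """Engineering strain ε = (L0 - Lt)/L0.

    Lt > L0 yields negative strain; a warning is emitted and the affected
    points are flagged (and excluded) by :func:`build_curve`.
    """
    Lt = np.asarray(Lt, dtype=float)
    if L0 <= 0:
        raise ValueError("L0 must be > 0")
    if np.any(Lt <= 0):
        raise ValueError("Lt must be > 0")
    if np.any(Lt > L0):
        warnings.warn("Lt > L0: negative strain point(s) flagged", stacklevel=2)
    out = (L0 - Lt) / L0
    return out.item() if out.ndim == 0 else out


@dataclass
class StressStrainCurve:
    """Per-timepoint stress/strain with loading/unloading branch labels."""

    strain: np.ndarray  # dimensionless, in [0, 1)
    stress: np.ndarray  # kPa
    branch: np.ndarray  # 'loading' | 'unloading'
    time: np.ndarray | None = None  # s, elapsed from record start
    n_dropped: int = 0  # no-contact points excluded

    def __post_init__(self):
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        self.branch = np.asarray(self.branch)
        if not (self.strain.shape == self.stress.shape == self.branch.shape):
            raise ValueError("strain/stress/branch length mismatch")

    @property
    def loading(self) -> "StressStrainCurve":
        m = self.branch == "loading"
        return StressStrainCurve(
            self.strain[m],
            self.stress[m],
            self.branch[m],
            None if self.time is None else self.time[m],
        )


def build_curve(record: CompressionRecord) -> StressStrainCurve:
    """Build the stress-strain curve of one compression run.

    Strain from the geometry series, stress from force over the contact
    circle π·Dt²/4. No-contact points (Dt = 0) are dropped and counted.
    The branch is split at the index of maximum strain: everything up to and
    including it is loading, the rest unloading.
    """
    strain_all = compute_strain(record.Lt, record.L0)
    area = contact_area(record.Dt)
    contact = (area > 0) & (np.atleast_1d(strain_all) >= 0)
    n_dropped = int(np.size(contact) - np.count_nonzero(contact))
    if np.count_nonzero(contact) < 3:
        raise ValueError("insufficient data: fewer than 3 contact points")
    strain = np.atleast_1d(strain_all)[contact]
    stress = np.asarray(record.force, dtype=float)[contact] / np.asarray(area)[contact]
    time = np.asarray(record.time, dtype=float)[contact]
    split = int(np.argmax(strain))
    branch = np.array(
        ["loading"] * (split + 1) + ["unloading"] * (strain.size - split - 1)
    )
    return StressStrainCurve(strain, stress, branch, time=time, n_dropped=n_dropped)


@dataclass
class ModulusEstimate:
    """Elastic modulus from the high-strain linear fit.

    E: slope of stress on strain, kPa. fit_strain_range: (lo, hi) strain
    window actually used. r_squared: coefficient of determination of the fit.
    """

    E: float
    fit_strain_range: tuple[float, float]
    r_squared: float
    n_points: int
    intercept: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.E):
            raise ValueError("E must be finite")
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")

    def summary(self) -> str:
        lo, hi = self.fit_strain_range
        return "\n".join(
            [
                "Elastic modulus (high-strain linear regression)",
                "=" * 47,
                f"E [kPa]          {self.E:>12.4f}",
                f"strain window    [{lo:.4f}, {hi:.4f}]",
                f"n points         {self.n_points:>12d}",
                f"R^2              {self.r_squared:>12.6f}",
            ]
        )


class ElasticModulusModel:
    """OLS fit of stress on strain over the high-strain loading window.

    The window contains loading points with ε >= (1 - high_strain_fraction)
    · ε_max. The regression includes an intercept; on linear data the slope
    equals the modulus either way, and an intercept absorbs contact-onset
    offsets.
    """

    def __init__(self, curve: StressStrainCurve, high_strain_fraction: float = 0.3):
        if not 0 < high_strain_fraction <= 1:
            raise ValueError("high_strain_fraction must be in (0, 1]")
        self.curve = curve
        self.high_strain_fraction = high_strain_fraction

    def fit(self) -> ModulusEstimate:
        load = self.curve.loading
        if load.strain.size == 0:
            raise ValueError("no loading points")
        eps_max = load.strain.max()
        cutoff = (1.0 - self.high_strain_fraction) * eps_max
        sel = load.strain >= cutoff
        if np.count_nonzero(sel) < 3:
            raise ValueError("insufficient data: fewer than 3 high-strain points")
        x = load.strain[sel]
        y = load.stress[sel]
        res = stats.linregress(x, y)
        return ModulusEstimate(
            E=float(res.slope),
            fit_strain_range=(float(x.min()), float(x.max())),
            r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0,
            n_points=int(x.size),
            intercept=float(res.intercept),
        )


def fit_elastic_modulus(
    curve: StressStrainCurve, high_strain_fraction: float = 0.3
) -> ModulusEstimate:
    """Fit the elastic modulus; see :class:`ElasticModulusModel`."""
    return ElasticModulusModel(curve, high_strain_fraction).fit()


def max_force(record: CompressionRecord) -> float:
    """Maximum force recorded during the compression run, nN."""
    force = np.asarray(record.force, dtype=float)
    if force.size == 0:
        raise ValueError("empty force series")
    return float(force.max())
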