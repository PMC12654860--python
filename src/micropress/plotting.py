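"""Quick-look plots for calibration sweeps, stress-strain curves, and
population stiffness densities. Each function draws onto a supplied (or
fresh) matplotlib Axes and returns it."""

from __future__ import annotations

import numpy as np

from .calibration import CalibrationResult, expected_axis_force
from .mechanics import StressStrainCurve
from .population import CellPopulation, histogram_density
from .virtual_instrument import CalibrationSweep

__all__ = ["plot_calibration", "plot_stress_strain", "plot_density"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_calibration(sweep: CalibrationSweep, result: CalibrationResult, ax=None):
    """Measured sweep (force units) against the fitted sinusoid."""
    ax = _ax(ax)
    force = (sweep.adc_values - result.baseline) * result.coefficient
    ax.plot(sweep.angles, force, "o", ms=4, label="measured")
    grid = np.linspace(sweep.angles[0], sweep.angles[-1], 400)
    ax.plot(
        grid,
        expected_axis_force(sweep.ball_mass, grid, result.phase, sweep.gravity),
        "-",
        label="fit",
    )
    ax.set_xlabel("rotation angle (deg)")
    ax.set_ylabel("axial force (nN)")
    ax.legend()
    return ax


def plot_stress_strain(curve: StressStrainCurve, ax=None):
    """Loading and unloading branches of one compression run."""
    ax = _ax(ax)
    for branch, color in (("loading", "tab:orange"), ("unloading", "tab:blue")):
        m = curve.branch == branch
        if m.any():
            ax.plot(curve.strain[m], curve.stress[m], ".", color=color, label=branch)
    ax.set_xlabel("strain")
    ax.set_ylabel("stress (kPa)")
    ax.legend()
    return ax


def plot_density(pop: CellPopulation, bin_width: float = 1.0, ax=None):
    """Fraction of cells per bin_width-kPa interval (density histogram)."""
    ax = _ax(ax)
    edges, dens = histogram_density(pop, bin_width)
    ax.bar(edges[:-1], dens, width=bin_width, align="edge", alpha=0.7)
    ax.set_xlabel("elastic modulus (kPa)")
    ax.set_ylabel(f"fraction of cells per {bin_width:g} kPa")
    ax.set_title(pop.condition)
    return ax
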