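"""Population-level stiffness statistics.

Summaries (mean ± sample SD), classic pooled-variance two-sample t-tests,
per-1-kPa density histograms, KDE-based mode detection (for spotting bimodal
stiffness distributions such as the progerin-overexpression phenotype), and
dose-response monotonicity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CellPopulation",
    "ConditionSummary",
    "summarize",
    "students_t_test",
    "histogram_density",
    "detect_modes",
    "dose_response_check",
]


@dataclass
class CellPopulation:
    """Condition-labelled collection of elastic moduli (kPa)."""

    condition: str
    moduli: np.ndarray

    def __post_init__(self):
        self.moduli = np.asarray(self.moduli, dtype=float)
        if self.moduli.size < 1:
            raise ValueError("population must contain at least one modulus")
        if np.any(self.moduli <= 0):
            raise ValueError("moduli must be > 0")

    @property
    def n(self) -> int:
        return int(self.moduli.size)


@dataclass
class ConditionSummary:
    """mean ± SD (n) with SEM, kPa."""

    condition: str
    mean: float
    sd: float
    n: int
    sem: float

    def __str__(self) -> str:
        return f"{self.condition}: {self.mean:.2f} ± {self.sd:.2f} kPa (n = {self.n})"


def summarize(pop: CellPopulation) -> ConditionSummary:
    """Mean, sample SD (n-1 denominator), n and SEM of one condition."""
    x = pop.moduli
    sd = float(np.std(x, ddof=1)) if x.size >= 2 else 0.0
    return ConditionSummary(
        condition=pop.condition,
        mean=float(np.mean(x)),
        sd=sd,
        n=x.size,
        sem=sd / np.sqrt(x.size),
    )


def students_t_test(
    a: CellPopulation, b: CellPopulation, welch: bool = False
) -> tuple[float, float]:
    """Two-sample Student's t-test (pooled variance, two-tailed).

    Returns (t, p) with df = n_a + n_b - 2. Welch's unequal-variance variant
    is available behind the `welch` flag. Degenerate case: zero pooled
    variance with equal means returns (0.0, 1.0); with unequal means it is an
    error.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    xa, xb = a.moduli, b.moduli
    if np.var(xa, ddof=1) == 0 and np.var(xb, ddof=1) == 0:
        if np.mean(xa) == np.mean(xb):
            return 0.0, 1.0
        raise ValueError("degenerate variance with unequal means")
    t, p = stats.ttest_ind(xa, xb, equal_var=not welch)
    return float(t), float(p)


def histogram_density(
    pop: CellPopulation, bin_width: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of cells per `bin_width`-kPa interval, as a density.

    Bins are [k·w, (k+1)·w); density = count / (n·w), so density × w sums
    to 1. Returns (bin_edges, density) with len(edges) = len(density) + 1.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    x = pop.moduli
    k_max = int(np.floor(x.max() / bin_width)) + 1
    edges = np.arange(0, k_max + 1) * bin_width
    counts, _ = np.histogram(x, bins=edges)
    density = counts / (x.size * bin_width)
    return edges, density


def detect_modes(
    pop: CellPopulation,
    prominence_fraction: float = 0.10,
    bimodal_separation: float = 2.0,
) -> dict:
    """Locate stiffness modes with a Gaussian KDE (Silverman bandwidth).

    Modes are local maxima of the KDE exceeding `prominence_fraction` of the
    global maximum, returned sorted. The population is flagged bimodal when
    at least two modes are separated by more than `bimodal_separation` kPa
    (the separation of the 2-4 and 6-8 kPa stiffness bands).
    """
    if pop.n < 20:
        raise ValueError("insufficient data: need n >= 20 for mode detection")
    x = pop.moduli
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(max(x.min() - 2, 0.01), x.max() + 2, 1024)
    dens = kde(grid)
    peak = dens.max()
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    idx = np.flatnonzero(interior) + 1
    idx = idx[dens[idx] >= prominence_fraction * peak]
    modes = np.sort(grid[idx])
    bimodal = bool(modes.size >= 2 and np.max(np.diff(modes)) > bimodal_separation)
    return {"modes_kPa": modes, "n_modes": int(modes.size), "bimodal": bimodal}


def dose_response_check(summaries: list[ConditionSummary]) -> dict:
    """Check whether condition means decrease monotonically with dose.

    `summaries` must be ordered by increasing dose; reports whether means are
    non-increasing and the total relative decrease from first to last.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 summaries in dose order")
    means = np.array([s.mean for s in summaries])
    monotone = bool(np.all(np.diff(means) <= 0))
    return {
        "conditions": [s.condition for s in summaries],
        "means_kPa": means,
        "monotone_decreasing": monotone,
        "total_relative_decrease": float((means[0] - means[-1]) / means[0]),
    }
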