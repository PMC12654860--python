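"""Virtual two-plate compression instrument.

Synthesises everything the analysis chain consumes, so the full pipeline is
testable without hardware:

* gravimetric calibration sweeps — a steel ball loads the force sensor while
  it is rotated through one revolution, giving a sinusoidal ADC trace;
* constant-speed compression runs on a two-compartment (cytoplasm/nucleus)
  power-law viscoelastic cell, producing synchronized force and geometry
  series with loading and unloading branches;
* bright-field-like micrographs of the squashed cell between two plate edges;
* cell populations drawn from truncated normal mixtures that encode the
  measured stiffness distributions of the studied conditions.

Geometry model: the cell is a rigid truncated sphere of initial diameter L0.
At engineering strain ε the plate separation is Lt = L0(1-ε) and the
cell-plate contact patch is the sphere chord D(ε) = L0·sqrt(2ε-ε²); the
contact area is the circle π D²/4. Lateral bulging and volume conservation
are deliberately not modelled.

Compartment model: the nucleus (diameter nucleus_fraction·L0) engages once
the plates reach it, at strain ε* = 1 - nucleus_fraction. Below ε* the
apparent modulus is the cytoplasm's power law; above it the compartments act
in series along the compression axis and the apparent modulus is the
strain-weighted harmonic mean of the two power laws.

All randomness is behind explicit integer seeds; no global RNG state is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import STANDARD_GRAVITY, weight_nN

__all__ = [
    "SensorParams",
    "VirtualCellParams",
    "CompressionRunSpec",
    "PopulationPreset",
    "CalibrationSweep",
    "CompressionRecord",
    "simulate_calibration_sweep",
    "simulate_compression",
    "contact_diameter",
    "render_frame",
    "sample_population",
    "simulate_max_force_scenario",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class SensorParams:
    """Ground-truth characteristics of a virtual strain-gauge force sensor.

    true_coefficient
        Force-to-signal conversion coefficient, nN per ADC unit (> 0).
    phase_offset
        Angular offset of the sensitive axis, degrees.
    adc_baseline
        ADC output at zero force, ADU.
    adc_noise_sd
        SD of additive Gaussian ADC noise, ADU (>= 0).
    """

    true_coefficient: float
    phase_offset: float = 0.0
    adc_baseline: float = 0.0
    adc_noise_sd: float = 0.0

    def __post_init__(self):
        if self.true_coefficient <= 0:
            raise ValueError("true_coefficient must be > 0")
        if self.adc_noise_sd < 0:
            raise ValueError("adc_noise_sd must be >= 0")


@dataclass(frozen=True)
class VirtualCellParams:
    """Two-compartment power-law viscoelastic cell.

    L0 is the initial cell diameter (µm); the nucleus has diameter
    nucleus_fraction * L0. Each compartment follows
    E(t) = E0 * (t / tref)^(-beta) with tref = 1 s; beta = 0 is a purely
    elastic solid, beta = 1 a Newtonian liquid. unload_retention scales the
    unloading-branch stress relative to loading at equal strain (hysteresis).
    """

    L0: float = 15.0
    nucleus_fraction: float = 0.6
    E0_cyto: float = 2.0
    E0_nuc: float = 8.0
    beta_cyto: float = 0.35
    beta_nuc: float = 0.1
    unload_retention: float = 0.7

    def __post_init__(self):
        if self.L0 <= 0:
            raise ValueError("L0 must be > 0")
        if not 0 < self.nucleus_fraction < 1:
            raise ValueError("nucleus_fraction must be in (0, 1)")
        if self.E0_cyto <= 0 or self.E0_nuc <= 0:
            raise ValueError("moduli must be > 0")
        if not (0 <= self.beta_cyto <= 1 and 0 <= self.beta_nuc <= 1):
            raise ValueError("beta must be in [0, 1]")
        if not 0 < self.unload_retention <= 1:
            raise ValueError("unload_retention must be in (0, 1]")

    @property
    def nucleus_contact_strain(self) -> float:
        """Strain at which the plates reach the nucleus: 1 - nucleus_fraction."""
        return 1.0 - self.nucleus_fraction


@dataclass(frozen=True)
class CompressionRunSpec:
    """One constant-speed compression protocol.

    speed: plate approach speed, µm/s (the instrument operates at 2.5-15.0).
    max_strain: target engineering strain, in (0, 1).
    sample_rate: force/frame sampling rate, Hz.
    include_unloading: append the retraction branch.
    force_noise_sd: additive Gaussian force noise, nN.
    """

    speed: float = 10.0
    max_strain: float = 0.5
    sample_rate: float = 100.0
    include_unloading: bool = True
    force_noise_sd: float = 0.0

    def __post_init__(self):
        if self.speed <= 0:
            raise ValueError("speed must be > 0")
        if not 0 < self.max_strain < 1:
            raise ValueError("max_strain must be in (0, 1)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.force_noise_sd < 0:
            raise ValueError("force_noise_sd must be >= 0")


@dataclass(frozen=True)
class PopulationPreset:
    """A condition-labelled stiffness distribution.

    components: (weight, mean kPa, sd kPa) triples of a normal mixture,
    truncated below at `truncation` kPa so moduli are positive.
    """

    name: str
    components: tuple
    truncation: float = 0.1

    def __post_init__(self):
        w = sum(c[0] for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if any(c[2] < 0 for c in self.components):
            raise ValueError("component sds must be >= 0")
        if self.truncation <= 0:
            raise ValueError("truncation must be > 0")

    @property
    def mean(self) -> float:
        """Mixture mean of the untruncated normal components, kPa."""
        return sum(w * m for w, m, _ in self.components)

    @property
    def sd(self) -> float:
        mu = self.mean
        var = sum(w * (s**2 + (m - mu) ** 2) for w, m, s in self.components)
        return float(np.sqrt(var))

    @property
    def truncated_mean(self) -> float:
        """Exact mean of the mixture after truncation below `truncation` kPa.

        This is the generator's true expected modulus; for conditions whose
        mean sits several SDs above the bound it is within a fraction of a
        percent of the nominal mixture mean.
        """
        from scipy.stats import truncnorm

        total = 0.0
        for w, m, s in self.components:
            if s == 0:
                total += w * max(m, self.truncation)
                continue
            a = (self.truncation - m) / s
            total += w * truncnorm.mean(a, np.inf, loc=m, scale=s)
        return float(total)


# ---------------------------------------------------------------------------
# records produced by the simulator


@dataclass
class CalibrationSweep:
    """Raw rotation-sweep record: angle/ADC pairs plus the loading mass."""

    angles: np.ndarray  # degrees, strictly increasing within one revolution
    adc_values: np.ndarray  # ADU
    ball_mass: float  # grams
    gravity: float = STANDARD_GRAVITY  # m/s^2

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.adc_values = np.asarray(self.adc_values, dtype=float)
        if self.angles.shape != self.adc_values.shape:
            raise ValueError("angles and adc_values must have equal length")
        if self.angles.size < 4:
            raise ValueError("need at least 4 angular positions")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.ball_mass <= 0:
            raise ValueError("ball_mass must be > 0")


@dataclass
class CompressionRecord:
    """Synchronized time/force/geometry series for one compression run.

    Geometry (Dt, Lt) is the simulator's ground truth; image-based analysis
    replaces it with measured values. `branch` labels each sample 'loading'
    or 'unloading'.
    """

    time: np.ndarray  # s
    force: np.ndarray  # nN
    Dt: np.ndarray  # contact length, µm
    Lt: np.ndarray  # plate separation / cell width, µm
    L0: float  # µm
    branch: np.ndarray = field(default=None)  # type: ignore[assignment]
    speed: float = np.nan  # µm/s

    def __post_init__(self):
        n = len(self.time)
        for name in ("force", "Dt", "Lt"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if self.branch is None:
            self.branch = np.array(["loading"] * n)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


# ---------------------------------------------------------------------------
# calibration sweep


def simulate_calibration_sweep(
    sensor: SensorParams,
    ball_mass: float,
    n_steps: int = 50,
    seed: int = 0,
    gravity: float = STANDARD_GRAVITY,
) -> CalibrationSweep:
    """Simulate a gravimetric rotation sweep of the force sensor.

    The sensor is rotated through one full revolution in `n_steps` equal
    increments (angle_i = i * 360/n_steps degrees). At each angle the axial
    gravity component of the steel ball, m·g·cos(angle - phase_offset),
    divided by the true conversion coefficient, adds to the ADC baseline;
    Gaussian ADC noise is applied when the sensor has adc_noise_sd > 0.

    Parameters
    ----------
    ball_mass : float
        Mass of the loading ball in grams (> 0).
    n_steps : int
        Number of angular positions (>= 4); 50 gives the 7.2°/step protocol.
    """
    if ball_mass <= 0:
        raise ValueError("ball_mass must be > 0")
    if n_steps < 4:
        raise ValueError("n_steps must be >= 4")
    rng = np.random.default_rng(seed)
    angles = np.arange(n_steps) * (360.0 / n_steps)
    mg = weight_nN(ball_mass, gravity)
    axial = mg * np.cos(np.deg2rad(angles - sensor.phase_offset))
    adc = sensor.adc_baseline + axial / sensor.true_coefficient
    if sensor.adc_noise_sd > 0:
        adc = adc + rng.normal(0.0, sensor.adc_noise_sd, size=n_steps)
    return CalibrationSweep(angles, adc, ball_mass, gravity)


# ---------------------------------------------------------------------------
# compression mechanics of the virtual cell


def contact_diameter(strain, L0):
    """Truncated-sphere chord: D(ε) = L0·sqrt(2ε - ε²), µm.

    D(0) = 0, strictly increasing on (0, 1), D(1) = L0.
    """
    strain = np.asarray(strain, dtype=float)
    return L0 * np.sqrt(np.clip(2.0 * strain - strain**2, 0.0, None))


def _apparent_modulus(cell: VirtualCellParams, strain, t):
    """Apparent (secant) modulus of the stacked compartments at strain/time.

    Below the nucleus-contact strain only the cytoplasm deforms; above it the
    compartments are in series along the compression axis and the combined
    modulus is the strain-weighted harmonic mean.
    """
    strain = np.asarray(strain, dtype=float)
    t = np.asarray(t, dtype=float)
    tsafe = np.where(t > 0, t, 1.0)  # E is only used where strain>0 (t>0)
    E_c = cell.E0_cyto * tsafe**-cell.beta_cyto
    E_n = cell.E0_nuc * tsafe**-cell.beta_nuc
    eps_star = cell.nucleus_contact_strain
    with np.errstate(divide="ignore", invalid="ignore"):
        w_c = np.where(strain > 0, np.minimum(eps_star, strain) / np.where(strain > 0, strain, 1.0), 1.0)
        w_n = 1.0 - w_c
        E = 1.0 / (w_c / E_c + w_n / E_n)
    return E


def simulate_compression(
    cell: VirtualCellParams,
    run: CompressionRunSpec,
    seed: int = 0,
) -> CompressionRecord:
    """Simulate one constant-speed two-plate compression run.

    Loading: ε(t) = min(speed·t / L0, max_strain); stress σ = E_app(ε, t)·ε
    with the two-compartment power-law modulus; force F = σ·πD²/4 on the
    truncated-sphere contact patch, plus additive Gaussian noise. Unloading
    (if requested) retraces the strain ramp in reverse with stress scaled by
    `unload_retention` at equal strain. Ground-truth geometry
    (Dt = L0·sqrt(2ε-ε²), Lt = L0(1-ε)) is stored with the trace.
    """
    rng = np.random.default_rng(seed)
    t_load = cell.L0 * run.max_strain / run.speed
    n_load = max(int(np.floor(t_load * run.sample_rate)), 3)
    dt = 1.0 / run.sample_rate
    time_load = np.arange(1, n_load + 1) * dt
    strain_load = np.minimum(run.speed * time_load / cell.L0, run.max_strain)

    E_load = _apparent_modulus(cell, strain_load, time_load)
    stress_load = E_load * strain_load

    if run.include_unloading:
        # retraction mirrors the ramp; stress at equal strain is scaled
        strain_unload = strain_load[-2::-1]
        time_unload = time_load[-1] + np.arange(1, strain_unload.size + 1) * dt
        # unloading modulus evaluated at the loading time of equal strain,
        # so stress_unload(ε) = retention * stress_load(ε) exactly
        t_equiv = time_load[-2::-1]
        E_unload = _apparent_modulus(cell, strain_unload, t_equiv)
        stress_unload = cell.unload_retention * E_unload * strain_unload
        time = np.concatenate([time_load, time_unload])
        strain = np.concatenate([strain_load, strain_unload])
        stress = np.concatenate([stress_load, stress_unload])
        branch = np.array(
            ["loading"] * strain_load.size + ["unloading"] * strain_unload.size
        )
    else:
        time, strain, stress = time_load, strain_load, stress_load
        branch = np.array(["loading"] * strain_load.size)

    Dt = contact_diameter(strain, cell.L0)
    area = np.pi * Dt**2 / 4.0
    force = stress * area  # 1 kPa * µm² = 1 nN, exact
    if run.force_noise_sd > 0:
        force = force + rng.normal(0.0, run.force_noise_sd, size=force.size)
    Lt = cell.L0 * (1.0 - strain)
    return CompressionRecord(
        time=time, force=force, Dt=Dt, Lt=Lt, L0=cell.L0, branch=branch,
        speed=run.speed,
    )


# ---------------------------------------------------------------------------
# synthetic micrographs

_BG, _CELL, _PLATE = 0.9, 0.5, 0.2


def render_frame(
    Lt: float,
    Dt: float,
    cell_center: tuple[float, float] | None = None,
    pixel_size: float = 0.1,
    image_shape: tuple[int, int] = (256, 256),
) -> tuple[np.ndarray, dict]:
    """Render a bright-field-like frame of a cell squeezed between two plates.

    The compression axis is horizontal: two dark plate bands occupy the left
    and right image margins with inner edges Lt apart, and a darker cell sits
    between them. The cell silhouette is a circular barrel with flat contact
    pads: within a thin zone at each plate the transverse chord is exactly Dt
    (a compressed cell is flat against the plate over its contact patch), and
    the silhouette bulges circularly in between. Dt = 0 renders a pre-contact
    frame: a circle of diameter Lt with the plates opened a few pixels wider
    than the cell, as they are before touching it.

    Returns (intensities, truth) where truth records the ground-truth
    Lt/Dt (µm) and the plate inner-edge x positions (µm).
    """
    if Lt <= 0:
        raise ValueError("Lt must be > 0")
    if Dt < 0:
        raise ValueError("Dt must be >= 0")
    ny, nx = image_shape
    if cell_center is None:
        cell_center = (nx / 2.0, ny / 2.0)  # (x, y) in pixels
    cx_um = cell_center[0] * pixel_size
    cy_um = cell_center[1] * pixel_size
    width_um = nx * pixel_size
    height_um = ny * pixel_size

    # pre-contact frames: plates sit a little wider than the cell
    gap = Lt if Dt > 0 else Lt + 8.0 * pixel_size
    left_edge = cx_um - gap / 2.0
    right_edge = cx_um + gap / 2.0

    # flat contact pad depth (along the axis) at each plate
    w_flat = 3.0 * pixel_size if Dt > 0 else 0.0
    w_flat = min(w_flat, 0.45 * Lt)
    half_len = Lt / 2.0 - w_flat  # axial half-extent of the circular barrel
    barrel_radius = float(np.hypot(half_len, Dt / 2.0))
    lateral_half = max(barrel_radius, Dt / 2.0)

    if left_edge <= 2 * pixel_size or right_edge >= width_um - 2 * pixel_size:
        raise ValueError("plate gap does not fit inside the frame")
    if cy_um - lateral_half < 0 or cy_um + lateral_half > height_um:
        raise ValueError("cell does not fit inside the frame")

    # pixel-centre sampling
    x = (np.arange(nx) + 0.5) * pixel_size
    y = (np.arange(ny) + 0.5) * pixel_size
    X, Y = np.meshgrid(x, y)

    img = np.full(image_shape, _BG, dtype=float)
    img[:, x <= left_edge] = _PLATE
    img[:, x >= right_edge] = _PLATE

    u = np.abs(X - cx_um)  # axial distance from cell centre
    with np.errstate(invalid="ignore"):
        chord = np.where(
            u >= half_len,
            Dt,
            2.0 * np.sqrt(np.maximum(barrel_radius**2 - u**2, 0.0)),
        )
    in_cell = (np.abs(Y - cy_um) <= chord / 2.0) & (u <= Lt / 2.0)
    between = (X > left_edge) & (X < right_edge)
    img[in_cell & between] = _CELL

    truth = {
        "Lt_um": Lt,
        "Dt_um": Dt,
        "left_edge_um": left_edge,
        "right_edge_um": right_edge,
        "pixel_size": pixel_size,
    }
    return img, truth


# ---------------------------------------------------------------------------
# populations


def sample_moduli(preset: PopulationPreset, n: int, seed: int = 0) -> np.ndarray:
    """Draw n whole-cell moduli (kPa) from the preset's truncated mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    weights = np.array([c[0] for c in preset.components])
    comp = rng.choice(len(preset.components), size=n, p=weights)
    out = np.empty(n)
    for i, k in enumerate(comp):
        _, mu, sd = preset.components[k]
        if sd == 0:
            out[i] = max(mu, preset.truncation)
            continue
        v = rng.normal(mu, sd)
        while v < preset.truncation:  # rejection below the support bound
            v = rng.normal(mu, sd)
        out[i] = v
    return out


def sample_population(
    preset: PopulationPreset,
    n: int,
    seed: int = 0,
    L0: float = 15.0,
    nucleus_fraction: float = 0.6,
) -> list[VirtualCellParams]:
    """Draw n virtual cells whose measured modulus matches the preset draw.

    Each drawn whole-cell modulus becomes an elastic (β = 0) cell with both
    compartments at that modulus, so the stress-strain slope recovered by the
    analysis chain equals the drawn value: the presets encode distributions
    of *measured* stiffness, not compartment rheology.
    """
    moduli = sample_moduli(preset, n, seed)
    return [
        VirtualCellParams(
            L0=L0,
            nucleus_fraction=nucleus_fraction,
            E0_cyto=float(e),
            E0_nuc=float(e),
            beta_cyto=0.0,
            beta_nuc=0.0,
        )
        for e in moduli
    ]


# ---------------------------------------------------------------------------
# end-effector scenario: plate vs needle


def simulate_max_force_scenario(
    cells: list[VirtualCellParams],
    run: CompressionRunSpec,
    effector: str = "plate",
    seed: int = 0,
    needle_contact_um: float = 2.0,
    slip_noise_cv: float = 0.5,
) -> np.ndarray:
    """Maximum compression force per cell for plate- or needle-shaped tips.

    The plate scenario uses the standard simulator. The needle scenario keeps
    the whole-cell reaction force (the force needed to impose a displacement
    is transmitted through the cell body, not set by the tip footprint) but
    models the unstable engagement of the fixed small contact patch
    (diameter `needle_contact_um`) as multiplicative log-normal slip noise
    with unit mean and coefficient of variation `slip_noise_cv`. At equal
    cell parameters this widens the max-force distribution relative to the
    plate, whose broad contact engages reproducibly.
    """
    if effector not in ("plate", "needle"):
        raise ValueError("effector must be 'plate' or 'needle'")
    if needle_contact_um <= 0:
        raise ValueError("needle_contact_um must be > 0")
    rng = np.random.default_rng(seed)
    out = np.empty(len(cells))
    for i, cell in enumerate(cells):
        rec = simulate_compression(cell, run, seed=int(rng.integers(2**31)))
        fmax = float(np.max(rec.force))
        if effector == "needle":
            sigma = np.sqrt(np.log1p(slip_noise_cv**2))
            fmax *= rng.lognormal(-0.5 * sigma**2, sigma)
        out[i] = fmax
    return out
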