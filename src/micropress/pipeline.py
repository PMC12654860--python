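"""End-to-end virtual experiments.

Each scenario composes the virtual instrument with the analysis chain the
way the physical experiments are run: populations of virtual cells are
compressed one by one, their geometry is measured (from rendered micrographs
by default, or from the simulator's ground-truth geometry tables), stress-
strain curves are built, moduli extracted, and condition-level statistics
computed. Identical seed and config give identical outputs.

Scenarios
---------
calibration      gravimetric sweep of a representative sensor, fitted
cell_panel       five cell-type stiffness panels
cd_dose          Cytochalasin D dose series + monotonicity check
tsa_dose         Trichostatin A dose series + monotonicity check
trypsinization   trypsinized vs non-trypsinized comparison (t-test)
progerin         lamin A / progerin overexpression panel + mode detection
rheology_sweep   speed sweep, power-law fits per depth regime
needle_vs_plate  max-force spread for needle vs plate end-effectors
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import io as mio
from .config import PipelineConfig, validate_and_log
from .image_geometry import Micrograph, measure_frame
from .mechanics import ModulusEstimate, build_curve, fit_elastic_modulus, max_force
from .population import (
    CellPopulation,
    detect_modes,
    dose_response_check,
    students_t_test,
    summarize,
)
from .presets import get_preset, reported_n
from .rheology import apparent_modulus_at_checkpoint, compare_regimes, fit_power_law
from .virtual_instrument import (
    CompressionRecord,
    CompressionRunSpec,
    SensorParams,
    VirtualCellParams,
    render_frame,
    sample_population,
    simulate_calibration_sweep,
    simulate_compression,
    simulate_max_force_scenario,
)

__all__ = [
    "measure_geometry_from_images",
    "measure_cell_modulus",
    "run_condition",
    "run_virtual_experiment",
    "SCENARIOS",
]

#: indentation speeds for the rheology sweep, µm/s
RHEOLOGY_SPEEDS = (2.5, 5.0, 10.0, 15.0)


def _child_seeds(seed: int, n: int) -> list[int]:
    """n reproducible sub-seeds below 2**31 derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def _frame_shape(L0: float, pixel_size: float) -> tuple[int, int]:
    ny = int(np.ceil(1.25 * L0 / pixel_size))
    nx = int(np.ceil(1.45 * L0 / pixel_size))
    return ny, nx


def measure_geometry_from_images(
    record: CompressionRecord, pixel_size: float = 0.1
) -> CompressionRecord:
    """Replace ground-truth geometry by image-measured geometry.

    Renders one micrograph per sample from the ground-truth (Lt, Dt), then
    measures plate separation and contact length back from the pixels. The
    initial width L0 is measured from an approach frame — the undeformed cell
    imaged just before plate contact — via the segmented cell mask, exactly
    as an image-only analysis reads the initial width off the video. (Taking
    L0 from the first *contact* frame instead would under-read it by one
    frame-period of travel and bias every modulus down by speed/(rate·L0).)
    """
    shape = _frame_shape(record.L0, pixel_size)
    approach, _ = render_frame(
        float(record.L0), 0.0, pixel_size=pixel_size, image_shape=shape
    )
    L0_meas = float(measure_frame(Micrograph(approach, pixel_size)).Lt)
    Dt_meas = np.empty(len(record.time))
    Lt_meas = np.empty(len(record.time))
    for i, (Lt, Dt) in enumerate(zip(record.Lt, record.Dt)):
        img, _ = render_frame(
            float(Lt), float(Dt), pixel_size=pixel_size, image_shape=shape
        )
        g = measure_frame(Micrograph(img, pixel_size), frame_index=i)
        Dt_meas[i], Lt_meas[i] = g.Dt, g.Lt
    if not np.any(Dt_meas > 0):
        raise ValueError("no contact detected in any frame")
    return CompressionRecord(
        time=np.asarray(record.time, dtype=float),
        force=np.asarray(record.force, dtype=float),
        Dt=Dt_meas,
        Lt=Lt_meas,
        L0=L0_meas,
        branch=record.branch,
        speed=record.speed,
    )


def measure_cell_modulus(
    cell: VirtualCellParams,
    run: CompressionRunSpec,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> ModulusEstimate:
    """Full single-cell chain: simulate → measure geometry → regress E."""
    cfg = config or PipelineConfig()
    record = simulate_compression(cell, run, seed=seed)
    if cfg.geometry_source == "images":
        record = measure_geometry_from_images(record, pixel_size=cfg.pixel_size)
    curve = build_curve(record)
    return fit_elastic_modulus(curve, high_strain_fraction=cfg.high_strain_fraction)


def run_condition(
    preset_name: str,
    n: int | None = None,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> CellPopulation:
    """Measure a whole virtual condition through the pipeline.

    Draws `n` cells from the named preset (default: the condition's reported
    sample size), compresses and analyses each, and returns the population of
    *measured* moduli.
    """
    cfg = config or PipelineConfig()
    preset = get_preset(preset_name)
    if n is None:
        n = reported_n(preset_name)
    seeds = _child_seeds(seed, n + 1)
    cells = sample_population(
        preset, n, seed=seeds[0], L0=cfg.L0, nucleus_fraction=cfg.nucleus_fraction
    )
    run = CompressionRunSpec(
        speed=cfg.speed,
        max_strain=cfg.max_strain,
        sample_rate=cfg.sample_rate,
        include_unloading=False,
        force_noise_sd=cfg.force_noise_sd,
    )
    moduli = np.array(
        [
            measure_cell_modulus(cell, run, seed=s, config=cfg).E
            for cell, s in zip(cells, seeds[1:])
        ]
    )
    # cells softer than the force-noise floor can regress to E <= 0; such
    # below-detection measurements are excluded, as they would be at the bench
    detectable = moduli > 0
    return CellPopulation(condition=preset_name, moduli=moduli[detectable])


# ---------------------------------------------------------------------------
# scenarios


def _panel(conditions, seed, cfg, n_override=None):
    pops, summaries = {}, []
    seeds = _child_seeds(seed, len(conditions))
    for name, s in zip(conditions, seeds):
        pop = run_condition(name, n=n_override, seed=s, config=cfg)
        pops[name] = pop
        summaries.append(summarize(pop))
    return pops, summaries


def _scenario_calibration(cfg: PipelineConfig, seed: int) -> dict:
    sensor = SensorParams(
        true_coefficient=2.0, phase_offset=20.0, adc_baseline=120.0, adc_noise_sd=1.0
    )
    sweep = simulate_calibration_sweep(
        sensor, ball_mass=3.27e-5, n_steps=50, seed=seed, gravity=cfg.gravity
    )
    result = cal.fit_calibration(sweep)
    return {"scenario": "calibration", "result": result.to_dict(), "sweep": sweep}


def _scenario_cell_panel(cfg, seed):
    names = ["HEK293A", "C2C12", "HeLa", "10T1/2", "UE7T-13"]
    pops, summaries = _panel(names, seed, cfg)
    return {"scenario": "cell_panel", "populations": pops, "summaries": summaries}


def _dose_scenario(name, conditions, cfg, seed):
    pops, summaries = _panel(conditions, seed, cfg)
    report = dose_response_check(summaries)
    t, p = students_t_test(pops[conditions[0]], pops[conditions[-1]])
    return {
        "scenario": name,
        "populations": pops,
        "summaries": summaries,
        "dose_response": report,
        "t_test_first_vs_last": {"t": t, "p": p, "significant": p < 0.05},
    }


def _scenario_cd_dose(cfg, seed):
    return _dose_scenario("cd_dose", ["CD_untreated", "CD_1uM", "CD_2uM"], cfg, seed)


def _scenario_tsa_dose(cfg, seed):
    return _dose_scenario(
        "tsa_dose", ["TSA_control", "TSA_250nM", "TSA_500nM"], cfg, seed
    )


def _scenario_trypsinization(cfg, seed):
    pops, summaries = _panel(["trypsinized", "non_trypsinized"], seed, cfg)
    t, p = students_t_test(pops["trypsinized"], pops["non_trypsinized"])
    return {
        "scenario": "trypsinization",
        "populations": pops,
        "summaries": summaries,
        "t_test": {"t": t, "p": p, "significant": p < 0.05},
    }


def _scenario_progerin(cfg, seed, n=100):
    names = ["normal_HEK293A", "LaminA_OX", "Progerin_OX"]
    pops, summaries = _panel(names, seed, cfg, n_override=n)
    modes = {name: detect_modes(pops[name]) for name in names}
    return {
        "scenario": "progerin",
        "populations": pops,
        "summaries": summaries,
        "modes": modes,
    }


def _scenario_rheology_sweep(cfg, seed):
    # the log-log fit needs exact checkpoint times: ground-truth geometry and
    # a sample grid on which the checkpoints land exactly
    cell = VirtualCellParams(
        L0=cfg.L0, nucleus_fraction=cfg.nucleus_fraction,
        E0_cyto=2.0, E0_nuc=8.0, beta_cyto=0.35, beta_nuc=0.10,
    )
    samples = {"low_compression": [], "high_compression": []}
    for speed in RHEOLOGY_SPEEDS:
        run = CompressionRunSpec(
            speed=speed, max_strain=cfg.max_strain, sample_rate=200.0,
            include_unloading=False, force_noise_sd=0.0,
        )
        record = simulate_compression(cell, run, seed=seed)
        curve = build_curve(record)
        for checkpoint, regime in (
            (cfg.strain_checkpoint_low, "low_compression"),
            (cfg.strain_checkpoint_high, "high_compression"),
        ):
            s = apparent_modulus_at_checkpoint(
                curve, record, checkpoint,
                nucleus_contact_strain=cell.nucleus_contact_strain,
            )
            samples[regime].append(s)
    fits = {regime: fit_power_law(s) for regime, s in samples.items()}
    report = compare_regimes(fits["low_compression"], fits["high_compression"])
    return {
        "scenario": "rheology_sweep",
        "samples": samples,
        "fits": fits,
        "regime_report": report,
    }


def _scenario_needle_vs_plate(cfg, seed, n=30):
    preset = get_preset("HEK293A")
    seeds = _child_seeds(seed, 3)
    cells = sample_population(
        preset, n, seed=seeds[0], L0=cfg.L0, nucleus_fraction=cfg.nucleus_fraction
    )
    run = CompressionRunSpec(
        speed=cfg.speed, max_strain=cfg.max_strain, sample_rate=cfg.sample_rate,
        include_unloading=False, force_noise_sd=cfg.force_noise_sd,
    )
    plate = simulate_max_force_scenario(cells, run, "plate", seed=seeds[1])
    needle = simulate_max_force_scenario(cells, run, "needle", seed=seeds[2])
    return {
        "scenario": "needle_vs_plate",
        "plate_max_force_nN": plate,
        "needle_max_force_nN": needle,
        "plate_cv": float(np.std(plate, ddof=1) / np.mean(plate)),
        "needle_cv": float(np.std(needle, ddof=1) / np.mean(needle)),
    }


SCENARIOS = {
    "calibration": _scenario_calibration,
    "cell_panel": _scenario_cell_panel,
    "cd_dose": _scenario_cd_dose,
    "tsa_dose": _scenario_tsa_dose,
    "trypsinization": _scenario_trypsinization,
    "progerin": _scenario_progerin,
    "rheology_sweep": _scenario_rheology_sweep,
    "needle_vs_plate": _scenario_needle_vs_plate,
}


def run_virtual_experiment(
    config: PipelineConfig | dict | None,
    scenario: str,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run one named scenario end to end; optionally write its report bundle.

    With `out_dir`, condition populations go to `<scenario>_moduli.csv`
    (condition, modulus_kPa), summaries to `<scenario>_summary.csv`, and the
    remaining scalar results to `<scenario>_report.json`; every file carries
    the config hash in its header.
    """
    cfg, _ = validate_and_log(config)
    if scenario not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {scenario!r}; available: {sorted(SCENARIOS)}"
        )
    if seed is None:
        seed = cfg.seed
    result = SCENARIOS[scenario](cfg, seed)
    if out_dir is not None:
        _write_bundle(result, cfg, Path(out_dir))
    return result


def _write_bundle(result: dict, cfg: PipelineConfig, out_dir: Path) -> None:
    h = cfg.config_hash()
    name = result["scenario"]
    out_dir.mkdir(parents=True, exist_ok=True)
    if "populations" in result:
        rows = [
            {"condition": cond, "modulus_kPa": m}
            for cond, pop in result["populations"].items()
            for m in pop.moduli
        ]
        mio.write_csv(pd.DataFrame(rows), out_dir / f"{name}_moduli.csv", h)
    if "summaries" in result:
        df = pd.DataFrame(
            [
                {
                    "condition": s.condition,
                    "mean_kPa": s.mean,
                    "sd_kPa": s.sd,
                    "sem_kPa": s.sem,
                    "n": s.n,
                }
                for s in result["summaries"]
            ]
        )
        mio.write_csv(df, out_dir / f"{name}_summary.csv", h)
    report = {}
    for key, value in result.items():
        if key in ("populations", "summaries", "samples", "sweep"):
            continue
        if key == "fits":
            report[key] = {k: vars(v) for k, v in value.items()}
        elif key == "modes":
            report[key] = {
                k: {**v, "modes_kPa": list(v["modes_kPa"])} for k, v in value.items()
            }
        elif hasattr(value, "to_dict"):
            report[key] = value.to_dict()
        else:
            report[key] = value
    mio.write_json(report, out_dir / f"{name}_report.json", h)
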