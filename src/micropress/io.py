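"""File formats: CSV with unit-suffixed columns, JSON for fitted parameters.

Every file written carries a header comment with the package version and the
configuration hash, so outputs are traceable to the exact settings that
produced them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationResult
from .virtual_instrument import CalibrationSweep, CompressionRecord

__all__ = [
    "write_csv",
    "read_csv",
    "write_json",
    "read_json",
    "sweep_to_frame",
    "read_sweep",
    "record_to_frame",
    "read_record",
    "read_calibration_result",
]


def write_csv(df: pd.DataFrame, path, config_hash: str = "none") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# micropress config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj: dict, path, config_hash: str = "none") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"_config_hash": config_hash, **_jsonable(obj)}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def sweep_to_frame(sweep: CalibrationSweep) -> pd.DataFrame:
    return pd.DataFrame({"angle_deg": sweep.angles, "adc_value": sweep.adc_values})


def read_sweep(csv_path, meta_path) -> CalibrationSweep:
    """Read a sweep CSV (angle_deg, adc_value) plus its JSON sidecar
    (ball_mass_g, gravity)."""
    df = read_csv(csv_path)
    meta = read_json(meta_path)
    return CalibrationSweep(
        angles=df["angle_deg"].to_numpy(),
        adc_values=df["adc_value"].to_numpy(),
        ball_mass=float(meta["ball_mass_g"]),
        gravity=float(meta.get("gravity", 9.80665)),
    )


def record_to_frame(record: CompressionRecord) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": record.time,
            "force_nN": record.force,
            "Dt_um": record.Dt,
            "Lt_um": record.Lt,
            "branch": record.branch,
        }
    )


def read_record(path, L0: float | None = None, speed: float = np.nan) -> CompressionRecord:
    """Read a compression CSV (time_s, force_nN, Dt_um, Lt_um[, branch])."""
    df = read_csv(path)
    Lt = df["Lt_um"].to_numpy()
    return CompressionRecord(
        time=df["time_s"].to_numpy(),
        force=df["force_nN"].to_numpy(),
        Dt=df["Dt_um"].to_numpy(),
        Lt=Lt,
        L0=float(Lt[0]) if L0 is None else float(L0),
        branch=df["branch"].to_numpy() if "branch" in df else None,
        speed=speed,
    )


def read_calibration_result(path) -> CalibrationResult:
    d = read_json(path)
    return CalibrationResult(
        coefficient=d["coefficient_nN_per_ADU"],
        phase=d["phase_deg"],
        baseline=d["baseline_ADU"],
        rmse=d["rmse_nN"],
        max_error=d["max_error_nN"],
        resolution=d["resolution_nN"],
        n_points=d["n_points"],
    )
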