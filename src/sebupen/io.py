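"""CSV readers/writers and configuration loading.

All tabular I/O is headered CSV (UTF-8, '.' decimal separator) with a
stable column order; floats are written with ``repr`` precision so a
write-then-read round trip is lossless.  Configuration is YAML or JSON
with blocks for the amine, the sebum, the tube geometry, the pixel
calibration and the method options.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .chem import AlcoholamineSpec
from .optical import PixelCalibration, TubeGeometry
from .pipeline import (
    HeightSeries,
    PH_DEVICE_ACCURACY,
    PHSeries,
    REFERENCE_TIME_MIN,
    VolumeSeries,
)
from .stoichiometry import DEFAULT_SEBUM_FRACTIONS, SebumComposition

__all__ = [
    "RunConfig",
    "load_config",
    "read_ph_csv",
    "write_ph_csv",
    "read_heights_csv",
    "write_heights_csv",
    "read_volume_csv",
    "write_volume_csv",
]

PathLike = Union[str, Path]

#: shortest format guaranteeing lossless float round trips through CSV
FLOAT_FORMAT = "%.17g"


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the measurement files."""

    amine: AlcoholamineSpec = field(default_factory=AlcoholamineSpec)
    sebum: SebumComposition = field(default_factory=SebumComposition)
    geometry: TubeGeometry = field(default_factory=TubeGeometry)
    calibration: PixelCalibration = field(default_factory=PixelCalibration)
    Vr_cm3: float = 3.0
    eq_direction: str = "physical"
    clamp_policy: str = "clamp"
    reference_time_min: float = REFERENCE_TIME_MIN
    ph_accuracy: float = PH_DEVICE_ACCURACY
    seed: int = 0
    log_level: str = "INFO"

    @property
    def Vr_dm3(self) -> float:
        return self.Vr_cm3 * 1e-3


def load_config(path: Optional[PathLike] = None) -> RunConfig:
    """Load a RunConfig from YAML or JSON; missing keys take defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    cfg = cfg or {}
    amine = AlcoholamineSpec.from_config(cfg.get("amine", {}))
    seb = cfg.get("sebum", {})
    sebum = SebumComposition(
        fractions=seb.get("fractions", dict(DEFAULT_SEBUM_FRACTIONS)),
        density_mg_per_mm3=float(seb.get("density_mg_per_mm3", 0.842)),
    )
    geo = cfg.get("geometry", {})
    geometry = TubeGeometry(
        radius_mm=float(geo.get("radius_mm", 8.0)),
        sebum_column_height_mm=float(geo.get("sebum_column_height_mm", 20.0)),
    )
    cal = cfg.get("calibration", {})
    calibration = PixelCalibration(pixels_per_mm=float(cal.get("pixels_per_mm", 50.0)))
    return RunConfig(
        amine=amine,
        sebum=sebum,
        geometry=geometry,
        calibration=calibration,
        Vr_cm3=float(cfg.get("Vr_cm3", 3.0)),
        eq_direction=str(cfg.get("eq8_direction", "physical")),
        clamp_policy=str(cfg.get("clamp_policy", "clamp")),
        reference_time_min=float(cfg.get("reference_time_min", REFERENCE_TIME_MIN)),
        ph_accuracy=float(cfg.get("ph_accuracy", PH_DEVICE_ACCURACY)),
        seed=int(cfg.get("seed", 0)),
        log_level=str(cfg.get("log_level", "INFO")),
    )


def _read_csv(path: PathLike, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_ph_csv(
    path: PathLike, concentration_label: str = "", replicate_id: int = 0
) -> PHSeries:
    """Read a pH time series (columns ``time_min``, ``ph``).

    Rows are sorted by time; duplicate times and out-of-range pH are
    rejected with the offending row named.
    """
    df = _read_csv(path, ["time_min", "ph"]).sort_values("time_min")
    times = df["time_min"].to_numpy(float)
    dup = np.flatnonzero(np.diff(times) == 0)
    if dup.size:
        raise ValueError(f"{path}: duplicate time at row {int(dup[0]) + 1}")
    bad = np.flatnonzero((df["ph"] <= 0) | (df["ph"] >= 14))
    if bad.size:
        raise ValueError(
            f"{path}: pH out of (0, 14) at row {int(bad[0])} "
            f"(value {df['ph'].iloc[int(bad[0])]})"
        )
    return PHSeries(
        concentration_label=concentration_label,
        times_min=times,
        ph=df["ph"].to_numpy(float),
        replicate_id=replicate_id,
    )


def write_ph_csv(series: PHSeries, path: PathLike) -> None:
    pd.DataFrame({"time_min": series.times_min, "ph": series.ph}).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_heights_csv(path: PathLike, replicate_id: int = 0) -> HeightSeries:
    """Read one replicate of layer heights (columns ``time_min``,
    ``h_penetration_mm``, ``h_increase_mm``)."""
    df = _read_csv(path, ["time_min", "h_penetration_mm", "h_increase_mm"])
    df = df.sort_values("time_min")
    return HeightSeries(
        times_min=df["time_min"].to_numpy(float),
        penetration_mm=df["h_penetration_mm"].to_numpy(float),
        increase_mm=df["h_increase_mm"].to_numpy(float),
        replicate_id=replicate_id,
    )


def write_heights_csv(series: HeightSeries, path: PathLike) -> None:
    pd.DataFrame(
        {
            "time_min": series.times_min,
            "h_penetration_mm": series.penetration_mm,
            "h_increase_mm": series.increase_mm,
        }
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


_VOLUME_COLUMNS = [
    "v_penetrated_mm3",
    "v_increased_mm3",
    "v_reacted_mm3",
    "sd_mm3",
    "sd_increased_mm3",
]
_VOLUME_FIELDS = [
    "penetrated_mm3",
    "increased_mm3",
    "reacted_mm3",
    "sd_mm3",
    "sd_increased_mm3",
]


def write_volume_csv(series: VolumeSeries, path: PathLike) -> None:
    """Write a volume series; only the populated columns are emitted, in a
    fixed order, so output files are byte-stable across runs."""
    data = {"time_min": series.times_min}
    for col, fld in zip(_VOLUME_COLUMNS, _VOLUME_FIELDS):
        arr = getattr(series, fld)
        if arr is not None:
            data[col] = arr
    pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_volume_csv(path: PathLike, concentration_label: str = "") -> VolumeSeries:
    df = _read_csv(path, ["time_min"])
    kwargs = {}
    for col, fld in zip(_VOLUME_COLUMNS, _VOLUME_FIELDS):
        if col in df.columns:
            kwargs[fld] = df[col].to_numpy(float)
    return VolumeSeries(
        concentration_label=concentration_label,
        times_min=df["time_min"].to_numpy(float),
        **kwargs,
    )
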