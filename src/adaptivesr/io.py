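"""CSV round-trips for time series and analysis curves."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .benefit import ACThresholdCurve
from .environment import EnvironmentConfig, IntensityTimeSeries
from .resonance import FeedbackTrajectory, ResonanceCurve
from .sensor import FiringRateSeries

__all__ = [
    "write_series",
    "read_series",
    "write_rates",
    "write_resonance_curve",
    "write_ac_threshold_curve",
    "write_trajectory",
]


def write_series(
    series: IntensityTimeSeries, path: str | Path, config: EnvironmentConfig | None = None
) -> None:
    """Write (time, intensity_db) CSV, with the config as a JSON sidecar."""
    path = Path(path)
    pd.DataFrame({"time": series.times, "intensity_db": series.values}).to_csv(path, index=False)
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(dataclasses.asdict(config), indent=2))


def read_series(path: str | Path) -> tuple[IntensityTimeSeries, EnvironmentConfig | None]:
    path = Path(path)
    frame = pd.read_csv(path)
    times = frame["time"].to_numpy()
    dt = float(times[1] - times[0]) if times.size > 1 else 1.0
    series = IntensityTimeSeries(values=frame["intensity_db"].to_numpy(), dt=dt)
    sidecar = path.with_suffix(path.suffix + ".json")
    config = None
    if sidecar.exists():
        config = EnvironmentConfig(**json.loads(sidecar.read_text()))
    return series, config


def write_rates(rates: FiringRateSeries, path: str | Path) -> None:
    pd.DataFrame({"time": rates.times, "rate_hz": rates.values}).to_csv(path, index=False)


def write_resonance_curve(curve: ResonanceCurve, path: str | Path) -> None:
    data = {"sigma_n_sq": curve.sigma_n_sq_grid, "mean_ac": curve.mean_ac}
    if curve.mi_bits is not None:
        data["mi_bits"] = curve.mi_bits
    pd.DataFrame(data).to_csv(path, index=False)


def write_ac_threshold_curve(curve: ACThresholdCurve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "threshold_db": curve.thresholds,
            "mean_ac_no_sr": curve.mean_ac_no_sr,
            "mean_ac_with_sr": curve.mean_ac_with_sr,
            "sigma_n_opt_sq": curve.sigma_n_opt,
        }
    ).to_csv(path, index=False)


def write_trajectory(trajectory: FeedbackTrajectory, path: str | Path) -> None:
    pd.DataFrame(
        {
            "iteration": np.arange(trajectory.sigma_n_sq.size),
            "sigma_n_sq": trajectory.sigma_n_sq,
            "mean_ac": trajectory.mean_ac,
        }
    ).to_csv(path, index=False)
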