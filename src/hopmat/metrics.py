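"""Per-run load parameters and limb-load symmetry ratios.

Two load parameters are computed per hind-paw contact:

* **peak pressure** (kPa) — the highest reading of any single sensor over
  the whole contact; an animal in pain offloads the affected paw, lowering
  its peak contact pressure.
* **time-force integral** (N·s) — the integral over the stance of the
  summed per-sensor forces; offloading can also show as a shorter or
  lighter stance without a change in peak.

Force comes from pressure times sensor area: 1 kPa on a 10 x 10 mm sensor
is 0.1 N.  Integration uses the rectangle rule on the device clock — at
10 Hz a stance spans only a handful of frames, and because both paws are
sampled on the same clock most discretisation bias cancels in the ratio.

Left/right loading is compared by the symmetry index

    I = (x_right - x_left) / (x_right + x_left)

which is 0 for perfect symmetry, negative when the left limb bears more
load, +1 when the left hindlimb bears none, and -1 when the right hindlimb
bears none.  Applied to peak pressures it is called ``ratio_pressure``;
applied to time-force integrals, ``ratio_force``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mat_io import GridSpec
from .segmentation import Contact, HopPair

__all__ = [
    "RunMetrics",
    "UndefinedRatioError",
    "peak_pressure",
    "sensor_force",
    "force_trace",
    "time_force_integral",
    "symmetry_index",
    "run_metrics",
    "metrics_to_frame",
]


class UndefinedRatioError(ZeroDivisionError):
    """Symmetry index of two zero loads is undefined."""


@dataclass(frozen=True)
class RunMetrics:
    """Load parameters and symmetry ratios of one evaluated run.

    The sign convention is anatomical: ratios below zero mean the left
    hindlimb bears more load.  Which side counts as "affected" is a
    reporting decision, not part of the metric.
    """

    run_id: str
    animal_id: str
    session_id: str
    peak_pressure_left: float
    peak_pressure_right: float
    tfi_left: float
    tfi_right: float
    ratio_pressure: float
    ratio_force: float


def peak_pressure(contact: Contact) -> float:
    """Highest single-sensor pressure (kPa) over the whole contact."""
    if contact.samples.size == 0:
        raise ValueError("peak_pressure of an empty contact is undefined")
    return float(contact.samples["pressure"].max())


def sensor_force(pressure_kpa: float, grid: GridSpec) -> float:
    """Force (N) exerted on one sensor by a given pressure reading.

    force = p[kPa] * 1000 * (sensor_size[m])^2; for the 10 mm sensor this
    is 0.1 N per kPa.
    """
    if pressure_kpa < 0:
        raise ValueError("pressure must be non-negative")
    return pressure_kpa * 1000.0 * grid.sensor_area_m2


def force_trace(contact: Contact, grid: GridSpec) -> np.ndarray:
    """Per-frame total force of a contact as an (n, 2) array of (t_s, F_N).

    Covers every frame of the contact's span; frames without samples carry
    zero force.  Time is frame index over the device frame rate.
    """
    if contact.samples.size == 0:
        raise ValueError("force_trace of an empty contact is undefined")
    first, last = contact.frame_span
    frames = np.arange(first, last + 1)
    forces = np.zeros(frames.shape)
    scale = 1000.0 * grid.sensor_area_m2
    np.add.at(forces, contact.samples["frame"] - first, contact.samples["pressure"] * scale)
    times = frames / grid.frame_rate_hz
    return np.column_stack([times, forces])


def time_force_integral(trace: np.ndarray, frame_rate_hz: float) -> float:
    """Rectangle-rule impulse (N·s) of a force trace sampled at a fixed rate."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("time_force_integral of an empty trace is undefined")
    return float(trace[:, 1].sum() / frame_rate_hz)


def symmetry_index(x_right: float, x_left: float) -> float:
    """Symmetry index I = (x_right - x_left)/(x_right + x_left).

    Both loads must be non-negative and not both zero.  The result lies in
    [-1, 1], is antisymmetric under swapping the limbs, and is invariant
    under scaling both loads by the same positive constant.
    """
    if x_right < 0 or x_left < 0:
        raise ValueError("loads must be non-negative")
    total = x_right + x_left
    if total == 0:
        raise UndefinedRatioError("symmetry index undefined when both loads are zero")
    return (x_right - x_left) / total


def run_metrics(
    pair: HopPair,
    grid: GridSpec,
    run_id: str = "",
    animal_id: str = "",
    session_id: str = "",
) -> RunMetrics:
    """Compute both load parameters and both symmetry ratios for one hop.

    ``ratio_pressure`` compares the hind paws' peak pressures,
    ``ratio_force`` their time-force integrals, each as
    ``symmetry_index(right, left)``.
    """
    pp_left = peak_pressure(pair.left)
    pp_right = peak_pressure(pair.right)
    tfi_left = time_force_integral(force_trace(pair.left, grid), grid.frame_rate_hz)
    tfi_right = time_force_integral(force_trace(pair.right, grid), grid.frame_rate_hz)
    return RunMetrics(
        run_id=run_id,
        animal_id=animal_id,
        session_id=session_id,
        peak_pressure_left=pp_left,
        peak_pressure_right=pp_right,
        tfi_left=tfi_left,
        tfi_right=tfi_right,
        ratio_pressure=symmetry_index(pp_right, pp_left),
        ratio_force=symmetry_index(tfi_right, tfi_left),
    )


def metrics_to_frame(metrics: list[RunMetrics]) -> pd.DataFrame:
    """Tabulate run metrics, one row per evaluated run."""
    return pd.DataFrame([m.__dict__ for m in metrics])
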