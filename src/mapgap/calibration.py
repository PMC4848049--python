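"""Fiber-Bragg-grating force calibration.

The catheter measures contact force optically: tissue contact strains a
short fiber Bragg grating, displacing its reflected wavelength. Each fiber
is benched before use — known forces (grams) are applied to the tip while
the wavelength shift (nm) is read out — and an ordinary-least-squares line

    force = slope * shift + intercept

is fitted per fiber. At analysis time the line maps the raw sensor channel
to a contact-force series; negative calibrated forces are clipped to zero,
since tip–tissue contact force is non-negative by definition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationMismatchError, DegenerateInputError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationPoint:
    """One bench observation: a known applied force and the measured shift."""

    applied_force: float  # grams, >= 0
    measured_shift: float  # nm, displacement from the unloaded reference

    def __post_init__(self) -> None:
        if not np.isfinite(self.applied_force) or not np.isfinite(self.measured_shift):
            raise ValueError("calibration point values must be finite")
        if self.applied_force < 0:
            raise ValueError("applied force must be non-negative")


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted linear wavelength-shift → force mapping for one fiber."""

    fiber_id: str
    slope: float  # grams per nm
    intercept: float  # grams
    rmse: float  # grams, root-mean-square residual of the fit
    n_points: int
    shift_accuracy: float = 1.0  # nm, interrogator accuracy spec

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("calibration requires at least 2 points")
        if not np.isfinite(self.slope) or self.slope == 0:
            raise ValueError("slope must be finite and nonzero")
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")

    def predict(self, shift_nm: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(shift_nm, dtype=float) + self.intercept


@dataclass
class ForceSeries:
    """Calibrated contact-force series, clipped at zero."""

    time: np.ndarray  # s
    force: np.ndarray  # grams
    fiber_id: str

    def __post_init__(self) -> None:
        if len(self.time) != len(self.force):
            raise ValueError("time and force must have equal length")


def fit_calibration(
    points: Iterable[CalibrationPoint] | Sequence[tuple[float, float]],
    fiber_id: str = "fiber-0",
    shift_accuracy: float = 1.0,
) -> CalibrationCurve:
    """Fit ``force = slope * shift + intercept`` by ordinary least squares.

    Parameters
    ----------
    points:
        Bench observations; either :class:`CalibrationPoint` s or raw
        ``(force_g, shift_nm)`` pairs. At least two distinct shift values
        are required.

    Raises
    ------
    DegenerateInputError
        Fewer than two distinct shift values (rank-deficient design).
    ValueError
        Non-finite input values.
    """
    pts = [
        p if isinstance(p, CalibrationPoint) else CalibrationPoint(*p) for p in points
    ]
    if len(pts) < 2:
        raise DegenerateInputError("need at least 2 calibration points")
    force = np.array([p.applied_force for p in pts], dtype=float)
    shift = np.array([p.measured_shift for p in pts], dtype=float)
    if np.unique(shift).size < 2:
        raise DegenerateInputError("need at least 2 distinct shift values")

    # least squares on the centred design for numerical stability
    sbar, fbar = shift.mean(), force.mean()
    slope = float(np.dot(shift - sbar, force - fbar) / np.dot(shift - sbar, shift - sbar))
    intercept = float(fbar - slope * sbar)
    resid = force - (slope * shift + intercept)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return CalibrationCurve(
        fiber_id=fiber_id,
        slope=slope,
        intercept=intercept,
        rmse=rmse,
        n_points=len(pts),
        shift_accuracy=shift_accuracy,
    )


def apply_calibration(
    time: np.ndarray,
    shift_nm: np.ndarray,
    curve: CalibrationCurve,
    fiber_id: str | None = None,
) -> ForceSeries:
    """Map a raw wavelength-shift series to contact force in grams.

    ``fiber_id`` identifies the fiber the series was recorded with; it must
    match ``curve.fiber_id`` (per-fiber calibration is mandatory — applying
    an unmatched curve is an error, not a warning). Pass ``None`` to accept
    the curve's fiber. Negative calibrated forces are clipped to zero; the
    number of clipped samples is logged.
    """
    if fiber_id is not None and fiber_id != curve.fiber_id:
        raise CalibrationMismatchError(
            f"series from fiber {fiber_id!r} but curve fitted for {curve.fiber_id!r}"
        )
    force = curve.predict(shift_nm)
    n_neg = int(np.sum(force < 0))
    if n_neg:
        log.debug("clipped %d negative force samples to 0", n_neg)
    return ForceSeries(
        time=np.asarray(time, dtype=float),
        force=np.clip(force, 0.0, None),
        fiber_id=curve.fiber_id,
    )


def calibrate_trace(trace, curve: CalibrationCurve):
    """Attach a calibrated force channel to a :class:`~mapgap.trace.Trace`.

    The trace must carry a raw sensor channel; its ``fiber_id`` (when set)
    must match the curve's.
    """
    if trace.sensor_nm is None:
        raise ValueError("trace has no raw sensor channel to calibrate")
    series = apply_calibration(trace.time, trace.sensor_nm, curve, trace.fiber_id)
    return trace.with_force(series.force)


# ---------------------------------------------------------------- persistence

def read_bench_csv(path: str | Path) -> list[CalibrationPoint]:
    """Read a calibration bench CSV with columns ``force_g,shift_nm``."""
    df = pd.read_csv(path)
    if not {"force_g", "shift_nm"} <= set(df.columns):
        raise ValueError("bench CSV must have columns force_g,shift_nm")
    return [
        CalibrationPoint(float(f), float(s))
        for f, s in zip(df["force_g"], df["shift_nm"])
    ]


def save_calibrations(curves: Iterable[CalibrationCurve], path: str | Path) -> None:
    """Write a calibration store: JSON keyed by fiber_id."""
    store = {c.fiber_id: asdict(c) for c in curves}
    Path(path).write_text(json.dumps(store, indent=2))


def load_calibrations(path: str | Path) -> dict[str, CalibrationCurve]:
    store = json.loads(Path(path).read_text())
    return {fid: CalibrationCurve(**entry) for fid, entry in store.items()}
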