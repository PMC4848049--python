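"""The core recording container: a uniformly sampled multichannel trace.

A :class:`Trace` holds the three co-recorded channels of the assessment
catheter — the bipolar MAP electrogram (mV), a reference ECG (mV) and the
raw fiber-Bragg-grating sensor readout (wavelength shift, nm) — plus, once
calibration has been applied, a contact-force channel in grams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: bit set in ``Trace.quality`` while a breath hold is in effect
QUALITY_BREATH_HOLD = 0x01


@dataclass
class TraceTruth:
    """Generator-side ground truth attached to synthetic traces (never used
    by the detector; exists so tests can score the pipeline)."""

    site_id: str
    viable: bool
    cf_threshold: Optional[float]
    qrs_times: np.ndarray  # s, R-peak times
    beat_elicited: np.ndarray  # bool per beat
    cf_at_beat: np.ndarray  # grams, true applied force at each MAP upstroke
    map_amplitude: Optional[float] = None  # mV
    map_duration_ms: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "viable": self.viable,
            "cf_threshold": self.cf_threshold,
            "qrs_times": [float(x) for x in self.qrs_times],
            "beat_elicited": [bool(x) for x in self.beat_elicited],
            "cf_at_beat": [float(x) for x in self.cf_at_beat],
            "map_amplitude": self.map_amplitude,
            "map_duration_ms": self.map_duration_ms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TraceTruth":
        return cls(
            site_id=d["site_id"],
            viable=d["viable"],
            cf_threshold=d["cf_threshold"],
            qrs_times=np.asarray(d["qrs_times"], dtype=float),
            beat_elicited=np.asarray(d["beat_elicited"], dtype=bool),
            cf_at_beat=np.asarray(d["cf_at_beat"], dtype=float),
            map_amplitude=d.get("map_amplitude"),
            map_duration_ms=d.get("map_duration_ms"),
        )


@dataclass
class Trace:
    """Uniformly sampled multichannel recording.

    Invariants: all channels share one length; ``sample_rate`` >= 500 Hz;
    ``time`` is strictly increasing and uniform (``time[i] = time[0] + i/fs``).
    """

    sample_rate: float
    time: np.ndarray
    map_mv: np.ndarray
    ecg_mv: np.ndarray
    sensor_nm: Optional[np.ndarray] = None
    force_g: Optional[np.ndarray] = None
    fiber_id: Optional[str] = None
    quality: Optional[np.ndarray] = None  # per-sample uint8 flag bitmask
    truth: Optional[TraceTruth] = None

    def __post_init__(self) -> None:
        if self.sample_rate < 500:
            raise ValueError("sample_rate must be >= 500 Hz")
        n = len(self.time)
        for name in ("map_mv", "ecg_mv", "sensor_nm", "force_g", "quality"):
            ch = getattr(self, name)
            if ch is not None and len(ch) != n:
                raise ValueError(f"channel {name} length {len(ch)} != time length {n}")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate

    def with_force(self, force_g: np.ndarray) -> "Trace":
        """Return a copy carrying a calibrated contact-force channel."""
        return replace(self, force_g=np.asarray(force_g, dtype=float))
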