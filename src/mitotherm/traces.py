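"""Fluorimeter trace container shared by the simulator and the analysis pipelines.

A :class:`FluorescenceTrace` is the universal exchange object of the package:
a uniformly sampled time base (seconds), one intensity channel for the MTY dye
or two channels (mT-Sapphire, Sirius) for the mito-gTEMP reporter pair, the
Peltier setpoint track (°C), and a sparse list of annotated events (drug
addition, calibration steps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: event label used for every Peltier calibration step
CALIBRATION_EVENT = "calibration"

MTY_COLUMNS = ("time_s", "f_main", "setpoint_c", "event")
GTEMP_COLUMNS = ("time_s", "f_sapphire", "f_sirius", "setpoint_c", "event")


@dataclass
class FluorescenceTrace:
    """Timestamped fluorescence record with setpoint track and events.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing, uniformly spaced.
    channels
        Array of shape ``(n_channels, n_samples)``; one channel for MTY,
        two (mT-Sapphire, Sirius — in that order) for mito-gTEMP.
    setpoints
        Peltier setpoint in °C at each sample.
    events
        ``(time_s, label)`` annotations, sorted by time.
    metadata
        Free-form provenance: ambient °C, cell line, inhibitor, seed, ...
    """

    times: np.ndarray
    channels: np.ndarray
    setpoints: np.ndarray
    events: list[tuple[float, str]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        self.setpoints = np.asarray(self.setpoints, dtype=float)
        n = self.times.size
        if self.channels.shape[1] != n or self.setpoints.size != n:
            raise ValueError("times, channels and setpoints must share one length")
        if n >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.channels < 0):
            raise ValueError("fluorescence intensities must be non-negative")
        self.events = sorted((float(t), str(lab)) for t, lab in self.events)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 1.0

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) + self.dt

    def channel(self, index: int = 0) -> np.ndarray:
        return self.channels[index]

    def event_times(self, label: str) -> list[float]:
        """Times of all events whose label matches exactly."""
        return [t for t, lab in self.events if lab == label]

    def first_event(self, label: str) -> float | None:
        ts = self.event_times(label)
        return ts[0] if ts else None

    def window_mean(self, start: float, stop: float, channel: int = 0) -> float:
        """Mean intensity over the half-open time window ``[start, stop)``."""
        sel = (self.times >= start) & (self.times < stop)
        if not np.any(sel):
            raise ValueError(f"window [{start}, {stop}) contains no samples")
        return float(self.channels[channel, sel].mean())

    # -- interop -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Tidy DataFrame using the on-disk column schema."""
        cols: dict[str, object] = {"time_s": self.times}
        if self.n_channels == 1:
            cols["f_main"] = self.channels[0]
        else:
            cols["f_sapphire"] = self.channels[0]
            cols["f_sirius"] = self.channels[1]
        cols["setpoint_c"] = self.setpoints
        event_col = np.full(self.times.size, "", dtype=object)
        for t, lab in self.events:
            idx = int(np.argmin(np.abs(self.times - t)))
            event_col[idx] = lab if event_col[idx] == "" else f"{event_col[idx]};{lab}"
        cols["event"] = event_col
        return pd.DataFrame(cols)

    def scaled(self, factor: float) -> "FluorescenceTrace":
        """Copy with every channel multiplied by ``factor`` (gain change)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return FluorescenceTrace(
            self.times.copy(), self.channels * factor, self.setpoints.copy(),
            list(self.events), dict(self.metadata),
        )

    def offset(self, shift: float) -> "FluorescenceTrace":
        """Copy with a constant added to every channel."""
        out = self.channels + shift
        if np.any(out < 0):
            raise ValueError("offset would produce negative intensities")
        return FluorescenceTrace(
            self.times.copy(), out, self.setpoints.copy(),
            list(self.events), dict(self.metadata),
        )


def rolling_mean(series: Sequence[float], width: int) -> np.ndarray:
    """Centered boxcar smoothing; edges use the partial window (no padding bias)."""
    x = np.asarray(series, dtype=float)
    if width <= 1:
        return x.copy()
    kernel = np.ones(int(width))
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den
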