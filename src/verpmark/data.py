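"""Core containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .montage import Montage

GROUPS = ("CC", "DC", "Control")

EVENT_COLUMNS = ("field", "side", "target", "response_ms")


@dataclass(frozen=True)
class ParticipantMeta:
    """Per-participant demographic and clinical metadata.

    Surgery fields are in months and present only for the two
    cataract-reversal groups.
    """

    pid: str
    group: str
    age_years: float
    age_at_surgery_months: Optional[float] = None
    time_since_surgery_months: Optional[float] = None
    responds_manually: bool = True

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}")
        has_surgery = self.age_at_surgery_months is not None
        if (self.group == "Control") == has_surgery:
            raise ValueError(
                "surgery fields must be present iff group is CC or DC "
                f"(group={self.group})"
            )


@dataclass
class EpochSet:
    """Trial x electrode x time EEG epochs (uV) with event metadata.

    ``times`` is in ms relative to stimulus onset and must span it.
    ``keep`` is a boolean mask; rejection stages only clear bits, never
    delete trials, so provenance survives.
    """

    data: np.ndarray  # (n_trials, n_electrodes, n_times), uV
    times: np.ndarray  # (n_times,), ms
    sfreq: float
    montage: Montage
    events: pd.DataFrame
    keep: np.ndarray = None
    pid: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, electrodes, times)")
        if self.data.shape[1] != len(self.montage):
            raise ValueError("electrode count does not match montage")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not (self.times[0] <= 0.0 <= self.times[-1]):
            raise ValueError("time axis must span stimulus onset")
        if self.keep is None:
            self.keep = np.ones(self.n_trials, dtype=bool)
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.size != self.n_trials:
            raise ValueError("keep mask length must equal trial count")
        if len(self.events) != self.n_trials:
            raise ValueError("events table length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            times=self.times.copy(),
            sfreq=self.sfreq,
            montage=self.montage,
            events=self.events.copy(),
            keep=self.keep.copy(),
            pid=self.pid,
        )

    def with_data(self, data: np.ndarray) -> "EpochSet":
        out = self.copy()
        out.data = np.asarray(data, dtype=float)
        return out

    def time_indices(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Sample indices with start <= t <= stop (bounds inclusive)."""
        return np.nonzero((self.times >= start_ms) & (self.times <= stop_ms))[0]


@dataclass
class OcularComponents:
    """Ground-truth separated ocular source time courses for an EpochSet.

    ``blink``/``saccade`` are (n_trials, n_times) source signals; the
    corresponding topographies project a source onto the scalp as
    ``topo[:, None] * source``.
    """

    blink: Optional[np.ndarray]
    blink_topo: Optional[np.ndarray]
    saccade: Optional[np.ndarray]
    saccade_topo: Optional[np.ndarray]
    times: np.ndarray

    def projected(self, which: str, electrode_index: int) -> np.ndarray:
        source = getattr(self, which)
        topo = getattr(self, f"{which}_topo")
        return topo[electrode_index] * source


@dataclass
class VERP:
    """Trial-averaged visual event-related potential for one condition."""

    data: np.ndarray  # (n_electrodes, n_times), uV
    times: np.ndarray
    condition: str  # "upper" | "lower"
    n_trials: int
    montage: Montage
    pid: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.n_trials < 1:
            raise ValueError("VERP requires at least one contributing trial")
        if self.data.shape != (len(self.montage), self.times.size):
            raise ValueError("VERP shape must be (electrodes, times)")

    def electrode(self, name: str) -> np.ndarray:
        return self.data[self.montage.index(name)]

    def time_indices(self, start_ms: float, stop_ms: float) -> np.ndarray:
        return np.nonzero((self.times >= start_ms) & (self.times <= stop_ms))[0]

    def scaled(self, factor: float) -> "VERP":
        return replace(self, data=self.data * factor)
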