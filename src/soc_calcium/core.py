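"""Core data containers for the conditioning-imaging pipeline.

The pipeline moves data through a small set of containers:

``TraceMatrix``
    Per-neuron fluorescence over one session (raw F or normalized ΔF/F),
    sampled uniformly.
``EventTable``
    A plain :class:`pandas.DataFrame` of timed cue / shock annotations with
    columns ``event_label, onset_s, duration_s, phase, trial_index``.
``WindowSpec``
    A peri-event window, seconds before / after a stimulus onset.
``PeriEventTensor``
    neuron x trial x relative-time block of normalized activity cut around
    the onsets of one event label.
``MotionTrace``
    A per-mouse motion-magnitude series used to quantify freezing.

All containers round-trip through small CSV dialects so every intermediate
stage of the pipeline can be inspected with ordinary tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_COLUMNS = ["event_label", "onset_s", "duration_s", "phase", "trial_index"]

#: Spacing tolerance for the uniform time axis, in seconds.
TIME_TOL = 1e-6


@dataclass
class TraceMatrix:
    """Fluorescence of many neurons over one session.

    Parameters
    ----------
    neuron_ids
        One identifier per row of ``values``.
    times
        Sample times in seconds, strictly increasing, uniformly spaced.
    values
        Array of shape ``(n_neurons, n_times)``; raw F in arbitrary units
        or unitless ΔF/F depending on pipeline stage.
    sampling_rate_hz
        Sampling frequency; must agree with ``times`` spacing.
    phase
        Session / phase label (e.g. ``"test"``).
    """

    neuron_ids: list[str]
    times: np.ndarray
    values: np.ndarray
    sampling_rate_hz: float
    phase: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (neurons x time)")
        if len(self.neuron_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.neuron_ids)} neuron ids for {self.values.shape[0]} rows"
            )
        if self.values.shape[0] < 1:
            raise ValueError("TraceMatrix needs at least one neuron")
        if self.times.shape != (self.values.shape[1],):
            raise ValueError("times length does not match values columns")
        dt = np.diff(self.times)
        if self.times.size > 1:
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.ptp(dt) > TIME_TOL:
                raise ValueError("times must be uniformly spaced")
            if abs(dt[0] - 1.0 / self.sampling_rate_hz) > TIME_TOL:
                raise ValueError("sampling_rate_hz inconsistent with times")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain missing / non-finite entries")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        """Write rows = neurons, header row = times in s, first col neuron_id."""
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.neuron_ids, name="neuron_id"),
            columns=[f"{t:.6f}" for t in self.times],
        )
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, sampling_rate_hz: float | None = None,
                 phase: str = "") -> "TraceMatrix":
        df = pd.read_csv(path, index_col=0)
        times = np.array([float(c) for c in df.columns])
        if sampling_rate_hz is None:
            if times.size < 2:
                raise ValueError("cannot infer sampling rate from one sample")
            sampling_rate_hz = 1.0 / (times[1] - times[0])
        return cls(
            neuron_ids=[str(i) for i in df.index],
            times=times,
            values=df.to_numpy(dtype=float),
            sampling_rate_hz=sampling_rate_hz,
            phase=phase,
        )


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check an event table has the canonical columns and sane values."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    if (events["duration_s"] <= 0).any():
        raise ValueError("event durations must be positive")
    return events


def read_events(path) -> pd.DataFrame:
    return validate_events(pd.read_csv(path))


def write_events(events: pd.DataFrame, path) -> None:
    validate_events(events)[EVENT_COLUMNS].to_csv(path, index=False)


@dataclass(frozen=True)
class WindowSpec:
    """Peri-event window: ``pre_s`` seconds before onset to ``post_s`` after.

    Baseline samples are those with relative time in ``[-pre_s, 0)``; the
    response window is ``[0, post_s]``. Onset maps to the first sample with
    ``t >= onset``.
    """

    pre_s: float = 10.0
    post_s: float = 20.0

    def __post_init__(self) -> None:
        if self.pre_s <= 0 or self.post_s <= 0:
            raise ValueError("window extents must be positive")


@dataclass
class PeriEventTensor:
    """Normalized activity cut around event onsets.

    ``values`` has shape ``(n_neurons, n_trials, n_rel_times)``; the relative
    time axis ``rel_times`` is shared by every neuron and trial.
    ``excluded_trials`` lists trial indices dropped because their window did
    not fit in the session or had a degenerate (zero-SD) baseline.
    """

    neuron_ids: list[str]
    rel_times: np.ndarray
    values: np.ndarray
    event_label: str
    window: WindowSpec
    phase: str = ""
    excluded_trials: list[int] = field(default_factory=list)
    degenerate_trials: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rel_times = np.asarray(self.rel_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D (neuron x trial x time)")
        if self.values.shape[2] != self.rel_times.size:
            raise ValueError("relative time axis does not match values")
        if self.values.shape[1] < 1:
            raise ValueError("tensor needs at least one trial")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    def to_long_csv(self, path) -> None:
        """Serialize as long-format CSV (neuron_id, event_label, trial, time_s_rel, z)."""
        n, t, s = self.values.shape
        df = pd.DataFrame({
            "neuron_id": np.repeat(self.neuron_ids, t * s),
            "event_label": self.event_label,
            "trial": np.tile(np.repeat(np.arange(t), s), n),
            "time_s_rel": np.tile(self.rel_times, n * t),
            "z": self.values.ravel(),
        })
        df.to_csv(path, index=False)


@dataclass
class MotionTrace:
    """Motion magnitude over time for one mouse; zero means no movement."""

    times: np.ndarray
    motion: np.ndarray
    mouse_id: str = "m0"
    phase: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        if self.times.shape != self.motion.shape:
            raise ValueError("times and motion must have equal length")
        if np.any(self.motion < 0):
            raise ValueError("motion magnitudes must be non-negative")
        if self.times.size > 1 and np.ptp(np.diff(self.times)) > TIME_TOL:
            raise ValueError("motion trace must be uniformly sampled")

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / (self.times[1] - self.times[0])

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "motion": self.motion}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, mouse_id: str = "m0", phase: str = "") -> "MotionTrace":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["motion"].to_numpy(),
                   mouse_id=mouse_id, phase=phase)
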