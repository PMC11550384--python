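"""Freezing quantification, memory-strength ratio and extinction curves.

Freezing is scored frame by frame from a motion-magnitude trace: a frame
is frozen when it belongs to a contiguous run of sub-threshold motion at
least ``min_bout_s`` long (the bout floor suppresses single-frame noise;
0 reproduces pure thresholding). Percent freezing is the percentage of
frozen frames inside each 10-s cue window, optionally also the 10-s
post-cue window.

Second-order memory strength is the per-mouse ratio of test-day freezing
to the tone CS2 over freezing to the light CS1 (during CS2-CS1 pairing),
x100. Extinction over repeated cue presentations is summarized by the
trial-ordered group means plus a log-space least-squares decay rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MotionTrace, validate_events


@dataclass(frozen=True)
class FreezingRecord:
    mouse_id: str
    event_label: str
    trial_index: int
    freeze_pct: float            # of the cue window, in [0, 100]
    post_freeze_pct: float       # of the 10 s after cue offset (NaN if cut)
    phase: str = ""


@dataclass(frozen=True)
class MemoryStrength:
    mouse_id: str
    cs2_test_pct: float          # mean over test trials
    cs1_reference_pct: float
    ratio_pct: float             # 100 * cs2 / cs1


def _frozen_frames(motion: np.ndarray, fs: float, threshold: float,
                   min_bout_s: float) -> np.ndarray:
    """Boolean mask of frames inside qualifying freeze bouts."""
    below = motion < threshold
    if min_bout_s <= 0:
        return below
    min_frames = int(round(min_bout_s * fs))
    frozen = np.zeros_like(below)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], below.view(np.int8),
                                                   [0]))))
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start >= min_frames:
            frozen[start:end] = True
    return frozen


def freezing_percent(motion: MotionTrace, events: pd.DataFrame,
                     threshold: float = 0.5, min_bout_s: float = 1.0,
                     post_window_s: float = 10.0) -> list[FreezingRecord]:
    """Percent of frozen frames per cue window (and post-cue window)."""
    validate_events(events)
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    fs = motion.sampling_rate_hz
    frozen = _frozen_frames(motion.motion, fs, threshold, min_bout_s)
    records = []
    for _, ev in events.iterrows():
        j0 = int(np.ceil(ev["onset_s"] * fs - 1e-9))
        j1 = int(np.ceil((ev["onset_s"] + ev["duration_s"]) * fs - 1e-9))
        if j0 >= j1 or j1 > frozen.size:
            raise ValueError(
                f"empty or out-of-range window for {ev['event_label']} "
                f"trial {ev['trial_index']}")
        pct = 100.0 * frozen[j0:j1].mean()
        j2 = int(np.ceil((ev["onset_s"] + ev["duration_s"] + post_window_s)
                         * fs - 1e-9))
        post = 100.0 * frozen[j1:j2].mean() if j2 <= frozen.size else np.nan
        records.append(FreezingRecord(
            mouse_id=motion.mouse_id,
            event_label=str(ev["event_label"]),
            trial_index=int(ev["trial_index"]),
            freeze_pct=float(pct),
            post_freeze_pct=float(post),
            phase=str(ev["phase"]),
        ))
    return records


def records_table(records: list[FreezingRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def memory_strength(records: list[FreezingRecord],
                    cs2_label: str = "CS2", cs2_phase: str = "test",
                    cs1_label: str = "CS1", cs1_phase: str = "CS2-CS1",
                    ) -> tuple[list[MemoryStrength], dict[str, float]]:
    """Second-order memory strength per mouse plus the group summary.

    Ratio = 100 x (mean test-day CS2 freezing) / (mean CS1 freezing during
    the CS2-CS1 pairing session). Mice without a positive CS1 reference are
    excluded with a warning.
    """
    df = records_table(records)
    out: list[MemoryStrength] = []
    for mouse, grp in df.groupby("mouse_id"):
        cs2 = grp[(grp["event_label"] == cs2_label) & (grp["phase"] == cs2_phase)]
        cs1 = grp[(grp["event_label"] == cs1_label) & (grp["phase"] == cs1_phase)]
        if cs2.empty or cs1.empty:
            raise ValueError(f"mouse {mouse} lacks CS2-test or CS1-reference "
                             f"freezing records")
        cs2_pct = float(cs2["freeze_pct"].mean())
        cs1_pct = float(cs1["freeze_pct"].mean())
        if cs1_pct <= 0:
            warnings.warn(f"mouse {mouse} excluded: CS1 reference freezing "
                          f"is zero", stacklevel=2)
            continue
        out.append(MemoryStrength(str(mouse), cs2_pct, cs1_pct,
                                  100.0 * cs2_pct / cs1_pct))
    if not out:
        raise ValueError("no mouse with a positive CS1 reference")
    ratios = np.array([m.ratio_pct for m in out])
    summary = {
        "mean_ratio_pct": float(ratios.mean()),
        "sem_ratio_pct": float(ratios.std(ddof=1) / np.sqrt(ratios.size))
        if ratios.size > 1 else float("nan"),
        "n_mice": int(ratios.size),
    }
    return out, summary


def extinction_curve(records: list[FreezingRecord], event_label: str,
                     floor_pct: float = 1.0) -> pd.DataFrame:
    """Trial-ordered group mean freezing plus an exponential decay rate.

    The decay rate r comes from least squares of ``log(max(mean, floor))``
    on trial index: ``mean_t ~ a * exp(-r t)``. A flat curve gives r = 0.
    The result table carries the per-trial means; the rate is stored in
    ``DataFrame.attrs["decay_rate"]`` (NaN, with a warning, if the curve
    is entirely at zero).
    """
    df = records_table(records)
    df = df[df["event_label"] == event_label]
    if df.empty:
        raise ValueError(f"no freezing records for {event_label!r}")
    curve = (df.groupby("trial_index")["freeze_pct"].agg(["mean", "sem", "count"])
             .reset_index())
    if len(curve) < 2:
        raise ValueError("extinction needs at least 2 trials")
    y = curve["mean"].to_numpy()
    t = curve["trial_index"].to_numpy(dtype=float)
    if np.all(y <= 0):
        warnings.warn(f"all-zero freezing curve for {event_label!r}; decay "
                      f"rate undefined", stacklevel=2)
        rate = float("nan")
    else:
        logy = np.log(np.maximum(y, floor_pct))
        slope = np.polyfit(t, logy, 1)[0]
        rate = float(-slope)
    curve.attrs["decay_rate"] = rate
    curve.attrs["event_label"] = event_label
    return curve
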