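"""Peri-event alignment, trial averaging and area under the curve.

Responsiveness is quantified from the area under the trial-averaged ΔF/F
trace in three windows around stimulus onset: pre (-10..0 s), post
(0..+10 s) and late (+10..+20 s, the sustained post-cue period). Integrals
use the trapezoidal rule on the sample grid; window boundaries are shared
integration endpoints only, so a constant trace c over a 10-s window
integrates to exactly 10 c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PeriEventTensor, TraceMatrix, WindowSpec, validate_events
from .preprocessing import _onset_index


@dataclass(frozen=True)
class AUCRecord:
    """Pre/post/late AUC of one neuron's trial-averaged response."""

    neuron_id: str
    event_label: str
    auc_pre: float    # unitless ΔF/F · s over [-10, 0]
    auc_post: float   # over [0, +10]
    auc_late: float   # over [+10, +20]

    @property
    def ratio(self) -> float:
        """Raw post/pre AUC ratio (see classification for the guarded form)."""
        return self.auc_post / self.auc_pre if self.auc_pre != 0 else np.inf


def align(trace: TraceMatrix, events: pd.DataFrame, label: str,
          window: WindowSpec = WindowSpec()) -> PeriEventTensor:
    """Cut one slice per qualifying event of ``label`` from a normalized trace.

    Events whose window does not fit inside the session are excluded and
    enumerated in ``excluded_trials``.
    """
    validate_events(events)
    sel = events[events["event_label"] == label].sort_values("onset_s")
    if sel.empty:
        available = sorted(events["event_label"].unique())
        raise ValueError(f"no events labelled {label!r}; available: {available}")

    fs = trace.sampling_rate_hz
    n_pre = int(round(window.pre_s * fs))
    n_post = int(round(window.post_s * fs))
    rel = (np.arange(n_pre + n_post + 1) - n_pre) / fs

    slices, excluded = [], []
    for trial_no, (_, ev) in enumerate(sel.iterrows()):
        i0 = _onset_index(trace.times, ev["onset_s"], fs)
        lo, hi = i0 - n_pre, i0 + n_post + 1
        if lo < 0 or hi > trace.n_samples:
            excluded.append(trial_no)
            continue
        slices.append(trace.values[:, lo:hi])
    if not slices:
        raise ValueError(f"no {label!r} trial window fits inside the session")
    return PeriEventTensor(
        neuron_ids=list(trace.neuron_ids),
        rel_times=rel,
        values=np.stack(slices, axis=1),
        event_label=label,
        window=window,
        phase=trace.phase,
        excluded_trials=excluded,
    )


def trial_average(tensor: PeriEventTensor) -> np.ndarray:
    """Pointwise mean across trials per neuron (neuron x time).

    NaN samples (degenerate neuron-trials flagged upstream) are omitted
    from the mean; a neuron whose every trial is degenerate stays NaN.
    """
    with np.errstate(invalid="ignore"):
        return np.nanmean(tensor.values, axis=1)


def population_average(tensor: PeriEventTensor) -> pd.DataFrame:
    """Mean ± SEM across neurons of the trial-averaged traces."""
    per_neuron = trial_average(tensor)
    n = np.sum(np.isfinite(per_neuron), axis=0)
    mean = np.nanmean(per_neuron, axis=0)
    sem = np.nanstd(per_neuron, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
    return pd.DataFrame({"time_s_rel": tensor.rel_times, "mean": mean,
                         "sem": sem, "n": n})


def _window_auc(rel_times: np.ndarray, traces: np.ndarray,
                lo: float, hi: float) -> np.ndarray:
    if lo < rel_times[0] - 1e-9 or hi > rel_times[-1] + 1e-9:
        raise ValueError(f"window [{lo}, {hi}] s outside tensor range "
                         f"[{rel_times[0]}, {rel_times[-1]}] s")
    mask = (rel_times >= lo - 1e-9) & (rel_times <= hi + 1e-9)
    return np.trapezoid(traces[:, mask], rel_times[mask], axis=1)


def auc(tensor: PeriEventTensor,
        pre: tuple[float, float] = (-10.0, 0.0),
        post: tuple[float, float] = (0.0, 10.0),
        late: tuple[float, float] | None = (10.0, 20.0),
        ) -> list[AUCRecord]:
    """Trapezoidal AUC of the trial-averaged trace per neuron.

    ``late`` covers the sustained post-cue period and is skipped when the
    tensor window is too short for it.
    """
    avg = trial_average(tensor)
    rel = tensor.rel_times
    a_pre = _window_auc(rel, avg, *pre)
    a_post = _window_auc(rel, avg, *post)
    if late is not None and rel[-1] >= late[1] - 1e-9:
        a_late = _window_auc(rel, avg, *late)
    else:
        a_late = np.full(tensor.n_neurons, np.nan)
    return [
        AUCRecord(nid, tensor.event_label,
                  float(a_pre[i]), float(a_post[i]), float(a_late[i]))
        for i, nid in enumerate(tensor.neuron_ids)
    ]


def per_trial_auc(tensor: PeriEventTensor,
                  window: tuple[float, float] = (0.0, 10.0)) -> pd.DataFrame:
    """AUC of each individual trial, for trial-course analyses.

    Returns long-format columns ``neuron_id, trial, auc``.
    """
    rel = tensor.rel_times
    mask = (rel >= window[0] - 1e-9) & (rel <= window[1] + 1e-9)
    vals = np.trapezoid(tensor.values[:, :, mask], rel[mask], axis=2)
    n, t = vals.shape
    return pd.DataFrame({
        "neuron_id": np.repeat(tensor.neuron_ids, t),
        "trial": np.tile(np.arange(t), n),
        "auc": vals.ravel(),
    })


def auc_table(records: list[AUCRecord]) -> pd.DataFrame:
    """AUC records as a DataFrame (the CSV output dialect)."""
    return pd.DataFrame({
        "neuron_id": [r.neuron_id for r in records],
        "event_label": [r.event_label for r in records],
        "auc_pre": [r.auc_pre for r in records],
        "auc_post": [r.auc_post for r in records],
        "auc_late": [r.auc_late for r in records],
        "ratio": [r.ratio for r in records],
    })
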