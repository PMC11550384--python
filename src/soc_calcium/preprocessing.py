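"""Fluorescence normalization.

Two normalizations are applied, in this order:

1. whole-trace ΔF/F per neuron: ``(F - mean(F)) / mean(F)`` where the mean
   is taken over the entire session trace;
2. peri-event Z-score per neuron *per trial*: ``(F - mean(F0)) / SD(F0)``
   where F0 is the baseline segment from -10 s to 0 s before stimulus
   onset (time 0 = onset of any stimulus: US, CS1 or CS2).

The SD is the population SD (divisor N). Trials whose baseline has zero SD,
or whose window does not fit inside the session, are excluded and counted
rather than padded or allowed to produce infinities.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import PeriEventTensor, TraceMatrix, WindowSpec, validate_events


def delta_f_over_f(trace: TraceMatrix) -> TraceMatrix:
    """Whole-trace ΔF/F: ``(F - mean(F)) / mean(F)`` per neuron.

    Raises if any neuron has a non-positive trace mean (raw fluorescence is
    strictly positive, so a non-positive mean marks a corrupt row).
    """
    means = trace.values.mean(axis=1)
    bad = np.flatnonzero(means <= 0)
    if bad.size:
        names = [trace.neuron_ids[i] for i in bad]
        raise ValueError(f"non-positive trace mean for neurons {names}")
    values = (trace.values - means[:, None]) / means[:, None]
    return TraceMatrix(
        neuron_ids=list(trace.neuron_ids),
        times=trace.times,
        values=values,
        sampling_rate_hz=trace.sampling_rate_hz,
        phase=trace.phase,
    )


def _onset_index(times: np.ndarray, onset_s: float, fs: float) -> int:
    """First sample with t >= onset."""
    return int(np.searchsorted(times, onset_s - 1e-9))


def z_score(trace: TraceMatrix, events: pd.DataFrame, label: str,
            window: WindowSpec = WindowSpec(),
            per_session_baseline: bool = False) -> PeriEventTensor:
    """Peri-event Z-score around every onset of ``label``.

    Each trial's samples in ``[-pre_s, +post_s]`` are standardized by the
    mean and population SD of that trial's own baseline ``[-pre_s, 0)``
    (``per_session_baseline=True`` pools the baseline statistics across a
    session's trials instead). Trials with an incomplete window are
    excluded and listed in ``excluded_trials``; neuron-trials with zero
    baseline SD are excluded and listed in ``degenerate_trials``.
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

    slices, excluded, trial_ids = [], [], []
    for trial_no, (_, ev) in enumerate(sel.iterrows()):
        i0 = _onset_index(trace.times, ev["onset_s"], fs)
        lo, hi = i0 - n_pre, i0 + n_post + 1
        if lo < 0 or hi > trace.n_samples:
            excluded.append(trial_no)
            continue
        slices.append(trace.values[:, lo:hi])
        trial_ids.append(trial_no)
    if not slices:
        raise ValueError(f"no {label!r} trial window fits inside the session")

    raw = np.stack(slices, axis=1)  # neuron x trial x time
    base = raw[:, :, :n_pre]        # [-pre, 0)
    if per_session_baseline:
        mu = base.mean(axis=(1, 2), keepdims=True)
        sd = base.std(axis=(1, 2), keepdims=True)
        mu = np.broadcast_to(mu, (raw.shape[0], raw.shape[1], 1)).copy()
        sd = np.broadcast_to(sd, (raw.shape[0], raw.shape[1], 1)).copy()
    else:
        mu = base.mean(axis=2, keepdims=True)
        sd = base.std(axis=2, keepdims=True)

    degenerate = [(trace.neuron_ids[i], trial_ids[j])
                  for i, j in zip(*np.nonzero(sd[:, :, 0] == 0))]
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} neuron-trial(s) with zero baseline SD "
            f"excluded from z-scoring", stacklevel=2)
        sd = np.where(sd == 0, np.nan, sd)

    z = (raw - mu) / sd
    z[~np.isfinite(z)] = np.nan
    return PeriEventTensor(
        neuron_ids=list(trace.neuron_ids),
        rel_times=rel,
        values=z,
        event_label=label,
        window=window,
        phase=trace.phase,
        excluded_trials=excluded,
        degenerate_trials=degenerate,
    )
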