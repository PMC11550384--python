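"""Ensemble-correlation comparison across behavioral states.

For a chosen state (baseline, tone, light, ...) defined by a set of time
intervals, each neuron's trace samples inside the state are concatenated
and correlated (zero-lag Pearson) against every other neuron; the per-
neuron statistic is the maximum correlation over partners. Two states are
compared by the Cohen's d of their per-neuron maximum correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TraceMatrix


@dataclass
class StateWindowSet:
    """Named behavioral state as a list of ``(start_s, end_s)`` intervals."""

    label: str
    intervals: list[tuple[float, float]]

    def __post_init__(self) -> None:
        iv = sorted((float(a), float(b)) for a, b in self.intervals)
        if not iv:
            raise ValueError(f"state {self.label!r} has no intervals")
        for (a, b) in iv:
            if b <= a:
                raise ValueError(f"empty interval ({a}, {b}) in {self.label!r}")
        for (_, b0), (a1, _) in zip(iv, iv[1:]):
            if a1 < b0:
                raise ValueError(f"overlapping intervals in state {self.label!r}")
        self.intervals = iv

    def mask(self, times: np.ndarray) -> np.ndarray:
        m = np.zeros(times.size, dtype=bool)
        for a, b in self.intervals:
            m |= (times >= a - 1e-9) & (times < b - 1e-9)
        return m

    @classmethod
    def from_events(cls, events: pd.DataFrame, event_label: str,
                    state_label: str | None = None) -> "StateWindowSet":
        sel = events[events["event_label"] == event_label]
        if sel.empty:
            raise ValueError(f"no events labelled {event_label!r}")
        return cls(state_label or event_label,
                   [(r["onset_s"], r["onset_s"] + r["duration_s"])
                    for _, r in sel.iterrows()])


@dataclass
class CorrelationComparison:
    """Per-neuron max pairwise r in two states plus their Cohen's d."""

    state_a: str
    state_b: str
    max_r_a: pd.Series
    max_r_b: pd.Series
    d: float

    @property
    def n_a(self) -> int:
        return int(self.max_r_a.size)

    @property
    def n_b(self) -> int:
        return int(self.max_r_b.size)


def max_pairwise_corr(trace: TraceMatrix, state: StateWindowSet
                      ) -> pd.Series:
    """Per-neuron maximum Pearson r against any partner within a state.

    Samples from all of the state's intervals are concatenated before
    correlating. Zero-variance neurons are excluded with a warning.
    """
    if trace.n_neurons < 2:
        raise ValueError("need at least 2 neurons for pairwise correlation")
    mask = state.mask(trace.times)
    if mask.sum() < 2:
        raise ValueError(f"state {state.label!r} covers fewer than 2 samples")
    segment = trace.values[:, mask]
    sd = segment.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-variance "
                      f"neuron(s) in state {state.label!r}", stacklevel=2)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 neurons with variance in state")
    ids = [n for n, k in zip(trace.neuron_ids, keep) if k]
    r = np.corrcoef(segment[keep])
    np.fill_diagonal(r, -np.inf)  # a neuron is not its own partner
    return pd.Series(r.max(axis=1), index=pd.Index(ids, name="neuron_id"),
                     name=f"max_r_{state.label}")


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Standardized mean difference, pooled SD with N-1 weighting.

    ``d = (mean_a - mean_b) / s_pooled`` with
    ``s_pooled² = ((n_a-1)s_a² + (n_b-1)s_b²) / (n_a + n_b - 2)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = ((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2)
    if pooled == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("pooled SD is zero with unequal means")
    return float((a.mean() - b.mean()) / np.sqrt(pooled))


def compare_states(trace: TraceMatrix, state_a: StateWindowSet,
                   state_b: StateWindowSet) -> CorrelationComparison:
    """Max pairwise correlations in two states and their Cohen's d (a - b)."""
    ra = max_pairwise_corr(trace, state_a)
    rb = max_pairwise_corr(trace, state_b)
    return CorrelationComparison(
        state_a=state_a.label, state_b=state_b.label,
        max_r_a=ra, max_r_b=rb,
        d=cohens_d(ra.to_numpy(), rb.to_numpy()),
    )


def comparison_table(comp: CorrelationComparison) -> pd.DataFrame:
    return pd.DataFrame([{
        "state_a": comp.state_a, "state_b": comp.state_b,
        "mean_max_r_a": float(comp.max_r_a.mean()),
        "mean_max_r_b": float(comp.max_r_b.mean()),
        "cohens_d": comp.d, "n_a": comp.n_a, "n_b": comp.n_b,
    }])
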