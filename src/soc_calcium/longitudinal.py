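"""Cross-session neuron matching and longitudinal category tracking.

Neurons recorded on different days are matched one-to-one by a greedy
best-score assignment over candidate pairs. The match score combines
footprint-centroid proximity and the Pearson correlation of a per-neuron
reference trace (the session-mean peri-event response), each weighted 0.5;
with traces only, the score is the correlation alone. Pairs scoring below
the acceptance threshold (default 0.5, the standard minimum-correlation
criterion for longitudinal registration) are rejected.

Matched neurons are then tracked across the conditioning phases that admit
registration — habituation, CS2–CS1 pairing and test; the shock day is
excluded because foot-shock motion artifacts corrupt registration — and
their response categories are laid out as trajectories plus a
habituation-by-test transition matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .classification import ResponseClassification, format_percent

TRACKING_PHASES = ("habituation", "CS2-CS1", "test")
MIN_MATCH_SCORE = 0.5


@dataclass
class SessionFeatures:
    """Per-session matching features: ids, optional centroids, reference traces."""

    session_id: str
    neuron_ids: list[str]
    traces: np.ndarray                      # n_neurons x n_features
    centroids: np.ndarray | None = None     # n_neurons x 2

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.shape[0] != len(self.neuron_ids):
            raise ValueError("one reference trace per neuron required")
        if not self.neuron_ids:
            raise ValueError(f"session {self.session_id} is empty")
        if self.centroids is not None:
            self.centroids = np.asarray(self.centroids, dtype=float)
            if self.centroids.shape != (len(self.neuron_ids), 2):
                raise ValueError("centroids must be n_neurons x 2")


@dataclass
class RegistrationMap:
    """One-to-one matches between two sessions with their scores."""

    session_a: str
    session_b: str
    pairs: list[tuple[str, str, float]]
    unmatched_a: list[str] = field(default_factory=list)
    unmatched_b: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, str]:
        return {a: b for a, b, _ in self.pairs}

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs,
                            columns=["session_a_id", "session_b_id", "score"])


def _score_matrix(a: SessionFeatures, b: SessionFeatures,
                  distance_scale: float) -> np.ndarray:
    ta = a.traces - a.traces.mean(axis=1, keepdims=True)
    tb = b.traces - b.traces.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ta, axis=1)
    nb = np.linalg.norm(tb, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (ta @ tb.T) / np.outer(na, nb)
    corr = np.nan_to_num(corr, nan=-1.0)
    if a.centroids is None or b.centroids is None:
        return corr
    d = np.linalg.norm(a.centroids[:, None, :] - b.centroids[None, :, :],
                       axis=2)
    proximity = np.clip(1.0 - d / distance_scale, 0.0, 1.0)
    return 0.5 * proximity + 0.5 * corr


def match_sessions(a: SessionFeatures, b: SessionFeatures,
                   threshold: float = MIN_MATCH_SCORE,
                   distance_scale: float = 10.0,
                   optimal: bool = False) -> RegistrationMap:
    """Greedy one-to-one matching of neurons between two sessions.

    Candidate pairs are ranked by score (ties broken by neuron ids) and
    accepted greedily while both partners are free and the score reaches
    ``threshold``. ``optimal=True`` solves the assignment problem instead
    (Hungarian algorithm), still discarding below-threshold pairs.
    Symmetric: swapping the sessions yields the mirrored pairs.
    """
    scores = _score_matrix(a, b, distance_scale)
    pairs: list[tuple[str, str, float]] = []
    if optimal:
        rows, cols = linear_sum_assignment(-scores)
        for i, j in zip(rows, cols):
            if scores[i, j] >= threshold:
                pairs.append((a.neuron_ids[i], b.neuron_ids[j],
                              float(scores[i, j])))
    else:
        order = sorted(
            ((i, j) for i in range(len(a.neuron_ids))
             for j in range(len(b.neuron_ids))),
            key=lambda ij: (-scores[ij], a.neuron_ids[ij[0]],
                            b.neuron_ids[ij[1]]),
        )
        used_a: set[int] = set()
        used_b: set[int] = set()
        for i, j in order:
            if scores[i, j] < threshold:
                break
            if i in used_a or j in used_b:
                continue
            pairs.append((a.neuron_ids[i], b.neuron_ids[j],
                          float(scores[i, j])))
            used_a.add(i)
            used_b.add(j)
    pairs.sort(key=lambda p: (p[0], p[1]))
    matched_a = {p[0] for p in pairs}
    matched_b = {p[1] for p in pairs}
    return RegistrationMap(
        session_a=a.session_id,
        session_b=b.session_id,
        pairs=pairs,
        unmatched_a=[n for n in a.neuron_ids if n not in matched_a],
        unmatched_b=[n for n in b.neuron_ids if n not in matched_b],
    )


@dataclass
class CategoryTrajectory:
    """Ordered per-phase categories (and AUCs) of one tracked neuron."""

    neuron_id: str                      # id in the first tracked phase
    categories: dict[str, str]          # phase -> category
    auc_post: dict[str, float]          # phase -> post-event AUC


@dataclass
class TrackingResult:
    trajectories: list[CategoryTrajectory]
    transition: pd.DataFrame            # habituation category x test category
    group_auc: pd.DataFrame             # habituation group -> mean AUC per phase
    n_dropped: int

    @property
    def n_tracked(self) -> int:
        return len(self.trajectories)


def track_categories(
    maps: list[RegistrationMap],
    classifications: dict[str, list[ResponseClassification]],
    phases: tuple[str, ...] = TRACKING_PHASES,
) -> TrackingResult:
    """Follow matched neurons across phases and tabulate category changes.

    ``maps`` chains consecutive phases (``phases[i]`` to ``phases[i+1]``).
    Neurons missing a link or a classification in any phase are dropped and
    counted. The transition matrix cross-tabulates first-phase against
    last-phase categories; its row sums equal the first-phase category
    counts restricted to tracked neurons.
    """
    if len(maps) != len(phases) - 1:
        raise ValueError(f"need {len(phases) - 1} registration maps for "
                         f"{len(phases)} phases")
    for phase in phases:
        if phase not in classifications:
            raise ValueError(f"no classifications for phase {phase!r}")
    lookup = [
        {c.neuron_id: c for c in classifications[phase]} for phase in phases
    ]
    chain = [m.as_dict() for m in maps]

    trajectories: list[CategoryTrajectory] = []
    n_dropped = 0
    for nid in sorted(lookup[0]):
        ids = [nid]
        ok = True
        for link in chain:
            nxt = link.get(ids[-1])
            if nxt is None:
                ok = False
                break
            ids.append(nxt)
        if not ok or any(i not in lk for i, lk in zip(ids, lookup)):
            n_dropped += 1
            continue
        cls = [lk[i] for i, lk in zip(ids, lookup)]
        trajectories.append(CategoryTrajectory(
            neuron_id=nid,
            categories={ph: c.category for ph, c in zip(phases, cls)},
            auc_post={ph: c.auc_post for ph, c in zip(phases, cls)},
        ))

    cats = sorted({c for t in trajectories for c in t.categories.values()}
                  | {"increased", "no_change", "decreased"})
    first, last = phases[0], phases[-1]
    transition = pd.DataFrame(0, index=cats, columns=cats)
    for t in trajectories:
        transition.loc[t.categories[first], t.categories[last]] += 1
    transition.index.name = f"{first}_category"
    transition.columns.name = f"{last}_category"

    rows = []
    for cat in cats:
        members = [t for t in trajectories if t.categories[first] == cat]
        if not members:
            continue
        row = {"habituation_category": cat, "n": len(members),
               "pct": format_percent(len(members), len(trajectories))}
        for ph in phases:
            row[f"auc_{ph}"] = float(np.mean([t.auc_post[ph] for t in members]))
        rows.append(row)
    group_auc = pd.DataFrame(rows)
    return TrackingResult(trajectories=trajectories, transition=transition,
                          group_auc=group_auc, n_dropped=n_dropped)
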