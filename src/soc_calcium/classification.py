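"""AUC-ratio response classification and population summaries.

A neuron is *increased* when its post-event AUC exceeds the pre-event AUC
by more than 50% (post/pre ratio > 1.5), *decreased* when it falls by more
than 50% (ratio < 0.5), and *no change* otherwise; inequalities are strict.

The ratio rule is only meaningful for a clearly positive pre-AUC. ΔF/F
integrates can be negative or near zero, so when ``auc_pre <= eps`` (with
``eps = 0.01 * window length``) the decision falls back to the AUC
*difference*, thresholded at half the robust spread of pre-AUCs across the
population (1.4826 · MAD). A record classified in isolation, where no
population scale exists, is labelled *degenerate* instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .peri_event import AUCRecord

CATEGORIES = ("increased", "no_change", "decreased", "degenerate")

INCREASE_RATIO = 1.5   # "> 50% increase of AUC (after/before the event)"
DECREASE_RATIO = 0.5   # "> 50% decrease"


@dataclass(frozen=True)
class ResponseClassification:
    neuron_id: str
    event_label: str
    category: str
    auc_pre: float
    auc_post: float
    effective_ratio: float  # NaN when the difference fallback decided


@dataclass(frozen=True)
class PopulationSummary:
    """Counts and printed-style percentages per category."""

    event_label: str
    phase: str
    n_total: int
    counts: dict[str, int]
    percentages: dict[str, float]


def format_percent(count: int, total: int) -> float:
    """Percentage with one decimal, round half up — the printed convention."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = Decimal(100) * Decimal(count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _pre_eps(window_length_s: float) -> float:
    return 0.01 * window_length_s


def classify(record: AUCRecord, window_length_s: float = 10.0,
             diff_scale: float | None = None) -> ResponseClassification:
    """Classify one neuron from its pre/post AUCs.

    ``diff_scale`` is the robust SD of pre-AUCs across the population; it
    drives the difference fallback when ``auc_pre`` is not clearly
    positive. Without it such a record is *degenerate*.
    """
    pre, post = record.auc_pre, record.auc_post
    if not (np.isfinite(pre) and np.isfinite(post)):
        raise ValueError(f"non-finite AUC for neuron {record.neuron_id}")
    eps = _pre_eps(window_length_s)
    if pre > eps:
        ratio = post / pre
        if ratio > INCREASE_RATIO:
            category = "increased"
        elif ratio < DECREASE_RATIO:
            category = "decreased"
        else:
            category = "no_change"
        return ResponseClassification(record.neuron_id, record.event_label,
                                      category, pre, post, float(ratio))
    if diff_scale is None or diff_scale < 0:
        return ResponseClassification(record.neuron_id, record.event_label,
                                      "degenerate", pre, post, float("nan"))
    diff = post - pre
    # absolute floor guards against float-rounding noise on noiseless data
    thr = max(0.5 * diff_scale, 1e-9)
    if diff > thr:
        category = "increased"
    elif diff < -thr:
        category = "decreased"
    else:
        category = "no_change"
    return ResponseClassification(record.neuron_id, record.event_label,
                                  category, pre, post, float("nan"))


def robust_pre_scale(records: list[AUCRecord]) -> float:
    """1.4826 · median absolute deviation of pre-AUCs (robust SD)."""
    pre = np.array([r.auc_pre for r in records])
    return float(1.4826 * np.median(np.abs(pre - np.median(pre))))


def classify_population(records: list[AUCRecord],
                        window_length_s: float = 10.0
                        ) -> list[ResponseClassification]:
    """Classify a whole population, enabling the difference fallback."""
    if not records:
        raise ValueError("no AUC records to classify")
    scale = robust_pre_scale(records)
    return [classify(r, window_length_s, diff_scale=scale)
            for r in records]


def summarize(classifications: list[ResponseClassification],
              phase: str = "") -> PopulationSummary:
    """Exact category counts and one-decimal percentages."""
    if not classifications:
        raise ValueError("no classifications to summarize")
    ids = [c.neuron_id for c in classifications]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate neuron_id in classification set")
    labels = {c.event_label for c in classifications}
    if len(labels) != 1:
        raise ValueError(f"mixed event labels in summary: {sorted(labels)}")
    n = len(classifications)
    counts = {cat: sum(c.category == cat for c in classifications)
              for cat in CATEGORIES}
    percentages = {cat: format_percent(k, n) for cat, k in counts.items()}
    return PopulationSummary(event_label=labels.pop(), phase=phase,
                             n_total=n, counts=counts, percentages=percentages)


def encode_overlap(class_by_event: dict[str, list[ResponseClassification]],
                   label_a: str = "CS1", label_b: str = "CS2"
                   ) -> pd.DataFrame:
    """Partition neurons by responsiveness to two cues.

    Returns one row per partition cell — ``both`` (e.g. CS1/CS2-encoding),
    ``{a}_only``, ``{b}_only`` (e.g. CS2-encoding) and ``neither`` — with
    counts, percent of all neurons, and percent of ``label_b`` responders
    (the printed "of the CS2 responders, x% also responded to CS1" style).
    """
    try:
        cls_a = {c.neuron_id: c for c in class_by_event[label_a]}
        cls_b = {c.neuron_id: c for c in class_by_event[label_b]}
    except KeyError as exc:
        raise ValueError(f"missing classifications for label {exc}") from None
    if set(cls_a) != set(cls_b):
        raise ValueError("classifications cover different neuron universes")
    resp_a = {n for n, c in cls_a.items() if c.category == "increased"}
    resp_b = {n for n, c in cls_b.items() if c.category == "increased"}
    n_total = len(cls_a)
    n_b = len(resp_b)
    cells = {
        "both": len(resp_a & resp_b),
        f"{label_a}_only": len(resp_a - resp_b),
        f"{label_b}_only": len(resp_b - resp_a),
        "neither": n_total - len(resp_a | resp_b),
    }
    rows = []
    for name, count in cells.items():
        pct_of_b = (format_percent(count, n_b)
                    if n_b and name in ("both", f"{label_b}_only") else np.nan)
        rows.append({"partition": name, "count": count,
                     "pct_of_total": format_percent(count, n_total),
                     f"pct_of_{label_b}_responders": pct_of_b})
    return pd.DataFrame(rows)


def classification_table(classifications: list[ResponseClassification]
                         ) -> pd.DataFrame:
    return pd.DataFrame({
        "neuron_id": [c.neuron_id for c in classifications],
        "event_label": [c.event_label for c in classifications],
        "category": [c.category for c in classifications],
        "auc_pre": [c.auc_pre for c in classifications],
        "auc_post": [c.auc_post for c in classifications],
        "effective_ratio": [c.effective_ratio for c in classifications],
    })
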