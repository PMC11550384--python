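"""Response-archetype clustering of peri-event traces.

Per-neuron trial-averaged Z-scored traces over the -10..+20 s analysis
window are clustered with K-means (Euclidean distance on the raw time-
sample vectors, many restarts, fixed seed). The working group number is 5;
a silhouette scan over a k range validates that choice, taking the k with
the highest mean silhouette (smallest k on ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .classification import format_percent
from .peri_event import trial_average
from .core import PeriEventTensor

DEFAULT_K = 5
DEFAULT_K_RANGE = range(2, 9)
#: Mean silhouette below this in a scan is reported as "no structure".
NO_STRUCTURE_SILHOUETTE = 0.2


@dataclass
class ClusterResult:
    """K-means partition of per-neuron response traces.

    ``labels`` maps neuron_id to a 1-based cluster label; ``centroids`` has
    shape ``(k, n_times)`` on the tensor's relative-time axis.
    """

    labels: dict[str, int]
    centroids: np.ndarray
    rel_times: np.ndarray
    sizes: dict[int, int]
    percentages: dict[int, float]
    k: int
    seed: int
    inertia: float
    silhouette: float | None = None
    silhouette_curve: dict[int, float] = field(default_factory=dict)


def _trace_vectors(tensor: PeriEventTensor) -> tuple[np.ndarray, list[str]]:
    vecs = trial_average(tensor)
    ok = np.all(np.isfinite(vecs), axis=1)
    if not ok.all():
        dropped = [n for n, good in zip(tensor.neuron_ids, ok) if not good]
        warnings.warn(f"dropping {len(dropped)} neuron(s) with non-finite "
                      f"average traces: {dropped[:5]}...", stacklevel=3)
    ids = [n for n, good in zip(tensor.neuron_ids, ok) if good]
    return vecs[ok], ids


def cluster_traces(tensor: PeriEventTensor, k: int = DEFAULT_K,
                   seed: int = 0, n_restarts: int = 50) -> ClusterResult:
    """K-means over per-neuron averaged traces; deterministic given seed."""
    vecs, ids = _trace_vectors(tensor)
    n = len(ids)
    if k < 2 or k >= n:
        raise ValueError(f"k={k} out of range for {n} neurons")
    if np.allclose(vecs, vecs[0]):
        raise ValueError("all traces identical; clustering is degenerate")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(vecs)
    # relabel clusters by decreasing size (stable presentation order)
    order = np.argsort([-(raw == c).sum() for c in range(k)], kind="stable")
    remap = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = {nid: remap[int(c)] for nid, c in zip(ids, raw)}
    sizes = {lbl: sum(1 for v in labels.values() if v == lbl)
             for lbl in range(1, k + 1)}
    sil = float(silhouette_score(vecs, raw)) if k < n else None
    return ClusterResult(
        labels=labels,
        centroids=np.stack([km.cluster_centers_[int(old)] for old in order]),
        rel_times=tensor.rel_times,
        sizes=sizes,
        percentages={lbl: format_percent(s, n) for lbl, s in sizes.items()},
        k=k,
        seed=seed,
        inertia=float(km.inertia_),
        silhouette=sil,
    )


def select_k(tensor: PeriEventTensor, k_range=DEFAULT_K_RANGE,
             seed: int = 0, n_restarts: int = 50) -> ClusterResult:
    """Pick k by maximum mean silhouette over ``k_range`` (ties -> smallest k)."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    vecs, _ = _trace_vectors(tensor)
    n = vecs.shape[0]
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k range {ks[0]}..{ks[-1]} outside [2, {n - 1}]")
    curve: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        curve[k] = float(silhouette_score(vecs, km.fit_predict(vecs)))
    best_k = max(ks, key=lambda k: (curve[k], -k))
    if max(curve.values()) <= NO_STRUCTURE_SILHOUETTE:
        warnings.warn(
            f"no cluster structure: max silhouette "
            f"{max(curve.values()):.3f} <= {NO_STRUCTURE_SILHOUETTE}",
            stacklevel=2)
    result = cluster_traces(tensor, k=best_k, seed=seed, n_restarts=n_restarts)
    result.silhouette_curve = curve
    return result


def labels_table(result: ClusterResult) -> pd.DataFrame:
    return pd.DataFrame({
        "neuron_id": list(result.labels),
        "cluster": list(result.labels.values()),
    })


def centroids_table(result: ClusterResult) -> pd.DataFrame:
    df = pd.DataFrame(result.centroids.T,
                      columns=[f"cluster_{i + 1}" for i in range(result.k)])
    df.insert(0, "time_s_rel", result.rel_times)
    return df


def silhouette_table(result: ClusterResult) -> pd.DataFrame:
    return pd.DataFrame({
        "k": list(result.silhouette_curve),
        "silhouette": list(result.silhouette_curve.values()),
    })
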