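"""Constructed fixtures: planted response-archetype tensors.

The shapes mirror the response families seen around a 10-s cue: broad
cue-tuned, post-cue riser, small delayed, onset-transient and flat.
Everything is generated at call time from a seed.
"""

from __future__ import annotations

import numpy as np

from soc_calcium.core import PeriEventTensor, WindowSpec

FS = 10.0
REL = (np.arange(301) - 100) / FS  # -10 .. +20 s


def _shapes() -> list[np.ndarray]:
    # equal-energy responses at distinct peak times: cue onset, mid-cue,
    # late cue, just after offset, and sustained-period peak. Disjoint
    # supports make the archetypes evenly separated.
    t = REL
    centers = (1.0, 4.5, 8.0, 12.5, 16.5)
    return [3.0 * np.exp(-((t - c) / 1.5) ** 2) for c in centers]


def archetype_tensor(n_archetypes: int, per_cluster, noise_sd: float,
                     seed: int) -> tuple[PeriEventTensor, list[int]]:
    """Tensor of planted archetype traces plus the planted label list."""
    shapes = _shapes()[:n_archetypes]
    if isinstance(per_cluster, int):
        counts = [per_cluster] * n_archetypes
    else:
        counts = list(per_cluster)
        assert len(counts) == n_archetypes
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for k, (shape, count) in enumerate(zip(shapes, counts)):
        for _ in range(count):
            rows.append(shape + rng.normal(0, noise_sd, size=shape.size))
            labels.append(k)
    values = np.asarray(rows)[:, None, :]
    tensor = PeriEventTensor(
        neuron_ids=[f"n{i:03d}" for i in range(values.shape[0])],
        rel_times=REL,
        values=values,
        event_label="CS2",
        window=WindowSpec(10.0, 20.0),
    )
    return tensor, labels
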