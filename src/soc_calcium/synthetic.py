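"""Seeded synthetic second-order-conditioning (SOC) experiments.

Generates the three ingredients every downstream stage consumes:

* fluorescence trace matrices with planted per-neuron response classes,
  GCaMP6m-like double-exponential transients, slow baseline drift and
  Gaussian noise;
* event tables following the SOC paradigm — habituation (10 light CS1 +
  10 tone CS2, random order), CS1–US (10 light cues co-terminating with a
  0.5-s foot shock), CS2–CS1 (4 tone→light pairings, 0.5-s gap), and test
  (3 tones) — with 2-min inter-trial intervals and a 5-min baseline
  lead-in;
* two-state (freeze / move) motion traces whose freeze probability inside
  each cue window is planted per event label.

Every planted quantity is returned in a :class:`SimGroundTruth` so recovery
can be scored exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .core import EVENT_COLUMNS, MotionTrace, TraceMatrix, validate_events

PHASES = ("habituation", "CS1-US", "CS2-CS1", "test")

#: Planted response classes.
CLASSES = (
    "us_responsive",
    "cs1_responsive",
    "cs2_responsive",
    "sustained_post_cs",
    "inhibited",
    "unresponsive",
)

#: Which event label drives each responsive class.
_DRIVER = {
    "us_responsive": "US",
    "cs1_responsive": "CS1",
    "cs2_responsive": "CS2",
    "sustained_post_cs": "CS2",
    "inhibited": "CS2",
}


@dataclass(frozen=True)
class PhaseSpec:
    """Trial schedule for one experimental phase."""

    name: str
    n_trials: dict[str, int]          # event label -> trial count
    iti_s: float = 120.0              # inter-trial interval
    cue_duration_s: float = 10.0
    us_duration_s: float = 0.5
    cs2_cs1_gap_s: float = 0.5        # CS2 offset -> CS1 onset

    def __post_init__(self) -> None:
        if self.iti_s <= 0 or self.cue_duration_s <= 0 or self.us_duration_s <= 0:
            raise ValueError("durations and intervals must be positive")


def default_phases() -> dict[str, PhaseSpec]:
    """The standard SOC schedule: 10-s cues, 0.5-s US, 2-min ITI."""
    return {
        "habituation": PhaseSpec("habituation", {"CS1": 10, "CS2": 10}),
        "CS1-US": PhaseSpec("CS1-US", {"CS1": 10, "US": 10}),
        "CS2-CS1": PhaseSpec("CS2-CS1", {"CS2": 4, "CS1": 4}),
        "test": PhaseSpec("test", {"CS2": 3}),
    }


def default_class_fractions() -> dict[str, dict[str, float]]:
    """Planted class mix per phase.

    Habituation is mostly unresponsive; the US recruits most neurons during
    CS1–US; CS1 responders appear during CS2–CS1; CS2 responders emerge at
    test, some with sustained post-cue activity and a small inhibited group.
    """
    return {
        "habituation": {"cs2_responsive": 0.15, "inhibited": 0.05},
        "CS1-US": {"us_responsive": 0.8},
        "CS2-CS1": {"cs1_responsive": 0.45, "cs2_responsive": 0.25},
        "test": {"cs2_responsive": 0.30, "sustained_post_cs": 0.10,
                 "inhibited": 0.06},
    }


@dataclass(frozen=True)
class KernelSpec:
    """Double-exponential calcium transient kernel.

    ``h(t) ∝ exp(-t/decay_tau_s) - exp(-t/rise_tau_s)``, normalized so the
    peak equals ``amplitude`` (in ΔF/F units). Defaults approximate GCaMP6m
    kinetics.
    """

    rise_tau_s: float = 0.2
    decay_tau_s: float = 1.2
    amplitude: float = 0.5

    def __post_init__(self) -> None:
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("kernel taus must be positive")
        if self.decay_tau_s <= self.rise_tau_s:
            raise ValueError("decay tau must exceed rise tau")

    @property
    def peak_time_s(self) -> float:
        """Analytic peak time of the double exponential."""
        tr, td = self.rise_tau_s, self.decay_tau_s
        return tr * td / (td - tr) * np.log(td / tr)

    def sample(self, sampling_rate_hz: float) -> np.ndarray:
        """Kernel sampled until it has decayed to <1% of its peak."""
        t_end = self.peak_time_s + 5.0 * self.decay_tau_s
        t = np.arange(0.0, t_end, 1.0 / sampling_rate_hz)
        h = np.exp(-t / self.decay_tau_s) - np.exp(-t / self.rise_tau_s)
        peak = np.exp(-self.peak_time_s / self.decay_tau_s) - np.exp(
            -self.peak_time_s / self.rise_tau_s)
        return self.amplitude * h / peak


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic SOC experiment.

    ``class_fractions[phase]`` maps class name to the fraction of neurons
    planted with that response during the phase; the remainder is
    unresponsive. ``freeze_fractions`` plants the behavioral freeze
    probability inside each cue window (and ``"baseline"`` elsewhere).
    """

    n_neurons: int = 100
    sampling_rate_hz: float = 10.0
    phases: dict[str, PhaseSpec] = field(default_factory=default_phases)
    class_fractions: dict[str, dict[str, float]] = field(
        default_factory=default_class_fractions)
    kernel: KernelSpec = field(default_factory=KernelSpec)
    noise_sd: float = 0.1             # ΔF/F units
    fingerprint_amplitude: float = 0.15  # stable per-neuron cue-locked motif
    baseline_f: float = 100.0         # raw fluorescence offset, a.u.
    drift_amplitude: float = 0.1      # fraction of baseline
    drift_period_s: float = 600.0
    lead_in_s: float = 300.0          # pre-session baseline (5 min)
    dropout: float = 0.2              # per-session neuron dropout
    fov_size: float = 100.0           # centroid field of view, a.u.
    centroid_jitter: float = 0.5      # per-session centroid jitter SD
    freeze_fractions: dict[str, float] = field(
        default_factory=lambda: {"CS1": 0.7, "CS2": 0.5, "baseline": 0.05})
    freeze_bout_mean_s: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("need at least one neuron")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        for phase, fracs in self.class_fractions.items():
            unknown = set(fracs) - set(CLASSES)
            if unknown:
                raise ValueError(f"unknown classes {unknown} in phase {phase}")
            total = sum(fracs.values())
            if total > 1 + 1e-12:
                raise ValueError(
                    f"class fractions for {phase} sum to {total:.3f} > 1")
            if any(f < 0 for f in fracs.values()):
                raise ValueError("class fractions must be non-negative")
        for label, p in self.freeze_fractions.items():
            if not 0 <= p <= 1:
                raise ValueError(f"freeze fraction for {label} not in [0,1]")


@dataclass
class SimGroundTruth:
    """Everything that was planted, for recovery scoring.

    One record per emitted neuron: class label for the phase, event-locked
    gain and latency, and the footprint centroid (with the per-session
    jitter applied). ``freeze_fractions`` repeats the planted per-label
    freeze probabilities; ``present`` lists the neurons that survived
    session dropout.
    """

    phase: str
    classes: dict[str, str]
    gains: dict[str, float]
    latencies: dict[str, float]
    centroids: dict[str, tuple[float, float]]
    present: list[str]
    freeze_fractions: dict[str, float]


def _experiment_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng(config.seed)


#: Harmonics of the per-neuron fingerprint motif (full periods per 10 s).
_FINGERPRINT_HARMONICS = 6


def _neuron_properties(config: SimConfig):
    """Per-neuron properties shared by every phase (identity across sessions)."""
    rng = _experiment_rng(config)
    ids = [f"n{i:03d}" for i in range(config.n_neurons)]
    gains = rng.lognormal(mean=0.0, sigma=0.2, size=config.n_neurons)
    latencies = rng.uniform(0.0, 0.2, size=config.n_neurons)
    centroids = rng.uniform(0.0, config.fov_size, size=(config.n_neurons, 2))
    drift_phases = rng.uniform(0.0, 2 * np.pi, size=config.n_neurons)
    w = rng.normal(size=(config.n_neurons, _FINGERPRINT_HARMONICS))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    return ids, gains, latencies, centroids, drift_phases, w


def _fingerprints(config: SimConfig, weights: np.ndarray) -> np.ndarray:
    """Stable per-neuron cue-locked motif over the 20 s after cue onset.

    Each neuron's motif is a fixed mixture of sine harmonics with whole
    periods per 10-s analysis window, so its trapezoidal AUC over the
    0..10 s and 10..20 s windows is exactly zero: the motif identifies a
    neuron across sessions (its idiosyncratic response dynamics) without
    moving the AUC-based classification.
    """
    fs = config.sampling_rate_hz
    t = np.arange(int(round(20.0 * fs))) / fs
    basis = np.stack([np.sin(2 * np.pi * (k + 1) * t / 10.0)
                      for k in range(weights.shape[1])])
    return config.fingerprint_amplitude * weights @ basis


def _assign_classes(config: SimConfig, phase: str,
                    rng: np.random.Generator) -> list[str]:
    """Deterministic per-phase class assignment honoring exact fractions."""
    fracs = config.class_fractions.get(phase, {})
    n = config.n_neurons
    labels = ["unresponsive"] * n
    order = rng.permutation(n)
    start = 0
    for cls in CLASSES[:-1]:
        k = int(round(fracs.get(cls, 0.0) * n))
        for idx in order[start:start + k]:
            labels[idx] = cls
        start += k
    return labels


def build_events(config: SimConfig, phase: str) -> pd.DataFrame:
    """Event table for one phase of the standard SOC schedule."""
    if phase not in config.phases:
        raise ValueError(f"unknown phase {phase!r}; known: {sorted(config.phases)}")
    spec = config.phases[phase]
    rows = []
    t = config.lead_in_s
    cue = spec.cue_duration_s
    if phase == "habituation":
        # interleaved light/tone presentations in seeded random order
        order = []
        for label, k in spec.n_trials.items():
            order += [label] * k
        rng = np.random.default_rng(config.seed + 1)
        rng.shuffle(order)
        counters = {label: 0 for label in spec.n_trials}
        for label in order:
            rows.append((label, t, cue, phase, counters[label]))
            counters[label] += 1
            t += cue + spec.iti_s
    elif phase == "CS1-US":
        for i in range(spec.n_trials.get("CS1", 0)):
            rows.append(("CS1", t, cue, phase, i))
            # shock co-terminates with the light cue
            rows.append(("US", t + cue - spec.us_duration_s,
                         spec.us_duration_s, phase, i))
            t += cue + spec.iti_s
    elif phase == "CS2-CS1":
        for i in range(spec.n_trials.get("CS2", 0)):
            rows.append(("CS2", t, cue, phase, i))
            rows.append(("CS1", t + cue + spec.cs2_cs1_gap_s, cue, phase, i))
            t += 2 * cue + spec.cs2_cs1_gap_s + spec.iti_s
    elif phase == "test":
        for i in range(spec.n_trials.get("CS2", 0)):
            rows.append(("CS2", t, cue, phase, i))
            t += cue + spec.iti_s
    else:
        for label, k in spec.n_trials.items():
            for i in range(k):
                rows.append((label, t, cue, phase, i))
                t += cue + spec.iti_s
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return validate_events(events)


def _session_length_s(config: SimConfig, events: pd.DataFrame) -> float:
    tail = 30.0  # room for the post-cue analysis window after the last event
    return float((events["onset_s"] + events["duration_s"]).max() + tail)


def simulate_session(config: SimConfig, phase: str, replicate: int = 0
                     ) -> tuple[TraceMatrix, pd.DataFrame, SimGroundTruth]:
    """Simulate fluorescence and events for one phase.

    The trace is ``baseline * (1 + drift + signal + noise)`` where ``signal``
    is the kernel-convolved, event-locked drive of the neuron's planted
    class (in ΔF/F units). The same config (including seed) reproduces the
    output bit for bit. ``replicate`` re-records the same phase — identical
    planted classes, fresh noise, dropout and centroid jitter — for
    validating cross-session matching against a known correspondence.
    """
    events = build_events(config, phase)
    (ids, gains, latencies, centroids, drift_phases,
     fp_weights) = _neuron_properties(config)
    phase_idx = list(config.phases).index(phase)
    class_rng = np.random.default_rng((config.seed, 200 + phase_idx))
    classes = _assign_classes(config, phase, class_rng)
    rng = np.random.default_rng((config.seed, 100 + phase_idx, replicate))

    fs = config.sampling_rate_hz
    n_samp = int(round(_session_length_s(config, events) * fs))
    times = np.arange(n_samp) / fs
    kernel = config.kernel.sample(fs)
    box_norm = kernel.sum()  # boxcar drive scaling so plateau ~= amplitude
    fingerprints = _fingerprints(config, fp_weights)
    cue_onsets = events.loc[events["event_label"].isin(("CS1", "CS2")),
                            "onset_s"].to_numpy()

    values = np.empty((config.n_neurons, n_samp))
    for i in range(config.n_neurons):
        cls = classes[i]
        drive = np.zeros(n_samp)
        if cls != "unresponsive":
            label = _DRIVER[cls]
            sign = 1.0
            for _, ev in events[events["event_label"] == label].iterrows():
                onset = ev["onset_s"] + latencies[i]
                j0 = int(np.ceil(onset * fs - 1e-9))
                if cls in ("sustained_post_cs", "inhibited"):
                    # boxcar drive over the cue (sustained: +10 s past offset)
                    extent = ev["duration_s"] + (10.0 if cls == "sustained_post_cs" else 0.0)
                    j1 = min(n_samp, int(np.ceil((onset + extent) * fs - 1e-9)))
                    if j0 < n_samp:
                        amp = gains[i] / box_norm
                        drive[j0:j1] += -0.5 * amp if cls == "inhibited" else amp
                else:
                    if j0 < n_samp:
                        drive[j0] += gains[i]
        if np.any(drive):
            signal = fftconvolve(drive, kernel)[:n_samp]
        else:
            signal = np.zeros(n_samp)
        if config.fingerprint_amplitude > 0:
            m = fingerprints.shape[1]
            for onset in cue_onsets:
                j0 = int(np.ceil(onset * fs - 1e-9))
                j1 = min(n_samp, j0 + m)
                if j0 < n_samp:
                    signal[j0:j1] += fingerprints[i, :j1 - j0]
        drift = 0.5 * config.drift_amplitude * (
            np.sin(2 * np.pi * times / config.drift_period_s + drift_phases[i])
            + 2.0 * (times / times[-1] - 0.5) * (1 if i % 2 else -1)
        )
        noise = rng.normal(0.0, config.noise_sd, n_samp) if config.noise_sd > 0 \
            else np.zeros(n_samp)
        values[i] = config.baseline_f * (1.0 + drift + signal + noise)

    # session dropout + per-session centroid jitter (longitudinal realism)
    keep = np.ones(config.n_neurons, dtype=bool)
    if config.dropout > 0:
        keep = rng.uniform(size=config.n_neurons) >= config.dropout
        if not keep.any():
            keep[0] = True
    jitter = rng.normal(0.0, config.centroid_jitter,
                        size=(config.n_neurons, 2)) \
        if config.centroid_jitter > 0 else np.zeros((config.n_neurons, 2))

    kept_ids = [ids[i] for i in range(config.n_neurons) if keep[i]]
    trace = TraceMatrix(
        neuron_ids=kept_ids,
        times=times,
        values=values[keep],
        sampling_rate_hz=fs,
        phase=phase,
    )
    truth = SimGroundTruth(
        phase=phase,
        classes={ids[i]: classes[i] for i in range(config.n_neurons)},
        gains={ids[i]: float(gains[i]) for i in range(config.n_neurons)},
        latencies={ids[i]: float(latencies[i]) for i in range(config.n_neurons)},
        centroids={ids[i]: (float(centroids[i, 0] + jitter[i, 0]),
                            float(centroids[i, 1] + jitter[i, 1]))
                   for i in range(config.n_neurons)},
        present=kept_ids,
        freeze_fractions=dict(config.freeze_fractions),
    )
    return trace, events, truth


def simulate_behavior(config: SimConfig, events: pd.DataFrame,
                      mouse_id: str = "m0") -> MotionTrace:
    """Two-state freeze/move motion series driven by the planted fractions.

    Behavior alternates freeze bouts (motion exactly zero) and move bouts
    (positive motion) as a renewal process; inside each cue window the
    stationary freeze probability equals the planted fraction for that
    event label, elsewhere the ``"baseline"`` fraction. A planted fraction
    of 1 (or 0) yields deterministic all-freeze (all-move) in the window.
    """
    validate_events(events)
    if events.empty:
        raise ValueError("event table is empty")
    for label, grp in events.groupby("event_label"):
        iv = grp.sort_values("onset_s")
        ends = (iv["onset_s"] + iv["duration_s"]).to_numpy()
        if np.any(iv["onset_s"].to_numpy()[1:] < ends[:-1]):
            raise ValueError(f"overlapping {label} windows")

    fs = config.sampling_rate_hz
    phase = str(events["phase"].iloc[0])
    n_samp = int(round(_session_length_s(config, events) * fs))
    times = np.arange(n_samp) / fs

    p_frame = np.full(n_samp, config.freeze_fractions.get("baseline", 0.0))
    for _, ev in events.iterrows():
        p = config.freeze_fractions.get(ev["event_label"])
        if p is None:
            continue
        j0 = int(np.ceil(ev["onset_s"] * fs - 1e-9))
        j1 = min(n_samp, int(np.ceil((ev["onset_s"] + ev["duration_s"]) * fs - 1e-9)))
        p_frame[j0:j1] = p

    mouse_key = zlib.crc32(mouse_id.encode()) % (2**31)
    rng = np.random.default_rng((config.seed, mouse_key, 7))
    frozen = np.zeros(n_samp, dtype=bool)
    mean_f = config.freeze_bout_mean_s
    # simulate each constant-probability segment from its stationary state;
    # exponential bouts are memoryless, so this is exactly unbiased
    boundaries = np.flatnonzero(np.diff(p_frame) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n_samp]))
    for j0, j1 in zip(starts, ends):
        p = p_frame[j0]
        if p >= 1.0:
            frozen[j0:j1] = True
            continue
        if p <= 0.0:
            continue
        j = j0
        state_frozen = bool(rng.uniform() < p)
        while j < j1:
            if state_frozen:
                bout_s = rng.exponential(mean_f)
            else:
                # move-bout mean chosen so stationary freeze fraction is p
                bout_s = rng.exponential(mean_f * (1.0 - p) / p)
            n_bout = max(1, int(round(bout_s * fs)))
            frozen[j:min(j + n_bout, j1)] = state_frozen
            j += n_bout
            state_frozen = not state_frozen

    motion = np.where(frozen, 0.0, 1.0 + np.abs(rng.normal(0.0, 0.3, n_samp)))
    return MotionTrace(times=times, motion=motion, mouse_id=mouse_id, phase=phase)


def simulate_experiment(config: SimConfig
                        ) -> dict[str, tuple[TraceMatrix, pd.DataFrame, SimGroundTruth]]:
    """Simulate every phase of the paradigm with consistent neuron identity."""
    return {phase: simulate_session(config, phase) for phase in config.phases}


def noiseless(config: SimConfig) -> SimConfig:
    """Copy of a config with noise, drift and dropout removed."""
    return replace(config, noise_sd=0.0, drift_amplitude=0.0, dropout=0.0,
                   centroid_jitter=0.0, fingerprint_amplitude=0.0)
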