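"""End-to-end orchestration: simulate -> normalize -> align -> classify ->
cluster -> track -> correlate -> behavior -> report.

A run is driven by one :class:`RunConfig` (loadable from a flat YAML file)
whose defaults pin the analysis constants: the >50% AUC-ratio
classification boundaries, K-means group number 5 with a 2..8 silhouette
scan, and the 0.5 longitudinal-registration acceptance threshold. Every
run writes per-stage CSVs, a resolved copy of its configuration and a JSON
report with record counts and a checksummed file manifest; the same config
and seed reproduce every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .behavior import freezing_percent, memory_strength, records_table
from .classification import (classification_table, classify_population,
                             encode_overlap, summarize)
from .clustering import (centroids_table, cluster_traces, labels_table,
                         select_k, silhouette_table)
from .core import WindowSpec, write_events
from .correlation import StateWindowSet, compare_states, comparison_table
from .longitudinal import (SessionFeatures, TrackingResult, match_sessions,
                           track_categories)
from .peri_event import align, auc, auc_table, trial_average
from .preprocessing import delta_f_over_f, z_score
from .synthetic import SimConfig, simulate_behavior, simulate_session

log = logging.getLogger("soc_calcium")

#: Cue analyzed per phase for classification and tracking.
PHASE_CUE = {"habituation": "CS2", "CS1-US": "CS1", "CS2-CS1": "CS2",
             "test": "CS2"}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    outdir: str = "soc_run"
    seed: int = 0
    n_neurons: int = 100
    pre_s: float = 10.0
    post_s: float = 20.0
    k: int = 5
    k_min: int = 2
    k_max: int = 8
    registration_threshold: float = 0.5
    freeze_threshold: float = 0.5
    min_bout_s: float = 1.0
    sim: dict = field(default_factory=dict)  # extra SimConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def sim_config(self) -> SimConfig:
        return SimConfig(n_neurons=self.n_neurons, seed=self.seed, **self.sim)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the full analysis on a simulated experiment; return the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_resolved.yaml")
    window = WindowSpec(config.pre_s, config.post_s)
    sim = config.sim_config()
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    def stage(name: str, **info):
        log.info("stage %s: %s", name, info)
        report["stages"][name] = info

    # --- simulate + normalize -------------------------------------------
    sessions = {}
    for phase in sim.phases:
        trace, events, truth = simulate_session(sim, phase)
        dff = delta_f_over_f(trace)
        tag = phase.replace("-", "_").lower()
        trace.to_csv(outdir / f"traces_raw_{tag}.csv")
        dff.to_csv(outdir / f"traces_dff_{tag}.csv")
        write_events(events, outdir / f"events_{tag}.csv")
        sessions[phase] = (dff, events, truth)
        stage(f"simulate[{phase}]", n_neurons=trace.n_neurons,
              n_events=len(events), status="ok")

    # --- align, AUC, classify -------------------------------------------
    class_by_phase = {}
    tensors = {}
    for phase, (dff, events, _) in sessions.items():
        label = PHASE_CUE[phase]
        tensor = align(dff, events, label, window)
        tensors[phase] = tensor
        records = auc(tensor)
        cls = classify_population(records)
        class_by_phase[phase] = cls
        tag = phase.replace("-", "_").lower()
        auc_table(records).to_csv(outdir / f"auc_{tag}.csv", index=False)
        classification_table(cls).to_csv(
            outdir / f"classification_{tag}.csv", index=False)
        summary = summarize(cls, phase=phase)
        stage(f"classify[{phase}]", event_label=label,
              n_neurons=len(cls), excluded_trials=len(tensor.excluded_trials),
              counts=summary.counts, percentages=summary.percentages,
              status="ok")

    # CS1 vs CS2 overlap on the CS2-CS1 pairing session
    dff_p, events_p, _ = sessions["CS2-CS1"]
    cls_cs1 = classify_population(auc(align(dff_p, events_p, "CS1", window)))
    overlap = encode_overlap(
        {"CS1": cls_cs1, "CS2": class_by_phase["CS2-CS1"]})
    overlap.to_csv(outdir / "overlap_cs1_cs2.csv", index=False)
    stage("overlap", cells={r["partition"]: int(r["count"])
                            for _, r in overlap.iterrows()}, status="ok")

    # --- clustering on test-phase z-scored responses --------------------
    dff_t, events_t, _ = sessions["test"]
    ztensor = z_score(dff_t, events_t, "CS2", window)
    result = cluster_traces(ztensor, k=config.k, seed=config.seed)
    scan = select_k(ztensor, range(config.k_min, config.k_max + 1),
                    seed=config.seed)
    labels_table(result).to_csv(outdir / "clusters_test.csv", index=False)
    centroids_table(result).to_csv(outdir / "cluster_centroids_test.csv",
                                   index=False)
    silhouette_table(scan).to_csv(outdir / "silhouette_test.csv", index=False)
    stage("cluster", k=result.k, sizes=result.sizes,
          percentages=result.percentages, selected_k=scan.k,
          silhouette=result.silhouette, status="ok")

    # --- longitudinal tracking (shock day excluded) ---------------------
    features = {}
    for phase in ("habituation", "CS2-CS1", "test"):
        dff, _, truth = sessions[phase]
        avg = trial_average(tensors[phase])
        features[phase] = SessionFeatures(
            session_id=phase,
            neuron_ids=list(dff.neuron_ids),
            traces=avg,
            centroids=np.array([truth.centroids[n] for n in dff.neuron_ids]),
        )
    maps = [
        match_sessions(features["habituation"], features["CS2-CS1"],
                       threshold=config.registration_threshold),
        match_sessions(features["CS2-CS1"], features["test"],
                       threshold=config.registration_threshold),
    ]
    for m in maps:
        m.to_table().to_csv(
            outdir / f"registration_{m.session_a.replace('-', '_').lower()}"
                     f"__{m.session_b.replace('-', '_').lower()}.csv",
            index=False)
    tracking: TrackingResult = track_categories(maps, class_by_phase)
    tracking.transition.to_csv(outdir / "transition_matrix.csv")
    tracking.group_auc.to_csv(outdir / "group_auc_by_habituation.csv",
                              index=False)
    stage("track", n_tracked=tracking.n_tracked, n_dropped=tracking.n_dropped,
          status="ok")

    # --- state correlations on the test session -------------------------
    baseline = StateWindowSet("baseline", [(0.0, sim.lead_in_s)])
    tone = StateWindowSet.from_events(events_t, "CS2", "tone")
    comp = compare_states(dff_t, baseline, tone)
    comparison_table(comp).to_csv(outdir / "correlation_comparison.csv",
                                  index=False)
    stage("correlate", cohens_d=comp.d, n=comp.n_a, status="ok")

    # --- behavior -------------------------------------------------------
    freezing = []
    for phase in ("CS2-CS1", "test"):
        _, events, _ = sessions[phase]
        motion = simulate_behavior(sim, events)
        motion.to_csv(outdir / f"motion_{phase.replace('-', '_').lower()}.csv")
        freezing += freezing_percent(motion, events,
                                     threshold=config.freeze_threshold,
                                     min_bout_s=config.min_bout_s)
    records_table(freezing).to_csv(outdir / "freezing.csv", index=False)
    strengths, group = memory_strength(freezing)
    stage("behavior", n_records=len(freezing),
          memory_strength=group, status="ok")

    # --- manifest + report ----------------------------------------------
    manifest = {p.name: _sha256(p) for p in sorted(outdir.glob("*.csv"))}
    report["manifest"] = manifest
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return report


def _jsonable(obj):
    """Plain-JSON form: numpy scalars to Python, NaN to null."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, int)) and not isinstance(obj, bool):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    return obj
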