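"""Cross-session matching score/threshold behavior and category tracking."""

import numpy as np
import pytest

from soc_calcium.classification import ResponseClassification
from soc_calcium.core import WindowSpec
from soc_calcium.longitudinal import (
    RegistrationMap,
    SessionFeatures,
    match_sessions,
    track_categories,
)
from soc_calcium.peri_event import align, trial_average
from soc_calcium.preprocessing import delta_f_over_f
from soc_calcium.synthetic import SimConfig, simulate_session


def features(sid, traces, centroids=None):
    return SessionFeatures(sid, [f"n{i}" for i in range(len(traces))],
                           np.asarray(traces, dtype=float),
                           centroids=centroids)


class TestMatchSessions:
    def test_identical_features_identity_match_score_one(self, rng):
        traces = rng.normal(size=(6, 80))
        cents = rng.uniform(0, 50, size=(6, 2))
        reg = match_sessions(features("a", traces, cents),
                             features("b", traces, cents))
        assert reg.as_dict() == {f"n{i}": f"n{i}" for i in range(6)}
        assert all(s == pytest.approx(1.0) for _, _, s in reg.pairs)

    def test_correlation_point_four_rejected_by_threshold(self, rng):
        """Pairs correlating at exactly 0.4 fall below the 0.5 minimum."""
        x = rng.normal(size=80)
        x = (x - x.mean()) / x.std()
        z = rng.normal(size=80)
        z -= z.mean() + 0.0
        z -= x * (x @ z) / (x @ x)          # orthogonalize
        z /= z.std()
        y = 0.4 * x + np.sqrt(1 - 0.16) * z
        reg = match_sessions(features("a", [x]), features("b", [y]))
        assert reg.pairs == []
        assert reg.unmatched_a == ["n0"]

    def test_dropout_and_jitter_recovery(self):
        """>=95% of true correspondences recovered at threshold 0.5."""
        cfg = SimConfig(n_neurons=100, seed=2)
        feats, present = {}, {}
        for rep in (0, 1):
            trace, events, truth = simulate_session(cfg, "test", replicate=rep)
            dff = delta_f_over_f(trace)
            tensor = align(dff, events, "CS2", WindowSpec(10.0, 20.0))
            feats[rep] = SessionFeatures(
                f"r{rep}", list(trace.neuron_ids), trial_average(tensor),
                centroids=np.array([truth.centroids[n]
                                    for n in trace.neuron_ids]))
            present[rep] = set(trace.neuron_ids)
        true_pairs = present[0] & present[1]
        assert len(true_pairs) < 100  # dropout actually removed neurons
        reg = match_sessions(feats[0], feats[1])
        correct = sum(a == b for a, b, _ in reg.pairs)
        assert correct / len(true_pairs) >= 0.95

    def test_symmetry(self, rng):
        ta = rng.normal(size=(7, 60))
        tb = ta[::-1] + rng.normal(0, 0.3, size=(7, 60))
        ca = rng.uniform(0, 30, size=(7, 2))
        cb = ca[::-1] + rng.normal(0, 0.2, size=(7, 2))
        ab = match_sessions(features("a", ta, ca), features("b", tb, cb))
        ba = match_sessions(features("b", tb, cb), features("a", ta, ca))
        assert {(a, b) for a, b, _ in ab.pairs} == \
            {(b, a) for a, b, _ in ba.pairs}

    def test_optimal_assignment_agrees_on_easy_problem(self, rng):
        traces = rng.normal(size=(5, 60))
        cents = rng.uniform(0, 40, size=(5, 2))
        greedy = match_sessions(features("a", traces, cents),
                                features("b", traces, cents))
        optimal = match_sessions(features("a", traces, cents),
                                 features("b", traces, cents), optimal=True)
        assert greedy.as_dict() == optimal.as_dict()

    def test_empty_session_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SessionFeatures("a", [], np.empty((0, 10)))


def _cls(mapping, label="CS2"):
    return [ResponseClassification(n, label, cat, 1.0, 2.0, 2.0)
            for n, cat in mapping.items()]


def _identity_maps(ids, phases=("habituation", "CS2-CS1", "test")):
    return [RegistrationMap(a, b, [(n, n, 1.0) for n in ids])
            for a, b in zip(phases, phases[1:])]


class TestTrackCategories:
    def test_identity_classifications_give_diagonal_transition(self):
        ids = [f"n{i}" for i in range(9)]
        cats = {n: ("increased" if i % 3 == 0 else "no_change")
                for i, n in enumerate(ids)}
        result = track_categories(
            _identity_maps(ids),
            {ph: _cls(cats) for ph in ("habituation", "CS2-CS1", "test")})
        t = result.transition
        assert t.values.sum() == 9
        assert np.all(t.values == np.diag(np.diag(t.values)))

    def test_transition_marginals_match_phase_counts(self, rng):
        ids = [f"n{i}" for i in range(30)]
        cats = ["increased", "no_change", "decreased"]
        phases = ("habituation", "CS2-CS1", "test")
        cls = {ph: _cls({n: rng.choice(cats) for n in ids}) for ph in phases}
        result = track_categories(_identity_maps(ids), cls)
        for cat in cats:
            hab = sum(1 for c in cls["habituation"] if c.category == cat)
            tst = sum(1 for c in cls["test"] if c.category == cat)
            assert result.transition.loc[cat].sum() == hab
            assert result.transition[cat].sum() == tst

    def test_planted_class_flip_lands_off_diagonal(self):
        ids = [f"n{i}" for i in range(10)]
        hab = {n: "no_change" for n in ids}
        test = {n: "increased" for n in ids}  # every neuron became responsive
        result = track_categories(
            _identity_maps(ids),
            {"habituation": _cls(hab), "CS2-CS1": _cls(hab),
             "test": _cls(test)})
        assert result.transition.loc["no_change", "increased"] == 10
        assert np.trace(result.transition.values) == 0

    def test_tracked_fraction_printed_convention(self):
        """76 of 122 tracked neurons in the no-change group prints as 62.3%."""
        ids = [f"n{i}" for i in range(122)]
        hab = {n: ("no_change" if i < 76 else "increased")
               for i, n in enumerate(ids)}
        result = track_categories(
            _identity_maps(ids),
            {ph: _cls(hab) for ph in ("habituation", "CS2-CS1", "test")})
        row = result.group_auc.set_index("habituation_category")
        assert row.loc["no_change", "n"] == 76
        assert row.loc["no_change", "pct"] == 62.3

    def test_partial_chain_drops_and_counts(self):
        ids = [f"n{i}" for i in range(5)]
        maps = _identity_maps(ids)
        maps[1] = RegistrationMap("CS2-CS1", "test",
                                  [(n, n, 1.0) for n in ids[:3]])
        cats = {n: "no_change" for n in ids}
        result = track_categories(
            maps, {ph: _cls(cats) for ph in ("habituation", "CS2-CS1", "test")})
        assert result.n_tracked == 3
        assert result.n_dropped == 2

    def test_missing_phase_classifications_rejected(self):
        ids = ["n0"]
        with pytest.raises(ValueError, match="test"):
            track_categories(_identity_maps(ids),
                             {"habituation": _cls({"n0": "no_change"}),
                              "CS2-CS1": _cls({"n0": "no_change"})})
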