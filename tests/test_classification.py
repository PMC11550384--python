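"""The >50% AUC-ratio rule, printed-percentage formatting, overlap partition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soc_calcium.classification import (
    ResponseClassification,
    classify,
    classify_population,
    encode_overlap,
    format_percent,
    summarize,
)
from soc_calcium.core import WindowSpec
from soc_calcium.peri_event import AUCRecord, align, auc
from soc_calcium.preprocessing import delta_f_over_f
from soc_calcium.synthetic import SimConfig, noiseless, simulate_session


def record(pre, post, nid="n0"):
    return AUCRecord(nid, "CS2", pre, post, 0.0)


class TestRatioRule:
    @pytest.mark.parametrize("pre,post,expected", [
        (1.0, 1.6, "increased"),     # >50% increase
        (1.0, 1.51, "increased"),
        (1.0, 1.5, "no_change"),     # boundary is strict
        (1.0, 0.5, "no_change"),
        (1.0, 0.4, "decreased"),     # >50% decrease
        (2.0, 2.9, "no_change"),
        (0.2, 0.5, "increased"),
    ])
    def test_rule_table(self, pre, post, expected):
        assert classify(record(pre, post)).category == expected

    @pytest.mark.parametrize("scale", [0.25, 1.0, 4.0, 100.0])
    def test_scale_invariance_of_ratio_path(self, scale):
        """Rescaling both AUCs leaves the category unchanged (pre above eps)."""
        for pre, post in [(1.0, 1.7), (1.0, 1.2), (1.0, 0.3)]:
            base = classify(record(pre, post)).category
            assert classify(record(scale * pre, scale * post)).category == base

    def test_isolated_near_zero_pre_is_degenerate(self):
        assert classify(record(0.001, 5.0)).category == "degenerate"
        assert classify(record(-2.0, 5.0)).category == "degenerate"

    def test_difference_fallback_with_population_scale(self):
        assert classify(record(0.0, 2.0), diff_scale=1.0).category == "increased"
        assert classify(record(0.0, -2.0), diff_scale=1.0).category == "decreased"
        assert classify(record(0.0, 0.2), diff_scale=1.0).category == "no_change"

    def test_nonfinite_auc_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            classify(record(np.nan, 1.0))


class TestSummarize:
    @pytest.mark.parametrize("count,total,expected", [
        (53, 122, 43.4),   # second-order memory recall responders
        (25, 53, 47.2),    # of those, also first-order responders
        (76, 122, 62.3),   # initially unresponsive tracked neurons
        (0, 57, 0.0),
        (1, 400, 0.3),     # 0.25 rounds half UP to 0.3, not half-even to 0.2
    ])
    def test_printed_percent_convention(self, count, total, expected):
        assert format_percent(count, total) == expected

    def test_counts_and_percentages(self):
        cls = [ResponseClassification(f"n{i}", "CS2",
                                      "increased" if i < 53 else "no_change",
                                      1.0, 2.0, 2.0)
               for i in range(122)]
        summary = summarize(cls)
        assert summary.counts["increased"] == 53
        assert summary.percentages["increased"] == 43.4
        assert sum(summary.counts.values()) == summary.n_total == 122

    def test_duplicate_neuron_rejected(self):
        cls = [ResponseClassification("n0", "CS2", "increased", 1, 2, 2)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            summarize(cls)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 500), n=st.integers(2, 60))
    def test_categories_partition_population(self, seed, n):
        g = np.random.default_rng(seed)
        records = [record(g.normal(), g.normal(), nid=f"n{i}")
                   for i in range(n)]
        summary = summarize(classify_population(records))
        assert sum(summary.counts.values()) == n


class TestOverlap:
    def make(self, ids_a, ids_b, universe):
        def cls(responders, label):
            return [ResponseClassification(
                n, label, "increased" if n in responders else "no_change",
                1.0, 1.0, 1.0) for n in universe]
        return {"CS1": cls(ids_a, "CS1"), "CS2": cls(ids_b, "CS2")}

    def test_disjoint_responders_no_both(self):
        universe = [f"n{i}" for i in range(10)]
        table = self.make({"n0", "n1"}, {"n2", "n3"}, universe)
        df = encode_overlap(table).set_index("partition")
        assert df.loc["both", "count"] == 0
        assert df.loc["CS1_only", "count"] == 2
        assert df.loc["CS2_only", "count"] == 2
        assert df.loc["neither", "count"] == 6

    def test_identical_responders_all_both(self):
        universe = [f"n{i}" for i in range(8)]
        df = encode_overlap(self.make({"n0", "n1"}, {"n0", "n1"}, universe))
        df = df.set_index("partition")
        assert df.loc["both", "count"] == 2
        assert df.loc["CS1_only", "count"] == df.loc["CS2_only", "count"] == 0

    def test_partition_sums_to_universe(self, rng):
        universe = [f"n{i}" for i in range(40)]
        a = set(rng.choice(universe, 12, replace=False))
        b = set(rng.choice(universe, 17, replace=False))
        df = encode_overlap(self.make(a, b, universe))
        assert df["count"].sum() == 40

    def test_mismatched_universe_rejected(self):
        table = self.make(set(), set(), ["n0", "n1"])
        table["CS2"] = table["CS2"][:1]
        with pytest.raises(ValueError, match="universe"):
            encode_overlap(table)


class TestRecoveryFromSimulation:
    FRACS = {"test": {"cs2_responsive": 0.40, "inhibited": 0.10}}
    EXPECT = {"cs2_responsive": "increased", "inhibited": "decreased",
              "unresponsive": "no_change", "sustained_post_cs": "increased"}

    def classify_sim(self, cfg):
        trace, events, truth = simulate_session(cfg, "test")
        dff = delta_f_over_f(trace)
        tensor = align(dff, events, "CS2", WindowSpec(10.0, 20.0))
        cls = classify_population(auc(tensor))
        return cls, truth

    def test_noiseless_plant_recovered_exactly(self):
        cfg = noiseless(SimConfig(n_neurons=50, class_fractions=self.FRACS,
                                  seed=11))
        cls, truth = self.classify_sim(cfg)
        for c in cls:
            assert c.category == self.EXPECT[truth.classes[c.neuron_id]]

    def test_snr5_agreement_at_least_90pct(self):
        cfg = SimConfig(n_neurons=100, class_fractions=self.FRACS, seed=11,
                        dropout=0.0)
        cls, truth = self.classify_sim(cfg)
        agree = np.mean([c.category == self.EXPECT[truth.classes[c.neuron_id]]
                         for c in cls])
        assert agree >= 0.90
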