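"""Gate primitives: bead calibration, doublet discrimination, control
thresholds, hierarchy evaluation and population summaries."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sputumflow as sf
from sputumflow.fcs_io import TRUTH_CHANNEL
from sputumflow.gating import Gate, GateNode
from sputumflow.synthetic import TRUTH_DOUBLET


@pytest.fixture(scope="module")
def beads():
    return sf.generate_bead_run([5.0, 20.0, 30.0], np.random.default_rng(0))


class TestSizeGateFromBeads:
    def test_brackets_middle_cluster(self, beads):
        gate = sf.size_gate_from_beads(beads, [5, 20, 30])
        fsc = beads.channel("FSC-A")
        mid = fsc[(fsc > 90_000) & (fsc < 150_000)]  # the 20 um cluster
        assert len(mid) > 1000
        assert np.all(mid >= gate.bounds[0]) and np.all(mid < gate.bounds[1])

    def test_excludes_events_below_small_bead_bound(self, beads):
        gate = sf.size_gate_from_beads(beads, [5, 20, 30])
        t = sf.EventTable(
            np.array([[gate.bounds[0] - 1.0, 1000.0], [gate.bounds[0], 1000.0]]),
            ["FSC-A", "SSC-A"],
        )
        assert list(gate.membership(t)) == [False, True]

    def test_translation_equivariance(self, beads):
        gate = sf.size_gate_from_beads(beads, [5, 20, 30])
        shifted = beads.copy()
        k = 5000.0
        shifted.values[:, 0] += k
        gate2 = sf.size_gate_from_beads(shifted, [5, 20, 30])
        assert gate2.bounds[0] == pytest.approx(gate.bounds[0] + k, rel=1e-6)
        assert gate2.bounds[1] == pytest.approx(gate.bounds[1] + k, rel=1e-6)

    def test_missing_required_cluster(self, beads):
        with pytest.raises(sf.CalibrationError):
            sf.size_gate_from_beads(
                sf.generate_bead_run([5.0, 20.0], np.random.default_rng(1)),
                [5, 20], lo_um=5, hi_um=30,
            )

    def test_indistinct_clusters_rejected(self):
        rng = np.random.default_rng(2)
        smeared = sf.generate_bead_run([20.0, 21.0], rng, cv=0.2)
        with pytest.raises(sf.CalibrationError):
            sf.size_gate_from_beads(smeared, [20.0, 21.0], lo_um=20.0, hi_um=21.0)


class TestDoubletGate:
    def test_pure_singlets_retained(self):
        params = dataclasses.replace(sf.default_sample_params(), doublet_rate=0.0)
        cfg = sf.build_sample_config(params, "S", n_events=10_000, seed=3)
        t = sf.generate_sample(cfg).leukocyte
        gate = sf.doublet_gate(t)
        assert gate.membership(t).mean() >= 0.99

    def test_injected_doublets_removed(self):
        params = dataclasses.replace(sf.default_sample_params(), doublet_rate=0.1)
        cfg = sf.build_sample_config(params, "S", n_events=20_000, seed=4)
        t = sf.generate_sample(cfg).leukocyte
        gate = sf.doublet_gate(t)
        kept = gate.membership(t)
        is_doublet = t.channel(TRUTH_CHANNEL) == TRUTH_DOUBLET
        assert (~kept[is_doublet]).mean() >= 0.90
        assert kept[~is_doublet].mean() >= 0.99

    def test_identical_events_all_retained(self):
        t = sf.EventTable(np.tile([50_000.0, 47_500.0], (60, 1)), ["FSC-A", "FSC-H"])
        gate = sf.doublet_gate(t)
        assert gate.membership(t).all()

    def test_too_few_events(self):
        t = sf.EventTable(np.ones((10, 2)), ["FSC-A", "FSC-H"])
        with pytest.raises(sf.InsufficientEventsError):
            sf.doublet_gate(t)


class TestThresholdFromControl:
    def test_median_quantile(self):
        x = np.random.default_rng(0).normal(10, 2, 5000)
        thr = sf.threshold_from_control(x, q=0.5)
        assert thr == pytest.approx(np.median(x))

    def test_expected_background_count_at_default_quantile(self):
        # at q = 0.9995 about 0.05% of the control's own events sit above
        x = np.random.default_rng(1).lognormal(4.1, 0.5, 100_000)
        thr = sf.threshold_from_control(x)
        above = (x > thr).sum()
        assert abs(above - 50) <= 4 * math.sqrt(50)

    def test_separated_population_called_positive(self):
        rng = np.random.default_rng(2)
        baseline = rng.lognormal(4.1, 0.5, 50_000)
        thr = sf.threshold_from_control(baseline)
        stained = rng.lognormal(4.1 + 5.0, 0.5, 10_000)
        assert (stained >= thr).mean() >= 0.99

    def test_too_few_events(self):
        with pytest.raises(sf.InsufficientEventsError):
            sf.threshold_from_control(np.ones(10), q=0.5)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        q1=st.floats(0.0, 1.0, allow_nan=False),
        q2=st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_monotone_in_quantile(self, q1, q2):
        x = np.random.default_rng(3).normal(0, 1, 2000)
        lo, hi = sorted([q1, q2])
        assert sf.threshold_from_control(x, q=lo) <= sf.threshold_from_control(x, q=hi)


def _brute_force_membership(values, names, nodes):
    """Independent per-event reimplementation of hierarchy evaluation."""
    idx = {n: i for i, n in enumerate(names)}
    member = {"root": [True] * len(values)}
    for node in nodes:
        g = node.gate
        out = []
        for row, parent_ok in zip(values, member[node.parent]):
            if g.kind == "rectangle":
                x, y = row[idx[g.channels[0]]], row[idx[g.channels[1]]]
                ok = g.bounds[0] <= x < g.bounds[1] and g.bounds[2] <= y < g.bounds[3]
            elif g.kind == "threshold_above":
                ok = row[idx[g.channels[0]]] >= g.bounds[0]
            elif g.kind == "threshold_below":
                ok = row[idx[g.channels[0]]] < g.bounds[0]
            elif g.kind == "interval":
                ok = g.bounds[0] <= row[idx[g.channels[0]]] < g.bounds[1]
            else:
                r = row[idx[g.channels[0]]] / row[idx[g.channels[1]]]
                ok = g.bounds[0] <= r < g.bounds[1]
            out.append(ok and parent_ok)
        member[node.name] = out
    return member


@pytest.fixture(scope="module")
def small_tree():
    rng = np.random.default_rng(7)
    values = rng.uniform(0, 10, size=(20, 3))
    t = sf.EventTable(values, ["a", "b", "c"])
    nodes = [
        GateNode("big_a", Gate("threshold_above", ("a",), (5.0,)), "root"),
        GateNode("mid_b", Gate("interval", ("b",), (2.0, 8.0)), "big_a"),
        GateNode("box", Gate("rectangle", ("b", "c"), (1.0, 9.0, 0.0, 5.0)), "big_a"),
        GateNode("low_c", Gate("threshold_below", ("c",), (5.0,)), "root"),
    ]
    return t, nodes


class TestEvaluateHierarchy:
    def test_matches_brute_force_oracle(self, small_tree):
        t, nodes = small_tree
        res = sf.evaluate_hierarchy(t, nodes)
        expected = _brute_force_membership(t.values, t.channel_names, nodes)
        for name, exp in expected.items():
            assert list(res.membership(name)) == exp

    def test_root_covers_all(self, small_tree):
        t, nodes = small_tree
        res = sf.evaluate_hierarchy(t, nodes)
        assert res.count("root") == t.n_events

    def test_exclusive_siblings_disjoint_and_conserved(self):
        t = sf.EventTable(np.random.default_rng(1).uniform(0, 10, (100, 1)), ["a"])
        nodes = [
            GateNode("lo", Gate("threshold_below", ("a",), (4.0,)), "root"),
            GateNode("hi", Gate("threshold_above", ("a",), (4.0,)), "root"),
        ]
        res = sf.evaluate_hierarchy(t, nodes)
        assert not np.any(res.membership("lo") & res.membership("hi"))
        assert res.count("lo") + res.count("hi") == res.count("root")

    def test_child_subset_of_parent(self, small_tree):
        t, nodes = small_tree
        res = sf.evaluate_hierarchy(t, nodes)
        for node in nodes:
            child = res.membership(node.name)
            parent = res.membership(node.parent)
            assert not np.any(child & ~parent)

    def test_membership_invariant_under_reordering(self, small_tree):
        t, nodes = small_tree
        perm = np.random.default_rng(0).permutation(t.n_events)
        res = sf.evaluate_hierarchy(t, nodes)
        res_p = sf.evaluate_hierarchy(t.subset(perm), nodes)
        for name in res.counts:
            assert res.count(name) == res_p.count(name)
            assert np.array_equal(res.membership(name)[perm], res_p.membership(name))

    def test_dangling_parent(self, small_tree):
        t, _ = small_tree
        nodes = [GateNode("x", Gate("threshold_above", ("a",), (1.0,)), "ghost")]
        with pytest.raises(sf.GateTreeError):
            sf.evaluate_hierarchy(t, nodes)

    def test_missing_channel(self, small_tree):
        t, _ = small_tree
        nodes = [GateNode("x", Gate("threshold_above", ("zz",), (1.0,)), "root")]
        with pytest.raises(sf.GateTreeError):
            sf.evaluate_hierarchy(t, nodes)


@pytest.fixture(scope="module")
def result():
    t = sf.EventTable(np.column_stack([np.arange(100_000, dtype=float)]), ["x"])
    nodes = [
        GateNode("all_x", Gate("threshold_above", ("x",), (0.0,)), "root"),
        GateNode("six", Gate("interval", ("x",), (0.0, 6.0)), "all_x"),
    ]
    return sf.evaluate_hierarchy(t, nodes)


class TestSummaries:
    def test_node_equals_denominator(self, result):
        assert sf.population_frequency(result, "all_x", "all_x") == 100.0

    def test_macrophage_scale_arithmetic(self, result):
        # 6 events among 100,000 live singles is 0.006%
        assert sf.population_frequency(result, "six", "all_x") == pytest.approx(0.006)

    def test_non_descendant_rejected(self, result):
        with pytest.raises(sf.GateTreeError):
            sf.population_frequency(result, "all_x", "six")

    def test_truth_fraction_within_binomial_ci(self):
        params = sf.default_sample_params()
        cfg = sf.build_sample_config(params, "S", n_events=20_000, seed=8)
        t = sf.generate_sample(cfg).leukocyte
        truth = t.channel(TRUTH_CHANNEL)
        sec_code = sf.synthetic.TRUTH_CODES["sec"]
        observed = (truth == sec_code).mean()
        p = params.sec_frac * (1 - params.doublet_rate)
        assert abs(observed - p) < 4 * math.sqrt(p * (1 - p) / 20_000)

    def test_mfi_simple_values(self):
        t = sf.EventTable(np.array([[100.0], [300.0]]), ["EpCAM"])
        assert sf.channel_mfi(t, np.array([True, True]), "EpCAM") == 200.0
        assert sf.channel_mfi(t, np.array([True, False]), "EpCAM") == 100.0
        assert math.isnan(sf.channel_mfi(t, np.array([False, False]), "EpCAM"))

    def test_mfi_lognormal_closed_form(self):
        mu, sigma, n = 8.0, 0.5, 200_000
        x = np.random.default_rng(9).lognormal(mu, sigma, n)
        t = sf.EventTable(x[:, None], ["EpCAM"])
        mean_true = math.exp(mu + sigma**2 / 2)
        se = mean_true * math.sqrt((math.exp(sigma**2) - 1) / n)
        got = sf.channel_mfi(t, np.ones(n, dtype=bool), "EpCAM")
        assert abs(got - mean_true) < 3 * se


class TestGateSerialization:
    def test_tree_roundtrip(self, tmp_path):
        nodes = [
            GateNode("size", Gate("rectangle", ("FSC-A", "SSC-A"), (1.0, 2.0, 0.0, 5.0))),
            GateNode("live", Gate("threshold_below", ("FVS510",), (1.5,)), "size"),
        ]
        path = tmp_path / "tree.tsv"
        sf.save_gate_tree(nodes, path)
        back = sf.load_gate_tree(path)
        assert back == nodes
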