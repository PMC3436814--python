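"""Bow-tie partition, composition, average degrees, permutation nulls, patterns."""

import numpy as np
import pytest

from tissuenet import (
    RegulatoryNetwork,
    average_degree,
    classify_pattern,
    composition,
    decompose,
    partition_genes,
    permutation_test,
    size_ratios,
)

from conftest import make_network


class TestPartition:
    def test_basic_set_algebra(self):
        core, cm_only, ts_only = partition_genes(
            [("A", "B", "C")], [("C", "D", "E")]
        )
        assert core == {"C"} and cm_only == {"A", "B"} and ts_only == {"D", "E"}

    def test_empty_ts_is_liver_case(self):
        core, cm_only, ts_only = partition_genes([("A", "B", "C")], [])
        assert core == set() and ts_only == set() and cm_only == {"A", "B", "C"}

    def test_identical_gene_sets_all_core(self):
        core, cm_only, ts_only = partition_genes(
            [("A", "B", "C")], [("B", "C", "A")]
        )
        assert core == {"A", "B", "C"} and not cm_only and not ts_only

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_set_operations(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        cm = [tuple(rng.choice(genes, 3, replace=False)) for _ in range(8)]
        ts = [tuple(rng.choice(genes, 3, replace=False)) for _ in range(8)]
        core, cm_only, ts_only = partition_genes(cm, ts)
        cm_g = set().union(*map(set, cm))
        ts_g = set().union(*map(set, ts))
        assert core == cm_g & ts_g
        assert cm_only == cm_g - ts_g and ts_only == ts_g - cm_g
        assert not (core & cm_only or core & ts_only or cm_only & ts_only)
        assert core | cm_only | ts_only == cm_g | ts_g


class TestComposition:
    def test_fractions(self):
        roles = {"a": "TF", "b": "TF", "c": "nonTF", "d": "miRNA"}
        df = composition({"s": ["a", "b", "c", "d"]}, roles)
        assert df.loc["s", "TF"] == 0.5
        assert df.loc["s", "miRNA"] == 0.25
        assert df.loc["s", "nonTF"] == 0.25
        assert df.loc["s", "defined"]

    def test_empty_set_flagged(self):
        df = composition({"s": []}, {})
        assert not df.loc["s", "defined"]
        assert df.loc["s", ["TF", "miRNA", "nonTF"]].sum() == 0.0

    def test_nonempty_rows_sum_to_one(self):
        roles = {"a": "TF", "b": "miRNA", "c": "nonTF"}
        df = composition({"x": ["a", "b"], "y": ["c"]}, roles)
        assert df.loc["x", ["TF", "miRNA", "nonTF"]].sum() == pytest.approx(1.0)
        assert df.loc["y", ["TF", "miRNA", "nonTF"]].sum() == pytest.approx(1.0)


class TestAverageDegree:
    def test_within_set(self):
        arcs = [("a", "b"), ("b", "c")]
        assert average_degree({"a", "b", "c"}, None, arcs) == pytest.approx(2 / 3)

    def test_between_sets(self):
        assert average_degree({"a", "b"}, {"c"}, [("a", "c")]) == pytest.approx(0.5)

    def test_no_touching_arcs_is_zero(self):
        assert average_degree({"a"}, {"b"}, [("x", "y")]) == 0.0

    def test_empty_source_errors(self):
        with pytest.raises(ValueError):
            average_degree(set(), {"a"}, [])

    def test_alternative_normalizations(self):
        arcs = [("a", "c"), ("b", "c")]
        assert average_degree({"a", "b"}, {"c", "d"}, arcs, norm="pair") == pytest.approx(
            2 / 4
        )
        assert average_degree({"a", "b"}, {"c", "d"}, arcs, norm="mean") == pytest.approx(
            2 / 2
        )


class TestSizeRatios:
    def test_simple(self):
        sr = size_ratios(core={"c"}, noncore_cm=set("ABCDEFG"), noncore_ts={"x", "y"})
        assert sr == (0.2, 0.1, 0.7)

    def test_no_ts_gives_pure_output(self):
        sr = size_ratios(core=set(), noncore_cm={"a", "b"}, noncore_ts=set())
        assert sr == (0.0, 0.0, 1.0)

    def test_kidney_like_input_share(self):
        core = {f"c{i}" for i in range(9)}
        out = {f"o{i}" for i in range(3)}
        inp = {f"i{i}" for i in range(88)}
        sr = size_ratios(core=core, noncore_cm=out, noncore_ts=inp)
        assert sr[0] == pytest.approx(0.88)
        assert sum(sr) == pytest.approx(1.0, abs=1e-12)

    def test_empty_union_errors(self):
        with pytest.raises(ValueError):
            size_ratios(set(), set(), set())


class TestPatternClassification:
    @pytest.mark.parametrize(
        "sr,expected",
        [
            ((0.15, 0.25, 0.60), "output-dominated"),
            ((0.45, 0.10, 0.45), "symmetric"),
            ((0.70, 0.20, 0.10), "input-dominated"),
        ],
    )
    def test_decision_rule(self, sr, expected):
        call = classify_pattern(sr)
        assert call.pattern == expected and not call.degenerate

    def test_liver_endpoint_is_degenerate_output_dominated(self):
        call = classify_pattern((0.0, 0.0, 1.0))
        assert call.pattern == "output-dominated" and call.degenerate

    def test_unclassified_rather_than_forced(self):
        call = classify_pattern((0.34, 0.33, 0.33))
        assert call.pattern == "unclassified"

    def test_invalid_ratios_rejected(self):
        with pytest.raises(ValueError):
            classify_pattern((0.5, 0.5, 0.5))


def _bowtie_network(seed=0, n_in=10, n_core=4, n_out=12, dense_flow=True):
    """Synthetic decomposition input with planted input->core->output flow."""
    rng = np.random.default_rng(seed)
    inputs = [f"i{k}" for k in range(n_in)]
    cores = [f"c{k}" for k in range(n_core)]
    outs = [f"o{k}" for k in range(n_out)]
    roles = {
        **dict.fromkeys(inputs, "miRNA"),
        **dict.fromkeys(cores, "TF"),
        **dict.fromkeys(outs, "nonTF"),
    }
    arcs = set()
    if dense_flow:
        for i in inputs:
            for c in cores:
                arcs.add((i, c))
        for c in cores:
            for o in outs:
                arcs.add((c, o))
    net = RegulatoryNetwork(roles=roles, arcs=arcs, label="synthetic")
    cm = [(cores[k % n_core], cores[(k + 1) % n_core], outs[k % n_out])
          for k in range(max(n_out, n_core))]
    ts = [(inputs[k % n_in], cores[k % n_core], cores[(k + 1) % n_core])
          for k in range(max(n_in, n_core))]
    return net, cm, ts


class TestPermutationTest:
    def test_constant_statistic_p_near_one(self):
        """All genes the same role: composition is shuffle-invariant, p ~ 1."""
        net, cm, ts = _bowtie_network(dense_flow=False)
        roles = dict.fromkeys(net.roles, "TF")
        net2 = RegulatoryNetwork(roles=roles, arcs=set(), label="t")
        d = decompose("t", cm, ts, net2)
        res = permutation_test(d, net2, n_random=300, seed=0)
        for layer in ("input", "core", "output"):
            assert res.comp_p_high.loc[layer, "TF"] == pytest.approx(1.0, abs=1 / 301)
            assert res.comp_p_low.loc[layer, "TF"] == pytest.approx(1.0, abs=1 / 301)

    def test_planted_flow_is_significant(self):
        """Dense input->core arcs: D_input->core enriched in >=90% of seeds."""
        hits = 0
        for seed in range(20):
            net, cm, ts = _bowtie_network(seed=seed)
            d = decompose("t", cm, ts, net)
            res = permutation_test(d, net, n_random=300, seed=seed)
            if res.deg_p_high.loc["input", "core"] < 0.05:
                hits += 1
        assert hits >= 18

    def test_p_values_in_unit_interval(self):
        net, cm, ts = _bowtie_network(seed=1)
        d = decompose("t", cm, ts, net)
        res = permutation_test(d, net, n_random=200, seed=1)
        for frame in (res.comp_p_high, res.comp_p_low, res.deg_p_high, res.deg_p_low):
            vals = frame.to_numpy().ravel()
            vals = vals[~np.isnan(vals)]
            assert ((vals > 0) & (vals <= 1)).all()

    def test_tiny_union_errors(self):
        net = make_network({"A": "TF", "B": "TF", "C": "nonTF"},
                           {("A", "B"), ("A", "C"), ("B", "C")}, "t")
        d = decompose("t", [("A", "B", "C")], [], net)
        d.core, d.noncore_cm = set(), {"A", "B"}
        with pytest.raises(ValueError):
            permutation_test(d, net, n_random=10, seed=0)


class TestDecompose:
    def test_full_decomposition_consistency(self):
        net, cm, ts = _bowtie_network(seed=3)
        d = decompose("t", cm, ts, net)
        assert d.core == {f"c{k}" for k in range(4)}
        assert d.noncore_ts == {f"i{k}" for k in range(10)}
        assert d.noncore_cm == {f"o{k}" for k in range(12)}
        assert sum(d.size_ratios) == pytest.approx(1.0, abs=1e-12)
        assert d.composition.loc["input", "miRNA"] == 1.0
        assert d.avg_degree.loc["input", "core"] == pytest.approx(4.0)  # 10*4 arcs / 10

    def test_liver_like_decomposition(self):
        net, cm, _ = _bowtie_network(seed=4)
        d = decompose("t", cm, [], net)
        assert d.core == set() and d.noncore_ts == set()
        assert d.size_ratios == (0.0, 0.0, 1.0)
        assert d.pattern.pattern == "output-dominated" and d.pattern.degenerate
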