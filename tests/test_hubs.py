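"""Hub calling, specificity index, active ratios, strength and sigma_RF."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tissuenet import (
    HubProfile,
    RegulatoryNetwork,
    active_ratio,
    build_hub_profiles,
    call_hubs,
    classify_strength,
    er_randomize,
    sigma_rf,
    specificity_index,
)

from conftest import make_network


class TestErRandomize:
    def test_contract(self):
        net = er_randomize(10, 15, seed=0)
        assert net.n_vertices == 10 and net.n_arcs == 15
        assert all(a != b for a, b in net.arcs)

    def test_saturation_is_complete_loop_free_digraph(self):
        net = er_randomize(5, 20, seed=1)
        assert net.n_arcs == 20
        assert {(a, b) for a in net.vertices for b in net.vertices if a != b} == net.arcs

    def test_too_many_arcs_rejected(self):
        with pytest.raises(ValueError):
            er_randomize(5, 21, seed=0)

    def test_mean_in_degree_matches_binomial_expectation(self):
        """Fixed vertex's in-degree over 2000 replicates: mean 1.5 +/- 3 SE."""
        rng = np.random.default_rng(0)
        from tissuenet.hubs import _sample_er_pairs

        vals = []
        for _ in range(2000):
            _, dst = _sample_er_pairs(10, 15, rng)
            vals.append(int((dst == 0).sum()))
        mean, se = np.mean(vals), np.std(vals, ddof=1) / math.sqrt(2000)
        assert abs(mean - 1.5) <= 3 * se


class TestCallHubs:
    def test_zero_degree_never_hub(self):
        net = make_network(
            {"A": "TF", "B": "nonTF", "C": "nonTF"}, {("A", "B"), ("A", "C")}, "t"
        )
        calls = {c.gene_id: c for c in call_hubs(net, "out", n_random=200, seed=0)}
        assert calls["B"].p_value == 1.0 and not calls["B"].is_hub

    def test_zero_arcs_all_p_one(self):
        net = make_network({"A": "TF", "B": "nonTF"}, set(), "t")
        assert all(c.p_value == 1.0 for c in call_hubs(net, "in", n_random=200, seed=0))

    def test_planted_high_degree_vertex_is_hub(self):
        """In-degree 50 against a null with mean in-degree ~2 is a clear hub."""
        rng = np.random.default_rng(3)
        genes = {f"g{i:03d}": ("TF" if i < 100 else "nonTF") for i in range(200)}
        net0 = er_randomize(200, 350, seed=3)
        mapping = dict(zip(sorted(net0.vertices), sorted(genes)))
        arcs = {
            (mapping[a], mapping[b])
            for a, b in net0.arcs
            if genes[mapping[a]] == "TF" and mapping[b] != "g000"
        }
        regs = [g for g, r in genes.items() if r == "TF" and g != "g000"]
        for src in rng.choice(regs, size=50, replace=False):
            arcs.add((src, "g000"))
        net = RegulatoryNetwork(roles=genes, arcs=arcs, label="t")
        calls = {c.gene_id: c for c in call_hubs(net, "in", n_random=400, seed=1)}
        assert calls["g000"].observed_degree >= 50
        assert calls["g000"].is_hub

    def test_warns_on_tiny_ensemble(self):
        net = make_network({"A": "TF", "B": "nonTF"}, {("A", "B")}, "t")
        with pytest.warns(UserWarning, match="unstable"):
            call_hubs(net, "out", n_random=50, seed=0)

    def test_role_preserving_null_runs(self, small_reference, small_params):
        from tissuenet import build_trn, generate_expression

        prof = generate_expression(small_params, small_reference)
        trn = build_trn(small_reference, prof.expressed["tissue_1"], "tissue_1")
        calls = call_hubs(trn, "in", n_random=150, seed=0, role_preserving=True)
        assert len(calls) == trn.n_vertices


class TestSpecificityIndex:
    def test_boundary_values(self):
        assert specificity_index(8, 1) == 1.0
        assert specificity_index(8, 8) == 0.0

    def test_intermediate_value(self):
        assert specificity_index(8, 5) == pytest.approx(3 / 7)

    @pytest.mark.parametrize("N,n", [(8, 0), (1, 1), (8, 9)])
    def test_invalid_inputs(self, N, n):
        with pytest.raises(ValueError):
            specificity_index(N, n)

    @given(st.integers(2, 30))
    @settings(max_examples=20, deadline=None)
    def test_bijective_and_monotone_decreasing(self, N):
        vals = [specificity_index(N, n) for n in range(1, N + 1)]
        assert len(set(vals)) == N
        assert vals == sorted(vals, reverse=True)
        assert all(0 <= v <= 1 for v in vals)


class TestActiveRatio:
    def setup_method(self):
        self.ref = make_network(
            {"A": "TF", "B": "TF", "C": "nonTF", "D": "nonTF"},
            {("A", "B"), ("A", "C"), ("A", "D"), ("B", "C")},
            "ref",
        )

    def test_partial(self):
        trn = make_network(
            {"A": "TF", "B": "TF", "C": "nonTF"}, {("A", "B"), ("A", "C")}, "t"
        )
        assert active_ratio("A", "out", trn, self.ref) == pytest.approx(2 / 3)

    def test_identity_trn(self):
        assert active_ratio("A", "out", self.ref, self.ref) == 1.0

    def test_absent_gene_is_zero(self):
        trn = make_network({"B": "TF", "C": "nonTF"}, {("B", "C")}, "t")
        assert active_ratio("A", "out", trn, self.ref) == 0.0

    def test_zero_reference_degree_errors(self):
        with pytest.raises(ValueError):
            active_ratio("C", "out", self.ref, self.ref)


class TestStrength:
    @pytest.mark.parametrize(
        "n_expr,n_hub,expected", [(5, 5, "strong"), (5, 2, "weak"), (5, 0, "non-hub")]
    )
    def test_classification(self, n_expr, n_hub, expected):
        p = HubProfile(
            gene_id="g", role="TF", direction="in", n_tissues=8,
            n_expressed=n_expr, n_hub=n_hub,
            si=float("nan") if n_hub == 0 else specificity_index(8, n_hub),
        )
        assert classify_strength([p])[0].strength == expected


def _shared_hub_tissues(seed: int, n_tissues: int = 8):
    """Tissues where the same 8 of 12 TFs are massive out-hubs everywhere.

    The TF pool is kept small (12) with a high hub fraction (8/12) so that
    the degree-redistribution null scatters hub status yet still produces
    fully shared hubs in some replicates — the sigma_RF denominator at SI=0
    then has genuine variance.
    """
    rng = np.random.default_rng(seed)
    tfs = [f"t{i:02d}" for i in range(12)]
    targets = [f"g{i:02d}" for i in range(40)]
    roles = {**dict.fromkeys(tfs, "TF"), **dict.fromkeys(targets, "nonTF")}
    trns = []
    for t in range(n_tissues):
        arcs = set()
        for hub in tfs[:8]:
            picks = rng.choice(targets, size=15, replace=False)
            arcs |= {(hub, g) for g in picks}
        for tf in tfs[8:]:
            picks = rng.choice(targets, size=2, replace=False)
            arcs |= {(tf, g) for g in picks}
        trns.append(RegulatoryNetwork(roles=dict(roles), arcs=arcs, label=f"t{t}"))
    return trns


class TestSigmaRF:
    def test_rf_real_sums_to_one_and_shared_hubs_sign(self):
        """Hubs shared by all tissues: sigma_RF > 0 at SI=0, < 0 at SI=1."""
        hits = 0
        for seed in range(20):
            trns = _shared_hub_tissues(seed)
            calls = {
                t.label: call_hubs(t, "out", n_random=150, seed=seed + 1000)
                for t in trns
            }
            curve = sigma_rf(trns, calls, "out", "TF", n_random=200, seed=seed)
            rf_sum = sum(p.rf_real for p in curve.points)
            assert rf_sum == pytest.approx(1.0)
            at_si0 = next(p for p in curve.points if p.si == 0.0)
            at_si1 = next(p for p in curve.points if p.si == 1.0)
            if at_si0.sigma_rf > 0 and at_si1.sigma_rf < 0:
                hits += 1
        assert hits >= 19

    def test_no_hubs_gives_empty_curve_with_warning(self):
        net = make_network({"A": "TF", "B": "nonTF"}, {("A", "B")}, "t0")
        trns = [net, make_network(net.roles, net.arcs, "t1")]
        calls = {
            t.label: call_hubs(t, "in", n_random=150, seed=0) for t in trns
        }
        with pytest.warns(UserWarning, match="empty sigma_rf"):
            curve = sigma_rf(trns, calls, "in", "miRNA", n_random=100, seed=0)
        assert curve.points == []


class TestProfiles:
    def test_profile_counts_and_si(self, small_params, small_reference):
        from tissuenet import build_trn, generate_expression

        prof = generate_expression(small_params, small_reference)
        trns = [
            build_trn(small_reference, prof.expressed[t], t) for t in prof.tissues
        ]
        calls = {t.label: call_hubs(t, "in", n_random=150, seed=9) for t in trns}
        profiles = build_hub_profiles(small_reference, trns, calls, "in")
        assert len(profiles) == small_reference.n_vertices
        for p in profiles:
            assert p.n_hub <= p.n_expressed <= p.n_tissues
            if p.n_hub:
                assert p.si == specificity_index(p.n_tissues, p.n_hub)
                assert p.strength in ("strong", "weak")
            else:
                assert math.isnan(p.si) and p.strength == "non-hub"
            for r in p.active_ratios.values():
                assert 0.0 <= r <= 1.0
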