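"""Permutation test against the transcriptome null, classification,
condition networks and their intersection."""
import math

import numpy as np
import pandas as pd
import pytest

from critfact.detection import (
    ConditionNetwork,
    build_condition_network,
    classify_regulator,
    degree_comparison,
    detect_critical_tfs,
    exhaustive_group_test,
    intersect_networks,
    make_regulatory_network,
    target_group_test,
    targets_of,
)
from critfact.proteome import tf_fold_changes
from critfact.synthetic import (
    SimulationConfig,
    generate_planted_truth,
    generate_regulatory_network,
    simulate_all,
)
from critfact.transcriptome import (
    DEFlags,
    FoldChangeVector,
    compute_fpkm,
    flag_de_genes,
    gene_fold_changes,
)
from critfact.proteome import build_activity_table


# --------------------------------------------------------------- group test

def test_exhaustive_five_gene_example(five_gene_network, five_gene_fc):
    """Of the C(5,2)=10 two-gene subsets only {g4,g5} reaches mean 4.5, so
    the exact upper-tail p is 0.1; the low pair {g1,g2} mirrors it below."""
    hi = exhaustive_group_test("TF_hi", five_gene_network, five_gene_fc)
    assert hi.p_greater == pytest.approx(0.1)
    assert hi.mean_t == 4.5 and hi.mean_g == 3.0
    lo = exhaustive_group_test("TF_lo", five_gene_network, five_gene_fc)
    assert lo.p_less == pytest.approx(0.1)


def test_permutation_converges_to_exhaustive(five_gene_network, five_gene_fc):
    perm = target_group_test(
        "TF_hi", five_gene_network, five_gene_fc,
        n_permutations=100_000, seed=1, min_targets=2,
    )
    se = math.sqrt(0.1 * 0.9 / 100_000)
    assert abs(perm.p_greater - 0.1) < 3 * se + 2 / 100_000


def test_permutation_deterministic_under_seed(five_gene_network, five_gene_fc):
    a = target_group_test("TF_hi", five_gene_network, five_gene_fc, 5000, seed=42, min_targets=2)
    b = target_group_test("TF_hi", five_gene_network, five_gene_fc, 5000, seed=42, min_targets=2)
    assert a.p_value == b.p_value and a.p_greater == b.p_greater


def test_whole_universe_target_set_is_null():
    net = make_regulatory_network({"TF_all": [f"g{i}" for i in range(1, 6)]})
    fc = FoldChangeVector("t", pd.Series(np.arange(1.0, 6.0), index=[f"g{i}" for i in range(1, 6)]))
    perm = target_group_test("TF_all", net, fc, 1000, seed=0)
    assert perm.mean_t == perm.mean_g
    assert perm.p_value == 1.0
    assert perm.direction == "none"
    exact = exhaustive_group_test("TF_all", net, fc)
    assert exact.p_value == 1.0  # single subset of size |G|


def test_too_few_targets_flagged_untestable(five_gene_network, five_gene_fc):
    res = target_group_test("TF_hi", five_gene_network, five_gene_fc, 100, seed=0, min_targets=3)
    assert not res.testable
    assert math.isnan(res.p_value)
    with pytest.raises(ValueError, match="empty"):
        target_group_test("TF_hi", five_gene_network,
                          FoldChangeVector("t", pd.Series(dtype=float)), 100, seed=0)


def test_exhaustive_refuses_huge_enumeration():
    genes = [f"g{i}" for i in range(60)]
    net = make_regulatory_network({"TF": genes[:20]})
    fc = FoldChangeVector("t", pd.Series(np.ones(60), index=genes))
    with pytest.raises(ValueError, match="exceeds the cap"):
        exhaustive_group_test("TF", net, fc)


def test_pvalue_lower_bound_is_add_one(five_gene_network):
    """Strong signal: empirical p bottoms out at 1/(N+1), never zero."""
    genes = [f"g{i}" for i in range(200)]
    vals = np.ones(200)
    vals[:2] = 100.0
    net = make_regulatory_network({"TF": genes[:2]})
    fc = FoldChangeVector("t", pd.Series(vals, index=genes))
    res = target_group_test("TF", net, fc, 1000, seed=3, min_targets=2)
    assert res.p_value == pytest.approx(1 / 1001)
    assert res.direction == "up"


# ----------------------------------------------------------- classification

def _result(mean_t, mean_g, p):
    from critfact.detection import TargetGroupTestResult

    return TargetGroupTestResult("TF", "t", 5, mean_t, mean_g,
                                 "up" if mean_t > mean_g else "down",
                                 p, p, p, "permutation", 1000)


@pytest.mark.parametrize(
    "status, mean_t, expected",
    [
        ("activated", 2.0, "activator"),   # consistent directions
        ("activated", 0.5, "repressor"),   # inconsistent
        ("repressed", 0.5, "activator"),
        ("repressed", 2.0, "repressor"),
        ("unchanged", 2.0, None),          # needs both signals
    ],
)
def test_regulator_classification(status, mean_t, expected):
    assert classify_regulator(status, _result(mean_t, 1.0, 0.01)) == expected


def test_regulator_requires_significance():
    assert classify_regulator("activated", _result(2.0, 1.0, 0.2)) is None
    assert classify_regulator("activated", _result(1.0, 1.0, 0.01)) is None  # tied means


# ----------------------------------------------------------------- detect

def _analyse(config, transition_idx=0, **detect_kw):
    ds = simulate_all(config)
    table = build_activity_table(ds.intensities, ds.proteins)
    cond_a = config.conditions[transition_idx]
    cond_b = config.conditions[transition_idx + 1]
    changes = tf_fold_changes(table, cond_a, cond_b)
    fpkm = compute_fpkm(ds.expression)
    fc = gene_fold_changes(fpkm, ds.expression.condition_of, cond_a, cond_b)
    crit, results = detect_critical_tfs(changes, ds.network, fc, seed=99, **detect_kw)
    return ds, crit, results, fc


def test_detect_recovers_planted_tfs(small_config):
    ds, crit, results, _ = _analyse(small_config)
    detected = {c.tf_id for c in crit}
    planted = set(ds.truth.roles)
    assert detected == planted
    for c in crit:
        assert c.regulator_class == ds.truth.roles[c.tf_id]  # no class swaps


def test_detect_deterministic(small_config):
    _, crit1, res1, _ = _analyse(small_config)
    _, crit2, res2, _ = _analyse(small_config)
    assert [(c.tf_id, c.test.p_value) for c in crit1] == [(c.tf_id, c.test.p_value) for c in crit2]
    assert [r.p_value for r in res1] == [r.p_value for r in res2]


def test_detect_bh_adjustment_is_recorded(small_config):
    _, crit, results, _ = _analyse(small_config, adjust="BH")
    testable = [r for r in results if r.testable]
    assert all(r.adjusted_p is not None for r in testable)
    assert all(r.adjusted_p >= r.p_value for r in testable)
    assert {c.tf_id for c in crit} == set(simulate_all(small_config).truth.roles)


def test_detect_all_tfs_below_min_targets_yields_empty(five_gene_fc):
    net = make_regulatory_network({"TF1": ["g1", "g2"]})
    changes = pd.DataFrame({"tf_id": ["TF1"], "status": ["activated"]})
    crit, results = detect_critical_tfs(changes, net, five_gene_fc, min_targets=3, seed=0)
    assert crit == []
    assert not results[0].testable


# -------------------------------------------------------- condition networks

def _crit(tf_id, transition="t"):
    from critfact.detection import CriticalTF

    return CriticalTF(tf_id, transition, "activator", "activated", "up",
                      _result(2.0, 1.0, 0.01))


def test_condition_network_keeps_only_de_targets():
    net = make_regulatory_network({"TF1": [f"g{i}" for i in range(10)], "TF2": ["g90", "g91"]})
    flags = DEFlags("t", frozenset({"g0", "g1"}), frozenset({"g2"}), "threshold-standin")
    cn = build_condition_network([_crit("TF1"), _crit("TF2")], net, flags)
    assert sorted(cn.graph.successors("TF1")) == ["g0", "g1", "g2"]
    assert "TF2" not in cn.graph  # all targets non-DE -> TF dropped
    for _, tgt in cn.edges:
        assert tgt in flags.genes
    assert cn.graph.nodes["g0"]["de_direction"] == "up"
    assert cn.graph.nodes["g2"]["de_direction"] == "down"


def test_condition_network_transition_mismatch_rejected():
    net = make_regulatory_network({"TF1": ["g0"]})
    flags = DEFlags("other", frozenset({"g0"}), frozenset(), "threshold-standin")
    with pytest.raises(ValueError, match="other"):
        build_condition_network([_crit("TF1", "t")], net, flags)


def _cond_net(tf_targets: dict, transition="t") -> ConditionNetwork:
    import networkx as nx

    g = nx.DiGraph()
    for tf, tgts in tf_targets.items():
        g.add_node(tf, role="tf")
        for t in tgts:
            g.add_node(t, role="target")
            g.add_edge(tf, t)
    return ConditionNetwork(transition, g)


def test_intersection_set_semantics():
    n1 = _cond_net({"A": ["x"], "B": ["y"], "C": ["z"]})
    n2 = _cond_net({"B": ["y"], "C": ["w"], "D": ["z"]})
    co, shared = intersect_networks(n1, n2)
    assert co == {"B", "C"}
    assert set(shared.edges()) == {("B", "y")}
    co_rev, _ = intersect_networks(n2, n1)
    assert co == co_rev  # commutative
    co_self, shared_self = intersect_networks(n1, n1)
    assert co_self == {"A", "B", "C"}  # idempotent
    assert set(shared_self.edges()) == set(n1.edges)
    co_disjoint, _ = intersect_networks(n1, _cond_net({"Z": ["q"]}))
    assert co_disjoint == frozenset()


# ----------------------------------------------------------- degree analysis

def test_degree_comparison_exact_small_case():
    """Two annotated TFs of degree 3 vs two others of degree 1: the exact
    two-sided Mann-Whitney p for the most extreme ranking of 2 vs 2 is 1/3."""
    net = make_regulatory_network(
        {"A": ["x", "y", "z"], "B": ["x", "y", "z"], "C": ["x"], "D": ["y"]}
    )
    mean_in, mean_out, p = degree_comparison(net, {"A", "B"})
    assert mean_in == 3.0 and mean_out == 1.0
    assert p == pytest.approx(1 / 3)


def test_degree_comparison_equal_groups_and_errors():
    net = make_regulatory_network({"A": ["x", "y"], "B": ["x", "y"], "C": ["z"], "D": ["z"]})
    mean_in, mean_out, _ = degree_comparison(net, {"A", "C"})
    assert mean_in == mean_out
    with pytest.raises(ValueError, match="non-empty"):
        degree_comparison(net, {"A", "B", "C", "D"})
    with pytest.raises(ValueError, match="not TF nodes"):
        degree_comparison(net, {"A", "x"})


def test_degree_comparison_label_permutation_invariant():
    net = make_regulatory_network(
        {"A": ["x", "y", "z"], "B": ["x"], "C": ["x", "y"], "D": ["y"], "E": ["z", "x"]}
    )
    r1 = degree_comparison(net, {"A", "C"})
    r2 = degree_comparison(net, {"C", "A"})
    assert r1 == r2
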