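"""Generator determinism, planted-effect fidelity, and table structure."""
import numpy as np
import pandas as pd
import pytest

from critfact.detection import tf_nodes, targets_of
from critfact.proteome import count_theoretical_peptides
from critfact.synthetic import (
    PlantedTruth,
    SimulationConfig,
    expected_expression_means,
    generate_pharmacology_tables,
    generate_planted_truth,
    generate_protein_fasta,
    generate_regulatory_network,
    simulate_all,
    simulate_expression,
    simulate_tf_intensities,
)


def _noiseless(config: SimulationConfig, **kw) -> SimulationConfig:
    from dataclasses import asdict

    return SimulationConfig(**{**asdict(config), "noise_cv": 0.0, **kw})


def test_single_tf_targets_whole_universe():
    cfg = SimulationConfig(
        n_tfs=1, n_genes=5, targets_per_tf=(5, 5),
        n_activators=0, n_repressors=0, n_final_tfs=0, seed=1,
    )
    net = generate_regulatory_network(cfg)
    assert sorted(net.successors("TF0001")) == cfg.gene_ids


def test_network_determinism_and_degree_bounds():
    cfg = SimulationConfig(
        n_tfs=50, n_genes=2000, targets_per_tf=(10, 40),
        n_activators=0, n_repressors=0, n_final_tfs=0, seed=1,
    )
    net1 = generate_regulatory_network(cfg)
    net2 = generate_regulatory_network(cfg)
    assert sorted(net1.edges()) == sorted(net2.edges())
    for tf in tf_nodes(net1):
        assert 10 <= net1.out_degree(tf) <= 40


def test_infeasible_target_range_rejected():
    with pytest.raises(ValueError, match="exceeds n_genes"):
        SimulationConfig(n_tfs=2, n_genes=5, targets_per_tf=(6, 6),
                         n_activators=0, n_repressors=0, n_final_tfs=0)


def test_fasta_records_match_tf_universe_and_digest():
    cfg = SimulationConfig(n_tfs=3, n_genes=50, targets_per_tf=(5, 5),
                           n_activators=0, n_repressors=0, n_final_tfs=0, seed=2)
    proteins = generate_protein_fasta(cfg)
    assert sorted(proteins) == cfg.tf_ids
    assert proteins == generate_protein_fasta(cfg)  # determinism
    for seq in proteins.values():
        assert 150 <= len(seq) <= 800
        assert count_theoretical_peptides(seq) >= 0  # digestion runs cleanly


def _manual_truth(cfg, tf, role, direction):
    labels = cfg.transitions
    return PlantedTruth(
        {tf: role},
        {labels[0]: {tf: direction}, **{l: {tf: -direction} for l in labels[1:]}},
        frozenset({tf}),
        frozenset(),
    )


def test_noiseless_intensity_ratios():
    cfg = SimulationConfig(n_tfs=3, n_genes=60, targets_per_tf=(5, 5),
                           n_activators=1, n_repressors=0, n_final_tfs=0,
                           noise_cv=0.0, seed=3)
    net = generate_regulatory_network(cfg)
    truth = _manual_truth(cfg, "TF0002", "activator", +1)
    table = simulate_tf_intensities(net, truth, cfg)
    means = table.groupby(["tf_id", "condition"])["intensity"].mean().unstack()
    assert means.loc["TF0002", "model"] / means.loc["TF0002", "control"] == pytest.approx(4.0)
    # rescue: reversed in the treated transition
    assert means.loc["TF0002", "treated"] / means.loc["TF0002", "model"] == pytest.approx(0.25)
    for null_tf in ("TF0001", "TF0003"):
        assert means.loc[null_tf, "model"] / means.loc[null_tf, "control"] == pytest.approx(1.0)


def test_noisy_intensity_ratio_unbiased():
    """With cv = 0.1 and 1000 planted activated TFs, the mean realized
    model/control ratio sits within 3 standard errors of the planted 4.0."""
    cfg = SimulationConfig(n_tfs=1000, n_genes=60, targets_per_tf=(5, 5),
                           n_activators=0, n_repressors=0, n_final_tfs=0,
                           noise_cv=0.1, seed=4)
    net = generate_regulatory_network(cfg)
    labels = cfg.transitions
    truth = PlantedTruth(
        {tf: "activator" for tf in cfg.tf_ids},
        {labels[0]: {tf: +1 for tf in cfg.tf_ids},
         labels[1]: {tf: -1 for tf in cfg.tf_ids}},
        frozenset(cfg.tf_ids),
        frozenset(),
    )
    table = simulate_tf_intensities(net, truth, cfg)
    means = table.groupby(["tf_id", "condition"])["intensity"].mean().unstack()
    ratios = (means["model"] / means["control"]).to_numpy()
    sem = ratios.std(ddof=1) / np.sqrt(len(ratios))
    assert abs(ratios.mean() - 4.0) < 3 * sem + 4.0 * cfg.noise_cv**2  # small plug-in bias allowance


def test_noiseless_expression_means_shift_targets_only(small_config):
    cfg = small_config
    net = generate_regulatory_network(cfg)
    truth = generate_planted_truth(cfg, net)
    means, lengths = expected_expression_means(net, truth, cfg)
    assert means.shape == (cfg.n_genes, 3)
    assert lengths.between(500, 5000).all()
    # expected net exponent per gene: signed 2.5-fold effects multiply when
    # several planted TFs share a target (and may cancel exactly)
    label = cfg.transitions[0]
    exponent: dict[str, int] = {}
    for tf, role in truth.roles.items():
        adir = truth.activity_direction[label][tf]
        tdir = adir if role == "activator" else -adir
        for g in targets_of(net, tf):
            exponent[g] = exponent.get(g, 0) + tdir
    for g in means.index:
        ratio = means.loc[g, "model"] / means.loc[g, "control"]
        assert ratio == pytest.approx(cfg.target_effect_fc ** exponent.get(g, 0))


def test_single_activator_target_mean_times_effect():
    cfg = SimulationConfig(n_tfs=1, n_genes=10, targets_per_tf=(3, 3),
                           n_activators=1, n_repressors=0, n_final_tfs=0,
                           noise_cv=0.0, seed=6)
    net = generate_regulatory_network(cfg)
    truth = _manual_truth(cfg, "TF0001", "activator", +1)
    means, _ = expected_expression_means(net, truth, cfg)
    for g in targets_of(net, "TF0001"):
        assert means.loc[g, "model"] / means.loc[g, "control"] == pytest.approx(2.5)
    # repressor with the same upward activity pushes targets down instead
    truth_rep = _manual_truth(cfg, "TF0001", "repressor", +1)
    means_rep, _ = expected_expression_means(net, truth_rep, cfg)
    for g in targets_of(net, "TF0001"):
        assert means_rep.loc[g, "model"] / means_rep.loc[g, "control"] == pytest.approx(1 / 2.5)


def test_expression_counts_deterministic_and_sized(small_config):
    net = generate_regulatory_network(small_config)
    truth = generate_planted_truth(small_config, net)
    em1 = simulate_expression(net, truth, small_config)
    em2 = simulate_expression(net, truth, small_config)
    pd.testing.assert_frame_equal(em1.counts, em2.counts)
    assert em1.counts.shape == (small_config.n_genes, 9)
    totals = em1.counts.sum(axis=0)
    assert ((totals > 0.5 * small_config.library_size) & (totals < 2 * small_config.library_size)).all()


def test_pharmacology_path_mode_structure():
    cfg = SimulationConfig(n_tfs=20, n_genes=200, targets_per_tf=(5, 5),
                           n_activators=2, n_repressors=2, n_final_tfs=1,
                           n_coactivators=5, n_compounds=3, seed=7)
    net = generate_regulatory_network(cfg)
    truth = generate_planted_truth(cfg, net)
    tables = generate_pharmacology_tables(truth, cfg)
    (final_tf,) = truth.final_tfs
    bridges = tables.ppi[tables.ppi["protein_b"] == final_tf]
    assert len(bridges) == 1
    assert (bridges["confidence"] >= 0.5).all()
    coact = bridges["protein_a"].iloc[0]
    assert ((tables.compound_targets["target_id"] == coact)).sum() == 1
    # decoy PPI edges to non-final critical TFs stay below the cutoff
    decoys = tables.ppi[tables.ppi["protein_b"] != final_tf]
    assert (decoys["confidence"] < 0.5).all()
    assert len(tables.coactivators) == cfg.n_coactivators


def test_pharmacology_no_final_tfs_means_no_confident_edges():
    cfg = SimulationConfig(n_tfs=20, n_genes=200, targets_per_tf=(5, 5),
                           n_activators=2, n_repressors=2, n_final_tfs=0,
                           n_coactivators=5, n_compounds=3, seed=8)
    truth = generate_planted_truth(cfg)
    tables = generate_pharmacology_tables(truth, cfg)
    critical = truth.coregulated
    to_critical = tables.ppi[tables.ppi["protein_b"].isin(critical)]
    assert (to_critical["confidence"] < 0.5).all()


def test_pharmacology_tables_deterministic():
    cfg = SimulationConfig(n_tfs=20, n_genes=200, targets_per_tf=(5, 5),
                           n_activators=2, n_repressors=2, n_final_tfs=2,
                           n_coactivators=5, n_compounds=3, seed=9)
    truth = generate_planted_truth(cfg)
    t1 = generate_pharmacology_tables(truth, cfg)
    t2 = generate_pharmacology_tables(truth, cfg)
    pd.testing.assert_frame_equal(t1.compound_targets, t2.compound_targets)
    pd.testing.assert_frame_equal(t1.ppi, t2.ppi)
    assert t1.coactivators == t2.coactivators


def test_truth_invariants(small_config):
    truth = generate_planted_truth(small_config)
    assert truth.final_tfs <= truth.coregulated
    assert set(truth.roles) == set(truth.coregulated)
    assert sum(r == "activator" for r in truth.roles.values()) == small_config.n_activators
    for label in small_config.transitions:
        assert set(truth.activity_direction[label]) == set(truth.roles)
    with pytest.raises(ValueError, match="co-regulated"):
        PlantedTruth({"TF1": "activator"}, {"t": {"TF1": 1}}, frozenset(), frozenset({"TF1"}))


def test_simulate_all_writes_deterministic_bundle(tmp_path, small_config):
    ds = simulate_all(small_config)
    out1, out2 = tmp_path / "a", tmp_path / "b"
    ds.write(out1)
    simulate_all(small_config).write(out2)
    for f in sorted(out1.iterdir()):
        assert f.read_bytes() == (out2 / f.name).read_bytes(), f.name
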