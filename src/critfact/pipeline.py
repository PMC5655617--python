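"""End-to-end orchestration of the integrated strategy.

One config drives the whole run: simulate (or load) inputs, quantify TF
binding activity by iBAQ, compute FPKM fold changes and DE flags per
transition, detect and classify critical TFs against the transcriptome
null, build and intersect the per-transition condition networks, and pass
the co-regulated TFs through the compound / co-activator pharmacology
filter.  Every artifact is written as TSV/GMT/FASTA/JSON together with a
JSON manifest (parameters, seed, file checksums) sufficient to reproduce
the run bit-for-bit.
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from functools import reduce
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .detection import (
    ConditionNetwork,
    build_condition_network,
    critical_tfs_to_frame,
    detect_critical_tfs,
    intersect_networks,
    make_regulatory_network,
    test_results_to_frame,
    tf_nodes,
)
from .pharmacology import (
    build_pharmacology_network,
    filter_ppi,
    identify_final_tfs,
    network_to_frames,
    select_coactivators,
)
from .proteome import build_activity_table, tf_fold_changes
from .synthetic import SimulationConfig, simulate_all
from .transcriptome import compute_fpkm, flag_de_genes, gene_fold_changes

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    """Stage parameters; defaults follow the study's stated conventions
    (activity thresholds 2 / 0.5, PPI confidence >= 0.5, alpha 0.05)."""

    alpha: float = 0.05
    n_permutations: int = 10_000
    min_targets: int = 3
    adjust: str = "none"
    sided: str = "two"
    up_threshold: float = 2.0
    down_threshold: float = 0.5
    pseudocount: float = 1.0
    log2fc_threshold: float = 1.0
    min_confidence: float = 0.5


@dataclass
class PipelineConfig:
    seed: int
    out: str
    simulation: SimulationConfig | None = None
    inputs: dict[str, str] | None = None
    conditions: tuple[str, ...] | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("config needs exactly one of 'simulation' or 'inputs'")
        if self.simulation is not None:
            if self.simulation.seed != self.seed:
                # the pipeline seed is authoritative
                self.simulation = SimulationConfig(
                    **{**asdict(self.simulation), "seed": self.seed}
                )
            self.conditions = self.simulation.conditions
        elif self.conditions is None:
            raise ValueError("loading external inputs requires a 'conditions' list")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sim = raw.get("simulation")
        if sim is not None:
            if "conditions" in sim:
                sim["conditions"] = tuple(sim["conditions"])
            if "targets_per_tf" in sim:
                sim["targets_per_tf"] = tuple(sim["targets_per_tf"])
            sim = SimulationConfig(**{"seed": raw.get("seed", 0), **sim})
        params = PipelineParams(**raw.get("params", {}))
        conditions = tuple(raw["conditions"]) if "conditions" in raw else None
        return cls(
            seed=int(raw.get("seed", 0)),
            out=str(raw.get("out", "results")),
            simulation=sim,
            inputs=raw.get("inputs"),
            conditions=conditions,
            params=params,
        )

    @property
    def transitions(self) -> list[tuple[str, str]]:
        conds = self.conditions
        return list(zip(conds[:-1], conds[1:]))


@dataclass
class LoadedInputs:
    proteins: dict
    intensities: pd.DataFrame
    expression: object
    network: nx.DiGraph
    compound_targets: pd.DataFrame
    ppi: pd.DataFrame
    coactivators: list[str]
    truth: object | None = None


def _load_inputs(config: PipelineConfig) -> LoadedInputs:
    if config.simulation is not None:
        ds = simulate_all(config.simulation)
        return LoadedInputs(
            ds.proteins, ds.intensities, ds.expression, ds.network,
            ds.pharmacology.compound_targets, ds.pharmacology.ppi,
            ds.pharmacology.coactivators, ds.truth,
        )
    paths = config.inputs
    network_path = paths["network"]
    if str(network_path).endswith(".gmt"):
        sets = cio.read_gmt(network_path)
    else:
        sets = cio.read_edge_list(network_path)
    return LoadedInputs(
        cio.read_fasta(paths["proteins"]),
        cio.read_tsv(paths["intensities"]),
        cio.read_expression_matrix(paths["expression"], paths["samples"]),
        make_regulatory_network(sets),
        cio.read_tsv(paths["compound_targets"]),
        cio.read_tsv(paths["ppi"]),
        cio.read_id_list(paths["coactivators"]),
    )


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Cross-check id namespaces and condition coverage; returns every
    violation found (an empty list means the inputs are consistent)."""
    data = _load_inputs(config)
    violations: list[str] = []

    fasta_ids = set(data.proteins)
    for tf in sorted(set(data.intensities["tf_id"]) - fasta_ids):
        violations.append(f"intensity table TF {tf!r} has no protein record")

    genes = set(data.expression.genes)
    tfs = set(tf_nodes(data.network))
    for tf in sorted(tfs):
        for g in data.network.successors(tf):
            if g not in genes and g not in tfs:
                violations.append(f"network target {g!r} (TF {tf!r}) not in expression matrix")

    intensity_conditions = set(data.intensities["condition"])
    expression_conditions = set(data.expression.condition_of.values())
    for cond in config.conditions:
        if cond not in intensity_conditions:
            violations.append(f"condition {cond!r} missing from the intensity table")
        if cond not in expression_conditions:
            violations.append(f"condition {cond!r} missing from the expression samples")
    return violations


@dataclass
class ResultsBundle:
    """In-memory results of one orchestrated run (also written to disk)."""

    outdir: Path
    activity_table: pd.DataFrame
    activity_changes: dict[str, pd.DataFrame]
    fold_changes: dict[str, object]
    de_flags: dict[str, object]
    test_results: dict[str, list]
    critical_tfs: dict[str, list]
    condition_networks: dict[str, ConditionNetwork]
    coregulated: frozenset
    pharmacology_network: nx.Graph
    final_tfs: frozenset
    manifest: dict


def _transition_seed(seed: int, index: int) -> int:
    state = np.random.SeedSequence(seed, spawn_key=(100, index))
    return int(state.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, force: bool = False) -> ResultsBundle:
    """Execute every stage in order and write the results bundle.

    Two transitions (model-vs-control, treated-vs-model under the default
    condition labels) produce two condition networks whose intersection —
    the co-regulated TFs — feeds the pharmacology filter.  Deterministic
    under the config seed.  A stage failure aborts with a stage-named
    error; outputs written so far are kept next to a FAILED marker.
    """
    out = Path(config.out)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    params = config.params
    files: dict[str, Path] = {}
    stage = "load-inputs"
    try:
        data = _load_inputs(config)

        stage = "tf-activity"
        activity = build_activity_table(data.intensities, data.proteins)
        log.info("tf-activity: %d TFs quantified", activity["tf_id"].nunique())
        files["activity_table"] = out / "activity_table.tsv"
        cio.write_tsv(activity, files["activity_table"])

        stage = "expression"
        fpkm = compute_fpkm(data.expression)
        files["fpkm"] = out / "fpkm.tsv"
        fpkm_out = fpkm.copy()
        fpkm_out.index.name = "gene_id"
        cio.write_tsv(fpkm_out.reset_index(), files["fpkm"])

        activity_changes: dict[str, pd.DataFrame] = {}
        fold_changes: dict[str, object] = {}
        de_flags: dict[str, object] = {}
        test_results: dict[str, list] = {}
        critical: dict[str, list] = {}
        networks: dict[str, ConditionNetwork] = {}
        for i, (cond_a, cond_b) in enumerate(config.transitions):
            label = f"{cond_b}_vs_{cond_a}"
            stage = f"detect[{label}]"

            changes = tf_fold_changes(
                activity, cond_a, cond_b,
                up_threshold=params.up_threshold, down_threshold=params.down_threshold,
            )
            activity_changes[label] = changes
            files[f"activity_changes_{label}"] = out / f"activity_changes_{label}.tsv"
            cio.write_tsv(changes, files[f"activity_changes_{label}"])

            fc = gene_fold_changes(
                fpkm, data.expression.condition_of, cond_a, cond_b,
                pseudocount=params.pseudocount,
            )
            fold_changes[label] = fc
            files[f"fold_changes_{label}"] = out / f"fold_changes_{label}.tsv"
            cio.write_fold_changes(fc, files[f"fold_changes_{label}"])

            flags = flag_de_genes(fc, log2fc_threshold=params.log2fc_threshold)
            de_flags[label] = flags
            files[f"de_flags_{label}"] = out / f"de_flags_{label}.tsv"
            cio.write_de_flags(flags, files[f"de_flags_{label}"])
            log.info("%s: %d up / %d down DE genes", label, len(flags.up), len(flags.down))

            crit, results = detect_critical_tfs(
                changes, data.network, fc,
                alpha=params.alpha, min_targets=params.min_targets,
                n_permutations=params.n_permutations,
                seed=_transition_seed(config.seed, i),
                adjust=params.adjust, sided=params.sided,
            )
            test_results[label] = results
            critical[label] = crit
            log.info(
                "%s: %d TFs testable, %d critical (%d activators, %d repressors)",
                label, sum(r.testable for r in results), len(crit),
                sum(c.regulator_class == "activator" for c in crit),
                sum(c.regulator_class == "repressor" for c in crit),
            )
            files[f"test_results_{label}"] = out / f"test_results_{label}.tsv"
            cio.write_tsv(test_results_to_frame(results), files[f"test_results_{label}"])
            files[f"critical_tfs_{label}"] = out / f"critical_tfs_{label}.tsv"
            cio.write_tsv(critical_tfs_to_frame(crit), files[f"critical_tfs_{label}"])

            net = build_condition_network(crit, data.network, flags)
            networks[label] = net
            files[f"condition_network_{label}"] = out / f"condition_network_{label}.tsv"
            cio.write_tsv(
                pd.DataFrame(sorted(net.edges), columns=["source", "target"]),
                files[f"condition_network_{label}"],
            )

        stage = "intersect"
        labels = [f"{b}_vs_{a}" for a, b in config.transitions]
        if len(labels) >= 2:
            coregulated, shared = reduce(
                lambda acc, lab: (
                    acc[0] & networks[lab].tfs,
                    _edge_intersection(acc[1], networks[lab].graph),
                ),
                labels[1:],
                (networks[labels[0]].tfs, networks[labels[0]].graph),
            )
        else:
            coregulated, shared = networks[labels[0]].tfs, networks[labels[0]].graph
        log.info("intersection: %d co-regulated TFs", len(coregulated))
        files["coregulated_tfs"] = out / "coregulated_tfs.txt"
        cio.write_id_list(coregulated, files["coregulated_tfs"])
        files["shared_network"] = out / "shared_network.tsv"
        cio.write_tsv(
            pd.DataFrame(sorted(shared.edges()), columns=["source", "target"]),
            files["shared_network"],
        )

        stage = "netpharm"
        ppi_kept = filter_ppi(data.ppi, params.min_confidence)
        log.info("netpharm: %d / %d PPI edges retained", len(ppi_kept), len(data.ppi))
        coacts = select_coactivators(data.coactivators, de_flags[labels[-1]])
        log.info("netpharm: %d / %d co-activators co-expressed", len(coacts), len(data.coactivators))
        pharm_net = build_pharmacology_network(
            data.compound_targets, ppi_kept, coregulated, coacts
        )
        final = identify_final_tfs(pharm_net)
        log.info("netpharm: %d final TFs", len(final))
        edges_df, nodes_df = network_to_frames(pharm_net)
        files["pharmacology_edges"] = out / "pharmacology_edges.tsv"
        cio.write_tsv(edges_df, files["pharmacology_edges"])
        files["pharmacology_nodes"] = out / "pharmacology_nodes.tsv"
        cio.write_tsv(nodes_df, files["pharmacology_nodes"])
        files["final_tfs"] = out / "final_tfs.txt"
        cio.write_id_list(final, files["final_tfs"])

        stage = "manifest"
        manifest = {
            "package": "critfact",
            "version": __version__,
            "seed": config.seed,
            "conditions": list(config.conditions),
            "params": asdict(params),
            "simulation": asdict(config.simulation) if config.simulation else None,
            "inputs": config.inputs,
            "files": {name: cio.sha256_of(path) for name, path in sorted(files.items())},
        }
        cio.write_json(manifest, out / "manifest.json")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return ResultsBundle(
        out, activity, activity_changes, fold_changes, de_flags,
        test_results, critical, networks, coregulated, pharm_net, final, manifest,
    )


def _edge_intersection(g1: nx.DiGraph, g2: nx.DiGraph) -> nx.DiGraph:
    shared = nx.DiGraph()
    for u, v in set(g1.edges()) & set(g2.edges()):
        shared.add_node(u, **g1.nodes[u])
        shared.add_node(v, **g1.nodes[v])
        shared.add_edge(u, v)
    return shared
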