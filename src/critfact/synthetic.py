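"""Seeded synthetic data with planted ground truth for the whole pipeline.

The generator emulates a three-condition cell study (untreated control,
oxidative-stress model, drug-pretreated) measured on two complementary
layers: TF binding-activity intensities from a DNA-bait pull-down assay and
RNA-seq fragment counts for the transcriptome.  A subset of TFs is planted
as *critical*: their binding activity shifts by ``tf_effect_fc`` between
consecutive conditions, and their target genes' expression means shift by
``target_effect_fc`` — in the same direction for activators and the
opposite direction for repressors.  In the drug-treated transition the
activity direction of every planted TF is reversed, emulating a rescue.
Compound-target and protein-protein interaction tables are constructed so
that a designated subset of the planted TFs (the intended *final* TFs) is
reachable from compounds through high-confidence co-activator bridges,
while decoy edges stay below the confidence cutoff.

Every generator is a pure function of (config, seed): sub-streams are
derived from the master seed by fixed labelled offsets, so outputs are
bit-for-bit reproducible.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .detection import make_regulatory_network, tf_nodes, targets_of
from .transcriptome import ExpressionMatrix, compute_fpkm, flag_de_genes, gene_fold_changes

log = logging.getLogger(__name__)

_STREAMS = {
    "network": 1,
    "truth": 2,
    "fasta": 3,
    "intensity": 4,
    "expression_model": 5,
    "expression_counts": 6,
    "pharmacology": 7,
}

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    The defaults describe the emulated design: 200 TFs over a 2000-gene
    transcriptome, 20 targets per TF, 10 planted activators plus 10 planted
    repressors shared by both transitions, a 4-fold activity effect and a
    2.5-fold target-expression effect, 20 % multiplicative noise on
    intensities, three replicates per condition, and a pharmacology layer
    of 15 compounds, 24 co-activator candidates and 7 intended final TFs.
    """

    n_tfs: int = 200
    n_genes: int = 2000
    targets_per_tf: tuple[int, int] = (20, 20)
    n_activators: int = 10
    n_repressors: int = 10
    tf_effect_fc: float = 4.0
    target_effect_fc: float = 2.5
    noise_cv: float = 0.2
    dispersion: float = 0.05
    fraction_targets_affected: float = 1.0
    n_replicates: int = 3
    library_size: float = 20_000_000.0
    conditions: tuple[str, ...] = ("control", "model", "treated")
    n_compounds: int = 15
    n_coactivators: int = 24
    n_final_tfs: int = 7
    tf_baseline_log10: tuple[float, float] = (4.0, 7.0)
    gene_baseline_log10: tuple[float, float] = (1.0, 3.0)
    protein_length: tuple[int, int] = (150, 800)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tfs", "n_genes", "n_replicates", "n_compounds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.targets_per_tf
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid targets_per_tf range {self.targets_per_tf}")
        if hi > self.n_genes:
            raise ValueError(
                f"targets_per_tf upper bound {hi} exceeds n_genes {self.n_genes}"
            )
        if self.n_activators + self.n_repressors > self.n_tfs:
            raise ValueError("more planted TFs than TFs")
        if self.n_final_tfs > self.n_activators + self.n_repressors:
            raise ValueError("intended final TFs must be a subset of planted TFs")
        if len(self.conditions) < 2:
            raise ValueError("need at least two conditions")
        if self.noise_cv < 0 or self.dispersion < 0:
            raise ValueError("noise_cv and dispersion must be >= 0")
        if not 0 <= self.fraction_targets_affected <= 1:
            raise ValueError("fraction_targets_affected must be in [0, 1]")
        planted = self.n_activators + self.n_repressors
        if planted and (self.tf_effect_fc <= 2 or self.target_effect_fc <= 1):
            raise ValueError(
                "planting detectable signal requires tf_effect_fc > 2 "
                "and target_effect_fc > 1"
            )

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{i:04d}" for i in range(1, self.n_tfs + 1)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(1, self.n_genes + 1)]

    @property
    def transitions(self) -> list[str]:
        return [
            f"{b}_vs_{a}" for a, b in zip(self.conditions[:-1], self.conditions[1:])
        ]

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of the planted signal.

    ``roles`` maps planted TF ids to ``activator`` or ``repressor`` (the
    regulator class is a property of the TF, constant across transitions);
    unmentioned TFs are null.  ``activity_direction`` gives the signed
    activity change (+1 up, -1 down) per transition for every planted TF.
    ``coregulated`` are the TFs planted in both transitions, and
    ``final_tfs`` the subset intended to be reachable from compounds.
    """

    roles: dict[str, str]
    activity_direction: dict[str, dict[str, int]]
    coregulated: frozenset[str]
    final_tfs: frozenset[str]

    def __post_init__(self) -> None:
        if not self.final_tfs <= self.coregulated:
            raise ValueError("intended final TFs must be co-regulated TFs")

    def role_of(self, tf_id: str) -> str:
        return self.roles.get(tf_id, "null")

    def to_json(self) -> dict:
        return {
            "roles": dict(sorted(self.roles.items())),
            "activity_direction": {
                t: dict(sorted(d.items())) for t, d in sorted(self.activity_direction.items())
            },
            "coregulated": sorted(self.coregulated),
            "final_tfs": sorted(self.final_tfs),
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "PlantedTruth":
        return cls(
            dict(obj["roles"]),
            {t: {k: int(v) for k, v in d.items()} for t, d in obj["activity_direction"].items()},
            frozenset(obj["coregulated"]),
            frozenset(obj["final_tfs"]),
        )


# ---------------------------------------------------------------------------
# generators

def generate_regulatory_network(config: SimulationConfig) -> nx.DiGraph:
    """Random TF -> target network: each TF draws an out-degree uniformly
    from ``targets_per_tf`` and samples that many distinct genes."""
    rng = config.rng("network")
    lo, hi = config.targets_per_tf
    genes = np.array(config.gene_ids)
    sets: dict[str, list[str]] = {}
    for tf_id in config.tf_ids:
        d = int(rng.integers(lo, hi + 1))
        sets[tf_id] = sorted(map(str, rng.choice(genes, size=d, replace=False)))
    return make_regulatory_network(sets)


def generate_planted_truth(config: SimulationConfig, network: nx.DiGraph | None = None) -> PlantedTruth:
    """Choose the planted activators/repressors, their per-transition
    activity directions (reversed in the second transition, emulating a
    rescue by the treatment), and the intended final TF subset."""
    rng = config.rng("truth")
    tfs = np.array(config.tf_ids if network is None else tf_nodes(network))
    n_planted = config.n_activators + config.n_repressors
    planted = sorted(map(str, rng.choice(tfs, size=n_planted, replace=False)))
    roles = {
        tf: ("activator" if i < config.n_activators else "repressor")
        for i, tf in enumerate(planted)
    }
    directions: dict[str, dict[str, int]] = {}
    base = {tf: int(rng.choice([-1, 1])) for tf in planted}
    for i, label in enumerate(config.transitions):
        sign = 1 if i % 2 == 0 else -1
        directions[label] = {tf: sign * d for tf, d in base.items()}
    final = frozenset(map(str, rng.choice(np.array(planted), size=config.n_final_tfs, replace=False)))
    return PlantedTruth(roles, directions, frozenset(planted), final)


def generate_protein_fasta(config: SimulationConfig) -> dict[str, str]:
    """One random protein sequence per TF, lengths uniform over
    ``protein_length``; each sequence is guaranteed at least one K or R so
    a tryptic digest is never empty."""
    rng = config.rng("fasta")
    lo, hi = config.protein_length
    proteins: dict[str, str] = {}
    for tf_id in config.tf_ids:
        n = int(rng.integers(lo, hi + 1))
        seq = rng.choice(_AA, size=n)
        if not np.isin(seq, ("K", "R")).any():
            seq[int(rng.integers(0, n))] = rng.choice(np.array(["K", "R"]))
        proteins[tf_id] = "".join(seq)
    return proteins


def _cumulative_multipliers(
    tf_id: str, truth: PlantedTruth, config: SimulationConfig, effect: float, as_target_of: str | None = None
) -> np.ndarray:
    """Per-condition multiplier path (length n_conditions, starting at 1)."""
    mult = np.ones(len(config.conditions))
    for i, label in enumerate(config.transitions):
        step = 1.0
        d = truth.activity_direction.get(label, {}).get(tf_id)
        if d is not None:
            step = effect ** d
        mult[i + 1] = mult[i] * step
    return mult


def simulate_tf_intensities(
    network: nx.DiGraph, truth: PlantedTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Raw MS intensity table (tf_id, condition, replicate, intensity).

    Intensity = baseline x planted multiplier x multiplicative log-normal
    noise with unit mean and coefficient of variation ``noise_cv``.
    Baselines are log-uniform over three orders of magnitude, reflecting
    the wide, generally low abundance range of TFs.  A planted TF whose
    activity goes up in a transition has an expected between-condition
    ratio of ``tf_effect_fc``; down gives the reciprocal; null TFs ratio 1.
    """
    rng = config.rng("intensity")
    tfs = tf_nodes(network)
    for tf_id in truth.roles:
        if tf_id not in tfs:
            raise ValueError(f"truth role for {tf_id!r} not present in the network")
    lo, hi = config.tf_baseline_log10
    baselines = 10.0 ** rng.uniform(lo, hi, size=len(tfs))
    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
    rows = []
    for tf_id, base in zip(tfs, baselines):
        if tf_id not in truth.roles:
            log.debug("TF %s has no planted role; treated as null", tf_id)
        mult = _cumulative_multipliers(tf_id, truth, config, config.tf_effect_fc)
        for ci, cond in enumerate(config.conditions):
            mean = base * mult[ci]
            for rep in range(1, config.n_replicates + 1):
                noise = rng.lognormal(-sigma**2 / 2.0, sigma) if sigma > 0 else 1.0
                rows.append((tf_id, cond, rep, mean * noise))
    return pd.DataFrame(rows, columns=["tf_id", "condition", "replicate", "intensity"])


def _affected_targets(
    network: nx.DiGraph, truth: PlantedTruth, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, list[str]]:
    """Per planted TF, the target subset that actually responds (the full
    set at the default fraction of 1.0); chosen once so both transitions
    move the same genes."""
    affected: dict[str, list[str]] = {}
    for tf_id in sorted(truth.roles):
        tgts = targets_of(network, tf_id)
        if config.fraction_targets_affected < 1.0:
            k = max(1, int(round(config.fraction_targets_affected * len(tgts))))
            tgts = sorted(map(str, rng.choice(np.array(tgts), size=k, replace=False)))
        affected[tf_id] = tgts
    return affected


def expected_expression_means(
    network: nx.DiGraph, truth: PlantedTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.Series]:
    """Noiseless expression model: expected fragment count per gene per
    condition, and gene lengths in bp.

    Baseline relative abundances are log-uniform; targets of a planted
    activator shift their mean by ``target_effect_fc`` in the direction of
    the TF's activity change, targets of a repressor in the opposite
    direction, cumulatively along the condition order; non-target genes
    keep their baseline.  Means are scaled once (on the first condition) so
    the expected library size matches ``library_size``.
    """
    rng = config.rng("expression_model")
    genes = config.gene_ids
    lo, hi = config.gene_baseline_log10
    base = 10.0 ** rng.uniform(lo, hi, size=len(genes))
    lengths = pd.Series(rng.integers(500, 5001, size=len(genes)), index=genes, name="length_bp")

    gene_pos = {g: i for i, g in enumerate(genes)}
    shift = np.ones((len(genes), len(config.conditions)))
    affected = _affected_targets(network, truth, config, rng)
    for i, label in enumerate(config.transitions):
        step = np.ones(len(genes))
        for tf_id, role in sorted(truth.roles.items()):
            adir = truth.activity_direction[label][tf_id]
            tdir = adir if role == "activator" else -adir
            for g in affected[tf_id]:
                step[gene_pos[g]] *= config.target_effect_fc ** tdir
        shift[:, i + 1] = shift[:, i] * step

    scale = config.library_size / float(base.sum())
    means = pd.DataFrame(
        base[:, None] * shift * scale, index=genes, columns=list(config.conditions)
    )
    return means, lengths


def simulate_expression(
    network: nx.DiGraph, truth: PlantedTruth, config: SimulationConfig
) -> ExpressionMatrix:
    """Fragment counts drawn per replicate from a negative-binomial model
    around :func:`expected_expression_means` (Poisson when ``dispersion``
    is zero), with gene lengths for FPKM alongside."""
    means, lengths = expected_expression_means(network, truth, config)
    rng = config.rng("expression_counts")
    data: dict[str, np.ndarray] = {}
    condition_of: dict[str, str] = {}
    for cond in config.conditions:
        mu = means[cond].to_numpy()
        for rep in range(1, config.n_replicates + 1):
            sample = f"{cond}_r{rep}"
            if config.dispersion > 0:
                size = 1.0 / config.dispersion
                counts = rng.negative_binomial(size, size / (size + mu))
            else:
                counts = rng.poisson(mu)
            data[sample] = counts
            condition_of[sample] = cond
    counts_df = pd.DataFrame(data, index=means.index)
    return ExpressionMatrix(counts_df, lengths, condition_of)


@dataclass
class PharmacologyTables:
    """Compound-target table, PPI edge table and co-activator candidates."""

    compound_targets: pd.DataFrame  # compound_id, target_id, evidence, score
    ppi: pd.DataFrame  # protein_a, protein_b, confidence
    coactivators: list[str]


def generate_pharmacology_tables(
    truth: PlantedTruth,
    config: SimulationConfig,
    coactivator_pool: Sequence[str] | None = None,
    decoy_pool: Sequence[str] | None = None,
    mode: str = "path",
) -> PharmacologyTables:
    """Compound-target and PPI tables consistent with the intended final TFs.

    In the default ``path`` mode every intended final TF is reached by a
    compound -> co-activator drug-target edge plus a co-activator -> TF PPI
    edge with confidence >= 0.5; ``direct`` mode uses a compound -> TF edge
    instead.  Decoy co-activators receive compound edges and low-confidence
    (< 0.5) PPI edges to non-final critical TFs, so the confidence filter
    alone separates intended from decoy routes.  *coactivator_pool* and
    *decoy_pool* supply the bridge and decoy co-activator identities (gene
    ids by default; the orchestrated simulation passes genes that really
    are differentially expressed under treatment, so the co-expression
    filter keeps the bridges).
    """
    if mode not in ("path", "direct"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = config.rng("pharmacology")
    compounds = [f"CMP{i:02d}" for i in range(1, config.n_compounds + 1)]
    final = sorted(truth.final_tfs)
    nonfinal = sorted(truth.coregulated - truth.final_tfs)

    genes = config.gene_ids
    if coactivator_pool is None:
        coactivator_pool = sorted(
            map(str, rng.choice(np.array(genes), size=min(len(genes), config.n_coactivators), replace=False))
        )
    if decoy_pool is None:
        decoy_pool = [g for g in genes if g not in set(coactivator_pool)]

    n_bridge = len(final) if mode == "path" else 0
    if len(coactivator_pool) < n_bridge:
        raise ValueError("coactivator_pool smaller than the number of intended final TFs")
    bridge = list(coactivator_pool[:n_bridge])
    n_decoy = max(0, config.n_coactivators - n_bridge)
    decoy_candidates = [g for g in decoy_pool if g not in set(bridge)]
    decoys = list(decoy_candidates[:n_decoy])

    ct_rows: list[tuple[str, str, str, float]] = []
    ppi_rows: list[tuple[str, str, float]] = []
    for i, tf in enumerate(final):
        compound = compounds[i % len(compounds)]
        if mode == "direct":
            ct_rows.append((compound, tf, "predicted", float(rng.uniform(0.5, 1.0))))
        else:
            x = bridge[i]
            ct_rows.append((compound, x, "predicted", float(rng.uniform(0.5, 1.0))))
            ppi_rows.append((x, tf, float(rng.uniform(0.6, 0.95))))
    for j, x in enumerate(decoys):
        compound = compounds[(j + len(final)) % len(compounds)]
        ct_rows.append((compound, x, "predicted", float(rng.uniform(0.2, 1.0))))
        if nonfinal:
            tf = nonfinal[j % len(nonfinal)]
        elif final:
            tf = final[j % len(final)]
        else:
            continue
        ppi_rows.append((x, tf, float(rng.uniform(0.05, 0.45))))

    compound_targets = pd.DataFrame(
        ct_rows, columns=["compound_id", "target_id", "evidence", "score"]
    ).drop_duplicates(subset=["compound_id", "target_id"], ignore_index=True)
    ppi = pd.DataFrame(ppi_rows, columns=["protein_a", "protein_b", "confidence"])
    return PharmacologyTables(compound_targets, ppi, bridge + decoys)


# ---------------------------------------------------------------------------
# orchestrated simulation

@dataclass
class SimulatedDataset:
    """All generated inputs plus the planted truth, ready to write."""

    config: SimulationConfig
    truth: PlantedTruth
    network: nx.DiGraph
    proteins: dict[str, str]
    intensities: pd.DataFrame
    expression: ExpressionMatrix
    pharmacology: PharmacologyTables

    def write(self, outdir) -> dict[str, str]:
        """Write every input to *outdir*; returns name -> path."""
        from pathlib import Path

        from . import io as cio

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteins": out / "proteins.fasta",
            "intensities": out / "intensities.tsv",
            "expression": out / "expression.tsv",
            "samples": out / "samples.tsv",
            "network": out / "network.gmt",
            "compound_targets": out / "compound_targets.tsv",
            "ppi": out / "ppi.tsv",
            "coactivators": out / "coactivators.txt",
            "truth": out / "truth.json",
        }
        cio.write_fasta(self.proteins, paths["proteins"])
        cio.write_tsv(self.intensities, paths["intensities"])
        cio.write_expression_matrix(self.expression, paths["expression"], paths["samples"])
        cio.write_gmt({tf: targets_of(self.network, tf) for tf in tf_nodes(self.network)}, paths["network"])
        cio.write_tsv(self.pharmacology.compound_targets, paths["compound_targets"])
        cio.write_tsv(self.pharmacology.ppi, paths["ppi"])
        cio.write_id_list(self.pharmacology.coactivators, paths["coactivators"])
        cio.write_json(self.truth.to_json(), paths["truth"])
        return {k: str(v) for k, v in paths.items()}


def simulate_all(config: SimulationConfig) -> SimulatedDataset:
    """Generate the complete input bundle for one study.

    Bridge co-activators are drawn from genes that come out differentially
    expressed in the last transition of the realized expression data
    (preferring targets of the intended final TFs), so that the
    co-expression filter of the pharmacology stage retains them; decoy
    co-activators are drawn from non-DE genes.
    """
    network = generate_regulatory_network(config)
    truth = generate_planted_truth(config, network)
    proteins = generate_protein_fasta(config)
    intensities = simulate_tf_intensities(network, truth, config)
    expression = simulate_expression(network, truth, config)

    fpkm = compute_fpkm(expression)
    cond_a, cond_b = config.conditions[-2], config.conditions[-1]
    fc = gene_fold_changes(fpkm, expression.condition_of, cond_a, cond_b)
    de = flag_de_genes(fc)
    de_genes = de.up | de.down

    final_targets: list[str] = []
    for tf in sorted(truth.final_tfs):
        final_targets.extend(t for t in targets_of(network, tf) if t in de_genes)
    other_de = sorted(de_genes - set(final_targets))
    bridge_pool = list(dict.fromkeys(final_targets)) + other_de
    if len(bridge_pool) < config.n_final_tfs:
        log.warning(
            "only %d DE genes available for %d co-activator bridges; "
            "falling back to planted target genes",
            len(bridge_pool), config.n_final_tfs,
        )
        extra = [
            t for tf in sorted(truth.final_tfs) for t in targets_of(network, tf)
            if t not in set(bridge_pool)
        ]
        bridge_pool += extra
    decoy_pool = [g for g in config.gene_ids if g not in de_genes]

    pharmacology = generate_pharmacology_tables(
        truth, config, coactivator_pool=bridge_pool, decoy_pool=decoy_pool
    )
    return SimulatedDataset(
        config, truth, network, proteins, intensities, expression, pharmacology
    )
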