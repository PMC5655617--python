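"""Critical-TF detection: the permutation test and network operations.

A TF is *critical* when the mean fold change of its target-gene set T shifts
significantly relative to the whole-transcriptome fold-change vector G,
which serves as the null distribution: random gene sets of size |T| are
drawn without replacement from the transcriptome and the empirical p-value
is the add-one fraction of permuted means at least as extreme as the
observed one.  Crossing the target-set direction with the TF's own binding
activity change classifies the regulator: direction-consistent TFs are
activators, direction-inconsistent TFs repressors.  Per-transition networks
of critical TFs and their differentially expressed targets are intersected
to find TFs co-regulated in both transitions (the study's "pink" nodes).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .transcriptome import DEFlags, FoldChangeVector

log = logging.getLogger(__name__)

_REL_EPS = 1e-12  # tolerance when comparing permuted means with the observed one


# ---------------------------------------------------------------------------
# regulatory network container

def make_regulatory_network(targets: Mapping[str, Iterable[str]]) -> nx.DiGraph:
    """Directed TF -> target-gene graph from a mapping of target sets.

    TF nodes get ``kind="tf"``, plain genes ``kind="gene"``; a gene that is
    itself a TF keeps ``kind="tf"`` (dual role).  Self-loops and empty
    target sets are rejected.
    """
    g = nx.DiGraph()
    for tf_id, tgts in targets.items():
        tgts = list(tgts)
        if not tgts:
            raise ValueError(f"TF {tf_id!r} has an empty target set")
        if tf_id in tgts:
            raise ValueError(f"self-loop on {tf_id!r}")
        g.add_node(tf_id, kind="tf")
        for t in tgts:
            if t not in g or g.nodes[t].get("kind") != "tf":
                g.add_node(t, kind="gene")
            g.add_edge(tf_id, t)
    return g


def tf_nodes(network: nx.DiGraph) -> list[str]:
    return sorted(n for n, d in network.nodes(data=True) if d.get("kind") == "tf")


def targets_of(network: nx.DiGraph, tf_id: str) -> list[str]:
    if tf_id not in network:
        raise KeyError(f"TF {tf_id!r} not in network")
    return sorted(network.successors(tf_id))


# ---------------------------------------------------------------------------
# results

@dataclass
class TargetGroupTestResult:
    """Outcome of testing one TF's target set against the transcriptome null."""

    tf_id: str
    transition: str
    n_targets_tested: int
    mean_t: float
    mean_g: float
    direction: str  # up | down | none
    p_value: float
    p_greater: float
    p_less: float
    method: str  # permutation | exhaustive | untestable
    n_permutations: int | None = None
    adjusted_p: float | None = None

    @property
    def testable(self) -> bool:
        return self.method != "untestable"


@dataclass
class CriticalTF:
    """A TF passing both the activity-change and the target-set filters."""

    tf_id: str
    transition: str
    regulator_class: str  # activator | repressor
    tf_status: str  # activated | repressed
    target_direction: str  # up | down
    test: TargetGroupTestResult


@dataclass
class ConditionNetwork:
    """Critical TFs wired to their differentially expressed targets for one
    transition.  Node attributes carry the TF class and the DE direction."""

    transition: str
    graph: nx.DiGraph

    @property
    def tfs(self) -> frozenset[str]:
        return frozenset(
            n for n, d in self.graph.nodes(data=True) if d.get("role") == "tf"
        )

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.graph.edges())


# ---------------------------------------------------------------------------
# subset sampling

def _sample_subsets(rng: np.random.Generator, n: int, k: int, n_sets: int) -> np.ndarray:
    """(n_sets, k) index array; each row a uniform k-subset of range(n),
    sampled without replacement within the row."""
    if not 1 <= k <= n:
        raise ValueError(f"subset size {k} out of range for universe of {n}")
    if k == n:
        return np.tile(np.arange(n), (n_sets, 1))
    if k <= n // 8:
        # rejection sampling on rows with duplicate indices: expected few
        # rounds when k << n, far cheaper than a per-row partial shuffle
        idx = rng.integers(0, n, size=(n_sets, k))
        while True:
            srt = np.sort(idx, axis=1)
            bad = (srt[:, 1:] == srt[:, :-1]).any(axis=1)
            if not bad.any():
                return idx
            idx[bad] = rng.integers(0, n, size=(int(bad.sum()), k))
    keys = rng.random((n_sets, n))
    return np.argpartition(keys, k - 1, axis=1)[:, :k]


def _resolve_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _pvalues_from_null(
    null_means: np.ndarray, mean_t: float, mean_g: float, add_one: bool
) -> tuple[float, float, float]:
    """Two-sided / upper / lower tail probabilities of the observed mean
    under the empirical null of permuted means."""
    obs = mean_t - mean_g
    diffs = null_means - mean_g
    eps = _REL_EPS * max(1.0, abs(obs), float(np.abs(diffs).max(initial=0.0)))
    n = len(null_means)
    r_two = int(np.count_nonzero(np.abs(diffs) >= abs(obs) - eps))
    r_up = int(np.count_nonzero(diffs >= obs - eps))
    r_down = int(np.count_nonzero(diffs <= obs + eps))
    if add_one:
        return (r_two + 1) / (n + 1), (r_up + 1) / (n + 1), (r_down + 1) / (n + 1)
    return r_two / n, r_up / n, r_down / n


def _pick_sided(sided: str, p_two: float, p_up: float, p_down: float) -> float:
    if sided == "two":
        return p_two
    if sided == "greater":
        return p_up
    if sided == "less":
        return p_down
    raise ValueError(f"unknown sidedness {sided!r}")


def _direction(mean_t: float, mean_g: float, p: float, alpha: float) -> str:
    if p <= alpha and mean_t > mean_g:
        return "up"
    if p <= alpha and mean_t < mean_g:
        return "down"
    return "none"


def target_group_test(
    tf_id: str,
    network: nx.DiGraph,
    fc: FoldChangeVector,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    sided: str = "two",
    min_targets: int = 3,
) -> TargetGroupTestResult:
    """Permutation test of the TF's target-set mean fold change against the
    whole-transcriptome null.

    Draws *n_permutations* gene sets of size |T| without replacement from
    the fold-change domain; the empirical p-value uses the add-one
    estimator (r + 1) / (N + 1), so it can never be exactly zero.  The
    direction is the sign of mean(T) - mean(G) when significant at *alpha*.
    TFs with fewer than *min_targets* usable targets yield an ``untestable``
    result rather than an exception; an empty fold-change vector is an error.
    """
    if len(fc) == 0:
        raise ValueError("empty fold-change vector")
    usable = [t for t in targets_of(network, tf_id) if t in fc.ratio.index]
    if len(usable) < min_targets:
        return TargetGroupTestResult(
            tf_id, fc.transition, len(usable), math.nan, math.nan,
            "none", math.nan, math.nan, math.nan, "untestable",
        )
    vals = fc.ratio.to_numpy(dtype=float)
    mean_g = float(vals.mean())
    mean_t = float(fc.ratio[usable].mean())
    k, n = len(usable), len(vals)

    rng = _resolve_rng(seed)
    idx = _sample_subsets(rng, n, k, n_permutations)
    null_means = vals[idx].mean(axis=1)
    p_two, p_up, p_down = _pvalues_from_null(null_means, mean_t, mean_g, add_one=True)
    p = _pick_sided(sided, p_two, p_up, p_down)
    return TargetGroupTestResult(
        tf_id, fc.transition, k, mean_t, mean_g,
        _direction(mean_t, mean_g, p, alpha), p, p_up, p_down,
        "permutation", n_permutations,
    )


def exhaustive_group_test(
    tf_id: str,
    network: nx.DiGraph,
    fc: FoldChangeVector,
    alpha: float = 0.05,
    sided: str = "two",
    min_targets: int = 1,
    max_subsets: int = 1_000_000,
) -> TargetGroupTestResult:
    """Exact version of :func:`target_group_test`: enumerates every gene
    subset of size |T| instead of sampling, so the p-value is the exact
    fraction of subsets with a mean at least as extreme.  Usable only on
    small universes; refuses when C(|G|, |T|) exceeds *max_subsets*."""
    if len(fc) == 0:
        raise ValueError("empty fold-change vector")
    usable = [t for t in targets_of(network, tf_id) if t in fc.ratio.index]
    if len(usable) < min_targets:
        return TargetGroupTestResult(
            tf_id, fc.transition, len(usable), math.nan, math.nan,
            "none", math.nan, math.nan, math.nan, "untestable",
        )
    vals = fc.ratio.to_numpy(dtype=float)
    k, n = len(usable), len(vals)
    total = math.comb(n, k)
    if total > max_subsets:
        raise ValueError(
            f"C({n}, {k}) = {total} subsets exceeds the cap of {max_subsets}"
        )
    mean_g = float(vals.mean())
    mean_t = float(fc.ratio[usable].mean())
    null_means = np.array(
        [vals[list(c)].mean() for c in combinations(range(n), k)]
    )
    p_two, p_up, p_down = _pvalues_from_null(null_means, mean_t, mean_g, add_one=False)
    p = _pick_sided(sided, p_two, p_up, p_down)
    return TargetGroupTestResult(
        tf_id, fc.transition, k, mean_t, mean_g,
        _direction(mean_t, mean_g, p, alpha), p, p_up, p_down,
        "exhaustive", None,
    )


# ---------------------------------------------------------------------------
# classification and detection

def classify_regulator(
    tf_status: str,
    test: TargetGroupTestResult,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> str | None:
    """Cross TF activity direction with target-set direction.

    Consistent directions (activated & targets up, or repressed & targets
    down) make an activator; inconsistent directions a repressor.  Returns
    None when the TF activity is unchanged, the test is untestable or not
    significant, or the target means are tied.
    """
    if tf_status not in ("activated", "repressed"):
        return None
    if not test.testable:
        return None
    p = test.adjusted_p if (use_adjusted and test.adjusted_p is not None) else test.p_value
    if not p <= alpha:
        return None
    if test.mean_t > test.mean_g:
        tgt_dir = "up"
    elif test.mean_t < test.mean_g:
        tgt_dir = "down"
    else:
        return None
    consistent = (tf_status == "activated") == (tgt_dir == "up")
    return "activator" if consistent else "repressor"


def detect_critical_tfs(
    activity_changes: pd.DataFrame,
    network: nx.DiGraph,
    fc: FoldChangeVector,
    alpha: float = 0.05,
    min_targets: int = 3,
    n_permutations: int = 10_000,
    seed: int = 0,
    adjust: str = "none",
    sided: str = "two",
) -> tuple[list[CriticalTF], list[TargetGroupTestResult]]:
    """Run the target-group permutation test for every eligible TF and keep
    those that classify as activator or repressor.

    *activity_changes* is the per-TF table from
    :func:`critfact.proteome.tf_fold_changes` (columns ``tf_id, status``).
    ``adjust="BH"`` applies Benjamini-Hochberg across the testable TFs and
    judges significance on the adjusted p-values.  Per-TF permutation
    streams are spawned deterministically from *seed* in sorted TF order.

    Returns ``(critical_tfs, all_test_results)``.
    """
    if adjust not in ("none", "BH"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    tfs = tf_nodes(network)
    if not tfs:
        log.warning("empty regulatory network; no TFs to test")
        return [], []

    children = np.random.SeedSequence(seed).spawn(len(tfs))
    results: list[TargetGroupTestResult] = []
    for tf_id, child in zip(tfs, children):
        res = target_group_test(
            tf_id, network, fc,
            n_permutations=n_permutations,
            seed=np.random.default_rng(child),
            alpha=alpha, sided=sided, min_targets=min_targets,
        )
        results.append(res)

    testable = [r for r in results if r.testable]
    if adjust == "BH" and testable:
        adj = multipletests([r.p_value for r in testable], method="fdr_bh")[1]
        for r, a in zip(testable, adj):
            r.adjusted_p = float(a)

    status_of = dict(zip(activity_changes["tf_id"], activity_changes["status"]))
    critical: list[CriticalTF] = []
    for res in testable:
        status = status_of.get(res.tf_id)
        if status is None:
            continue
        cls = classify_regulator(status, res, alpha=alpha, use_adjusted=(adjust == "BH"))
        if cls is None:
            continue
        tgt_dir = "up" if res.mean_t > res.mean_g else "down"
        # keep the reported direction consistent with the classification
        res.direction = tgt_dir
        critical.append(CriticalTF(res.tf_id, res.transition, cls, status, tgt_dir, res))
    return critical, results


# ---------------------------------------------------------------------------
# condition networks

def build_condition_network(
    critical_tfs: Sequence[CriticalTF],
    network: nx.DiGraph,
    de_flags: DEFlags,
) -> ConditionNetwork:
    """Wire each critical TF to the subset of its targets that are
    differentially expressed in the same transition; TFs left without a
    single DE target are dropped."""
    if critical_tfs:
        transitions = {c.transition for c in critical_tfs}
        if transitions != {de_flags.transition}:
            raise ValueError(
                f"DE flags are for {de_flags.transition!r} but critical TFs "
                f"are for {sorted(transitions)}"
            )
    g = nx.DiGraph()
    de_genes = de_flags.genes
    for crit in critical_tfs:
        kept = [t for t in targets_of(network, crit.tf_id) if t in de_genes]
        if not kept:
            continue
        g.add_node(
            crit.tf_id, role="tf",
            regulator_class=crit.regulator_class, tf_status=crit.tf_status,
        )
        for t in kept:
            direction = "up" if t in de_flags.up else "down"
            if t not in g or g.nodes[t].get("role") != "tf":
                g.add_node(t, role="target", de_direction=direction)
            g.add_edge(crit.tf_id, t)
    return ConditionNetwork(de_flags.transition, g)


def intersect_networks(
    net_1: ConditionNetwork, net_2: ConditionNetwork
) -> tuple[frozenset[str], nx.DiGraph]:
    """TFs appearing in both condition networks (the co-regulated set) and
    the subgraph of TF->target edges shared by both.  Pure set semantics:
    commutative and idempotent."""
    co_tfs = net_1.tfs & net_2.tfs
    shared = nx.DiGraph()
    for u, v in net_1.edges & net_2.edges:
        shared.add_node(u, **net_1.graph.nodes[u])
        shared.add_node(v, **net_1.graph.nodes[v])
        shared.add_edge(u, v)
    return co_tfs, shared


def degree_comparison(
    network: nx.DiGraph, annotated_set: Iterable[str]
) -> tuple[float, float, float]:
    """Compare undirected node degree between an annotated TF subset (e.g.
    apoptosis-related TFs) and the remaining TFs of a regulatory network.

    Returns (mean degree in-set, mean degree out-of-set, two-sided
    Mann-Whitney U p-value).  The exact U distribution is used when both
    groups have fewer than 20 members, the tie-corrected normal
    approximation otherwise.
    """
    annotated = set(annotated_set)
    tfs = tf_nodes(network)
    unknown = annotated - set(tfs)
    if unknown:
        raise ValueError(f"annotated ids not TF nodes of the network: {sorted(unknown)}")
    und = network.to_undirected(as_view=True)
    deg_in = [und.degree(t) for t in tfs if t in annotated]
    deg_out = [und.degree(t) for t in tfs if t not in annotated]
    if not deg_in or not deg_out:
        raise ValueError("both the annotated and the complement group must be non-empty")
    method = "exact" if max(len(deg_in), len(deg_out)) < 20 else "asymptotic"
    stat = stats.mannwhitneyu(deg_in, deg_out, alternative="two-sided", method=method)
    return float(np.mean(deg_in)), float(np.mean(deg_out)), float(stat.pvalue)


# ---------------------------------------------------------------------------
# tabular views

def test_results_to_frame(results: Sequence[TargetGroupTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tf_id": r.tf_id,
                "transition": r.transition,
                "n_targets_tested": r.n_targets_tested,
                "mean_t": r.mean_t,
                "mean_g": r.mean_g,
                "direction": r.direction,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
                "method": r.method,
            }
            for r in results
        ]
    )


def critical_tfs_to_frame(critical: Sequence[CriticalTF]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tf_id": c.tf_id,
                "transition": c.transition,
                "regulator_class": c.regulator_class,
                "tf_status": c.tf_status,
                "target_direction": c.target_direction,
                "n_targets_tested": c.test.n_targets_tested,
                "mean_t": c.test.mean_t,
                "mean_g": c.test.mean_g,
                "p_value": c.test.p_value,
                "adjusted_p": c.test.adjusted_p,
            }
            for c in critical
        ]
    )
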