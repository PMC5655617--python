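"""Expression matrices, FPKM normalization, fold-change vectors, DE flags.

The downstream detector works on per-gene linear fold changes between two
conditions (the target vector T and the whole-transcriptome vector G).  Fold
changes are computed on FPKM — fragments per kilobase of transcript per
million fragments sequenced — so that gene length and sequencing depth are
normalized out first.  Differential-expression flags either come from an
external caller (e.g. a count-based NB model run upstream) or from a simple
|log2 fold change| threshold stand-in that keeps the simulated pipeline
closed; the provenance of the flags is recorded either way.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample fragment counts (or abundances) with gene lengths.

    Attributes
    ----------
    counts : DataFrame
        Genes on the index, one column per sample; values >= 0.
    lengths : Series
        Gene length in base pairs, same index as ``counts``; values >= 1.
    condition_of : dict
        Sample name -> condition label; every sample column must be mapped.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    condition_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be >= 0")
        if not self.lengths.index.equals(self.counts.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any() or (self.lengths < 1).any():
            raise ValueError("every gene needs a length >= 1 bp")
        unmapped = [s for s in self.counts.columns if s not in self.condition_of]
        if unmapped:
            raise ValueError(f"samples not mapped to a condition: {unmapped}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition_of[s] == condition]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns:
            c = self.condition_of[s]
            if c not in seen:
                seen.append(c)
        return seen


def compute_fpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """FPKM(g, s) = count(g, s) / (length_kb(g) * total_fragments(s) / 1e6).

    Raises ``ValueError`` naming the sample if a library size is zero.
    """
    totals = matrix.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    length_kb = matrix.lengths / 1_000.0
    per_million = totals / 1e6
    return matrix.counts.div(per_million, axis=1).div(length_kb, axis=0)


@dataclass
class FoldChangeVector:
    """Per-gene linear fold change (condition B over A) for one transition,
    with the log2 companion derived from the same ratio."""

    transition: str
    ratio: pd.Series

    def __post_init__(self) -> None:
        if (self.ratio <= 0).any():
            raise ValueError("fold-change ratios must be > 0")

    @property
    def log2(self) -> pd.Series:
        return np.log2(self.ratio)

    @property
    def genes(self) -> pd.Index:
        return self.ratio.index

    def __len__(self) -> int:
        return len(self.ratio)


def gene_fold_changes(
    abundance: pd.DataFrame,
    condition_of: dict[str, str],
    condition_a: str,
    condition_b: str,
    pseudocount: float = 1.0,
) -> FoldChangeVector:
    """Fold change of mean abundance (FPKM) in *condition_b* over
    *condition_a*, with *pseudocount* added to both means for ratio
    stability.  Genes with an undefined mean in either condition are
    excluded and logged."""
    cols_a = [s for s in abundance.columns if condition_of.get(s) == condition_a]
    cols_b = [s for s in abundance.columns if condition_of.get(s) == condition_b]
    if not cols_a:
        raise ValueError(f"no samples for condition {condition_a!r}")
    if not cols_b:
        raise ValueError(f"no samples for condition {condition_b!r}")

    mean_a = abundance[cols_a].mean(axis=1)
    mean_b = abundance[cols_b].mean(axis=1)
    ok = mean_a.notna() & mean_b.notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("%d genes lack abundance in both conditions; excluded", n_dropped)
    ratio = (mean_b[ok] + pseudocount) / (mean_a[ok] + pseudocount)
    return FoldChangeVector(f"{condition_b}_vs_{condition_a}", ratio)


@dataclass(frozen=True)
class DEFlags:
    """Differential-expression call sets for one transition.

    ``provenance`` records whether the flags came from an external caller
    (``external``) or the built-in fold-change threshold (``threshold-standin``).
    """

    transition: str
    up: frozenset[str]
    down: frozenset[str]
    provenance: str

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down DE sets must be disjoint")

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down


def flag_de_genes(
    fc: FoldChangeVector,
    external_flags: DEFlags | None = None,
    log2fc_threshold: float = 1.0,
) -> DEFlags:
    """DE flags for the transition of *fc*.

    With *external_flags* supplied, they are validated against the
    fold-change domain and passed through (provenance ``external``).
    Otherwise genes with |log2 FC| >= *log2fc_threshold* are flagged up or
    down by sign (provenance ``threshold-standin``).
    """
    if external_flags is not None:
        domain = set(fc.genes)
        unknown = sorted((external_flags.up | external_flags.down) - domain)
        if unknown:
            raise ValueError(f"external DE flags reference unknown genes: {unknown}")
        return DEFlags(fc.transition, external_flags.up, external_flags.down, "external")

    lfc = fc.log2
    up = frozenset(lfc.index[lfc >= log2fc_threshold])
    down = frozenset(lfc.index[lfc <= -log2fc_threshold])
    return DEFlags(fc.transition, up, down, "threshold-standin")
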