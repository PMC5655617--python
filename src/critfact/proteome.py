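"""TF binding-activity quantification from raw MS intensities.

Transcription factors pulled down on a concatenated TF-response-element DNA
bait are quantified by mass spectrometry; absolute abundance is estimated by
iBAQ, i.e. the raw protein intensity divided by the number of theoretically
observable tryptic peptides (length 6-30 residues, missed cleavages ignored).
Per-transition activity status is then classified from the ratio of mean iBAQ
values between two conditions: activated above a 2-fold gain, repressed below
a 0.5-fold loss, unchanged otherwise (strict inequalities).
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: the 20 standard one-letter amino-acid codes accepted in protein sequences
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: defaults of the theoretical-peptide length window, in residues
MIN_PEPTIDE_LEN = 6
MAX_PEPTIDE_LEN = 30


def validate_sequence(sequence: str) -> None:
    """Raise ``ValueError`` if *sequence* is empty or contains a residue
    outside the 20 standard amino acids; the error names the position."""
    if not sequence:
        raise ValueError("empty protein sequence")
    for pos, residue in enumerate(sequence):
        if residue not in AMINO_ACIDS:
            raise ValueError(
                f"invalid residue {residue!r} at position {pos} "
                "(expected one of the 20 standard one-letter codes)"
            )


def digest_trypsin(
    sequence: str,
    cleave_after: str = "KR",
    block_before: str = "P",
) -> list[str]:
    """In-silico tryptic digestion with zero missed cleavages.

    Cleaves C-terminal to lysine (K) or arginine (R) unless the following
    residue is proline (P).  The returned peptides partition the input:
    their concatenation equals *sequence* and order is preserved.

    Parameters
    ----------
    sequence : str
        Protein sequence over the 20 standard one-letter codes.
    cleave_after, block_before : str
        Residues after which to cleave and residues that block cleavage
        when they immediately follow the site.  The defaults give the
        standard trypsin rule.
    """
    validate_sequence(sequence)
    peptides: list[str] = []
    start = 0
    last = len(sequence) - 1
    for i, residue in enumerate(sequence):
        if residue in cleave_after and (i == last or sequence[i + 1] not in block_before):
            peptides.append(sequence[start : i + 1])
            start = i + 1
    if start <= last:
        peptides.append(sequence[start:])
    return peptides


def count_theoretical_peptides(
    sequence: str,
    min_len: int = MIN_PEPTIDE_LEN,
    max_len: int = MAX_PEPTIDE_LEN,
) -> int:
    """Number of tryptic peptides with length in ``[min_len, max_len]``
    (bounds inclusive), counted on the zero-missed-cleavage digest."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} exceeds max_len {max_len}")
    return sum(min_len <= len(p) <= max_len for p in digest_trypsin(sequence))


def compute_ibaq(raw_intensity: float, n_theoretical_peptides: int) -> float:
    """iBAQ value: raw MS intensity normalized to the theoretical peptide
    count.  ``n_theoretical_peptides`` must be >= 1; proteins with zero
    observable peptides are non-quantifiable and must be excluded upstream
    (see :func:`build_activity_table`)."""
    if raw_intensity < 0:
        raise ValueError(f"negative raw intensity {raw_intensity}")
    if n_theoretical_peptides < 1:
        raise ValueError(
            "iBAQ undefined for zero theoretical peptides; "
            "the protein is non-quantifiable"
        )
    return raw_intensity / n_theoretical_peptides


def build_activity_table(
    intensities: pd.DataFrame,
    proteins: Mapping[str, str],
    min_len: int = MIN_PEPTIDE_LEN,
    max_len: int = MAX_PEPTIDE_LEN,
) -> pd.DataFrame:
    """Attach theoretical-peptide counts and iBAQ values to a raw intensity
    table.

    Parameters
    ----------
    intensities : DataFrame
        Columns ``tf_id, condition, replicate, intensity``.  Rows sharing the
        same (tf_id, condition, replicate) key — e.g. isoforms mapped to one
        TF — are summed before normalization.
    proteins : mapping
        tf_id -> amino-acid sequence (e.g. from :func:`critfact.io.read_fasta`).

    Returns
    -------
    DataFrame with columns ``tf_id, condition, replicate, raw_intensity,
    n_theoretical_peptides, ibaq``.  TFs without a protein record or with
    zero theoretical peptides are excluded and logged, never silently zeroed.
    """
    required = {"tf_id", "condition", "replicate", "intensity"}
    missing = required - set(intensities.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    if (intensities["intensity"] < 0).any():
        raise ValueError("raw intensities must be >= 0")

    pooled = (
        intensities.groupby(["tf_id", "condition", "replicate"], as_index=False)["intensity"]
        .sum()
        .rename(columns={"intensity": "raw_intensity"})
    )

    n_pep: dict[str, int] = {}
    for tf_id in pooled["tf_id"].unique():
        seq = proteins.get(tf_id)
        if seq is None:
            log.warning("TF %s has no protein record; excluded from iBAQ table", tf_id)
            continue
        n = count_theoretical_peptides(seq, min_len, max_len)
        if n == 0:
            log.warning("TF %s has zero theoretical peptides; non-quantifiable, excluded", tf_id)
            continue
        n_pep[tf_id] = n

    table = pooled[pooled["tf_id"].isin(n_pep)].copy()
    table["n_theoretical_peptides"] = table["tf_id"].map(n_pep).astype(int)
    table["ibaq"] = table["raw_intensity"] / table["n_theoretical_peptides"]
    return table.sort_values(["tf_id", "condition", "replicate"], ignore_index=True)


def classify_tf_status(
    fold_change: float,
    up_threshold: float = 2.0,
    down_threshold: float = 0.5,
) -> str:
    """Classify a TF activity fold change: ``activated`` if strictly above
    *up_threshold*, ``repressed`` if strictly below *down_threshold*, else
    ``unchanged``.  Values sitting exactly on a threshold are unchanged."""
    if not fold_change > 0:
        raise ValueError(f"fold change must be positive, got {fold_change}")
    if fold_change > up_threshold:
        return "activated"
    if fold_change < down_threshold:
        return "repressed"
    return "unchanged"


def tf_fold_changes(
    table: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    floor: float | None = None,
    agg: str = "arithmetic",
    up_threshold: float = 2.0,
    down_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-TF iBAQ fold change of *condition_b* over *condition_a*.

    Replicates are aggregated by the arithmetic mean of iBAQ (``agg
    ="geometric"`` switches to the geometric mean).  Zero condition means
    are replaced by *floor*; when *floor* is None it defaults to half the
    smallest nonzero iBAQ in the table, which keeps ratios finite without
    discarding strong on/off signals.  TFs quantified in only one condition
    are excluded and logged.

    Returns a DataFrame ``tf_id, transition, mean_a, mean_b, fold_change,
    status`` with the transition labelled ``{condition_b}_vs_{condition_a}``.
    """
    for cond in (condition_a, condition_b):
        if cond not in set(table["condition"]):
            raise ValueError(f"condition {cond!r} absent from activity table")
    if agg not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown aggregation {agg!r}")

    sub = table[table["condition"].isin([condition_a, condition_b])]
    if agg == "arithmetic":
        means = sub.groupby(["tf_id", "condition"])["ibaq"].mean().unstack("condition")
    else:
        means = (
            sub.groupby(["tf_id", "condition"])["ibaq"]
            .apply(lambda v: float(np.exp(np.mean(np.log(np.asarray(v) + 1e-300)))))
            .unstack("condition")
        )

    both = means.dropna(subset=[condition_a, condition_b])
    dropped = set(means.index) - set(both.index)
    for tf_id in sorted(dropped):
        log.warning("TF %s not quantified in both conditions; excluded", tf_id)

    if floor is None:
        nonzero = table.loc[table["ibaq"] > 0, "ibaq"]
        floor = float(nonzero.min()) * 0.5 if len(nonzero) else 1.0

    mean_a = both[condition_a].to_numpy(dtype=float)
    mean_b = both[condition_b].to_numpy(dtype=float)
    fc = np.where(mean_b == 0, floor, mean_b) / np.where(mean_a == 0, floor, mean_a)

    transition = f"{condition_b}_vs_{condition_a}"
    out = pd.DataFrame(
        {
            "tf_id": both.index,
            "transition": transition,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
        }
    )
    out["status"] = [classify_tf_status(x, up_threshold, down_threshold) for x in out["fold_change"]]
    return out.sort_values("tf_id", ignore_index=True)
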