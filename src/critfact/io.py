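"""Readers and writers for the pipeline's on-disk formats.

All tables are plain TSV with documented headers, protein sequences are
FASTA, TF target sets are GMT, and the run manifest is JSON.  Writers sort
rows deterministically so that a rerun with the same seed is byte-identical.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .proteome import validate_sequence
from .transcriptome import DEFlags, ExpressionMatrix, FoldChangeVector


# --------------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein records as id -> sequence; sequences are validated against
    the 20 standard amino acids."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        validate_sequence(seq)
        records[rec.id] = seq
    return records


def write_fasta(proteins: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sorted(proteins.items())]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


# ----------------------------------------------------------------------- GMT

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT file of target sets: set name (= TF id), description, members."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "targets") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


# ----------------------------------------------------------------------- TSV

def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> dict[str, list[str]]:
    """TF -> target mapping from a two-plus-column edge-list TSV
    (``source``, ``target``, extra columns ignored)."""
    df = read_tsv(path)
    if not {"source", "target"} <= set(df.columns):
        raise ValueError("edge list needs 'source' and 'target' columns")
    out: dict[str, list[str]] = {}
    for src, tgt in zip(df["source"], df["target"]):
        out.setdefault(str(src), []).append(str(tgt))
    return out


# ------------------------------------------------------------- expression

def write_expression_matrix(matrix: ExpressionMatrix, matrix_path: str | Path, samples_path: str | Path) -> None:
    df = matrix.counts.copy()
    df.insert(0, "length_bp", matrix.lengths)
    df.index.name = "gene_id"
    df.reset_index().to_csv(matrix_path, sep="\t", index=False)
    pd.DataFrame(
        sorted(matrix.condition_of.items()), columns=["sample", "condition"]
    ).to_csv(samples_path, sep="\t", index=False)


def read_expression_matrix(matrix_path: str | Path, samples_path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(matrix_path, sep="\t").set_index("gene_id")
    lengths = df.pop("length_bp")
    smap = pd.read_csv(samples_path, sep="\t")
    condition_of = dict(zip(smap["sample"], smap["condition"]))
    return ExpressionMatrix(df, lengths, condition_of)


# ------------------------------------------------------------- fold changes

def write_fold_changes(fc: FoldChangeVector, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "gene_id": fc.ratio.index,
            "transition": fc.transition,
            "fold_change": fc.ratio.to_numpy(),
            "log2_fold_change": fc.log2.to_numpy(),
        }
    ).sort_values("gene_id", ignore_index=True)
    out.to_csv(path, sep="\t", index=False)


def read_fold_changes(path: str | Path) -> FoldChangeVector:
    df = read_tsv(path)
    transitions = df["transition"].unique()
    if len(transitions) != 1:
        raise ValueError(f"expected one transition per file, found {list(transitions)}")
    ratio = pd.Series(df["fold_change"].to_numpy(), index=df["gene_id"])
    return FoldChangeVector(str(transitions[0]), ratio)


# ---------------------------------------------------------------- DE flags

def write_de_flags(flags: DEFlags, path: str | Path) -> None:
    rows = [(g, "up") for g in sorted(flags.up)] + [(g, "down") for g in sorted(flags.down)]
    df = pd.DataFrame(rows, columns=["gene_id", "direction"])
    df.insert(1, "transition", flags.transition)
    df["provenance"] = flags.provenance
    df.to_csv(path, sep="\t", index=False)


def read_de_flags(path: str | Path, transition: str | None = None) -> DEFlags:
    df = read_tsv(path)
    if transition is None:
        transitions = df["transition"].unique()
        if len(transitions) != 1:
            raise ValueError(f"expected one transition per file, found {list(transitions)}")
        transition = str(transitions[0])
    else:
        df = df[df["transition"] == transition]
    provenance = str(df["provenance"].iloc[0]) if len(df) else "external"
    up = frozenset(df.loc[df["direction"] == "up", "gene_id"])
    down = frozenset(df.loc[df["direction"] == "down", "gene_id"])
    return DEFlags(transition, up, down, provenance)


# -------------------------------------------------------------------- misc

def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in sorted(set(ids)):
            fh.write(f"{i}\n")


def read_id_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
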