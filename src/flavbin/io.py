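"""Readers and writers for the pipeline's file formats.

Scaffolds travel as FASTA (wrapped at 60 columns); read alignments,
annotations and pangenome counts as TSV. Coordinates are 0-based
half-open everywhere in memory and in the TSV schemas.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")
_SEASONS = {"summer", "winter"}


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: sequence}; lowercase is uppercased with a warning.

    Raises ``ValueError`` on characters outside A/C/G/T/N, naming the
    offending record.
    """
    out: dict[str, str] = {}
    warned = False
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper() and not warned:
            logger.warning("%s: lowercase bases uppercased", rec.id)
            warned = True
        seq = seq.upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} has invalid characters {sorted(bad)}"
            )
        if rec.id in out:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    """Write sequences as FASTA, line-wrapped at 60 columns."""
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_alignment_table(
    path: str | Path, scaffolds: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read and validate a read-alignment TSV.

    Checks: required columns present, unique read ids, nonnegative
    coordinates with start < end, known season tokens, and (when
    ``scaffolds`` is given) that every read maps to a known scaffold and
    lies within it. Errors name the offending row (1-based, excluding the
    header).
    """
    from .simulate import READ_COLUMNS

    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "scaffold_id": str})
    missing = [c for c in READ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dup = df["read_id"].duplicated()
    if dup.any():
        row = int(dup.idxmax()) + 1
        raise ValueError(
            f"{path}: duplicate read_id {df.at[dup.idxmax(), 'read_id']!r} at row {row}"
        )
    for i, r in enumerate(df.itertuples(index=False), start=1):
        if r.start < 0 or r.end <= r.start:
            raise ValueError(f"{path}: bad coordinates at row {i} ({r.read_id})")
        if r.season not in _SEASONS:
            raise ValueError(f"{path}: bad season token {r.season!r} at row {i}")
        if scaffolds is not None:
            if r.scaffold_id not in scaffolds:
                raise ValueError(
                    f"{path}: row {i} references unknown scaffold {r.scaffold_id!r}"
                )
            if r.end > len(scaffolds[r.scaffold_id]):
                raise ValueError(
                    f"{path}: row {i} read {r.read_id} extends beyond scaffold "
                    f"{r.scaffold_id} ({r.end} > {len(scaffolds[r.scaffold_id])})"
                )
        if len(r.sequence) != r.end - r.start:
            raise ValueError(
                f"{path}: row {i} sequence length != span for {r.read_id}"
            )
    return df


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Per-CDS annotation TSV (coordinates, product, taxon, family ids)."""
    df = pd.read_csv(path, sep="\t", dtype={"cds_id": str, "scaffold_id": str})
    df["family_ids"] = df["family_ids"].fillna("")
    if "is_marker" in df.columns:
        df["is_marker"] = df["is_marker"].astype(bool)
    bad = df[df["start"] >= df["end"]]
    if not bad.empty:
        raise ValueError(f"{path}: start >= end for {list(bad['cds_id'])}")
    return df


def read_pangenome_counts(path: str | Path) -> pd.DataFrame:
    """Genome x family occurrence counts (wide TSV, genomes as rows)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative occurrence counts")
    return df.astype(int)


def read_bin_table(path: str | Path) -> dict[str, list[str]]:
    """bin_id/scaffold_id TSV -> {bin_id: [scaffold ids]}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.bin_id, []).append(r.scaffold_id)
    return out


def write_bin_table(bins: dict[str, list[str]], path: str | Path) -> None:
    rows = [
        {"bin_id": b, "scaffold_id": s} for b in sorted(bins) for s in bins[b]
    ]
    pd.DataFrame(rows, columns=["bin_id", "scaffold_id"]).to_csv(
        path, sep="\t", index=False
    )
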