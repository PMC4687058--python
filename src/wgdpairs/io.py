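"""Readers and writers for the external formats the pipeline consumes.

All genomic coordinates are held internally as 0-based half-open intervals;
GFF3 input (1-based, closed) is converted on read.  Readers are total on this
module's writers' output (round-trip property).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

_DNA_RE = re.compile(r"^[ACGTN]*$")
_PEP_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX*]*$")

HIT_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "align_len", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
]


@dataclass
class SequenceRecord:
    """A contig/gene with its CDS, derived peptide and genomic placement."""

    id: str
    cds: str = ""
    peptide: str = ""
    chromosome: str | None = None
    start: int | None = None  # 0-based
    end: int | None = None  # half-open
    strand: str | None = None

    @property
    def length(self) -> int:
        return len(self.cds)

    @property
    def placed(self) -> bool:
        return self.chromosome is not None and self.start is not None


@dataclass
class HitRecord:
    """One row of an all-vs-all similarity table (12-column tabular dialect)."""

    query_id: str
    subject_id: str
    pct_identity: float = 100.0
    align_len: int = 0
    mismatches: int = 0
    gap_opens: int = 0
    q_start: int = 1
    q_end: int = 0
    s_start: int = 1
    s_end: int = 0
    evalue: float = 0.0
    bitscore: float = 0.0


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, *, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased.  Duplicate identifiers and characters outside
    the alphabet (DNA: A/C/G/T/N, peptide: the 20 residues plus X/*) raise
    ``ValueError`` naming the offending record.
    """
    pattern = _DNA_RE if alphabet == "dna" else _PEP_RE
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not pattern.match(seq):
            raise ValueError(f"record {rec.id!r}: invalid {alphabet} character")
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        if alphabet == "dna":
            records.append(SequenceRecord(id=rec.id, cds=seq))
        else:
            records.append(SequenceRecord(id=rec.id, peptide=seq))
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, *, what: str = "cds"
) -> None:
    """Write CDS (``what="cds"``) or peptide (``what="peptide"``) FASTA."""
    bio = [
        _BioSeqRecord(Seq(getattr(r, what)), id=r.id, description="")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta-2line")


# ---------------------------------------------------------------------------
# Tabular similarity hits


def read_hits_tabular(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tab-separated similarity table (BLAST outfmt-6
    dialect).  ``#`` comment lines are skipped; a row with the wrong column
    count raises ``ValueError`` with its line number."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(fields)}"
                )
            hits.append(
                HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    align_len=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
    return hits


def write_hits_tabular(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id, h.subject_id, h.pct_identity, h.align_len,
                        h.mismatches, h.gap_opens, h.q_start, h.q_end,
                        h.s_start, h.s_end, h.evalue, h.bitscore,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Genomic positions


@dataclass
class Position:
    chromosome: str
    start: int  # 0-based
    end: int  # half-open
    strand: str | None = None


def read_positions(path: str | Path, dialect: str = "bed") -> dict[str, Position]:
    """Read gene placements from BED (0-based half-open) or GFF3 (1-based
    closed, converted on read).  Returns id -> :class:`Position`."""
    if dialect not in {"bed", "gff3"}:
        raise ValueError(f"unknown positions dialect {dialect!r}")
    out: dict[str, Position] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if dialect == "bed":
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 else f"{chrom}:{start}-{end}"
                strand = f[5] if len(f) > 5 else None
            else:
                if len(f) < 9:
                    raise ValueError(f"{path}: line {lineno}: short GFF3 line")
                chrom, start, end = f[0], int(f[3]) - 1, int(f[4])
                strand = f[6] if f[6] in "+-" else None
                m = re.search(r"(?:^|;)ID=([^;]+)", f[8])
                name = m.group(1) if m else f"{chrom}:{start}-{end}"
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: end <= start")
            out[name] = Position(chrom, start, end, strand)
    return out


def write_bed(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            if not r.placed:
                continue
            fh.write(
                f"{r.chromosome}\t{r.start}\t{r.end}\t{r.id}\t0\t{r.strand or '+'}\n"
            )


def attach_positions(
    records: Iterable[SequenceRecord], positions: dict[str, Position]
) -> None:
    for r in records:
        pos = positions.get(r.id)
        if pos is not None:
            r.chromosome, r.start, r.end, r.strand = (
                pos.chromosome, pos.start, pos.end, pos.strand,
            )


# ---------------------------------------------------------------------------
# Matrices, sample sheets, GO maps, config


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Counts (or any gene x sample) matrix with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet with columns sample, tissue, genotype, replicate."""
    df = pd.read_csv(path, sep="\t", dtype={"genotype": str})
    return df.set_index("sample")


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample")


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column gene -> GO-term TSV (one term per row)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            out.setdefault(gene, set()).add(term)
    return out


def write_go_map(go_map: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(go_map):
            for term in sorted(go_map[gene]):
                fh.write(f"{gene}\t{term}\n")


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}
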