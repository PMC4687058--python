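"""Assembly filtering cascade: length, expression (FPKM) and ORF filters.

Each filter is a pure predicate, so the retained set is order-insensitive;
the report counts follow the fixed order length -> expression -> ORF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .genetics import CODON_TABLE, revcomp, translate
from .io import SequenceRecord

FPKM_RULES = ("any", "all", "mean")


@dataclass
class Orf:
    start: int  # 0-based, on the forward strand of the input sequence
    end: int  # half-open
    frame: int  # 1..3 forward, -1..-3 reverse
    peptide: str

    @property
    def n_codons(self) -> int:
        return (self.end - self.start) // 3 - 1  # excludes the stop codon


@dataclass
class FilterReport:
    n_input: int = 0
    n_after_length: int = 0
    n_after_expression: int = 0
    n_after_orf: int = 0
    reasons: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input", self.n_input),
            ("after_length", self.n_after_length),
            ("after_expression", self.n_after_expression),
            ("after_orf", self.n_after_orf),
        ]
        return pd.DataFrame(rows, columns=["stage", "n_contigs"])


def filter_by_length(contigs: list[SequenceRecord], min_len: int = 500
                     ) -> list[SequenceRecord]:
    """Keep contigs with sequence length >= ``min_len`` (inclusive)."""
    return [c for c in contigs if len(c.cds) >= min_len]


def filter_by_expression(contigs: list[SequenceRecord], fpkm: pd.DataFrame,
                         min_fpkm: float = 1.0, rule: str = "any"
                         ) -> list[SequenceRecord]:
    """Keep contigs whose FPKM reaches ``min_fpkm`` (inclusive) under ``rule``:
    in at least one sample (``any``, default), in every sample (``all``) or on
    the across-sample mean (``mean``).  Contigs absent from the table count as
    zero, with a warning."""
    if rule not in FPKM_RULES:
        raise ValueError(f"unknown FPKM rule {rule!r}")
    if min_fpkm <= 0:
        return list(contigs)
    kept = []
    missing = []
    for c in contigs:
        if c.id not in fpkm.index:
            missing.append(c.id)
            continue
        values = fpkm.loc[c.id]
        if rule == "any":
            ok = (values >= min_fpkm).any()
        elif rule == "all":
            ok = (values >= min_fpkm).all()
        else:
            ok = values.mean() >= min_fpkm
        if ok:
            kept.append(c)
    if missing:
        warnings.warn(
            f"{len(missing)} contig(s) missing from the FPKM table; treated as 0"
        )
    return kept


def find_orf(sequence: str, min_codons: int = 100) -> Orf | None:
    """Longest ATG-to-stop open reading frame across all six frames.

    The ORF must contain at least ``min_codons`` codons from the ATG through
    the codon before the stop, and must terminate at a stop codon.  Returns
    ``None`` when no qualifying ORF exists.  Coordinates are on the forward
    strand of the input; reverse-strand ORFs have negative frames.
    """
    seq = sequence.upper()
    n = len(seq)
    best: Orf | None = None

    def scan(s: str, reverse: bool) -> None:
        nonlocal best
        for off in range(3):
            i = off
            start = None
            while i + 3 <= len(s):
                codon = s[i : i + 3]
                aa = CODON_TABLE.get(codon, "X")
                if start is None:
                    if codon == "ATG":
                        start = i
                elif aa == "*":
                    n_codons = (i - start) // 3
                    if n_codons >= min_codons:
                        end = i + 3
                        if reverse:
                            fwd_start, fwd_end = n - end, n - start
                            frame = -(off + 1)
                        else:
                            fwd_start, fwd_end = start, end
                            frame = off + 1
                        pep = translate(s[start:end])
                        cand = Orf(fwd_start, fwd_end, frame, pep)
                        if best is None or (cand.end - cand.start) > (best.end - best.start):
                            best = cand
                    start = None
                i += 3
            # an ORF running off the end without a stop does not qualify

    scan(seq, reverse=False)
    scan(revcomp(seq), reverse=True)
    return best


def apply_filters(contigs: list[SequenceRecord], fpkm: pd.DataFrame,
                  min_len: int = 500, min_fpkm: float = 1.0,
                  fpkm_rule: str = "any", min_orf_codons: int = 100
                  ) -> tuple[list[SequenceRecord], FilterReport]:
    """Full cascade.  Retained records get their ORF peptide attached; the
    report carries per-contig rejection reasons for the first failing filter."""
    report = FilterReport(n_input=len(contigs))
    by_len = filter_by_length(contigs, min_len)
    report.n_after_length = len(by_len)
    for c in contigs:
        if c not in by_len:
            report.reasons[c.id] = "length"

    by_expr = filter_by_expression(by_len, fpkm, min_fpkm, fpkm_rule)
    report.n_after_expression = len(by_expr)
    kept_ids = {c.id for c in by_expr}
    for c in by_len:
        if c.id not in kept_ids:
            report.reasons[c.id] = "expression"

    retained = []
    for c in by_expr:
        orf = find_orf(c.cds, min_codons=min_orf_codons)
        if orf is None:
            report.reasons[c.id] = "no_orf"
            continue
        if not c.peptide:
            c.peptide = orf.peptide
        retained.append(c)
    report.n_after_orf = len(retained)
    return retained, report
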