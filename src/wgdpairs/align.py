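"""Pairwise peptide alignment, back-translation and 4D-site location.

Peptides are aligned globally (affine gaps, BLOSUM62; a gap of length L costs
``gap_open + gap_extend * L``) and the alignment is back-translated onto the
source CDSs, replacing each residue by its codon and each gap by ``---``.
A column yields a fourfold-degenerate (4D) site when both codons are
ungapped, their first two bases agree, and that shared prefix is one of the
eight codon families whose third position is fourfold degenerate; the site
is the pair of third-position bases.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .genetics import FOURFOLD_PREFIXES, STOP_CODONS, codons_of, translate

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
GAP_CODON = "---"


@dataclass
class CodonAlignment:
    """Aligned codon columns for one pair (triplet or ``---`` per sequence)."""

    id_a: str
    id_b: str
    codons_a: list[str]
    codons_b: list[str]

    def __len__(self) -> int:
        return len(self.codons_a)

    def ungapped_columns(self) -> list[tuple[str, str]]:
        return [
            (ca, cb)
            for ca, cb in zip(self.codons_a, self.codons_b)
            if ca != GAP_CODON and cb != GAP_CODON
        ]


def make_aligner(gap_open: float = 10.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    # Biopython charges open+extend*(L-1); shifting open by one extend gives
    # the gap cost convention open + extend*L used here.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_peptides(pep_a: str, pep_b: str, gap_open: float = 10.0,
                   gap_extend: float = 1.0) -> tuple[str, str, float]:
    """Global affine-gap alignment of two peptides.

    Returns the two gapped strings and the alignment score.  Raises
    ``ValueError`` on empty input or residues outside the 20 standard amino
    acids."""
    for name, pep in (("a", pep_a), ("b", pep_b)):
        if not pep:
            raise ValueError(f"peptide {name} is empty")
        bad = set(pep) - _VALID_RESIDUES
        if bad:
            raise ValueError(f"peptide {name}: invalid residue(s) {sorted(bad)}")
    aligner = make_aligner(gap_open, gap_extend)
    alignment = aligner.align(pep_a, pep_b)[0]
    return str(alignment[0]), str(alignment[1]), float(alignment.score)


def _strip_terminal_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def back_translate(aln_a: str, aln_b: str, cds_a: str, cds_b: str,
                   id_a: str = "a", id_b: str = "b") -> CodonAlignment:
    """Replace each aligned residue by its source codon (gaps by ``---``).

    Terminal stop codons are stripped from the CDSs first; each CDS must then
    translate exactly to its ungapped peptide."""
    if len(aln_a) != len(aln_b):
        raise ValueError("aligned peptides differ in length")
    cols_a, cols_b = [], []
    for aln, cds, cols, gid in ((aln_a, cds_a, cols_a, id_a),
                                (aln_b, cds_b, cols_b, id_b)):
        coding = _strip_terminal_stop(cds)
        pep = aln.replace("-", "")
        if len(coding) != 3 * len(pep):
            raise ValueError(
                f"{gid}: CDS length {len(coding)} does not match peptide "
                f"length {len(pep)} x 3"
            )
        if translate(coding, strip_terminal_stop=False) != pep:
            raise ValueError(f"{gid}: CDS does not translate to the aligned peptide")
        codons = codons_of(coding)
        if any(c in STOP_CODONS for c in codons):
            raise ValueError(f"{gid}: internal stop codon")
        it = iter(codons)
        for res in aln:
            cols.append(GAP_CODON if res == "-" else next(it))
    return CodonAlignment(id_a=id_a, id_b=id_b, codons_a=cols_a, codons_b=cols_b)


def find_4d_sites(aln: CodonAlignment) -> list[tuple[int, str, str]]:
    """(column, base_a, base_b) for every fourfold-degenerate site.

    Requires both codons ungapped and unambiguous, identical two-base
    prefixes, and the prefix in one of the eight 4D families; the degeneracy
    class of the third position is otherwise ambiguous between the sequences.
    """
    sites = []
    for i, (ca, cb) in enumerate(zip(aln.codons_a, aln.codons_b)):
        if ca == GAP_CODON or cb == GAP_CODON:
            continue
        if "N" in ca or "N" in cb:
            continue
        if ca[:2] != cb[:2] or ca[:2] not in FOURFOLD_PREFIXES:
            continue
        sites.append((i, ca[2], cb[2]))
    return sites


def codon_alignment_for_pair(cds_a: str, cds_b: str, id_a: str = "a",
                             id_b: str = "b", gap_open: float = 10.0,
                             gap_extend: float = 1.0) -> CodonAlignment:
    """Translate, align and back-translate one CDS pair."""
    pep_a = translate(cds_a)
    pep_b = translate(cds_b)
    aln_a, aln_b, _ = align_peptides(pep_a, pep_b, gap_open, gap_extend)
    return back_translate(aln_a, aln_b, cds_a, cds_b, id_a=id_a, id_b=id_b)
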