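"""Standard genetic code tables and small nucleotide utilities.

The standard (nuclear) code is hard-coded: the organisms of interest are
plants and all coding sequences handled here are nuclear genes.
"""

from __future__ import annotations

CODON_TABLE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c, aa in CODON_TABLE.items() if aa != "*"))

#: Two-base prefixes whose four codons all encode the same amino acid, i.e.
#: the codon families with a fourfold-degenerate (4D) third position.
FOURFOLD_PREFIXES = frozenset(
    {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}
)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: The unique transition partner of each base.
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
#: The two transversion partners of each base.
TRANSVERSIONS = {"A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G")}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_transversion(a: str, b: str) -> bool:
    """True when the two bases differ and belong to different chemical classes
    (one purine, one pyrimidine)."""
    if a == b:
        return False
    return (a in PURINES) != (b in PURINES)


def is_transition(a: str, b: str) -> bool:
    return a != b and (a in PURINES) == (b in PURINES)


def translate(cds: str, *, strip_terminal_stop: bool = True) -> str:
    """Translate a CDS with the standard code.

    ``N``-containing codons translate to ``X``.  Raises ``ValueError`` when the
    length is not a multiple of three.  A single terminal stop codon is dropped
    when ``strip_terminal_stop`` is set; internal stops translate to ``*`` and
    are left for callers to reject where they are illegal.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        aa = CODON_TABLE.get(codon)
        if aa is None:
            if "N" in codon:
                aa = "X"
            else:
                raise ValueError(f"unknown codon {codon!r} at position {i}")
        aas.append(aa)
    if strip_terminal_stop and aas and aas[-1] == "*":
        aas.pop()
    return "".join(aas)


def codons_of(cds: str) -> list[str]:
    """Split a CDS into codons; length must be a multiple of three."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]
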