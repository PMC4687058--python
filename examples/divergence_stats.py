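"""Divergence statistics for one duplicate pair.

Aligns the peptides of two coding sequences, back-translates to a codon
alignment, and prints 4DTV (raw and multiple-hit corrected) and NG86
Ka, Ks and Ka/Ks.
"""

from wgdpairs.align import codon_alignment_for_pair, find_4d_sites
from wgdpairs.divergence import pair_divergence

# two short paralogous CDSs: a few synonymous third-position changes and one
# nonsynonymous change (GCT Ala -> TCT Ser)
cds_a = "ATGGGAGCTCTTCGAACCGGAGTATTA" + "TAA"
cds_b = "ATGGGTTCTCTCCGAACGGGAGTGTTA" + "TAA"

aln = codon_alignment_for_pair(cds_a, cds_b, id_a="copyA", id_b="copyB")
sites = find_4d_sites(aln)
est = pair_divergence(aln)

print("codon alignment:", list(zip(aln.codons_a, aln.codons_b)))
print(f"4D sites: {len(sites)} -> {sites}")
print(f"raw 4DTV      = {est.four_dtv_raw:.4f}")
print(f"corrected 4DTV= {est.four_dtv_corr:.4f}")
print(f"Ka = {est.ka:.4f}  Ks = {est.ks:.4f}  Ka/Ks = {est.omega:.3f}")

# The transversion proportion at fourfold-degenerate sites dates the
# duplication; Ka/Ks well below 1 indicates purifying selection on the
# protein sequence.
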