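"""Fold an RNA hairpin and locate the miRNA* partner of a mature miRNA.

The folder maximizes helix stacking (G:C -3, A:U -2, G:U -1 kcal/mol per
stacked pair, averaged across a stack) over all nested structures; the star
is the segment pairing mature positions 1..L-2 with 2-nt 3' overhangs on
both strands — the geometry a Dicer-like enzyme leaves behind.
"""

from plantmir import HairpinCandidate, find_star, fold_rna
from plantmir.preprocess import Locus

from plantmir.seqtools import revcomp

mature = "CUGUUAUGAAUUGAUGGAGUG"
arm5 = "GC" + mature + "GUUAC"  # 2 nt below the duplex, 5 toward the loop
precursor = arm5 + "GAAUAAUC" + revcomp(arm5)
structure, mfe = fold_rna(precursor)
print(precursor)
print(structure)
print(f"MFE = {mfe} kcal/mol (model energy; more negative = more stable)")

hairpin = HairpinCandidate(
    precursor, Locus("scaffold_1", 1, len(precursor), "+"),
    structure, mfe, mature_offset=2, mature_length=21,
)
star, offset = find_star(hairpin)
print(f"\nmature: {hairpin.mature} (5' arm)")
print(f"star:   {star} at precursor offset {offset}")
# A stable fold (MFE well below -30) plus a recoverable star with the 2-nt
# overhang geometry is what qualifies a candidate under the plant criteria.
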