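"""Decompose the seven recorded minisatellite alleles into motif units.

Builds each allele from its unit composition, decomposes the raw DNA back
into units, and prints the haplotype table — including the size homoplasy
between haplotypes 1 and 7 (equal length, different unit content), which is
invisible to fragment-length genotyping.
"""

from phoenixbarcode import decompose, enumerate_recorded_haplotypes
from phoenixbarcode.minisat import M1, M2
from phoenixbarcode.reference import revcomp

print(f"motif 1: {M1}\nmotif 2: {M2}")
print(f"reverse-complement(M1) == M2 rotated by 4: {revcomp(M1) == M2[-4:] + M2[:-4]}\n")

print(f"{'hap':>3}  {'units':<18} {'bp':>3}  sequence")
for hap, seq in enumerate(enumerate_recorded_haplotypes(), start=1):
    allele = decompose(seq)
    print(f"{hap:>3}  {str(allele):<18} {allele.length_bp:>3}  {seq}")

h1, h7 = enumerate_recorded_haplotypes()[0], enumerate_recorded_haplotypes()[6]
print(
    f"\nsize homoplasy: haplotypes 1 and 7 are both {len(h1)} bp "
    f"but identical? {h1 == h7}"
)
# Each line above is one allele of the tandem repeat; 'units' is the ordered
# motif tiling (P5 is the 5 bp partial unit of haplotype 6) and 'bp' its length.
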