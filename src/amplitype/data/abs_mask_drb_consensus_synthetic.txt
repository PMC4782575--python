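# Synthetic consensus-derived antigen-binding-site mask for a 57-codon
# class-II DRB exon-2 window (1-based codon indices; 15 positions).
# Approximates the human DRB1 peptide-contact residues that fall inside
# this window.  Override with a locus-specific mask file for real
# analyses; the ABS/non-ABS partition is only as good as this mask.
5
9
11
13
16
26
28
30
32
36
37
38
47
56
57
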