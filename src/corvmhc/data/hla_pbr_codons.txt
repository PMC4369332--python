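# Default peptide-binding-region codon positions (1-based) within the
# 82-codon class IIB exon-2 fragment. Derived from the human class II
# beta-1 domain contact residues (Brown et al. crystal-structure
# mapping) assuming the fragment starts at beta-1 position 4, i.e.
# fragment codon i = beta-1 position i + 3. Edit or replace this file
# to use a different mapping; every PBR-dependent result is computed
# relative to the supplied site set.
6 8 10 23 25 27 29 34 35 44 53
54 57 58 62 64 65 67 68 71 75 78
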