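"""The approximated information distance (AID) and its closed form.

AID between two sequence sets is the fraction of non-shared distinct k-mers
among all distinct k-mers occurring in either set.  Because an FCGR's support
equals its distinct-k-mer count, AID is computable directly from signatures:
d = 2 - (#F + #G) / #(F + G).  Both routes are shown to agree here.
"""

from addsig import additive_signature, aid, fcgr, generalized_aid

contigs = ["AAAA", "CCCC", "GGGG", "TTTT"]
sequence = "AAAACCCCGGGGTTTT"
k = 3

F = additive_signature(contigs, k)   # the contig set's additive signature
G = fcgr(sequence, k)                # the full sequence's conventional signature

print(f"contig set: {contigs}  -> #F = {F.support} distinct 3-mers")
print(f"sequence:   {sequence} -> #G = {G.support} distinct 3-mers")
print(f"AID via closed form   2 - (#F + #G)/#(F + G) = {aid(F, G)}")
print(f"AID via k-mer sets    (set-difference form)  = "
      f"{generalized_aid(contigs, [sequence], k)}")
# 0.6: of the 10 distinct 3-mers in the full sequence, only the 4 homopolymer
# 3-mers survive in the contig set; the 6 junction-spanning 3-mers are the
# information the partition loses.
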