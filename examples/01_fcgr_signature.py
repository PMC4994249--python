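"""Build a conventional DNA signature (FCGR) and inspect its structure.

The FCGR of order k is a 2^k x 2^k matrix whose cells count the occurrences
of every k-mer, arranged by the Chaos Game Representation grid.  Its total is
|s| - k + 1 (every window counted once) and its support (#FCGR, the number of
non-zero cells) is the number of distinct k-mers.
"""

from addsig import fcgr, kmer_set, kmer_to_cell

s = "AAAACCCCGGGGTTTT"
k = 3
F = fcgr(s, k)

print(f"sequence: {s}  (length {len(s)})")
print(f"FCGR order k={k}: {2**k}x{2**k} grid")
print(f"total k-mer occurrences: {F.total}   (= |s| - k + 1 = {len(s) - k + 1})")
print(f"support (#FCGR, distinct k-mers): {F.support}")
print(f"distinct 3-mers: {sorted(kmer_set(s, k).members)}")
print(f"grid cell of 'AAA' (row, col): {kmer_to_cell('AAA')}  "
      f"count there: {F.counts[kmer_to_cell('AAA')]}")
# The 10 distinct 3-mers occupy 10 cells; homopolymer runs pile counts into
# the grid corners, which is what makes CGR patterns species-recognisable.
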