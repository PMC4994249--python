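# Methods

## Signatures

A DNA sequence over {A, C, G, T} is mapped by the Chaos Game Representation
(CGR) into the unit square: starting at the centre, each nucleotide moves the
current point halfway towards the corner labelled with that nucleotide. We
adopt Jeffrey's corner convention — A = (0, 0), C = (0, 1), G = (1, 1),
T = (1, 0) — which the distances in this package are invariant to (only the
orientation of rendered patterns depends on it). Dividing the square into a
2^k × 2^k grid and counting points per cell gives the order-k FCGR; cell
contents are exactly k-mer occurrence counts, because the CGR point after
reading a k-mer lies in the quadrant of its last nucleotide, the sub-quadrant
of its second-to-last, and so on. We exploit that structure directly: the
k-mer ↔ cell bijection is computed by integer bit-interleaving of per-
nucleotide half-plane bits (character j of the k-mer contributes bit j of the
cell's x and y coordinates), never by floating-point midpoint simulation, so
cell assignment has no boundary-rounding ambiguity. Grid indexing is
row 0 = top, column 0 = left. A test cross-checks the arithmetic against an
exact rational-arithmetic simulation of the midpoint walk.

The additive signature of a sequence set is the elementwise sum of the
members' FCGRs. Composite signatures (optionally weighted) sum signatures of
different DNA types of one organism — e.g. a nuclear fragment plus an
organellar genome. A fully-assembled signature partitions a sequence into
⌊|s|/n⌋ consecutive length-n contigs (remainder < n discarded) and sums their
FCGRs; an assembled signature instead samples r contig start positions
independently and uniformly **with replacement** over [1, |s| − n + 1]
(contigs may overlap or repeat; the sampling scheme is a package choice, as
only "random" placement is inherent to the definition). When a coverage
fraction t is given instead of r, the contig count is q = ⌊t·|s|/n⌋. The
variable-length mode draws each contig length from N(μ = n, σ = 40 bp),
rounds to the nearest integer and clamps to [k, |s| − start]; rounding and
clamping are package choices.

Both partition-based constructions are computed on a single windowed cell
array per sequence (each contig selects an index range), so an assembled
signature costs O(|s| + r·n) regardless of r.

## Distances

The approximated information distance (AID) between sequence sets S and T is
the number of distinct k-mers occurring in exactly one of the two sets,
divided by the number occurring in either. Because an FCGR's support
(#F, its non-zero-cell count) equals the distinct-k-mer count of its set, AID
has the closed form d = 2 − (#F + #G)/#(F + G), which is how `aid` computes
it: numerator and denominator are exact integers, and only the final division
is floating point. `generalized_aid` evaluates the set-theoretic definition
on explicit k-mer sets; the two routes are independent code paths and agree
bit-for-bit (tested on hundreds of random instances). AID between a
fully-assembled and a conventional signature of the same sequence is bounded
by min{(r − 1)(k − 1), m}/m with m the sequence's distinct-k-mer count: only
k-mers spanning the r − 1 contig junctions can be lost, at most k − 1 per
junction. The bound presumes the contigs partition the sequence exactly
(no tail); a discarded tail can contribute additional missing k-mers beyond
the junction count, so the bound tests use |s| = r·n.

The four magnitude-based metrics (Euclidean, Manhattan, Pearson distance,
DSSIM) operate on frequency-normalised matrices (counts divided by their
total), because composite and assembled signatures mix very different amounts
of sequence; AID needs no normalisation (support-only). Pearson distance is
1 − r on the flattened matrices, with the convention that a constant matrix
is at distance 1 from any non-constant one and 0 from an identical constant.
DSSIM is (1 − meanSSIM)/2 with mean local SSIM computed over a uniform
sliding window, default 7 × 7 (the SSIM implementation requires an odd
window; configurable), standard SSIM constants, and dynamic range equal to
the larger maximum of the two normalised matrices.

## Embedding and separation

Classical (Torgerson) MDS: B = −½·J·D²·J is symmetrised, eigendecomposed,
and the q = 3 leading eigenvectors scaled by √eigenvalue give the Molecular
Distance Map. AID matrices are generally not Euclidean-embeddable; retained
negative eigenvalues are clamped to zero with a warning and flagged
(`clamped_negative`), and eigenvalues within 1e−9 (relative) of zero are
treated as zero when deciding whether the embedding was padded. Because MDS
output is unique only up to rigid motions, axis signs follow a deterministic
convention (largest-magnitude loading per axis made positive) so repeated
runs are bit-identical. Each axis is then affinely rescaled to span [−1, 1];
a degenerate axis (zero range) is set to 0 and flagged.

Separation of two groups of embedded points is decided in two stages.
First, 2-means clustering (Lloyd's algorithm, 10 k-means++ restarts, seeded)
is scored by the accuracy Acc = max over the two cluster-group labelings of
the agreement fraction; Acc ∈ [0.5, 1], and Acc > 0.85 (configurable) counts
as separation. Second — because elongated parallel clusters can defeat
2-means while being visibly disjoint — a failing accuracy triggers a search
for a strictly separating plane: maximise the margin λ subject to
a·xᵢ + d ≥ λ (group 1), a·yⱼ + d ≤ −λ (group 2), ‖(a,b,c)‖∞ ≤ 1, solved by
linear programming (HiGHS). Strict inequality is realised as margin
> 1e−9 after normalising the coefficient magnitude, and every returned plane
is re-verified by direct substitution before being reported. The coverage
scan repeats the assembled-signature pipeline over an ascending grid of
coverage fractions t and reports the verdict (plane existence) per t plus
the interval (largest failing t, smallest passing t) bracketing the
separation threshold.

## Synthetic data

The simulator emulates what the signatures actually exploit — genome-specific
short-range composition — with an order-2 nucleotide Markov chain (order
configurable). Transition rows are drawn from a flat Dirichlet(1) prior. A
genome pair has a *divergence* dial: genome B's transition table is the
convex interpolation between genome A's table (divergence 0 — the pair is
exchangeable, the null case for false-positive testing) and an independently
drawn table (divergence 1). Organellar-scale fixtures (default 16.5 kbp,
mitochondrial-genome sized) give composite-signature tests discriminating
content. Defaults for the end-to-end experiments are 20 units of 50 kbp per
genome at k = 6, sized so the full suite runs in minutes on one CPU. What
these fixtures do **not** emulate: repeats, GC gradients, indels,
rearrangements, horizontal transfer, or any long-range chromosomal structure
— so green tests demonstrate the machinery's correctness and the method's
behaviour under controlled composition differences, not its discriminating
power on real genomes.

## Preparation defaults

Cleaning keeps only A/C/G/T (case-folded); everything else (N, IUPAC codes)
is dropped, and all downstream coordinates are 1-based on the cleaned
sequence. Chromosome-level genomes are cut into non-overlapping 150 kbp
fragments (tail dropped) and up to 20 fragments are sampled per chromosome
without replacement (fragments are distinct genome regions, so replacement
would be meaningless). Contig/scaffold-level assemblies contribute the first
150 kbp fragment of each of the 500 longest contigs — "longest" because
sorting descending by cleaned length is the reading of "top contigs" that
maximises usable sequence; ties break lexicographically by unit id for
determinism.

## Parameter defaults at a glance

| parameter | default | unit | rationale |
|---|---|---|---|
| k (FCGR order) | 9 (library); 6 in synthetic experiments | — | 2⁹ grid matches 150 kbp fragments; k = 6 suffices at 50 kbp |
| fragment length | 150 000 | bp | resolution-matched fragment size |
| fragments per chromosome | 20 | — | sampling cap |
| contigs per assembly | 500 | — | longest-contig cap |
| contig length n | 300 | bp | coverage-scan contig size |
| σ (variable-length contigs) | 40 | bp | spread of contig-length distribution |
| accuracy threshold | 0.85 | — | separation cutoff |
| k-means restarts | 10 | — | k-means++ initialisation |
| plane margin tolerance | 1e−9 | — | strictness of plane inequalities |

## Known limitations

AID ignores multiplicities entirely (support-only), so two sequences with
identical k-mer *sets* but different k-mer *frequencies* are at distance 0.
The plane check is only attempted in 3D maps and only when the accuracy
criterion fails. The coverage-scan verdict at each t depends on one sampled
set of contigs per fragment (no replication averaging), matching the
single-draw character of the protocol it implements. Weighted composite
signatures with non-integer weights produce float matrices whose "support"
remains well-defined but whose totals are no longer window counts.
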