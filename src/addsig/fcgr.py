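"""Chaos Game Representation signatures of DNA sequences.

The Chaos Game Representation (CGR) plots a DNA sequence in the unit square
by iterated midpoints: starting from the centre, each nucleotide moves the
current point halfway towards the corner labelled by that nucleotide.  Corner
convention (Jeffrey): A = (0, 0), C = (0, 1), G = (1, 1), T = (1, 0).

Dividing the square into a ``2**k x 2**k`` grid and counting the CGR points
per cell yields the frequency CGR (FCGR): a matrix whose cell counts are
exactly the occurrence counts of the ``4**k`` possible k-mers.  The FCGR of a
sequence is its *conventional* DNA signature; summing FCGRs over a set of
sequences gives the *additive* signature, of which composite, assembled and
fully-assembled signatures are special cases.

All grid arithmetic here is integer bit-interleaving, never floating-point
midpoint simulation, so cell assignment has no rounding ambiguity.  Row 0 is
the top of the image, column 0 the left.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DnaSequence",
    "KmerSet",
    "FcgrMatrix",
    "ContigSpec",
    "InvalidSequenceError",
    "kmer_set",
    "fcgr",
    "additive_signature",
    "composite_signature",
    "fully_assembled_signature",
    "assembled_signature",
    "kmer_to_cell",
    "coverage_contig_count",
]

DEFAULT_K = 9
MAX_K = 12

_ALPHABET = "ACGT"

# 2-bit encoding A=0, C=1, G=2, T=3; lowercase accepted, everything else -1.
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i


class InvalidSequenceError(ValueError):
    """A residue outside the {A, C, G, T} alphabet was encountered."""


def _encode(residues: str) -> np.ndarray:
    """Encode a DNA string to the 2-bit alphabet, rejecting non-ACGT."""
    raw = np.frombuffer(residues.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _CODE[raw]
    bad = np.flatnonzero(codes < 0)
    if bad.size:
        pos = int(bad[0])
        raise InvalidSequenceError(
            f"non-ACGT character {residues[pos]!r} at position {pos + 1}"
        )
    return codes


@dataclass(frozen=True)
class DnaSequence:
    """A DNA sequence over {A, C, G, T} with an identifier and provenance.

    Lowercase input is folded to uppercase on construction; any other
    character raises :class:`InvalidSequenceError`.  Cleaning of raw records
    (dropping Ns etc.) belongs to :mod:`addsig.prep`, not here.
    """

    residues: str
    id: str = ""
    provenance: dict | None = None

    def __post_init__(self) -> None:
        folded = self.residues.upper()
        _encode(folded)  # validation
        object.__setattr__(self, "residues", folded)

    def __len__(self) -> int:
        return len(self.residues)

    def codes(self) -> np.ndarray:
        return _encode(self.residues)


def _as_codes(s: "DnaSequence | str") -> np.ndarray:
    if isinstance(s, DnaSequence):
        return s.codes()
    return _encode(str(s).upper())


@dataclass(frozen=True)
class KmerSet:
    """The set M_k of distinct k-mers occurring in a sequence or set."""

    k: int
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.members


@dataclass(eq=False)
class FcgrMatrix:
    """A ``2**k x 2**k`` FCGR count matrix (an additive DNA signature).

    ``counts`` is integer for unweighted signatures; weighted composites may
    carry float counts.  ``support`` (the number of non-zero cells, #FCGR)
    equals the number of distinct k-mers of the underlying sequence set.
    """

    k: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        side = 1 << self.k
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (side, side):
            raise ValueError(
                f"counts must be {side}x{side} for k={self.k}, got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("FCGR counts must be non-negative")

    @property
    def total(self) -> float:
        """Sum of all cell counts (= |s| - k + 1 for a single sequence)."""
        t = self.counts.sum()
        return int(t) if np.issubdtype(self.counts.dtype, np.integer) else float(t)

    @property
    def support(self) -> int:
        """#FCGR: the number of non-zero cells, i.e. |M_k|."""
        return int(np.count_nonzero(self.counts))

    def __add__(self, other: "FcgrMatrix") -> "FcgrMatrix":
        if not isinstance(other, FcgrMatrix):
            return NotImplemented
        if self.k != other.k:
            raise ValueError(f"cannot add FCGRs of different order: k={self.k} vs k={other.k}")
        return FcgrMatrix(self.k, self.counts + other.counts)

    def copy(self) -> "FcgrMatrix":
        return FcgrMatrix(self.k, self.counts.copy())

    @classmethod
    def zeros(cls, k: int) -> "FcgrMatrix":
        side = 1 << k
        return cls(k, np.zeros((side, side), dtype=np.int64))


@dataclass(frozen=True)
class ContigSpec:
    """Parameters of an assembled-signature sampling scheme.

    ``n`` is the contig length in bp.  The number of contigs is ``r`` if
    given, else ``q = floor(t * |s| / n)`` from the coverage fraction ``t``.
    In ``assembled_variable`` mode each contig length is drawn from
    N(mu, sigma) (defaults mu = n, sigma = 40 bp), rounded to the nearest
    integer and clamped to stay inside the sequence.
    """

    n: int
    r: int | None = None
    t: float | None = None
    mu: float | None = None
    sigma: float = 40.0
    mode: str = "assembled_fixed"

    _MODES = ("fully_assembled", "assembled_fixed", "assembled_variable")

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("contig length n must be >= 1")
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}")
        if self.r is not None and self.r < 1:
            raise ValueError("contig count r must be >= 1 when given")
        if self.t is not None and not (0.0 <= self.t <= 1.0):
            raise ValueError("coverage fraction t must lie in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.mode != "fully_assembled" and self.r is None and self.t is None:
            raise ValueError("assembled modes need either r or t")

    def resolve_count(self, seq_length: int) -> int:
        """Number of contigs for a sequence of the given length."""
        if self.r is not None:
            return self.r
        return coverage_contig_count(self.t, seq_length, self.n)


def coverage_contig_count(t: float, seq_length: int, n: int) -> int:
    """q = floor(t * |s| / n), the contig count at coverage fraction t."""
    return math.floor(t * seq_length / n)


def _validate_k(k: int) -> None:
    if not 1 <= int(k) <= MAX_K:
        raise ValueError(f"k must be an integer in [1, {MAX_K}], got {k}")


# --- k-mer <-> grid-cell arithmetic -----------------------------------------
#
# After plotting a k-mer the CGR point lies in the quadrant of the *last*
# nucleotide; within it, in the sub-quadrant of the second-to-last, and so on.
# With corners A=(0,0), C=(0,1), G=(1,1), T=(1,0): the x half-plane bit is 1
# for G/T (code >> 1) and the y bit is 1 for C/G ((code & 1) ^ (code >> 1)).
# Character j of the k-mer therefore contributes bit j (LSB = first char) to
# the cell's x and y coordinates; row = 2**k - 1 - y puts y_max at row 0.


def _window_cells(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Grid cell (row, col) of every k-mer window of an encoded sequence."""
    m = codes.size - k + 1
    if m <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    xb = (codes >> 1).astype(np.int64)
    yb = ((codes & 1) ^ (codes >> 1)).astype(np.int64)
    x = np.zeros(m, np.int64)
    y = np.zeros(m, np.int64)
    for j in range(k):
        x |= xb[j : j + m] << j
        y |= yb[j : j + m] << j
    row = ((1 << k) - 1) - y
    return row, x


def kmer_to_cell(kmer: str) -> tuple[int, int]:
    """Map a k-mer to its (row, col) grid cell; bijective over all 4**k k-mers."""
    codes = _encode(kmer.upper())
    k = codes.size
    if k < 1:
        raise ValueError("k-mer must be non-empty")
    _validate_k(k)
    row, col = _window_cells(codes, k)
    return int(row[0]), int(col[0])


def _counts_from_cells(row: np.ndarray, col: np.ndarray, k: int) -> np.ndarray:
    side = 1 << k
    flat = np.bincount(row * side + col, minlength=side * side)
    return flat.reshape(side, side).astype(np.int64)


# --- operations -------------------------------------------------------------


def kmer_set(s: "DnaSequence | str", k: int) -> KmerSet:
    """All distinct k-mers of ``s`` (M_k(s)); empty when |s| < k."""
    _validate_k(k)
    codes = _as_codes(s)
    m = codes.size - k + 1
    if m <= 0:
        return KmerSet(k, frozenset())
    idx = np.zeros(m, np.int64)
    for j in range(k):
        idx = (idx << 2) | codes[j : j + m].astype(np.int64)
    uniq = np.unique(idx)
    members = []
    for v in uniq:
        chars = [_ALPHABET[(int(v) >> (2 * (k - 1 - j))) & 3] for j in range(k)]
        members.append("".join(chars))
    return KmerSet(k, frozenset(members))


def fcgr(s: "DnaSequence | str", k: int = DEFAULT_K) -> FcgrMatrix:
    """The conventional DNA signature FCGR_k(s): k-mer counts on the CGR grid."""
    _validate_k(k)
    codes = _as_codes(s)
    row, col = _window_cells(codes, k)
    return FcgrMatrix(k, _counts_from_cells(row, col, k))


def additive_signature(S: Sequence["DnaSequence | str"] | Iterable, k: int = DEFAULT_K) -> FcgrMatrix:
    """The additive DNA signature of a set: FCGR_k(S) = sum_i FCGR_k(s_i)."""
    seqs = list(S)
    if not seqs:
        raise ValueError("additive signature needs a non-empty sequence set")
    out = fcgr(seqs[0], k)
    for s in seqs[1:]:
        out = out + fcgr(s, k)
    return out


def composite_signature(
    parts: Sequence[FcgrMatrix], weights: Sequence[float] | None = None
) -> FcgrMatrix:
    """Weighted elementwise sum of signatures sharing the same order k.

    With unit weights (the default) this equals the additive signature of the
    concatenated sequence sets, e.g. a nuclear-fragment FCGR plus the FCGR of
    the organellar genome(s) of the same organism.
    """
    parts = list(parts)
    if not parts:
        raise ValueError("composite signature needs at least one part")
    k = parts[0].k
    if any(p.k != k for p in parts):
        raise ValueError("all parts of a composite signature must share the same k")
    if weights is None:
        out = parts[0].counts.copy()
        for p in parts[1:]:
            out = out + p.counts
        return FcgrMatrix(k, out)
    weights = list(weights)
    if len(weights) != len(parts):
        raise ValueError("weights must match parts in length")
    if any(w <= 0 for w in weights):
        raise ValueError("weights must be positive")
    acc = np.zeros_like(parts[0].counts, dtype=np.float64)
    for w, p in zip(weights, parts):
        acc = acc + w * p.counts
    if all(float(w).is_integer() for w in weights):
        acc = acc.astype(np.int64)
    return FcgrMatrix(k, acc)


def fully_assembled_signature(s: "DnaSequence | str", n: int, k: int = DEFAULT_K) -> FcgrMatrix:
    """Additive signature of the floor(|s|/n) consecutive contigs of length n.

    The sequence is partitioned from position 1 into non-overlapping contigs
    of exactly n bp; a remainder shorter than n is discarded.  Unique for a
    given (s, n, k).
    """
    _validate_k(k)
    if n < k:
        raise ValueError(f"contig length n={n} must be >= k={k}")
    codes = _as_codes(s)
    r = codes.size // n
    if r == 0:
        raise ValueError(f"sequence of length {codes.size} is shorter than one contig (n={n})")
    codes = codes[: r * n]
    row, col = _window_cells(codes, k)
    # keep only windows lying inside a single contig: start offset within the
    # contig must leave room for k characters
    starts = np.arange(row.size)
    keep = (starts % n) <= (n - k)
    return FcgrMatrix(k, _counts_from_cells(row[keep], col[keep], k))


def _draw_starts(rng: np.random.Generator, count: int, max_start: int) -> np.ndarray:
    """0-based contig start positions, uniform on [0, max_start], with replacement."""
    return rng.integers(0, max_start + 1, size=count)


def assembled_signature(
    s: "DnaSequence | str",
    spec: ContigSpec,
    seed: "int | np.random.Generator" = 0,
    k: int = DEFAULT_K,
) -> FcgrMatrix:
    """Additive signature of randomly sampled (possibly overlapping) contigs.

    Start positions are drawn independently and uniformly over all valid
    positions, with replacement, so contigs may overlap or repeat.  With
    ``spec.t`` given, the contig count is q = floor(t * |s| / n).  In
    ``assembled_variable`` mode each contig length is drawn from N(mu, sigma),
    rounded, and clamped to [k, |s| - start].  Reproducible for a fixed seed.
    """
    _validate_k(k)
    if spec.n < k:
        raise ValueError(f"contig length n={spec.n} must be >= k={k}")
    codes = _as_codes(s)
    L = codes.size
    if L < spec.n:
        raise ValueError(f"sequence of length {L} is shorter than one contig (n={spec.n})")
    count = spec.resolve_count(L)
    if count < 1:
        raise ValueError(
            f"resolved contig count is {count}; increase coverage t or give r explicitly"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    starts = _draw_starts(rng, count, L - spec.n)
    if spec.mode == "assembled_variable":
        mu = spec.mu if spec.mu is not None else float(spec.n)
        lengths = np.rint(rng.normal(mu, spec.sigma, size=count)).astype(np.int64)
        lengths = np.maximum(lengths, k)
        lengths = np.minimum(lengths, L - starts)
    else:
        lengths = np.full(count, spec.n, dtype=np.int64)
    # one cell array for the whole sequence; each contig contributes the
    # window range [start, start + len - k]
    row, col = _window_cells(codes, k)
    idx_parts = [np.arange(a, a + ln - k + 1) for a, ln in zip(starts, lengths)]
    idx = np.concatenate(idx_parts)
    return FcgrMatrix(k, _counts_from_cells(row[idx], col[idx], k))
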