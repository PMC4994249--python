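"""Distances between FCGR signatures and pairwise distance matrices.

The workhorse is the approximated information distance (AID): the fraction of
non-shared distinct k-mers among all distinct k-mers of two sequences (or
sequence sets).  Because the support of an FCGR equals the number of distinct
k-mers, AID has the closed form

    d = 2 - (#F + #G) / #(F + G)

where ``#`` counts non-zero cells.  The numerator and denominator are kept as
exact integers; only the final division is floating point.

Four auxiliary distances operate on frequency-normalised matrices (counts
divided by their total, so signatures built from very different amounts of
sequence remain comparable): Euclidean (L2), Manhattan (L1), Pearson
correlation distance (1 - r), and DSSIM, a structural-dissimilarity image
distance derived from the mean local SSIM.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from skimage.metrics import structural_similarity

from .fcgr import DnaSequence, FcgrMatrix, additive_signature, kmer_set

__all__ = [
    "MetricId",
    "DistanceMatrix",
    "UndefinedDistanceError",
    "aid",
    "generalized_aid",
    "aid_fully_assembled_bound",
    "euclidean",
    "manhattan",
    "pearson_distance",
    "dssim",
    "distance_matrix",
]


class MetricId(str, Enum):
    AID = "aid"
    DSSIM = "dssim"
    EUCLIDEAN = "euclidean"
    PEARSON = "pearson"
    MANHATTAN = "manhattan"


class UndefinedDistanceError(ValueError):
    """The distance is undefined for the given inputs (e.g. no k-mers at all)."""


def _check_same_k(F: FcgrMatrix, G: FcgrMatrix) -> None:
    if F.k != G.k:
        raise ValueError(f"signatures have different order: k={F.k} vs k={G.k}")


def aid(F: FcgrMatrix, G: FcgrMatrix) -> float:
    """Approximated information distance from FCGR supports (the #FCGR form).

    Returns ``2 - (#F + #G) / #(F + G)``; lies in [0, 1], is symmetric, and is
    0 exactly when the two signatures share the same k-mer support.
    """
    _check_same_k(F, G)
    a = F.support
    b = G.support
    union = int(np.count_nonzero((F.counts != 0) | (G.counts != 0)))
    if union == 0:
        raise UndefinedDistanceError("both signatures are empty; AID is undefined")
    return (2 * union - a - b) / union


def generalized_aid(
    S: Sequence[DnaSequence | str], T: Sequence[DnaSequence | str], k: int
) -> float:
    """Generalized AID between two sets of sequences, from explicit k-mer sets.

    Computes (|M_k(S) \\ M_k(T)| + |M_k(T) \\ M_k(S)|) / |M_k(S u T)| with set
    arithmetic.  Agrees bit-for-bit with :func:`aid` on the corresponding
    additive signatures (same integer numerator and denominator).
    """
    ms: set[str] = set()
    for s in S:
        ms |= kmer_set(s, k).members
    mt: set[str] = set()
    for t in T:
        mt |= kmer_set(t, k).members
    union = len(ms | mt)
    if union == 0:
        raise UndefinedDistanceError("no k-mers occur in either set; AID is undefined")
    return (len(ms - mt) + len(mt - ms)) / union


def aid_fully_assembled_bound(r: int, k: int, m: int) -> float:
    """Upper bound on AID between a fully-assembled and a conventional signature.

    A fully-assembled signature built from r contigs misses only k-mers that
    span contig junctions; each of the r - 1 junctions contributes at most
    k - 1 of them, hence the bound min{(r - 1)(k - 1), m} / m where m is the
    number of distinct k-mers of the full sequence.
    """
    if m < 1:
        raise ValueError("m (number of distinct k-mers) must be >= 1")
    if r < 1:
        raise ValueError("r must be >= 1")
    if k < 2:
        raise ValueError("the bound requires k >= 2")
    return min((r - 1) * (k - 1), m) / m


def _frequencies(F: FcgrMatrix) -> np.ndarray:
    total = F.counts.sum()
    if total <= 0:
        raise ValueError("normalized distances need a signature with positive total")
    return F.counts.astype(np.float64) / float(total)


def euclidean(F: FcgrMatrix, G: FcgrMatrix) -> float:
    """L2 distance between frequency-normalised signatures."""
    _check_same_k(F, G)
    return float(np.linalg.norm(_frequencies(F) - _frequencies(G)))


def manhattan(F: FcgrMatrix, G: FcgrMatrix) -> float:
    """L1 distance between frequency-normalised signatures."""
    _check_same_k(F, G)
    return float(np.abs(_frequencies(F) - _frequencies(G)).sum())


def pearson_distance(F: FcgrMatrix, G: FcgrMatrix) -> float:
    """1 - Pearson correlation of the flattened frequency matrices.

    Convention for degenerate input: if exactly one matrix is constant the
    distance is 1 (no linear association can exist); if both are constant
    they are identical frequency matrices, distance 0.
    """
    _check_same_k(F, G)
    f = _frequencies(F).ravel()
    g = _frequencies(G).ravel()
    sf = f.std()
    sg = g.std()
    if sf == 0.0 and sg == 0.0:
        return 0.0
    if sf == 0.0 or sg == 0.0:
        return 1.0
    r = float(np.corrcoef(f, g)[0, 1])
    return 1.0 - r


def dssim(F: FcgrMatrix, G: FcgrMatrix, win_size: int | None = None) -> float:
    """Structural dissimilarity between signatures, mapped to [0, 1].

    Computes the mean local SSIM of the two frequency-normalised matrices
    (uniform sliding window, default 7x7 or the largest odd size that fits;
    dynamic range = the larger maximum of the two matrices) and returns
    (1 - meanSSIM) / 2.
    """
    _check_same_k(F, G)
    f = _frequencies(F)
    g = _frequencies(G)
    side = f.shape[0]
    if win_size is None:
        win_size = min(7, side if side % 2 == 1 else side - 1)
    data_range = float(max(f.max(), g.max()))
    if data_range == 0.0:
        return 0.0
    mssim = structural_similarity(
        f, g, win_size=win_size, gaussian_weights=False, data_range=data_range
    )
    return (1.0 - float(mssim)) / 2.0


_METRIC_FUNCS = {
    MetricId.AID: aid,
    MetricId.DSSIM: dssim,
    MetricId.EUCLIDEAN: euclidean,
    MetricId.PEARSON: pearson_distance,
    MetricId.MANHATTAN: manhattan,
}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise-distance table with item labels."""

    labels: list[str]
    values: np.ndarray
    metric: MetricId

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        m = len(self.labels)
        if self.values.shape != (m, m):
            raise ValueError("values must be square and match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)


def distance_matrix(
    signatures: Sequence[FcgrMatrix],
    metric: MetricId | str = MetricId.AID,
    labels: Sequence[str] | None = None,
) -> DistanceMatrix:
    """All pairwise distances between signatures, in input order."""
    sigs = list(signatures)
    if len(sigs) < 2:
        raise ValueError("distance matrix needs at least 2 signatures")
    k = sigs[0].k
    if any(s.k != k for s in sigs):
        raise ValueError("all signatures must share the same k")
    metric = MetricId(metric)
    func = _METRIC_FUNCS[metric]
    m = len(sigs)
    if labels is None:
        labels = [f"item{i}" for i in range(m)]
    labels = [str(x) for x in labels]
    if len(labels) != m:
        raise ValueError("labels must match signatures in length")
    vals = np.zeros((m, m), dtype=np.float64)
    for i in range(m):
        for j in range(i + 1, m):
            d = func(sigs[i], sigs[j])
            vals[i, j] = d
            vals[j, i] = d
    return DistanceMatrix(labels, vals, metric)
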