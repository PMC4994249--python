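"""Quantitative separation assessment of two groups of embedded signatures.

Two groups of points in a Molecular Distance Map are called *separated* when
either (a) 2-means clustering recovers the grouping with accuracy above a
threshold (default 85%), where

    Acc = max{ |A_S1| + |B_S2|, |B_S1| + |A_S2| } / (|S1| + |S2|)

over the two possible cluster-to-group labelings, or (b) a plane
a*x + b*y + c*z + d = 0 strictly separates the groups.  The plane check
rescues elongated, parallel clusters that 2-means splits crosswise; it is
attempted whenever the accuracy criterion fails.

The coverage scan rebuilds assembled signatures at increasing coverage
fractions t (q = floor(t*|s|/n) contigs per fragment), embeds each AID
distance matrix, and brackets the smallest t at which a separating plane
exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linprog
from sklearn.cluster import KMeans

from .distances import MetricId, distance_matrix
from .embedding import EmbeddedMap, classical_mds, scale_map
from .fcgr import ContigSpec, DnaSequence, assembled_signature

__all__ = [
    "SeparationResult",
    "CoverageScanResult",
    "accuracy_score",
    "kmeans_accuracy",
    "separating_plane",
    "assess_separation",
    "coverage_threshold_scan",
]

DEFAULT_ACCURACY_THRESHOLD = 0.85
PLANE_MARGIN_TOL = 1e-9


@dataclass
class SeparationResult:
    accuracy: float
    assignment: np.ndarray  # per-point cluster label (0/1)
    plane: tuple[float, float, float, float] | None
    verdict: str  # separated_by_accuracy | separated_by_plane | not_separated
    threshold: float = DEFAULT_ACCURACY_THRESHOLD

    @property
    def separated(self) -> bool:
        return self.verdict != "not_separated"


@dataclass
class CoverageScanResult:
    per_t: list[tuple[float, int, str]]  # (t, q, verdict)
    threshold_interval: tuple[float | None, float | None]  # (t_fail, t_pass)


def accuracy_score(cluster_labels: Sequence[int], group_labels: Sequence[int]) -> float:
    """The 2-means accuracy: best agreement over the two cluster-group labelings."""
    c = np.asarray(cluster_labels)
    g = np.asarray(group_labels)
    if c.shape != g.shape:
        raise ValueError("cluster and group labels must have equal length")
    n = c.size
    agree = int(np.sum(c == g))
    return max(agree, n - agree) / n


def _check_two_groups(group_labels: np.ndarray) -> np.ndarray:
    groups = np.unique(group_labels)
    if groups.size != 2:
        raise ValueError(f"exactly two groups are required, got {groups.size}")
    return (np.asarray(group_labels) == groups[1]).astype(int)


def kmeans_accuracy(
    points: np.ndarray,
    group_labels: Sequence,
    seed: int = 0,
    threshold: float = DEFAULT_ACCURACY_THRESHOLD,
) -> SeparationResult:
    """2-means clustering accuracy of the true grouping (no plane check).

    Lloyd's algorithm with 10 k-means++ restarts.  If all points coincide the
    clustering is degenerate: the trivial one-cluster assignment is scored and
    a warning issued.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    g = _check_two_groups(np.asarray(group_labels))
    if np.all(points == points[0]):
        warnings.warn("all points identical; clustering is degenerate", stacklevel=2)
        assignment = np.zeros(len(points), dtype=int)
    else:
        km = KMeans(n_clusters=2, n_init=10, random_state=seed)
        assignment = km.fit_predict(points)
    acc = accuracy_score(assignment, g)
    verdict = "separated_by_accuracy" if acc > threshold else "not_separated"
    return SeparationResult(acc, assignment, None, verdict, threshold)


def separating_plane(
    P1: np.ndarray, P2: np.ndarray, margin_tol: float = PLANE_MARGIN_TOL
) -> tuple[float, float, float, float] | None:
    """A plane a*x + b*y + c*z + d = 0 strictly separating two 3D point sets.

    Solved as a margin-maximising linear program with the normal bounded in
    the unit box; the groups are strictly separable iff the optimal margin is
    positive.  A returned plane is re-verified by direct substitution
    (P1 strictly positive side, P2 strictly negative); marginal feasibility
    (margin within ``margin_tol`` of zero) is reported as None.
    """
    P1 = np.atleast_2d(np.asarray(P1, dtype=np.float64))
    P2 = np.atleast_2d(np.asarray(P2, dtype=np.float64))
    if P1.shape[1] != 3 or P2.shape[1] != 3:
        raise ValueError("separating_plane expects 3D points")
    if len(P1) == 0 or len(P2) == 0:
        raise ValueError("both groups must be non-empty")
    scale = float(np.abs(np.vstack([P1, P2])).max())
    d_bound = 3.0 * scale + 1.0
    # variables: a, b, c, d, m; maximize m
    c_obj = np.array([0.0, 0.0, 0.0, 0.0, -1.0])
    # m - (a.x + d) <= 0 for x in P1;  m + (a.y + d) <= 0 for y in P2
    A1 = np.hstack([-P1, -np.ones((len(P1), 1)), np.ones((len(P1), 1))])
    A2 = np.hstack([P2, np.ones((len(P2), 1)), np.ones((len(P2), 1))])
    A_ub = np.vstack([A1, A2])
    b_ub = np.zeros(len(P1) + len(P2))
    bounds = [(-1, 1), (-1, 1), (-1, 1), (-d_bound, d_bound), (0, None)]
    res = linprog(c_obj, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:
        return None
    a, b, c, d, m = res.x
    if m <= margin_tol:
        return None
    coeffs = np.array([a, b, c, d])
    norm = np.abs(coeffs).max()
    if norm > 0:
        coeffs = coeffs / norm
    a, b, c, d = coeffs
    v1 = P1 @ coeffs[:3] + d
    v2 = P2 @ coeffs[:3] + d
    if np.all(v1 > 0) and np.all(v2 < 0):
        return float(a), float(b), float(c), float(d)
    return None


def assess_separation(
    emap: EmbeddedMap,
    group_labels: Sequence,
    threshold: float = DEFAULT_ACCURACY_THRESHOLD,
    seed: int = 0,
) -> SeparationResult:
    """Full separation verdict: 2-means accuracy first, plane check as fallback."""
    g = _check_two_groups(np.asarray(group_labels))
    res = kmeans_accuracy(emap.coords, g, seed=seed, threshold=threshold)
    if res.verdict == "separated_by_accuracy":
        return res
    if emap.q != 3:
        return res
    plane = separating_plane(emap.coords[g == 0], emap.coords[g == 1])
    if plane is not None:
        # convention: group listed first lies on the positive side
        return SeparationResult(res.accuracy, res.assignment, plane, "separated_by_plane", threshold)
    return res


def coverage_threshold_scan(
    frags_a: Sequence[DnaSequence],
    frags_b: Sequence[DnaSequence],
    n: int = 300,
    t_grid: Sequence[float] = (0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.4, 0.8),
    k: int = 9,
    seed: int = 0,
) -> CoverageScanResult:
    """Bracket the coverage fraction at which assembled signatures separate.

    For each t (ascending) every fragment gets an assembled signature from
    q = floor(t*|s|/n) random contigs of length n; the AID distance matrix is
    embedded in 3D and separation is decided by the existence of a separating
    plane between the two fragment groups.  Returns the verdict per t and the
    interval (largest failing t, smallest passing t) bracketing the
    transition.
    """
    frags_a = list(frags_a)
    frags_b = list(frags_b)
    if not frags_a or not frags_b:
        raise ValueError("both fragment groups must be non-empty")
    all_frags = frags_a + frags_b
    groups = np.array([0] * len(frags_a) + [1] * len(frags_b))
    ss = np.random.SeedSequence(seed)
    per_t: list[tuple[float, int, str]] = []
    ts = sorted(t_grid)
    for ti, t in enumerate(ts):
        if not 0.0 < t <= 1.0:
            raise ValueError("t values must lie in (0, 1]")
        q0 = int(np.floor(t * len(all_frags[0]) / n))
        if q0 == 0:
            warnings.warn(f"t={t} yields q=0 contigs; skipped", stacklevel=2)
            continue
        rng = np.random.default_rng(np.random.SeedSequence(entropy=ss.entropy, spawn_key=(ti,)))
        sigs = [
            assembled_signature(f, ContigSpec(n=n, t=t), seed=rng, k=k) for f in all_frags
        ]
        D = distance_matrix(sigs, MetricId.AID, labels=[f.id for f in all_frags])
        emap = scale_map(classical_mds(D, q=3))
        plane = separating_plane(emap.coords[groups == 0], emap.coords[groups == 1])
        per_t.append((t, q0, "separated" if plane is not None else "not_separated"))
    t_pass: float | None = None
    t_fail: float | None = None
    for t, _q, verdict in per_t:
        if verdict == "separated" and t_pass is None:
            t_pass = t
        if verdict == "not_separated" and (t_pass is None):
            t_fail = t
    return CoverageScanResult(per_t, (t_fail, t_pass))
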