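"""Classical multidimensional scaling into a Molecular Distance Map.

Classical (Torgerson) MDS double-centers the squared distance matrix,
B = -1/2 * J D^2 J with J = I - (1/m) 11', eigendecomposes B, and places each
item at the leading eigenvectors scaled by the square roots of their
eigenvalues.  With q = 3 retained dimensions the result is a Molecular
Distance Map: points whose pairwise Euclidean distances approximate the input
distances.  For display, each axis is affinely rescaled to span [-1, 1]:

    x_sca = 2 * (x - x_min) / (x_max - x_min) - 1

Non-Euclidean inputs (AID matrices generally are) produce negative
eigenvalues; retained negative eigenvalues are clamped to zero and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix

__all__ = ["EmbeddedMap", "classical_mds", "scale_map"]


@dataclass
class EmbeddedMap:
    """m labelled points in q-dimensional space, with the retained eigenvalues."""

    labels: list[str]
    coords: np.ndarray  # (m, q)
    eigenvalues: np.ndarray  # (q,), sorted descending, non-negative
    scaled: bool = False
    clamped_negative: bool = False  # some retained eigenvalues were negative
    padded: bool = False  # fewer positive eigenvalues than q
    degenerate_axes: list[int] = field(default_factory=list)
    provenance: list[dict | None] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape[0] != len(self.labels):
            raise ValueError("coords count must equal labels count")

    @property
    def q(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return len(self.labels)


def classical_mds(D: DistanceMatrix, q: int = 3) -> EmbeddedMap:
    """Embed a distance matrix in q dimensions by classical MDS.

    Eigenvalues are reported sorted descending; retained negative ones are
    clamped to zero (``clamped_negative``).  If fewer than q eigenvalues are
    positive the missing coordinates are zero and ``padded`` is set.  Axis
    signs follow a deterministic convention: the largest-magnitude loading of
    each axis is made positive.
    """
    m = len(D)
    if m < 2:
        raise ValueError("classical MDS needs at least 2 items")
    if not 1 <= q <= m - 1:
        raise ValueError(f"q must lie in [1, m-1] = [1, {m - 1}], got {q}")
    d2 = D.values.astype(np.float64) ** 2
    J = np.eye(m) - np.full((m, m), 1.0 / m)
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2.0
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals = vals[order][:q]
    vecs = vecs[:, order][:, :q]
    clamped = bool(np.any(vals < -1e-12 * max(1.0, abs(vals[0]))))
    if clamped:
        warnings.warn(
            "distance matrix is not Euclidean-embeddable: negative eigenvalues "
            "clamped to zero",
            stacklevel=2,
        )
    vals = np.maximum(vals, 0.0)
    tol = 1e-9 * max(1.0, float(vals[0]))
    vals[vals < tol] = 0.0
    padded = bool(np.count_nonzero(vals) < q)
    coords = vecs * np.sqrt(vals)[None, :]
    # deterministic sign: largest-|loading| per axis positive
    for a in range(q):
        col = coords[:, a]
        if col.any():
            i = int(np.argmax(np.abs(col)))
            if col[i] < 0:
                coords[:, a] = -col
    return EmbeddedMap(
        labels=list(D.labels),
        coords=coords,
        eigenvalues=vals,
        scaled=False,
        clamped_negative=clamped,
        padded=padded,
    )


def scale_map(emap: EmbeddedMap) -> EmbeddedMap:
    """Rescale each axis to span [-1, 1] via 2*(x - min)/(max - min) - 1.

    A degenerate axis (all values equal) is set to 0 and recorded in
    ``degenerate_axes``.
    """
    if emap.scaled:
        raise ValueError("map is already scaled")
    coords = emap.coords.copy()
    degenerate: list[int] = []
    for a in range(coords.shape[1]):
        lo = coords[:, a].min()
        hi = coords[:, a].max()
        if hi == lo:
            coords[:, a] = 0.0
            degenerate.append(a)
        else:
            coords[:, a] = 2.0 * (coords[:, a] - lo) / (hi - lo) - 1.0
    return EmbeddedMap(
        labels=list(emap.labels),
        coords=coords,
        eigenvalues=emap.eigenvalues.copy(),
        scaled=True,
        clamped_negative=emap.clamped_negative,
        padded=emap.padded,
        degenerate_axes=degenerate,
        provenance=emap.provenance,
    )
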