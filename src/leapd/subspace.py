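"""Affine-subspace modelling of LPC vectors and the bounded index.

Each cognitive class (normal / impaired) is modelled as the best-fit
affine subspace — a centroid plus the top-k principal directions — of
its training subjects' LPC coefficient vectors.  A test vector yields
two point-to-flat distances, D1 to the normal-class subspace and D2 to
the impaired-class subspace, which are fused into a bounded index

    L = D2 / (D1 + D2)  in [0, 1],

so a large L means the vector sits far from the impaired-class subspace:
high index = cognitively normal.  This orientation makes the index
correlate positively with cognitive scores.  Per-electrode indices are
combined across electrodes by their geometric mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AffineSubspace",
    "fit_affine_subspace",
    "distance_to_subspace",
    "leapd_index",
    "combine_channels",
]


@dataclass(frozen=True)
class AffineSubspace:
    """centroid + orthonormal basis (k x p; k may be 0) of one class."""

    centroid: np.ndarray
    basis: np.ndarray  # shape (k, p), rows orthonormal
    class_label: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.centroid, dtype=float)
        B = np.asarray(self.basis, dtype=float)
        if B.ndim != 2 or B.shape[1] != c.size:
            raise ValueError("basis must be (k, p) with p matching the centroid")
        if B.shape[0] > 0:
            gram = B @ B.T
            if not np.allclose(gram, np.eye(B.shape[0]), atol=1e-10):
                raise ValueError("basis vectors must be orthonormal")
        object.__setattr__(self, "centroid", c)
        object.__setattr__(self, "basis", B)

    @property
    def dim(self) -> int:
        return self.basis.shape[0]


def fit_affine_subspace(vectors, k: int, class_label: str = "") -> AffineSubspace:
    """Best-fit k-dimensional affine subspace of a point cloud.

    Centroid is the mean; the basis spans the top-k principal directions
    of the centred scatter, so the summed squared residual equals the sum
    of the discarded scatter eigenvalues.  ``k = 0`` gives a centroid-only
    model (distance reduces to Euclidean distance to the mean).
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2:
        raise ValueError("vectors must form an (n, p) matrix")
    n, p = X.shape
    if k < 0 or k > p:
        raise ValueError(f"subspace dimension k={k} must be in [0, {p}]")
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} vectors, got {n}")
    centroid = X.mean(axis=0)
    if k == 0:
        return AffineSubspace(centroid, np.empty((0, p)), class_label)
    _, _, vt = np.linalg.svd(X - centroid, full_matrices=False)
    return AffineSubspace(centroid, vt[:k], class_label)


def distance_to_subspace(v, s: AffineSubspace) -> float:
    """Minimum Euclidean distance from a point to the affine subspace."""
    v = np.asarray(v, dtype=float)
    if v.shape != s.centroid.shape:
        raise ValueError(
            f"vector dimension {v.shape} does not match centroid {s.centroid.shape}"
        )
    w = v - s.centroid
    sq = w @ w
    if s.dim:
        proj = s.basis @ w
        sq -= proj @ proj
    return float(np.sqrt(max(sq, 0.0)))


def _distances_to_subspace(V: np.ndarray, s: AffineSubspace) -> np.ndarray:
    """Vectorised distance for an (n, p) stack of test points."""
    W = V - s.centroid
    sq = np.einsum("ij,ij->i", W, W)
    if s.dim:
        P = W @ s.basis.T
        sq = sq - np.einsum("ij,ij->i", P, P)
    return np.sqrt(np.maximum(sq, 0.0))


def leapd_index(d_normal: float, d_impaired: float) -> float:
    """Bounded index ``d_impaired / (d_normal + d_impaired)``.

    1.0 = exactly on the normal-class subspace, 0.0 = exactly on the
    impaired-class subspace; the degenerate 0/0 case (a point on both)
    maps to 0.5 by symmetry.
    """
    if d_normal < 0 or d_impaired < 0:
        raise ValueError("distances must be nonnegative")
    if not (np.isfinite(d_normal) and np.isfinite(d_impaired)):
        raise ValueError("distances must be finite")
    total = d_normal + d_impaired
    if total == 0.0:
        return 0.5
    return d_impaired / total


def combine_channels(indices) -> float:
    """Geometric mean of per-electrode indices, with exact zero poles.

    A zero index short-circuits to a combined index of exactly 0 (no
    epsilon flooring); positive inputs are averaged in log space to avoid
    product underflow with many electrodes.
    """
    idx = np.asarray(indices, dtype=float)
    if idx.size == 0:
        raise ValueError("need at least one channel index")
    if np.any(idx < 0) or np.any(idx > 1):
        raise ValueError("indices must lie in [0, 1]")
    if np.any(idx == 0.0):
        return 0.0
    return float(np.exp(np.mean(np.log(idx))))
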