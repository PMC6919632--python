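"""Principal angles between subspaces and the scalar comparison metric.

Given orthonormal bases U and W of two subspaces of the same ambient
space, the principal (canonical) angles are
``theta_i = arccos(sigma_i(U^T W))`` for the singular values sigma_i,
reported ascending in [0, pi/2].  Conditions are compared with the
metric ``d = sqrt(sum_i theta_i^2)``, which is a true metric on the
Grassmannian when both subspaces have equal dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SubspaceComparison", "principal_angles", "angle_metric", "compare_subspaces", "orthonormalize"]


@dataclass
class SubspaceComparison:
    angles: np.ndarray  # ascending, in [0, pi/2]
    metric_d: float


def orthonormalize(vectors: np.ndarray) -> np.ndarray:
    """Orthonormal basis (columns) for the column span of ``vectors``."""
    from scipy.linalg import orth

    return orth(np.asarray(vectors, dtype=float))


def _check_orthonormal(B: np.ndarray, name: str) -> np.ndarray:
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if B.shape[0] < B.shape[1]:
        raise ValueError(f"{name}: more columns than ambient dimensions")
    G = B.T @ B
    if not np.allclose(G, np.eye(B.shape[1]), atol=1e-8):
        raise ValueError(f"{name} must have orthonormal columns")
    return B


def principal_angles(U: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Ascending principal angles between the column spans of U and W.

    Angles are arccos of the singular values of ``U.T @ W`` (clipped into
    [0, 1] against floating-point overshoot); angles below pi/4 are
    evaluated through the sine form, which keeps precision for nearly
    coincident subspaces where arccos alone bottoms out near 1e-8.
    """
    from scipy.linalg import subspace_angles

    U = _check_orthonormal(U, "U")
    W = _check_orthonormal(W, "W")
    if U.shape[0] != W.shape[0]:
        raise ValueError(
            f"ambient dimension mismatch: {U.shape[0]} vs {W.shape[0]}"
        )
    return np.sort(subspace_angles(U, W))


def angle_metric(angles: np.ndarray) -> float:
    """Euclidean norm of the principal-angle vector."""
    return float(np.linalg.norm(np.asarray(angles, dtype=float)))


def compare_subspaces(U: np.ndarray, W: np.ndarray, require_equal_dim: bool = True) -> SubspaceComparison:
    """Principal angles plus the metric d; flags unequal dimensions.

    The metric is only interpretable between equal-dimension subspaces,
    so a mismatch raises unless ``require_equal_dim`` is False.
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if require_equal_dim and U.shape[1] != W.shape[1]:
        raise ValueError(
            f"subspaces must have equal dimension for the metric: {U.shape[1]} vs {W.shape[1]}"
        )
    ang = principal_angles(U, W)
    return SubspaceComparison(angles=ang, metric_d=angle_metric(ang))
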