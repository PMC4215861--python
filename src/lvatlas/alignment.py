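"""Rigid Procrustes alignment of corresponded point sets.

Shapes are superposed by rotation and translation only: heart size is itself
a marker of disease, so scale is deliberately retained in all statistics.
Pairwise alignment is the SVD (Kabsch) solution with the determinant sign
corrected so anatomies never mirror; cohort alignment iterates alignment to
the running mean shape until the mean stabilizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray     # (3, 3), proper orthogonal
    translation: np.ndarray  # (3,), mm

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-10):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-10):
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


def _kabsch_rotation(moving_centered: np.ndarray,
                     target_centered: np.ndarray) -> np.ndarray:
    h = moving_centered.T @ target_centered
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def procrustes_pair(moving: np.ndarray,
                    target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid alignment of ``moving`` onto ``target``.

    Returns the optimal proper rotation + translation and the post-alignment
    root-mean-square distance.  No scaling is applied, so a pure size
    difference remains in the residual.
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.shape != target.shape:
        raise ValueError(f"point counts differ: {moving.shape} vs {target.shape}")
    if moving.ndim != 2 or moving.shape[1] != 3 or moving.shape[0] < 3:
        raise ValueError("shapes must be (n >= 3, 3) arrays")
    mc = moving - moving.mean(axis=0)
    tc = target - target.mean(axis=0)
    if np.allclose(mc, 0.0) or np.allclose(tc, 0.0):
        raise ValueError("all points coincide; alignment is undefined")
    rot = _kabsch_rotation(mc, tc)
    translation = target.mean(axis=0) - rot @ moving.mean(axis=0)
    aligned = moving @ rot.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - target) ** 2, axis=1))))
    return RigidTransform(rotation=rot, translation=translation), rmsd


def _principal_axis_gauge(mean: np.ndarray) -> np.ndarray:
    """Rotation fixing the visualization frame of a converged mean shape:
    principal axes of the mean point cloud are mapped to the coordinate axes
    (largest-extent axis -> z), with signs made deterministic by requiring
    non-negative coordinate skewness along z and x."""
    centered = mean - mean.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    # rows of vt: descending variance; put the long axis (row 0) on z
    rot = vt[[1, 2, 0], :]
    rotated = centered @ rot.T
    flip = np.ones(3)
    for axis in (2, 0):  # z then x
        if np.sum(rotated[:, axis] ** 3) < 0:
            flip[axis] = -1.0
    flip[1] = np.sign(np.linalg.det(np.diag(flip) @ rot)) * flip[1]
    if flip[1] == 0:
        flip[1] = 1.0
    return np.diag(flip) @ rot


def generalized_procrustes(shapes: np.ndarray, tol: float = 1e-8,
                           max_iter: int = 100
                           ) -> tuple[np.ndarray, np.ndarray, int]:
    """Generalized Procrustes alignment of a stack of corresponded shapes.

    Iterates {rigidly align every shape to the current mean; recompute the
    mean} starting from the first shape as reference, until the mean moves by
    less than ``tol`` (RMS, mm) or ``max_iter`` is reached.  After
    convergence a deterministic principal-axis gauge rotation is applied to
    the mean and all aligned shapes.

    Parameters
    ----------
    shapes : (n_shapes, n_points, 3) array
    """
    shapes = np.asarray(shapes, dtype=float)
    if shapes.ndim != 3 or shapes.shape[2] != 3:
        raise ValueError("shapes must be (n_shapes, n_points, 3)")
    if shapes.shape[0] < 2:
        raise ValueError("need at least 2 shapes")

    aligned = shapes.copy()
    mean = shapes[0].copy()
    n_iter = 0
    displacement = np.inf
    for n_iter in range(1, max_iter + 1):
        for i in range(aligned.shape[0]):
            transform, _ = procrustes_pair(aligned[i], mean)
            aligned[i] = transform.apply(aligned[i])
        new_mean = aligned.mean(axis=0)
        displacement = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if displacement < tol:
            break
    else:
        warnings.warn(
            f"generalized Procrustes did not converge in {max_iter} iterations "
            f"(final mean displacement {displacement:.3g} mm)", RuntimeWarning)

    gauge = _principal_axis_gauge(mean)
    centroid = mean.mean(axis=0)
    mean = (mean - centroid) @ gauge.T
    aligned = (aligned - centroid) @ gauge.T
    return aligned, mean, n_iter
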