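"""Rigid-body superposition and RMSD.

Every graft and evaluation in the pipeline reduces to least-squares
superposition of backbone heavy atoms.  The optimal proper rotation is the
Kabsch solution: SVD of the covariance of the centred point sets with a
determinant sign correction so that reflections are never returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ConditioningError, InputError

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation: ``x -> R @ x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise InputError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise InputError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise InputError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation of paired points, no fitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InputError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 1:
        raise InputError("expected (n, 3) coordinates with n >= 1")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares proper-rotation fit of ``mobile`` onto ``reference``.

    Returns the transform and the post-fit RMSD.  All points are weighted
    equally; reflections are suppressed by flipping the sign of the smallest
    singular-vector pair when the raw solution has determinant -1.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise InputError(
            f"point counts differ: {mobile.shape} vs {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise InputError("expected (n, 3) coordinates")
    n = mobile.shape[0]
    if n < 3:
        raise ConditioningError("superposition needs at least 3 points")

    mob_mean = mobile.mean(axis=0)
    ref_mean = reference.mean(axis=0)
    P = mobile - mob_mean
    Q = reference - ref_mean

    # collinear (or coincident) reference points leave the rotation about the
    # line undetermined
    s_ref = np.linalg.svd(Q, compute_uv=False)
    if s_ref[1] < 1e-8 * max(1.0, s_ref[0]):
        raise ConditioningError("degenerate geometry: points are (near-)collinear")

    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_mean - R @ mob_mean
    transform = RigidTransform(R, t)
    fitted = rmsd(transform.apply(mobile), reference)
    return transform, fitted


def random_rigid_transform(rng: np.random.Generator, max_shift: float = 20.0) -> RigidTransform:
    """A uniformly random rotation (QR of a Gaussian matrix) plus shift."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-max_shift, max_shift, size=3)
    return RigidTransform(Q, t)
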