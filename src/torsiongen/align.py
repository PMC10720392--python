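"""Rigid superposition of corresponding point clouds.

Two routes are provided: the Kabsch algorithm (via scipy's rotation
machinery, used as the reference) and a quaternion method that reduces the
optimal rotation to the maximal-eigenvalue eigenvector of a symmetric 4x4
key matrix.  The eigenpair is found without a full eigendecomposition, by
power iteration accelerated with repeated matrix squaring, which is the
numerically friendly route for gradient-based pipelines.

Because the quaternion method needs the largest *algebraic* eigenvalue while
repeated squaring amplifies the largest *magnitude* one, the matrix is
shifted by sigma = max row absolute sum before squaring (making the target
dominant in magnitude) and the eigenvalue is recovered by a Rayleigh
quotient on the unshifted matrix.

Also here: exact three-point superposition used for fragment assembly
(orthonormal-frame construction, differentiable, no eigensolver), and the
plain no-superposition RMSD order parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConvergenceError, DegenerateGeometryError, UsageError, ValidationError

__all__ = [
    "RigidTransform",
    "AlignmentResult",
    "kabsch_align",
    "quaternion_key_matrix",
    "dominant_eigenpair",
    "quaternion_to_rotation",
    "quaternion_align",
    "three_point_transform",
    "rmsd",
]


@dataclass
class RigidTransform:
    """y = rotation @ x + translation, with a proper rotation."""

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # (3,), nm

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or np.abs(R @ R.T - np.eye(3)).max() > 1e-8:
            raise ValidationError("rotation must be 3x3 orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValidationError("rotation must be proper (det +1)")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation


@dataclass
class AlignmentResult:
    transform: RigidTransform
    rmsd: float


def _check_clouds(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise UsageError("point clouds must both be n x 3 with equal n")
    if P.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points to superpose")
    for cloud, name in ((P, "P"), (Q, "Q")):
        centered = cloud - cloud.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[1] < 1e-9 * max(1.0, sv[0]):
            raise DegenerateGeometryError(f"cloud {name} is collinear or degenerate")
    return P, Q


def rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Root-mean-square row-wise distance without any superposition."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise UsageError("rmsd requires equally shaped point sets")
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=-1))))


def kabsch_align(P: np.ndarray, Q: np.ndarray, weights=None) -> AlignmentResult:
    """Least-squares rigid superposition of P onto Q (reflections corrected)."""
    P, Q = _check_clouds(P, Q)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (P.shape[0],) or np.any(weights < 0) or weights.sum() <= 0:
            raise UsageError("weights must be nonnegative with positive sum")
        w = weights / weights.sum()
    else:
        w = np.full(P.shape[0], 1.0 / P.shape[0])
    cP = (w[:, None] * P).sum(axis=0)
    cQ = (w[:, None] * Q).sum(axis=0)
    rot, _ = Rotation.align_vectors(Q - cQ, P - cP, weights=w)
    R = rot.as_matrix()
    t = cQ - R @ cP
    transform = RigidTransform(rotation=R, translation=t)
    moved = transform.apply(P)
    value = float(np.sqrt(np.sum(w * np.sum((moved - Q) ** 2, axis=-1))))
    return AlignmentResult(transform=transform, rmsd=value)


def quaternion_key_matrix(P_centered: np.ndarray, Q_centered: np.ndarray) -> np.ndarray:
    """Symmetric traceless 4x4 key matrix of the quaternion superposition.

    The maximal-eigenvalue eigenvector is the unit quaternion of the optimal
    rotation carrying P onto Q.  Inputs must already be centered.
    """
    P = np.asarray(P_centered, dtype=float)
    Q = np.asarray(Q_centered, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise UsageError("inputs must be equally shaped n x 3 arrays")
    scale = max(1.0, np.abs(P).max(), np.abs(Q).max())
    if (np.linalg.norm(P.mean(axis=0)) > 1e-9 * scale
            or np.linalg.norm(Q.mean(axis=0)) > 1e-9 * scale):
        raise ValidationError("quaternion_key_matrix requires centered inputs")
    S = P.T @ Q  # cross-covariance
    sxx, sxy, sxz = S[0]
    syx, syy, syz = S[1]
    szx, szy, szz = S[2]
    return np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )


def dominant_eigenpair(
    M_sym: np.ndarray, tol: float = 1e-12, max_squarings: int = 64
) -> tuple[float, np.ndarray]:
    """Largest *algebraic* eigenpair of a symmetric matrix by repeated squaring.

    The matrix is shifted by sigma = max row absolute sum so the target
    eigenvalue dominates in magnitude, squared (with normalization after each
    squaring) until the eigenvector estimate stabilizes, and the eigenvalue is
    read off with a Rayleigh quotient on the unshifted matrix.
    """
    A = np.asarray(M_sym, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("matrix must be square")
    if np.abs(A - A.T).max() > 1e-10 * max(1.0, np.abs(A).max()):
        raise ValidationError("matrix must be symmetric")
    n = A.shape[0]
    sigma = float(np.abs(A).sum(axis=1).max())
    B = A + sigma * np.eye(n)
    norm = np.linalg.norm(B)
    if norm == 0.0:
        return 0.0, np.eye(n)[0]
    B = B / norm

    v0 = np.ones(n) / np.sqrt(n)
    v_prev = None
    for _ in range(max_squarings):
        w = B @ v0
        wn = np.linalg.norm(w)
        if wn < 1e-300:  # start vector orthogonal to the dominant space
            v0 = np.eye(n)[0]
            w = B @ v0
            wn = np.linalg.norm(w)
        v = w / wn
        if v_prev is not None:
            if v @ v_prev < 0:
                v = -v
            if np.linalg.norm(v - v_prev) < tol:
                eigval = float(v @ A @ v)
                return eigval, v
        v_prev = v
        B = B @ B
        B = B / np.linalg.norm(B)
    residual = float(np.linalg.norm(A @ v_prev - (v_prev @ A @ v_prev) * v_prev))
    raise ConvergenceError(
        f"dominant eigenpair did not converge in {max_squarings} squarings "
        f"(residual {residual:.3e})"
    )


def quaternion_to_rotation(q: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) -> proper rotation matrix; q and -q agree."""
    q = np.asarray(q, dtype=float)
    if q.shape != (4,) or abs(np.linalg.norm(q) - 1.0) > 1e-9:
        raise ValidationError("quaternion must be a unit 4-vector")
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quaternion_align(P: np.ndarray, Q: np.ndarray) -> AlignmentResult:
    """Superpose P onto Q via the key matrix and the squaring eigensolver."""
    P, Q = _check_clouds(P, Q)
    cP = P.mean(axis=0)
    cQ = Q.mean(axis=0)
    key = quaternion_key_matrix(P - cP, Q - cQ)
    _, q = dominant_eigenpair(key)
    R = quaternion_to_rotation(q)
    t = cQ - R @ cP
    transform = RigidTransform(rotation=R, translation=t)
    value = rmsd(transform.apply(P), Q)
    return AlignmentResult(transform=transform, rmsd=value)


def three_point_transform(P_triple: np.ndarray, Q_triple: np.ndarray) -> RigidTransform:
    """Exact rigid transform mapping one non-collinear triple onto a congruent one.

    Builds an orthonormal frame on each triple (Gram-Schmidt of the two edge
    vectors plus their cross product) and composes the frames.  Exact when the
    triples are congruent; used for anchor-based fragment assembly.
    """
    frames = []
    for name, tri in (("P", P_triple), ("Q", Q_triple)):
        tri = np.asarray(tri, dtype=float)
        if tri.shape != (3, 3):
            raise UsageError("anchor triples must be 3 x 3 arrays")
        e1 = tri[1] - tri[0]
        n1 = np.linalg.norm(e1)
        w = tri[2] - tri[0]
        cross = np.cross(e1, w)
        if n1 < 1e-9 or np.linalg.norm(cross) < 1e-9 * max(1.0, n1 * np.linalg.norm(w)):
            raise DegenerateGeometryError(
                f"anchor triple {name} is collinear; cannot define a frame"
            )
        e1 = e1 / n1
        e2 = w - (w @ e1) * e1
        e2 = e2 / np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        frames.append(np.stack([e1, e2, e3], axis=1))
    EP, EQ = frames
    R = EQ @ EP.T
    t = np.asarray(Q_triple, dtype=float)[0] - R @ np.asarray(P_triple, dtype=float)[0]
    return RigidTransform(rotation=R, translation=t)
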