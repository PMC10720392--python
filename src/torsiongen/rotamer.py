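"""Serial differentiable torsion sampling.

Each dihedral is applied as a Rodrigues rotation of its rotating component
about the bond axis, with the axis and bond centroid recomputed from the
*intermediate* coordinates, so application order matters and the canonical
order is the (sorted-edge) order of the dihedral topology.  Angles are deltas
from the input conformation.

Differentiability is provided as analytic forward-mode Jacobians: when
requested, the returned conformation carries d(position)/d(angle) for every
angle, propagated through the axis/centroid recomputation of later rotations.
The Jacobians satisfy the same finite-difference oracle an autodiff
implementation would.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError, UsageError, ValidationError
from .molio import Conformation
from .molgraph import DihedralTopology

__all__ = [
    "RotationSpec",
    "bond_axis_and_centroid",
    "rodrigues_matrix",
    "apply_dihedral_rotation",
    "sample_rotamers",
    "measure_dihedral",
]

_AXIS_TOL = 1e-9


class RotationSpec:
    """Unit rotation axis k_hat, bond centroid c, and the skew matrix K."""

    __slots__ = ("k_hat", "c", "K")

    def __init__(self, k_hat: np.ndarray, c: np.ndarray):
        k_hat = np.asarray(k_hat, dtype=float)
        if abs(np.linalg.norm(k_hat) - 1.0) > _AXIS_TOL:
            raise ValidationError("rotation axis must be a unit vector")
        self.k_hat = k_hat
        self.c = np.asarray(c, dtype=float)
        self.K = _skew(k_hat)


def _skew(k: np.ndarray) -> np.ndarray:
    kx, ky, kz = k
    return np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])


def bond_axis_and_centroid(conf: Conformation, edge: tuple[int, int]) -> RotationSpec:
    """Axis k = p_u - p_v (normalized) and centroid c = (p_u + p_v)/2."""
    u, v = edge
    p_u = conf.positions[u]
    p_v = conf.positions[v]
    k = p_u - p_v
    norm = np.linalg.norm(k)
    if norm <= 1e-6:
        raise DegenerateGeometryError(
            f"bond ({u},{v}): endpoints coincide, rotation axis undefined"
        )
    return RotationSpec(k_hat=k / norm, c=0.5 * (p_u + p_v))


def rodrigues_matrix(theta: float, k_hat: np.ndarray) -> np.ndarray:
    """R = I + sin(theta) K + (1 - cos(theta)) K^2 for a unit axis."""
    k_hat = np.asarray(k_hat, dtype=float)
    if abs(np.linalg.norm(k_hat) - 1.0) > 1e-6:
        raise ValidationError("rodrigues_matrix requires a unit axis")
    K = _skew(k_hat)
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def apply_dihedral_rotation(
    conf: Conformation,
    spec: RotationSpec,
    rotating_set,
    theta: float,
) -> Conformation:
    """Rotate the atoms of `rotating_set` by theta about the bond axis.

    Rows outside the rotating set are bit-identical to the input.
    """
    idx = np.fromiter(sorted(rotating_set), dtype=int)
    if idx.size == 0:
        raise UsageError("rotating_set must be nonempty")
    if idx.min() < 0 or idx.max() >= conf.n_atoms:
        raise UsageError("rotating_set contains out-of-range atom indices")
    out = conf.positions.copy()
    if theta == 0.0:  # identity rotation: bit-exact no-op
        return Conformation(positions=out)
    R = np.eye(3) + np.sin(theta) * spec.K + (1.0 - np.cos(theta)) * (spec.K @ spec.K)
    out[idx] = (out[idx] - spec.c) @ R.T + spec.c
    return Conformation(positions=out)


def sample_rotamers(
    conf0: Conformation,
    topology: DihedralTopology,
    angles,
    jacobian: bool = False,
) -> Conformation:
    """Apply the M dihedral deltas sequentially in topology order.

    With ``jacobian=True`` the result carries ``angle_jacobian`` of shape
    (M, N, 3): the derivative of every output coordinate with respect to every
    applied angle, including the flow of earlier angles through the
    recomputed axes and centroids of later rotations.
    """
    angles = np.asarray(angles, dtype=float)
    M = topology.M
    if angles.shape != (M,):
        raise ValidationError(f"expected {M} angles, got shape {angles.shape}")
    x = conf0.positions.copy()
    N = x.shape[0]
    T = np.zeros((M, N, 3)) if jacobian else None

    for m, spec_m in enumerate(topology.specs):
        u, v = spec_m.edge
        idx = np.fromiter(sorted(spec_m.rotating_set), dtype=int)
        k = x[u] - x[v]
        L = np.linalg.norm(k)
        if L <= 1e-6:
            raise DegenerateGeometryError(
                f"bond ({u},{v}): endpoints coincide during sampling"
            )
        k_hat = k / L
        c = 0.5 * (x[u] + x[v])
        K = _skew(k_hat)
        K2 = K @ K
        theta = angles[m]
        local = x[idx] - c
        if theta == 0.0:
            # exact no-op for the positions; only the direct tangent is nonzero
            if jacobian:
                T[m, idx] += local @ K.T
            continue
        sin_t, cos_t = np.sin(theta), np.cos(theta)
        R = np.eye(3) + sin_t * K + (1.0 - cos_t) * K2

        if jacobian:
            proj = (np.eye(3) - np.outer(k_hat, k_hat)) / L
            for j in range(M):
                if j < m:
                    dk = proj @ (T[j, u] - T[j, v])
                    dc = 0.5 * (T[j, u] + T[j, v])
                    dK = _skew(dk)
                    dR = sin_t * dK + (1.0 - cos_t) * (dK @ K + K @ dK)
                    T[j, idx] = local @ dR.T + (T[j, idx] - dc) @ R.T + dc
                elif j == m:
                    dR = cos_t * K + sin_t * K2
                    T[j, idx] = local @ dR.T + T[j, idx] @ R.T
                # j > m: theta_j not yet applied, tangent stays zero

        x[idx] = local @ R.T + c

    return Conformation(positions=x, angle_jacobian=T)


def measure_dihedral(conf: Conformation, quadruple) -> float:
    """Signed dihedral of four atoms, in [-pi, pi).

    The sine reference axis points from the lower-indexed to the
    higher-indexed of the two central atoms; with quadruples oriented as in
    :class:`~torsiongen.molgraph.DihedralSpec` (rotating endpoint second),
    applying a rotation of +theta increases the measured value by +theta
    (mod 2 pi).
    """
    q1, q2, q3, q4 = quadruple
    if len({q1, q2, q3, q4}) != 4:
        raise UsageError("dihedral quadruple must contain four distinct atoms")
    p = conf.positions
    b1 = p[q2] - p[q1]
    b2 = p[q3] - p[q2]
    b3 = p[q4] - p[q3]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("collinear atom triple in dihedral quadruple")
    ref = b2 if q2 < q3 else -b2
    ref = ref / np.linalg.norm(ref)
    angle = np.arctan2(np.dot(np.cross(n1, n2), ref), np.dot(n1, n2))
    if angle >= np.pi:  # canonical range [-pi, pi)
        angle -= 2.0 * np.pi
    return float(angle)
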