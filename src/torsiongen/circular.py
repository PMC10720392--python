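"""Circular (toroidal) angle machinery.

A dihedral angle lives on a circle, so the generator predicts two raw outputs
(x_m, y_m) per angle and the angle is recovered with atan2 -- a continuous,
bias-free parameterization with a bounded gradient, unlike direct interval
regression whose boundary penalty biases angles toward the interval center
(``interval_penalty_loss`` implements that baseline for comparison).

The toroidal metric sums squared shortest arclengths per angle; the entropy
of a batch of angle vectors is estimated from first-nearest-neighbor
distances under that metric, deliberately dropping the bias-correction
constants -- only the gradient of the estimate matters for training.
"""

from __future__ import annotations

import numpy as np

from .errors import UsageError, ValidationError

__all__ = [
    "angles_from_pairs",
    "atan2_gradient",
    "modulus_loss",
    "modulus_loss_gradient",
    "interval_penalty_loss",
    "circular_distance_sq",
    "pairwise_circular_distances",
    "nn_entropy",
    "nn_entropy_with_gradient",
]

#: nearest-neighbor distances are floored here before the log, so duplicate
#: samples give a large-negative but finite entropy contribution
DISTANCE_FLOOR = 1e-12


def angles_from_pairs(pairs: np.ndarray) -> np.ndarray:
    """theta = atan2(y, x) per pair, in [-pi, pi); (0, 0) maps to 0.

    Accepts shape (M, 2) or a batch (B, M, 2); returns (M,) or (B, M).
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.shape[-1] != 2:
        raise UsageError("pairs must have a trailing dimension of 2 (x, y)")
    theta = np.arctan2(pairs[..., 1], pairs[..., 0])
    return np.where(theta >= np.pi, theta - 2.0 * np.pi, theta)


def atan2_gradient(c: float, s: float):
    """(d theta/d c, d theta/d s) = (-s, c) / (c^2 + s^2); undefined at origin."""
    r2 = c * c + s * s
    if r2 == 0.0:
        raise ValidationError("atan2 gradient undefined at the origin")
    return (-s / r2, c / r2)


def modulus_loss(pairs: np.ndarray, eps_xy: float) -> float:
    """eps_xy * sum_m (x_m^2 + y_m^2 - 1)^2, keeping pairs near the unit circle."""
    if eps_xy < 0:
        raise UsageError("eps_xy must be nonnegative")
    pairs = np.asarray(pairs, dtype=float)
    r2 = pairs[..., 0] ** 2 + pairs[..., 1] ** 2
    return float(eps_xy * np.sum((r2 - 1.0) ** 2))


def modulus_loss_gradient(pairs: np.ndarray, eps_xy: float) -> np.ndarray:
    """d modulus_loss / d pairs, same shape as pairs."""
    pairs = np.asarray(pairs, dtype=float)
    r2 = pairs[..., 0] ** 2 + pairs[..., 1] ** 2
    return eps_xy * 4.0 * (r2 - 1.0)[..., None] * pairs


def interval_penalty_loss(
    angles: np.ndarray, theta_min: float, theta_max: float, eps_theta: float
) -> float:
    """Boundary penalty eps * (sum_{th<min} th^2 + sum_{th>max} th^2).

    Comparison baseline only: this loss biases sampling toward the interval
    center and is what the two-output representation avoids.
    """
    if not theta_min < theta_max:
        raise UsageError("theta_min must be < theta_max")
    angles = np.asarray(angles, dtype=float)
    below = angles[angles < theta_min]
    above = angles[angles > theta_max]
    return float(eps_theta * (np.sum(below**2) + np.sum(above**2)))


def _arc(delta: np.ndarray) -> np.ndarray:
    """Shortest arclength per angle: pi - |pi - |delta|| after mod-2pi reduction."""
    d = np.mod(np.abs(delta), 2.0 * np.pi)
    return np.pi - np.abs(np.pi - d)


def circular_distance_sq(phi, psi) -> float:
    """Squared toroidal distance: sum_i arc(phi_i - psi_i)^2, each term <= pi^2."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    if phi.shape != psi.shape:
        raise UsageError("angle vectors must have equal length")
    return float(np.sum(_arc(phi - psi) ** 2))


def pairwise_circular_distances(batch: np.ndarray) -> np.ndarray:
    """B x B matrix of toroidal distances between rows of a B x M batch."""
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    delta = batch[:, None, :] - batch[None, :, :]
    return np.sqrt(np.sum(_arc(delta) ** 2, axis=-1))


def nn_entropy(samples: np.ndarray) -> float:
    """Mean log first-nearest-neighbor distance under the toroidal metric.

    Bias-correction constants are intentionally omitted; the value is only
    meaningful up to an additive constant (gradient-grade estimate).
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.ndim == 2 and samples.shape[1] == 0:
        raise UsageError("samples must have at least one angle per row")
    B = samples.shape[0]
    if B < 2:
        raise UsageError("need at least 2 samples to estimate entropy")
    dist = pairwise_circular_distances(samples)
    np.fill_diagonal(dist, np.inf)
    nn = np.maximum(dist.min(axis=1), DISTANCE_FLOOR)
    return float(np.mean(np.log(nn)))


def nn_entropy_with_gradient(samples: np.ndarray):
    """Entropy estimate plus its gradient with respect to every angle.

    The nearest-neighbor *index* is held fixed (standard subgradient of a
    min); gradients flow through the toroidal distances to both members of
    each nearest-neighbor pair.  Distances at the floor contribute zero
    gradient.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    B, M = samples.shape
    if B < 2:
        raise UsageError("need at least 2 samples to estimate entropy")
    dist = pairwise_circular_distances(samples)
    np.fill_diagonal(dist, np.inf)
    nn_idx = np.argmin(dist, axis=1)
    nn_dist = dist[np.arange(B), nn_idx]
    floored = np.maximum(nn_dist, DISTANCE_FLOOR)
    value = float(np.mean(np.log(floored)))

    grad = np.zeros_like(samples)
    for i in range(B):
        j = nn_idx[i]
        d = nn_dist[i]
        if d <= DISTANCE_FLOOR:
            continue
        delta = samples[i] - samples[j]
        arc = _arc(delta)
        # d arc/d delta is +1 on the short side of the circle, -1 past pi (a.e.)
        reduced = np.mod(delta, 2.0 * np.pi)
        darc = np.where(reduced < np.pi, 1.0, -1.0)
        darc = np.where(arc == 0.0, 0.0, darc)
        contrib = (arc * darc) / (B * d * d)  # d(log d_i)/d delta, averaged
        grad[i] += contrib
        grad[j] -= contrib
    return value, grad
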