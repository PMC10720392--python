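"""Boltzmann-generator training in torsion space.

A small fully connected network maps latent noise to two raw outputs per
dihedral; angles are recovered with atan2 and applied to the input structure
by the differentiable sampler.  Training minimizes

* pre-training:  L = sum_m theta_m^2 + L_reg          (outputs the native state)
* energy-only:   L = U(theta) + L_reg
* full loss:     L = U/T - S + L_reg   if T >= 1
                 L = U - T*S + L_reg   if T < 1

where U is the molecular-mechanics energy of the generated conformation, S
the nearest-neighbor circular entropy of the *same* batch of angles, T the
reduced temperature (T = R * T_kelvin, kJ/mol), and L_reg the modulus loss
plus weight decay.  The branch switch keeps the dynamic range of both terms
bounded: U is never divided by a small T and S is never multiplied by a
large T, so neither term's gradient explodes; both branches agree at T = 1.

The energy and entropy contributions are decoupled: the energy function is
called exactly once per generated sample and the entropy estimate reuses the
batch of angles, adding zero energy calls (an instrumented counter on the
model makes this assertable).  Gradients are assembled analytically:
d(U)/d(theta) through the sampler Jacobian, d(S)/d(theta) through the
toroidal metric with the nearest-neighbor index held fixed, then through
atan2 into the network by ordinary backpropagation.

The network is deliberately *not* invertible: an invertible generator over
3N Cartesian coordinates needs at least 9 N^2 weights per layer, while a
torsion-space generator only scales with the number of rotatable bonds
(``invertible_param_lower_bound`` computes the Cartesian bound for
comparison).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import GAS_CONSTANT
from .errors import TrainingDivergenceError, UsageError, ValidationError
from .molio import Conformation, EnsembleTrajectory, MolecularSystem
from .molgraph import DihedralTopology
from . import circular
from .align import quaternion_align
from .forcefield import build_pairing, _energy_and_gradient
from .rotamer import sample_rotamers

__all__ = [
    "LatentSpec",
    "GeneratorModel",
    "TrainingConfig",
    "TrainingReport",
    "sample_latent",
    "pretrain_loss",
    "energy_only_loss",
    "boltzmann_loss",
    "temperature_from_kelvin",
    "invertible_param_lower_bound",
    "pretrain",
    "train",
    "generate_ensemble",
    "rmsf",
]


# --------------------------------------------------------------------------
# latent noise
# --------------------------------------------------------------------------


@dataclass
class LatentSpec:
    """Input-noise family: standard Gaussian, uniform, or a sum of unit
    Gaussians centered on a list of points (a metadynamics-flavored prior
    whose modes can be made responsible for distinct energy basins)."""

    kind: str = "gaussian"
    dim: int = 8
    centers: list | None = None  # for kind="sum_of_gaussians"
    low: float = -1.0
    high: float = 1.0

    def __post_init__(self):
        if self.dim < 1:
            raise UsageError("latent dim must be >= 1")
        if self.kind == "sum_of_gaussians":
            if not self.centers:
                raise UsageError("sum_of_gaussians needs at least one center")
            self.centers = [np.asarray(c, dtype=float).reshape(self.dim)
                            for c in self.centers]
        elif self.kind not in ("gaussian", "uniform"):
            raise UsageError(f"unknown latent kind '{self.kind}'")


def sample_latent(spec: LatentSpec, batch: int, seed) -> np.ndarray:
    """Seeded B x m latent draw; `seed` may be an int or a Generator."""
    if batch < 1:
        raise UsageError("batch must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.kind == "gaussian":
        return rng.standard_normal((batch, spec.dim))
    if spec.kind == "uniform":
        return rng.uniform(spec.low, spec.high, size=(batch, spec.dim))
    which = rng.integers(0, len(spec.centers), size=batch)
    base = rng.standard_normal((batch, spec.dim))
    return base + np.stack([spec.centers[i] for i in which])


# --------------------------------------------------------------------------
# losses and analytic targets
# --------------------------------------------------------------------------


def pretrain_loss(pairs: np.ndarray, eps_xy: float, weight_decay_term: float = 0.0) -> float:
    """sum_m theta_m^2 + modulus loss + weight decay (native-state loss)."""
    theta = circular.angles_from_pairs(pairs)
    return float(np.sum(theta**2) + circular.modulus_loss(pairs, eps_xy)
                 + weight_decay_term)


def energy_only_loss(U: float, L_reg: float) -> float:
    """U + L_reg: energy minimization with no entropy term."""
    return float(U + L_reg)


def boltzmann_loss(U: float, S: float, L_reg: float, T_NN: float) -> float:
    """Branching energy/entropy loss; continuous at T_NN = 1."""
    if T_NN < 0:
        raise UsageError("T_NN must be nonnegative")
    if T_NN >= 1.0:
        return float(U / T_NN - S + L_reg)
    return float(U - T_NN * S + L_reg)


def temperature_from_kelvin(T_kelvin: float) -> float:
    """Reduced temperature T_NN = R * T (kJ/mol); 310 K -> 2.58."""
    if T_kelvin < 0:
        raise UsageError("temperature must be nonnegative")
    return GAS_CONSTANT * T_kelvin


def invertible_param_lower_bound(n_atoms: int) -> int:
    """Minimum weight count, 9 N^2, of an invertible Cartesian generator.

    Every layer of an invertible network over 3N coordinates must keep full
    rank, hence at least (3N)^2 weights per layer; biases excluded.
    """
    if n_atoms < 1:
        raise UsageError("n_atoms must be >= 1")
    return 9 * n_atoms * n_atoms


# --------------------------------------------------------------------------
# generator network (plain NumPy, manual backprop)
# --------------------------------------------------------------------------


class GeneratorModel:
    """Fully connected tanh network from latent dim m to 2M raw pair outputs.

    Defaults follow the training setup this toolkit targets: 10 linear
    layers, hidden width max(64, 4M).  tanh keeps every activation
    derivative bounded, which combines with the bounded atan2 gradient to
    give a well-conditioned end-to-end gradient.
    """

    def __init__(self, latent_dim: int, n_dihedrals: int, n_layers: int = 10,
                 hidden: int | None = None, seed: int = 0):
        if n_layers < 2:
            raise UsageError("need at least 2 layers (input and output)")
        self.latent_dim = latent_dim
        self.n_dihedrals = n_dihedrals
        hidden = hidden if hidden is not None else max(64, 4 * n_dihedrals)
        sizes = [latent_dim] + [hidden] * (n_layers - 1) + [2 * n_dihedrals]
        rng = np.random.default_rng(seed)
        self.weights = [
            rng.standard_normal((sizes[i], sizes[i + 1])) / math.sqrt(sizes[i])
            for i in range(len(sizes) - 1)
        ]
        self.biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self._cache = None

    @property
    def parameter_count(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def forward(self, z: np.ndarray) -> np.ndarray:
        """B x m latent -> B x M x 2 raw pairs (caches activations)."""
        a = np.asarray(z, dtype=float)
        acts = [a]
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            a = a @ W + b
            if i < last:
                a = np.tanh(a)
            acts.append(a)
        self._cache = acts
        return a.reshape(a.shape[0], self.n_dihedrals, 2)

    def backward(self, dpairs: np.ndarray):
        """Gradient of a scalar loss wrt parameters given d loss/d pairs."""
        if self._cache is None:
            raise ValidationError("backward called before forward")
        acts = self._cache
        delta = np.asarray(dpairs, dtype=float).reshape(acts[-1].shape)
        gW = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        last = len(self.weights) - 1
        for i in range(last, -1, -1):
            if i < last:
                delta = delta * (1.0 - acts[i + 1] ** 2)
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
        return gW, gb


class _Optimizer:
    def __init__(self, model, lr, weight_decay):
        self.model = model
        self.lr = lr
        self.weight_decay = weight_decay

    def decay_loss(self) -> float:
        return self.weight_decay * sum(float(np.sum(w * w))
                                       for w in self.model.weights)

    def _apply_decay(self, gW):
        if self.weight_decay:
            return [g + 2.0 * self.weight_decay * w
                    for g, w in zip(gW, self.model.weights)]
        return gW


class SGD(_Optimizer):
    def step(self, gW, gb):
        gW = self._apply_decay(gW)
        for w, g in zip(self.model.weights, gW):
            w -= self.lr * g
        for b, g in zip(self.model.biases, gb):
            b -= self.lr * g


class Adam(_Optimizer):
    def __init__(self, model, lr, weight_decay, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(model, lr, weight_decay)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.mW = [np.zeros_like(w) for w in model.weights]
        self.vW = [np.zeros_like(w) for w in model.weights]
        self.mb = [np.zeros_like(b) for b in model.biases]
        self.vb = [np.zeros_like(b) for b in model.biases]

    def step(self, gW, gb):
        gW = self._apply_decay(gW)
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for w, g, m, v in zip(self.model.weights, gW, self.mW, self.vW):
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            w -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
        for b, g, m, v in zip(self.model.biases, gb, self.mb, self.vb):
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            b -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def _make_optimizer(kind, model, lr, weight_decay):
    if kind == "adam":
        return Adam(model, lr, weight_decay)
    if kind == "sgd":
        return SGD(model, lr, weight_decay)
    raise UsageError(f"unknown optimizer '{kind}'")


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------


@dataclass
class TrainingConfig:
    """Full, seeded experiment specification."""

    t_nn: float = 2.58  # reduced temperature (R * 310 K)
    n_pre: int = 200
    n_train: int = 300
    batch_size: int = 32
    learning_rate: float = 5e-3
    eps_xy: float = 0.1
    weight_decay: float = 0.0
    optimizer: str = "adam"
    latent: LatentSpec = field(default_factory=LatentSpec)
    seed: int = 0
    grad_clip: float = 100.0
    soft_core_delta: float = 0.05
    use_entropy: bool = True  # False reproduces the energy-only loss

    def __post_init__(self):
        if min(self.n_train, self.batch_size) < 1 or self.n_pre < 0:
            raise UsageError("epoch counts and batch size must be positive")
        if self.t_nn < 0:
            raise UsageError("t_nn must be nonnegative")
        if self.batch_size < 2:
            raise UsageError("batch size must be >= 2 (entropy needs pairs)")


@dataclass
class TrainingReport:
    """Per-epoch diagnostics; one row per epoch."""

    epochs: pd.DataFrame
    energy_calls: int = 0

    def validate(self):
        if self.epochs.isna().any().any() or not np.all(np.isfinite(self.epochs)):
            raise TrainingDivergenceError("training report contains non-finite values")


def _clip(gW, gb, max_norm):
    total = math.sqrt(sum(float(np.sum(g * g)) for g in gW)
                      + sum(float(np.sum(g * g)) for g in gb))
    if max_norm and total > max_norm:
        scale = max_norm / total
        gW = [g * scale for g in gW]
        gb = [g * scale for g in gb]
    return gW, gb


def _pairs_to_angle_grad(pairs, dangles):
    """Chain d loss/d theta through theta = atan2(y, x) to the raw pairs."""
    x = pairs[..., 0]
    y = pairs[..., 1]
    r2 = np.maximum(x * x + y * y, 1e-12)
    dpairs = np.empty_like(pairs)
    dpairs[..., 0] = dangles * (-y / r2)
    dpairs[..., 1] = dangles * (x / r2)
    return dpairs


def pretrain(model: GeneratorModel, system: MolecularSystem,
             topology: DihedralTopology, config: TrainingConfig) -> GeneratorModel:
    """Train the generator to output theta = 0 (the native conformation).

    Minimizes the angle-squared loss plus regularizers over seeded latent
    batches; no energy calls are made.
    """
    if config.n_pre == 0:
        import logging
        logging.getLogger(__name__).warning(
            "pre-training skipped (n_pre = 0); the full loss is unlikely to "
            "converge from a random initialization"
        )
        return model
    rng = np.random.default_rng(config.seed)
    opt = _make_optimizer(config.optimizer, model, config.learning_rate,
                          config.weight_decay)
    for epoch in range(config.n_pre):
        z = sample_latent(config.latent, config.batch_size, rng)
        pairs = model.forward(z)
        theta = circular.angles_from_pairs(pairs)
        loss = pretrain_loss(pairs, config.eps_xy, opt.decay_loss())
        if not np.isfinite(loss):
            raise TrainingDivergenceError(f"non-finite pre-training loss at epoch {epoch}")
        dangles = 2.0 * theta
        dpairs = _pairs_to_angle_grad(pairs, dangles)
        dpairs += circular.modulus_loss_gradient(pairs, config.eps_xy)
        gW, gb = model.backward(dpairs)
        gW, gb = _clip(gW, gb, config.grad_clip)
        opt.step(gW, gb)
    return model


def train(
    model: GeneratorModel,
    system: MolecularSystem,
    topology: DihedralTopology,
    config: TrainingConfig,
    conf0: Conformation | None = None,
) -> tuple[GeneratorModel, TrainingReport]:
    """Train on the decoupled energy/entropy loss.

    Per epoch: one latent batch -> pairs -> angles -> conformations -> one
    energy (and force) evaluation per sample; the entropy term is estimated
    from the same batch of angles with no additional energy calls.
    Deterministic for a fixed config seed on a single thread.
    """
    if conf0 is None:
        conf0 = Conformation(system.positions())
    rng = np.random.default_rng(config.seed + 1)
    opt = _make_optimizer(config.optimizer, model, config.learning_rate,
                          config.weight_decay)
    pairing = build_pairing(system)
    B = config.batch_size
    T = config.t_nn
    rows = []
    energy_calls = 0
    for epoch in range(config.n_train):
        z = sample_latent(config.latent, B, rng)
        pairs = model.forward(z)
        theta = circular.angles_from_pairs(pairs)
        U = np.empty(B)
        dU = np.empty((B, topology.M))
        for b in range(B):
            conf = sample_rotamers(conf0, topology, theta[b], jacobian=True)
            breakdown, g = _energy_and_gradient(
                conf, system, config.soft_core_delta, pairing
            )
            energy_calls += 1
            U[b] = breakdown.total
            dU[b] = np.einsum("mnk,nk->m", conf.angle_jacobian, g)
        if not np.all(np.isfinite(U)):
            raise TrainingDivergenceError(
                f"non-finite energy at epoch {epoch} despite the soft core"
            )
        if config.use_entropy:
            S, dS = circular.nn_entropy_with_gradient(theta)
        else:
            S, dS = 0.0, np.zeros_like(theta)
        L_reg = circular.modulus_loss(pairs, config.eps_xy) + opt.decay_loss()
        U_mean = float(U.mean())
        if config.use_entropy:
            loss = boltzmann_loss(U_mean, S, L_reg, T)
            u_scale, s_scale = (1.0 / T, 1.0) if T >= 1.0 else (1.0, T)
        else:
            loss = energy_only_loss(U_mean, L_reg)
            u_scale, s_scale = 1.0, 0.0
        if not np.isfinite(loss):
            raise TrainingDivergenceError(f"non-finite loss at epoch {epoch}")
        dangles = (u_scale / B) * dU - s_scale * dS
        dpairs = _pairs_to_angle_grad(pairs, dangles)
        dpairs += circular.modulus_loss_gradient(pairs, config.eps_xy)
        gW, gb = model.backward(dpairs)
        gW, gb = _clip(gW, gb, config.grad_clip)
        opt.step(gW, gb)
        rows.append(
            {
                "epoch": epoch,
                "loss": loss,
                "median_energy": float(np.median(U)),
                "min_energy": float(U.min()),
                "entropy": float(S),
                "l_reg": float(L_reg),
            }
        )
    report = TrainingReport(epochs=pd.DataFrame(rows), energy_calls=energy_calls)
    report.validate()
    return model, report


def generate_ensemble(
    model: GeneratorModel,
    system: MolecularSystem,
    topology: DihedralTopology,
    n: int,
    seed: int,
    latent: LatentSpec | None = None,
    conf0: Conformation | None = None,
) -> EnsembleTrajectory:
    """Draw n seeded latent vectors and emit the generated conformations."""
    if conf0 is None:
        conf0 = Conformation(system.positions())
    latent = latent if latent is not None else LatentSpec(dim=model.latent_dim)
    z = sample_latent(latent, n, seed)
    pairs = model.forward(z)
    theta = circular.angles_from_pairs(pairs)
    frames = [sample_rotamers(conf0, topology, theta[b]) for b in range(n)]
    return EnsembleTrajectory(topology=system, frames=frames)


def rmsf(ensemble: EnsembleTrajectory, selection=None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation after superposing every frame
    onto the first (quaternion superposition on the selection)."""
    if len(ensemble.frames) < 2:
        raise UsageError("RMSF needs at least 2 frames")
    n = ensemble.topology.n_atoms
    selection = np.arange(n) if selection is None else np.asarray(selection, dtype=int)
    ref = ensemble.frames[0].positions
    aligned = []
    for f in ensemble.frames:
        res = quaternion_align(f.positions[selection], ref[selection])
        aligned.append(res.transform.apply(f.positions))
    stack = np.stack(aligned)
    mean = stack.mean(axis=0)
    return np.sqrt(np.mean(np.sum((stack - mean) ** 2, axis=-1), axis=0))
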