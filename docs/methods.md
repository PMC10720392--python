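# Methods

This note documents the models and numerical choices behind torsiongen, in
the order a conformation flows through the toolkit.

## Units and conventions

nm, kJ/mol, radians, elementary charge, everywhere. PDB files (Å) are
converted at the I/O boundary only. Atom indexing is 0-based internally;
PDB serials are presentation. Angles are canonicalized to [−π, π), the
codomain of atan2.

## Rotatable-bond metadata

The covalent structure is an undirected graph G = (V, E); a depth-first
spanning tree T (root = atom 0, neighbors visited in ascending index)
breaks each cycle at exactly one bond, and |E| − |V| + 1 bonds are recorded
as broken-cycle edges. Leaf pruning is a **single pass**: every node of
tree degree 1 and its incident edge are dropped, and each surviving edge
carries one dihedral degree of freedom. Single-pass (rather than iterating
to the 2-core) is deliberate: iterated pruning would delete genuine
terminal-group torsions such as the methyl rotation of all-atom ethane,
whose carbons each keep a single heavy neighbor once the hydrogens go.
A consequence worth knowing: a bare ring contributes dihedrals for its
interior (post-break) bonds — the broken-cycle bond is simply removed from
the rotatable set, matching the tree-based sampling model in which the
closure bond is not maintained.

For each dihedral edge, the *rotating set* is the smaller of the two
components produced by deleting the edge from the tree (ties go to the
component containing the lower-indexed endpoint). The measurement
quadruple is stored as (a, r, s, b) with r the endpoint inside the rotating
set, s the static endpoint, and a, b the smallest-index tree neighbors of
r and s. `measure_dihedral` uses the standard two-half-plane construction
with its sine reference axis pointing from the lower- to the higher-indexed
central atom; together with the quadruple orientation this fixes the sign
convention so that applying +θ increases the measured dihedral by +θ. (With
an always-sorted quadruple no quadruple-only function can satisfy that
identity, because the sign flips with which side of the bond rotates.)

## Differentiable rotation

Each dihedral applies Rodrigues' rotation about the unit bond axis
k̂ = (p_u − p_v)/|p_u − p_v| through the bond midpoint, to the rotating set
only. Axis orientation is whatever the endpoint difference yields — no
canonicalization, since the full 2π range is sampled. Rotations are applied
sequentially in topology order (sorted edges), each axis recomputed from
the *intermediate* coordinates; exact inversion therefore requires
reversing the order, which the tests exercise. Angles are deltas from the
input conformation.

Differentiability is implemented as analytic forward-mode Jacobians rather
than an autodiff framework: the sampler propagates ∂x/∂θ_j through the
normalization, the skew matrix, and the rotation of every later step.
θ = 0 is special-cased to a bit-exact no-op (the position update is the
identity, only the direct tangent K·(x − c) is recorded), so that zero
angle vectors reproduce inputs exactly. The contract is behavioral: every
Jacobian must match central finite differences, and the suite enforces
relative error < 1e-4 (measured errors are ~1e-9).

## Fragments and assembly

Fragments are contiguous cuts along the spanning-tree traversal, placed to
balance *dihedral* counts (parallel work is per-dihedral, not per-atom).
Each junction duplicates three anchor atoms into both fragments: the cut
bond's endpoints plus the smallest-index tree neighbor of the upstream
endpoint — three points being the minimum for a unique rigid transform.
No dihedral assigned to a fragment moves one anchor relative to another
(all anchors lie on or upstream of every local axis), so the two copies of
an anchor triple stay congruent and assembly is an *exact* three-point
superposition, built from Gram–Schmidt frames with an analytic derivative
— no SVD or eigensolver in the gradient path.

Within a fragment the rotated side of a bond is always the local downstream
side, even when the global rule picked the (smaller) upstream side;
rotating the complement by the inverse rotation differs only by a rigid
motion of the whole molecule, and axis recomputation is rigid-equivariant,
so the serial and fragment-parallel paths agree up to one global rigid
transform (post-superposition RMSD ~1e-16 nm in practice, tested at 1e-6).

## Superposition

`kabsch_align` delegates to scipy's rotation machinery (reflection-
corrected, optional weights) and serves as the oracle. `quaternion_align`
builds the standard symmetric, traceless 4×4 key matrix from the 3×3
cross-covariance of the centered clouds; the optimal rotation is the unit
quaternion spanning its maximal-eigenvalue eigenspace. The eigenpair is
found by power iteration with repeated matrix squaring (64 squarings reach
the 2⁶⁴-th power); because squaring amplifies the largest *magnitude*
eigenvalue while the method needs the largest *algebraic* one, the matrix
is first shifted by σ = max row absolute sum (a Gershgorin bound, making
the shifted matrix positive semidefinite), normalized after every squaring
to avoid overflow, applied to the deterministic start vector 1/√n (e₁
fallback if annihilated), and the eigenvalue is recovered by a Rayleigh
quotient on the unshifted matrix. Defaults: tol 1e-12 on successive
eigenvector estimates, 64 max squarings. The exact key-matrix basis
convention is verified against Kabsch rather than against any published
sign convention.

## Circular representation and entropy

Each angle is produced from two raw outputs as θ = atan2(y, x): continuous
on the circle, bias-free, with the bounded gradient (−s, c)/(c² + s²). The
modulus loss ε_xy Σ(x² + y² − 1)² keeps pairs away from the origin (where
atan2 is undefined; the forward map defines atan2(0,0) := 0, while the
explicit gradient op raises). The interval penalty
ε_θ(Σ_{θ<min} θ² + Σ_{θ>max} θ²) is implemented only as the comparison
baseline that demonstrates boundary bias.

Entropy of a batch of angle vectors is the mean log distance to the first
nearest neighbor under the toroidal metric Σᵢ[π − |π − |φᵢ − ψᵢ||]²; all
bias-correction constants are dropped, so the value is gradient-grade only
(meaningful up to an additive constant). Nearest-neighbor distances are
floored at 1e-12 before the log, so duplicate samples give a large negative
but finite contribution. For gradients, the nearest-neighbor *index* is
held fixed (standard subgradient of a min) and derivatives flow through the
distances to both members of each pair.

## Force field

Declared functional forms (no ½ factors): bond k_b(r − r0)², angle
k_a(θ − θ0)², torsion k_t(1 + cos(nφ − γ)); Lennard-Jones
4ε[(σ/r_eff)¹² − (σ/r_eff)⁶] with the soft core r_eff = (r⁶ + δ⁶)^(1/6);
Coulomb k_e q_i q_j / r with k_e = 138.935456 kJ mol⁻¹ nm e⁻²; Generalized
Born E = −(k_e/2)(1/ε_in − 1/ε_w) Σ_{ij, incl. i=j} q_i q_j / f_GB with
f_GB = sqrt(r² + R_i R_j exp(−r²/(4 R_i R_j))) — the i = j term is the Born
self-energy, and the r ≫ R limit reproduces the screened Coulomb
interaction (tested to 1% at r = 20R). Born radii are fixed per-atom inputs
with no pairwise descreening: a declared simplification that keeps the
solvent model smooth, differentiable and testable against closed-form
limits; a descreening variant is the natural extension point. Lorentz–
Berthelot combination (arithmetic σ, geometric ε); 1-2/1-3 pairs excluded,
1-4 pairs scaled (defaults 1/2.0 LJ, 1/1.2 Coulomb); no cutoffs or periodic
boundaries (all-pairs, single molecule in implicit solvent); pairs are
enumerated once, not twice.

Soft-core default δ = 0.05 nm during training, δ = 0 for reported energies.
With δ > 0 the softened distance is also used for the Coulomb term inside
`total_energy` (and the GB distance argument), so the total energy and its
forces are finite for *any* conformation, fully overlapping nonbonded atoms
included — the property that keeps training robust. (Bonded terms assume
intact bond geometry, which torsion moves cannot break.) All gradients are
analytic — the torsion gradient uses the standard cross-product form with
translation-invariant middle-atom terms — and every term is validated
against central finite differences, with translation- and rotation-
invariance (net force and net torque ~0) tested separately.

The external-engine bridge accepts any callable returning (energy,
gradient) for a position matrix, validates the shapes, and hands back the
pair in the same form the native force field uses, so a non-differentiable
engine can supply its own forces to training (a surrogate linearization:
value from the engine, derivative from the engine).

## Generator and training

The generator is a fully connected tanh network (default 10 linear layers,
hidden width max(64, 4M)) from an m-dimensional latent space to 2M raw
outputs; tanh's bounded derivative combines with the bounded atan2 gradient
to keep backpropagation well conditioned. Latent families: standard
Gaussian, uniform, and an equal-weight sum of unit Gaussians. Optimizers:
Adam (default) and plain SGD, both with optional L2 weight decay; gradients
are clipped at a configurable max norm (default 100).

Pre-training minimizes Σθ² + L_reg so the network reproduces the input
structure; ~100 epochs suffice on the toy fixtures (the suite uses 200 and
checks mean |θ| < 0.05 rad on a fresh batch). Skipping pre-training is
allowed but logged, since a randomly initialized generator tends to produce
clashed, effectively untrainable structures. Full training uses
U/T − S + L_reg for T ≥ 1 and U − T·S + L_reg for T < 1 (continuous at
T = 1); the branch form preserves the dynamic range of both terms without
dividing U by a small T or multiplying S by a large T. T converts from
Kelvin as T = R·T_K with R = 8.314×10⁻³ kJ mol⁻¹ K⁻¹ (310 K → 2.58).

Decoupling is structural: per epoch the energy function is called exactly
once per generated sample (an instrumented counter makes this a test
assertion), and the entropy gradient is computed from the same batch of
angles. Training is bit-reproducible for a fixed seed on a single thread.

Defaults for the toy experiments: batch 32, learning rate 5e-3 (Adam),
ε_xy = 0.1, soft core δ = 0.05 nm. The learning rate was chosen once as the
smallest round value at which pre-training converges comfortably within
100–200 epochs on the fixtures.

## Synthetic fixtures and what they do (not) show

`make_fixture` builds united-atom chains (0.153 nm bonds, 111° angles,
3-fold torsions), single rings, branched chains, and simplified
polyalanine backbones (N, CA, C, O per residue with standard bond lengths,
AMBER-like partial charges, extended-chain starting geometry). The seed
only jitters coordinates by a few mÅ to break exact symmetry; topology and
parameters are seed-independent. The energy-descent training surrogate
starts from a conformation displaced by 0.8 rad on a dihedral, because the
fixtures are generated near their torsional minima and descent from an
already-minimal start would be unobservable.

These molecules have tens of atoms and 1–13 dihedrals. Passing tests
demonstrate the correctness of the geometry, gradients, losses and the
qualitative training behaviors (pre-training convergence, energy descent,
entropy broadening, call-count decoupling) — they do not demonstrate that
generated ensembles of a real protein match molecular dynamics, which
requires reference MD trajectories and is out of scope here.

## Degenerate inputs and tie-breaks

Coincident bond endpoints → degenerate-axis error; collinear dihedral
triples → degenerate-geometry error; collinear anchor triples →
degenerate-anchor error; non-symmetric matrices and non-unit quaternions →
validation errors; equal component sizes → lower-indexed endpoint's side;
eigensolver non-convergence reports the residual. atan2(0,0) := 0 in the
forward pass only.
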