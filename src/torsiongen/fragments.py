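"""Fragment-parallel torsion sampling with rigid reassembly.

The molecule's spanning tree is cut at dihedral bonds into contiguous
fragments with balanced dihedral counts.  Each fragment is sampled
independently by the serial algorithm restricted to its own atoms and
dihedrals (no cross-fragment data dependency, so fragments may be evaluated
in any order or in parallel), and the fragments are then reassembled by
exact three-point superposition on anchor triples that are duplicated into
both fragments of every junction: the cut bond's two endpoints plus the
smallest-index tree neighbor of the upstream endpoint.

Because no dihedral assigned to a fragment moves one junction anchor
relative to another (the anchors sit on or upstream of every local rotation
axis), the anchor triples of the two fragments are congruent and the
superposition is exact.  Assembly is differentiable: the orthonormal-frame
construction of the three-point transform has an analytic derivative, and
``sample_and_assemble`` propagates the full Jacobian of the assembled
coordinates with respect to every angle.

Equivalence with the serial path holds up to one global rigid transform:
within a fragment the rotated side of each bond may be the opposite of the
global smaller-component choice, which changes the result only by a rigid
motion of the whole molecule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UsageError, ValidationError
from .molio import Conformation, MolecularSystem
from .molgraph import (
    DihedralSpec,
    DihedralTopology,
    build_graph,
    spanning_tree_dfs,
)
from .align import three_point_transform
from .rotamer import sample_rotamers

__all__ = ["FragmentDecomposition", "decompose", "sample_fragments", "assemble",
           "sample_and_assemble"]


@dataclass
class FragmentDecomposition:
    """Atom/dihedral partition plus junction anchors.

    ``fragments[k]`` lists global atom indices (sorted) of fragment k,
    including duplicated anchors; ``dihedral_indices[k]`` indexes into the
    global topology's specs; ``anchors[k]`` is the (a, u, v) triple shared
    by fragments k and k+1; ``local_topologies[k]`` re-expresses fragment
    k's dihedrals in fragment-local atom indices.
    """

    fragments: list[list[int]]
    dihedral_indices: list[list[int]]
    anchors: list[tuple[int, int, int]]
    local_topologies: list[DihedralTopology]
    topology: DihedralTopology

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


def _tree_structure(system: MolecularSystem):
    """Parent map, preorder positions and subtree sets of the DFS tree."""
    tree = spanning_tree_dfs(build_graph(system))
    adj = tree.tree_adjacency()
    parent = {tree.root: None}
    preorder = []
    stack = [tree.root]
    seen = {tree.root}
    while stack:
        x = stack.pop()
        preorder.append(x)
        for y in reversed(adj[x]):  # ascending visit order
            if y not in seen:
                seen.add(y)
                parent[y] = x
                stack.append(y)
    pos_of = {a: i for i, a in enumerate(preorder)}
    children = {a: [] for a in preorder}
    for a, p in parent.items():
        if p is not None:
            children[p].append(a)
    subtree = {}

    def collect(x):
        s = {x}
        for c in children[x]:
            s |= collect(c)
        subtree[x] = s
        return s

    collect(tree.root)
    return tree, adj, parent, pos_of, subtree


def decompose(
    system: MolecularSystem, topology: DihedralTopology, n_fragments: int
) -> FragmentDecomposition:
    """Cut the spanning tree into `n_fragments` dihedral-balanced fragments."""
    M = topology.M
    if not 1 <= n_fragments <= max(M, 1):
        raise UsageError(f"n_fragments must be in [1, {max(M, 1)}]")
    tree, adj, parent, pos_of, subtree = _tree_structure(system)
    n_atoms = system.n_atoms

    # dihedrals ordered along the tree traversal (preorder of the child endpoint)
    def child_of(spec: DihedralSpec) -> int:
        u, v = spec.edge
        return v if parent.get(v) == u else u

    order = sorted(range(M), key=lambda i: pos_of[child_of(topology.specs[i])])

    if n_fragments == 1:
        local = _local_topology(system, topology, list(range(n_atoms)),
                                list(range(M)), subtree, child_of, root_side=None)
        return FragmentDecomposition(
            fragments=[list(range(n_atoms))],
            dihedral_indices=[list(range(M))],
            anchors=[],
            local_topologies=[local],
            topology=topology,
        )

    # candidate cut positions: suffix of the ordered dihedrals = subtree(child)
    candidates = []  # (position in `order`, cut spec index)
    suffix_sets = []
    running = set()
    for p in range(M - 1, -1, -1):
        running = running | {order[p]}
        suffix_sets.append((p, frozenset(running)))
    suffix_of = dict(suffix_sets)
    for p in range(1, M):
        i = order[p]
        c = child_of(topology.specs[i])
        in_subtree = frozenset(
            j for j in range(M) if child_of(topology.specs[j]) in subtree[c]
        )
        if in_subtree == suffix_of[p]:
            candidates.append((p, i))
    if len(candidates) < n_fragments - 1:
        raise UsageError(
            f"only {len(candidates)} cut points available for "
            f"{n_fragments} fragments"
        )

    targets = [round(k * M / n_fragments) for k in range(1, n_fragments)]
    chosen: list[tuple[int, int]] = []
    used = set()
    for t in targets:
        best = min(
            (c for c in candidates if c[0] not in used and
             all(c[0] > p for p, _ in chosen)),
            key=lambda c: abs(c[0] - t),
            default=None,
        )
        if best is None:
            raise UsageError("could not place the requested number of cuts")
        chosen.append(best)
        used.add(best[0])

    cut_positions = [p for p, _ in chosen]
    cut_specs = [topology.specs[i] for _, i in chosen]
    boundaries = [0] + cut_positions + [M]
    dihedral_indices = [
        [order[p] for p in range(boundaries[k], boundaries[k + 1])]
        for k in range(n_fragments)
    ]

    anchors = []
    for spec in cut_specs:
        u, v = spec.edge
        child = v if parent.get(v) == u else u
        up = u if child == v else v
        a_candidates = [x for x in adj[up] if x != child]
        if not a_candidates:
            raise ValidationError("cut bond has no upstream anchor neighbor")
        anchors.append((min(a_candidates), up, child))

    cut_children = [a[2] for a in anchors]
    fragments = []
    for k in range(n_fragments):
        atoms = set(range(n_atoms)) if k == 0 else set(subtree[cut_children[k - 1]])
        if k < n_fragments - 1:
            atoms -= subtree[cut_children[k]]
            atoms |= set(anchors[k])  # duplicate next junction's child
        if k > 0:
            atoms |= set(anchors[k - 1])  # duplicate upstream anchor pair
        fragments.append(sorted(atoms))

    local_topologies = []
    for k in range(n_fragments):
        root_side = set(anchors[k - 1][:2]) if k > 0 else None
        local_topologies.append(
            _local_topology(system, topology, fragments[k], dihedral_indices[k],
                            subtree, child_of, root_side)
        )
    return FragmentDecomposition(
        fragments=fragments,
        dihedral_indices=dihedral_indices,
        anchors=anchors,
        local_topologies=local_topologies,
        topology=topology,
    )


def _local_topology(system, topology, frag_atoms, dihedral_ids, subtree,
                    child_of, root_side):
    """Fragment-local dihedral specs: rotate the downstream (child) side.

    When the *global* rotating set of a bond is the upstream side, rotating
    the local child side about the reversed axis by the same angle produces
    the identical relative geometry (the two choices differ by one rigid
    motion of everything); the local edge tuple is oriented accordingly so
    the serial sampler applied per fragment stays equivalent to the global
    serial path.
    """
    gl_to_loc = {g: i for i, g in enumerate(frag_atoms)}
    frag_set = set(frag_atoms)
    specs = []
    for i in dihedral_ids:
        spec = topology.specs[i]
        child = child_of(spec)
        u, v = spec.edge
        up = u if child == v else v
        rotating = (subtree[child] & frag_set) - {up}
        orient = (u, v) if child in spec.rotating_set else (v, u)
        if not all(q in frag_set for q in spec.quadruple):
            raise ValidationError(
                f"dihedral {spec.edge}: measurement quadruple not contained "
                "in its fragment"
            )
        specs.append(
            DihedralSpec(
                edge=(gl_to_loc[orient[0]], gl_to_loc[orient[1]]),
                rotating_set=frozenset(gl_to_loc[x] for x in rotating),
                quadruple=tuple(gl_to_loc[q] for q in spec.quadruple),
            )
        )
    return DihedralTopology(specs=specs)


def sample_fragments(
    conf0: Conformation,
    decomp: FragmentDecomposition,
    angles,
    jacobian: bool = False,
) -> list[Conformation]:
    """Sample every fragment independently (parallel-safe: no shared state).

    Each returned conformation covers one fragment's atoms in fragment-local
    order; its ``angle_jacobian`` (if requested) is with respect to the
    fragment's own dihedral subset.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.shape != (decomp.topology.M,):
        raise ValidationError(
            f"expected {decomp.topology.M} angles, got {angles.shape}"
        )
    out = []
    for k in range(decomp.n_fragments):
        frag_conf0 = Conformation(conf0.positions[decomp.fragments[k]])
        local_angles = angles[decomp.dihedral_indices[k]]
        out.append(
            sample_rotamers(frag_conf0, decomp.local_topologies[k],
                            local_angles, jacobian=jacobian)
        )
    return out


def _frame(tri: np.ndarray) -> np.ndarray:
    e1 = tri[1] - tri[0]
    e1 = e1 / np.linalg.norm(e1)
    w = tri[2] - tri[0]
    e2 = w - (w @ e1) * e1
    e2 = e2 / np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=1)


def _frame_tangent(tri: np.ndarray, dtri: np.ndarray) -> np.ndarray:
    """Directional derivative of the Gram-Schmidt frame."""
    v1 = tri[1] - tri[0]
    dv1 = dtri[1] - dtri[0]
    n1 = np.linalg.norm(v1)
    e1 = v1 / n1
    de1 = (dv1 - (e1 @ dv1) * e1) / n1
    w = tri[2] - tri[0]
    dw = dtri[2] - dtri[0]
    u2 = w - (w @ e1) * e1
    du2 = dw - (dw @ e1 + w @ de1) * e1 - (w @ e1) * de1
    n2 = np.linalg.norm(u2)
    e2 = u2 / n2
    de2 = (du2 - (e2 @ du2) * e2) / n2
    de3 = np.cross(de1, e2) + np.cross(e1, de2)
    return np.stack([de1, de2, de3], axis=1)


def assemble(
    fragment_confs: list[Conformation], decomp: FragmentDecomposition
) -> Conformation:
    """Rigidly chain fragments onto fragment 0 via their anchor triples.

    Duplicated anchor coordinates are taken from the upstream fragment, so
    junction anchors coincide exactly after assembly.
    """
    conf, _ = _assemble_impl(fragment_confs, decomp, jacobian=False)
    return conf


def sample_and_assemble(
    conf0: Conformation,
    decomp: FragmentDecomposition,
    angles,
    jacobian: bool = False,
) -> Conformation:
    """Fragment-parallel analog of the serial sampler, with optional Jacobian."""
    frag_confs = sample_fragments(conf0, decomp, angles, jacobian=jacobian)
    conf, T = _assemble_impl(frag_confs, decomp, jacobian=jacobian)
    if jacobian:
        conf.angle_jacobian = T
    return conf


def _assemble_impl(fragment_confs, decomp, jacobian):
    if len(fragment_confs) != decomp.n_fragments:
        raise ValidationError("fragment conformation count mismatch")
    n_atoms = max(max(f) for f in decomp.fragments) + 1
    M = decomp.topology.M
    positions = np.full((n_atoms, 3), np.nan)
    T = np.zeros((M, n_atoms, 3)) if jacobian else None

    frag0 = decomp.fragments[0]
    positions[frag0] = fragment_confs[0].positions
    if jacobian:
        jac0 = fragment_confs[0].angle_jacobian
        for lj, gj in enumerate(decomp.dihedral_indices[0]):
            T[gj, frag0] = jac0[lj]

    for k in range(1, decomp.n_fragments):
        frag = decomp.fragments[k]
        gl_to_loc = {g: i for i, g in enumerate(frag)}
        anchor = decomp.anchors[k - 1]
        loc_anchor = [gl_to_loc[a] for a in anchor]
        local = fragment_confs[k].positions
        P_tri = local[loc_anchor]
        Q_tri = positions[list(anchor)]
        if np.any(np.isnan(Q_tri)):
            raise ValidationError("junction anchors missing from upstream fragment")
        transform = three_point_transform(P_tri, Q_tri)
        moved = transform.apply(local)
        new_atoms = [g for g in frag if np.isnan(positions[g, 0])]
        loc_new = [gl_to_loc[g] for g in new_atoms]
        positions[new_atoms] = moved[loc_new]

        if jacobian:
            EP = _frame(P_tri)
            EQ = _frame(Q_tri)
            R = transform.rotation
            local_jac = fragment_confs[k].angle_jacobian
            own = {gj: lj for lj, gj in enumerate(decomp.dihedral_indices[k])}
            rel = local - P_tri[0]
            for gj in range(M):
                dx = local_jac[own[gj]] if gj in own else np.zeros_like(local)
                dP = dx[loc_anchor]
                dQ = T[gj, list(anchor)]
                dEP = _frame_tangent(P_tri, dP)
                dEQ = _frame_tangent(Q_tri, dQ)
                dR = dEQ @ EP.T + EQ @ dEP.T
                dy = rel @ dR.T + (dx - dP[0]) @ R.T + dQ[0]
                T[gj, new_atoms] = dy[loc_new]

    if np.any(np.isnan(positions)):
        raise ValidationError("assembly left unplaced atoms")
    return Conformation(positions=positions), T
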