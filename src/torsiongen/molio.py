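"""Structure and parameter I/O plus deterministic synthetic fixture molecules.

This module is the only place where units are converted: PDB files are in
Angstrom, everything inside the toolkit is nm / kJ/mol / radian / elementary
charge.  Structures are parsed and written with biotite; CONECT records are
interpreted directly from the raw lines so that bonds come *only* from CONECT
(never from residue-name templates).

The topology/parameter format is a small JSON schema documented in
``docs/topology_schema.md``: per-atom charges, Lennard-Jones sigma/epsilon and
Born radii, plus tables of bond, angle and torsion terms.
"""

from __future__ import annotations

import io
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .constants import ANGSTROM_TO_NM
from .errors import FormatError, UsageError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "BondTerm",
    "AngleTerm",
    "TorsionTerm",
    "ForceFieldParameters",
    "MolecularSystem",
    "Conformation",
    "EnsembleTrajectory",
    "read_pdb",
    "write_pdb_models",
    "read_topology",
    "write_topology",
    "infer_bonds_by_distance",
    "make_fixture",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus position in nm."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray  # shape (3,), nm

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValidationError(
                f"atom serial {self.serial}: position must be a finite 3-vector"
            )
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    k_b: float  # kJ/mol/nm^2, E = k_b (r - r0)^2
    r0: float  # nm


@dataclass(frozen=True)
class AngleTerm:
    i: int
    j: int
    k: int
    k_a: float  # kJ/mol/rad^2, E = k_a (theta - theta0)^2
    theta0: float  # rad


@dataclass(frozen=True)
class TorsionTerm:
    i: int
    j: int
    k: int
    l: int
    k_t: float  # kJ/mol, E = k_t (1 + cos(n phi - gamma))
    periodicity: int
    phase: float  # rad


@dataclass
class ForceFieldParameters:
    """Per-atom nonbonded parameters and bonded term tables.

    Units: charge in elementary charges, sigma and Born radii in nm,
    epsilon and torsion barriers in kJ/mol, angles in radians.
    """

    charges: np.ndarray  # (N,) e
    sigmas: np.ndarray  # (N,) nm
    epsilons: np.ndarray  # (N,) kJ/mol
    born_radii: np.ndarray  # (N,) nm
    bond_terms: list[BondTerm] = field(default_factory=list)
    angle_terms: list[AngleTerm] = field(default_factory=list)
    torsion_terms: list[TorsionTerm] = field(default_factory=list)
    scale14_lj: float = 0.5
    scale14_coulomb: float = 1.0 / 1.2
    eps_solute: float = 1.0
    eps_solvent: float = 78.5

    def validate(self, n_atoms: int) -> None:
        for arr, label in (
            (self.charges, "charge"),
            (self.sigmas, "sigma"),
            (self.epsilons, "epsilon"),
            (self.born_radii, "born_radius"),
        ):
            if np.asarray(arr).shape != (n_atoms,):
                raise ValidationError(f"{label} array must have length {n_atoms}")
        bad = np.nonzero(np.asarray(self.sigmas) <= 0)[0]
        if bad.size:
            raise ValidationError(f"atom {bad[0]}: sigma must be > 0")
        bad = np.nonzero(np.asarray(self.epsilons) < 0)[0]
        if bad.size:
            raise ValidationError(f"atom {bad[0]}: epsilon must be >= 0")
        bad = np.nonzero(np.asarray(self.born_radii) <= 0)[0]
        if bad.size:
            raise ValidationError(f"atom {bad[0]}: Born radius must be > 0")
        for t in self.torsion_terms:
            if int(t.periodicity) < 1:
                raise ValidationError(
                    f"torsion ({t.i},{t.j},{t.k},{t.l}): periodicity must be >= 1"
                )


@dataclass
class MolecularSystem:
    """Atoms, covalent bonds and (optionally) force-field parameters.

    Bonds are unordered pairs of 0-based atom indices; PDB serials are
    presentation-only.  This object is the single source of topology truth.
    """

    atoms: list[AtomRecord]
    bonds: set[tuple[int, int]] = field(default_factory=set)
    params: ForceFieldParameters | None = None

    def __post_init__(self):
        n = len(self.atoms)
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != n:
            raise ValidationError("atom serials must be unique within a model")
        canon = set()
        for i, j in self.bonds:
            if i == j:
                raise ValidationError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError(f"bond ({i},{j}) references a nonexistent atom")
            canon.add((min(i, j), max(i, j)))
        self.bonds = canon
        if self.params is not None:
            self.params.validate(n)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        """N x 3 coordinate matrix in nm."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_positions(self, positions: np.ndarray) -> "MolecularSystem":
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (self.n_atoms, 3):
            raise ValidationError("position matrix shape mismatch")
        atoms = [replace(a, position=positions[i]) for i, a in enumerate(self.atoms)]
        return MolecularSystem(atoms=atoms, bonds=set(self.bonds), params=self.params)


@dataclass
class Conformation:
    """An N x 3 coordinate matrix (nm), optionally carrying the Jacobian of the
    coordinates with respect to the dihedral angles that produced it
    (``angle_jacobian``, shape M x N x 3)."""

    positions: np.ndarray
    angle_jacobian: np.ndarray | None = None

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValidationError("Conformation.positions must be N x 3")
        if not np.all(np.isfinite(pos)):
            raise ValidationError("Conformation.positions must be finite")
        self.positions = pos

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


@dataclass
class EnsembleTrajectory:
    """A topology plus a list of frames sharing its atom count."""

    topology: MolecularSystem
    frames: list[Conformation]

    def __post_init__(self):
        n = self.topology.n_atoms
        for t, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise ValidationError(
                    f"frame {t} has {f.n_atoms} atoms, topology has {n}"
                )


# --------------------------------------------------------------------------
# PDB I/O
# --------------------------------------------------------------------------


def _as_text(text_or_path) -> str:
    if hasattr(text_or_path, "read"):
        return text_or_path.read()
    s = str(text_or_path)
    if "\n" in s or s.strip().startswith(("ATOM", "HETATM", "MODEL", "HEADER")):
        return s
    path = Path(s)
    if path.exists():
        return path.read_text()
    return s


def _locate_bad_atom_line(lines: Sequence[str]) -> int | None:
    for lineno, line in enumerate(lines, start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except (ValueError, IndexError):
                return lineno
    return None


def _conect_bonds(lines: Iterable[str], serial_to_index: dict[int, int]) -> set:
    bonds = set()
    for line in lines:
        if not line.startswith("CONECT"):
            continue
        fields = [line[6:11]] + [line[11 + 5 * k : 16 + 5 * k] for k in range(4)]
        serials = []
        for f in fields:
            f = f.strip()
            if f:
                serials.append(int(f))
        if len(serials) < 2:
            continue
        a = serial_to_index.get(serials[0])
        if a is None:
            continue
        for s in serials[1:]:
            b = serial_to_index.get(s)
            if b is None:
                continue
            if a != b:
                bonds.add((min(a, b), max(a, b)))
    return bonds


def read_pdb(text_or_path) -> MolecularSystem:
    """Read the first MODEL of a PDB file (path, text or stream).

    Coordinates are converted Angstrom -> nm.  Bonds come exclusively from
    CONECT records (deduplicated); without CONECT the bond set is empty.
    """
    text = _as_text(text_or_path)
    lines = text.splitlines()
    pdb = PDBFile.read(io.StringIO(text))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise FormatError("no ATOM/HETATM records found (empty input)")
    if n_models > 1:
        logger.warning("PDB contains %d models; reading only the first", n_models)
    try:
        arr = pdb.get_structure(model=1)
    except Exception as exc:  # biotite raises its own error types
        lineno = _locate_bad_atom_line(lines)
        if lineno is not None:
            raise FormatError(f"unparseable ATOM/HETATM record at line {lineno}") from exc
        raise FormatError(f"could not parse PDB: {exc}") from exc
    if arr.array_length() == 0:
        raise FormatError("no ATOM/HETATM records found (empty input)")
    lineno = _locate_bad_atom_line(lines)
    if lineno is not None:
        raise FormatError(f"unparseable ATOM/HETATM record at line {lineno}")

    atoms = []
    for i in range(arr.array_length()):
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]),
                residue_name=str(arr.res_name[i]),
                residue_index=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]),
                position=arr.coord[i] * ANGSTROM_TO_NM,
            )
        )
    serial_to_index = {i + 1: i for i in range(len(atoms))}
    bonds = _conect_bonds(lines, serial_to_index)
    return MolecularSystem(atoms=atoms, bonds=bonds)


def write_pdb_models(ensemble: EnsembleTrajectory, path_or_stream) -> None:
    """Write an ensemble as a multi-MODEL PDB file (nm -> Angstrom)."""
    if not ensemble.frames:
        raise ValidationError("ensemble has no frames")
    topo = ensemble.topology
    n = topo.n_atoms
    template = struc.AtomArray(n)
    template.atom_name = np.array([a.name for a in topo.atoms])
    template.res_name = np.array([a.residue_name for a in topo.atoms])
    template.res_id = np.array([a.residue_index for a in topo.atoms])
    template.chain_id = np.array([a.chain_id for a in topo.atoms])
    template.element = np.array([a.element for a in topo.atoms])
    coords = np.stack([f.positions for f in ensemble.frames]) / ANGSTROM_TO_NM
    stack = struc.AtomArrayStack(len(ensemble.frames), n)
    for ann in ("atom_name", "res_name", "res_id", "chain_id", "element"):
        stack.set_annotation(ann, template.get_annotation(ann))
    stack.coord = coords
    pdb = PDBFile()
    pdb.set_structure(stack)
    lines = list(pdb.lines)
    if len(ensemble.frames) == 1 and not any(l.startswith("MODEL") for l in lines):
        # one MODEL/ENDMDL block per frame, even for a single frame
        lines = ["MODEL        1"] + lines + ["ENDMDL"]
    for i, j in sorted(topo.bonds):
        lines.append(f"CONECT{i + 1:>5d}{j + 1:>5d}")
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text)
    else:
        Path(path_or_stream).write_text(text)


# --------------------------------------------------------------------------
# Topology / parameter JSON
# --------------------------------------------------------------------------


def read_topology(path_or_stream) -> MolecularSystem:
    """Read the toolkit's JSON topology/parameter file into a MolecularSystem."""
    if hasattr(path_or_stream, "read"):
        doc = json.load(path_or_stream)
    else:
        doc = json.loads(Path(path_or_stream).read_text())
    try:
        atom_docs = doc["atoms"]
        bond_list = doc["bonds"]
    except KeyError as exc:
        raise ValidationError(f"topology JSON missing required key {exc}") from exc
    n = len(atom_docs)
    atoms, charges, sigmas, epsilons, born = [], [], [], [], []
    for i, ad in enumerate(atom_docs):
        for key in ("charge", "sigma_nm", "epsilon_kj", "born_radius_nm"):
            if key not in ad:
                raise ValidationError(f"atom {i}: missing required field '{key}'")
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name=str(ad.get("name", f"X{i + 1}")),
                element=str(ad.get("element", "C")),
                residue_name=str(ad.get("residue_name", "LIG")),
                residue_index=int(ad.get("residue_index", 1)),
                chain_id=str(ad.get("chain_id", "A")),
                position=np.asarray(ad.get("position_nm", (0.0, 0.0, 0.0)), dtype=float),
            )
        )
        charges.append(float(ad["charge"]))
        sigmas.append(float(ad["sigma_nm"]))
        epsilons.append(float(ad["epsilon_kj"]))
        born.append(float(ad["born_radius_nm"]))
    bonds = set()
    for b in bond_list:
        i, j = int(b[0]), int(b[1])
        if not (0 <= i < n and 0 <= j < n):
            raise ValidationError(f"bond ({i},{j}) references atom outside 0..{n - 1}")
        bonds.add((min(i, j), max(i, j)))
    params = ForceFieldParameters(
        charges=np.array(charges),
        sigmas=np.array(sigmas),
        epsilons=np.array(epsilons),
        born_radii=np.array(born),
        bond_terms=[BondTerm(**bt) for bt in doc.get("bond_terms", [])],
        angle_terms=[AngleTerm(**at) for at in doc.get("angle_terms", [])],
        torsion_terms=[TorsionTerm(**tt) for tt in doc.get("torsion_terms", [])],
        scale14_lj=float(doc.get("scale14_lj", 0.5)),
        scale14_coulomb=float(doc.get("scale14_coulomb", 1.0 / 1.2)),
        eps_solute=float(doc.get("eps_solute", 1.0)),
        eps_solvent=float(doc.get("eps_solvent", 78.5)),
    )
    return MolecularSystem(atoms=atoms, bonds=bonds, params=params)


def write_topology(system: MolecularSystem, path_or_stream) -> None:
    """Write a MolecularSystem (with parameters) to the JSON topology format."""
    if system.params is None:
        raise ValidationError("system has no force-field parameters to write")
    p = system.params
    doc = {
        "atoms": [
            {
                "name": a.name,
                "element": a.element,
                "residue_name": a.residue_name,
                "residue_index": a.residue_index,
                "chain_id": a.chain_id,
                "position_nm": [float(v) for v in a.position],
                "charge": float(p.charges[i]),
                "sigma_nm": float(p.sigmas[i]),
                "epsilon_kj": float(p.epsilons[i]),
                "born_radius_nm": float(p.born_radii[i]),
            }
            for i, a in enumerate(system.atoms)
        ],
        "bonds": [list(b) for b in sorted(system.bonds)],
        "bond_terms": [vars(t) for t in p.bond_terms],
        "angle_terms": [vars(t) for t in p.angle_terms],
        "torsion_terms": [vars(t) for t in p.torsion_terms],
        "scale14_lj": p.scale14_lj,
        "scale14_coulomb": p.scale14_coulomb,
        "eps_solute": p.eps_solute,
        "eps_solvent": p.eps_solvent,
    }
    text = json.dumps(doc, indent=1)
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text)
    else:
        Path(path_or_stream).write_text(text)


def infer_bonds_by_distance(
    system: MolecularSystem, cutoff_table: dict[tuple[str, str], float]
) -> MolecularSystem:
    """Add a bond for every atom pair closer than the element-pair cutoff (nm).

    Fallback for structures without CONECT records or a topology file.  The
    cutoff table keys are unordered element pairs, e.g. ``{("C", "C"): 0.19}``.
    """
    table = {}
    for (e1, e2), cut in cutoff_table.items():
        table[(e1, e2)] = float(cut)
        table[(e2, e1)] = float(cut)
    pos = system.positions()
    n = system.n_atoms
    bonds = set(system.bonds)
    for i in range(n):
        for j in range(i + 1, n):
            cut = table.get((system.atoms[i].element, system.atoms[j].element))
            if cut is None:
                continue
            if np.linalg.norm(pos[i] - pos[j]) <= cut:
                bonds.add((i, j))
    return MolecularSystem(atoms=list(system.atoms), bonds=bonds, params=system.params)


# --------------------------------------------------------------------------
# Synthetic fixtures
# --------------------------------------------------------------------------

_CC_BOND = 0.153  # nm, united-atom carbon backbone
_CC_ANGLE = math.radians(111.0)

# backbone geometry for the simplified polyalanine chain (nm / rad)
_N_CA = 0.1458
_CA_C = 0.1525
_C_O = 0.1229
_C_N = 0.1329
_BB_ANGLE = math.radians(114.0)


def _place_zigzag(n: int, bond: float, angle: float) -> np.ndarray:
    """Ideal all-trans zigzag chain in the xy plane."""
    pos = np.zeros((n, 3))
    half = (math.pi - angle) / 2.0
    step = np.array([math.cos(half), math.sin(half), 0.0]) * bond
    for i in range(1, n):
        flip = step.copy()
        flip[1] *= (-1) ** (i - 1)
        pos[i] = pos[i - 1] + flip
    return pos


def _chain_params(n: int, bonds, triples, quads) -> ForceFieldParameters:
    charges = np.array([0.05 * (-1) ** i for i in range(n)])
    if n % 2 == 1:
        charges[-1] = 0.0  # keep the molecule neutral
    return ForceFieldParameters(
        charges=charges,
        sigmas=np.full(n, 0.34),
        epsilons=np.full(n, 0.36),
        born_radii=np.full(n, 0.20),
        bond_terms=[BondTerm(i, j, 1.1e5, _CC_BOND) for i, j in bonds],
        angle_terms=[AngleTerm(i, j, k, 250.0, _CC_ANGLE) for i, j, k in triples],
        torsion_terms=[TorsionTerm(i, j, k, l, 4.0, 3, 0.0) for i, j, k, l in quads],
    )


def _atoms_from_positions(pos, names, elements, res_names, res_ids) -> list[AtomRecord]:
    return [
        AtomRecord(
            serial=i + 1,
            name=names[i],
            element=elements[i],
            residue_name=res_names[i],
            residue_index=res_ids[i],
            chain_id="A",
            position=pos[i],
        )
        for i in range(len(names))
    ]


def _chain_like(size: int, rng: np.random.Generator, branch: bool) -> MolecularSystem:
    n = size
    min_size = 5 if branch else 2
    if n < min_size:
        raise UsageError(f"fixture needs size >= {min_size}")
    n_backbone = n - 1 if branch else n
    pos = _place_zigzag(n_backbone, _CC_BOND, _CC_ANGLE)
    bonds = [(i, i + 1) for i in range(n_backbone - 1)]
    if branch:
        attach = n_backbone // 2
        direction = np.array([0.0, 0.0, 1.0])
        pos = np.vstack([pos, pos[attach] + direction * _CC_BOND])
        bonds.append((attach, n - 1))
    pos = pos + rng.normal(scale=0.004, size=pos.shape)  # break exact symmetry
    adjacency = {i: [] for i in range(n)}
    for i, j in bonds:
        adjacency[i].append(j)
        adjacency[j].append(i)
    triples = []
    for j in range(n):
        nb = sorted(adjacency[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                triples.append((nb[a], j, nb[b]))
    quads = _paths_of_length_four(adjacency)
    names = [f"C{i + 1}" for i in range(n)]
    atoms = _atoms_from_positions(pos, names, ["C"] * n, ["LIG"] * n, [1] * n)
    return MolecularSystem(
        atoms=atoms, bonds=set(bonds), params=_chain_params(n, bonds, triples, quads)
    )


def _paths_of_length_four(adjacency: dict[int, list[int]]) -> list[tuple]:
    quads = []
    seen = set()
    for j in adjacency:
        for k in adjacency[j]:
            if j >= k:
                continue
            for i in adjacency[j]:
                if i == k:
                    continue
                for l in adjacency[k]:
                    if l == j or l == i:
                        continue
                    key = (i, j, k, l)
                    if key not in seen:
                        seen.add(key)
                        quads.append(key)
    return quads


def _ring(size: int, rng: np.random.Generator) -> MolecularSystem:
    if size < 3:
        raise UsageError("ring fixture needs size >= 3")
    n = size
    radius = _CC_BOND / (2.0 * math.sin(math.pi / n))
    angles = 2.0 * math.pi * np.arange(n) / n
    pos = np.stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(n)], axis=1
    )
    pos = pos + rng.normal(scale=0.003, size=pos.shape)
    bonds = [(i, (i + 1) % n) for i in range(n)]
    adjacency = {i: [] for i in range(n)}
    for i, j in bonds:
        adjacency[i].append(j)
        adjacency[j].append(i)
    interior = math.pi * (n - 2) / n
    triples = [((j - 1) % n, j, (j + 1) % n) for j in range(n)]
    params = ForceFieldParameters(
        charges=np.zeros(n),
        sigmas=np.full(n, 0.34),
        epsilons=np.full(n, 0.36),
        born_radii=np.full(n, 0.20),
        bond_terms=[BondTerm(i, j, 1.1e5, _CC_BOND) for i, j in bonds],
        angle_terms=[AngleTerm(i, j, k, 250.0, interior) for i, j, k in triples],
        torsion_terms=[
            TorsionTerm(*q, 1.0, 3, 0.0) for q in _paths_of_length_four(adjacency)
        ],
    )
    names = [f"C{i + 1}" for i in range(n)]
    atoms = _atoms_from_positions(pos, names, ["C"] * n, ["RNG"] * n, [1] * n)
    return MolecularSystem(atoms=atoms, bonds=set(bonds), params=params)


# simplified AMBER-like backbone charges for the polyalanine fixture
_BB_CHARGES = {"N": -0.4157, "CA": 0.0337, "C": 0.5973, "O": -0.5679}
_BB_SIGMA = {"N": 0.325, "CA": 0.340, "C": 0.340, "O": 0.296}
_BB_EPS = {"N": 0.711, "CA": 0.458, "C": 0.359, "O": 0.880}
_BB_BORN = {"N": 0.155, "CA": 0.170, "C": 0.170, "O": 0.150}


def _extend(p1, p2, p3, bond, angle, torsion):
    """NeRF-style placement of the next atom from internal coordinates."""
    b1 = p2 - p1
    b2 = p3 - p2
    b2h = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    nh = n / np.linalg.norm(n)
    mh = np.cross(nh, b2h)
    d = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    frame = np.stack([b2h, mh, nh], axis=1)
    return p3 + frame @ d


def _polyala(size: int, rng: np.random.Generator) -> MolecularSystem:
    if size < 2:
        raise UsageError("polyala fixture needs size >= 2 residues")
    phi, psi, omega = math.radians(-135.0), math.radians(135.0), math.pi
    coords = [
        np.array([0.0, 0.0, 0.0]),
        np.array([_N_CA, 0.0, 0.0]),
    ]
    coords.append(
        coords[1]
        + _CA_C * np.array([math.cos(math.pi - _BB_ANGLE), math.sin(math.pi - _BB_ANGLE), 0.0])
    )
    names, res_ids = ["N", "CA", "C"], [1, 1, 1]
    backbone = list(coords)  # N, CA, C of the growing chain (no O)
    torsions = [psi, omega, phi]
    lengths = [_C_N, _N_CA, _CA_C]
    next_names = ["N", "CA", "C"]
    for res in range(2, size + 1):
        for step in range(3):
            p = _extend(
                backbone[-3], backbone[-2], backbone[-1],
                lengths[step], _BB_ANGLE, torsions[step],
            )
            backbone.append(p)
            names.append(next_names[step])
            res_ids.append(res)
    # insert carbonyl O after each C, placed in the peptide plane
    positions, full_names, full_res = [], [], []
    index_of = {}
    for i, (nm, rid) in enumerate(zip(names, res_ids)):
        index_of[(rid, nm)] = len(positions)
        positions.append(backbone[i])
        full_names.append(nm)
        full_res.append(rid)
        if nm == "C":
            n_atom = backbone[i - 2]
            ca = backbone[i - 1]
            c = backbone[i]
            if i + 1 < len(backbone):  # bisector opposite the next N
                ref = backbone[i + 1]
                d = (c - ca) / np.linalg.norm(c - ca) + (c - ref) / np.linalg.norm(c - ref)
            else:
                d = (c - ca) / np.linalg.norm(c - ca) + (c - n_atom) / np.linalg.norm(c - n_atom)
            d = d / np.linalg.norm(d)
            positions.append(c + _C_O * d)
            full_names.append("O")
            full_res.append(rid)
    pos = np.array(positions) + rng.normal(scale=0.002, size=(len(positions), 3))
    n = len(positions)
    bonds = []
    for rid in range(1, size + 1):
        iN, iCA, iC, iO = (
            index_of[(rid, "N")],
            index_of[(rid, "CA")],
            index_of[(rid, "C")],
            index_of[(rid, "C")] + 1,
        )
        bonds += [(iN, iCA), (iCA, iC), (iC, iO)]
        if rid < size:
            bonds.append((iC, index_of[(rid + 1, "N")]))
    adjacency = {i: [] for i in range(n)}
    for i, j in bonds:
        adjacency[i].append(j)
        adjacency[j].append(i)
    triples = []
    for j in range(n):
        nb = sorted(adjacency[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                triples.append((nb[a], j, nb[b]))
    quads = _paths_of_length_four(adjacency)
    kinds = [full_names[i] if full_names[i] in _BB_CHARGES else "CA" for i in range(n)]
    bond_r0 = {}
    for i, j in bonds:
        pair = {full_names[i], full_names[j]}
        if pair == {"N", "CA"}:
            bond_r0[(i, j)] = _N_CA
        elif pair == {"CA", "C"}:
            bond_r0[(i, j)] = _CA_C
        elif pair == {"C", "O"}:
            bond_r0[(i, j)] = _C_O
        else:
            bond_r0[(i, j)] = _C_N
    params = ForceFieldParameters(
        charges=np.array([_BB_CHARGES[k] for k in kinds]),
        sigmas=np.array([_BB_SIGMA[k] for k in kinds]),
        epsilons=np.array([_BB_EPS[k] for k in kinds]),
        born_radii=np.array([_BB_BORN[k] for k in kinds]),
        bond_terms=[BondTerm(i, j, 1.5e5, bond_r0[(i, j)]) for i, j in bonds],
        angle_terms=[AngleTerm(i, j, k, 300.0, _BB_ANGLE) for i, j, k in triples],
        torsion_terms=[TorsionTerm(*q, 2.0, 3, 0.0) for q in quads],
    )
    atoms = _atoms_from_positions(pos, full_names, [nm[0] for nm in full_names],
                                  ["ALA"] * n, full_res)
    return MolecularSystem(atoms=atoms, bonds=set(bonds), params=params)


def make_fixture(kind: str, size: int, seed: int) -> MolecularSystem:
    """Deterministic synthetic molecule with full force-field parameters.

    Kinds: ``chain`` (united-atom alkane of `size` atoms), ``ring`` (single
    `size`-cycle), ``branched`` (chain with one single-atom branch), ``polyala``
    (`size` residues of N, CA, C, O backbone with standard geometry).  The seed
    only jitters coordinates slightly (<= ~0.01 nm) so that conformations are
    generic; topology and parameters are seed-independent.
    """
    rng = np.random.default_rng(seed)
    if kind == "chain":
        system = _chain_like(size, rng, branch=False)
    elif kind == "branched":
        system = _chain_like(size, rng, branch=True)
    elif kind == "ring":
        system = _ring(size, rng)
    elif kind == "polyala":
        system = _polyala(size, rng)
    else:
        raise UsageError(f"unknown fixture kind '{kind}'")
    pos = system.positions()
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)
    if dist.min() < 0.05:
        raise ValidationError("fixture generation produced clashing atoms")
    return system
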