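"""Internal structural model for protein complexes.

Reads PDB files into a light-weight atom/residue model carrying everything
the interface-contact machinery needs: coordinates, crystallographic B
factors, van der Waals radii, a covalent-bond topology with a bond-step
metric, and aromatic-ring pseudo-atoms used to represent pi systems.

Hydrogens are discarded on parsing (crystal structures typically lack
them and every downstream definition operates on heavy atoms or
pseudo-atoms). Alternate locations resolve to the highest-occupancy
conformer, ties broken by file order. Only the first model of multi-model
entries is read.
"""

from __future__ import annotations

import io
import math
import warnings
from collections import deque
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

__all__ = [
    "Atom",
    "Residue",
    "ComplexStructure",
    "CovalentBondGraph",
    "Mutation",
    "parse_pdb",
    "parse_pdb_string",
    "write_pdb",
    "infer_covalent_bonds",
    "bond_steps",
    "nearby_atoms",
    "add_ring_pseudo_atoms",
    "vdw_radius",
    "load_radius_table",
    "STANDARD_RESIDUES",
    "BACKBONE_ATOM_NAMES",
    "RING_ATOM_NAMES",
    "BEYOND",
]

# Sentinel returned by bond_steps when two atoms are farther apart than the
# requested maximum number of covalent-bond steps.
BEYOND = "beyond"

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

BACKBONE_ATOM_NAMES = {"N", "CA", "C", "O"}

# Canonical aromatic-ring atom sets per residue; TRP carries two rings.
RING_ATOM_NAMES: Dict[str, List[Tuple[str, ...]]] = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ],
}

# Covalent-bond inference cutoffs (heavy-atom distance criteria).
BOND_CUTOFF = 1.9  # Angstrom, heavy-heavy
BOND_CUTOFF_S = 2.2  # Angstrom, if either atom is sulfur

# Element used to look up the radius of ring pseudo-atoms (aromatic carbon).
PSEUDO_ELEMENT = "C"


@dataclass
class Atom:
    """A heavy structural atom or a pi-ring pseudo-atom."""

    atom_id: int
    name: str
    element: str
    coords: np.ndarray
    b_factor: float
    vdw_radius: float
    chain_id: str
    res_key: Tuple[str, int, str]  # (chain_id, seq_number, insertion_code)
    res_name: str
    is_water: bool = False
    is_pseudo: bool = False
    is_backbone: bool = False
    occupancy: float = 1.0
    # For pseudo-atoms: atom_ids of the parent ring members.
    pseudo_parents: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.vdw_radius <= 0:
            raise ValueError(f"non-positive vdW radius for atom {self.name}")
        if self.is_pseudo and self.is_backbone:
            raise ValueError("pseudo-atoms are never backbone atoms")
        if self.is_water and self.is_backbone:
            raise ValueError("water atoms are never backbone atoms")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        c, s, i = self.res_key
        return f"<Atom {self.res_name}{s}{i.strip()}:{c} {self.name}>"


@dataclass
class Residue:
    """One residue (or one water molecule) and its atoms."""

    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: List[Atom] = field(default_factory=list)

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def is_water(self) -> bool:
        return self.res_name == "HOH"

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Residue {self.res_name}{self.seq_number}:{self.chain_id}>"


class ComplexStructure:
    """A two-sided protein complex: residues, waters and chain partition."""

    def __init__(
        self,
        structure_id: str,
        side_a: Set[str],
        side_b: Set[str],
    ) -> None:
        if set(side_a) & set(side_b):
            raise ValueError("side_a and side_b share chains")
        self.structure_id = structure_id
        self.side_a = set(side_a)
        self.side_b = set(side_b)
        self.residues: Dict[Tuple[str, int, str], Residue] = {}
        self.waters: List[Residue] = []
        self._next_atom_id = 0

    # -- construction ---------------------------------------------------

    def new_atom_id(self) -> int:
        aid = self._next_atom_id
        self._next_atom_id += 1
        return aid

    def add_residue(self, residue: Residue) -> None:
        if residue.is_water:
            self.waters.append(residue)
        else:
            self.residues[residue.key] = residue

    # -- access ---------------------------------------------------------

    def protein_atoms(self) -> List[Atom]:
        """All non-water atoms, pseudo-atoms included, in file order."""
        out: List[Atom] = []
        for res in self.residues.values():
            out.extend(res.atoms)
        return out

    def water_atoms(self) -> List[Atom]:
        out: List[Atom] = []
        for res in self.waters:
            out.extend(res.atoms)
        return out

    def all_atoms(self) -> List[Atom]:
        return self.protein_atoms() + self.water_atoms()

    def atom_by_id(self) -> Dict[int, Atom]:
        return {a.atom_id: a for a in self.all_atoms()}

    def side_of(self, atom: Atom) -> Optional[str]:
        """'A' or 'B' for protein atoms, None for waters."""
        if atom.is_water:
            return None
        if atom.chain_id in self.side_a:
            return "A"
        if atom.chain_id in self.side_b:
            return "B"
        return None

    def get_residue(
        self, chain_id: str, seq_number: int, insertion_code: str = " "
    ) -> Residue:
        key = (chain_id, seq_number, insertion_code)
        if key not in self.residues:
            raise KeyError(f"residue {chain_id}:{seq_number}{insertion_code.strip()} not found")
        return self.residues[key]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<ComplexStructure {self.structure_id} "
            f"{len(self.residues)} residues, {len(self.waters)} waters>"
        )


@dataclass
class Mutation:
    """A single alanine point mutation at an interfacial residue."""

    chain_id: str
    seq_number: int
    wt_res: str
    insertion_code: str = " "
    mutant_res: str = "ALA"
    ddg_obs: Optional[float] = None  # kcal/mol
    label: Optional[str] = None  # Strong / Intermediate / Weak / Insignificant

    def __post_init__(self) -> None:
        self.wt_res = self.wt_res.upper()
        if self.wt_res == "GLY":
            raise ValueError("Gly->Ala mutations are excluded (backbone reconfiguration risk)")
        if self.wt_res == "ALA":
            raise ValueError("Ala->Ala is not a mutation")
        if self.mutant_res != "ALA":
            raise ValueError("only alanine mutations are supported")

    @property
    def res_key(self) -> Tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def residue(self, structure: ComplexStructure) -> Residue:
        res = structure.get_residue(self.chain_id, self.seq_number, self.insertion_code)
        if res.res_name != self.wt_res:
            raise ValueError(
                f"mutation lists {self.wt_res} at {self.chain_id}:{self.seq_number} "
                f"but structure has {res.res_name}"
            )
        return res


# ---------------------------------------------------------------------------
# van der Waals radii


def load_radius_table(path: Optional[str] = None) -> Dict[str, float]:
    """Load the element -> vdW radius (Angstrom) table.

    The bundled default is a published heavy-atom radius set (Bondi-type
    values). The file is editable: two tab-separated columns, element
    symbol and radius.
    """
    if path is None:
        text = resources.files("hotcontact.data").joinpath("vdw_radii.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: Dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        element, radius = line.split("\t")
        table[element.upper()] = float(radius)
    return table


_DEFAULT_RADII: Optional[Dict[str, float]] = None


def _default_radii() -> Dict[str, float]:
    global _DEFAULT_RADII
    if _DEFAULT_RADII is None:
        _DEFAULT_RADII = load_radius_table()
    return _DEFAULT_RADII


def vdw_radius(element: str, table: Optional[Dict[str, float]] = None) -> float:
    """van der Waals radius for an element symbol; fatal if unknown."""
    table = table if table is not None else _default_radii()
    key = element.upper()
    if key not in table:
        raise KeyError(f"unknown element {element!r}: no van der Waals radius")
    return table[key]


# ---------------------------------------------------------------------------
# Parsing


def parse_pdb(
    path: str,
    side_a: Iterable[str],
    side_b: Iterable[str],
    structure_id: Optional[str] = None,
    radius_table: Optional[Dict[str, float]] = None,
) -> ComplexStructure:
    """Parse a PDB file into a :class:`ComplexStructure`.

    Heavy atoms only (hydrogens discarded); alternate locations resolved
    to highest occupancy; waters (HOH) kept separately from the two
    protein sides. Missing chains and missing B factors are fatal;
    non-standard residues are skipped with a warning.
    """
    with open(path) as fh:
        return parse_pdb_string(
            fh.read(),
            side_a,
            side_b,
            structure_id=structure_id or path,
            radius_table=radius_table,
        )


def parse_pdb_string(
    text: str,
    side_a: Iterable[str],
    side_b: Iterable[str],
    structure_id: str = "complex",
    radius_table: Optional[Dict[str, float]] = None,
) -> ComplexStructure:
    side_a = set(side_a)
    side_b = set(side_b)
    radii = radius_table if radius_table is not None else _default_radii()

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        bio_structure = parser.get_structure(structure_id, io.StringIO(text))
    model = next(iter(bio_structure))  # first model only

    present_chains = {chain.id for chain in model}
    missing = (side_a | side_b) - present_chains
    if missing:
        raise ValueError(f"chains {sorted(missing)} requested but absent from {structure_id}")

    structure = ComplexStructure(structure_id, side_a, side_b)

    for chain in model:
        for bio_res in chain:
            hetflag, seq_number, icode = bio_res.id
            res_name = bio_res.get_resname().strip().upper()
            is_water = hetflag == "W" or res_name == "HOH"
            if is_water:
                res_name = "HOH"
            elif res_name not in STANDARD_RESIDUES:
                warnings.warn(
                    f"skipping non-standard residue {res_name} "
                    f"{chain.id}:{seq_number}{icode.strip()}"
                )
                continue
            elif chain.id not in side_a | side_b:
                # Protein chain not assigned to either side: treat as absent.
                continue
            residue = Residue(chain.id, seq_number, icode, res_name)
            # get_unpacked_list exposes every altloc copy; the loop below
            # collects them all and the de-duplication pass afterwards keeps
            # the highest-occupancy conformer (first in file order on ties).
            for bio_atom in bio_res.get_unpacked_list():
                element = (bio_atom.element or "").strip().upper()
                if element == "H" or element == "D":
                    continue
                if not element:
                    element = bio_atom.get_name().strip()[0]
                b = bio_atom.get_bfactor()
                if b is None:
                    raise ValueError(
                        f"atom {bio_atom.get_name()} in {res_name} {chain.id}:{seq_number} "
                        "has no B factor"
                    )
                name = bio_atom.get_name().strip()
                atom = Atom(
                    atom_id=structure.new_atom_id(),
                    name=name,
                    element=element,
                    coords=np.array(bio_atom.get_coord(), dtype=float),
                    b_factor=float(b),
                    vdw_radius=vdw_radius(element, radii),
                    chain_id=chain.id,
                    res_key=residue.key,
                    res_name=res_name,
                    is_water=is_water,
                    is_backbone=(not is_water) and name in BACKBONE_ATOM_NAMES,
                    occupancy=float(bio_atom.get_occupancy() or 1.0),
                )
                residue.atoms.append(atom)
            if residue.atoms:
                structure.add_residue(residue)

    # De-duplicate altloc copies Bio.PDB may have unpacked: keep the
    # highest-occupancy atom per (residue, atom name), first on ties.
    for res in list(structure.residues.values()) + structure.waters:
        best: Dict[str, Atom] = {}
        for a in res.atoms:
            cur = best.get(a.name)
            if cur is None or a.occupancy > cur.occupancy:
                best[a.name] = a
        if len(best) != len(res.atoms):
            res.atoms = [a for a in res.atoms if best[a.name] is a]
    return structure


def write_pdb(structure: ComplexStructure, path: Optional[str] = None) -> str:
    """Serialize back to PDB text (pseudo-atoms excluded). Returns the text."""
    lines: List[str] = []
    serial = 1
    for res in list(structure.residues.values()) + structure.waters:
        for a in res.atoms:
            if a.is_pseudo:
                continue
            record = "HETATM" if a.is_water else "ATOM  "
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            x, y, z = a.coords
            lines.append(
                f"{record}{serial:>5d} {name}{'':1s}{a.res_name:>3s} {a.chain_id:1s}"
                f"{res.seq_number:>4d}{res.insertion_code:1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
                f"          {a.element:>2s}"
            )
            serial += 1
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Covalent bond graph


class CovalentBondGraph:
    """Symmetric covalent-bond adjacency over atom ids with a step metric."""

    def __init__(self) -> None:
        self.adjacency: Dict[int, Set[int]] = {}

    def add_atom(self, atom_id: int) -> None:
        self.adjacency.setdefault(atom_id, set())

    def add_bond(self, a: int, b: int) -> None:
        if a == b:
            raise ValueError("covalent bonds have two distinct endpoints")
        self.adjacency.setdefault(a, set()).add(b)
        self.adjacency.setdefault(b, set()).add(a)

    def neighbors(self, atom_id: int) -> Set[int]:
        return self.adjacency.get(atom_id, set())

    def steps_within(self, atom_id: int, max_steps: int) -> Dict[int, int]:
        """BFS: atom_id -> step count for all atoms within max_steps."""
        dist = {atom_id: 0}
        queue = deque([atom_id])
        while queue:
            cur = queue.popleft()
            d = dist[cur]
            if d == max_steps:
                continue
            for nxt in self.adjacency.get(cur, ()):
                if nxt not in dist:
                    dist[nxt] = d + 1
                    queue.append(nxt)
        return dist


def _atom_id(atom: Union[Atom, int]) -> int:
    return atom.atom_id if isinstance(atom, Atom) else int(atom)


def bond_steps(
    graph: CovalentBondGraph,
    a: Union[Atom, int],
    b: Union[Atom, int],
    max_steps: int = 3,
) -> Union[int, str]:
    """Shortest covalent path length in bonds, or ``"beyond"`` past max_steps.

    Along a bonded chain i-j-k-l-m the step count from i is 0 to i itself,
    1 to j, 2 to k, 3 to l and 4 to m.
    """
    ia, ib = _atom_id(a), _atom_id(b)
    if ia == ib:
        return 0
    dist = graph.steps_within(ia, max_steps)
    return dist.get(ib, BEYOND)


def nearby_atoms(
    graph: CovalentBondGraph,
    a: Union[Atom, int],
    max_steps: int = 3,
) -> Set[int]:
    """Atom ids within ``max_steps`` covalent-bond steps of ``a`` (inclusive of a)."""
    return set(graph.steps_within(_atom_id(a), max_steps))


def infer_covalent_bonds(structure: ComplexStructure) -> CovalentBondGraph:
    """Distance-based covalent topology.

    Two heavy atoms of the same residue are bonded iff their distance is
    at most 1.9 A (2.2 A when either is sulfur). Consecutive residues of
    one chain are linked through C(i)-N(i+1) under the same cutoff. Waters
    carry no bonds. Ring pseudo-atoms are bonded (step 1) to every atom of
    their parent ring.
    """
    graph = CovalentBondGraph()
    for atom in structure.all_atoms():
        graph.add_atom(atom.atom_id)

    by_id = structure.atom_by_id()

    for res in structure.residues.values():
        real = [a for a in res.atoms if not a.is_pseudo]
        for i, a in enumerate(real):
            for b in real[i + 1 :]:
                cutoff = BOND_CUTOFF_S if "S" in (a.element, b.element) else BOND_CUTOFF
                if np.linalg.norm(a.coords - b.coords) <= cutoff:
                    graph.add_bond(a.atom_id, b.atom_id)
        for a in res.atoms:
            if a.is_pseudo:
                for parent in a.pseudo_parents:
                    graph.add_bond(a.atom_id, parent)

    # Peptide bonds: C of residue i to N of the next residue in the same chain.
    by_chain: Dict[str, List[Residue]] = {}
    for res in structure.residues.values():
        by_chain.setdefault(res.chain_id, []).append(res)
    for chain_residues in by_chain.values():
        for prev, nxt in zip(chain_residues, chain_residues[1:]):
            c = prev.atom("C")
            n = nxt.atom("N")
            if c is not None and n is not None:
                if np.linalg.norm(c.coords - n.coords) <= BOND_CUTOFF:
                    graph.add_bond(c.atom_id, n.atom_id)
    return graph


# ---------------------------------------------------------------------------
# Ring pseudo-atoms


def _ring_plane(coords: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of the least-squares plane through coords."""
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    # The right singular vector with the smallest singular value is the
    # normal of the best-fit plane.
    _, _, vt = np.linalg.svd(centered)
    normal = vt[-1]
    normal = normal / np.linalg.norm(normal)
    return centroid, normal


def add_ring_pseudo_atoms(
    structure: ComplexStructure,
    offset: float = 0.5,
    radius_table: Optional[Dict[str, float]] = None,
) -> ComplexStructure:
    """Represent each aromatic ring by two pseudo-atoms.

    The pair sits at the ring centroid displaced by ``offset`` (default
    0.5 A) along both directions of the unit normal of the ring's
    least-squares plane. The pseudo B factor is the mean B factor of the
    ring atoms. Incomplete rings are skipped with a warning. Idempotent:
    existing pseudo-atoms are not duplicated.
    """
    radii = radius_table if radius_table is not None else _default_radii()
    pseudo_radius = vdw_radius(PSEUDO_ELEMENT, radii)
    for res in structure.residues.values():
        if res.res_name not in RING_ATOM_NAMES:
            continue
        if any(a.is_pseudo for a in res.atoms):
            continue
        for ring_idx, ring_names in enumerate(RING_ATOM_NAMES[res.res_name]):
            ring_atoms = [res.atom(name) for name in ring_names]
            if any(a is None for a in ring_atoms):
                missing = [n for n, a in zip(ring_names, ring_atoms) if a is None]
                warnings.warn(
                    f"incomplete {res.res_name} ring at {res.chain_id}:{res.seq_number} "
                    f"(missing {missing}); no pseudo-atoms placed"
                )
                continue
            coords = np.array([a.coords for a in ring_atoms])
            centroid, normal = _ring_plane(coords)
            b_mean = float(np.mean([a.b_factor for a in ring_atoms]))
            parents = tuple(a.atom_id for a in ring_atoms)
            for sign in (+1.0, -1.0):
                structure_atom = Atom(
                    atom_id=structure.new_atom_id(),
                    name=f"PI{ring_idx}{'A' if sign > 0 else 'B'}",
                    element=PSEUDO_ELEMENT,
                    coords=centroid + sign * offset * normal,
                    b_factor=b_mean,
                    vdw_radius=pseudo_radius,
                    chain_id=res.chain_id,
                    res_key=res.key,
                    res_name=res.res_name,
                    is_pseudo=True,
                    pseudo_parents=parents,
                )
                res.atoms.append(structure_atom)
    return structure
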