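"""Synthetic two-chain complexes with planted interface geometry.

Real training data for hot-spot prediction requires curated crystal
structures and alanine-scanning ddG measurements. For hermetic testing
this module builds small synthetic complexes from ideal residue
templates instead: two short chains face each other across a flat
interface, selected residue columns ("motifs") are planted so their
side-chain tips meet at beta-contact distances, and every mutation gets
a synthetic ddG that is a linear function of its own extracted contact
features plus Gaussian noise.

The geometry is idealized, not physical: backbones are straight,
side chains extend perpendicular to the interface, and B factors are
drawn from a truncated normal distribution. What the fixtures preserve
exactly is the *combinatorics* the method measures - which atoms touch,
which contacts co-occur within three covalent-bond steps, which waters
are buried - so every contact-level quantity can be verified against
the brute-force oracles below.

Also here: the brute-force O(n^3) beta-contact oracle and the O(|C|^2)
co-occurrence oracle, deliberately simple re-implementations used to
cross-check the grid-accelerated production code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .beta_contacts import BetaContact, is_beta_contact
from .config import RunConfig
from .pipeline import extract_features
from .structure_model import (
    Atom,
    ComplexStructure,
    CovalentBondGraph,
    Mutation,
    add_ring_pseudo_atoms,
    bond_steps,
    infer_covalent_bonds,
    parse_pdb_string,
)

__all__ = [
    "FixtureSpec",
    "FixtureTruth",
    "MOTIFS",
    "make_toy_complex",
    "make_hbond_network_fixture",
    "make_buried_water_fixture",
    "make_mutation_table",
    "make_study",
    "random_atom_cloud",
    "brute_force_beta_contacts",
    "brute_force_cooccurring_pairs",
    "RESIDUE_TEMPLATES",
]

# ---------------------------------------------------------------------------
# Ideal residue templates (local frame: backbone near z=0, side chain up +z)

_SPACING = 3.6  # A between consecutive residues along x
_CHAIN_SEPARATION = 10.74  # A between the two backbone planes

_BRANCH_Y = 1.22  # tetrahedral-ish carbon branch offsets
_BRANCH_Z = 0.87


def _hexagon(cg: np.ndarray) -> Dict[str, np.ndarray]:
    """Benzene ring in the local yz-plane, attached at CG (bottom vertex)."""
    center = cg + np.array([0.0, 0.0, 1.39])
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    angles = [270.0, 330.0, 30.0, 90.0, 150.0, 210.0]
    return {
        n: center + 1.39 * np.array([0.0, math.cos(math.radians(a)), math.sin(math.radians(a))])
        for n, a in zip(names, angles)
    }


def _pentagon(cg: np.ndarray, names: List[str], edge: float = 1.37) -> Dict[str, np.ndarray]:
    radius = edge / (2.0 * math.sin(math.pi / 5.0))
    center = cg + np.array([0.0, 0.0, radius])
    angles = [270.0 + 72.0 * k for k in range(5)]
    return {
        n: center + radius * np.array([0.0, math.cos(math.radians(a)), math.sin(math.radians(a))])
        for n, a in zip(names, angles)
    }


def _trp_rings(cg: np.ndarray) -> Dict[str, np.ndarray]:
    """Fused indole: pentagon CG-CD1-NE1-CE2-CD2 plus benzo ring on CD2-CE2."""
    penta = _pentagon(cg, ["CG", "CD1", "NE1", "CE2", "CD2"], edge=1.40)
    cd2, ce2 = penta["CD2"], penta["CE2"]
    p_center = (cg + penta["CD1"] + penta["NE1"] + ce2 + cd2) / 5.0
    mid = 0.5 * (cd2 + ce2)
    out = mid - p_center
    out = out / np.linalg.norm(out)
    hex_center = mid + out * (math.sqrt(3.0) / 2.0) * 1.40

    def ang(p: np.ndarray) -> float:
        v = p - hex_center
        return math.atan2(v[2], v[1])

    a0, a1 = ang(cd2), ang(ce2)
    # Walk the hexagon from CD2 away from CE2: CE3, CZ3, CH2, CZ2.
    step = math.pi / 3.0
    diff = (a1 - a0) % (2.0 * math.pi)
    sign = -1.0 if abs(diff - step) < 1e-6 else 1.0
    r = np.linalg.norm(cd2 - hex_center)
    coords = dict(penta)
    for k, name in enumerate(["CE3", "CZ3", "CH2", "CZ2"], start=1):
        a = a0 + sign * step * k
        coords[name] = hex_center + r * np.array([0.0, math.cos(a), math.sin(a)])
    return coords


def _build_templates() -> Dict[str, Dict[str, Tuple[str, np.ndarray]]]:
    """res_name -> {atom_name: (element, local coords)}."""

    def T(**atoms: Tuple[str, Sequence[float]]):
        return {k: (el, np.array(xyz, dtype=float)) for k, (el, xyz) in atoms.items()}

    N = ("N", (0.0, 0.0, 0.0))
    CA = ("C", (1.46, 0.0, 0.0))
    C = ("C", (2.2, 1.2, 0.0))
    O = ("O", (2.2, 2.43, 0.0))
    cb = np.array([1.46, -0.9, 1.2])
    CB = ("C", tuple(cb))

    def up(p: np.ndarray, d: float) -> np.ndarray:
        return p + np.array([0.0, 0.0, d])

    def branch(p: np.ndarray, sign: float, d: float = 1.5) -> np.ndarray:
        scale = d / 1.5
        return p + np.array([0.0, sign * _BRANCH_Y * scale, _BRANCH_Z * scale])

    cg = up(cb, 1.5)
    templates: Dict[str, Dict[str, Tuple[str, np.ndarray]]] = {}

    templates["GLY"] = T(N=N, CA=CA, C=C, O=O)
    templates["ALA"] = T(N=N, CA=CA, C=C, O=O, CB=CB)
    templates["VAL"] = T(
        N=N, CA=CA, C=C, O=O, CB=CB,
        CG1=("C", tuple(branch(cb, +1))), CG2=("C", tuple(branch(cb, -1))),
    )
    templates["LEU"] = T(
        N=N, CA=CA, C=C, O=O, CB=CB, CG=("C", tuple(cg)),
        CD1=("C", tuple(branch(cg, +1))), CD2=("C", tuple(branch(cg, -1))),
    )
    templates["ILE"] = T(
        N=N, CA=CA, C=C, O=O, CB=CB,
        CG1=("C", tuple(branch(cb, +1))), CG2=("C", tuple(branch(cb, -1))),
        CD1=("C", tuple(up(branch(cb, +1), 1.5))),
    )
    templates["SER"] = T(N=N, CA=CA, C=C, O=O, CB=CB, OG=("O", tuple(up(cb, 1.4))))
    templates["THR"] = T(
        N=N, CA=CA, C=C, O=O, CB=CB,
        OG1=("O", tuple(branch(cb, +1, 1.4))), CG2=("C", tuple(branch(cb, -1))),
    )
    templates["CYS"] = T(N=N, CA=CA, C=C, O=O, CB=CB, SG=("S", tuple(up(cb, 1.8))))
    templates["MET"] = T(
        N=N, CA=CA, C=C, O=O, CB=CB, CG=("C", tuple(cg)),
        SD=("S", tuple(up(cg, 1.8))), CE=("C", tuple(up(cg, 3.3))),
    )
    templates["ASP"] = T(
        N=N, CA=CA, C=C, O=O, CB=CB, CG=("C", tuple(cg)),
        OD1=("O", tuple(branch(cg, +1, 1.25))), OD2=("O", tuple(branch(cg, -1, 1.25))),
    )
    templates["ASN"] = T(
        N=N, CA=CA, C=C, O=O, CB=CB, CG=("C", tuple(cg)),
        OD1=("O", tuple(branch(cg, +1, 1.25))), ND2=("N", tuple(branch(cg, -1, 1.33))),
    )
    cd = up(cg, 1.5)
    templates["GLU"] = T(
        N=N, CA=CA, C=C, O=O, CB=CB, CG=("C", tuple(cg)), CD=("C", tuple(cd)),
        OE1=("O", tuple(branch(cd, +1, 1.25))), OE2=("O", tuple(branch(cd, -1, 1.25))),
    )
    templates["GLN"] = T(
        N=N, CA=CA, C=C, O=O, CB=CB, CG=("C", tuple(cg)), CD=("C", tuple(cd)),
        OE1=("O", tuple(branch(cd, +1, 1.25))), NE2=("N", tuple(branch(cd, -1, 1.33))),
    )
    hexa = _hexagon(cg)
    templates["PHE"] = T(
        N=N, CA=CA, C=C, O=O, CB=CB,
        **{k: ("C", tuple(v)) for k, v in hexa.items()},
    )
    templates["TYR"] = T(
        N=N, CA=CA, C=C, O=O, CB=CB,
        **{k: ("C", tuple(v)) for k, v in hexa.items()},
        OH=("O", tuple(hexa["CZ"] + np.array([0.0, 0.0, 1.36]))),
    )
    penta = _pentagon(cg, ["CG", "ND1", "CE1", "NE2", "CD2"])
    templates["HIS"] = T(
        N=N, CA=CA, C=C, O=O, CB=CB,
        **{k: ("N" if k.startswith("N") else "C", tuple(v)) for k, v in penta.items()},
    )
    trp = _trp_rings(cg)
    templates["TRP"] = T(
        N=N, CA=CA, C=C, O=O, CB=CB,
        **{k: ("N" if k.startswith("N") else "C", tuple(v)) for k, v in trp.items()},
    )
    return templates


RESIDUE_TEMPLATES = _build_templates()


# ---------------------------------------------------------------------------
# Fixture specification and truth

# Planted interface motifs: (residue on side A, residue on side B).
# Each motif occupies one column of the interface lattice; the chain
# separation is fixed so the listed tip pairs meet at contact distance.
MOTIFS: Dict[str, Tuple[str, str]] = {
    "cc": ("LEU", "LEU"),  # hydrophobic C_c-C_c pair, co-occurring twice
    "hbond": ("SER", "GLU"),  # hydroxyl donor against carboxylate acceptors
    "polar": ("ASN", "GLN"),  # amide network: hbond/donor-donor/acc-acc mix
    "sulfur": ("CYS", "GLN"),  # thiol against amide: S-O/N contacts
    "pi": ("PHE", "ALA"),  # ring face approached by the next column's B GLN
    "pi_rev": ("ILE", "PHE"),  # side B ring over side A aliphatic tips
    "none": ("ALA", "ALA"),  # spacer, no cross-interface contact
}

# Side-A residues used to fill unplanted columns (no partner reach).
_FILLER_RESIDUES = ("SER", "THR", "VAL", "ASN", "LEU", "ILE")


@dataclass
class FixtureSpec:
    """Deterministic recipe for one synthetic complex."""

    n_residues_per_chain: int = 12
    planted_contacts: Sequence[Tuple[int, str]] = ()  # (column, motif name)
    planted_hbond_network_size: int = 0
    bfactor_mean: float = 30.0  # A^2
    bfactor_sd: float = 10.0  # A^2
    noise_sd: Optional[float] = None  # kcal/mol; None = calibrate to SNR 2:1
    seed: int = 0
    structure_id: str = "SYNTH"

    def __post_init__(self) -> None:
        for column, motif in self.planted_contacts:
            if motif not in MOTIFS:
                raise ValueError(f"unknown motif {motif!r}")
            if not 0 <= column < self.n_residues_per_chain:
                raise ValueError(f"column {column} outside the chain")
        if self.planted_hbond_network_size > 3:
            raise ValueError(
                "hydrogen-bond network fixtures support at most 3 partners "
                "(more would contact each other and contaminate the network count)"
            )


@dataclass
class FixtureTruth:
    """Oracle-derived ground truth for one emitted fixture."""

    contacts: Set[FrozenSet[int]]
    cross_contacts: Set[FrozenSet[int]]
    interfacial_atoms: Set[int]
    cooccurring_pairs: Set[FrozenSet[FrozenSet[int]]]
    atom_index: Dict[int, Tuple[str, int, str]]  # atom_id -> (chain, seq, name)
    mutations: List[Mutation] = field(default_factory=list)

    def atoms_named(self, chain: str, seq: int, names: Iterable[str]) -> Set[int]:
        wanted = set(names)
        return {
            aid
            for aid, (c, s, n) in self.atom_index.items()
            if c == chain and s == seq and n in wanted
        }


# ---------------------------------------------------------------------------
# PDB text emission


def _format_atom_line(
    serial: int,
    name: str,
    res_name: str,
    chain: str,
    seq: int,
    xyz: np.ndarray,
    b: float,
    element: str,
    hetatm: bool = False,
) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    padded = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record}{serial:>5d} {padded} {res_name:>3s} {chain:1s}{seq:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{b:6.2f}"
        f"          {element:>2s}"
    )


def _residue_atoms(
    res_name: str, column: int, flip: bool
) -> List[Tuple[str, str, np.ndarray]]:
    """(atom_name, element, global coords) for one lattice residue."""
    out = []
    offset = np.array([column * _SPACING, 0.0, 0.0])
    for atom_name, (element, local) in RESIDUE_TEMPLATES[res_name].items():
        coords = local.copy()
        if flip:
            coords = np.array([coords[0], coords[1], _CHAIN_SEPARATION - coords[2]])
        out.append((atom_name, element, coords + offset))
    return out


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix sending +z to ``direction`` (unit)."""
    z = np.array([0.0, 0.0, 1.0])
    d = direction / np.linalg.norm(direction)
    v = np.cross(z, d)
    c = float(np.dot(z, d))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _network_partner_atoms(
    og_target: np.ndarray, tip_direction: np.ndarray
) -> List[Tuple[str, str, np.ndarray]]:
    """A free-standing SER whose OG sits at ``og_target``.

    ``tip_direction`` is where the side chain points; the backbone trails
    behind the hydroxyl on the opposite side.
    """
    rot = _rotation_to(tip_direction)
    template = RESIDUE_TEMPLATES["SER"]
    og_local = template["OG"][1]
    out = []
    for atom_name, (element, local) in template.items():
        coords = og_target + rot @ (local - og_local)
        out.append((atom_name, element, coords))
    return out


def _water_cage_atoms(center: np.ndarray, radius: float = 2.8) -> List[np.ndarray]:
    """12 icosahedron vertices around ``center`` (a fully burying cage)."""
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    raw = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            raw.append(np.array([0.0, a, b]))
            raw.append(np.array([a, b, 0.0]))
            raw.append(np.array([b, 0.0, a]))
    return [center + radius * v / np.linalg.norm(v) for v in raw]


# ---------------------------------------------------------------------------
# Brute-force oracles


def brute_force_beta_contacts(
    atoms: Sequence[Atom],
    td_factor: float = 1.25,
    beta_angle_deg: float = 85.0,
    bonds: Optional[CovalentBondGraph] = None,
    structure: Optional[ComplexStructure] = None,
) -> List[BetaContact]:
    """All-pairs beta contacts with the full interrupter scan (no grid).

    Deliberately simple O(n^2) pair loop with an O(n) interruption test
    per pair, used as the independent oracle against the production
    grid-accelerated search. Same contact definition: pseudo-atoms never
    interrupt, water-water pairs, same-residue pairs and covalently
    bonded pairs are not contacts.
    """
    atoms = list(atoms)
    real = [a for a in atoms if not a.is_pseudo]
    coords = np.array([a.coords for a in real]) if real else np.empty((0, 3))
    ids = np.array([a.atom_id for a in real], dtype=int)
    cos_beta = math.cos(math.radians(beta_angle_deg))
    contacts: List[BetaContact] = []
    for i in range(len(atoms)):
        ai = atoms[i]
        for j in range(i + 1, len(atoms)):
            aj = atoms[j]
            if ai.is_water and aj.is_water:
                continue
            if (not ai.is_water) and (not aj.is_water) and ai.res_key == aj.res_key:
                continue
            if bonds is not None and aj.atom_id in bonds.neighbors(ai.atom_id):
                continue
            d = float(np.linalg.norm(ai.coords - aj.coords))
            if d > td_factor * (ai.vdw_radius + aj.vdw_radius):
                continue
            interrupted = False
            if len(real):
                mask = (ids != ai.atom_id) & (ids != aj.atom_id)
                v1 = ai.coords[None, :] - coords[mask]
                v2 = aj.coords[None, :] - coords[mask]
                n1 = np.linalg.norm(v1, axis=1)
                n2 = np.linalg.norm(v2, axis=1)
                ok = (n1 > 0) & (n2 > 0)
                cosang = (v1[ok] * v2[ok]).sum(axis=1) / (n1[ok] * n2[ok])
                interrupted = bool(np.any(cosang <= cos_beta))
            if interrupted:
                continue
            if structure is not None:
                si, sj = structure.side_of(ai), structure.side_of(aj)
                cross = si is not None and sj is not None and si != sj
            else:
                cross = False
            contacts.append(BetaContact(ai, aj, d, cross))
    return contacts


def brute_force_cooccurring_pairs(
    contacts: Sequence[BetaContact],
    bonds: CovalentBondGraph,
    seeds: Optional[Sequence[BetaContact]] = None,
) -> Set[FrozenSet[FrozenSet[int]]]:
    """O(|C|^2) double loop over contact pairs testing endpoint bond steps."""
    seeds = list(seeds) if seeds is not None else list(contacts)
    pairs: Set[FrozenSet[FrozenSet[int]]] = set()
    for s in seeds:
        for c in contacts:
            if c.key == s.key:
                continue
            hit = False
            for e1 in s.atom_ids:
                for e2 in c.atom_ids:
                    if bond_steps(bonds, e1, e2, max_steps=3) != "beyond":
                        hit = True
            if hit:
                pairs.add(frozenset((s.key, c.key)))
    return pairs


# ---------------------------------------------------------------------------
# Fixture generation


def _spec_layout(spec: FixtureSpec, rng: np.random.Generator):
    """Resolve each lattice column to (a_res, b_res, motif or None)."""
    layout: List[Tuple[str, str, Optional[str]]] = []
    planted = dict(spec.planted_contacts)
    for column in range(spec.n_residues_per_chain):
        motif = planted.get(column)
        if motif is not None:
            a_res, b_res = MOTIFS[motif]
            layout.append((a_res, b_res, motif))
        else:
            a_res = str(rng.choice(_FILLER_RESIDUES))
            layout.append((a_res, "ALA", None))
    # The "pi" motif needs its partner GLN one column downstream on side B.
    for column, (a_res, b_res, motif) in enumerate(layout):
        if motif == "pi" and column + 1 < len(layout):
            nxt = layout[column + 1]
            if nxt[2] is None:
                layout[column + 1] = ("ALA", "GLN", None)
    return layout


def make_toy_complex(spec: FixtureSpec) -> Tuple[str, FixtureTruth]:
    """Emit a synthetic complex as PDB text plus its oracle-derived truth.

    Chains A and B face each other across a flat interface; columns with
    planted motifs make cross-interface beta contacts, all other columns
    stay out of reach. Deterministic: the same spec yields byte-identical
    text. The truth is regenerated from the emitted text through the
    brute-force oracles, so it is self-consistent by construction.
    """
    rng = np.random.default_rng(spec.seed)
    layout = _spec_layout(spec, rng)

    records: List[Tuple[str, int, str, str, str, np.ndarray, bool]] = []
    # (chain, seq, res_name, atom_name, element, coords, hetatm)
    for column, (a_res, _, _) in enumerate(layout):
        for atom_name, element, coords in _residue_atoms(a_res, column, flip=False):
            records.append(("A", column + 1, a_res, atom_name, element, coords, False))
    for column, (_, b_res, _) in enumerate(layout):
        for atom_name, element, coords in _residue_atoms(b_res, column, flip=True):
            records.append(("B", column + 1, b_res, atom_name, element, coords, False))

    # Optional hydrogen-bond network: one side-A SER whose hydroxyl is
    # the hub of ``size`` side-B SER hydroxyls. The lattice is dropped in
    # this mode so the hub's contacts are exactly the planted hydrogen
    # bonds (the only other atom pairs in reach are interrupted or are
    # carbon contacts).
    if spec.planted_hbond_network_size > 0:
        records = []
        for atom_name, element, coords in _residue_atoms("SER", 0, flip=False):
            records.append(("A", 1, "SER", atom_name, element, coords, False))
        og = RESIDUE_TEMPLATES["SER"]["OG"][1]
        polar = math.radians(55.0)
        for k in range(spec.planted_hbond_network_size):
            azimuth = 2.0 * math.pi * k / max(spec.planted_hbond_network_size, 2)
            direction = np.array(
                [
                    math.sin(polar) * math.cos(azimuth),
                    math.sin(polar) * math.sin(azimuth),
                    math.cos(polar),
                ]
            )
            target = og + 3.0 * direction
            seq = 100 + k
            for atom_name, element, coords in _network_partner_atoms(target, -direction):
                records.append(("B", seq, "SER", atom_name, element, coords, False))

    records.sort(key=lambda r: (r[0], r[1]))
    lines = []
    serial = 1
    for chain, seq, res_name, atom_name, element, coords, hetatm in records:
        b = max(1.0, float(rng.normal(spec.bfactor_mean, spec.bfactor_sd)))
        lines.append(
            _format_atom_line(serial, atom_name, res_name, chain, seq, coords, b, element, hetatm)
        )
        serial += 1
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    truth = _truth_from_pdb(pdb_text, spec)
    if spec.planted_hbond_network_size > 0:
        truth.mutations = [Mutation(chain_id="A", seq_number=1, wt_res="SER")]
    else:
        truth.mutations = [
            Mutation(chain_id="A", seq_number=column + 1, wt_res=a_res)
            for column, (a_res, _, _) in enumerate(layout)
            if a_res not in ("ALA", "GLY")
        ]
    return pdb_text, truth


def _truth_from_pdb(pdb_text: str, spec: FixtureSpec) -> FixtureTruth:
    structure = parse_pdb_string(pdb_text, {"A"}, {"B"}, structure_id=spec.structure_id)
    add_ring_pseudo_atoms(structure)
    bonds = infer_covalent_bonds(structure)
    atoms = structure.all_atoms()
    contacts = brute_force_beta_contacts(atoms, bonds=bonds, structure=structure)
    cross = {c.key for c in contacts if c.cross_interface}
    interfacial: Set[int] = set()
    for c in contacts:
        if c.cross_interface:
            interfacial.update(c.atom_ids)
    cooc = brute_force_cooccurring_pairs(contacts, bonds)
    index = {
        a.atom_id: (a.chain_id, a.res_key[1], a.name)
        for a in atoms
    }
    return FixtureTruth(
        contacts={c.key for c in contacts},
        cross_contacts=cross,
        interfacial_atoms=interfacial,
        cooccurring_pairs=cooc,
        atom_index=index,
    )


def make_hbond_network_fixture(size: int, seed: int = 0) -> Tuple[str, FixtureTruth]:
    """A cluster of ``size`` mutually co-occurring hydrogen-bond contacts.

    One side-A serine hydroxyl is surrounded by ``size`` side-B serine
    hydroxyls; every cross-interface contact shares the central OG, so
    all hydrogen-bond contacts pairwise co-occur and the (hbond, hbond)
    co-occurrence element aggregates size*(size-1)/2 pairs.
    """
    if size < 1:
        raise ValueError("network size must be at least 1")
    spec = FixtureSpec(
        n_residues_per_chain=5,
        planted_contacts=(),
        planted_hbond_network_size=size,
        seed=seed,
        structure_id=f"HBNET{size}",
    )
    return make_toy_complex(spec)


def make_buried_water_fixture(
    qualify: bool = True, seed: int = 0
) -> Tuple[str, FixtureTruth]:
    """A water enclosed by an icosahedral cage of serine hydroxyls.

    With ``qualify`` the cage is polar (hydroxyl oxygens): the water is
    buried (ASA 0) with 12 beta contacts to acceptors and qualifies for
    the contact graph. With ``qualify=False`` the cage is built from
    alanine CB carbons instead, so the water stays buried but fails the
    donor/acceptor requirement.
    """
    rng = np.random.default_rng(seed)
    center = np.array([0.0, 0.0, 6.0])
    cage = _water_cage_atoms(center)
    lines = []
    serial = 1
    for k, vertex in enumerate(cage):
        chain = "A" if k < 6 else "B"
        seq = k + 1
        outward = (vertex - center) / np.linalg.norm(vertex - center)
        if qualify:
            for atom_name, element, coords in _network_partner_atoms(vertex, -outward):
                b = max(1.0, float(rng.normal(30.0, 10.0)))
                lines.append(
                    _format_atom_line(serial, atom_name, "SER", chain, seq, coords, b, element)
                )
                serial += 1
        else:
            template = RESIDUE_TEMPLATES["ALA"]
            rot = _rotation_to(-outward)
            cb_local = template["CB"][1]
            for atom_name, (element, local) in template.items():
                coords = vertex + rot @ (local - cb_local)
                b = max(1.0, float(rng.normal(30.0, 10.0)))
                lines.append(
                    _format_atom_line(serial, atom_name, "ALA", chain, seq, coords, b, element)
                )
                serial += 1
    b = max(1.0, float(rng.normal(30.0, 10.0)))
    lines.append(_format_atom_line(serial, "O", "HOH", "W", 1, center, b, "O", hetatm=True))
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"
    spec = FixtureSpec(n_residues_per_chain=1, seed=seed, structure_id="WATCAGE")
    return pdb_text, _truth_from_pdb(pdb_text, spec)


# ---------------------------------------------------------------------------
# Synthetic ddG and the planted-signal study

# Linear ddG weights over feature semantics the method emphasizes:
# hydrophobic mutated contacts, the hydrophobic/pi co-occurrence, the
# hydrogen-bond network co-occurrence, and neighborhood hydrogen bonds.
# Contact features are non-positive, so negative weights make dense
# contact neighborhoods raise ddG.
DEFAULT_DDG_WEIGHTS: Dict[str, float] = {
    "mut_t03": -0.5,
    "nbr_t00": -0.35,
    "cooc_t03_t09": -0.06,
    "cooc_t00_t00": -0.2,
}
DEFAULT_DDG_INTERCEPT = 0.3


def make_mutation_table(
    features: pd.DataFrame,
    weights: Optional[Dict[str, float]] = None,
    intercept: float = DEFAULT_DDG_INTERCEPT,
    noise_sd: Optional[float] = None,
    seed: int = 0,
    label_threshold: float = 2.0,
) -> pd.DataFrame:
    """Attach synthetic ddG (kcal/mol) to an extracted feature table.

    ddG = intercept + sum(w_f * x_f) + N(0, noise_sd). With
    ``noise_sd=None`` the noise is calibrated to a 2:1 signal-to-noise
    ratio (sd of the linear signal over the table, halved). Hot-spot
    labels use the >= 2 kcal/mol rule.
    """
    weights = weights if weights is not None else DEFAULT_DDG_WEIGHTS
    rng = np.random.default_rng(seed)
    signal = np.full(len(features), float(intercept))
    for name, w in weights.items():
        signal += w * features[name].to_numpy(dtype=float)
    if noise_sd is None:
        spread = float(np.std(signal))
        noise_sd = spread / 2.0 if spread > 0 else 0.25
    out = features.copy()
    out["ddg_obs"] = signal + rng.normal(0.0, noise_sd, size=len(features))
    out["label"] = np.where(out["ddg_obs"] >= label_threshold, "Strong", "Insignificant")
    return out


def _random_study_spec(index: int, rng: np.random.Generator, n_columns: int) -> FixtureSpec:
    motif_names = [m for m in MOTIFS if m != "none"]
    columns = list(range(0, n_columns, 2))  # motifs on even columns, spacers between
    rng.shuffle(columns)
    n_motifs = int(rng.integers(2, min(len(columns), 5) + 1))
    planted = tuple(
        (col, str(rng.choice(motif_names))) for col in sorted(columns[:n_motifs])
    )
    return FixtureSpec(
        n_residues_per_chain=n_columns,
        planted_contacts=planted,
        seed=int(rng.integers(0, 2**31 - 1)),
        structure_id=f"SYN{index:03d}",
    )


def make_study(
    n_complexes: int = 20,
    n_columns: int = 12,
    seed: int = 1,
    config: Optional[RunConfig] = None,
    weights: Optional[Dict[str, float]] = None,
    noise_sd: Optional[float] = None,
) -> pd.DataFrame:
    """The planted-signal benchmark: features + synthetic ddG for a cohort.

    Generates ``n_complexes`` synthetic complexes with randomly planted
    motifs, extracts the 143-element descriptors through the full
    pipeline, and attaches linear-plus-noise ddG (noise calibrated to a
    2:1 signal-to-noise ratio over the whole cohort unless given).
    """
    cfg = config or RunConfig()
    rng = np.random.default_rng(seed)
    tables = []
    for index in range(n_complexes):
        spec = _random_study_spec(index, rng, n_columns)
        pdb_text, truth = make_toy_complex(spec)
        structure = parse_pdb_string(pdb_text, {"A"}, {"B"}, structure_id=spec.structure_id)
        table = extract_features(structure, truth.mutations, cfg, complex_id=spec.structure_id)
        tables.append(table)
    features = pd.concat(tables, ignore_index=True)
    return make_mutation_table(
        features,
        weights=weights,
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# Random atom clouds (for oracle-equivalence stress tests)


def random_atom_cloud(
    n_atoms: int,
    seed: int = 0,
    box: float = 18.0,
    elements: Sequence[str] = ("C", "N", "O", "S"),
) -> List[Atom]:
    """Random unstructured atoms in a box, split into two pseudo-sides."""
    from .structure_model import vdw_radius as _vdw

    rng = np.random.default_rng(seed)
    atoms = []
    for i in range(n_atoms):
        element = str(rng.choice(elements))
        chain = "A" if i < n_atoms // 2 else "B"
        atoms.append(
            Atom(
                atom_id=i,
                name=f"X{i}",
                element=element,
                coords=rng.uniform(0.0, box, size=3),
                b_factor=float(rng.normal(30.0, 10.0)),
                vdw_radius=_vdw(element),
                chain_id=chain,
                res_key=(chain, i, " "),
                res_name="UNK",
            )
        )
    return atoms
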