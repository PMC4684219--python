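"""Atom typing, contact typing, and the 143-element mutation descriptor.

Atoms of the 20 standard residues (plus water oxygens and ring
pseudo-atoms) fall into 10 groups; unordered group pairs collapse into 14
contact types. The anchored semantics are: type 0 hydrogen-bond
(donor-acceptor) contacts, type 2 C_c with oxygen/nitrogen, type 3
C_c with C_c (hydrophobic), type 4 C_on with oxygen/nitrogen, type 5
C_on with C_c, type 9 pi-involving contacts, type 13 acceptor-acceptor
contacts; here C_c denotes carbons with no covalent bond to oxygen or
nitrogen and C_on carbons with such a bond. The remaining groups and
types (donor-donor, C_on-C_on, the sulfur and water splits) complete the
partition to exactly 10 groups and 14 types; both tables ship as
editable TSV data files.

A mutation's descriptor concatenates five blocks into 143 named values:

    [ B-factor (8) | dASA (2) | mutated contacts (14)
      | neighborhood cross-interface contacts (14) | co-occurrence (105) ]

Every contact-derived entry is a sum of contact weights
(B''_i + B''_j)/2 in [-2, 0], so positions 10-142 are never positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .beta_contacts import BetaContact, ContactGraph
from .bfactor_norm import (
    BfactorStats,
    b_norm_clamped,
    bfactor_vector,
    mutated_atoms,
)
from .structure_model import (
    Atom,
    ComplexStructure,
    CovalentBondGraph,
    Mutation,
    nearby_atoms,
)
from .surface_area import AsaTable, delta_asa_features

__all__ = [
    "N_ATOM_GROUPS",
    "N_CONTACT_TYPES",
    "N_COOC",
    "N_FEATURES",
    "ATOM_GROUP_NAMES",
    "CONTACT_TYPE_NAMES",
    "FEATURE_NAMES",
    "MutationFeatureVector",
    "load_atom_group_table",
    "atom_group",
    "contact_type",
    "contact_weight",
    "triangular_index",
    "triangular_pair",
    "mutated_contact_vector",
    "neighborhood_interface_vector",
    "cooccurring_pairs",
    "cooccurrence_vector",
    "assemble_features",
]

N_ATOM_GROUPS = 10
N_CONTACT_TYPES = 14
N_COOC = N_CONTACT_TYPES * (N_CONTACT_TYPES + 1) // 2  # 105
N_FEATURES = 8 + 2 + N_CONTACT_TYPES + N_CONTACT_TYPES + N_COOC  # 143

# Atom groups (indices are the package's own; the published supplementary
# table is unavailable and this partition is a documented reconstruction).
ATOM_GROUP_NAMES = [
    "N_DON",  # 0 nitrogen hydrogen-bond donors
    "O_ACC",  # 1 carbonyl/carboxylate oxygen acceptors
    "O_DA",  # 2 hydroxyl oxygens: donor and acceptor
    "N_DA",  # 3 histidine ring nitrogens: donor or acceptor
    "C_C",  # 4 carbons with no covalent bond to O/N
    "C_ON",  # 5 carbons covalently bonded to O or N
    "S",  # 6 sulfur
    "PI",  # 7 aromatic-ring pseudo-atoms
    "N_PRO",  # 8 proline backbone nitrogen (no donor hydrogen)
    "WAT",  # 9 water oxygen
]
_G = {name: i for i, name in enumerate(ATOM_GROUP_NAMES)}

DONOR_GROUPS = {_G["N_DON"], _G["O_DA"], _G["N_DA"], _G["WAT"]}
ACCEPTOR_GROUPS = {_G["O_ACC"], _G["O_DA"], _G["N_DA"], _G["N_PRO"], _G["WAT"]}
_POLAR_GROUPS = {_G["N_DON"], _G["O_ACC"], _G["O_DA"], _G["N_DA"], _G["N_PRO"]}
_CARBON_GROUPS = {_G["C_C"], _G["C_ON"]}

CONTACT_TYPE_NAMES = [
    "hbond",  # 0 donor-acceptor
    "don_don",  # 1 donor-donor
    "cc_on",  # 2 C_c with oxygen/nitrogen
    "cc_cc",  # 3 C_c with C_c (hydrophobic)
    "con_on",  # 4 C_on with oxygen/nitrogen
    "con_cc",  # 5 C_on with C_c
    "con_con",  # 6 C_on with C_on
    "s_c",  # 7 sulfur with carbon
    "s_on",  # 8 sulfur with oxygen/nitrogen
    "pi",  # 9 pi-involving
    "wat_on",  # 10 water with oxygen/nitrogen/sulfur
    "s_s",  # 11 sulfur-sulfur
    "wat_c",  # 12 water with carbon
    "acc_acc",  # 13 acceptor-acceptor
]


def _contact_type_of_groups(g: int, h: int) -> int:
    """Symmetric group-pair -> contact-type rule (total over all pairs)."""
    pair = {g, h}
    if _G["PI"] in pair:
        return 9
    if _G["WAT"] in pair:
        other = (pair - {_G["WAT"]}) or {_G["WAT"]}
        o = next(iter(other))
        return 12 if o in _CARBON_GROUPS else 10
    if g == _G["S"] and h == _G["S"]:
        return 11
    if _G["S"] in pair:
        o = next(iter(pair - {_G["S"]}))
        return 7 if o in _CARBON_GROUPS else 8
    if pair <= _CARBON_GROUPS:
        if g == h == _G["C_C"]:
            return 3
        if g == h == _G["C_ON"]:
            return 6
        return 5
    if _G["C_C"] in pair:
        return 2
    if _G["C_ON"] in pair:
        return 4
    # polar-polar
    gd, ga = g in DONOR_GROUPS, g in ACCEPTOR_GROUPS
    hd, ha = h in DONOR_GROUPS, h in ACCEPTOR_GROUPS
    if (gd and ha) or (ga and hd):
        return 0
    if gd and hd:
        return 1
    return 13


CONTACT_TYPE_TABLE: Dict[FrozenSet[int], int] = {
    frozenset((g, h)): _contact_type_of_groups(g, h)
    for g in range(N_ATOM_GROUPS)
    for h in range(N_ATOM_GROUPS)
}


# ---------------------------------------------------------------------------
# Atom group table


def load_atom_group_table(path: Optional[str] = None) -> Dict[Tuple[str, str], int]:
    """(res_name, atom_name) -> group index, from the bundled/editable TSV."""
    if path is None:
        text = resources.files("hotcontact.data").joinpath("atom_groups.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: Dict[Tuple[str, str], int] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, atom, group = line.split("\t")[:3]
        table[(res.upper(), atom.upper())] = int(group)
    return table


_ATOM_GROUP_TABLE: Optional[Dict[Tuple[str, str], int]] = None


def _atom_group_table() -> Dict[Tuple[str, str], int]:
    global _ATOM_GROUP_TABLE
    if _ATOM_GROUP_TABLE is None:
        _ATOM_GROUP_TABLE = load_atom_group_table()
    return _ATOM_GROUP_TABLE


def atom_group(
    atom: Atom,
    bonds: Optional[CovalentBondGraph] = None,
    table: Optional[Dict[Tuple[str, str], int]] = None,
    structure: Optional[ComplexStructure] = None,
) -> int:
    """Group index of one atom.

    Pseudo-atoms and water oxygens have dedicated groups. Atoms missing
    from the table fall back to element chemistry, classifying carbons
    C_c/C_on from the covalent-bond graph when one is supplied.
    """
    if atom.is_pseudo:
        return _G["PI"]
    if atom.is_water:
        return _G["WAT"]
    table = table if table is not None else _atom_group_table()
    key = (atom.res_name, atom.name)
    if key in table:
        return table[key]
    # Topology / element fallback.
    if atom.element == "C":
        if bonds is not None and structure is not None:
            by_id = structure.atom_by_id()
            bonded_on = any(
                by_id[n].element in ("N", "O") for n in bonds.neighbors(atom.atom_id)
            )
            return _G["C_ON"] if bonded_on else _G["C_C"]
        raise KeyError(f"unmapped carbon {key}: need covalent bonds to classify")
    if atom.element == "N":
        return _G["N_DON"]
    if atom.element == "O":
        return _G["O_ACC"]
    if atom.element == "S":
        return _G["S"]
    raise KeyError(f"atom {key} (element {atom.element}) has no atom group")


def contact_type(
    contact: BetaContact,
    bonds: Optional[CovalentBondGraph] = None,
    table: Optional[Dict[Tuple[str, str], int]] = None,
) -> int:
    """Contact type (0..13) of a beta contact; symmetric in the endpoints."""
    gi = atom_group(contact.atom_i, bonds, table)
    gj = atom_group(contact.atom_j, bonds, table)
    return CONTACT_TYPE_TABLE[frozenset((gi, gj))]


def contact_weight(contact: BetaContact, stats: BfactorStats) -> float:
    """(B''_i + B''_j) / 2, in [-2, 0]."""
    return 0.5 * (
        b_norm_clamped(contact.atom_i, stats) + b_norm_clamped(contact.atom_j, stats)
    )


# ---------------------------------------------------------------------------
# Triangular indexing of unordered contact-type pairs


def triangular_index(t1: int, t2: int) -> int:
    """Row-major upper-triangular index of the unordered pair (t1, t2)."""
    t, u = (t1, t2) if t1 <= t2 else (t2, t1)
    if not (0 <= t <= u < N_CONTACT_TYPES):
        raise IndexError(f"contact types out of range: ({t1}, {t2})")
    return t * N_CONTACT_TYPES - t * (t - 1) // 2 + (u - t)


def triangular_pair(index: int) -> Tuple[int, int]:
    """Inverse of :func:`triangular_index`."""
    if not (0 <= index < N_COOC):
        raise IndexError(f"co-occurrence index out of range: {index}")
    for t in range(N_CONTACT_TYPES):
        row = N_CONTACT_TYPES - t
        if index < row:
            return (t, t + index)
        index -= row
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Feature names


def _feature_names() -> List[str]:
    names: List[str] = []
    for p in range(4):
        names.append(f"bavg_g{p}")
        names.append(f"bdif_g{p}")
    names += ["dasa_log", "dasa_rel"]
    names += [f"mut_t{t:02d}" for t in range(N_CONTACT_TYPES)]
    names += [f"nbr_t{t:02d}" for t in range(N_CONTACT_TYPES)]
    for idx in range(N_COOC):
        t, u = triangular_pair(idx)
        names.append(f"cooc_t{t:02d}_t{u:02d}")
    return names


FEATURE_NAMES: List[str] = _feature_names()
assert len(FEATURE_NAMES) == N_FEATURES


@dataclass
class MutationFeatureVector:
    """The named 143-element descriptor of one alanine mutation."""

    mutation: Mutation
    values: np.ndarray
    names: Sequence[str] = tuple(FEATURE_NAMES)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have {N_FEATURES} elements")

    def __getitem__(self, name: str) -> float:
        return float(self.values[list(self.names).index(name)])


# ---------------------------------------------------------------------------
# Contact feature vectors


def _mutated_atom_ids(mutation: Mutation, structure: ComplexStructure) -> Set[int]:
    return {a.atom_id for a in mutated_atoms(mutation.residue(structure))}


def _mutated_contacts(
    mutation: Mutation, graph: ContactGraph, structure: ComplexStructure
) -> List[BetaContact]:
    ids = _mutated_atom_ids(mutation, structure)
    return graph.contacts_touching(ids)


def mutated_contact_vector(
    mutation: Mutation,
    graph: ContactGraph,
    structure: ComplexStructure,
    stats: BfactorStats,
    bonds: Optional[CovalentBondGraph] = None,
) -> np.ndarray:
    """14-element vector: summed weights of contacts touching mutated atoms.

    A contact touching two mutated atoms still counts once.
    """
    # Per-element exact summation: the vector is independent of the
    # contact enumeration order down to the last bit.
    contribs: List[List[float]] = [[] for _ in range(N_CONTACT_TYPES)]
    for c in _mutated_contacts(mutation, graph, structure):
        contribs[contact_type(c, bonds)].append(contact_weight(c, stats))
    return np.array([math.fsum(v) for v in contribs])


def neighborhood_interface_vector(
    mutation: Mutation,
    graph: ContactGraph,
    structure: ComplexStructure,
    stats: BfactorStats,
    bonds: CovalentBondGraph,
) -> np.ndarray:
    """14-element vector over cross-interface contacts near the mutation.

    The mutation's neighborhood is its mutated atoms, their beta-contact
    partners (either side), and all non-backbone atoms within 3 covalent
    steps of those. Only cross-interface contacts touching that set are
    summed; protein-water contacts are same-side by convention and never
    enter here.
    """
    ids = _mutated_atom_ids(mutation, structure)
    scope = set(ids)
    for c in graph.contacts_touching(ids):
        scope.update(c.atom_ids)
    atom_map = graph.atoms or structure.atom_by_id()
    for aid in list(scope):
        for near in nearby_atoms(bonds, aid, max_steps=3):
            if not atom_map[near].is_backbone:
                scope.add(near)
    contribs: List[List[float]] = [[] for _ in range(N_CONTACT_TYPES)]
    for c in graph.contacts:
        if not c.cross_interface:
            continue
        if c.atom_i.atom_id in scope or c.atom_j.atom_id in scope:
            contribs[contact_type(c, bonds)].append(contact_weight(c, stats))
    return np.array([math.fsum(v) for v in contribs])


def _contact_nearby_atoms(
    contact: BetaContact, bonds: CovalentBondGraph, cache: Dict[int, Set[int]]
) -> Set[int]:
    out: Set[int] = set()
    for aid in contact.atom_ids:
        if aid not in cache:
            cache[aid] = nearby_atoms(bonds, aid, max_steps=3)
        out |= cache[aid]
    return out


def cooccurring_pairs(
    contacts: Sequence[BetaContact],
    bonds: CovalentBondGraph,
    seeds: Optional[Sequence[BetaContact]] = None,
) -> Set[FrozenSet[FrozenSet[int]]]:
    """Unordered pairs of distinct co-occurring contacts.

    Two contacts co-occur when an endpoint of one lies within 3
    covalent-bond steps (step 0, a shared atom, included) of an endpoint
    of the other. With ``seeds`` given, only pairs with at least one
    member among the seeds are returned; each unordered pair is reported
    once however many nearby-atom relations link it.
    """
    seeds = list(seeds) if seeds is not None else list(contacts)
    by_atom: Dict[int, List[BetaContact]] = {}
    for c in contacts:
        for aid in c.atom_ids:
            by_atom.setdefault(aid, []).append(c)
    cache: Dict[int, Set[int]] = {}
    pairs: Set[FrozenSet[FrozenSet[int]]] = set()
    for s in seeds:
        near = _contact_nearby_atoms(s, bonds, cache)
        for aid in near:
            for c in by_atom.get(aid, ()):
                if c.key != s.key:
                    pairs.add(frozenset((s.key, c.key)))
    return pairs


def cooccurrence_vector(
    mutation: Mutation,
    graph: ContactGraph,
    structure: ComplexStructure,
    stats: BfactorStats,
    bonds: CovalentBondGraph,
) -> np.ndarray:
    """105-element vector of co-occurring contact-type pairs.

    Scope: pairs with at least one member among the mutation's mutated
    contacts (pairs among the mutated contacts included). The element for
    unordered types (t, t') accumulates the sum of both contacts'
    weights, once per unordered contact pair.
    """
    mutated = _mutated_contacts(mutation, graph, structure)
    if not mutated:
        return np.zeros(N_COOC)
    by_key = {c.key: c for c in graph.contacts}
    for m in mutated:
        by_key.setdefault(m.key, m)
    pairs = cooccurring_pairs(graph.contacts, bonds, seeds=mutated)
    contribs: List[List[float]] = [[] for _ in range(N_COOC)]
    for pair in pairs:
        key_a, key_b = tuple(pair)
        ca, cb = by_key[key_a], by_key[key_b]
        idx = triangular_index(contact_type(ca, bonds), contact_type(cb, bonds))
        contribs[idx].append(contact_weight(ca, stats) + contact_weight(cb, stats))
    return np.array([math.fsum(v) for v in contribs])


def assemble_features(
    mutation: Mutation,
    structure: ComplexStructure,
    graph: ContactGraph,
    bonds: CovalentBondGraph,
    stats: BfactorStats,
    asa_bound: AsaTable,
    asa_unbound: AsaTable,
) -> MutationFeatureVector:
    """Concatenate the five blocks into the 143-element descriptor."""
    b_block = bfactor_vector(mutation, structure, stats)
    f_log, f_rel = delta_asa_features(mutation, asa_bound, asa_unbound)
    mut_block = mutated_contact_vector(mutation, graph, structure, stats, bonds)
    nbr_block = neighborhood_interface_vector(mutation, graph, structure, stats, bonds)
    cooc_block = cooccurrence_vector(mutation, graph, structure, stats, bonds)
    values = np.concatenate([b_block, [f_log, f_rel], mut_block, nbr_block, cooc_block])
    return MutationFeatureVector(mutation=mutation, values=values)


def export_atom_groups(path: str, table: Optional[Dict[Tuple[str, str], int]] = None) -> None:
    """Write the atom-group table as TSV (res_name, atom_name, group, group_name)."""
    table = table if table is not None else _atom_group_table()
    with open(path, "w") as fh:
        fh.write("# res_name\tatom_name\tgroup\tgroup_name\n")
        for (res, atom), group in sorted(table.items()):
            fh.write(f"{res}\t{atom}\t{group}\t{ATOM_GROUP_NAMES[group]}\n")


def export_contact_types(path: str) -> None:
    """Write the contact-type table as TSV (group_i, group_j, type, type_name)."""
    with open(path, "w") as fh:
        fh.write("# group_i\tgroup_j\ttype\ttype_name\n")
        for g in range(N_ATOM_GROUPS):
            for h in range(g, N_ATOM_GROUPS):
                t = CONTACT_TYPE_TABLE[frozenset((g, h))]
                fh.write(
                    f"{ATOM_GROUP_NAMES[g]}\t{ATOM_GROUP_NAMES[h]}\t{t}\t"
                    f"{CONTACT_TYPE_NAMES[t]}\n"
                )
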