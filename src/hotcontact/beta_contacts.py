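"""Beta atomic contacts and the interface contact graph.

A beta contact between atoms i and j requires (a) their distance to be at
most T_d = td_factor * (vdw_i + vdw_j) and (b) an empty "forbidden
region": no third atom k may see the pair under an angle
angle(i, k, j) >= beta_angle (measured at k's center). The angle test is
the lune characterization of a beta-skeleton; an atom sitting between i
and j sees them under a wide angle and interrupts the contact.

Ring pseudo-atoms may be contact endpoints but never interrupt (they are
bookkeeping constructs, not matter); water oxygens interrupt like any
real atom.

From all beta contacts of a complex the interface graph collects:
interfacial atoms (>= 1 cross-interface contact), supporting atoms
(non-interfacial atoms contacting an interfacial one), and neighborhood
atoms (the previous two sets plus their non-backbone covalently-bonded
atoms within 3 bond steps). Buried waters join the graph when their ASA
in the crystallized complex is below 1 A^2 and they make at least 3 beta
contacts with hydrogen-bond donors or acceptors; water-water contacts are
never recorded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import RunConfig
from .structure_model import (
    Atom,
    ComplexStructure,
    CovalentBondGraph,
    nearby_atoms,
)
from .surface_area import AsaTable, compute_asa

__all__ = [
    "BetaContact",
    "ContactGraph",
    "is_beta_contact",
    "all_beta_contacts",
    "qualified_waters",
    "build_contact_graph",
    "contact_edge_table",
]


@dataclass(frozen=True)
class BetaContact:
    """One unordered beta contact."""

    atom_i: Atom
    atom_j: Atom
    distance: float
    cross_interface: bool

    @property
    def key(self) -> FrozenSet[int]:
        return frozenset((self.atom_i.atom_id, self.atom_j.atom_id))

    @property
    def atom_ids(self) -> Tuple[int, int]:
        return (self.atom_i.atom_id, self.atom_j.atom_id)


@dataclass
class ContactGraph:
    """Beta contacts plus the atom sets of one complex interface."""

    contacts: List[BetaContact]
    interfacial_atoms: Set[int]
    supporting_atoms: Set[int]
    neighborhood_atoms: Set[int]
    qualified_waters: Set[int]
    atoms: Dict[int, Atom] = field(default_factory=dict)

    def contacts_touching(self, atom_ids: Set[int]) -> List[BetaContact]:
        return [
            c
            for c in self.contacts
            if c.atom_i.atom_id in atom_ids or c.atom_j.atom_id in atom_ids
        ]


def _angle_interrupted(
    ci: np.ndarray,
    cj: np.ndarray,
    candidates: np.ndarray,
    cos_beta: float,
) -> bool:
    """True if any candidate center sees (ci, cj) under angle >= beta."""
    if candidates.size == 0:
        return False
    v1 = ci[None, :] - candidates
    v2 = cj[None, :] - candidates
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 == 0.0) or np.any(n2 == 0.0):
        raise ValueError("interrupting atom coincides with a contact endpoint")
    cos_angle = (v1 * v2).sum(axis=1) / (n1 * n2)
    # angle >= beta  <=>  cos(angle) <= cos(beta)
    return bool(np.any(cos_angle <= cos_beta))


def is_beta_contact(
    atom_i: Atom,
    atom_j: Atom,
    candidates: Sequence[Atom],
    td_factor: float = 1.25,
    beta_angle_deg: float = 85.0,
) -> bool:
    """Decide one beta contact against an explicit interrupter set.

    ``candidates`` must exclude the endpoints themselves; pseudo-atoms in
    it are ignored (they never interrupt).
    """
    if atom_i.atom_id == atom_j.atom_id:
        raise ValueError("a contact needs two distinct atoms")
    if not 0.0 < beta_angle_deg < 180.0:
        raise ValueError("beta_angle_deg must lie in (0, 180)")
    ci, cj = atom_i.coords, atom_j.coords
    d = float(np.linalg.norm(ci - cj))
    if d == 0.0:
        raise ValueError("contact endpoints coincide")
    if d > td_factor * (atom_i.vdw_radius + atom_j.vdw_radius):
        return False
    real = [
        a
        for a in candidates
        if not a.is_pseudo and a.atom_id not in (atom_i.atom_id, atom_j.atom_id)
    ]
    if not real:
        return True
    coords = np.array([a.coords for a in real])
    # Any interrupter with angle >= beta lies within d/sin(beta) of both
    # endpoints, hence within d/sin(beta) of the midpoint; prune on that.
    mid = 0.5 * (ci + cj)
    reach = d / math.sin(math.radians(beta_angle_deg))
    close = np.linalg.norm(coords - mid[None, :], axis=1) <= reach
    cos_beta = math.cos(math.radians(beta_angle_deg))
    return not _angle_interrupted(ci, cj, coords[close], cos_beta)


def all_beta_contacts(
    endpoints: Sequence[Atom],
    interrupters: Optional[Sequence[Atom]] = None,
    td_factor: float = 1.25,
    beta_angle_deg: float = 85.0,
    structure: Optional[ComplexStructure] = None,
    bonds: Optional[CovalentBondGraph] = None,
) -> List[BetaContact]:
    """All beta contacts among ``endpoints``, grid-accelerated.

    ``interrupters`` defaults to the non-pseudo endpoints. When a
    ``structure`` is given, each contact's cross_interface flag reflects
    the chain partition (waters belong to neither side). Atom pairs of
    the same residue, and covalently bonded pairs when ``bonds`` is
    given, are never contacts: a contact is a non-bonded interaction.
    """
    endpoints = list(endpoints)
    if interrupters is None:
        interrupters = endpoints
    real_int = [a for a in interrupters if not a.is_pseudo]

    if len(endpoints) < 2:
        return []
    coords = np.array([a.coords for a in endpoints])
    radii = np.array([a.vdw_radius for a in endpoints])
    tree = cKDTree(coords)
    max_reach = td_factor * 2.0 * radii.max()

    int_coords = (
        np.array([a.coords for a in real_int]) if real_int else np.empty((0, 3))
    )
    int_ids = np.array([a.atom_id for a in real_int], dtype=int)
    int_tree = cKDTree(int_coords) if len(real_int) else None

    sin_beta = math.sin(math.radians(beta_angle_deg))
    cos_beta = math.cos(math.radians(beta_angle_deg))

    contacts: List[BetaContact] = []
    for i, j in sorted(tree.query_pairs(max_reach)):
        ai, aj = endpoints[i], endpoints[j]
        if ai.is_water and aj.is_water:
            continue
        if (not ai.is_water) and (not aj.is_water) and ai.res_key == aj.res_key:
            continue
        if bonds is not None and aj.atom_id in bonds.neighbors(ai.atom_id):
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d == 0.0:
            raise ValueError(
                f"atoms {ai.name} and {aj.name} have coincident centers"
            )
        if d > td_factor * (radii[i] + radii[j]):
            continue
        interrupted = False
        if int_tree is not None:
            mid = 0.5 * (coords[i] + coords[j])
            cand = int_tree.query_ball_point(mid, d / sin_beta)
            cand = [
                k
                for k in cand
                if int_ids[k] not in (ai.atom_id, aj.atom_id)
            ]
            if cand:
                interrupted = _angle_interrupted(
                    coords[i], coords[j], int_coords[cand], cos_beta
                )
        if interrupted:
            continue
        if structure is not None:
            side_i, side_j = structure.side_of(ai), structure.side_of(aj)
            cross = side_i is not None and side_j is not None and side_i != side_j
        else:
            cross = False
        contacts.append(BetaContact(ai, aj, d, cross))
    return contacts


# Elements accepted as hydrogen-bond donors or acceptors by the water rule.
_DONOR_ACCEPTOR_ELEMENTS = {"N", "O"}


def qualified_waters(
    structure: ComplexStructure,
    asa: AsaTable,
    td_factor: float = 1.25,
    beta_angle_deg: float = 85.0,
    asa_max: float = 1.0,
    min_contacts: int = 3,
) -> Set[int]:
    """Water oxygens that join the contact graph.

    A water qualifies when its ASA in the full crystallized complex
    (waters included) is below ``asa_max`` and it makes at least
    ``min_contacts`` beta contacts with hydrogen-bond donor or acceptor
    atoms (N or O) of the protein. Contacts between two waters never
    count.
    """
    protein = [a for a in structure.protein_atoms() if not a.is_pseudo]
    waters = structure.water_atoms()
    interrupters = protein + waters
    partners = [a for a in protein if a.element in _DONOR_ACCEPTOR_ELEMENTS]

    qualified: Set[int] = set()
    for w in waters:
        if asa.atom(w) >= asa_max:
            continue
        n_contacts = sum(
            1
            for p in partners
            if is_beta_contact(w, p, interrupters, td_factor, beta_angle_deg)
        )
        if n_contacts >= min_contacts:
            qualified.add(w.atom_id)
    return qualified


def build_contact_graph(
    structure: ComplexStructure,
    bonds: CovalentBondGraph,
    config: Optional[RunConfig] = None,
) -> ContactGraph:
    """Assemble the interface contact graph of a complex.

    Requires ring pseudo-atoms to be present and the covalent-bond graph
    built. An empty interface (no cross-interface beta contact) yields an
    empty graph with a warning.
    """
    cfg = config or RunConfig()

    # Water qualification needs ASA of the crystallized complex, waters in.
    protein = structure.protein_atoms()
    waters = structure.water_atoms()
    asa_full = compute_asa(
        [a for a in protein if not a.is_pseudo] + waters,
        probe_radius=cfg.probe_radius,
        n_points=cfg.asa_n_points,
    )
    qual = qualified_waters(
        structure,
        asa_full,
        td_factor=cfg.td_factor,
        beta_angle_deg=cfg.beta_angle_deg,
        asa_max=cfg.water_asa_max,
        min_contacts=cfg.water_min_contacts,
    )

    endpoints = protein + [a for a in waters if a.atom_id in qual]
    # All waters interrupt, qualified or not; pseudo-atoms never do.
    interrupters = [a for a in protein if not a.is_pseudo] + waters
    contacts = all_beta_contacts(
        endpoints,
        interrupters,
        td_factor=cfg.td_factor,
        beta_angle_deg=cfg.beta_angle_deg,
        structure=structure,
        bonds=bonds,
    )

    interfacial: Set[int] = set()
    for c in contacts:
        if c.cross_interface:
            interfacial.update(c.atom_ids)
    if not interfacial:
        warnings.warn(f"{structure.structure_id}: empty interface (no cross-interface beta contacts)")

    supporting: Set[int] = set()
    for c in contacts:
        i, j = c.atom_ids
        if i in interfacial and j not in interfacial:
            supporting.add(j)
        elif j in interfacial and i not in interfacial:
            supporting.add(i)

    atom_map = structure.atom_by_id()
    neighborhood = set(interfacial) | set(supporting)
    for aid in list(interfacial | supporting):
        for near in nearby_atoms(bonds, aid, max_steps=3):
            near_atom = atom_map[near]
            if not near_atom.is_backbone:
                neighborhood.add(near)

    kept = [
        c
        for c in contacts
        if c.atom_i.atom_id in neighborhood or c.atom_j.atom_id in neighborhood
    ]
    return ContactGraph(
        contacts=kept,
        interfacial_atoms=interfacial,
        supporting_atoms=supporting,
        neighborhood_atoms=neighborhood,
        qualified_waters=qual,
        atoms=atom_map,
    )


def contact_edge_table(graph: ContactGraph) -> pd.DataFrame:
    """Tabular edge list of the graph (one row per contact)."""
    rows = []
    for c in graph.contacts:
        ai, aj = c.atom_i, c.atom_j
        rows.append(
            {
                "atom_i": ai.atom_id,
                "atom_j": aj.atom_id,
                "name_i": ai.name,
                "name_j": aj.name,
                "residue_i": f"{ai.res_name}{ai.res_key[1]}:{ai.chain_id}",
                "residue_j": f"{aj.res_name}{aj.res_key[1]}:{aj.chain_id}",
                "distance": round(c.distance, 3),
                "cross_interface": c.cross_interface,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "atom_i",
            "atom_j",
            "name_i",
            "name_j",
            "residue_i",
            "residue_j",
            "distance",
            "cross_interface",
        ],
    )
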