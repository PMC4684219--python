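"""Solvent-accessible surface area (ASA).

Numerical Shrake-Rupley ASA on the package's own atom model: each atom is
surrounded by a quasi-uniform point shell at radius (vdw + probe); the
accessible fraction is the fraction of shell points not inside any other
atom's expanded sphere. Pseudo-atoms are bookkeeping constructs and are
excluded both as surfaces and as occluders.

ASA enters the pipeline twice: the water-burial test of the contact graph
(ASA of a water oxygen in the crystallized complex, waters included) and
the two per-mutation dASA features (protein atoms only, waters excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .structure_model import Atom, ComplexStructure, Mutation

__all__ = ["AsaTable", "compute_asa", "delta_asa_features", "sphere_points"]

DEFAULT_PROBE_RADIUS = 1.4  # Angstrom, conventional water probe
DEFAULT_N_POINTS = 960


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (Fibonacci / golden-section spiral)."""
    if n < 1:
        raise ValueError("n_points must be at least 1")
    k = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k  # golden angle increments
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class AsaTable:
    """Per-atom ASA (A^2) with per-residue sums derived on demand."""

    per_atom: Dict[int, float]
    _atoms: Dict[int, Atom] = field(default_factory=dict, repr=False)

    def atom(self, atom: Atom | int) -> float:
        aid = atom.atom_id if isinstance(atom, Atom) else int(atom)
        return self.per_atom[aid]

    def residue(self, res_key: Tuple[str, int, str]) -> float:
        values = [
            asa
            for aid, asa in self.per_atom.items()
            if self._atoms[aid].res_key == res_key
        ]
        if not values:
            raise KeyError(f"residue {res_key} absent from ASA table")
        return math.fsum(values)  # exact: atom-order independent


def compute_asa(
    atoms: Sequence[Atom],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> AsaTable:
    """Shrake-Rupley numerical ASA over an atom set.

    Pseudo-atoms are ignored (neither surface nor occluder). For an
    isolated atom the result converges to the closed form 4*pi*(r+w)^2.
    """
    if n_points < 1:
        raise ValueError("n_points must be at least 1")
    real = [a for a in atoms if not a.is_pseudo]
    table: Dict[int, float] = {a.atom_id: 0.0 for a in atoms if a.is_pseudo}
    atom_map = {a.atom_id: a for a in atoms}
    if not real:
        return AsaTable(table, atom_map)

    coords = np.array([a.coords for a in real])
    radii = np.array([a.vdw_radius + probe_radius for a in real])
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()

    for idx, atom in enumerate(real):
        r = radii[idx]
        shell = coords[idx] + r * unit
        # Occluders can only be atoms whose expanded sphere reaches the shell.
        neighbor_idx = [
            j for j in tree.query_ball_point(coords[idx], r + max_r) if j != idx
        ]
        if neighbor_idx:
            ncoords = coords[neighbor_idx]
            nradii = radii[neighbor_idx]
            d2 = ((shell[:, None, :] - ncoords[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nradii**2)[None, :]).any(axis=1)
            accessible_fraction = 1.0 - buried.mean()
        else:
            accessible_fraction = 1.0
        table[atom.atom_id] = accessible_fraction * 4.0 * math.pi * r * r
    return AsaTable(table, atom_map)


def delta_asa_features(
    mutation: Mutation,
    bound: AsaTable,
    unbound: AsaTable,
) -> Tuple[float, float]:
    """The two dASA features of a mutated residue.

    dASA = ASA(unbound side) - ASA(bound complex), clamped at zero against
    numerical noise. Returns (ln(dASA + 1), dASA / ASA_unbound); the
    relative term is 0 when the unbound residue is itself fully buried.
    """
    key = mutation.res_key
    asa_unbound = unbound.residue(key)
    asa_bound = bound.residue(key)
    delta = max(asa_unbound - asa_bound, 0.0)
    f_log = math.log(delta + 1.0)
    f_rel = delta / asa_unbound if asa_unbound > 0 else 0.0
    return f_log, f_rel
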