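"""B-factor normalization and the 8-element B-factor feature block.

Raw crystallographic B factors vary widely between depositions, so each
complex is normalized against its own trimmed distribution: drop the 1%
smallest values (guards against erroneous B = 0) and the 9% largest
(outliers), then scale so the 90% confidence band of a normal fit maps to
[-1, 1]:

    B_norm = (B - mean) / (1.645 * sd)
    B''    = clamp(B_norm - 1, [-2, 0])

B'' (the doubly-normalized, clamped value) lives in [-2, 0]: rigid atoms
sit near -2, atoms at the flexible end of the band at 0. Every contact
weight downstream is a mean of two B'' values, hence also in [-2, 0].

The per-mutation block has 8 slots, two per amino-acid class of the
mutated residue: B_avg (mean B'' over the atoms removed by the X->Ala
substitution) and B_dif (B_avg minus the mean B'' of the residue's
backbone N and C atoms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .structure_model import Atom, ComplexStructure, Mutation, Residue

__all__ = [
    "BfactorStats",
    "AMINO_GROUPS",
    "amino_group",
    "trimmed_stats",
    "normalize_b",
    "clamp_b",
    "b_norm_clamped",
    "mutated_atoms",
    "bfactor_vector",
    "complex_bfactor_stats",
]

CONFIDENCE_SCALE = 1.645  # two-sided 90% band of a standard normal

# Amino-acid classes for the B-factor block (0-indexed):
#   0 small/hydrophobic, 1 polar, 2 charged, 3 aromatic.
AMINO_GROUPS: Dict[str, int] = {}
for _name in ("ILE", "VAL", "LEU", "MET", "ALA", "GLY"):
    AMINO_GROUPS[_name] = 0
for _name in ("CYS", "THR", "SER", "PRO", "HIS", "GLN", "ASN"):
    AMINO_GROUPS[_name] = 1
for _name in ("GLU", "ASP", "LYS", "ARG"):
    AMINO_GROUPS[_name] = 2
for _name in ("PHE", "TRP", "TYR"):
    AMINO_GROUPS[_name] = 3


def amino_group(res_name: str) -> int:
    return AMINO_GROUPS[res_name.upper()]


@dataclass(frozen=True)
class BfactorStats:
    """Trimmed mean/sd of one complex's B factors."""

    mean: float
    std: float
    n_used: int
    trim_low_frac: float = 0.01
    trim_high_frac: float = 0.09

    def __post_init__(self) -> None:
        if self.std <= 0:
            raise ValueError("B-factor standard deviation must be positive")


def trimmed_stats(
    b_values: Sequence[float],
    trim_low_frac: float = 0.01,
    trim_high_frac: float = 0.09,
) -> BfactorStats:
    """Mean and population sd after trimming the distribution tails.

    Sort ascending, drop floor(trim_low_frac * n) smallest and
    floor(trim_high_frac * n) largest values (ties keep file order, which
    is immaterial for the statistics). Fatal when fewer than 10 values or
    when the remainder is constant.
    """
    values = np.asarray(list(b_values), dtype=float)
    n = values.size
    if n < 10:
        raise ValueError(f"need at least 10 B factors, got {n}")
    order = np.argsort(values, kind="stable")
    n_low = math.floor(trim_low_frac * n)
    n_high = math.floor(trim_high_frac * n)
    kept = values[order[n_low : n - n_high]]
    mean = float(kept.mean())
    std = float(kept.std(ddof=0))
    if std <= 0:
        raise ValueError("B factors are constant after trimming; cannot normalize")
    return BfactorStats(mean, std, kept.size, trim_low_frac, trim_high_frac)


def complex_bfactor_stats(
    structure: ComplexStructure,
    trim_low_frac: float = 0.01,
    trim_high_frac: float = 0.09,
) -> BfactorStats:
    """Trimmed stats over all parsed heavy atoms of a complex.

    Protein and water atoms both enter the statistics; ring pseudo-atoms
    do not (their B factors are derived, not measured).
    """
    values = [a.b_factor for a in structure.all_atoms() if not a.is_pseudo]
    return trimmed_stats(values, trim_low_frac, trim_high_frac)


def normalize_b(b: float, stats: BfactorStats) -> float:
    """(B - mean) / (1.645 * sd): the 90% band maps to [-1, 1]."""
    return (b - stats.mean) / (stats.std * CONFIDENCE_SCALE)


def clamp_b(b_norm: float) -> float:
    """Clamp (B_norm - 1) to [-2, 0].

    Values outside the 90% confidence band collapse to whichever endpoint
    is closer: rigid outliers to -2, flexible outliers to 0.
    """
    return max(min(b_norm - 1.0, 0.0), -2.0)


def b_norm_clamped(atom: Atom | float, stats: BfactorStats) -> float:
    """B'' of an atom (or raw B value): normalize then clamp."""
    b = atom.b_factor if isinstance(atom, Atom) else float(atom)
    return clamp_b(normalize_b(b, stats))


def mutated_atoms(residue: Residue) -> List[Atom]:
    """Atoms removed by the X->Ala substitution.

    Side-chain heavy atoms beyond CB, plus the residue's ring pseudo-atoms
    (an aromatic ring disappears with the side chain, taking its pi
    pseudo-atoms with it).
    """
    out = [
        a
        for a in residue.atoms
        if not a.is_backbone and a.name not in ("CB", "OXT")
    ]
    if not out:
        raise ValueError(
            f"no mutated atoms for {residue.res_name} "
            f"{residue.chain_id}:{residue.seq_number}"
        )
    return out


def bfactor_vector(
    mutation: Mutation,
    structure: ComplexStructure,
    stats: BfactorStats,
) -> np.ndarray:
    """The 8-element B-factor block of one mutation.

    For the mutated residue's amino-acid class p, position 2p holds B_avg
    (mean B'' over mutated atoms) and position 2p+1 holds B_dif
    (B_avg minus the mean B'' of the residue's backbone N and C atoms).
    The six positions of the other classes are exactly zero.
    """
    residue = mutation.residue(structure)
    p = amino_group(residue.res_name)
    atoms = mutated_atoms(residue)
    # fsum: exact, hence independent of atom enumeration order
    b_avg = math.fsum(b_norm_clamped(a, stats) for a in atoms) / len(atoms)
    backbone = [residue.atom("N"), residue.atom("C")]
    if any(a is None for a in backbone):
        raise ValueError(
            f"residue {residue.chain_id}:{residue.seq_number} lacks backbone N or C"
        )
    b_backbone = math.fsum(b_norm_clamped(a, stats) for a in backbone) / 2.0
    vector = np.zeros(8)
    vector[2 * p] = b_avg
    vector[2 * p + 1] = b_avg - b_backbone
    return vector
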