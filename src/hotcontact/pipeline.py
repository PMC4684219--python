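"""End-to-end feature extraction: structure in, feature table out."""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .beta_contacts import ContactGraph, build_contact_graph
from .bfactor_norm import BfactorStats, complex_bfactor_stats
from .config import RunConfig
from .contact_features import FEATURE_NAMES, assemble_features
from .structure_model import (
    ComplexStructure,
    CovalentBondGraph,
    Mutation,
    add_ring_pseudo_atoms,
    infer_covalent_bonds,
    parse_pdb,
)
from .surface_area import AsaTable, compute_asa

__all__ = ["prepare_structure", "extract_features", "extract_from_pdb"]


def prepare_structure(
    structure: ComplexStructure, config: Optional[RunConfig] = None
) -> Tuple[ComplexStructure, CovalentBondGraph, ContactGraph, BfactorStats]:
    """Pseudo-atoms, covalent bonds, B-factor stats and the contact graph."""
    cfg = config or RunConfig()
    stats = complex_bfactor_stats(structure, cfg.trim_low_frac, cfg.trim_high_frac)
    add_ring_pseudo_atoms(structure)
    bonds = infer_covalent_bonds(structure)
    graph = build_contact_graph(structure, bonds, cfg)
    return structure, bonds, graph, stats


def _side_asa_tables(
    structure: ComplexStructure, cfg: RunConfig
) -> Tuple[AsaTable, Dict[str, AsaTable]]:
    """Bound-complex and per-side unbound ASA tables (protein only, no waters)."""
    protein = [a for a in structure.protein_atoms() if not a.is_pseudo]
    bound = compute_asa(protein, cfg.probe_radius, cfg.asa_n_points)
    unbound: Dict[str, AsaTable] = {}
    for side_name, chains in (("A", structure.side_a), ("B", structure.side_b)):
        side_atoms = [a for a in protein if a.chain_id in chains]
        unbound[side_name] = compute_asa(side_atoms, cfg.probe_radius, cfg.asa_n_points)
    return bound, unbound


def extract_features(
    structure: ComplexStructure,
    mutations: Sequence[Mutation],
    config: Optional[RunConfig] = None,
    complex_id: Optional[str] = None,
) -> pd.DataFrame:
    """One row per mutation: identity columns plus the 143 named features."""
    cfg = config or RunConfig()
    structure, bonds, graph, stats = prepare_structure(structure, cfg)
    asa_bound, asa_unbound = _side_asa_tables(structure, cfg)

    rows = []
    for mutation in mutations:
        side = "A" if mutation.chain_id in structure.side_a else "B"
        fv = assemble_features(
            mutation,
            structure,
            graph,
            bonds,
            stats,
            asa_bound,
            asa_unbound[side],
        )
        row = {
            "complex_id": complex_id or structure.structure_id,
            "chain": mutation.chain_id,
            "seq_number": mutation.seq_number,
            "wt_res": mutation.wt_res,
            "ddg_obs": mutation.ddg_obs,
            "label": mutation.label,
        }
        row.update(dict(zip(FEATURE_NAMES, fv.values)))
        rows.append(row)
    columns = ["complex_id", "chain", "seq_number", "wt_res", "ddg_obs", "label"]
    return pd.DataFrame(rows, columns=columns + FEATURE_NAMES)


def extract_from_pdb(
    pdb_path: str,
    side_a: Iterable[str],
    side_b: Iterable[str],
    mutations: Sequence[Mutation],
    config: Optional[RunConfig] = None,
) -> pd.DataFrame:
    structure = parse_pdb(pdb_path, side_a, side_b)
    return extract_features(structure, mutations, config)
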