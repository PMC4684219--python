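"""Structural model: parsing, covalent topology, pseudo-atoms, radii."""

import math

import networkx as nx
import numpy as np
import pytest

from hotcontact.structure_model import (
    BEYOND,
    CovalentBondGraph,
    Mutation,
    add_ring_pseudo_atoms,
    bond_steps,
    infer_covalent_bonds,
    nearby_atoms,
    parse_pdb_string,
    vdw_radius,
    write_pdb,
)
from hotcontact.synthetic_fixtures import RESIDUE_TEMPLATES

from conftest import HAND_PDB, HAND_PROTEIN_ATOMS, HAND_WATERS, make_atom


class TestParsing:
    def test_hand_fixture_counts_and_sides(self, hand_structure):
        s = hand_structure
        assert len(s.protein_atoms()) == HAND_PROTEIN_ATOMS
        assert len(s.water_atoms()) == HAND_WATERS
        assert s.side_a == {"A"} and s.side_b == {"B"}
        # waters belong to neither side
        for w in s.water_atoms():
            assert s.side_of(w) is None
        # hydrogens discarded
        assert all(a.element != "H" for a in s.all_atoms())

    def test_altloc_keeps_highest_occupancy(self, hand_structure):
        og = hand_structure.get_residue("A", 2).atom("OG")
        assert og.b_factor == pytest.approx(31.0)  # the 0.60-occupancy conformer
        assert og.occupancy == pytest.approx(0.60)

    def test_backbone_and_water_flags(self, hand_structure):
        res = hand_structure.get_residue("A", 3)
        flags = {a.name: a.is_backbone for a in res.atoms}
        assert flags["N"] and flags["CA"] and flags["C"] and flags["O"]
        assert not flags["CB"] and not flags["CD1"]

    def test_missing_chain_is_fatal(self):
        with pytest.raises(ValueError, match="absent"):
            parse_pdb_string(HAND_PDB, {"A"}, {"C"})

    def test_nonstandard_residue_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="LIG"):
            s = parse_pdb_string(HAND_PDB, {"A"}, {"B"})
        assert all(r.res_name != "LIG" for r in s.residues.values())

    def test_roundtrip_preserves_atoms_and_bfactors(self, hand_structure):
        text = write_pdb(hand_structure)
        reparsed = parse_pdb_string(text, {"A"}, {"B"})
        orig = hand_structure.all_atoms()
        back = reparsed.all_atoms()
        assert len(back) == len(orig)
        assert [a.b_factor for a in back] == [a.b_factor for a in orig]


class TestCovalentBonds:
    def _single_residue_structure(self, res_name: str):
        lines = []
        serial = 1
        for name, (el, xyz) in RESIDUE_TEMPLATES[res_name].items():
            lines.append(
                f"ATOM  {serial:>5d}  {name:<3s} {res_name} A   1    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00 30.00"
                f"           {el:>2s}"
            )
            serial += 1
        text = "\n".join(lines) + "\nEND\n"
        return parse_pdb_string(text, {"A"}, set())

    def test_ala_ideal_geometry_bonds(self):
        s = self._single_residue_structure("ALA")
        graph = infer_covalent_bonds(s)
        res = s.get_residue("A", 1)
        name = {a.atom_id: a.name for a in res.atoms}
        bonds = {
            frozenset((name[i], name[j]))
            for i in graph.adjacency
            for j in graph.adjacency[i]
        }
        assert bonds == {
            frozenset(p) for p in [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB")]
        }

    def test_above_cutoff_not_bonded(self):
        s = self._single_residue_structure("ALA")
        graph = infer_covalent_bonds(s)
        res = s.get_residue("A", 1)
        n = res.atom("N")
        o = res.atom("O")
        assert np.linalg.norm(n.coords - o.coords) > 1.9
        assert o.atom_id not in graph.neighbors(n.atom_id)

    def test_chain_break_leaves_no_peptide_bond(self):
        # Two residues 50 A apart: no C-N link.
        t = RESIDUE_TEMPLATES["ALA"]
        lines = []
        serial = 1
        for seq, shift in ((1, 0.0), (2, 50.0)):
            for name, (el, xyz) in t.items():
                lines.append(
                    f"ATOM  {serial:>5d}  {name:<3s} ALA A{seq:>4d}    "
                    f"{xyz[0] + shift:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00 30.00           {el:>2s}"
                )
                serial += 1
        s = parse_pdb_string("\n".join(lines) + "\nEND\n", {"A"}, set())
        graph = infer_covalent_bonds(s)
        c = s.get_residue("A", 1).atom("C")
        n = s.get_residue("A", 2).atom("N")
        assert n.atom_id not in graph.neighbors(c.atom_id)

    def test_sulfur_cutoff_extends_to_2_2(self):
        s = self._single_residue_structure("CYS")
        graph = infer_covalent_bonds(s)
        res = s.get_residue("A", 1)
        cb, sg = res.atom("CB"), res.atom("SG")
        assert np.linalg.norm(cb.coords - sg.coords) == pytest.approx(1.8, abs=0.01)
        assert sg.atom_id in graph.neighbors(cb.atom_id)


class TestBondSteps:
    @pytest.fixture
    def linear_chain(self):
        graph = CovalentBondGraph()
        for a, b in [(0, 1), (1, 2), (2, 3), (3, 4)]:
            graph.add_bond(a, b)
        return graph

    def test_steps_along_a_bonded_chain(self, linear_chain):
        # chain i-j-k-l-m: 0 to itself, 3 to the fourth atom, beyond to the fifth
        assert bond_steps(linear_chain, 0, 0) == 0
        assert bond_steps(linear_chain, 0, 3, max_steps=3) == 3
        assert bond_steps(linear_chain, 0, 4, max_steps=3) == BEYOND

    def test_nearby_atoms_of_chain_head(self, linear_chain):
        assert nearby_atoms(linear_chain, 0, max_steps=3) == {0, 1, 2, 3}

    def test_isolated_atom_is_its_own_neighborhood(self):
        graph = CovalentBondGraph()
        graph.add_atom(7)
        assert nearby_atoms(graph, 7) == {7}

    def test_nearby_monotone_in_max_steps(self, linear_chain):
        prev = set()
        for k in range(5):
            cur = nearby_atoms(linear_chain, 0, max_steps=k)
            assert prev <= cur
            prev = cur

    @pytest.mark.parametrize("seed", range(5))
    def test_metric_against_networkx_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        g = nx.gnm_random_graph(n, 40, seed=seed)
        graph = CovalentBondGraph()
        for i in range(n):
            graph.add_atom(i)
        for a, b in g.edges:
            graph.add_bond(a, b)
        lengths = dict(nx.all_pairs_shortest_path_length(g))
        for _ in range(60):
            a, b = rng.integers(0, n, size=2)
            expected = lengths.get(int(a), {}).get(int(b))
            got = bond_steps(graph, int(a), int(b), max_steps=6)
            if expected is None or expected > 6:
                assert got == BEYOND
            else:
                assert got == expected
                # symmetry of the metric
                assert bond_steps(graph, int(b), int(a), max_steps=6) == expected


class TestRingPseudoAtoms:
    def _phe_in_xy_plane(self):
        """PHE whose ring is a regular hexagon centered at the origin in z=0."""
        lines = []
        coords = {
            "N": (-6.0, 0.0, 0.0),
            "CA": (-5.0, 0.0, 0.0),
            "CB": (-3.6, 0.4, 0.0),
            "C": (-5.3, 1.4, 0.0),
            "O": (-5.3, 2.6, 0.0),
        }
        for k, atom in enumerate(["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]):
            angle = math.radians(60.0 * k)
            coords[atom] = (1.39 * math.cos(angle), 1.39 * math.sin(angle), 0.0)
        serial = 1
        for name, xyz in coords.items():
            el = name[0]
            lines.append(
                f"ATOM  {serial:>5d}  {name:<3s} PHE A   1    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00 {20.0 + serial:5.2f}"
                f"           {el:>2s}"
            )
            serial += 1
        return parse_pdb_string("\n".join(lines) + "\nEND\n", {"A"}, set())

    def test_planar_ring_pseudo_positions_and_bfactor(self):
        s = self._phe_in_xy_plane()
        add_ring_pseudo_atoms(s)
        res = s.get_residue("A", 1)
        pseudo = [a for a in res.atoms if a.is_pseudo]
        assert len(pseudo) == 2
        positions = sorted(round(p.coords[2], 6) for p in pseudo)
        assert positions == [-0.5, 0.5]
        for p in pseudo:
            assert p.coords[0] == pytest.approx(0.0, abs=1e-9)
            assert p.coords[1] == pytest.approx(0.0, abs=1e-9)
            assert not p.is_backbone
        ring_b = [a.b_factor for a in res.atoms if a.name in
                  ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")]
        assert pseudo[0].b_factor == pytest.approx(np.mean(ring_b))
        # pair symmetric about the centroid
        mid = 0.5 * (pseudo[0].coords + pseudo[1].coords)
        assert np.allclose(mid, [0.0, 0.0, 0.0], atol=1e-9)

    def test_trp_gets_two_rings_four_pseudo_atoms(self):
        t = RESIDUE_TEMPLATES["TRP"]
        lines = []
        for serial, (name, (el, xyz)) in enumerate(t.items(), start=1):
            lines.append(
                f"ATOM  {serial:>5d}  {name:<3s} TRP A   1    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00 30.00           {el:>2s}"
            )
        s = parse_pdb_string("\n".join(lines) + "\nEND\n", {"A"}, set())
        add_ring_pseudo_atoms(s)
        assert sum(a.is_pseudo for a in s.protein_atoms()) == 4

    def test_incomplete_ring_skipped_with_warning(self):
        s = self._phe_in_xy_plane()
        res = s.get_residue("A", 1)
        res.atoms = [a for a in res.atoms if a.name != "CZ"]
        with pytest.warns(UserWarning, match="incomplete"):
            add_ring_pseudo_atoms(s)
        assert not any(a.is_pseudo for a in res.atoms)

    def test_pseudo_atoms_bond_to_parent_ring(self):
        s = self._phe_in_xy_plane()
        add_ring_pseudo_atoms(s)
        graph = infer_covalent_bonds(s)
        res = s.get_residue("A", 1)
        pseudo = next(a for a in res.atoms if a.is_pseudo)
        ring_ids = {a.atom_id for a in res.atoms
                    if a.name in ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")}
        assert graph.neighbors(pseudo.atom_id) == ring_ids


class TestVdwRadii:
    def test_carbon_default(self):
        assert vdw_radius("C") == pytest.approx(1.70)

    def test_oxygen_smaller_than_carbon(self):
        assert vdw_radius("O") < vdw_radius("C")

    def test_unknown_element_fatal(self):
        with pytest.raises(KeyError):
            vdw_radius("X")


class TestMutation:
    def test_gly_and_ala_excluded(self):
        with pytest.raises(ValueError):
            Mutation("A", 1, "GLY")
        with pytest.raises(ValueError):
            Mutation("A", 1, "ALA")

    def test_wildtype_mismatch_detected(self, hand_structure):
        m = Mutation("A", 2, "LEU")  # structure has SER at A:2
        with pytest.raises(ValueError, match="SER"):
            m.residue(hand_structure)
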