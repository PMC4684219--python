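"""Beta contacts: geometry, the water rule, and the interface graph."""

import numpy as np
import pytest

from hotcontact.beta_contacts import (
    all_beta_contacts,
    build_contact_graph,
    contact_edge_table,
    is_beta_contact,
    qualified_waters,
)
from hotcontact.structure_model import (
    add_ring_pseudo_atoms,
    infer_covalent_bonds,
    parse_pdb_string,
)
from hotcontact.surface_area import compute_asa
from hotcontact.synthetic_fixtures import (
    FixtureSpec,
    brute_force_beta_contacts,
    make_buried_water_fixture,
    make_toy_complex,
    random_atom_cloud,
)

from conftest import RICH_SPEC, make_atom


class TestIsBetaContact:
    def test_distance_threshold_excludes_far_pair(self):
        # Two carbons (vdw 1.70) at 4.30 A with T_d = 1.25*3.40 = 4.25.
        i = make_atom(0, (0, 0, 0))
        j = make_atom(1, (4.30, 0, 0), seq=2)
        assert not is_beta_contact(i, j, [])

    def test_collinear_atom_interrupts(self):
        i = make_atom(0, (0, 0, 0))
        j = make_atom(1, (3.5, 0, 0), seq=2)
        k = make_atom(2, (1.75, 0, 0), seq=3)  # angle(i,k,j) = 180 degrees
        assert not is_beta_contact(i, j, [k])

    def test_distant_bystander_does_not_interrupt(self):
        i = make_atom(0, (0, 0, 0))
        j = make_atom(1, (3.5, 0, 0), seq=2)
        k = make_atom(2, (1.75, 5.0, 0), seq=3)  # angle about 38.6 degrees
        assert is_beta_contact(i, j, [k])

    def test_pseudo_atom_never_interrupts(self):
        i = make_atom(0, (0, 0, 0))
        j = make_atom(1, (3.5, 0, 0), seq=2)
        ghost = make_atom(2, (1.75, 0, 0), seq=3, is_pseudo=True)
        assert is_beta_contact(i, j, [ghost])

    def test_coincident_centers_fatal(self):
        i = make_atom(0, (0, 0, 0))
        j = make_atom(1, (3.5, 0, 0), seq=2)
        k = make_atom(2, (0, 0, 0), seq=3)
        with pytest.raises(ValueError, match="coincide"):
            is_beta_contact(i, j, [k])

    @pytest.mark.parametrize("seed", range(3))
    def test_symmetry_in_endpoints(self, seed):
        atoms = random_atom_cloud(30, seed=seed)
        for i in range(0, 28, 3):
            a, b = atoms[i], atoms[i + 1]
            others = [x for x in atoms if x.atom_id not in (a.atom_id, b.atom_id)]
            assert is_beta_contact(a, b, others) == is_beta_contact(b, a, others)


class TestContactEnumeration:
    def test_beta_contacts_subset_of_distance_contacts(self):
        atoms = random_atom_cloud(120, seed=4)
        beta = all_beta_contacts(atoms)
        # distance-only: disable the interruption test via empty interrupters
        distance = all_beta_contacts(atoms, interrupters=[])
        assert {c.key for c in beta} <= {c.key for c in distance}
        assert len(beta) < len(distance)

    def test_wider_angle_never_loses_contacts(self):
        atoms = random_atom_cloud(120, seed=5)
        strict = {c.key for c in all_beta_contacts(atoms, beta_angle_deg=85.0)}
        loose = {c.key for c in all_beta_contacts(atoms, beta_angle_deg=120.0)}
        assert strict <= loose

    @pytest.mark.parametrize("seed", range(8))
    def test_grid_matches_brute_force_oracle(self, seed):
        atoms = random_atom_cloud(130, seed=seed)
        grid = {c.key for c in all_beta_contacts(atoms)}
        brute = {c.key for c in brute_force_beta_contacts(atoms)}
        assert grid == brute


class TestQualifiedWaters:
    def test_buried_polar_cage_water_qualifies(self):
        pdb, _ = make_buried_water_fixture(qualify=True)
        s = parse_pdb_string(pdb, {"A"}, {"B"})
        waters = s.water_atoms()
        asa = compute_asa([a for a in s.protein_atoms()] + waters)
        assert asa.atom(waters[0]) < 1.0
        assert qualified_waters(s, asa) == {waters[0].atom_id}

    def test_carbon_cage_water_fails_donor_rule(self):
        pdb, _ = make_buried_water_fixture(qualify=False)
        s = parse_pdb_string(pdb, {"A"}, {"B"})
        waters = s.water_atoms()
        asa = compute_asa([a for a in s.protein_atoms()] + waters)
        assert asa.atom(waters[0]) < 1.0  # buried, but carbon-only partners
        assert qualified_waters(s, asa) == set()

    def test_exposed_water_excluded(self, hand_structure):
        s = hand_structure
        waters = s.water_atoms()
        asa = compute_asa([a for a in s.protein_atoms()] + waters)
        assert all(asa.atom(w) > 1.0 for w in waters)
        assert qualified_waters(s, asa) == set()


@pytest.fixture(scope="module")
def rich_graph(rich_fixture):
    pdb, truth = rich_fixture
    s = parse_pdb_string(pdb, {"A"}, {"B"})
    add_ring_pseudo_atoms(s)
    bonds = infer_covalent_bonds(s)
    return s, bonds, build_contact_graph(s, bonds), truth


class TestContactGraph:
    def test_cross_contacts_match_oracle_truth(self, rich_graph):
        _, _, graph, truth = rich_graph
        assert {c.key for c in graph.contacts if c.cross_interface} == truth.cross_contacts
        assert graph.interfacial_atoms == truth.interfacial_atoms

    def test_atom_set_nesting(self, rich_graph):
        _, _, graph, _ = rich_graph
        assert graph.interfacial_atoms <= graph.neighborhood_atoms
        assert graph.supporting_atoms <= graph.neighborhood_atoms
        assert not (graph.interfacial_atoms & graph.supporting_atoms)
        for c in graph.contacts:
            assert (
                c.atom_i.atom_id in graph.neighborhood_atoms
                or c.atom_j.atom_id in graph.neighborhood_atoms
            )

    def test_nearby_backbone_atoms_stay_out_of_neighborhood(self, rich_graph):
        s, _, graph, _ = rich_graph
        atom_map = s.atom_by_id()
        core = graph.interfacial_atoms | graph.supporting_atoms
        for aid in graph.neighborhood_atoms - core:
            assert not atom_map[aid].is_backbone

    def test_no_water_water_contacts(self, rich_graph):
        _, _, graph, _ = rich_graph
        for c in graph.contacts:
            assert not (c.atom_i.is_water and c.atom_j.is_water)

    def test_separated_chains_give_empty_graph(self):
        spec = FixtureSpec(n_residues_per_chain=4, planted_contacts=(), seed=1)
        pdb, _ = make_toy_complex(spec)  # fillers never reach across
        s = parse_pdb_string(pdb, {"A"}, {"B"})
        add_ring_pseudo_atoms(s)
        bonds = infer_covalent_bonds(s)
        with pytest.warns(UserWarning, match="empty interface"):
            graph = build_contact_graph(s, bonds)
        assert graph.interfacial_atoms == set()
        assert all(not c.cross_interface for c in graph.contacts)

    def test_edge_table_has_one_row_per_contact(self, rich_graph):
        _, _, graph, _ = rich_graph
        table = contact_edge_table(graph)
        assert len(table) == len(graph.contacts)
        assert table["cross_interface"].sum() == sum(
            c.cross_interface for c in graph.contacts
        )
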