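"""Atom/contact typing and the 143-element descriptor, against oracles."""

import numpy as np
import pytest

from hotcontact.beta_contacts import BetaContact, build_contact_graph
from hotcontact.bfactor_norm import complex_bfactor_stats, mutated_atoms
from hotcontact.contact_features import (
    ATOM_GROUP_NAMES,
    CONTACT_TYPE_TABLE,
    FEATURE_NAMES,
    N_ATOM_GROUPS,
    N_CONTACT_TYPES,
    N_COOC,
    N_FEATURES,
    MutationFeatureVector,
    assemble_features,
    atom_group,
    contact_type,
    contact_weight,
    cooccurrence_vector,
    cooccurring_pairs,
    mutated_contact_vector,
    neighborhood_interface_vector,
    triangular_index,
    triangular_pair,
)
from hotcontact.pipeline import extract_features, prepare_structure
from hotcontact.structure_model import (
    Mutation,
    add_ring_pseudo_atoms,
    infer_covalent_bonds,
    parse_pdb_string,
)
from hotcontact.synthetic_fixtures import (
    brute_force_beta_contacts,
    brute_force_cooccurring_pairs,
)

from conftest import RICH_SPEC, make_atom

_G = {name: i for i, name in enumerate(ATOM_GROUP_NAMES)}


@pytest.fixture(scope="module")
def rich_prepared(rich_fixture):
    pdb, truth = rich_fixture
    s = parse_pdb_string(pdb, {"A"}, {"B"})
    s, bonds, graph, stats = prepare_structure(s)
    return s, bonds, graph, stats, truth


class TestAtomGroups:
    def _named(self, structure, chain, seq, name):
        return structure.get_residue(chain, seq).atom(name)

    def test_anchored_group_examples(self, rich_prepared):
        s, bonds, _, _, _ = rich_prepared
        leu_cd1 = self._named(s, "A", 1, "CD1")
        assert atom_group(leu_cd1, bonds) == _G["C_C"]  # no O/N neighbor
        ser_cb = self._named(s, "A", 3, "CB")
        assert atom_group(ser_cb, bonds) == _G["C_ON"]  # bonded to OG
        phe_pseudo = next(
            a for a in s.get_residue("A", 7).atoms if a.is_pseudo
        )
        assert atom_group(phe_pseudo, bonds) == _G["PI"]

    def test_every_standard_heavy_atom_mapped(self, rich_prepared):
        s, bonds, _, _, _ = rich_prepared
        for atom in s.all_atoms():
            group = atom_group(atom, bonds)
            assert 0 <= group < N_ATOM_GROUPS

    def test_unknown_atom_fatal(self):
        stray = make_atom(0, (0, 0, 0), element="P", res_name="UNK", name="P1")
        with pytest.raises(KeyError):
            atom_group(stray)

    def test_bundled_table_covers_all_twenty_residues(self):
        from hotcontact.contact_features import load_atom_group_table
        from hotcontact.structure_model import STANDARD_RESIDUES

        table = load_atom_group_table()
        residues = {res for res, _ in table}
        assert STANDARD_RESIDUES <= residues
        assert set(table.values()) <= set(range(N_ATOM_GROUPS))
        # the anchored carbon split from the bundled table itself
        assert table[("LEU", "CD1")] == _G["C_C"]
        assert table[("SER", "CB")] == _G["C_ON"]
        assert table[("HOH", "O")] == _G["WAT"]


class TestContactTypes:
    def test_table_is_total_and_uses_14_types(self):
        values = set(CONTACT_TYPE_TABLE.values())
        assert values == set(range(N_CONTACT_TYPES))
        assert len(CONTACT_TYPE_TABLE) == N_ATOM_GROUPS * (N_ATOM_GROUPS + 1) // 2

    @pytest.mark.parametrize(
        "pair,expected",
        [
            (("N_DON", "O_ACC"), 0),  # hydrogen bond
            (("C_C", "O_ACC"), 2),  # C_c with oxygen/nitrogen
            (("C_C", "C_C"), 3),  # hydrophobic
            (("C_ON", "N_DON"), 4),  # C_on with oxygen/nitrogen
            (("C_ON", "C_C"), 5),
            (("PI", "C_C"), 9),  # pi-involving
            (("PI", "WAT"), 9),
            (("O_ACC", "O_ACC"), 13),  # acceptor-acceptor
            (("O_ACC", "N_PRO"), 13),
        ],
    )
    def test_anchored_type_assignments(self, pair, expected):
        key = frozenset((_G[pair[0]], _G[pair[1]]))
        assert CONTACT_TYPE_TABLE[key] == expected

    def test_symmetric_under_endpoint_swap(self, rich_prepared):
        _, bonds, graph, _, _ = rich_prepared
        for c in graph.contacts[:50]:
            swapped = BetaContact(c.atom_j, c.atom_i, c.distance, c.cross_interface)
            assert contact_type(c, bonds) == contact_type(swapped, bonds)


class TestTriangularIndex:
    def test_bijection_over_all_105_pairs(self):
        seen = set()
        for t in range(N_CONTACT_TYPES):
            for u in range(t, N_CONTACT_TYPES):
                idx = triangular_index(t, u)
                assert triangular_pair(idx) == (t, u)
                assert triangular_index(u, t) == idx
                seen.add(idx)
        assert seen == set(range(N_COOC))

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            triangular_index(0, 14)
        with pytest.raises(IndexError):
            triangular_pair(105)


def _oracle_vectors(structure, bonds, graph, stats, mutation):
    """Independent recomputation of the three contact blocks.

    Uses the brute-force contact and co-occurrence oracles plus direct
    set arithmetic, sharing only the typing tables with the production
    path.
    """
    from hotcontact.structure_model import nearby_atoms

    mutated_ids = {a.atom_id for a in mutated_atoms(mutation.residue(structure))}
    contacts = list(graph.contacts)
    mut = np.zeros(N_CONTACT_TYPES)
    mutated_contacts = []
    for c in contacts:
        if set(c.atom_ids) & mutated_ids:
            mutated_contacts.append(c)
            mut[contact_type(c, bonds)] += contact_weight(c, stats)

    scope = set(mutated_ids)
    for c in mutated_contacts:
        scope |= set(c.atom_ids)
    atom_map = structure.atom_by_id()
    for aid in list(scope):
        scope |= {
            x for x in nearby_atoms(bonds, aid, 3) if not atom_map[x].is_backbone
        }
    nbr = np.zeros(N_CONTACT_TYPES)
    for c in contacts:
        if c.cross_interface and set(c.atom_ids) & scope:
            nbr[contact_type(c, bonds)] += contact_weight(c, stats)

    cooc = np.zeros(N_COOC)
    by_key = {c.key: c for c in contacts}
    pairs = brute_force_cooccurring_pairs(contacts, bonds, seeds=mutated_contacts)
    for pair in pairs:
        ka, kb = tuple(pair)
        ca, cb = by_key[ka], by_key[kb]
        idx = triangular_index(contact_type(ca, bonds), contact_type(cb, bonds))
        cooc[idx] += contact_weight(ca, stats) + contact_weight(cb, stats)
    return mut, nbr, cooc


class TestContactVectors:
    def test_far_mutation_has_all_zero_contact_blocks(self, rich_prepared):
        s, bonds, graph, stats, truth = rich_prepared
        # column 8 filler pairs with ALA across: its mutated atoms make no
        # cross-interface contacts, but same-side contacts may exist, so
        # check against the oracle rather than asserting all-zero blindly.
        for mutation in truth.mutations:
            mut, nbr, cooc = _oracle_vectors(s, bonds, graph, stats, mutation)
            got_mut = mutated_contact_vector(mutation, graph, s, stats, bonds)
            got_nbr = neighborhood_interface_vector(mutation, graph, s, stats, bonds)
            got_cooc = cooccurrence_vector(mutation, graph, s, stats, bonds)
            assert np.allclose(got_mut, mut, atol=1e-12)
            assert np.allclose(got_nbr, nbr, atol=1e-12)
            assert np.allclose(got_cooc, cooc, atol=1e-12)

    def test_single_planted_contact_arithmetic(self, flat_stats):
        # One type-3 contact with both B'' = -1 contributes exactly -1.
        i = make_atom(0, (0, 0, 0), name="CD1", res_name="LEU", chain="A", b=30.0)
        j = make_atom(1, (3.5, 0, 0), name="CD1", res_name="LEU", chain="B", seq=2, b=30.0)
        c = BetaContact(i, j, 3.5, cross_interface=True)
        assert contact_weight(c, flat_stats) == pytest.approx(-1.0)
        assert contact_type(c) == 3

    def test_cooccurrence_shared_endpoint_and_step_limit(self, rich_prepared):
        s, bonds, graph, stats, _ = rich_prepared
        contacts = graph.contacts
        pairs = cooccurring_pairs(contacts, bonds)
        brute = brute_force_cooccurring_pairs(contacts, bonds)
        assert pairs == brute
        # contacts sharing an endpoint always co-occur
        for a in contacts[:30]:
            for b in contacts[:30]:
                if a.key != b.key and set(a.atom_ids) & set(b.atom_ids):
                    assert frozenset((a.key, b.key)) in pairs


class TestAssembledVector:
    def test_length_and_block_layout(self, rich_prepared):
        s, bonds, graph, stats, truth = rich_prepared
        from hotcontact.pipeline import _side_asa_tables
        from hotcontact.config import RunConfig

        bound, unbound = _side_asa_tables(s, RunConfig())
        fv = assemble_features(
            truth.mutations[0], s, graph, bonds, stats, bound, unbound["A"]
        )
        assert fv.values.shape == (N_FEATURES,)
        assert len(FEATURE_NAMES) == 143
        assert FEATURE_NAMES[8] == "dasa_log" and FEATURE_NAMES[10] == "mut_t00"

    def test_contact_positions_never_positive(self, study):
        contact_cols = FEATURE_NAMES[10:]
        assert (study[contact_cols].to_numpy() <= 1e-12).all()

    def test_atom_order_permutation_leaves_vector_identical(self, rich_fixture):
        pdb, truth = rich_fixture
        rng = np.random.default_rng(0)
        lines = [l for l in pdb.splitlines() if l.startswith(("ATOM", "HETATM"))]
        # shuffle atoms within each residue, keeping residue order
        groups = {}
        order = []
        for line in lines:
            key = line[21] + line[22:26]
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(line)
        shuffled = []
        for key in order:
            block = groups[key][:]
            rng.shuffle(block)
            shuffled.extend(block)
        pdb_shuffled = "\n".join(shuffled) + "\nEND\n"

        mutations = truth.mutations[:3]
        base = extract_features(
            parse_pdb_string(pdb, {"A"}, {"B"}), mutations, complex_id="X"
        )
        perm = extract_features(
            parse_pdb_string(pdb_shuffled, {"A"}, {"B"}), mutations, complex_id="X"
        )
        assert np.array_equal(
            base[FEATURE_NAMES].to_numpy(), perm[FEATURE_NAMES].to_numpy()
        )

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            MutationFeatureVector(
                mutation=Mutation("A", 1, "SER"), values=np.zeros(100)
            )
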