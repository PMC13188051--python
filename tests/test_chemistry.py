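"""Structures, descriptors, fingerprints and descriptor tables."""

import io

import networkx as nx
import numpy as np
import pytest
from rdkit import Chem

from qsarprofiler.base import DescriptorSpec, MissingDescriptorError, ValidationError
from qsarprofiler.chemistry import (
    SmilesParseError,
    available_descriptors,
    compute_descriptors,
    compute_fingerprint,
    parse_smiles,
    read_descriptor_table,
    read_smiles_file,
    register_fingerprint_kind,
    resolve_descriptor_vector,
)
from qsarprofiler.fixtures import TOY_CHEMICALS, toy_chemical_set


def _desc(smiles, name):
    return compute_descriptors(parse_smiles(smiles), [DescriptorSpec(name=name)]).values[0]


class TestParseSmiles:
    def test_benzene(self):
        s = parse_smiles("c1ccccc1")
        assert s.mol.GetNumHeavyAtoms() == 6

    def test_unclosed_ring_is_a_parse_error(self):
        with pytest.raises(SmilesParseError, match="C1CC"):
            parse_smiles("C1CC")

    def test_canonicalization_identifies_rewrites(self):
        assert parse_smiles("OCC").canonical_smiles == parse_smiles("CCO").canonical_smiles

    def test_empty_string_rejected(self):
        with pytest.raises(SmilesParseError):
            parse_smiles("  ")


class TestDescriptors:
    @pytest.mark.parametrize(
        "smiles,name,expected",
        [
            ("CCO", "heavy_atom_count", 3),
            ("c1ccccc1", "ring_count", 1),
            ("CCCC", "wiener_index", 10),
            ("CCO", "hbond_donor_count", 1),
            ("CCOCC", "hbond_acceptor_count", 1),  # backend (Lipinski-style) convention
            ("CCCC", "rotatable_bond_count", 1),
            ("C", "wiener_index", 0),
        ],
    )
    def test_hand_checked_values(self, smiles, name, expected):
        assert _desc(smiles, name) == pytest.approx(expected)

    def test_unknown_descriptor_lists_available_names(self):
        with pytest.raises(ValidationError, match="wiener_index"):
            _desc("CC", "no_such_descriptor")

    def test_values_invariant_under_smiles_rewriting(self):
        specs = [DescriptorSpec(name=n) for n in available_descriptors()]
        a = compute_descriptors(parse_smiles("OCC"), specs).values
        b = compute_descriptors(parse_smiles("CCO"), specs).values
        assert a == b

    def test_wiener_index_matches_graph_oracle_on_random_trees(self, rng):
        # random carbon trees: Wiener = sum of all-pairs shortest paths / 2
        for _ in range(50):
            n = int(rng.integers(2, 12))
            tree = nx.random_labeled_tree(n, seed=int(rng.integers(0, 2**31)))
            mol = Chem.RWMol()
            for _ in range(n):
                mol.AddAtom(Chem.Atom(6))
            for u, v in tree.edges:
                mol.AddBond(int(u), int(v), Chem.BondType.SINGLE)
            m = mol.GetMol()
            Chem.SanitizeMol(m)
            oracle = sum(
                d for _, lengths in nx.all_pairs_shortest_path_length(tree)
                for d in lengths.values()
            ) / 2
            s = parse_smiles(Chem.MolToSmiles(m))
            assert _desc(s.smiles, "wiener_index") == pytest.approx(oracle)


class TestFingerprints:
    def test_deterministic_per_molecule(self):
        a = compute_fingerprint(parse_smiles("CCO"), "hashed_path")
        b = compute_fingerprint(parse_smiles("OCC"), "hashed_path")
        assert a == b

    def test_heavy_atom_graph_determines_hashed_paths(self):
        # deuterated ethanol has the same heavy-atom graph as ethanol
        a = compute_fingerprint(parse_smiles("CCO"), "hashed_path")
        b = compute_fingerprint(parse_smiles("[2H]C([2H])([2H])CO"), "hashed_path")
        assert a.bits == b.bits

    def test_methane_has_no_ring_or_aromatic_smarts_keys(self):
        from qsarprofiler.smarts_keys import SMARTS_KEYS

        fp = compute_fingerprint(parse_smiles("C"), "smarts_keys")
        names = list(SMARTS_KEYS)
        set_names = {names[i] for i in fp.bits}
        assert not any("ring" in n or "aromatic" in n for n in set_names)

    def test_disconnected_union_contains_component_bits(self):
        benzene = compute_fingerprint(parse_smiles("c1ccccc1"), "hashed_path")
        ethanol = compute_fingerprint(parse_smiles("CCO"), "hashed_path")
        union = compute_fingerprint(parse_smiles("c1ccccc1.CCO"), "hashed_path")
        assert (benzene.bits | ethanol.bits) <= union.bits

    def test_count_kind_counts_matches(self):
        fp = compute_fingerprint(parse_smiles("OCCO"), "smarts_keys_count")
        from qsarprofiler.smarts_keys import SMARTS_KEYS

        idx = list(SMARTS_KEYS).index("alcohol")
        assert fp.counts[idx] == 2

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError, match="hashed_path"):
            compute_fingerprint(parse_smiles("CC"), "no_such_kind")

    def test_registered_adapter_kind_is_usable(self):
        from qsarprofiler.chemistry import Fingerprint

        register_fingerprint_kind(
            "heavy_parity",
            lambda s: Fingerprint(kind="heavy_parity", length=2,
                                  bits=frozenset({s.mol.GetNumHeavyAtoms() % 2})),
        )
        fp = compute_fingerprint(parse_smiles("CCO"), "heavy_parity")
        assert fp.bits == {1}


class TestTables:
    def test_read_descriptor_table(self):
        csv = io.StringIO("id,logKow,mw\nc1,1.5,46.07\nc2,-0.3,18.02\n")
        table = read_descriptor_table(csv)
        assert set(table) == {"c1", "c2"}
        assert table["c1"]["logKow"] == pytest.approx(1.5)

    def test_exponent_notation_parsed_exactly(self):
        csv = io.StringIO("id,x\nc1,1.25e-3\n")
        assert read_descriptor_table(csv)["c1"]["x"] == 1.25e-3

    def test_missing_cell_names_row_and_column(self):
        csv = io.StringIO("id,a,b\nc1,1.0,\n")
        with pytest.raises(ValidationError, match="c1.*'b'"):
            read_descriptor_table(csv)

    def test_model_descriptor_missing_from_table_fails_late(self):
        # read succeeds; resolution for a model needing 'other' fails, named
        csv = io.StringIO("id,a\nc1,1.0\n")
        table = read_descriptor_table(csv)
        with pytest.raises(MissingDescriptorError, match="other"):
            resolve_descriptor_vector(
                [DescriptorSpec(name="other", source="supplied")],
                supplied=table["c1"],
            )

    def test_supplied_value_wins_over_computed(self):
        vec = resolve_descriptor_vector(
            [DescriptorSpec(name="heavy_atom_count", source="computed")],
            structure=parse_smiles("CCO"),
            supplied={"heavy_atom_count": 99.0},
        )
        assert vec.values == (99.0,)
        assert vec.provenance == ("supplied",)

    def test_read_smiles_file(self, tmp_path):
        p = tmp_path / "targets.smi"
        p.write_text("# header comment\nCCO ethanol\nc1ccccc1 benzene\n\nCC\n")
        pairs = read_smiles_file(p)
        assert pairs[0] == ("ethanol", "CCO")
        assert pairs[1] == ("benzene", "c1ccccc1")
        assert pairs[2][1] == "CC"


def test_toy_chemical_set_is_frozen_and_parses():
    structures = toy_chemical_set()
    assert len(structures) == len(TOY_CHEMICALS) == 20
    names = [s.id for s in structures]
    assert names[3] == "butane"
    assert _desc("CCCC", "wiener_index") == 10
    # canonical forms stable across parses
    again = toy_chemical_set()
    assert [s.canonical_smiles for s in structures] == [
        s.canonical_smiles for s in again
    ]
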