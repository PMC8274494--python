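"""Dictionary loading and fingerprint computation semantics."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

from ersar.chem import parse_and_standardize
from ersar.dictionaries import BUILTIN_FAMILIES, builtin_dictionary
from ersar.features import count_feature
from ersar.fingerprints import (
    BitDefinition,
    DictionaryError,
    FingerprintDictionary,
    compute_fingerprint,
    compute_matrix,
    load_dictionary,
    save_dictionary,
)


def toy(*patterns):
    return FingerprintDictionary(
        "toy", [BitDefinition(i, "smarts_presence", p) for i, p in enumerate(patterns)]
    )


class TestComputeFingerprint:
    def test_presence_self_match(self):
        v = compute_fingerprint(parse_and_standardize("c1ccccc1"), toy("c1ccccc1"))
        assert v.values.tolist() == [1]

    def test_presence_absent_element(self):
        v = compute_fingerprint(parse_and_standardize("CC"), toy("[#8]"))
        assert v.values.tolist() == [0]

    def test_count_mode_deduplicates_symmetric_embeddings(self):
        # octane has exactly 7 C-C bonds; brute-force oracle: count bonded
        # carbon pairs directly from the adjacency structure
        mol = Chem.MolFromSmiles("CCCCCCCC")
        oracle = sum(
            1
            for b in mol.GetBonds()
            if b.GetBeginAtom().GetAtomicNum() == 6 and b.GetEndAtom().GetAtomicNum() == 6
        )
        v = compute_fingerprint(mol, toy("C-C"), mode="count")
        assert oracle == 7
        assert v.values.tolist() == [oracle]

    @pytest.mark.parametrize("smiles", ["Oc1ccc(CCN)cc1", "CC(=O)Nc1ccccc1", "CCCCCC"])
    def test_count_dominates_presence(self, smiles):
        mol = parse_and_standardize(smiles)
        d = builtin_dictionary("maccs")
        presence = compute_fingerprint(mol, d, "presence").values
        count = compute_fingerprint(mol, d, "count").values
        assert np.all(count >= presence)
        assert np.array_equal(count > 0, presence > 0)

    def test_invariant_to_atom_renumbering(self):
        d = builtin_dictionary("substructure")
        a = compute_fingerprint(parse_and_standardize("Oc1ccc(CC)cc1"), d).values
        b = compute_fingerprint(parse_and_standardize("CCc1ccc(O)cc1"), d).values
        assert np.array_equal(a, b)

    def test_feature_count_rule(self):
        d = FingerprintDictionary(
            "feat",
            [
                BitDefinition(0, "feature_count_at_least", "aromatic_ring", 2),
                BitDefinition(1, "feature_count_at_least", "element:N", 1),
            ],
        )
        naph = compute_fingerprint(parse_and_standardize("c1ccc2ccccc2c1"), d).values
        assert naph.tolist() == [1, 0]
        pyridine = compute_fingerprint(parse_and_standardize("c1ccncc1"), d).values
        assert pyridine.tolist() == [0, 1]


class TestDictionaryIO:
    def test_tsv_round_trip(self, tmp_path):
        d = builtin_dictionary("maccs")
        p = tmp_path / "maccs.tsv"
        save_dictionary(d, p)
        back = load_dictionary(p, name="maccs")
        assert back.n_bits == d.n_bits
        assert [(e.rule_kind, e.pattern, e.threshold) for e in back.entries] == [
            (e.rule_kind, e.pattern, e.threshold) for e in d.entries
        ]

    def test_bad_smarts_names_offending_index(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "index\trule_kind\tpattern\tthreshold\tdescription\n"
            "0\tsmarts_presence\tCC\t1\tok\n"
            "1\tsmarts_presence\tC1CC\t1\tbroken\n"
        )
        with pytest.raises(DictionaryError, match="bit 1"):
            load_dictionary(p)

    def test_duplicate_index_is_load_error(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text(
            "index\trule_kind\tpattern\tthreshold\tdescription\n"
            "5\tsmarts_presence\tCC\t1\ta\n"
            "5\tsmarts_presence\tCO\t1\tb\n"
        )
        with pytest.raises(DictionaryError, match="duplicate"):
            load_dictionary(p)

    def test_indices_must_be_contiguous(self):
        with pytest.raises(DictionaryError, match="contiguous"):
            FingerprintDictionary("gap", [BitDefinition(1, "smarts_presence", "C")])


class TestComputeMatrix:
    def test_shape_and_order(self):
        mols = [parse_and_standardize(s, mol_id=f"m{i}") for i, s in enumerate(["CCO", "CCN"])]
        d = builtin_dictionary("substructure")
        m = compute_matrix(mols, d)
        assert m.values.shape == (2, BUILTIN_FAMILIES["substructure"])
        assert m.ids == ["m0", "m1"]
        assert m.feature_names[0] == "substructureFP0"

    def test_identical_molecules_give_identical_rows(self):
        mols = [parse_and_standardize("Oc1ccc(CC)cc1", mol_id=i) for i in ("a", "b")]
        m = compute_matrix(mols, builtin_dictionary("maccs"))
        assert np.array_equal(m.values[0], m.values[1])

    def test_empty_molecule_list_is_error(self):
        with pytest.raises(DictionaryError):
            compute_matrix([], builtin_dictionary("maccs"))


class TestNamedFeatures:
    @pytest.mark.parametrize(
        "smiles,name,expected",
        [
            ("c1ccc2ccccc2c1", "ring_size:6", 2),
            ("c1ccc2ccccc2c1", "aromatic_ring", 2),
            ("C1CCCCC1", "saturated_ring", 1),
            ("c1ccncc1", "hetero_ring", 1),
            ("CCO", "H", 6),
            ("CC(N)C(=O)O", "element:N", 1),
            ("CCO.CCN", "fragment", 2),
        ],
    )
    def test_hand_counted_features(self, smiles, name, expected):
        assert count_feature(Chem.MolFromSmiles(smiles), name) == expected
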