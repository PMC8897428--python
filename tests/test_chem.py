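"""Atom-environment extraction, vocabulary and corpus statistics."""

import pytest
from rdkit import Chem

from retroae import chem
from retroae.chem import (
    MoleculeRecord,
    RadiusScheme,
    ae_sequence,
    build_vocabulary,
    canonicalize,
    collision_profile,
    coverage_stats,
    extract_aes,
    hashed_bit_indices,
    render_environment,
)

from oracles import environment_partition


class TestCanonicalize:
    def test_aromatic_perception_and_idempotence(self):
        canon = canonicalize("C1=CC=CC=C1")
        assert canon == "c1ccccc1"
        assert canonicalize(canon) == canon

    def test_atom_order_invariance(self):
        assert canonicalize("OCC") == canonicalize("CCO")

    @pytest.mark.parametrize("bad", ["C1CC", "not_a_smiles", "C(C"])
    def test_malformed_input_rejected_with_diagnostic(self, bad):
        with pytest.raises(ValueError, match="SMILES"):
            canonicalize(bad)

    def test_stereochemistry_is_stripped(self):
        assert "@" not in canonicalize("C[C@H](N)C(=O)O")


class TestExtractAes:
    def test_benzene_has_one_environment_per_radius(self):
        for radius in (0, 1):
            aes = extract_aes("c1ccccc1", radius)
            assert len(aes) == 1

    def test_methane_single_atom(self):
        (ae,) = extract_aes("C", 1)
        assert "D0" in ae.smarts

    def test_ethanol_three_distinct_environments(self):
        # CH3 / CH2 / OH differ in element or degree or H count
        assert len(extract_aes("CCO", 0)) == 3
        assert len(extract_aes("CCO", 1)) == 3

    def test_radius_two_rejected_as_tokens(self):
        with pytest.raises(ValueError, match="radius"):
            extract_aes("CCO", 2)

    def test_every_smarts_is_valid_and_self_matches(self, diverse_smiles):
        for smi in diverse_smiles:
            mol = Chem.MolFromSmiles(smi)
            for radius in (0, 1):
                for ae in extract_aes(smi, radius):
                    query = Chem.MolFromSmarts(ae.smarts)
                    assert query is not None, ae.smarts
                    assert mol.HasSubstructMatch(query), (smi, ae.smarts)

    def test_oracle_partition_agreement_on_fixed_molecules(self, diverse_smiles):
        """extract_aes groups atoms exactly like the independent WL oracle."""
        for smi in diverse_smiles:
            mol = Chem.MolFromSmiles(smi)
            for radius in (0, 1):
                oracle = environment_partition(mol, radius)
                mine: dict[str, set[int]] = {}
                for atom in mol.GetAtoms():
                    s = render_environment(mol, atom.GetIdx(), radius)
                    mine.setdefault(s, set()).add(atom.GetIdx())
                assert {frozenset(v) for v in mine.values()} == oracle, (smi, radius)

    def test_oracle_partition_agreement_on_synthetic_library(self, library_200):
        for rec in library_200[:100]:
            mol = Chem.MolFromSmiles(rec.smiles)
            for radius in (0, 1):
                oracle = environment_partition(mol, radius)
                mine: dict[str, set[int]] = {}
                for atom in mol.GetAtoms():
                    s = render_environment(mol, atom.GetIdx(), radius)
                    mine.setdefault(s, set()).add(atom.GetIdx())
                assert {frozenset(v) for v in mine.values()} == oracle


class TestAESequence:
    def test_benzene_union_sequence_length_two(self, library_vocab):
        vocab = build_vocabulary(["c1ccccc1"])
        seq = ae_sequence("c1ccccc1", RadiusScheme.AE0_UNION_AE2, vocab)
        assert len(seq) == 2

    def test_empty_molecule_rejected(self, library_vocab):
        with pytest.raises(ValueError):
            ae_sequence("", RadiusScheme.AE0_UNION_AE2, library_vocab)

    def test_atom_order_invariance(self, library_200, library_vocab):
        from rdkit.Chem import rdmolops
        import numpy as np

        rng = np.random.default_rng(5)
        for rec in library_200[:20]:
            mol = Chem.MolFromSmiles(rec.smiles)
            perm = rng.permutation(mol.GetNumAtoms()).tolist()
            shuffled = Chem.MolToSmiles(rdmolops.RenumberAtoms(mol, perm), canonical=False)
            a = ae_sequence(MoleculeRecord.from_smiles(rec.smiles), RadiusScheme.AE0_UNION_AE2, library_vocab)
            b = ae_sequence(MoleculeRecord.from_smiles(shuffled), RadiusScheme.AE0_UNION_AE2, library_vocab)
            assert a.tokens == b.tokens

    def test_unknown_ae_errors_without_unk(self):
        vocab = build_vocabulary(["c1ccccc1"], allow_unk=False)
        with pytest.raises(KeyError, match="UNK"):
            ae_sequence("CCO", RadiusScheme.AE0_UNION_AE2, vocab)


class TestVocabulary:
    def test_benzene_vocabulary_two_chemical_entries(self):
        vocab = build_vocabulary(["c1ccccc1"])
        assert len(vocab.smarts_to_id) == 2
        assert vocab.n_tokens == 7  # 5 reserved + 2 chemical

    def test_duplicate_and_order_invariance(self, library_200):
        corpus = [r.smiles for r in library_200[:30]]
        v1 = build_vocabulary(corpus)
        v2 = build_vocabulary(corpus + corpus)
        v3 = build_vocabulary(list(reversed(corpus)))
        assert v1.smarts_to_id == v2.smarts_to_id == v3.smarts_to_id

    def test_reserved_ids_disjoint_from_chemical(self, library_vocab):
        assert min(library_vocab.smarts_to_id.values()) >= 5

    def test_tsv_round_trip(self, library_vocab, tmp_path):
        path = tmp_path / "vocab.tsv"
        library_vocab.write_tsv(path)
        loaded = chem.Vocabulary.read_tsv(path)
        assert loaded.smarts_to_id == library_vocab.smarts_to_id
        assert loaded.fingerprint() == library_vocab.fingerprint()

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_vocabulary([])


class TestHashedBits:
    def test_bits_in_range_and_bounded_by_environment_count(self, diverse_smiles):
        for smi in diverse_smiles:
            n_envs = len(extract_aes(smi, 0)) + len(extract_aes(smi, 1))
            bits = hashed_bit_indices(smi, radius=1, n_bits=1024)
            assert bits == sorted(bits)
            assert all(0 <= b < 1024 for b in bits)
            assert len(bits) <= n_envs

    def test_two_bit_fingerprint_range(self):
        assert set(hashed_bit_indices("CC(=O)OCC", 1, n_bits=2)) <= {0, 1}

    def test_determinism(self):
        assert hashed_bit_indices("CCO", 2) == hashed_bit_indices("CCO", 2)


class TestCollisionProfile:
    def test_single_benzene_every_bit_count_one(self):
        for radius in (0, 1, 2):
            profile = collision_profile(["c1ccccc1"], radius)
            assert all(c == 1 for c in profile.per_bit_counts.values())

    def test_mean_collisions_monotone_in_radius(self, library_200):
        corpus = library_200
        means = [collision_profile(corpus, r, 1024).mean_smarts_per_bit for r in (0, 1, 2)]
        assert means[0] <= means[1] <= means[2]

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            collision_profile([], 1)


class TestCoverageStats:
    def test_single_benzene(self):
        per, pairwise = coverage_stats({"x": ["c1ccccc1"]})
        cov = per["x"]
        assert cov.n_unique_ae0 == 1 and cov.n_unique_ae2 == 1
        assert cov.singleton_fraction_ae0 == 1.0

    def test_disjoint_corpora_have_empty_intersection(self):
        per, pairwise = coverage_stats({"a": ["CCCC"], "b": ["c1ccccc1"]})
        assert pairwise[("a", "b")]["ae0_intersection"] == 0

    def test_counts_equal_brute_force_union(self, library_200):
        subset = library_200[:50]
        per, _ = coverage_stats({"lib": subset})
        brute0 = set()
        brute1 = set()
        for rec in subset:
            brute0 |= {ae.smarts for ae in extract_aes(rec.smiles, 0)}
            brute1 |= {ae.smarts for ae in extract_aes(rec.smiles, 1)}
        assert per["lib"].n_unique_ae0 == len(brute0)
        assert per["lib"].n_unique_ae2 == len(brute1)
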