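"""Reaction parsing, curation, encoding, splitting and augmentation."""

import numpy as np
import pytest

from retroae import corpus
from retroae.chem import BOS, EOS, SEP
from retroae.corpus import (
    RawReaction,
    augment,
    curate,
    decode_target,
    encode_example,
    parse_reaction,
    split,
)


class TestParseReaction:
    def test_well_formed_esterification(self):
        rxn = parse_reaction("CCO.CC(=O)O>>CCOC(C)=O")
        assert len(rxn.reactants) == 2
        assert rxn.reagents == ()
        assert len(rxn.products) == 1

    def test_single_separator_rejected(self):
        with pytest.raises(ValueError, match="separator"):
            parse_reaction("A>B")

    def test_reagent_captured_but_separate(self):
        rxn = parse_reaction("CCO.CC(=O)O>[H+]>CCOC(C)=O")
        assert rxn.reagents == ("[H+]",)
        assert "[H+]" not in rxn.reactants

    def test_members_canonicalized(self):
        rxn = parse_reaction("OCC>>C1=CC=CC=C1")
        assert rxn.reactants == ("CCO",)
        assert rxn.products == ("c1ccccc1",)


class TestCurate:
    def _raws(self):
        return [
            parse_reaction("CCO.CC(=O)O>>CCOC(C)=O", 1),
            parse_reaction("CCO.CC(=O)O>>CCOC(C)=O.O", 2),        # two products
            parse_reaction("CCO.CC(=O)O.CN>>CCOC(C)=O", 3),       # three reactants
            parse_reaction("CC(=O)O.CCO>>CCOC(C)=O", 4),          # duplicate of 1
            parse_reaction("OCCCCO>>O=C1CCCCO1", 5),              # unimolecular (reverse)
        ]

    def test_rules_applied_and_tallied(self):
        ds = curate(self._raws())
        assert len(ds.examples) == 2
        assert ds.rejections["multi_product"] == 1
        assert ds.rejections["multicomponent"] == 1
        assert ds.rejections["duplicate"] == 1

    def test_conservation_of_records(self):
        ds = curate(self._raws())
        assert len(ds.examples) + sum(ds.rejections.values()) == ds.n_raw

    def test_klass_assignment(self):
        ds = curate(self._raws())
        klasses = {ex.product_smiles: ex.klass.value for ex in ds.examples}
        assert klasses["CCOC(C)=O"] == "bimolecular"
        assert klasses["O=C1CCCCO1"] == "unimolecular"

    def test_over_length_dropped(self):
        # max_len=3 is below any real molecule's AE count
        ds = curate(self._raws(), max_len=3)
        assert len(ds.examples) == 0
        assert ds.rejections["over_length"] == 2

    def test_bimolecular_reactant_order_is_deterministic(self):
        ds = curate(self._raws())
        ex = next(e for e in ds.examples if e.klass.value == "bimolecular")
        lens = [len(s) for s in ex.reactant_seqs]
        assert lens == sorted(lens, reverse=True)


class TestEncodeDecode:
    def test_structure_and_lengths(self, small_curated):
        for ex in small_curated.examples[:30]:
            src, tgt = encode_example(ex)
            assert src == list(ex.product_seq.tokens)
            assert tgt[0] == BOS and tgt[-1] == EOS
            n_sep = tgt.count(SEP)
            assert n_sep == (1 if ex.klass.value == "bimolecular" else 0)
            expected = 2 + n_sep + sum(len(s) for s in ex.reactant_seqs)
            assert len(tgt) == expected

    def test_round_trip_recovers_reactant_sets(self, small_curated):
        for ex in small_curated.examples[:30]:
            _, tgt = encode_example(ex)
            blocks = decode_target(tgt)
            assert [set(b) for b in blocks] == [set(s.tokens) for s in ex.reactant_seqs]

    def test_decode_collapses_duplicates(self):
        assert decode_target([BOS, 7, 7, 8, EOS]) == [[7, 8]]

    def test_decode_stops_at_eos(self):
        assert decode_target([BOS, 7, EOS, 9]) == [[7]]


class TestSplit:
    def test_proportions(self, small_curated):
        n = len(small_curated.examples)
        n_train = len(small_curated.subset("train"))
        n_valid = len(small_curated.subset("valid"))
        n_test = len(small_curated.subset("test"))
        assert n_train + n_valid + n_test == n
        assert abs(n_test - round(0.1 * n)) <= 1
        assert abs(n_valid - round(0.09 * n)) <= 1

    def test_thousand_examples_split_sizes(self):
        # 1000 -> 810 train / 90 valid / 100 test from the 9:1 then 10% rule
        exs = [object()] * 1000
        ds = corpus.CuratedDataset(examples=list(exs), split_labels=["train"] * 1000)
        out = split(ds, seed=0)
        sizes = {lab: out.split_labels.count(lab) for lab in ("train", "valid", "test")}
        assert sizes == {"train": 810, "valid": 90, "test": 100}

    def test_determinism_and_seed_sensitivity(self, small_curated):
        a = split(small_curated, seed=42)
        b = split(small_curated, seed=42)
        c = split(small_curated, seed=43)
        assert a.split_labels == b.split_labels
        assert a.split_labels != c.split_labels
        assert sorted(a.split_labels) == sorted(c.split_labels)

    def test_too_few_examples_rejected(self):
        ds = corpus.CuratedDataset(examples=[object()] * 5, split_labels=["train"] * 5)
        with pytest.raises(ValueError):
            split(ds)


class TestAugment:
    def test_identity_at_k1(self, small_curated):
        assert augment(small_curated, k=1) is small_curated

    def test_k_replicates_train_only(self, small_curated):
        k = 4
        out = augment(small_curated, k=k, seed=0)
        n_train = len(small_curated.subset("train"))
        assert len(out.subset("train")) == k * n_train
        assert len(out.subset("test")) == len(small_curated.subset("test"))
        assert len(out.subset("valid")) == len(small_curated.subset("valid"))

    def test_replicates_preserve_token_multisets(self, small_curated):
        out = augment(small_curated, k=3, seed=1)
        train = out.subset("train")
        originals = small_curated.subset("train")
        by_product = {}
        for ex in train:
            key = ex.product_smiles
            by_product.setdefault(key, []).append(ex)
        for orig in originals:
            for rep in by_product[orig.product_smiles]:
                assert sorted(rep.product_seq.tokens) == sorted(orig.product_seq.tokens)
                assert [sorted(s.tokens) for s in rep.reactant_seqs] == [
                    sorted(s.tokens) for s in orig.reactant_seqs
                ]

    def test_single_token_product_yields_identical_replicates(self, library_vocab):
        from retroae.chem import AESequence, RadiusScheme

        seq = AESequence("m", [7], RadiusScheme.AE0_UNION_AE2)
        ex = corpus.ReactionExample(seq, [seq], corpus.ReactionClass.UNIMOLECULAR)
        ds = corpus.CuratedDataset(examples=[ex], split_labels=["train"])
        out = augment(ds, k=5, seed=0)
        assert all(e.product_seq.tokens == [7] for e in out.examples)
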