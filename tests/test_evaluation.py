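"""Tversky similarity, hard/soft match grading and background p-values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retroae.chem import build_vocabulary
from retroae.evaluation import (
    BackgroundDistribution,
    MatchCategory,
    background_distribution,
    classify_match,
    evaluate_predictions,
    similarity_score,
    tversky,
)

sets = st.sets(st.integers(0, 30), min_size=0, max_size=15)


class TestTversky:
    def test_identity_and_disjoint(self):
        assert tversky({1, 2}, {1, 2}, 0.3, 1.7) == 1.0
        assert tversky({1, 2}, {3, 4}, 1.0, 1.0) == 0.0

    def test_worked_cardinalities(self):
        x, y = {1, 2, 3}, {2, 3, 4}  # I=2, |x-y|=1, |y-x|=1
        assert tversky(x, y, 1, 1) == 0.5
        assert tversky(x, y, 0.5, 0.5) == pytest.approx(2 / 3)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            tversky(set(), set())

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            tversky({1}, {2}, -1, 1)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(x=sets, y=sets)
    def test_reductions_to_tanimoto_and_dice(self, x, y):
        if not x and not y:
            return
        assert tversky(x, y, 1, 1) == pytest.approx(
            len(x & y) / len(x | y) if x | y else 1.0
        )
        assert tversky(x, y, 0.5, 0.5) == pytest.approx(
            2 * len(x & y) / (len(x) + len(y))
        )

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(x=sets, y=sets)
    def test_dice_dominates_tanimoto(self, x, y):
        if not x and not y:
            return
        s = similarity_score(x, y)
        assert s.dice >= s.tanimoto
        if s.dice == s.tanimoto:
            assert x == y or not (x & y)


class TestClassifyMatch:
    def test_exact(self):
        r = classify_match([{1, 2, 3}], [{1, 2, 3}])
        assert r.category is MatchCategory.EXACT and r.mutation_count == 0
        assert r.score.tanimoto == 1.0

    def test_single_mutation_added_token(self):
        r = classify_match([{1, 2, 3, 9}], [{1, 2, 3}])
        assert r.category is MatchCategory.SM and r.mutation_count == 1

    def test_substitution_is_double_mutation(self):
        r = classify_match([{1, 2, 9}], [{1, 2, 3}])
        assert r.category is MatchCategory.DM and r.mutation_count == 2

    def test_soft_threshold_band(self):
        truth = set(range(22))
        pred = set(range(20)) | {100, 101}  # |Δ|=4, Tc = 20/24 ≈ 0.833
        r = classify_match([pred], [truth])
        assert r.category is MatchCategory.SOFT_080
        big_truth = set(range(30))
        big_pred = set(range(28)) | {100, 101}  # Tc = 28/32 = 0.875
        r2 = classify_match([big_pred], [big_truth])
        assert r2.category is MatchCategory.SOFT_085

    def test_reactant_count_mismatch_is_below(self):
        r = classify_match([{1, 2}], [{1}, {2}])
        assert r.category is MatchCategory.BELOW
        assert "mismatch" in r.note

    def test_bimolecular_assignment_ignores_order(self):
        truth = [{1, 2, 3}, {7, 8}]
        r = classify_match([{7, 8}, {1, 2, 3}], truth)
        assert r.category is MatchCategory.EXACT

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            classify_match([{1}], [set()])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        base=st.sets(st.integers(0, 60), min_size=4, max_size=25),
        removed=st.integers(0, 3),
        added=st.integers(0, 3),
    )
    def test_mutation_count_equals_symmetric_difference(self, base, removed, added):
        base = set(base)
        truth = base
        pred = set(sorted(base)[removed:]) | {1000 + i for i in range(added)}
        if not pred:
            return
        r = classify_match([pred], [truth])
        assert r.mutation_count == len(pred ^ truth)
        expected = {0: MatchCategory.EXACT, 1: MatchCategory.SM, 2: MatchCategory.DM}
        if r.mutation_count in expected:
            assert r.category is expected[r.mutation_count]
        else:
            assert r.category in (
                MatchCategory.SOFT_085, MatchCategory.SOFT_080, MatchCategory.BELOW
            )


class TestEvaluatePredictions:
    def test_all_exact(self):
        truths = [[{1, 2}], [{3, 4}, {5, 6, 7}]]
        s = evaluate_predictions(truths, truths)
        assert s.exact_pct == s.soft_080_pct == 100.0
        assert s.mean_tanimoto == 1.0 and s.mean_dice == 1.0

    def test_half_exact_half_disjoint(self):
        truths = [[{1, 2, 3}], [{4, 5, 6}]]
        preds = [[{1, 2, 3}], [{7, 8, 9}]]
        s = evaluate_predictions(preds, truths)
        assert s.exact_pct == 50.0
        assert s.sm_pct == s.dm_pct == s.soft_080_pct == 50.0
        assert s.mean_tanimoto == 0.5

    def test_columns_monotone_nondecreasing(self):
        rng = np.random.default_rng(0)
        truths, preds = [], []
        for _ in range(200):
            t = set(rng.choice(50, size=rng.integers(3, 15), replace=False).tolist())
            p = set(t)
            for tok in list(p)[: rng.integers(0, 4)]:
                p.discard(tok)
            p |= {int(x) + 100 for x in rng.choice(20, size=rng.integers(0, 4))}
            truths.append([t])
            preds.append([p or {999}])
        s = evaluate_predictions(preds, truths)
        cols = [s.exact_pct, s.sm_pct, s.dm_pct, s.soft_085_pct, s.soft_080_pct]
        assert cols == sorted(cols)
        assert sum(s.category_counts.values()) == s.n_examples == 200

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_predictions([[{1}]], [[{1}], [{2}]])


class TestBackground:
    def test_identical_molecules_pvalue_one(self):
        vocab = build_vocabulary(["c1ccccc1"])
        bg = background_distribution(["c1ccccc1", "c1ccccc1", "c1ccccc1"], vocab, n_pairs=50, seed=0)
        assert np.all(bg.samples == 1.0)
        assert bg.p_value(1.0) == 1.0

    def test_pvalue_monotone_nonincreasing(self):
        bg = BackgroundDistribution(np.array([0.1, 0.2, 0.5, 0.9]), seed=0)
        ts = np.linspace(0, 1, 21)
        ps = [bg.p_value(t) for t in ts]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_tiny_corpus_matches_exhaustive_counting(self, library_vocab, library_200):
        corpus = library_200[:5]
        from retroae.chem import RadiusScheme, ae_sequence

        token_sets = [
            set(ae_sequence(m, RadiusScheme.AE0_UNION_AE2, library_vocab).tokens)
            for m in corpus
        ]
        exhaustive = [
            tversky(token_sets[i], token_sets[j], 1, 1)
            for i in range(5)
            for j in range(5)
            if i != j
        ]
        bg = background_distribution(corpus, library_vocab, n_pairs=4000, seed=1)
        for t in (0.2, 0.5, 0.8):
            direct = (np.array(exhaustive) >= t).mean()
            assert bg.p_value(t) == pytest.approx(direct, abs=0.05)

    def test_singleton_corpus_rejected(self, library_vocab):
        with pytest.raises(ValueError):
            background_distribution(["CCO"], library_vocab)
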