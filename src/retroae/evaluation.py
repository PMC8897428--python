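"""Similarity scoring and prediction evaluation for AE-set predictions.

The central quantity is the Tversky index over two AE sets X, Y:

    S(X, Y) = |X ∩ Y| / (|X ∩ Y| + α|X − Y| + β|Y − X|),    α, β ≥ 0

with α = β = 1 the Tanimoto coefficient and α = β = 0.5 the
Sørensen–Dice coefficient.  Predictions are graded on two scales:

- *hard thresholds*: the symmetric-difference cardinality |X Δ Y|
  (the "mutation count") — 0 is an exact match, 1 a single mutation
  (SM: one environment added or removed at a terminal site), 2 a double
  mutation (DM: a misplaced branch or a single atom substitution, which
  removes one environment and adds another);
- *soft thresholds*: Tanimoto cutoffs, by default 0.85 (the classic
  bioactive-similarity level) and 0.80.

Summaries report the five cumulative categories plus mean Tanimoto and
mean Dice.  Statistical significance of a Tanimoto value is assessed
against an empirical background distribution of randomly paired corpus
molecules.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .chem import MoleculeRecord, RadiusScheme, Vocabulary, ae_sequence

__all__ = [
    "SimilarityScore",
    "MatchCategory",
    "MatchReport",
    "EvaluationSummary",
    "BackgroundDistribution",
    "tversky",
    "similarity_score",
    "classify_match",
    "evaluate_predictions",
    "background_distribution",
]

SOFT_THRESHOLDS = (0.85, 0.80)


def tversky(x: set, y: set, alpha: float = 1.0, beta: float = 1.0) -> float:
    """Tversky index of two finite sets; symmetric iff alpha == beta."""
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be >= 0")
    x, y = set(x), set(y)
    if not x and not y:
        raise ValueError("Tversky index of two empty sets is undefined (0/0)")
    inter = len(x & y)
    denom = inter + alpha * len(x - y) + beta * len(y - x)
    return inter / denom if denom else 0.0


@dataclass(frozen=True)
class SimilarityScore:
    """Tanimoto and Dice with the underlying cardinalities."""

    tanimoto: float
    dice: float
    intersection: int
    only_x: int
    only_y: int

    @property
    def mutation_count(self) -> int:
        return self.only_x + self.only_y


def similarity_score(x: set, y: set) -> SimilarityScore:
    x, y = set(x), set(y)
    return SimilarityScore(
        tanimoto=tversky(x, y, 1.0, 1.0),
        dice=tversky(x, y, 0.5, 0.5),
        intersection=len(x & y),
        only_x=len(x - y),
        only_y=len(y - x),
    )


class MatchCategory(str, enum.Enum):
    EXACT = "exact"       # Tc = 1.0, zero mutations
    SM = "SM"             # |XΔY| = 1
    DM = "DM"             # |XΔY| = 2
    SOFT_085 = "soft_085"  # Tc >= 0.85 but > 2 mutations
    SOFT_080 = "soft_080"  # Tc >= 0.80 but < 0.85
    BELOW = "below"


@dataclass
class MatchReport:
    """Category and similarity of one predicted reactant set vs truth."""

    category: MatchCategory
    mutation_count: int
    score: SimilarityScore
    per_reactant: list[SimilarityScore] = field(default_factory=list)
    note: str = ""


def _assign_pairs(
    pred: list[set], truth: list[set]
) -> list[tuple[set, set]]:
    """Maximal-Tanimoto one-to-one assignment of predicted to true reactants."""
    if len(pred) == 1 and len(truth) == 1:
        return [(pred[0], truth[0])]
    cost = np.zeros((len(pred), len(truth)))
    for i, p in enumerate(pred):
        for j, t in enumerate(truth):
            cost[i, j] = -tversky(p, t) if (p or t) else 0.0
    rows, cols = linear_sum_assignment(cost)
    return [(pred[i], truth[j]) for i, j in zip(rows, cols)]


def classify_match(
    pred: list[set],
    truth: list[set],
    soft_thresholds: tuple[float, float] = SOFT_THRESHOLDS,
    soft_aggregate: str = "min",
) -> MatchReport:
    """Grade a predicted reactant list against the ground truth.

    For bimolecular examples the predicted reactants are paired with the
    true ones by the maximal-Tanimoto one-to-one assignment; mutation
    counts are summed over pairs and soft categories use the ``min``
    (default, conservative) or ``mean`` Tanimoto over pairs.  A
    reactant-count mismatch is graded ``below`` directly.
    """
    if not truth or all(not t for t in truth):
        raise ValueError("empty ground truth")
    pred = [set(b) for b in pred]
    truth = [set(b) for b in truth]
    if len(pred) != len(truth):
        all_score = similarity_score(set().union(*pred) if pred else set(), set().union(*truth))
        return MatchReport(
            MatchCategory.BELOW,
            all_score.mutation_count,
            all_score,
            note=f"reactant count mismatch: predicted {len(pred)}, true {len(truth)}",
        )
    pairs = _assign_pairs(pred, truth)
    per_reactant = [similarity_score(p, t) if (p or t) else None for p, t in pairs]
    per_reactant = [s for s in per_reactant if s is not None]
    mutations = sum(s.mutation_count for s in per_reactant)
    tcs = [s.tanimoto for s in per_reactant]
    agg_tc = min(tcs) if soft_aggregate == "min" else float(np.mean(tcs))
    overall = similarity_score(set().union(*pred), set().union(*truth))
    hi, lo = soft_thresholds
    if mutations == 0:
        cat = MatchCategory.EXACT
    elif mutations == 1:
        cat = MatchCategory.SM
    elif mutations == 2:
        cat = MatchCategory.DM
    elif agg_tc >= hi:
        cat = MatchCategory.SOFT_085
    elif agg_tc >= lo:
        cat = MatchCategory.SOFT_080
    else:
        cat = MatchCategory.BELOW
    return MatchReport(cat, mutations, overall, per_reactant)


@dataclass
class EvaluationSummary:
    """Cumulative success percentages at the five standard thresholds."""

    exact_pct: float
    sm_pct: float
    dm_pct: float
    soft_085_pct: float
    soft_080_pct: float
    mean_tanimoto: float
    mean_dice: float
    n_examples: int
    category_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def evaluate_predictions(
    preds: list[list[set]],
    truths: list[list[set]],
    soft_thresholds: tuple[float, float] = SOFT_THRESHOLDS,
    soft_aggregate: str = "min",
) -> EvaluationSummary:
    """Aggregate match reports into the cumulative five-column summary.

    Columns are cumulative: the SM column counts exact matches too, DM
    counts exact+SM+DM, and each soft column includes every category at
    least as good, so percentages are non-decreasing left to right.
    """
    if len(preds) != len(truths):
        raise ValueError("preds and truths differ in length")
    if not preds:
        raise ValueError("nothing to evaluate")
    reports = [
        classify_match(p, t, soft_thresholds, soft_aggregate)
        for p, t in zip(preds, truths)
    ]
    counts = {c.value: 0 for c in MatchCategory}
    for r in reports:
        counts[r.category.value] += 1
    n = len(reports)
    order = [
        MatchCategory.EXACT,
        MatchCategory.SM,
        MatchCategory.DM,
        MatchCategory.SOFT_085,
        MatchCategory.SOFT_080,
    ]
    cumulative = []
    running = 0
    for cat in order:
        running += counts[cat.value]
        cumulative.append(100.0 * running / n)
    # per-reactant means where available, else overall-set score
    tcs, dices = [], []
    for r in reports:
        scores = r.per_reactant or [r.score]
        tcs.append(float(np.mean([s.tanimoto for s in scores])))
        dices.append(float(np.mean([s.dice for s in scores])))
    return EvaluationSummary(
        *cumulative,
        mean_tanimoto=float(np.mean(tcs)),
        mean_dice=float(np.mean(dices)),
        n_examples=n,
        category_counts=counts,
    )


@dataclass
class BackgroundDistribution:
    """Empirical Tanimoto distribution of randomly paired corpus molecules.

    ``p_value(t)`` is the smoothed upper-tail fraction (k + 1)/(n + 1)
    of background similarities ≥ t — the probability that two random
    corpus molecules are at least that similar, never exactly zero for a
    finite sample.
    """

    samples: np.ndarray
    seed: int

    def p_value(self, t: float) -> float:
        k = int((self.samples >= t).sum())
        return (k + 1) / (len(self.samples) + 1)


def background_distribution(
    corpus: list[MoleculeRecord | str],
    vocab: Vocabulary,
    n_pairs: int = 10_000,
    seed: int = 0,
    scheme: RadiusScheme = RadiusScheme.AE0_UNION_AE2,
) -> BackgroundDistribution:
    """Sample Tanimoto values between random non-identical molecule pairs."""
    if len(corpus) < 2:
        raise ValueError("background distribution needs at least 2 molecules")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    token_sets = [
        set(ae_sequence(m if isinstance(m, MoleculeRecord) else MoleculeRecord.from_smiles(m),
                        scheme, vocab).tokens)
        for m in corpus
    ]
    rng = np.random.default_rng(seed)
    n = len(token_sets)
    values = np.empty(n_pairs)
    for k in range(n_pairs):
        i = int(rng.integers(n))
        j = int(rng.integers(n - 1))
        if j >= i:
            j += 1
        values[k] = tversky(token_sets[i], token_sets[j], 1.0, 1.0)
    return BackgroundDistribution(values, seed)
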