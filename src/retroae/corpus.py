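"""Reaction-corpus curation and encoding.

Parses reaction SMILES in the ``reactants>reagents>products`` dialect,
curates them to the single-product uni-/bimolecular subset the translation
model is trained on, encodes product → reactant pairs as AE token
sequences, splits train/valid/test, and optionally augments training
examples by permuting token order.
"""

from __future__ import annotations

import csv
import enum
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from .chem import (
    BOS,
    EOS,
    MAX_TOKENS,
    SEP,
    AESequence,
    MoleculeRecord,
    RadiusScheme,
    Vocabulary,
    ae_sequence,
    build_vocabulary,
    canonicalize,
)

__all__ = [
    "ReactionClass",
    "RawReaction",
    "ReactionExample",
    "CuratedDataset",
    "parse_reaction",
    "read_reaction_file",
    "curate",
    "encode_example",
    "decode_target",
    "split",
    "augment",
]


class ReactionClass(str, enum.Enum):
    UNIMOLECULAR = "unimolecular"
    BIMOLECULAR = "bimolecular"


@dataclass(frozen=True)
class RawReaction:
    """One parsed reaction line; reagents are recorded then discarded."""

    reactants: tuple[str, ...]
    reagents: tuple[str, ...]
    products: tuple[str, ...]
    source_line: int = 0


@dataclass
class ReactionExample:
    """A curated product → reactant(s) pair in AE token space."""

    product_seq: AESequence
    reactant_seqs: list[AESequence]
    klass: ReactionClass
    product_smiles: str = ""
    reactant_smiles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.reactant_seqs)
        if n not in (1, 2):
            raise ValueError("a curated example has one or two reactants")
        expected = ReactionClass.UNIMOLECULAR if n == 1 else ReactionClass.BIMOLECULAR
        if self.klass != expected:
            raise ValueError(f"klass {self.klass} inconsistent with {n} reactants")


@dataclass
class CuratedDataset:
    """Curated examples with split labels and the curation ledger."""

    examples: list[ReactionExample]
    split_labels: list[str] = field(default_factory=list)  # train/valid/test per example
    seed: int = 0
    rejections: Counter = field(default_factory=Counter)
    n_raw: int = 0
    vocab: Vocabulary | None = None

    def subset(self, label: str) -> list[ReactionExample]:
        return [ex for ex, lab in zip(self.examples, self.split_labels) if lab == label]

    def subset_indices(self, label: str) -> list[int]:
        return [i for i, lab in enumerate(self.split_labels) if lab == label]


# ---------------------------------------------------------------------------
# parsing

def parse_reaction(line: str, source_line: int = 0) -> RawReaction:
    """Parse one ``reactants>reagents>products`` reaction SMILES line.

    Every member molecule is canonicalized.  The middle field holds
    reagents, which are kept in the record for bookkeeping but excluded
    from the reactant list downstream (no atom-mapping-based role
    reassignment is attempted).
    """
    fields = line.strip().split(">")
    if len(fields) != 3:
        raise ValueError(
            f"line {source_line}: expected 'reactants>reagents>products' "
            f"(2 '>' separators), got {line.strip()!r}"
        )

    def members(fld: str) -> tuple[str, ...]:
        if not fld:
            return ()
        return tuple(canonicalize(part) for part in fld.split("."))

    try:
        reactants = members(fields[0])
        reagents = members(fields[1])
        products = members(fields[2])
    except ValueError as exc:
        raise ValueError(f"line {source_line}: {exc}") from exc
    if not reactants or not products:
        raise ValueError(f"line {source_line}: empty reactant or product field")
    return RawReaction(reactants, reagents, products, source_line)


def read_reaction_file(path) -> tuple[list[RawReaction], Counter]:
    """Read a reaction SMILES file, collecting unparseable lines in a ledger."""
    raws: list[RawReaction] = []
    rejections: Counter = Counter()
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                raws.append(parse_reaction(line, i))
            except ValueError:
                rejections["unparseable"] += 1
    return raws, rejections


# ---------------------------------------------------------------------------
# curation

def _order_reactants(seqs: list[AESequence], smiles: list[str]) -> list[int]:
    """Deterministic bimolecular order: more AE tokens first, ties by SMILES."""
    return sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), smiles[i]))


def curate(
    raw: list[RawReaction],
    vocab: Vocabulary | None = None,
    scheme: RadiusScheme = RadiusScheme.AE0_UNION_AE2,
    max_len: int = MAX_TOKENS,
) -> CuratedDataset:
    """Filter raw reactions down to encodable single-product examples.

    Rules, applied in order and tallied in the rejection ledger:

    - ``multi_product``: more than one product molecule;
    - ``multicomponent``: more than two reactants (after reagent removal);
    - ``duplicate``: identical canonical product + sorted reactant strings
      already seen;
    - ``over_length``: product or any reactant exceeding ``max_len`` AE
      tokens;
    - ``fragment_error``: molecule that cannot be fragmented.

    If no vocabulary is supplied, one is built over all molecules of the
    kept reactions.  Rejections are data, not errors.
    """
    if not raw:
        raise ValueError("no raw reactions to curate")
    rejections: Counter = Counter()
    survivors: list[RawReaction] = []
    seen: set[tuple] = set()
    for rxn in raw:
        if len(rxn.products) != 1:
            rejections["multi_product"] += 1
            continue
        if not 1 <= len(rxn.reactants) <= 2:
            rejections["multicomponent"] += 1
            continue
        key = (rxn.products[0], tuple(sorted(rxn.reactants)))
        if key in seen:
            rejections["duplicate"] += 1
            continue
        seen.add(key)
        survivors.append(rxn)

    if vocab is None:
        molecules = sorted(
            {s for rxn in survivors for s in (*rxn.reactants, *rxn.products)}
        )
        vocab = build_vocabulary(
            [MoleculeRecord(s) for s in molecules], scheme=scheme
        )

    examples: list[ReactionExample] = []
    for rxn in survivors:
        try:
            prod = ae_sequence(MoleculeRecord(rxn.products[0]), scheme, vocab, max_len)
            reacts = [
                ae_sequence(MoleculeRecord(s), scheme, vocab, max_len)
                for s in rxn.reactants
            ]
        except ValueError as exc:
            kind = "over_length" if "AE tokens" in str(exc) else "fragment_error"
            rejections[kind] += 1
            continue
        order = _order_reactants(reacts, list(rxn.reactants))
        examples.append(
            ReactionExample(
                product_seq=prod,
                reactant_seqs=[reacts[i] for i in order],
                klass=(
                    ReactionClass.UNIMOLECULAR
                    if len(reacts) == 1
                    else ReactionClass.BIMOLECULAR
                ),
                product_smiles=rxn.products[0],
                reactant_smiles=tuple(rxn.reactants[i] for i in order),
            )
        )
    return CuratedDataset(
        examples=examples,
        split_labels=["train"] * len(examples),
        rejections=rejections,
        n_raw=len(raw),
        vocab=vocab,
    )


# ---------------------------------------------------------------------------
# encoding

def encode_example(ex: ReactionExample, max_len: int = MAX_TOKENS) -> tuple[list[int], list[int]]:
    """Encode one example: source = product tokens; target = BOS …(SEP)… EOS."""
    source = list(ex.product_seq.tokens)
    target = [BOS]
    for i, seq in enumerate(ex.reactant_seqs):
        if i:
            target.append(SEP)
        target.extend(seq.tokens)
    target.append(EOS)
    if len(target) > max_len + 3:  # BOS + EOS + SEP allowance
        raise ValueError(
            f"encoded target of {ex.product_seq.molecule_id} has {len(target)} "
            f"tokens (cap {max_len + 3})"
        )
    return source, target


def decode_target(tokens: list[int]) -> list[list[int]]:
    """Split a decoded target token stream into per-reactant unique-token sets.

    Special tokens are stripped; a SEP splits the stream into two reactant
    blocks; duplicate tokens within a block are collapsed (the AE
    representation is a set of unique environments).
    """
    blocks: list[list[int]] = [[]]
    for t in tokens:
        if t == BOS:
            continue
        if t == EOS:
            break
        if t == SEP:
            blocks.append([])
            continue
        if t not in blocks[-1]:
            blocks[-1].append(t)
    return [b for b in blocks if b] or [[]]


# ---------------------------------------------------------------------------
# splitting and augmentation

def split(
    ds: CuratedDataset,
    ratio: float = 0.9,
    valid_frac: float = 0.1,
    seed: int = 0,
) -> CuratedDataset:
    """Random 9:1 train/test split; validation drawn from the training part.

    Deterministic for a fixed seed; split labels are disjoint and
    exhaustive.
    """
    n = len(ds.examples)
    if n < 10:
        raise ValueError(f"need at least 10 examples to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train_all = round(n * ratio)
    n_valid = round(n_train_all * valid_frac)
    labels = [""] * n
    for rank, idx in enumerate(order):
        if rank < n_train_all - n_valid:
            labels[idx] = "train"
        elif rank < n_train_all:
            labels[idx] = "valid"
        else:
            labels[idx] = "test"
    return replace(ds, split_labels=labels, seed=seed)


def _permuted_example(ex: ReactionExample, rng: np.random.Generator) -> ReactionExample:
    def perm(seq: AESequence) -> AESequence:
        toks = list(seq.tokens)
        rng.shuffle(toks)
        return AESequence(seq.molecule_id, toks, seq.radius_scheme)

    return ReactionExample(
        product_seq=perm(ex.product_seq),
        reactant_seqs=[perm(s) for s in ex.reactant_seqs],
        klass=ex.klass,
        product_smiles=ex.product_smiles,
        reactant_smiles=ex.reactant_smiles,
    )


def augment(
    ds: CuratedDataset,
    k: int = 10,
    seed: int = 0,
    permute_target: bool = True,
) -> CuratedDataset:
    """Replicate each training example ``k`` times with permuted token order.

    The AE representation's only symmetry is permutation, so augmentation
    permutes the source sequence and (by default) each reactant block of
    the target; the SEP structure is preserved.  Replicate 1 keeps the
    canonical ordering.  Validation and test examples are untouched.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return ds
    rng = np.random.default_rng(seed)
    examples: list[ReactionExample] = []
    labels: list[str] = []
    for ex, lab in zip(ds.examples, ds.split_labels):
        examples.append(ex)
        labels.append(lab)
        if lab != "train":
            continue
        for _ in range(k - 1):
            aug = _permuted_example(ex, rng)
            if not permute_target:
                aug = replace(aug, reactant_seqs=ex.reactant_seqs)
            examples.append(aug)
            labels.append("train")
    return replace(ds, examples=examples, split_labels=labels)


# ---------------------------------------------------------------------------
# serialization

def write_dataset_tsv(ds: CuratedDataset, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["klass", "product_tokens", "target_tokens", "split"])
        for ex, lab in zip(ds.examples, ds.split_labels):
            src, tgt = encode_example(ex)
            w.writerow(
                [
                    ex.klass.value,
                    " ".join(map(str, src)),
                    " ".join(map(str, tgt)),
                    lab,
                ]
            )


def write_rejection_ledger(ds: CuratedDataset, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["rule", "count"])
        for rule, count in sorted(ds.rejections.items()):
            w.writerow([rule, count])
        w.writerow(["kept", len(ds.examples)])
        w.writerow(["raw_total", ds.n_raw])
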