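"""Mapping predicted AE sets back to real molecules.

The AE representation drops connectivity, so a predicted reactant is a
*set* of environment tokens, not a structure.  A :class:`CompoundIndex`
over a compound corpus restores structures: an exact map from frozen AE
sets to compound ids answers zero-mutation queries and degeneracy counts
(how many distinct molecules share one AE set), and an inverted index
from token to compounds supports mutation-tolerant lookup — retrieving
every compound whose AE set differs from the query by at most one or two
environments, mirroring the single/double-mutation (SM/DM) grades used
in evaluation.

Completeness of the pruned candidate generation follows from
|Q Δ C| = |Q| + |C| − 2·shared ≤ m  ⇒  shared ≥ (|Q| + |C| − m) / 2,
so any qualifying compound with at least one shared token is found
through the inverted index; compounds sharing no token can qualify only
when |Q| + |C| ≤ m, which a small size-bucketed side table covers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .chem import (
    MoleculeRecord,
    RadiusScheme,
    Vocabulary,
    ae_sequence,
    hashed_bit_indices,
)

__all__ = ["CompoundIndex", "RetrievalResult", "build_index", "retrieve", "degeneracy"]


@dataclass
class RetrievalResult:
    """Hits for one AE-set query, sorted by (mutations, -Tanimoto, id)."""

    query: frozenset[int]
    hits: list[tuple[str, int, float]]  # (compound id, mutation_count, tanimoto)
    max_mutations: int

    @property
    def compound_ids(self) -> list[str]:
        return [h[0] for h in self.hits]


@dataclass
class CompoundIndex:
    """Exact and inverted indexes over the AE sets of a compound corpus."""

    exact_map: dict[frozenset[int], list[str]] = field(default_factory=dict)
    inverted: dict[int, list[str]] = field(default_factory=dict)
    token_sets: dict[str, frozenset[int]] = field(default_factory=dict)
    vocab_fingerprint: str = ""
    key_scheme: str = "ae"  # "ae" (vocabulary ids) or "ecfp_bits"

    @property
    def n_compounds(self) -> int:
        return len(self.token_sets)

    # ------------------------------------------------------------ persistence
    def save(self, path) -> None:
        payload = {
            "vocab_fingerprint": self.vocab_fingerprint,
            "key_scheme": self.key_scheme,
            "compounds": {cid: sorted(s) for cid, s in self.token_sets.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "CompoundIndex":
        with open(path) as fh:
            payload = json.load(fh)
        index = cls(
            vocab_fingerprint=payload["vocab_fingerprint"],
            key_scheme=payload["key_scheme"],
        )
        for cid, tokens in payload["compounds"].items():
            index._insert(cid, frozenset(tokens))
        return index

    def _insert(self, cid: str, tokens: frozenset[int]) -> None:
        self.token_sets[cid] = tokens
        self.exact_map.setdefault(tokens, []).append(cid)
        for t in tokens:
            self.inverted.setdefault(t, []).append(cid)


def build_index(
    corpus: list[MoleculeRecord],
    vocab: Vocabulary | None = None,
    scheme: RadiusScheme = RadiusScheme.AE0_UNION_AE2,
    key_scheme: str = "ae",
    n_bits: int = 1024,
) -> CompoundIndex:
    """Index a compound corpus by AE set (or hashed ECFP bit set).

    Duplicate molecules (identical canonical SMILES) are stored once;
    distinct molecules with identical key sets share an ``exact_map``
    entry — that is the degeneracy the AE representation is meant to
    keep low relative to hashed fingerprints.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if key_scheme not in ("ae", "ecfp_bits"):
        raise ValueError(f"unknown key scheme {key_scheme!r}")
    if key_scheme == "ae" and vocab is None:
        raise ValueError("AE-keyed index needs a vocabulary")
    index = CompoundIndex(
        vocab_fingerprint=vocab.fingerprint() if vocab else "",
        key_scheme=key_scheme,
    )
    seen_smiles: set[str] = set()
    for rec in sorted(corpus, key=lambda r: (r.id, r.smiles)):
        if rec.smiles in seen_smiles:
            continue
        seen_smiles.add(rec.smiles)
        if key_scheme == "ae":
            tokens = frozenset(ae_sequence(rec, scheme, vocab).tokens)
        else:
            tokens = frozenset(hashed_bit_indices(rec, radius=1, n_bits=n_bits))
        index._insert(rec.id or rec.smiles, tokens)
    # deterministic postings regardless of corpus order
    for postings in index.inverted.values():
        postings.sort()
    for ids in index.exact_map.values():
        ids.sort()
    return index


def retrieve(
    index: CompoundIndex, query: set[int] | frozenset[int], max_mutations: int = 2
) -> RetrievalResult:
    """All indexed compounds within ``max_mutations`` set differences.

    Candidates are gathered from inverted-index postings and then
    filtered by the exact symmetric-difference count, so the hit list
    provably contains every compound C with |Q Δ C| ≤ ``max_mutations``.
    """
    if max_mutations not in (0, 1, 2):
        raise ValueError("max_mutations must be 0, 1 or 2")
    query = frozenset(query)
    if not query:
        raise ValueError("empty query set")
    candidates: set[str] = set()
    for t in query:
        candidates.update(index.inverted.get(t, ()))
    if len(query) + 1 <= max_mutations:
        # tiny-set corner: compounds sharing no token can still qualify
        # when |Q| + |C| <= max_mutations
        for cid, tokens in index.token_sets.items():
            if len(tokens) <= max_mutations - len(query):
                candidates.add(cid)
    hits = []
    for cid in candidates:
        tokens = index.token_sets[cid]
        mutations = len(query ^ tokens)
        if mutations <= max_mutations:
            union = len(query | tokens)
            tanimoto = len(query & tokens) / union if union else 1.0
            hits.append((cid, mutations, tanimoto))
    hits.sort(key=lambda h: (h[1], -h[2], h[0]))
    return RetrievalResult(query, hits, max_mutations)


def degeneracy(index: CompoundIndex, query: set[int] | frozenset[int]) -> int:
    """Number of distinct indexed molecules whose key set equals ``query``."""
    return len(index.exact_map.get(frozenset(query), ()))
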