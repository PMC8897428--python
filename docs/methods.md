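# Methods

## The representation: atom environments

A molecule is represented as the **set of its circular atom environments
(AEs)**.  The environment of an atom at radius *r* is the subgraph
containing every atom within topological distance *r* of it (bond-count
shortest path) and all bonds among those atoms.  Following the ECFP
diameter convention, the set of radius-0 environments is called **AE0**
and the set of radius-1 environments **AE2**; the default molecular
token sequence is their union.  The representation is a *set*: duplicate
environments collapse, and connectivity between environments is
deliberately dropped.  Radius-2 environments explode the vocabulary and
are supported only in hashed-bit form (see *Collision profiling*).

Each environment is rendered as a canonical SMARTS pattern.  Per atom
the pattern encodes element and aromaticity (lowercase symbol), total
hydrogen count (`H`), heavy-atom degree (`D`), ring membership
(`R` / `R0`) and formal charge when non-zero, e.g. `[cH1;D2;R]` for a
benzene carbon.  Radius-1 patterns include all environment bonds with
explicit bond symbols; bonds leaving the environment are rendered as
wildcard stubs `~[*]`.  The writer serializes the environment by a
depth-first traversal rooted at the central atom with sibling branches
ordered by their fully rendered subtree strings, so the string is
independent of input atom numbering; non-tree bonds inside the
environment (e.g. three-membered rings) become ring-closure digits.
Two invariants hold by construction and are enforced in tests: the
pattern always substructure-matches its source molecule, and two atoms
receive the same string exactly when an independent
Weisfeiler–Lehman-certified neighborhood enumeration considers their
environments isomorphic.  SMARTS strings are toolkit- and
dialect-sensitive; the package pins its own renderer rather than the
toolkit's generic fragment writer precisely so that token identities
are stable.  Token counts on other corpora may shift by a few under a
different dialect (e.g. whether zero charge is printed).

A `Vocabulary` maps each distinct SMARTS to an integer id.  Ids 0–4 are
reserved (`<pad>`, `<bos>`, `<eos>`, `<sep>`, `<unk>`); chemical ids are
assigned in sorted (radius, SMARTS) order, so vocabularies are
reproducible from corpus content alone.  Sequence order for the
position-aware model is (radius, first occurrence of the central atom
in canonical atom order) — deterministic and chemistry-correlated;
augmentation supplies permuted variants.

## Reaction corpora

Reaction SMILES in the `reactants>reagents>products` dialect are parsed
with every member canonicalized (stereochemistry stripped throughout —
the representation is achiral).  The middle field is treated as
reagents and excluded from reactants verbatim; no atom-mapping-based
role reassignment is attempted.  Curation keeps single-product
reactions with one or two reactants (unimolecular / bimolecular),
deduplicates at the reaction level (canonical product + sorted
reactants), and drops any example whose product or reactant exceeds 100
AE tokens; every rejection is tallied by rule so that kept + rejected
always reconstructs the raw count.  Bimolecular reactant order is the
reactant with more AE tokens first (ties by SMILES) — a deterministic
stand-in for "principal fragment first".

Splits are random 9:1 train/test with a validation tenth drawn from the
training part (so 1,000 examples yield 810/90/100).  Augmentation
replicates each training example *k* times under independent random
permutations of the source tokens and of each reactant block (the only
symmetry the set representation has); replicate 1 keeps canonical
order, and test/validation are never augmented.  Whether targets are
permuted too is a flag (`permute_target`, default on).

## Synthetic reactions

Real retrosynthesis corpora are far too large for a test environment,
so the generator builds desk-scale corpora with exact ground truth.
Library molecules are assembled from a seeded fragment grammar — random
alkyl trees (≤ 5–6 carbons, optional phenyl) and substituted phenyls —
around exactly one cleavable motif per molecule.  Four retro templates
(reaction SMARTS) cleave that motif:

| template | klass | rewrite |
|---|---|---|
| ester_hydrolysis | bimolecular | R-CO-O-R′ → acid + alcohol |
| amide_hydrolysis | bimolecular | R-CO-NH-R′ → acid + amine |
| ether_cleavage | bimolecular | Ar-O-R → phenol + R-Br |
| lactone_ring_opening | unimolecular | cyclic ester → hydroxy acid |

Multi-site matches are resolved by taking the lexicographically first
canonical outcome, so every product maps to a single truth.  Generated
sets are balanced across templates, survive curation with zero
rejections by construction, and each template induces a consistent
local AE rewrite — the desk-scale analogue of environments near the
reaction centre carrying the chemical change, and the reason a small
model can learn the mapping.

What the generator does **not** emulate: reagents and conditions,
yields, competing reaction channels, stereochemistry, atom-mapping
noise, the long-tail vocabulary (~250 tokens here vs ~16k AE2 tokens in
patent data) and length distribution of real corpora.  Passing tests
therefore demonstrate that the machinery is correct and that the
learning signal exists when the rewrite is consistent; they say nothing
about accuracy on patent-scale chemistry.

## The translator

A pre-norm transformer encoder–decoder over AE token ids, implemented
directly on NumPy with a small reverse-mode autograd (every primitive
is gradient-checked against central finite differences in the test
suite).  Layer normalization precedes each self-attention,
cross-attention and feed-forward sublayer, and the encoder and decoder
outputs are normalized once more.  Source and target share one token
embedding; the output projection is tied to it (transposed) by default
— measured on copy tasks, untied projections memorize without
generalizing at these data sizes.  The sinusoidal positional encoding
is optional (`positional_encoding`), since the representation is
permutation invariant but position-aware models are the stronger
default.

Training: teacher-forced negative log-likelihood under Adam (constant
learning rate by default; inverse-square-root decay when
`warmup_steps > 0`), dropout 0.1, batch size 300 by default, gradient
clipping at global norm 1.  The checkpoint with the best validation
loss is restored after the final epoch.  A single integer seed governs
initialization, batch order and dropout, making runs bit-reproducible
on one platform; across BLAS implementations small float drift is
possible.  Decoding is greedy (top-1); `<sep>` splits the output into
two reactant blocks, duplicate tokens within a block collapse to a set,
and a decode that never emits `<eos>` within the length cap is flagged
incomplete rather than silently truncated.

Desk-scale reference configuration (used by the acceptance script and
tests): 2 layers, 4 heads, model dim 64, feed-forward 256, dropout 0.1,
batch 64, lr 3·10⁻³, 50 epochs on 2,000 synthetic reactions — about
six minutes on one CPU, reaching ≥ 80 % top-1 exact match on the
held-out tenth.  The label-shuffled chance-floor control uses 15
epochs: the floor cannot rise with longer training on shuffled labels,
and the shorter run keeps the whole suite inside its time budget.

Cross-attention of a teacher-forced pass is recorded per layer and
head; the head-averaged final-layer matrix, its column sums (which
product environments are attended most) and the per-row argmax
alignment are exposed for interpretability.

## Evaluation

Predictions are compared with truth by the Tversky index (above);
Tanimoto (α = β = 1) and Dice (α = β = 0.5) are exact reductions, and
the similarity of two empty sets is an error, never a silent 0 or 1.
Hard thresholds read "discrepancy of one or two fragments" as symmetric
difference cardinality, so a substitution counts as a double mutation.
Categories (exact / SM / DM / Tc ≥ 0.85 / Tc ≥ 0.80 / below) are
mutually exclusive and assigned in that priority order; summaries are
cumulative left to right.  For bimolecular examples, predicted
reactants are paired with true ones by the maximal-Tanimoto one-to-one
assignment (which reduces to the fixed-first-reactant convention when
one pair matches exactly); mutation counts sum over pairs and soft
categories use the minimum pair Tanimoto by default (`mean` behind a
flag).  A reactant-count mismatch grades `below` with a diagnostic.

Significance of a Tanimoto value is the upper-tail fraction of an
empirical background of randomly paired corpus molecules, with
(k+1)/(n+1) add-one smoothing so finite samples never report zero.

## Retrieval

A compound index stores, per indexed molecule, its frozen AE-id set:
an exact map (set → compound ids) answers zero-mutation queries and
degeneracy counts; an inverted index (token → compounds) generates
candidates for mutation-tolerant queries.  Since
|Q Δ C| = |Q| + |C| − 2·shared, any compound within budget *m* that
shares at least one token is reachable through postings; the only
compounds with zero shared tokens that can qualify need
|Q| + |C| ≤ m, which a size-bucket fallback covers.  Candidates are
then filtered by the exact symmetric difference, so retrieval is
provably identical to a linear scan (asserted against one in tests).
Hits are ordered (mutations asc, Tanimoto desc, id) for determinism.
An alternate `ecfp_bits` key scheme indexes hashed 1,024-bit
fingerprints instead, reproducing the direction that hashed keys are
more degenerate than AE keys on any corpus.

## Collision profiling

The hashed-bit variant maps each environment SMARTS through a stable
32-bit hash (BLAKE2) modulo `n_bits` (default 1,024), accumulating all
radii up to the requested one, ECFP-style.  The collision profile
counts distinct SMARTS per active bit across a corpus; its corpus mean
is non-decreasing in radius (asserted on 1,000-molecule corpora) —
the quantitative reason radius-2 environments are unusable as
translation tokens while radii 0–1 are nearly collision-free at this
width.

## Numerical and engineering choices

- float64 throughout the model; attention masks are additive −10⁹.
- Softmax and log-sum-exp are max-shifted for stability; attention row
  sums are asserted to 1 ± 10⁻⁵.
- Checkpoints round-trip through a single `.npz` (parameters + JSON
  metadata incl. the vocabulary fingerprint); loading verifies shapes
  and optionally the fingerprint.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; derived seeds stay below 2³¹.
- Degenerate inputs error loudly: empty molecules, empty similarity
  arguments, singleton background corpora, radius > 1 tokens,
  mutation budgets outside {0, 1, 2}.

## Known limitations

- The AE set does not determine a structure; retrieval requires the
  true molecule (or a near neighbor) to be present in the indexed
  corpus.
- The synthetic task is far easier than patent chemistry; reported
  desk-scale accuracies do not transfer.
- Chain-length ambiguity is intrinsic: homologous alkanes share AE
  sets (the index records such degeneracy explicitly).
- The NumPy trainer is single-threaded and desk-scale by design;
  patent-scale training would need a GPU framework.
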