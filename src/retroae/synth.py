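"""Desk-scale synthetic reaction corpora with known ground truth.

Real retrosynthesis corpora (USPTO-scale) are far too large to train or
even download in a test environment.  This module builds small reaction
sets whose ground-truth reactants are known exactly, by (1) assembling
combinatorial libraries of small molecules that each carry exactly one
cleavable functional group, and (2) applying fixed retro transformation
templates (reaction SMARTS) to cleave that group.

Because each template induces a consistent, local rewrite of the
product's atom-environment set, the product→reactant AE mapping is
learnable by a sequence model — the desk-scale analogue of real
reactions, where the environments near the reaction centre carry the
chemical change.

Default templates (uni- and bimolecular, additive and ring-altering):

- ``ester_hydrolysis``     R-CO-O-R'  →  acid + alcohol      (bimolecular)
- ``amide_hydrolysis``     R-CO-NH-R' →  acid + amine        (bimolecular)
- ``ether_cleavage``       Ar-O-R     →  phenol + R-Br       (bimolecular)
- ``lactone_ring_opening`` cyclic ester → hydroxy acid       (unimolecular)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import MoleculeRecord, canonicalize
from .corpus import RawReaction, ReactionClass

__all__ = [
    "TransformationTemplate",
    "SyntheticReactionSet",
    "DEFAULT_TEMPLATES",
    "generate_library",
    "apply_template",
    "generate_dataset",
    "write_reaction_file",
]


@dataclass(frozen=True)
class TransformationTemplate:
    """A retro rewrite: product-side pattern plus a reaction-SMARTS rule."""

    name: str
    pattern: str          # product-side substructure SMARTS
    rewrite: str          # full reaction SMARTS, product >> reactant(s)
    klass: ReactionClass

    def matches(self, mol: Chem.Mol) -> bool:
        return mol.HasSubstructMatch(Chem.MolFromSmarts(self.pattern))


DEFAULT_TEMPLATES: tuple[TransformationTemplate, ...] = (
    TransformationTemplate(
        "ester_hydrolysis",
        "[C:1](=[O:2])-[O;!R:3]-[C;X4:4]",
        "[C:1](=[O:2])-[O;!R:3]-[C;X4:4]>>[C:1](=[O:2])-[OH1:3].[OH1]-[C:4]",
        ReactionClass.BIMOLECULAR,
    ),
    TransformationTemplate(
        "amide_hydrolysis",
        "[C;!R:1](=[O:2])-[NX3;H1;!R:3]",
        "[C;!R:1](=[O:2])-[NX3;H1;!R:3]>>[C:1](=[O:2])-[OH1].[NH2:3]",
        ReactionClass.BIMOLECULAR,
    ),
    TransformationTemplate(
        "ether_cleavage",
        "[c:1]-[O;X2;!R;!$(OC=O):2]-[C;X4;!R:3]",
        "[c:1]-[O;X2;!R;!$(OC=O):2]-[C;X4;!R:3]>>[c:1]-[OH1:2].Br[C:3]",
        ReactionClass.BIMOLECULAR,
    ),
    TransformationTemplate(
        "lactone_ring_opening",
        "[C;R:1](=[O:2])-[O;R:3]-[C;R;X4:4]",
        "[C;R:1](=[O:2])-[O;R:3]-[C;R;X4:4]>>([C:1](=[O:2])-[OH1].[OH1]-[C:4])",
        ReactionClass.UNIMOLECULAR,
    ),
)


@dataclass
class SyntheticReactionSet:
    """Reactions plus the template that generated each (the ground truth)."""

    reactions: list[RawReaction]
    truth: list[str]  # template name per reaction
    seed: int
    library_params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# building-block grammar

def _serialize_alkyl(children: list[list], node: int = 0) -> str:
    kids = children[node]
    parts = []
    for k in kids:
        parts.append(_serialize_alkyl(children, k) if isinstance(k, int) else k)
    out = "C"
    for i, p in enumerate(parts):
        out += p if i == len(parts) - 1 else f"({p})"
    return out


def _random_alkyl(rng: np.random.Generator, max_c: int = 5, phenyl_p: float = 0.25) -> str:
    """A random alkyl substituent SMILES; the first atom is the attachment."""
    n = int(rng.integers(1, max_c + 1))
    children: list[list] = [[]]
    for _ in range(n - 1):
        # attach to a random carbon with < 3 branches (keeps valence sane)
        open_nodes = [i for i, c in enumerate(children) if len(c) < 3]
        parent = int(rng.choice(open_nodes))
        children.append([])
        children[parent].append(len(children) - 1)
    if rng.random() < phenyl_p:
        leaves = [i for i, c in enumerate(children) if not c]
        children[int(rng.choice(leaves))].append("c1ccccc1")
    return _serialize_alkyl(children)


def _random_aryl(rng: np.random.Generator, max_c: int = 4) -> str:
    """A random (substituted) phenyl; the first ring atom is the attachment."""
    choice = rng.random()
    if choice < 0.15:
        return "c1ccccc1"
    sub = _random_alkyl(rng, max_c, phenyl_p=0.0)
    if choice < 0.45:
        return f"c1ccc({sub})cc1"
    if choice < 0.7:
        return f"c1cccc({sub})c1"
    sub2 = _random_alkyl(rng, 2, phenyl_p=0.0)
    return f"c1cc({sub})cc({sub2})c1"


def _random_acyl_side(rng: np.random.Generator) -> str:
    return _random_aryl(rng) if rng.random() < 0.3 else _random_alkyl(rng)


def _gen_ester(rng: np.random.Generator) -> str:
    return f"{_random_acyl_side(rng)}C(=O)O{_random_alkyl(rng)}"


def _gen_amide(rng: np.random.Generator) -> str:
    n_side = _random_aryl(rng) if rng.random() < 0.3 else _random_alkyl(rng)
    return f"{_random_acyl_side(rng)}C(=O)N{n_side}"


def _gen_ether(rng: np.random.Generator) -> str:
    return f"{_random_aryl(rng)}O{_random_alkyl(rng, 6)}"


def _gen_lactone(rng: np.random.Generator) -> str:
    n_ring_ch = int(rng.integers(3, 7))  # 5- to 8-membered lactone
    units = []
    n_subs = int(rng.integers(0, 4))
    sub_positions = set(rng.choice(n_ring_ch, size=min(n_subs, n_ring_ch), replace=False).tolist())
    for i in range(n_ring_ch):
        if i in sub_positions:
            units.append(f"C({_random_alkyl(rng, 4, phenyl_p=0.15)})")
        else:
            units.append("C")
    return "O=C1" + "".join(units) + "O1"


_MOTIF_GENERATORS = {
    "ester_hydrolysis": _gen_ester,
    "amide_hydrolysis": _gen_amide,
    "ether_cleavage": _gen_ether,
    "lactone_ring_opening": _gen_lactone,
}


# ---------------------------------------------------------------------------
# operations

def generate_library(n: int, seed: int = 0, max_c: int = 5) -> list[MoleculeRecord]:
    """``n`` distinct small molecules, each carrying one cleavable group.

    Motif classes (ester, amide, aryl ether, lactone) are cycled so the
    library covers all default templates; molecules are stereochemistry
    free and deduplicated by canonical SMILES.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    gens = list(_MOTIF_GENERATORS.values())
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    attempts = 0
    while len(records) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise RuntimeError(f"library generation stalled at {len(records)}/{n}")
        gen = gens[attempts % len(gens)]
        smi = canonicalize(gen(rng))
        if smi in seen:
            continue
        seen.add(smi)
        records.append(MoleculeRecord(smi, f"lib{len(records)}"))
    return records


def apply_template(
    mol: MoleculeRecord | str, template: TransformationTemplate
) -> RawReaction | None:
    """Apply one retro template to a product molecule.

    Returns a :class:`RawReaction` with the molecule as single product and
    the template-derived reactants, or ``None`` when the pattern does not
    match.  When several sites match, outcomes are canonicalized and the
    lexicographically first reactant tuple is kept, so the rewrite is a
    deterministic function of the product.  Unsanitizable rewrite products
    are discarded.
    """
    smiles = mol.smiles if isinstance(mol, MoleculeRecord) else canonicalize(mol)
    m = Chem.MolFromSmiles(smiles)
    rxn = AllChem.ReactionFromSmarts(template.rewrite)
    outcomes: set[tuple[str, ...]] = set()
    for product_set in rxn.RunReactants((m,)):
        try:
            reactants = tuple(
                sorted(canonicalize(Chem.MolToSmiles(p)) for p in product_set)
            )
        except ValueError:
            continue  # unsanitizable rewrite outcome
        expected = 1 if template.klass is ReactionClass.UNIMOLECULAR else 2
        if len(reactants) != expected:
            continue
        outcomes.add(reactants)
    if not outcomes:
        return None
    reactants = min(outcomes)
    return RawReaction(reactants=reactants, reagents=(), products=(smiles,))


def generate_dataset(
    n_reactions: int,
    templates: tuple[TransformationTemplate, ...] = DEFAULT_TEMPLATES,
    seed: int = 0,
    max_c: int = 5,
) -> SyntheticReactionSet:
    """A reaction set of ``n_reactions`` balanced across ``templates``.

    Products are drawn from each template's motif generator until the
    per-template quota of distinct products is met; every reaction records
    its generating template as ground truth.
    """
    if not templates:
        raise ValueError("need at least one template")
    rng = np.random.default_rng(seed)
    quotas = [n_reactions // len(templates)] * len(templates)
    for i in range(n_reactions - sum(quotas)):
        quotas[i] += 1
    reactions: list[RawReaction] = []
    truth: list[str] = []
    seen_products: set[str] = set()
    for template, quota in zip(templates, quotas):
        gen = _MOTIF_GENERATORS.get(template.name)
        if gen is None:
            raise ValueError(f"no molecule generator for template {template.name!r}")
        got = 0
        attempts = 0
        while got < quota:
            attempts += 1
            if attempts > 500 * quota + 1000:
                raise RuntimeError(
                    f"could not generate {quota} reactions for {template.name}; "
                    f"achieved {got}"
                )
            smi = canonicalize(gen(rng))
            if smi in seen_products:
                continue
            rxn = apply_template(smi, template)
            if rxn is None:
                continue
            seen_products.add(smi)
            reactions.append(rxn)
            truth.append(template.name)
            got += 1
    return SyntheticReactionSet(
        reactions,
        truth,
        seed,
        {"n_reactions": n_reactions, "max_c": max_c, "templates": [t.name for t in templates]},
    )


def write_reaction_file(rxns: SyntheticReactionSet | list[RawReaction], path) -> None:
    """Write reactions as ``reactants>>products`` lines (empty reagent field)."""
    reactions = rxns.reactions if isinstance(rxns, SyntheticReactionSet) else rxns
    with open(path, "w") as fh:
        for r in reactions:
            fh.write(".".join(r.reactants) + ">" + ".".join(r.reagents) + ">" + ".".join(r.products) + "\n")
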