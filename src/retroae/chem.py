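"""Atom-environment fragmentation of molecules.

A molecule is represented as the set of its circular atom environments
(AEs): for each atom, the subgraph containing every atom within a chosen
topological radius of it plus all bonds among those atoms.  Following the
ECFP diameter convention, the set of radius-0 environments is called AE0
and the set of radius-1 environments AE2.  Each distinct environment is
rendered as a canonical SMARTS pattern and, within a :class:`Vocabulary`,
mapped to a unique integer token id — the unit that the sequence model
translates.

The SMARTS dialect encodes, per atom: element and aromaticity, total
hydrogen count (``H``), heavy-atom degree (``D``), ring membership
(``R`` / ``R0``) and formal charge when non-zero.  Bonds from an
environment's boundary atoms to atoms outside the radius are rendered as
wildcard stubs ``~[*]``.  Every pattern matches the molecule it was
extracted from when used as a substructure query.
"""

from __future__ import annotations

import csv
import enum
import hashlib
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "RadiusScheme",
    "MoleculeRecord",
    "AtomEnvironment",
    "AESequence",
    "Vocabulary",
    "BitCollisionProfile",
    "canonicalize",
    "mol_from_smiles",
    "extract_aes",
    "ae_sequence",
    "hashed_bit_indices",
    "build_vocabulary",
    "collision_profile",
    "coverage_stats",
    "read_smiles_file",
]

#: Default cap on the number of AE tokens per molecule.
MAX_TOKENS = 100

_BOND_SYMBOL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


class RadiusScheme(str, enum.Enum):
    """Which environment radii make up a molecule's token sequence."""

    AE0 = "AE0"                    # radius-0 environments only
    AE2 = "AE2"                    # radius-1 environments only
    AE0_UNION_AE2 = "AE0_union_AE2"  # union of both (default model input)
    ECFP_BITS = "ECFP_bits"        # hashed bit indices instead of SMARTS ids

    @property
    def radii(self) -> tuple[int, ...]:
        if self is RadiusScheme.AE0:
            return (0,)
        if self is RadiusScheme.AE2:
            return (1,)
        return (0, 1)


@dataclass(frozen=True)
class MoleculeRecord:
    """A canonical SMILES plus an opaque identifier."""

    smiles: str
    id: str = ""

    @classmethod
    def from_smiles(cls, smiles: str, id: str = "") -> "MoleculeRecord":
        return cls(canonicalize(smiles), id)


@dataclass(frozen=True)
class AtomEnvironment:
    """One circular environment: canonical SMARTS, radius, optional token id."""

    smarts: str
    radius: int
    token_id: int | None = None


@dataclass
class AESequence:
    """The ordered unique-AE token sequence of one molecule."""

    molecule_id: str
    tokens: list[int]
    radius_scheme: RadiusScheme

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("AESequence tokens must be unique (set semantics)")

    def __len__(self) -> int:
        return len(self.tokens)


# ---------------------------------------------------------------------------
# canonicalization

def canonicalize(smiles: str) -> str:
    """Return the toolkit-canonical SMILES, or raise ``ValueError``.

    Stereochemistry is stripped: the AE representation is achiral and the
    reaction corpora this package targets carry no stereo annotations.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable or unsanitizable SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse, sanitize and strip stereochemistry; raise on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable or unsanitizable SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    return mol


# ---------------------------------------------------------------------------
# SMARTS rendering

def _atom_query(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    if atom.GetIsAromatic():
        sym = sym.lower()
    spec = f"{sym}H{atom.GetTotalNumHs()};D{atom.GetDegree()};"
    spec += "R" if atom.IsInRing() else "R0"
    charge = atom.GetFormalCharge()
    if charge:
        spec += ";" + (f"+{charge}" if charge > 0 else str(charge))
    return f"[{spec}]"


def _env_atoms(mol: Chem.Mol, center: int, radius: int) -> set[int]:
    dist = {center: 0}
    frontier = [center]
    for r in range(radius):
        nxt = []
        for a in frontier:
            for nb in mol.GetAtomWithIdx(a).GetNeighbors():
                if nb.GetIdx() not in dist:
                    dist[nb.GetIdx()] = r + 1
                    nxt.append(nb.GetIdx())
        frontier = nxt
    return set(dist)


def render_environment(mol: Chem.Mol, center: int, radius: int) -> str:
    """Canonical SMARTS of the environment of ``center`` at ``radius``.

    The string is written by a depth-first traversal rooted at the central
    atom; sibling branches are ordered by their fully rendered subtree
    strings, which makes the output independent of input atom numbering.
    Bonds among environment atoms that are not spanning-tree edges become
    ring closures; bonds leaving the environment become ``~[*]`` stubs.
    """
    if radius == 0:
        return _atom_query(mol.GetAtomWithIdx(center))
    env = _env_atoms(mol, center, radius)
    closures: dict[frozenset[int], int] = {}
    counter = [0]

    def subtree(a: int, parent: int | None, visited: set[int]) -> str:
        visited.add(a)
        atom = mol.GetAtomWithIdx(a)
        n_external = 0
        kids: list[tuple[str, str]] = []
        ring_bonds: list[tuple[str, frozenset[int]]] = []
        for nb in atom.GetNeighbors():
            j = nb.GetIdx()
            if j == parent:
                continue
            if j not in env:
                n_external += 1
                continue
            bond = _BOND_SYMBOL[mol.GetBondBetweenAtoms(a, j).GetBondType()]
            if j in visited:
                ring_bonds.append((bond, frozenset((a, j))))
            else:
                kids.append((bond, subtree(j, a, visited)))
        out = _atom_query(atom)
        for bond, key in sorted(ring_bonds, key=lambda t: t[0]):
            if key not in closures:
                counter[0] += 1
                closures[key] = counter[0]
            n = closures[key]
            out += bond + (f"%{n:02d}" if n > 9 else str(n))
        segments = [bond + sub for bond, sub in sorted(kids)]
        segments += ["~[*]"] * n_external
        for i, seg in enumerate(segments):
            out += seg if i == len(segments) - 1 else f"({seg})"
        return out

    return subtree(center, None, set())


# ---------------------------------------------------------------------------
# extraction

def extract_aes(mol: MoleculeRecord | Chem.Mol | str, radius: int) -> set[AtomEnvironment]:
    """All symmetry-distinct atom environments of a molecule at one radius.

    ``radius`` must be 0 or 1: radius-2 environments (AE4) produce a
    vocabulary far too large for translation and are supported only in
    hashed-bit form (:func:`hashed_bit_indices`, :func:`collision_profile`).
    """
    if radius not in (0, 1):
        raise ValueError(
            f"radius must be 0 or 1 (got {radius}); radius-2 environments are "
            "only available as hashed bits"
        )
    m = _as_mol(mol)
    smarts = {render_environment(m, a.GetIdx(), radius) for a in m.GetAtoms()}
    return {AtomEnvironment(s, radius) for s in smarts}


def _as_mol(mol: MoleculeRecord | Chem.Mol | str) -> Chem.Mol:
    if isinstance(mol, Chem.Mol):
        return mol
    if isinstance(mol, MoleculeRecord):
        return mol_from_smiles(mol.smiles)
    return mol_from_smiles(mol)


def _env_smarts_with_centers(
    m: Chem.Mol, radii: Iterable[int]
) -> dict[str, tuple[int, int]]:
    """Map SMARTS -> (radius, first canonical center index) over given radii.

    If the same string arises at both radii (single-atom molecules), the
    smaller radius wins, matching set-union semantics.
    """
    out: dict[str, tuple[int, int]] = {}
    for radius in sorted(radii):
        for atom in m.GetAtoms():
            s = render_environment(m, atom.GetIdx(), radius)
            if s not in out:
                out[s] = (radius, atom.GetIdx())
    return out


def ae_sequence(
    mol: MoleculeRecord | str,
    scheme: RadiusScheme,
    vocab: "Vocabulary",
    max_tokens: int = MAX_TOKENS,
) -> AESequence:
    """Tokenize a molecule under ``scheme`` into its unique-AE sequence.

    Tokens are ordered by (radius, first occurrence of the central atom in
    canonical atom order) — a deterministic, chemistry-correlated ordering
    for the position-aware model.
    """
    if scheme is RadiusScheme.ECFP_BITS:
        raise ValueError("ECFP_bits sequences use hashed_bit_indices(), not a vocabulary")
    rec = mol if isinstance(mol, MoleculeRecord) else MoleculeRecord.from_smiles(mol)
    m = mol_from_smiles(rec.smiles)
    if m.GetNumAtoms() == 0:
        raise ValueError(f"empty molecule: {rec.smiles!r}")
    entries = _env_smarts_with_centers(m, scheme.radii)
    ordered = sorted(entries.items(), key=lambda kv: kv[1])
    # distinct out-of-vocabulary AEs all collapse onto the single UNK id
    tokens = list(dict.fromkeys(vocab.id_for(s) for s, _ in ordered))
    if len(tokens) > max_tokens:
        raise ValueError(
            f"molecule {rec.id or rec.smiles!r} has {len(tokens)} AE tokens "
            f"(cap {max_tokens})"
        )
    return AESequence(rec.id or rec.smiles, tokens, scheme)


# ---------------------------------------------------------------------------
# hashed-bit variant

def _stable_hash(s: str) -> int:
    """Stable 32-bit hash of a SMARTS string (platform independent)."""
    return int.from_bytes(hashlib.blake2b(s.encode(), digest_size=4).digest(), "big")


def hashed_bit_indices(
    mol: MoleculeRecord | Chem.Mol | str, radius: int, n_bits: int = 1024
) -> list[int]:
    """Active bit indices of the hashed environment fingerprint.

    Environments of every radius up to ``radius`` contribute (the ECFP
    convention: ECFP2 = radii {0, 1} hashed).  ``radius`` may be 2 here —
    hashed bits do not enter the translation vocabulary.
    """
    if radius not in (0, 1, 2):
        raise ValueError(f"radius must be in {{0,1,2}} (got {radius})")
    if n_bits < 2:
        raise ValueError("n_bits must be >= 2")
    m = _as_mol(mol)
    bits = {
        _stable_hash(render_environment(m, a.GetIdx(), r)) % n_bits
        for r in range(radius + 1)
        for a in m.GetAtoms()
    }
    return sorted(bits)


@dataclass
class BitCollisionProfile:
    """How many distinct environment SMARTS hash onto each active bit."""

    radius: int
    n_bits: int
    per_bit_counts: dict[int, int]

    @property
    def mean_smarts_per_bit(self) -> float:
        if not self.per_bit_counts:
            return 0.0
        return sum(self.per_bit_counts.values()) / len(self.per_bit_counts)

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["bit", "count"])
            for bit in sorted(self.per_bit_counts):
                w.writerow([bit, self.per_bit_counts[bit]])


def collision_profile(
    corpus: Sequence[MoleculeRecord | str], radius: int, n_bits: int = 1024
) -> BitCollisionProfile:
    """Corpus-level bit-collision statistics at one radius.

    Each active bit maps to the number of distinct environment SMARTS
    (over all radii up to ``radius``, across the corpus) whose hash lands
    on it.  Higher radii produce more distinct environments and therefore
    more collisions per bit at a fixed fingerprint width — the reason
    radius-2 environments are unsuitable as translation tokens.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if radius not in (0, 1, 2):
        raise ValueError(f"radius must be in {{0,1,2}} (got {radius})")
    smarts_per_bit: dict[int, set[str]] = defaultdict(set)
    for rec in corpus:
        m = _as_mol(rec)
        for r in range(radius + 1):
            for atom in m.GetAtoms():
                s = render_environment(m, atom.GetIdx(), r)
                smarts_per_bit[_stable_hash(s) % n_bits].add(s)
    return BitCollisionProfile(
        radius, n_bits, {b: len(v) for b, v in smarts_per_bit.items()}
    )


# ---------------------------------------------------------------------------
# vocabulary

PAD, BOS, EOS, SEP, UNK = 0, 1, 2, 3, 4
RESERVED = {"<pad>": PAD, "<bos>": BOS, "<eos>": EOS, "<sep>": SEP, "<unk>": UNK}


@dataclass
class Vocabulary:
    """Bijection between AE SMARTS and integer token ids.

    Ids 0–4 are reserved for the special tokens (padding, begin/end of
    sequence, the reactant separator, and unknown); chemical ids start at
    5 and are assigned in sorted (radius, SMARTS) order so that two
    corpora with the same AE content yield identical vocabularies.
    """

    smarts_to_id: dict[str, int] = field(default_factory=dict)
    id_to_smarts: dict[int, str] = field(default_factory=dict)
    radius_of: dict[str, int] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    allow_unk: bool = True

    def __len__(self) -> int:
        return len(RESERVED) + len(self.smarts_to_id)

    @property
    def n_tokens(self) -> int:
        """Total id space size (max id + 1) for model embeddings."""
        return len(RESERVED) + len(self.smarts_to_id)

    def id_for(self, smarts: str) -> int:
        tid = self.smarts_to_id.get(smarts)
        if tid is None:
            if self.allow_unk:
                return UNK
            raise KeyError(f"AE not in vocabulary and UNK disabled: {smarts!r}")
        return tid

    def smarts_for(self, token_id: int) -> str:
        if token_id in self.id_to_smarts:
            return self.id_to_smarts[token_id]
        for name, tid in RESERVED.items():
            if tid == token_id:
                return name
        raise KeyError(f"unknown token id {token_id}")

    # -- serialization ------------------------------------------------------
    def write_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            for smarts, tid in sorted(self.smarts_to_id.items(), key=lambda kv: kv[1]):
                w.writerow([tid, smarts, self.radius_of[smarts], self.counts.get(smarts, 0)])

    @classmethod
    def read_tsv(cls, path) -> "Vocabulary":
        vocab = cls()
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                tid, smarts, radius, count = int(row[0]), row[1], int(row[2]), int(row[3])
                vocab.smarts_to_id[smarts] = tid
                vocab.id_to_smarts[tid] = smarts
                vocab.radius_of[smarts] = radius
                vocab.counts[smarts] = count
        return vocab

    def fingerprint(self) -> str:
        """Stable hash of the id assignment, stored with model checkpoints."""
        h = hashlib.blake2b(digest_size=8)
        for smarts, tid in sorted(self.smarts_to_id.items()):
            h.update(f"{smarts}\t{tid}\n".encode())
        return h.hexdigest()


def build_vocabulary(
    corpus: Sequence[MoleculeRecord | str],
    scheme: RadiusScheme = RadiusScheme.AE0_UNION_AE2,
    allow_unk: bool = True,
) -> Vocabulary:
    """Collect every AE in the corpus and assign deterministic token ids.

    The count retained per SMARTS is the number of molecules it occurs in
    (each molecule contributes its unique-AE set once).
    """
    if not corpus:
        raise ValueError("empty corpus")
    counts: Counter[str] = Counter()
    radius_of: dict[str, int] = {}
    for rec in corpus:
        m = _as_mol(rec)
        entries = _env_smarts_with_centers(m, scheme.radii)
        for smarts, (radius, _) in entries.items():
            counts[smarts] += 1
            radius_of.setdefault(smarts, radius)
    vocab = Vocabulary(allow_unk=allow_unk)
    next_id = len(RESERVED)
    for smarts in sorted(counts, key=lambda s: (radius_of[s], s)):
        vocab.smarts_to_id[smarts] = next_id
        vocab.id_to_smarts[next_id] = smarts
        vocab.radius_of[smarts] = radius_of[smarts]
        vocab.counts[smarts] = counts[smarts]
        next_id += 1
    return vocab


# ---------------------------------------------------------------------------
# corpus statistics

@dataclass
class CorpusCoverage:
    name: str
    n_unique_ae0: int
    n_unique_ae2: int
    singleton_fraction_ae0: float
    singleton_fraction_ae2: float


def coverage_stats(
    corpora: Mapping[str, Sequence[MoleculeRecord | str]]
) -> tuple[dict[str, CorpusCoverage], dict[tuple[str, str], dict[str, int]]]:
    """Unique-AE counts, singleton fractions and pairwise intersections.

    A *singleton* is an AE occurring in exactly one molecule of its corpus.
    Returns ``(per_corpus, pairwise)`` where ``pairwise[(a, b)]`` holds the
    sizes of the AE0 and AE2 unique-SMARTS set intersections.
    """
    sets: dict[str, dict[int, Counter]] = {}
    for name, corpus in corpora.items():
        if not corpus:
            raise ValueError(f"empty corpus: {name!r}")
        per_radius: dict[int, Counter] = {0: Counter(), 1: Counter()}
        for rec in corpus:
            m = _as_mol(rec)
            for radius in (0, 1):
                for s in {render_environment(m, a.GetIdx(), radius) for a in m.GetAtoms()}:
                    per_radius[radius][s] += 1
        sets[name] = per_radius

    def singleton_frac(c: Counter) -> float:
        return sum(1 for v in c.values() if v == 1) / len(c) if c else 0.0

    per_corpus = {
        name: CorpusCoverage(
            name,
            len(pr[0]),
            len(pr[1]),
            singleton_frac(pr[0]),
            singleton_frac(pr[1]),
        )
        for name, pr in sets.items()
    }
    names = list(corpora)
    pairwise: dict[tuple[str, str], dict[str, int]] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairwise[(a, b)] = {
                "ae0_intersection": len(set(sets[a][0]) & set(sets[b][0])),
                "ae2_intersection": len(set(sets[a][1]) & set(sets[b][1])),
            }
    return per_corpus, pairwise


# ---------------------------------------------------------------------------
# file I/O

def read_smiles_file(path) -> list[MoleculeRecord]:
    """Read a SMILES file (one molecule per line, optional tab-separated id)."""
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{i}"
            records.append(MoleculeRecord(canonicalize(smiles), mol_id))
    return records
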