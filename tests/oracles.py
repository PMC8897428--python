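"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: the atom-environment
oracle enumerates neighborhoods breadth-first with networkx and compares
Weisfeiler–Lehman certificates of center-marked subgraphs, never touching
the package's SMARTS renderer.
"""

from __future__ import annotations

import networkx as nx
from rdkit import Chem


def mol_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(
            atom.GetIdx(),
            label=(
                atom.GetSymbol(),
                atom.GetIsAromatic(),
                atom.GetTotalNumHs(),
                atom.GetDegree(),
                atom.IsInRing(),
                atom.GetFormalCharge(),
            ),
        )
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), label=str(bond.GetBondType()))
    return g


def environment_certificate(g: nx.Graph, center: int, radius: int) -> str:
    """Isomorphism certificate of the center-marked radius-r neighborhood."""
    sub = nx.ego_graph(g, center, radius=radius)
    sub = sub.copy()
    for node in sub.nodes:
        marked = (sub.nodes[node]["label"], node == center)
        sub.nodes[node]["cert_label"] = str(marked)
    return nx.weisfeiler_lehman_graph_hash(
        sub, node_attr="cert_label", edge_attr="label", iterations=4
    )


def environment_partition(mol: Chem.Mol, radius: int) -> set[frozenset[int]]:
    """Partition of atom indices into equal-environment classes."""
    g = mol_graph(mol)
    by_cert: dict[str, set[int]] = {}
    for atom in mol.GetAtoms():
        cert = environment_certificate(g, atom.GetIdx(), radius)
        by_cert.setdefault(cert, set()).add(atom.GetIdx())
    return {frozenset(v) for v in by_cert.values()}
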