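"""Systematic enumeration of small chemical graphs.

Connected simple graphs on up to a few vertices, bond-multiplicity
expansion (orders 1-3, vertex degree capped at six), and element labelling
under valency constraints with implicit hydrogen fill. Isomorphism
deduplication uses exhaustive canonical forms, which is cheap at this size.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations, product

from rdkit import Chem

from .chemgraph import ORGANIC_SUBSET, load_valency_table

MAX_VERTEX_DEGREE = 6


@dataclass(frozen=True)
class SimpleGraph:
    n_vertices: int
    edges: frozenset  # of frozenset({i, j})

    def degree(self, v: int) -> int:
        return sum(1 for e in self.edges if v in e)


@dataclass(frozen=True)
class Multigraph:
    n_vertices: int
    edges: frozenset  # of (frozenset({i, j}), multiplicity)

    def degree(self, v: int) -> int:
        return sum(m for e, m in self.edges if v in e)


def _is_connected(n: int, edge_list) -> bool:
    if n == 1:
        return True
    adj = {v: set() for v in range(n)}
    for i, j in edge_list:
        adj[i].add(j)
        adj[j].add(i)
    seen = {0}
    stack = [0]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == n


def _canonical_simple(n: int, edge_list) -> frozenset:
    """Lexicographically minimal edge set over all vertex permutations."""
    best = None
    edges = [tuple(sorted(e)) for e in edge_list]
    for perm in permutations(range(n)):
        relab = tuple(sorted(tuple(sorted((perm[i], perm[j])))
                             for i, j in edges))
        if best is None or relab < best:
            best = relab
    return frozenset(frozenset(e) for e in best)


def _canonical_multi(n: int, edges) -> frozenset:
    """Canonical form for edge-labelled (multiplicity) graphs."""
    best = None
    items = [(tuple(sorted(e)), m) for e, m in edges]
    for perm in permutations(range(n)):
        relab = tuple(sorted(
            (tuple(sorted((perm[i], perm[j]))), m) for (i, j), m in items))
        if best is None or relab < best:
            best = relab
    return frozenset((frozenset(e), m) for e, m in best)


def enumerate_connected_simple_graphs(max_vertices: int = 5) -> set[SimpleGraph]:
    """One representative per isomorphism class, sizes 1..max_vertices."""
    if not 1 <= max_vertices <= 6:
        raise ValueError("max_vertices must be in 1..6")
    out: set[SimpleGraph] = set()
    for n in range(1, max_vertices + 1):
        possible = list(combinations(range(n), 2))
        seen: set[frozenset] = set()
        for mask in range(2 ** len(possible)):
            edge_list = [possible[k] for k in range(len(possible))
                         if mask >> k & 1]
            if len(edge_list) < n - 1 or not _is_connected(n, edge_list):
                continue
            canon = _canonical_simple(n, edge_list)
            if canon not in seen:
                seen.add(canon)
                out.add(SimpleGraph(n_vertices=n, edges=canon))
    return out


def expand_bond_orders(g: SimpleGraph) -> set[Multigraph]:
    """All multiplicity assignments in {1,2,3} keeping every degree <= 6."""
    edges = sorted(tuple(sorted(e)) for e in g.edges)
    out: set[Multigraph] = set()
    seen: set[frozenset] = set()
    if not edges:  # single vertex
        return {Multigraph(n_vertices=g.n_vertices, edges=frozenset())}
    for mults in product((1, 2, 3), repeat=len(edges)):
        labelled = list(zip(edges, mults))
        degs = [0] * g.n_vertices
        for (i, j), m in labelled:
            degs[i] += m
            degs[j] += m
        if max(degs) > MAX_VERTEX_DEGREE:
            continue
        canon = _canonical_multi(
            g.n_vertices, [(frozenset(e), m) for e, m in labelled])
        if canon not in seen:
            seen.add(canon)
            out.add(Multigraph(n_vertices=g.n_vertices, edges=canon))
    return out


_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
               3: Chem.BondType.TRIPLE}


def _build_smiles(n: int, labelled_edges, symbols, valency) -> str | None:
    """RDKit molecule from a labelled multigraph; implicit H fill to valency."""
    rw = Chem.RWMol()
    for v in range(n):
        atom = Chem.Atom(symbols[v])
        rw.AddAtom(atom)
    degs = [0] * n
    for (i, j), m in labelled_edges:
        rw.AddBond(i, j, _BOND_TYPES[m])
        degs[i] += m
        degs[j] += m
    for v in range(n):
        atom = rw.GetAtomWithIdx(v)
        atom.SetNumExplicitHs(valency[symbols[v]] - degs[v])
        atom.SetNoImplicit(True)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


def label_elements(mg: Multigraph, elements=ORGANIC_SUBSET,
                   valency: dict[str, int] | None = None) -> set[str]:
    """All element labelings respecting max valency; canonical SMILES set."""
    valency = valency if valency is not None else load_valency_table()
    n = mg.n_vertices
    edges = sorted(((tuple(sorted(e)), m) for e, m in mg.edges))
    degs = [0] * n
    for (i, j), m in edges:
        degs[i] += m
        degs[j] += m
    per_vertex = [[el for el in elements if valency[el] >= degs[v]]
                  for v in range(n)]
    out: set[str] = set()
    labelled = [(e, m) for e, m in edges]
    for symbols in product(*per_vertex):
        smi = _build_smiles(n, labelled, symbols, valency)
        if smi is not None:
            out.add(smi)
    return out


def enumerate_molecules(max_vertices: int = 5, elements=ORGANIC_SUBSET,
                        valency: dict[str, int] | None = None) -> set[str]:
    """Full cascade: simple graphs -> bond orders -> element labels."""
    valency = valency if valency is not None else load_valency_table()
    out: set[str] = set()
    for sg in enumerate_connected_simple_graphs(max_vertices):
        for mg in expand_bond_orders(sg):
            out |= label_elements(mg, elements=elements, valency=valency)
    return out
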