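"""Data-enrichment generators.

Protonation-state combinations (rule-table driven), stereoisomer
enumeration, amons (hydrogen-saturated connected heavy-atom subgraphs),
tripeptides with disulfide/split variants, and the heavy-atom cutoff.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from importlib import resources

from rdkit import Chem
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)

from .chemgraph import SmilesError, canonicalize, heavy_atom_count

log = logging.getLogger(__name__)


@dataclass
class EnrichmentBatch:
    seed_smiles: str
    generator: str
    products: set[str] = field(default_factory=set)


def _load_json(name: str):
    with resources.files("molforge.data").joinpath(name).open() as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# protonation states
# ---------------------------------------------------------------------------

def _find_protonation_sites(mol, rules):
    """(atom index, list of (charge, delta_h)) per matched site.

    A given atom belongs to at most one site (first matching rule wins).
    """
    sites = []
    claimed: set[int] = set()
    for rule in rules:
        patt = Chem.MolFromSmarts(rule["smarts"])
        for match in mol.GetSubstructMatches(patt):
            idx = match[rule["atom"]]
            if idx in claimed:
                continue
            claimed.add(idx)
            states = [(s["charge"], s["delta_h"]) for s in rule["states"]]
            sites.append((idx, states))
    return sites


def enumerate_protonation_states(smiles: str,
                                 rules: list | None = None) -> set[str]:
    """All combinations of protonation states over detected sites.

    Includes the seed itself; combinations are generated even if they would
    not co-occur at any single pH.
    """
    if rules is None:
        rules = _load_json("protonation_rules.json")["rules"]
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparsable SMILES: {smiles!r}")
    sites = _find_protonation_sites(mol, rules)
    out = {canonicalize(smiles)}
    if not sites:
        return out
    base_h = {idx: mol.GetAtomWithIdx(idx).GetTotalNumHs()
              for idx, _ in sites}
    for combo in itertools.product(*[states for _, states in sites]):
        rw = Chem.RWMol(mol)
        ok = True
        for (idx, _), (charge, delta_h) in zip(sites, combo):
            atom = rw.GetAtomWithIdx(idx)
            new_h = base_h[idx] + delta_h
            if new_h < 0:
                ok = False
                break
            atom.SetFormalCharge(charge)
            atom.SetNumExplicitHs(new_h)
            atom.SetNoImplicit(True)
        if not ok:
            continue
        try:
            product = rw.GetMol()
            Chem.SanitizeMol(product)
            out.add(Chem.MolToSmiles(product))
        except Exception:
            log.debug("protonation combo failed on %s", smiles)
    return out


# ---------------------------------------------------------------------------
# stereoisomers
# ---------------------------------------------------------------------------

def enumerate_stereoisomers(smiles: str) -> set[str]:
    """All combinations over stereocentres/stereobonds, fully assigned."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparsable SMILES: {smiles!r}")
    opts = StereoEnumerationOptions(onlyUnassigned=False, unique=True)
    return {Chem.MolToSmiles(m) for m in EnumerateStereoisomers(mol, opts)}


# ---------------------------------------------------------------------------
# amons (connected heavy-atom subgraphs, H-saturated to original valency)
# ---------------------------------------------------------------------------

def _connected_subsets(adj: dict[int, set[int]]) -> list[frozenset]:
    atoms = sorted(adj)
    out = []
    for r in range(1, len(atoms) + 1):
        for subset in itertools.combinations(atoms, r):
            ss = set(subset)
            seen = {subset[0]}
            stack = [subset[0]]
            while stack:
                for w in adj[stack.pop()] & ss:
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            if len(seen) == len(ss):
                out.append(frozenset(ss))
    return out


def generate_amons(smiles: str) -> set[str]:
    """Amons of a seed graph (includes the seed itself).

    Heavy atoms keep the valency they had in the seed: bonds inside a
    fragment are retained with their (Kekule) orders and hydrogens fill the
    remainder. Fragments whose H-saturation fails valency rules are
    discarded and logged.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparsable SMILES: {smiles!r}")
    mol = Chem.Mol(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)

    adj = {a.GetIdx(): {n.GetIdx() for n in a.GetNeighbors()}
           for a in mol.GetAtoms()}
    # target total valence (heavy-bond orders + H) per heavy atom
    target = {}
    for a in mol.GetAtoms():
        heavy_order = sum(
            int(b.GetBondTypeAsDouble())
            for b in a.GetBonds())
        target[a.GetIdx()] = heavy_order + a.GetTotalNumHs()

    out: set[str] = set()
    for subset in _connected_subsets(adj):
        rw = Chem.RWMol()
        remap = {}
        for idx in sorted(subset):
            src = mol.GetAtomWithIdx(idx)
            atom = Chem.Atom(src.GetSymbol())
            atom.SetFormalCharge(src.GetFormalCharge())
            remap[idx] = rw.AddAtom(atom)
        for b in mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if i in subset and j in subset:
                rw.AddBond(remap[i], remap[j], b.GetBondType())
        ok = True
        for idx in subset:
            atom = rw.GetAtomWithIdx(remap[idx])
            used = sum(int(b.GetBondTypeAsDouble()) for b in atom.GetBonds())
            n_h = target[idx] - used
            if n_h < 0:
                ok = False
                break
            atom.SetNumExplicitHs(n_h)
            atom.SetNoImplicit(True)
        if not ok:
            log.debug("amon fragment of %s violates valency, dropped", smiles)
            continue
        try:
            frag = rw.GetMol()
            Chem.SanitizeMol(frag)
            out.add(Chem.MolToSmiles(frag))
        except Exception:
            log.debug("amon fragment of %s failed sanitization", smiles)
    return out


# ---------------------------------------------------------------------------
# tripeptides
# ---------------------------------------------------------------------------

# atom-map conventions in the amino-acid table
_MAP_N, _MAP_C, _MAP_OH, _MAP_CHALCOGEN = 1, 2, 3, 4
_BRIDGEABLE = ("Cys",)


def load_amino_acids() -> dict[str, str]:
    table = _load_json("amino_acids.json")
    return {k: v for k, v in table.items() if not k.startswith("_")}


class _PeptideBuilder:
    """Assembles one tripeptide variant from mapped residue SMILES."""

    def __init__(self, residue_smiles: list[str]):
        mol = Chem.Mol()
        self.maps: list[dict[int, int]] = []
        for smi in residue_smiles:
            frag = Chem.MolFromSmiles(smi)
            if frag is None:
                raise SmilesError(f"bad amino-acid SMILES: {smi!r}")
            offset = mol.GetNumAtoms()
            mol = Chem.CombineMols(mol, frag)
            self.maps.append({a.GetAtomMapNum(): offset + a.GetIdx()
                              for a in frag.GetAtoms() if a.GetAtomMapNum()})
        self.rw = Chem.RWMol(mol)

    def form_peptide_bond(self, i: int) -> None:
        """Condense residue i's carboxyl with residue i+1's amine."""
        oh = self.maps[i][_MAP_OH]
        self.rw.RemoveAtom(oh)
        for m in self.maps:  # atom removal shifts higher indices down
            for k, v in m.items():
                if v > oh:
                    m[k] = v - 1
        del self.maps[i][_MAP_OH]
        c = self.maps[i][_MAP_C]
        n = self.maps[i + 1][_MAP_N]
        na = self.rw.GetAtomWithIdx(n)
        na.SetNumExplicitHs(na.GetNumExplicitHs() - 1)
        self.rw.AddBond(c, n, Chem.BondType.SINGLE)

    def split_peptide_bond(self, i: int) -> None:
        """Hydrolyse the bond between residues i and i+1."""
        c = self.maps[i][_MAP_C]
        n = self.maps[i + 1][_MAP_N]
        self.rw.RemoveBond(c, n)
        na = self.rw.GetAtomWithIdx(n)
        na.SetNumExplicitHs(na.GetNumExplicitHs() + 1)
        o = self.rw.AddAtom(Chem.Atom(8))
        self.rw.AddBond(c, o, Chem.BondType.SINGLE)

    def form_disulfide(self, p: int, q: int) -> None:
        sp = self.maps[p][_MAP_CHALCOGEN]
        sq = self.maps[q][_MAP_CHALCOGEN]
        for s in (sp, sq):
            atom = self.rw.GetAtomWithIdx(s)
            atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)
        self.rw.AddBond(sp, sq, Chem.BondType.SINGLE)

    def n_fragments(self) -> int:
        return len(Chem.GetMolFrags(self.rw.GetMol()))

    def smiles(self) -> str:
        mol = self.rw.GetMol()
        for atom in mol.GetAtoms():
            atom.SetAtomMapNum(0)
        Chem.SanitizeMol(mol)
        return Chem.MolToSmiles(mol)


def _build_variant(residues, table, bridge=None, splits=()):
    builder = _PeptideBuilder([table[r] for r in residues])
    builder.form_peptide_bond(0)
    builder.form_peptide_bond(1)
    if bridge is not None:
        builder.form_disulfide(*bridge)
    for i in splits:
        builder.split_peptide_bond(i)
    return builder


def generate_tripeptides(amino_acids: dict[str, str] | None = None):
    """All 22^3 linear tripeptides plus disulfide-bridged/split variants.

    Bridged variants are generated for every ordered triple with at least
    two cysteines (all bridging patterns for tricysteine); split variants
    hydrolyse every non-empty subset of a bridged variant's peptide bonds,
    keeping only products that remain a single covalent component.

    Returns ``(products, report)`` where products is the full list of
    canonical SMILES (one entry per generated structure) and report holds
    ``n_linear``, ``n_bridged``, ``n_split`` and ``total``.
    """
    table = amino_acids if amino_acids is not None else load_amino_acids()
    names = sorted(table)
    products: list[str] = []
    n_linear = n_bridged = n_split = 0
    for triple in itertools.product(names, repeat=3):
        builder = _build_variant(triple, table)
        products.append(builder.smiles())
        n_linear += 1
        cys_pos = [i for i, r in enumerate(triple) if r in _BRIDGEABLE]
        if len(cys_pos) < 2:
            continue
        for p, q in itertools.combinations(cys_pos, 2):
            bridged = _build_variant(triple, table, bridge=(p, q))
            assert bridged.n_fragments() == 1
            products.append(bridged.smiles())
            n_bridged += 1
            for splits in ((0,), (1,), (0, 1)):
                split = _build_variant(triple, table, bridge=(p, q),
                                       splits=splits)
                if split.n_fragments() == 1:
                    products.append(split.smiles())
                    n_split += 1
    report = {
        "n_linear": n_linear,
        "n_bridged": n_bridged,
        "n_split": n_split,
        "total": n_linear + n_bridged + n_split,
    }
    return products, report


# ---------------------------------------------------------------------------
# heavy-atom restriction
# ---------------------------------------------------------------------------

def filter_heavy_atoms(smiles_set, max_heavy: int = 8) -> set[str]:
    """Retain molecules with at most ``max_heavy`` non-hydrogen atoms."""
    return {s for s in smiles_set if heavy_atom_count(s) <= max_heavy}
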