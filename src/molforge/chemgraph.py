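"""Chemical-graph data model and SMILES handling.

Molecule identity throughout the package is the RDKit canonical SMILES
string (uniqueness is only guaranteed within that canonical form).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

ORGANIC_SUBSET = ("B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I")

_ISOTOPE_RE = re.compile(r"\[(\d+)([A-IK-PR-Za-ik-pr-z@])")
_BARE_BRACKET_RE = re.compile(r"\[(B|C|N|O|P|S|F|Cl|Br|I|b|c|n|o|p|s)\]")


class SmilesError(ValueError):
    """Raised for unparsable or disallowed SMILES input."""


def load_valency_table(variant: str = "default") -> dict[str, int]:
    """Maximum valencies used for implicit-hydrogen assignment.

    ``variant`` is a key in the packaged ``valency.json`` ("default" follows
    the SMILES organic-subset convention; "hypervalent" allows P(V)/S(VI)).
    """
    with resources.files("molforge.data").joinpath("valency.json").open() as fh:
        table = json.load(fh)
    if variant not in table:
        raise KeyError(f"unknown valency table variant: {variant!r}")
    return dict(table[variant])


def load_charge_adjustments() -> dict[str, dict[int, int]]:
    """Charge-adjusted maximum valencies (e.g. O- -> 1, N+ -> 4)."""
    with resources.files("molforge.data").joinpath("valency.json").open() as fh:
        table = json.load(fh)
    return {
        el: {int(q): v for q, v in adj.items()}
        for el, adj in table["charge_adjust"].items()
    }


def max_valency(symbol: str, charge: int = 0,
                table: dict[str, int] | None = None) -> int:
    table = table if table is not None else load_valency_table()
    base = table[symbol]
    if charge:
        adj = load_charge_adjustments().get(symbol, {})
        if charge in adj:
            return adj[charge]
        # generic fallback: cations gain a bond, anions lose one
        return max(base + (1 if charge > 0 else -1), 0)
    return base


@dataclass(frozen=True)
class ElectronicState:
    """Total charge (e) and spin multiplicity of a structure."""

    charge: int
    multiplicity: int

    def __post_init__(self):
        if self.multiplicity not in (1, 2):
            raise ValueError("multiplicity restricted to {1, 2}")


@dataclass
class ChemicalGraph:
    """Labelled multigraph for one molecule, keyed by canonical SMILES.

    ``atoms`` holds (element symbol, formal charge, total H count) per heavy
    atom; ``bonds`` holds (i, j, order) with order in
    {"single", "aromatic", "double", "triple"}.
    """

    atoms: list[tuple[str, int, int]]
    bonds: list[tuple[int, int, str]]
    stereo: set[str] = field(default_factory=set)
    canonical_smiles: str = ""

    _BOND_NAMES = {
        Chem.BondType.SINGLE: "single",
        Chem.BondType.AROMATIC: "aromatic",
        Chem.BondType.DOUBLE: "double",
        Chem.BondType.TRIPLE: "triple",
    }

    @classmethod
    def from_smiles(cls, smiles: str) -> "ChemicalGraph":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise SmilesError(f"unparsable SMILES: {smiles!r}")
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
        atoms = [
            (a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs())
            for a in mol.GetAtoms()
        ]
        bonds = []
        for b in mol.GetBonds():
            name = cls._BOND_NAMES.get(b.GetBondType())
            if name is None:
                raise SmilesError(
                    f"unsupported bond type {b.GetBondType()} in {smiles!r}")
            bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), name))
        stereo = set()
        for a in mol.GetAtoms():
            if a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED:
                stereo.add(f"tetrahedral:{a.GetIdx()}:{a.GetChiralTag().name}")
        for b in mol.GetBonds():
            if b.GetStereo() != Chem.BondStereo.STEREONONE:
                stereo.add(
                    f"bond:{b.GetBeginAtomIdx()}-{b.GetEndAtomIdx()}:"
                    f"{b.GetStereo().name}")
        return cls(atoms=atoms, bonds=bonds, stereo=stereo,
                   canonical_smiles=Chem.MolToSmiles(mol))

    def to_mol(self, add_hs: bool = False) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.canonical_smiles)
        if mol is None:  # pragma: no cover - canonical SMILES always parses
            raise SmilesError(self.canonical_smiles)
        return Chem.AddHs(mol) if add_hs else mol

    @property
    def n_heavy(self) -> int:
        return len(self.atoms)


def sanitize(smiles: str) -> str:
    """Strip isotope labels; reject disconnected or unparsable SMILES.

    Isotope removal happens at string level so the output is otherwise
    unchanged (``"CCO"`` stays ``"CCO"``); bare bracket atoms left behind by
    a removed isotope (e.g. ``[13C]`` -> ``[C]``) are unbracketed so implicit
    hydrogens are re-perceived, matching ``"[13C]C" -> "CC"``.
    """
    if "." in smiles:
        raise SmilesError(f"disconnected SMILES rejected: {smiles!r}")
    out = _ISOTOPE_RE.sub(r"[\2", smiles)
    out = _BARE_BRACKET_RE.sub(r"\1", out)
    if Chem.MolFromSmiles(out) is None:
        raise SmilesError(f"unparsable SMILES: {smiles!r}")
    return out


def canonicalize(smiles: str) -> str:
    """Canonical SMILES; deterministic identity for configurational isomers."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def assign_electronic_state(g: ChemicalGraph) -> ElectronicState:
    """Charge = sum of formal charges; lowest multiplicity by electron parity."""
    mol = g.to_mol()
    charge = sum(a.GetFormalCharge() for a in mol.GetAtoms())
    n_electrons = (
        sum(a.GetAtomicNum() for a in mol.GetAtoms())
        + sum(a.GetTotalNumHs() for a in mol.GetAtoms())
        - charge
    )
    return ElectronicState(charge=charge, multiplicity=1 + n_electrons % 2)


def mirror(smiles: str) -> str:
    """Canonical SMILES of the mirror image.

    All tetrahedral parities are inverted; double-bond cis/trans descriptors
    are untouched (reflection preserves double-bond geometry).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparsable SMILES: {smiles!r}")
    for atom in mol.GetAtoms():
        if atom.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED:
            atom.InvertChirality()
    return Chem.MolToSmiles(mol)


def enantiomer_representative(smiles: str) -> tuple[str, bool]:
    """Lexicographically smaller member of the enantiomer pair.

    Returns ``(representative, kept)``; ``kept`` is False when the input is
    the larger member of a distinct pair (and should be skipped downstream).
    """
    s = canonicalize(smiles)
    m = mirror(s)
    if m == s:
        return s, True
    rep = min(s, m)
    return rep, rep == s


def heavy_atom_count(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparsable SMILES: {smiles!r}")
    return mol.GetNumHeavyAtoms()


def read_smiles_file(path) -> list[str]:
    """One SMILES per line; '#' comment lines and blanks ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line.split()[0])
    return out


def write_smiles_file(path, smiles_list, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for s in smiles_list:
            fh.write(s + "\n")
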