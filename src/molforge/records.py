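"""Hierarchical record store (graph -> conformation -> calculation),
stable keys, JSONL / extended-XYZ I/O, and the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import constants, enrichment, nms, qc
from .calculator import get_calculator_factory
from .chemgraph import (ChemicalGraph, SmilesError, assign_electronic_state,
                        canonicalize, enantiomer_representative,
                        heavy_atom_count, sanitize)
from .conformer import (ConvergenceError, EmbeddingError,
                        conformer_search, embed_initial, local_optimize)

log = logging.getLogger(__name__)


def _hash(payload: str) -> str:
    """SHA-256 truncated to 128 bits, hex."""
    return hashlib.sha256(payload.encode()).hexdigest()[:32]


def graph_key(canonical_smiles: str) -> str:
    return _hash("graph:" + canonical_smiles)


def conformation_key(parent: str, positions: np.ndarray) -> str:
    digest = hashlib.sha256(
        np.ascontiguousarray(np.round(positions, 8)).tobytes()).hexdigest()
    return _hash(f"conf:{parent}:{digest}")


def calculation_key(parent: str, calculator_name: str) -> str:
    return _hash(f"calc:{parent}:{calculator_name}")


@dataclass
class GraphRecord:
    key: str
    canonical_smiles: str
    heavy_atom_count: int
    provenance: list = field(default_factory=list)

    def to_dict(self):
        return {"key": self.key, "canonical_smiles": self.canonical_smiles,
                "heavy_atom_count": self.heavy_atom_count,
                "provenance": self.provenance}

    @classmethod
    def from_dict(cls, d):
        return cls(d["key"], d["canonical_smiles"], d["heavy_atom_count"],
                   d.get("provenance", []))


@dataclass
class ConformationRecord:
    key: str
    parent: str
    atomic_numbers: list
    positions: list          # (N, 3) Angstrom
    charge: int
    multiplicity: int
    kind: str                # "conformer" | "offequilibrium"
    sample_draw: dict | None = None

    def to_dict(self):
        return {"key": self.key, "parent": self.parent,
                "atomic_numbers": self.atomic_numbers,
                "positions": self.positions, "charge": self.charge,
                "multiplicity": self.multiplicity, "kind": self.kind,
                "sample_draw": self.sample_draw}

    @classmethod
    def from_dict(cls, d):
        return cls(d["key"], d["parent"], d["atomic_numbers"],
                   d["positions"], d["charge"], d["multiplicity"], d["kind"],
                   d.get("sample_draw"))


@dataclass
class CalculationRecord:
    """Per-structure property bundle. Energies/forces/positions are stored
    in internal units (eV, eV/A, A); export converts to E_h, E_h/a0, a0."""

    key: str
    parent: str
    calculator: str
    charge: int
    multiplicity: int
    atomic_numbers: list
    positions: list
    energy: float
    forces: list
    formation_energy: float | None = None
    bond_orders: list | None = None
    partial_charges: list | None = None
    flags: dict | None = None

    def to_dict(self):
        return {
            "key": self.key, "parent": self.parent,
            "calculator": self.calculator, "charge": self.charge,
            "multiplicity": self.multiplicity,
            "atomic_numbers": self.atomic_numbers,
            "positions": self.positions, "energy": self.energy,
            "forces": self.forces, "formation_energy": self.formation_energy,
            "bond_orders": self.bond_orders,
            "partial_charges": self.partial_charges, "flags": self.flags,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(**{k: d.get(k) for k in (
            "key", "parent", "calculator", "charge", "multiplicity",
            "atomic_numbers", "positions", "energy", "forces",
            "formation_energy", "bond_orders", "partial_charges", "flags")})


class StoreError(RuntimeError):
    pass


class Store:
    """In-memory hierarchical store with referential integrity."""

    def __init__(self):
        self.graphs: dict[str, GraphRecord] = {}
        self.conformations: dict[str, ConformationRecord] = {}
        self.calculations: dict[str, CalculationRecord] = {}
        self.rejections: list[dict] = []

    # -- insertion ----------------------------------------------------------

    def _put(self, table: dict, record, parent_table: dict | None):
        if parent_table is not None and record.parent not in parent_table:
            raise StoreError(f"orphan insert: parent {record.parent!r} "
                             "not in store")
        existing = table.get(record.key)
        if existing is not None:
            if existing.to_dict() != record.to_dict():
                raise StoreError(f"key collision with differing payload: "
                                 f"{record.key}")
            return existing
        table[record.key] = record
        return record

    def put_graph(self, record: GraphRecord) -> GraphRecord:
        existing = self.graphs.get(record.key)
        if existing is not None:
            a = {**existing.to_dict(), "provenance": None}
            b = {**record.to_dict(), "provenance": None}
            if a != b:
                raise StoreError(f"key collision with differing payload: "
                                 f"{record.key}")
            for src in record.provenance:  # same graph, new source
                if src not in existing.provenance:
                    existing.provenance.append(src)
            return existing
        return self._put(self.graphs, record, None)

    def put_conformation(self, record: ConformationRecord):
        return self._put(self.conformations, record, self.graphs)

    def put_calculation(self, record: CalculationRecord):
        return self._put(self.calculations, record, self.conformations)

    def reject(self, stage: str, item: str, reason: str) -> None:
        self.rejections.append({"stage": stage, "item": item,
                                "reason": reason})
        log.info("rejected at %s: %s (%s)", stage, item, reason)

    # -- navigation -----------------------------------------------------------

    def get(self, key: str):
        for table in (self.graphs, self.conformations, self.calculations):
            if key in table:
                return table[key]
        raise KeyError(key)

    def children(self, key: str) -> list:
        if key in self.graphs:
            return [c for c in self.conformations.values()
                    if c.parent == key]
        if key in self.conformations:
            return [c for c in self.calculations.values()
                    if c.parent == key]
        return []

    def audit(self) -> dict:
        """Referential-integrity check; returns counts and orphan keys."""
        orphans = [c.key for c in self.conformations.values()
                   if c.parent not in self.graphs]
        orphans += [c.key for c in self.calculations.values()
                    if c.parent not in self.conformations]
        return {
            "n_graphs": len(self.graphs),
            "n_conformations": len(self.conformations),
            "n_calculations": len(self.calculations),
            "n_rejections": len(self.rejections),
            "orphans": orphans,
            "ok": not orphans,
        }

    def digest(self) -> str:
        """Deterministic content hash over every record."""
        h = hashlib.sha256()
        for table in (self.graphs, self.conformations, self.calculations):
            for key in sorted(table):
                h.update(json.dumps(table[key].to_dict(),
                                    sort_keys=True).encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# JSONL and extended-XYZ I/O
# ---------------------------------------------------------------------------

_TABLES = (("graphs.jsonl", "graphs", GraphRecord),
           ("conformations.jsonl", "conformations", ConformationRecord),
           ("calculations.jsonl", "calculations", CalculationRecord))


def export_jsonl(store: Store, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for fname, attr, _ in _TABLES:
        with open(out / fname, "w") as fh:
            for key in sorted(getattr(store, attr)):
                record = getattr(store, attr)[key]
                row = record.to_dict()
                row["key_hash"] = _hash(record.key)
                fh.write(json.dumps(row, sort_keys=True) + "\n")


def import_jsonl(in_dir) -> Store:
    src = Path(in_dir)
    store = Store()
    for fname, attr, cls in _TABLES:
        path = src / fname
        if not path.exists():
            continue
        with open(path) as fh:
            for line in fh:
                d = json.loads(line)
                d.pop("key_hash", None)
                getattr(store, attr)[d["key"]] = cls.from_dict(d)
    bad = store.audit()
    if not bad["ok"]:
        raise StoreError(f"import has orphans: {bad['orphans'][:5]}")
    return store


_SYMBOLS = None


def _symbol(z: int) -> str:
    from rdkit import Chem
    return Chem.GetPeriodicTable().GetElementSymbol(int(z))


def export_extxyz(store: Store, path, selection=None) -> None:
    """Extended-XYZ export of calculation records.

    Positions in a0, energy in E_h, forces in E_h/a0 (export-unit contract);
    each frame carries key_hash, parent keys, charge and multiplicity.
    """
    keys = sorted(store.calculations if selection is None else selection)
    with open(path, "w") as fh:
        for key in keys:
            rec = store.calculations[key]
            pos = np.asarray(rec.positions) / constants.BOHR_ANGSTROM
            forces = (np.asarray(rec.forces)
                      * constants.BOHR_ANGSTROM / constants.HARTREE_EV)
            energy = rec.energy / constants.HARTREE_EV
            n = len(rec.atomic_numbers)
            comment = (
                f'energy={energy!r} charge={rec.charge} '
                f'multiplicity={rec.multiplicity} key_hash={_hash(rec.key)} '
                f'parent={rec.parent} '
                f'Properties=species:S:1:pos:R:3:forces:R:3')
            fh.write(f"{n}\n{comment}\n")
            for z, p, f in zip(rec.atomic_numbers, pos, forces):
                fh.write(f"{_symbol(z):2s} "
                         + " ".join(f"{v:.12f}" for v in p) + " "
                         + " ".join(f"{v:.12f}" for v in f) + "\n")


def read_extxyz(path) -> list[dict]:
    """Minimal reader for files written by export_extxyz (a0 / E_h units)."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        comment = lines[i + 1]
        meta = {}
        for token in comment.split():
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k] = v
        symbols, pos, forces = [], [], []
        for row in lines[i + 2:i + 2 + n]:
            parts = row.split()
            symbols.append(parts[0])
            pos.append([float(x) for x in parts[1:4]])
            forces.append([float(x) for x in parts[4:7]])
        frames.append({"symbols": symbols, "positions": np.array(pos),
                       "forces": np.array(forces),
                       "energy": float(meta["energy"]), "meta": meta})
        i += 2 + n
    return frames


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seeds": [],                  # seed SMILES
    "generators": ["protonation", "stereo", "amons"],
    "max_heavy": 8,
    "calculator": "toy",
    "seed": 0,
    "n_conformers": 10,
    "generations": 8,
    "samples_per_conformer": None,  # None -> heavy-atom schedule
    "sample_mode": "zmatrix",
    # conformers are re-optimized to this tighter threshold before the
    # stencil saddle check (soft toy modes need better than 5 meV/A)
    "sample_fmax": 2e-4,
    "t_max": constants.T_MAX_DEFAULT,
    "max_samples_min": 100,
    "max_samples_max": 1000,
}


def import_graph(store: Store, smiles: str, provenance: str) -> str | None:
    """Sanitize, canonicalize, enantiomer-filter and insert one graph.

    Returns the graph key, or None when skipped/rejected.
    """
    try:
        smi = canonicalize(sanitize(smiles))
    except SmilesError as exc:
        store.reject("import", smiles, str(exc))
        return None
    rep, kept = enantiomer_representative(smi)
    if not kept:
        store.reject("import", smi, "second enantiomer skipped")
        return None
    key = graph_key(rep)
    store.put_graph(GraphRecord(
        key=key, canonical_smiles=rep,
        heavy_atom_count=heavy_atom_count(rep),
        provenance=[provenance]))
    return key


def enrich_store(store: Store, generators, max_heavy: int) -> None:
    """Run enrichment generators to a fixed point under the heavy-atom cap."""
    gen_map = {
        "protonation": enrichment.enumerate_protonation_states,
        "stereo": enrichment.enumerate_stereoisomers,
        "amons": enrichment.generate_amons,
    }
    frontier = [g.canonical_smiles for g in store.graphs.values()]
    while frontier:
        new_frontier = []
        for smi in frontier:
            for name in generators:
                for product in sorted(gen_map[name](smi)):
                    if heavy_atom_count(product) > max_heavy:
                        continue
                    before = len(store.graphs)
                    key = import_graph(store, product, f"{name}({smi})")
                    if key is not None and len(store.graphs) > before:
                        new_frontier.append(
                            store.graphs[key].canonical_smiles)
        frontier = new_frontier


def run_pipeline(config: dict) -> Store:
    """End-to-end: import -> enrich -> conformers -> samples -> QC flags."""
    cfg = {**DEFAULT_CONFIG, **config}
    rng = np.random.default_rng(cfg["seed"])
    store = Store()
    counters = {"imported": 0, "enriched": 0, "conformers": 0,
                "samples": 0, "outliers": 0}

    for smi in cfg["seeds"]:
        if import_graph(store, smi, "seed") is not None:
            counters["imported"] += 1
    enrich_store(store, cfg["generators"], cfg["max_heavy"])
    counters["enriched"] = len(store.graphs) - counters["imported"]

    factory = get_calculator_factory(cfg["calculator"])
    for gkey in sorted(store.graphs):
        grec = store.graphs[gkey]
        if grec.heavy_atom_count > cfg["max_heavy"]:
            continue
        g = ChemicalGraph.from_smiles(grec.canonical_smiles)
        try:
            calc = factory(g)
        except Exception as exc:
            store.reject("calculator", grec.canonical_smiles, str(exc))
            continue
        try:
            s0 = embed_initial(g, seed=cfg["seed"])
            c0 = local_optimize(s0, calc)
        except (EmbeddingError, ConvergenceError, FloatingPointError) as exc:
            store.reject("conformer", grec.canonical_smiles, str(exc))
            continue
        confs = conformer_search(c0, g, calc,
                                 n_conformers=cfg["n_conformers"],
                                 seed=cfg["seed"],
                                 generations=cfg["generations"])
        reference = {int(z): calc.isolated_atom_energy(int(z))
                     for z in c0.structure.atomic_numbers} \
            if hasattr(calc, "isolated_atom_energy") else {}
        state = assign_electronic_state(g)
        n_samples = (cfg["samples_per_conformer"]
                     if cfg["samples_per_conformer"] is not None
                     else nms.sample_count_schedule(
                         grec.heavy_atom_count, cfg["max_samples_min"],
                         cfg["max_samples_max"], cfg["max_heavy"]))
        for conf in confs:
            counters["conformers"] += 1
            try:
                conf = local_optimize(conf.structure, calc,
                                      f_max=cfg["sample_fmax"])
            except (ConvergenceError, FloatingPointError) as exc:
                store.reject("tighten", grec.canonical_smiles, str(exc))
                continue
            ckey = conformation_key(gkey, conf.positions)
            store.put_conformation(ConformationRecord(
                key=ckey, parent=gkey,
                atomic_numbers=conf.structure.atomic_numbers.tolist(),
                positions=conf.positions.tolist(),
                charge=state.charge, multiplicity=state.multiplicity,
                kind="conformer"))
            try:
                samples = nms.sample_offequilibrium(
                    conf, calc, n_samples, rng, t_max=cfg["t_max"],
                    mode=cfg["sample_mode"])
            except nms.NotAMinimumError as exc:
                store.reject("nms", ckey, str(exc))
                continue
            for displaced, draw in samples:
                counters["samples"] += 1
                skey = conformation_key(gkey, displaced.positions)
                store.put_conformation(ConformationRecord(
                    key=skey, parent=gkey,
                    atomic_numbers=displaced.atomic_numbers.tolist(),
                    positions=displaced.positions.tolist(),
                    charge=state.charge, multiplicity=state.multiplicity,
                    kind="offequilibrium", sample_draw=draw.to_dict()))
                try:
                    res = calc.evaluate(displaced)
                except FloatingPointError as exc:
                    store.reject("calculation", skey, str(exc))
                    continue
                flags = qc.flag_outlier(
                    res.energy, res.forces, res.bond_orders, displaced, g,
                    reference)
                if flags.is_outlier:
                    counters["outliers"] += 1
                e_form = qc.formation_energy(
                    res.energy, displaced.atomic_numbers, reference)
                store.put_calculation(CalculationRecord(
                    key=calculation_key(skey, cfg["calculator"]),
                    parent=skey, calculator=cfg["calculator"],
                    charge=state.charge, multiplicity=state.multiplicity,
                    atomic_numbers=displaced.atomic_numbers.tolist(),
                    positions=displaced.positions.tolist(),
                    energy=res.energy, forces=res.forces.tolist(),
                    formation_energy=e_form,
                    bond_orders=None if res.bond_orders is None
                    else res.bond_orders.tolist(),
                    partial_charges=None if res.charges is None
                    else res.charges.tolist(),
                    flags=flags.to_dict()))
    log.info("pipeline counters: %s", counters)
    store.counters = counters
    return store
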