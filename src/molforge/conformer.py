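"""Conformer generation: embedding, local optimization, genetic torsion
search, and symmetry-aware RMSD deduplication (mirror images included)."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from . import constants
from .calculator import Calculator, Structure3D, covalent_radius
from .chemgraph import ChemicalGraph

log = logging.getLogger(__name__)


class EmbeddingError(RuntimeError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class Conformer:
    structure: Structure3D
    energy: float
    n_steps: int
    final_fmax: float
    cluster_id: int | None = None

    @property
    def positions(self) -> np.ndarray:
        return self.structure.positions


# ---------------------------------------------------------------------------
# initial embedding
# ---------------------------------------------------------------------------

def embed_initial(g: ChemicalGraph, seed: int = 0) -> Structure3D:
    """Distance-geometry 3D embedding (deterministic under fixed seed)."""
    mol = g.to_mol(add_hs=True)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise EmbeddingError(f"embedding failed for {g.canonical_smiles!r}")
    pos = mol.GetConformer().GetPositions()
    z = np.array([a.GetAtomicNum() for a in mol.GetAtoms()])
    from .chemgraph import assign_electronic_state
    return Structure3D(z, pos, state=assign_electronic_state(g))


# ---------------------------------------------------------------------------
# local optimization
# ---------------------------------------------------------------------------

def _max_atom_force(forces: np.ndarray) -> float:
    return float(np.sqrt((forces ** 2).sum(axis=1)).max())


def _backtrack(calc, s, x, e, g_flat, direction, max_reduction=30):
    """Armijo backtracking along ``direction``; returns (x_new, e_new) or None."""
    alpha = 1.0
    slope = float(g_flat @ direction)
    if slope >= 0:  # not a descent direction
        direction = -g_flat
        slope = float(g_flat @ direction)
    for _ in range(max_reduction):
        x_new = x + alpha * direction
        try:
            res = calc.evaluate(Structure3D(
                s.atomic_numbers, x_new.reshape(-1, 3), s.state))
        except FloatingPointError:
            alpha *= 0.5
            continue
        if np.isfinite(res.energy) and res.energy <= e + 1e-4 * alpha * slope:
            return x_new, res
        alpha *= 0.5
    return None


def local_optimize(s: Structure3D, calc: Calculator,
                   f_max: float = constants.FMAX_DEFAULT,
                   max_steps: int = 1000, pre_opt: bool = True) -> Conformer:
    """Two-stage minimization.

    Optional pre-optimization runs steepest descent until the per-atom
    energy change drops below 1 J/mol/atom; the main stage is BFGS with
    backtracking line search until the largest per-atom force norm is below
    ``f_max``. Energy is monotone non-increasing across accepted steps.
    Raises ConvergenceError when ``max_steps`` is exhausted.
    """
    calc.require("energy", "forces")
    x = s.positions.reshape(-1).astype(float).copy()
    res = calc.evaluate(Structure3D(s.atomic_numbers, x.reshape(-1, 3),
                                    s.state))
    n_steps = 0

    if pre_opt:
        etol = constants.PREOPT_ETOL_PER_ATOM * s.n_atoms
        for _ in range(max_steps):
            if _max_atom_force(res.forces) < f_max:
                break  # already converged; nothing to pre-optimize
            g = -res.forces.reshape(-1)
            gnorm = np.linalg.norm(g)
            if gnorm < 1e-12:
                break
            step = _backtrack(calc, s, x, res.energy, g, -g / max(gnorm, 1.0))
            if step is None:
                break
            x_new, res_new = step
            n_steps += 1
            if abs(res_new.energy - res.energy) < etol:
                x, res = x_new, res_new
                break
            x, res = x_new, res_new

    n = x.size
    h_inv = np.eye(n)
    g = -res.forces.reshape(-1)
    for _ in range(max_steps):
        if _max_atom_force(res.forces) < f_max:
            structure = Structure3D(s.atomic_numbers, x.reshape(-1, 3),
                                    s.state, s.graph_key, s.conformer_key)
            return Conformer(structure, res.energy, n_steps,
                             _max_atom_force(res.forces))
        direction = -h_inv @ g
        # trust-region style cap on the raw step
        dmax = np.abs(direction).max()
        if dmax > 0.3:
            direction *= 0.3 / dmax
        step = _backtrack(calc, s, x, res.energy, g, direction)
        if step is None:
            h_inv = np.eye(n)  # reset curvature and try steepest descent
            step = _backtrack(calc, s, x, res.energy, g, -g)
            if step is None:
                raise ConvergenceError("line search failed")
        x_new, res_new = step
        g_new = -res_new.forces.reshape(-1)
        sk = x_new - x
        yk = g_new - g
        ys = float(yk @ sk)
        if ys > 1e-12:
            rho = 1.0 / ys
            ident = np.eye(n)
            v = ident - rho * np.outer(sk, yk)
            h_inv = v @ h_inv @ v.T + rho * np.outer(sk, sk)
        x, res, g = x_new, res_new, g_new
        n_steps += 1
    raise ConvergenceError(
        f"no convergence within {max_steps} steps "
        f"(fmax={_max_atom_force(res.forces):.3g})")


# ---------------------------------------------------------------------------
# rotatable bonds and torsion driving
# ---------------------------------------------------------------------------

def find_rotatable_bonds(g: ChemicalGraph) -> list[tuple[int, int]]:
    """Heavy-atom single bonds eligible for torsion search.

    Acyclic single bonds where both ends carry at least one further
    substituent (hydrogens count, so R-OH and R-CH3 qualify), plus ring
    single bonds except in three-membered rings.
    """
    mol = g.to_mol()
    ring_info = mol.GetRingInfo()
    out = []
    for b in mol.GetBonds():
        if b.GetBondType() != Chem.BondType.SINGLE:
            continue
        i, j = b.GetBeginAtom(), b.GetEndAtom()
        if i.GetAtomicNum() == 1 or j.GetAtomicNum() == 1:
            continue
        if b.IsInRing():
            sizes = [len(r) for r in ring_info.BondRings()
                     if b.GetIdx() in r]
            if sizes and min(sizes) == 3:
                continue
            out.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
            continue
        if (i.GetDegree() + i.GetTotalNumHs() > 1
                and j.GetDegree() + j.GetTotalNumHs() > 1):
            out.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
    return out


def _graph_with_hs(g: ChemicalGraph) -> nx.Graph:
    mol = g.to_mol(add_hs=True)
    gx = nx.Graph()
    for a in mol.GetAtoms():
        gx.add_node(a.GetIdx(), z=a.GetAtomicNum())
    for b in mol.GetBonds():
        gx.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    return gx


def _side_atoms(gx: nx.Graph, i: int, j: int) -> set[int] | None:
    """Atoms on the j side of bond (i, j); None if the bond is in a cycle."""
    h = gx.copy()
    h.remove_edge(i, j)
    comp = nx.node_connected_component(h, j)
    return None if i in comp else comp


def dihedral_angle(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return math.atan2(y, x)


def set_torsion(positions: np.ndarray, gx: nx.Graph, a: int, i: int, j: int,
                b: int, angle: float) -> np.ndarray:
    """Rotate the j-side of acyclic bond (i, j) so dihedral a-i-j-b = angle."""
    side = _side_atoms(gx, i, j)
    if side is None:
        raise ValueError("cannot drive a ring bond")
    pos = positions.copy()
    current = dihedral_angle(pos[a], pos[i], pos[j], pos[b])
    delta = angle - current
    axis = pos[j] - pos[i]
    axis /= np.linalg.norm(axis)
    c, s_ = math.cos(delta), math.sin(delta)
    kx = np.array([[0, -axis[2], axis[1]],
                   [axis[2], 0, -axis[0]],
                   [-axis[1], axis[0], 0]])
    rot = np.eye(3) + s_ * kx + (1 - c) * kx @ kx
    moving = sorted(side - {j})
    pos[moving] = (pos[moving] - pos[j]) @ rot.T + pos[j]
    return pos


# ---------------------------------------------------------------------------
# RMSD machinery
# ---------------------------------------------------------------------------

def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum RMSD of q onto p over proper rotations + translation."""
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    c = qc.T @ pc
    u, s_, vt = np.linalg.svd(c)
    d = np.sign(np.linalg.det(u @ vt))
    s_ = s_.copy()
    s_[-1] *= d
    e0 = (pc ** 2).sum() + (qc ** 2).sum()
    msd = max((e0 - 2.0 * s_.sum()) / len(p), 0.0)
    return math.sqrt(msd)


def graph_automorphisms(g: ChemicalGraph, max_heavy_exact: int = 12,
                        limit: int = 20000) -> list[np.ndarray]:
    """Element-preserving automorphisms of the H-explicit molecular graph.

    Exact enumeration up to ``max_heavy_exact`` heavy atoms; beyond that a
    heavy-atom-colour approximation is used with a logged warning.
    """
    gx = _graph_with_hs(g)
    if g.n_heavy > max_heavy_exact:
        log.warning("more than %d heavy atoms: automorphism search uses "
                    "heavy-only colouring approximation", max_heavy_exact)
        for n, d in gx.nodes(data=True):
            d["z"] = min(d["z"], 2)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        gx, gx, node_match=lambda a, b: a["z"] == b["z"])
    n = gx.number_of_nodes()
    perms = []
    for mapping in matcher.isomorphisms_iter():
        perm = np.array([mapping[k] for k in range(n)])
        perms.append(perm)
        if len(perms) >= limit:
            log.warning("automorphism enumeration truncated at %d", limit)
            break
    return perms


def symmetry_rmsd(p: np.ndarray, q: np.ndarray,
                  automorphisms: list[np.ndarray],
                  include_mirror: bool = True) -> float:
    """Min RMSD over graph automorphisms, superposition, and reflection."""
    best = math.inf
    q_mirror = q * np.array([-1.0, 1.0, 1.0]) if include_mirror else None
    for perm in automorphisms:
        best = min(best, kabsch_rmsd(p, q[perm]))
        if include_mirror:
            best = min(best, kabsch_rmsd(p, q_mirror[perm]))
    return best


def deduplicate(confs: list[Conformer], g: ChemicalGraph,
                rmsd_threshold: float = constants.RMSD_DUPLICATE_A,
                include_mirror: bool = True) -> list[Conformer]:
    """Greedy keep-first clustering under symmetry-aware (mirror-including)
    RMSD; all conformers must share the atom ordering of ``g``."""
    if not confs:
        return []
    n_atoms = {c.structure.n_atoms for c in confs}
    if len(n_atoms) != 1:
        raise ValueError("inconsistent atom counts")
    autos = graph_automorphisms(g)
    kept: list[Conformer] = []
    for c in confs:
        dup = False
        for k in kept:
            if symmetry_rmsd(k.positions, c.positions, autos,
                             include_mirror) < rmsd_threshold:
                dup = True
                break
        if not dup:
            c.cluster_id = len(kept)
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# genetic conformer search
# ---------------------------------------------------------------------------

def is_local_minimum(calc: Calculator, s: Structure3D,
                     tol: float = 1e-6) -> bool:
    """Internal-curvature check for calculators exposing a Hessian.

    Drops the 6 (5 for near-linear) smallest-|eigenvalue| rigid modes and
    requires the rest positive. Calculators without ``analytic_hessian``
    are not filtered here (the sampling stage's stencil check covers them).
    """
    if not hasattr(calc, "analytic_hessian"):
        return True
    hess = calc.analytic_hessian(s.positions)
    evals = np.linalg.eigvalsh(0.5 * (hess + hess.T))
    n_rigid = 6 if s.n_atoms > 2 else 5
    internal = evals[np.argsort(np.abs(evals))[n_rigid:]]
    return bool(internal.size == 0 or internal.min() > tol)


def _torsion_refs(gx: nx.Graph, bonds):
    """(a, i, j, b) reference quadruples for driveable (acyclic) bonds."""
    refs = []
    for i, j in bonds:
        if _side_atoms(gx, i, j) is None:
            continue  # ring bond: relaxation only, no direct driving
        a = min(n for n in gx.neighbors(i) if n != j)
        b = min(n for n in gx.neighbors(j) if n != i)
        refs.append((a, i, j, b))
    return refs


def conformer_search(c0: Conformer, g: ChemicalGraph, calc: Calculator,
                     n_conformers: int = 10, seed: int = 0,
                     generations: int = 30,
                     rmsd_threshold: float = constants.RMSD_DUPLICATE_A,
                     f_max: float = constants.FMAX_DEFAULT
                     ) -> list[Conformer]:
    """Genetic search over torsion vectors around rotatable bonds.

    Candidates are torsion vectors applied to the optimized input geometry;
    every evaluated candidate is re-optimized with ``local_optimize`` and
    archived. Fitness is structural diversity (min pairwise RMSD). The
    deduplicated archive is returned (the input conformer's basin included).
    """
    rng = np.random.default_rng(seed)
    gx = _graph_with_hs(g)
    bonds = find_rotatable_bonds(g)
    refs = _torsion_refs(gx, bonds)
    if not refs:
        return deduplicate([c0], g, rmsd_threshold)

    base = c0.positions
    grid = np.radians([60.0, 120.0, 180.0, -60.0, -120.0, 0.0])

    def express(torsions):
        pos = base
        for (a, i, j, b), angle in zip(refs, torsions):
            pos = set_torsion(pos, gx, a, i, j, b, angle)
        return pos

    def optimize(torsions):
        pos = express(torsions)
        s = Structure3D(c0.structure.atomic_numbers, pos, c0.structure.state,
                        c0.structure.graph_key)
        try:
            return local_optimize(s, calc, f_max=f_max)
        except (ConvergenceError, FloatingPointError):
            return None

    current = np.array([dihedral_angle(base[a], base[i], base[j], base[b])
                        for a, i, j, b in refs])
    population = [current]
    while len(population) < n_conformers:
        population.append(rng.choice(grid, size=len(refs)))

    archive: list[Conformer] = [c0]
    archive_pos = [c0.positions]
    seen: set[tuple] = set()

    def consider(torsions):
        key = tuple(np.round(np.degrees(torsions) / 15.0).astype(int)
                    % 24)
        if key in seen:
            return
        seen.add(key)
        conf = optimize(np.asarray(torsions, dtype=float))
        if conf is not None and is_local_minimum(calc, conf.structure):
            archive.append(conf)
            archive_pos.append(conf.positions)

    for member in population:
        consider(member)

    for _ in range(generations):
        children = []
        for _ in range(n_conformers):
            pa, pb = rng.integers(0, len(population), size=2)
            mask = rng.integers(0, 2, size=len(refs)).astype(bool)
            child = np.where(mask, population[pa], population[pb])
            if rng.random() < 0.7:
                child = child.copy()
                child[rng.integers(0, len(refs))] = rng.choice(grid)
            children.append(child)
            consider(child)
        # diversity selection on the torsion population via plain RMSD
        pool = population + children
        scored = []
        for t in pool:
            pos = express(t)
            score = min((kabsch_rmsd(pos, other) for other in archive_pos),
                        default=math.inf)
            scored.append((score, rng.random(), t))
        scored.sort(key=lambda x: (-x[0], x[1]))
        population = [t for _, _, t in scored[:n_conformers]]

    return deduplicate(archive, g, rmsd_threshold)


def embed_distance_checks(s: Structure3D, g: ChemicalGraph) -> bool:
    """Post-conditions of embedding: no clashes, sane bonded distances."""
    pos = s.positions
    n = s.n_atoms
    dists = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    if n > 1 and dists[np.triu_indices(n, 1)].min() <= 0.3:
        return False
    mol = g.to_mol(add_hs=True)
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        ref = (covalent_radius(int(s.atomic_numbers[i]))
               + covalent_radius(int(s.atomic_numbers[j])))
        if not 0.5 * ref < dists[i, j] < 1.5 * ref:
            return False
    return True
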