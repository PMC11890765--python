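"""Desk-scale fixture generators: toy molecules with known mode counts and
analytic Hessians, and a planted-defect corpus for the outlier filters."""

from __future__ import annotations

import numpy as np

from .calculator import (BondOrderPair, HarmonicBond, Structure3D,
                         ToyForceField, covalent_radius)
from .chemgraph import ChemicalGraph


def toy_diatomic(k: float = 30.0, r0: float | None = None,
                 depth: float = 3.0, z=(1, 1)) -> tuple[ToyForceField,
                                                        Structure3D]:
    """Single harmonic bond along x; 1 internal mode (3N-5)."""
    if r0 is None:
        r0 = covalent_radius(z[0]) + covalent_radius(z[1])
    ff = ToyForceField(atomic_numbers=np.array(z))
    ff.terms.append(HarmonicBond(0, 1, k, r0, depth))
    ff.bond_order_pairs.append(BondOrderPair(0, 1, 1.0, r0, 2.0))
    s = Structure3D(np.array(z), np.array([[0.0, 0.0, 0.0],
                                           [r0, 0.0, 0.0]]))
    return ff, s


def toy_water() -> tuple[ToyForceField, Structure3D, ChemicalGraph]:
    """Graph-derived toy water at an embedded (non-optimized) geometry."""
    g = ChemicalGraph.from_smiles("O")
    ff = ToyForceField.from_graph(g)
    r_oh = covalent_radius(8) + covalent_radius(1)
    theta = np.radians(109.4712206)
    pos = np.array([
        [0.0, 0.0, 0.0],
        [r_oh, 0.0, 0.0],
        [r_oh * np.cos(theta), r_oh * np.sin(theta), 0.0],
    ])
    s = Structure3D(ff.atomic_numbers, pos)
    return ff, s, g


def toy_linear_triatomic(r0: float = 1.16, z=(8, 6, 8),
                         force_constants=(5.0, 8.0, 20.0, 30.0)):
    """Exactly quadratic linear ABA molecule with 3N-5 = 4 internal modes.

    Pair-distance potentials have no bending stiffness at a collinear
    geometry, so this fixture constructs the mass-weighted Hessian
    directly: zero on the 5 rigid translation/rotation directions and the
    given positive force constants on an orthonormal complement.
    """
    from .calculator import QuadraticCalculator, atomic_mass

    zarr = np.array(z)
    pos = np.array([[-r0, 0.0, 0.0], [0.0, 0.0, 0.0], [r0, 0.0, 0.0]])
    masses = np.array([atomic_mass(int(zz)) for zz in zarr])
    sqrt_m = np.sqrt(np.repeat(masses, 3))
    n3 = 9

    rigid = []
    for axis in range(3):  # translations
        v = np.zeros((3, 3))
        v[:, axis] = 1.0
        rigid.append(v.reshape(-1) * sqrt_m)
    com = np.average(pos, axis=0, weights=masses)
    for omega in (np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0])):
        v = np.cross(omega, pos - com)  # rotations about y and z
        rigid.append(v.reshape(-1) * sqrt_m)
    rigid = np.array(rigid).T  # (9, 5)

    # deterministic orthonormal completion
    seed = np.arange(1, n3 * n3 + 1, dtype=float).reshape(n3, n3)
    seed = np.sin(seed)
    basis, _ = np.linalg.qr(np.hstack([rigid, seed]))
    internal = basis[:, 5:9]
    k_mw = internal @ np.diag(force_constants) @ internal.T
    hessian = k_mw * np.outer(sqrt_m, sqrt_m)
    calc = QuadraticCalculator(zarr, pos.reshape(-1), hessian)
    return calc, Structure3D(zarr, pos)


def planted_defect_corpus(rng: np.random.Generator, n_clean: int = 40,
                          n_each_defect: int = 10):
    """Synthetic calculation inputs with known outlier labels.

    Starts from a clean toy diatomic record and plants, per defect class:
    compressed pairs (normalized distance < 0.5), oversized forces
    (> 0.5 E_h/a0), sign-flipped (positive) formation energies, and
    stretched bonds (bond order < 0.25). Returns a list of dicts with keys
    energy, forces, bond_orders, structure, graph, reference, planted.
    """
    from . import constants
    g = ChemicalGraph.from_smiles("[H][H]")
    r0 = 2.0 * covalent_radius(1)
    reference = {1: 0.0}
    corpus = []

    def record(positions, energy, force_scale=0.0, bo=1.0, planted=False,
               forces=None):
        n = len(positions)
        if forces is None:
            forces = rng.standard_normal((n, 3)) * force_scale
        forces = np.asarray(forces, dtype=float)
        bond_orders = np.zeros((n, n))
        bond_orders[0, 1] = bond_orders[1, 0] = bo
        s = Structure3D(np.array([1, 1]), np.asarray(positions, dtype=float))
        corpus.append({"energy": energy, "forces": forces,
                       "bond_orders": bond_orders, "structure": s,
                       "graph": g, "reference": reference,
                       "planted": planted})

    for _ in range(n_clean):
        jitter = 1.0 + 0.05 * rng.uniform(-1, 1)
        record([[0, 0, 0], [r0 * jitter, 0, 0]], energy=-3.0,
               force_scale=1e-3, bo=1.0, planted=False)
    for _ in range(n_each_defect):  # compressed pair
        record([[0, 0, 0], [0.4 * r0, 0, 0]], energy=-3.0, bo=1.0,
               planted=True)
    for _ in range(n_each_defect):  # huge force
        fmag = (1.2 + rng.uniform(0, 1)) * constants.FORCE_OUTLIER_EV_A
        record([[0, 0, 0], [r0, 0, 0]], energy=-3.0, bo=1.0, planted=True,
               forces=[[fmag, 0, 0], [-fmag, 0, 0]])
    for _ in range(n_each_defect):  # positive formation energy
        record([[0, 0, 0], [r0, 0, 0]], energy=+1.0, bo=1.0, planted=True)
    for _ in range(n_each_defect):  # dissociated bond
        record([[0, 0, 0], [2.5 * r0, 0, 0]], energy=-3.0, bo=0.1,
               planted=True)
    order = rng.permutation(len(corpus))
    return [corpus[i] for i in order]
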