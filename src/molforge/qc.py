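"""Quality checks: bond-order consistency, the four outlier criteria,
formation energy, and normalized principal-moment-of-inertia shape
descriptors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants
from .calculator import Structure3D, atomic_mass, covalent_radius
from .chemgraph import ChemicalGraph

_EXPECTED_ORDER = {"single": 1.0, "aromatic": 1.5, "double": 2.0,
                   "triple": 3.0}


@dataclass(frozen=True)
class OutlierThresholds:
    """Outlier criteria; defaults follow the published filter settings."""

    formation_energy_ev: float = constants.FORMATION_ENERGY_OUTLIER_EV
    max_force_ev_a: float = constants.FORCE_OUTLIER_EV_A
    min_norm_distance: float = constants.NORM_DISTANCE_OUTLIER
    bond_order_dissociation: float = constants.BOND_ORDER_DISSOCIATION
    force_norm: str = "euclidean"  # or "max_component"


@dataclass
class QCFlags:
    bond_order_consistent: bool = True
    positive_formation_energy: bool = False
    max_force_exceeded: bool = False
    min_norm_distance_low: bool = False
    bond_dissociated: bool = False

    @property
    def is_outlier(self) -> bool:
        return (self.positive_formation_energy or self.max_force_exceeded
                or self.min_norm_distance_low or self.bond_dissociated)

    def to_dict(self) -> dict:
        return {
            "bond_order_consistent": self.bond_order_consistent,
            "positive_formation_energy": self.positive_formation_energy,
            "max_force_exceeded": self.max_force_exceeded,
            "min_norm_distance_low": self.min_norm_distance_low,
            "bond_dissociated": self.bond_dissociated,
            "is_outlier": self.is_outlier,
        }


def bond_order_consistency(g: ChemicalGraph, bond_orders: np.ndarray,
                           tol: float = constants.BOND_ORDER_CONSISTENCY_TOL,
                           heavy_only: bool = False) -> bool:
    """True iff every bonded pair's computed order is within ``tol`` of the
    order expected from graph connectivity (1 / 1.5 / 2 / 3).

    ``bond_orders`` is indexed like ``g.to_mol(add_hs=True)`` unless
    ``heavy_only``; a hard filter applied to conformers, not an outlier flag.
    """
    bo = np.asarray(bond_orders, dtype=float)
    mol = g.to_mol(add_hs=not heavy_only)
    if bo.shape != (mol.GetNumAtoms(),) * 2:
        raise ValueError("bond-order matrix does not match atom count")
    for b in mol.GetBonds():
        expected = _EXPECTED_ORDER.get(b.GetBondType().name.lower(),
                                       b.GetBondTypeAsDouble())
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if abs(bo[i, j] - expected) > tol:
            return False
    return True


def formation_energy(e_total: float, atomic_numbers,
                     reference: dict[int, float]) -> float:
    """Total energy minus summed isolated-atom reference energies."""
    total_ref = 0.0
    for z in np.asarray(atomic_numbers, dtype=int):
        if int(z) not in reference:
            raise KeyError(f"no reference energy for element Z={int(z)}")
        total_ref += reference[int(z)]
    return float(e_total) - total_ref


def default_radii(atomic_numbers) -> np.ndarray:
    return np.array([covalent_radius(int(z)) for z in atomic_numbers])


def normalized_min_distance(s: Structure3D,
                            radii: np.ndarray | None = None) -> float:
    """min over pairs of r_ij / (R_i + R_j); +inf for single atoms."""
    if s.n_atoms < 2:
        return float("inf")
    r = default_radii(s.atomic_numbers) if radii is None \
        else np.asarray(radii, dtype=float)
    diff = s.positions[:, None, :] - s.positions[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    rsum = r[:, None] + r[None, :]
    iu = np.triu_indices(s.n_atoms, 1)
    return float((dist[iu] / rsum[iu]).min())


def _max_atom_force(forces: np.ndarray, norm: str) -> float:
    forces = np.asarray(forces, dtype=float)
    if norm == "euclidean":
        return float(np.sqrt((forces ** 2).sum(axis=1)).max())
    if norm == "max_component":
        return float(np.abs(forces).max())
    raise ValueError(f"unknown force norm: {norm!r}")


def flag_outlier(energy: float, forces: np.ndarray, bond_orders: np.ndarray,
                 s: Structure3D, g: ChemicalGraph,
                 reference: dict[int, float],
                 thresholds: OutlierThresholds | None = None,
                 radii: np.ndarray | None = None,
                 bo_tol: float = constants.BOND_ORDER_CONSISTENCY_TOL
                 ) -> QCFlags:
    """Evaluate all four outlier criteria independently.

    The bond-dissociation criterion checks only pairs covalently bonded in
    the parent graph; ``is_outlier`` is the OR of the four criteria.
    """
    th = thresholds if thresholds is not None else OutlierThresholds()
    flags = QCFlags()
    e_form = formation_energy(energy, s.atomic_numbers, reference)
    flags.positive_formation_energy = e_form > th.formation_energy_ev
    flags.max_force_exceeded = (
        _max_atom_force(forces, th.force_norm) > th.max_force_ev_a)
    flags.min_norm_distance_low = (
        normalized_min_distance(s, radii) < th.min_norm_distance)

    bo = np.asarray(bond_orders, dtype=float)
    mol = g.to_mol(add_hs=True)
    dissociated = False
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if bo[i, j] < th.bond_order_dissociation:
            dissociated = True
            break
    flags.bond_dissociated = dissociated
    flags.bond_order_consistent = bond_order_consistency(g, bo, tol=bo_tol)
    return flags


def npr(s: Structure3D, masses: np.ndarray | None = None
        ) -> tuple[float, float]:
    """Normalized principal-moment ratios (I1/I3, I2/I3).

    Archetypes: rod (0, 1), disc (0.5, 0.5), sphere (1, 1).
    """
    if s.n_atoms < 2:
        raise ValueError("need at least two atoms")
    m = (np.array([atomic_mass(int(z)) for z in s.atomic_numbers])
         if masses is None else np.asarray(masses, dtype=float))
    x = s.positions - np.average(s.positions, axis=0, weights=m)
    inertia = np.zeros((3, 3))
    for mi, xi in zip(m, x):
        inertia += mi * ((xi @ xi) * np.eye(3) - np.outer(xi, xi))
    moments = np.sort(np.linalg.eigvalsh(inertia))
    if moments[2] <= 0:
        raise ValueError("degenerate inertia tensor (coincident atoms)")
    return float(moments[0] / moments[2]), float(moments[1] / moments[2])
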