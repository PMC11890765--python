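"""Internal-coordinate (Z-matrix) representation.

Construction order is breadth-first from the highest-degree heavy atom;
rebuild uses the standard NeRF placement. Only used by the sampling step,
which falls back to Cartesian displacement when construction fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class ZMatrixError(RuntimeError):
    pass


@dataclass(frozen=True)
class ZMatrixTemplate:
    """Placement order and reference atoms; row k places atom ``order[k]``
    with distance to ``ref_bond``, angle via ``ref_angle``, dihedral via
    ``ref_dihedral`` (indices into the original atom numbering)."""

    order: tuple
    ref_bond: tuple      # len N, entry None for the first atom
    ref_angle: tuple
    ref_dihedral: tuple

    @property
    def n_atoms(self) -> int:
        return len(self.order)


def connectivity_from_distances(z: np.ndarray, positions: np.ndarray,
                                scale: float = 1.3) -> dict[int, set[int]]:
    from .calculator import covalent_radius
    n = len(z)
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            cutoff = scale * (covalent_radius(int(z[i]))
                              + covalent_radius(int(z[j])))
            if np.linalg.norm(positions[i] - positions[j]) < cutoff:
                adj[i].add(j)
                adj[j].add(i)
    return adj


def build_template(z: np.ndarray, adj: dict[int, set[int]]) -> ZMatrixTemplate:
    n = len(z)
    if n < 2:
        raise ZMatrixError("need at least two atoms")
    heavy = [i for i in range(n) if z[i] > 1] or list(range(n))
    root = max(heavy, key=lambda i: (len(adj[i]), -i))

    order = [root]
    placed = {root}
    ref_bond = {root: None}
    queue = [root]
    while queue:
        cur = queue.pop(0)
        for nb in sorted(adj[cur], key=lambda a: (z[a] == 1, a)):
            if nb not in placed:
                placed.add(nb)
                order.append(nb)
                ref_bond[nb] = cur
                queue.append(nb)
    if len(order) != n:
        raise ZMatrixError("disconnected structure")

    pos_in_order = {a: k for k, a in enumerate(order)}
    ref_angle: dict[int, int | None] = {}
    ref_dihedral: dict[int, int | None] = {}
    for k, atom in enumerate(order):
        if k == 0:
            ref_angle[atom] = ref_dihedral[atom] = None
            continue
        b = ref_bond[atom]
        if k == 1:
            ref_angle[atom] = ref_dihedral[atom] = None
            continue
        a = ref_bond[b]
        if a is None or a == atom:
            a = next(x for x in order if x not in (atom, b)
                     and pos_in_order[x] < k)
        ref_angle[atom] = a
        if k == 2:
            ref_dihedral[atom] = None
            continue
        d = ref_bond[a]
        if d is None or d in (atom, b, a):
            d = next(x for x in order if x not in (atom, b, a)
                     and pos_in_order[x] < k)
        ref_dihedral[atom] = d
    return ZMatrixTemplate(
        order=tuple(order),
        ref_bond=tuple(ref_bond[a] for a in order),
        ref_angle=tuple(ref_angle[a] for a in order),
        ref_dihedral=tuple(ref_dihedral[a] for a in order),
    )


def _angle(p0, p1, p2) -> float:
    v0 = p0 - p1
    v1 = p2 - p1
    cosang = (v0 @ v1) / (np.linalg.norm(v0) * np.linalg.norm(v1))
    return math.acos(min(1.0, max(-1.0, cosang)))


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    return math.atan2(np.cross(b1, v) @ w, v @ w)


def cart_to_internal(positions: np.ndarray, tmpl: ZMatrixTemplate
                     ) -> np.ndarray:
    """Internal coordinate vector: (N-1) bonds, (N-2) angles, (N-3)
    dihedrals, concatenated in placement order. Length 3N-6."""
    p = np.asarray(positions, dtype=float)
    bonds, angles, dihedrals = [], [], []
    for k in range(1, tmpl.n_atoms):
        atom = tmpl.order[k]
        b = tmpl.ref_bond[k]
        bonds.append(float(np.linalg.norm(p[atom] - p[b])))
        if k >= 2:
            a = tmpl.ref_angle[k]
            angles.append(_angle(p[atom], p[b], p[a]))
        if k >= 3:
            d = tmpl.ref_dihedral[k]
            dihedrals.append(_dihedral(p[atom], p[b],
                                       p[tmpl.ref_angle[k]], p[d]))
    return np.array(bonds + angles + dihedrals)


def internal_to_cart(internals: np.ndarray, tmpl: ZMatrixTemplate
                     ) -> np.ndarray:
    """NeRF rebuild of Cartesian coordinates from internals (arbitrary
    rigid-body frame)."""
    n = tmpl.n_atoms
    nb, na = n - 1, max(n - 2, 0)
    bonds = internals[:nb]
    angles = internals[nb:nb + na]
    dihedrals = internals[nb + na:]
    if np.any(bonds <= 1e-3):
        raise ZMatrixError("non-positive bond length in rebuild")
    pos = np.zeros((n, 3))
    placed = {}
    for k in range(n):
        atom = tmpl.order[k]
        if k == 0:
            placed[atom] = np.zeros(3)
            continue
        b = placed[tmpl.ref_bond[k]]
        r = bonds[k - 1]
        if k == 1:
            placed[atom] = b + np.array([r, 0.0, 0.0])
            continue
        a = placed[tmpl.ref_angle[k]]
        theta = angles[k - 2]
        if k == 2:
            # in the xy-plane
            ba = a - b
            ba /= np.linalg.norm(ba)
            perp = np.array([-ba[1], ba[0], 0.0])
            if np.linalg.norm(perp) < 1e-8:
                perp = np.array([0.0, 1.0, 0.0])
            else:
                perp /= np.linalg.norm(perp)
            placed[atom] = b + r * (math.cos(theta) * ba
                                    + math.sin(theta) * perp)
            continue
        d = placed[tmpl.ref_dihedral[k]]
        phi = dihedrals[k - 3]
        bc = b - a
        bc /= np.linalg.norm(bc)
        ab = a - d
        nvec = np.cross(ab, bc)
        norm = np.linalg.norm(nvec)
        if norm < 1e-10:
            raise ZMatrixError("collinear reference atoms")
        nvec /= norm
        m = np.cross(nvec, bc)
        d2 = np.array([-r * math.cos(theta),
                       r * math.sin(theta) * math.cos(phi),
                       r * math.sin(theta) * math.sin(phi)])
        placed[atom] = b + np.column_stack([bc, m, nvec]) @ d2
        if not np.all(np.isfinite(placed[atom])):
            raise ZMatrixError("non-finite rebuild")
    for atom, xyz in placed.items():
        pos[atom] = xyz
    return pos


def wrap_dihedrals(delta: np.ndarray, n_atoms: int) -> np.ndarray:
    """Wrap the dihedral block of an internal-coordinate difference vector
    into (-pi, pi]."""
    out = delta.copy()
    start = (n_atoms - 1) + max(n_atoms - 2, 0)
    d = out[start:]
    out[start:] = -((-d + math.pi) % (2.0 * math.pi) - math.pi)
    return out
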