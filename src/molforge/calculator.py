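"""Pluggable potential-energy calculators and the analytic toy force field.

The toy force field combines pair-distance terms — harmonic bonds with a
well-depth offset, harmonic 1-3 terms standing in for angle bending, and
exponential nonbonded repulsion — with proper 4-body periodic cosine
torsions (3-fold around single bonds, 2-fold around double bonds). Forces
are fully analytic; Hessians are exact (closed-form pair blocks plus
complex-step differentiation of the analytic torsion gradient).
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chemgraph import ChemicalGraph, ElectronicState

_PT = Chem.GetPeriodicTable()

# Pauling electronegativities for the toy partial-charge model
_ELECTRONEGATIVITY = {
    1: 2.20, 5: 2.04, 6: 2.55, 7: 3.04, 8: 3.44, 9: 3.98,
    14: 1.90, 15: 2.19, 16: 2.58, 17: 3.16, 34: 2.55, 35: 2.96, 53: 2.66,
}


def covalent_radius(z: int) -> float:
    return _PT.GetRcovalent(z)


def atomic_mass(z: int) -> float:
    return _PT.GetAtomicWeight(z)


@dataclass
class Structure3D:
    """Atomic numbers + Cartesian coordinates (Angstrom) + electronic state."""

    atomic_numbers: np.ndarray
    positions: np.ndarray
    state: ElectronicState = ElectronicState(0, 1)
    graph_key: str | None = None
    conformer_key: str | None = None

    def __post_init__(self):
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.atomic_numbers.size < 1:
            raise ValueError("structure needs at least one atom")
        if self.positions.shape != (self.atomic_numbers.size, 3):
            raise ValueError("positions must have shape (N, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if np.any(self.atomic_numbers < 1):
            raise ValueError("atomic numbers must be >= 1")

    @property
    def n_atoms(self) -> int:
        return int(self.atomic_numbers.size)

    @property
    def masses(self) -> np.ndarray:
        return np.array([atomic_mass(int(z)) for z in self.atomic_numbers])

    def copy(self) -> "Structure3D":
        return Structure3D(self.atomic_numbers.copy(), self.positions.copy(),
                           self.state, self.graph_key, self.conformer_key)


@dataclass
class CalcResult:
    energy: float
    forces: np.ndarray | None = None
    bond_orders: np.ndarray | None = None
    charges: np.ndarray | None = None


class CapabilityError(RuntimeError):
    pass


class Calculator(ABC):
    """Contract: energy/forces (and optionally bond orders, charges)."""

    capabilities: frozenset = frozenset({"energy", "forces"})

    @abstractmethod
    def evaluate(self, s: Structure3D) -> CalcResult:
        ...

    def require(self, *caps: str) -> None:
        missing = set(caps) - set(self.capabilities)
        if missing:
            raise CapabilityError(
                f"{type(self).__name__} lacks capabilities: {sorted(missing)}")


# ---------------------------------------------------------------------------
# pair terms: scalar functions of one interatomic distance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonicBond:
    i: int
    j: int
    k: float
    r0: float
    depth: float = 0.0

    def value(self, r):
        d = r - self.r0
        return 0.5 * self.k * d * d - self.depth, self.k * d, self.k


@dataclass(frozen=True)
class MorseBond:
    i: int
    j: int
    depth: float
    a: float
    r0: float

    def value(self, r):
        x = math.exp(-self.a * (r - self.r0))
        e = self.depth * (1.0 - x) ** 2 - self.depth
        de = 2.0 * self.depth * self.a * (x - x * x)
        d2e = 2.0 * self.depth * self.a * self.a * (2.0 * x * x - x)
        return e, de, d2e


def _cnorm(v):
    """Analytic (non-conjugating) vector norm, safe under complex step."""
    return np.sqrt((v * v).sum())


@dataclass(frozen=True)
class CosineTorsion:
    """Periodic 4-body torsion: E = kt * (1 + cos(n*phi - phase)).

    n=3, phase=pi gives staggered minima at +-60/180 deg around single
    bonds; n=2, phase=pi keeps double bonds planar (minima at 0/180 deg).
    cos/sin of multiples of phi are built algebraically from cross and dot
    products, so both energy and gradient are analytic compositions —
    which lets the Hessian be taken by complex-step differentiation of the
    gradient with no truncation error.
    """

    a: int
    b: int
    c: int
    d: int
    kt: float
    n: int = 3
    phase: float = math.pi

    @property
    def atoms(self):
        return (self.a, self.b, self.c, self.d)

    def _geometry(self, x):
        b1 = x[self.b] - x[self.a]
        b2 = x[self.c] - x[self.b]
        b3 = x[self.d] - x[self.c]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        ln1, ln2, lb2 = _cnorm(n1), _cnorm(n2), _cnorm(b2)
        cosp = (n1 @ n2) / (ln1 * ln2)
        sinp = (np.cross(n1, n2) @ b2) / (ln1 * ln2 * lb2)
        return b1, b2, b3, n1, n2, ln1, ln2, lb2, cosp, sinp

    def _cos_sin_n(self, cosp, sinp):
        if self.n == 3:
            cosn = 4.0 * cosp ** 3 - 3.0 * cosp
            sinn = sinp * (3.0 - 4.0 * sinp * sinp)
        elif self.n == 2:
            cosn = 2.0 * cosp * cosp - 1.0
            sinn = 2.0 * sinp * cosp
        else:
            raise ValueError("only n in {2, 3} supported")
        return cosn, sinn

    def energy(self, x):
        *_, cosp, sinp = self._geometry(x)
        cosn, sinn = self._cos_sin_n(cosp, sinp)
        cp, sp = math.cos(self.phase), math.sin(self.phase)
        return self.kt * (1.0 + cosn * cp + sinn * sp)

    def gradient(self, x):
        """dE/dx for the four atoms, shape (4, 3); complex-step safe."""
        b1, b2, b3, n1, n2, ln1, ln2, lb2, cosp, sinp = self._geometry(x)
        cp, sp = math.cos(self.phase), math.sin(self.phase)
        cosn, sinn = self._cos_sin_n(cosp, sinp)
        # dE/dphi; d(cos n phi)/dphi = -n sin(n phi), etc.
        de_dphi = self.kt * self.n * (-sinn * cp + cosn * sp)
        # standard dihedral derivatives (sum over atoms is zero)
        dphi_da = -(lb2 / (ln1 * ln1)) * n1
        dphi_dd = (lb2 / (ln2 * ln2)) * n2
        f1 = (b1 @ b2) / (lb2 * lb2)
        f3 = (b3 @ b2) / (lb2 * lb2)
        dphi_db = -(1.0 + f1) * dphi_da + f3 * dphi_dd
        dphi_dc = f1 * dphi_da - (1.0 + f3) * dphi_dd
        return de_dphi * np.stack([dphi_da, dphi_db, dphi_dc, dphi_dd])


@dataclass(frozen=True)
class Repulsion:
    i: int
    j: int
    amplitude: float
    rho: float

    def value(self, r):
        e = self.amplitude * math.exp(-r / self.rho)
        return e, -e / self.rho, e / (self.rho * self.rho)


@dataclass(frozen=True)
class BondOrderPair:
    """Distance-decay bond order: n*exp(-alpha*(r - r0)), clipped."""

    i: int
    j: int
    nominal: float
    r0: float
    alpha: float

    def order(self, r):
        bo = self.nominal * math.exp(-self.alpha * (r - self.r0))
        return float(np.clip(bo, 0.0, self.nominal + 1.0))


# ---------------------------------------------------------------------------
# toy force field
# ---------------------------------------------------------------------------

_ORDER_SCALE = {1.0: 1.00, 1.5: 0.93, 2.0: 0.87, 3.0: 0.78}


def _ideal_angle(mol, center: Chem.Atom) -> float:
    """VSEPR-lite ideal angle (radians) at a central atom."""
    orders = [b.GetBondTypeAsDouble() for b in center.GetBonds()]
    degree = len(orders)
    if degree == 2 and sum(orders) >= 4.0:
        return math.pi  # cumulated double bonds or a triple bond: linear
    if degree == 3 and (max(orders) >= 2.0 or center.GetIsAromatic()):
        return math.radians(120.0)
    return math.radians(109.4712206)


@dataclass
class ToyForceField(Calculator):
    """Analytic stand-in for a semi-empirical engine, derived from a graph."""

    atomic_numbers: np.ndarray
    terms: list = field(default_factory=list)      # pair-distance terms
    torsions: list = field(default_factory=list)   # 4-body cosine terms
    bond_order_pairs: list = field(default_factory=list)
    capabilities: frozenset = frozenset(
        {"energy", "forces", "bond_orders", "partial_charges"})
    charges_: np.ndarray | None = None

    # --- construction -----------------------------------------------------

    @classmethod
    def from_graph(cls, g: ChemicalGraph, k_bond: float = 25.0,
                   k_angle: float = 4.0, k_torsion_heavy: float = 0.10,
                   k_torsion_h: float = 0.02, depth_per_order: float = 3.0,
                   repulsion_amplitude: float = 60.0,
                   repulsion_rho: float = 0.25, alpha: float = 2.0,
                   morse: bool = False, morse_width: float = 2.0
                   ) -> "ToyForceField":
        """Build all terms from the molecular graph (explicit hydrogens).

        Atom ordering matches ``g.to_mol(add_hs=True)``, the same ordering
        the embedding step uses. With ``morse=True`` bond terms become
        anharmonic Morse wells of equal depth and curvature.
        """
        mol = g.to_mol(add_hs=True)
        Chem.Kekulize(mol, clearAromaticFlags=True)
        z = np.array([a.GetAtomicNum() for a in mol.GetAtoms()])
        ff = cls(atomic_numbers=z)

        r0_bond = {}
        order = {}
        for b in mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            n = b.GetBondTypeAsDouble()
            scale = _ORDER_SCALE.get(n, 1.0)
            r0 = scale * (covalent_radius(int(z[i])) +
                          covalent_radius(int(z[j])))
            key = (min(i, j), max(i, j))
            r0_bond[key] = r0
            order[key] = n
            k = k_bond * n
            depth = depth_per_order * n
            if morse:
                # match harmonic curvature: k = 2*D*a^2
                a = math.sqrt(k / (2.0 * depth)) if morse_width <= 0 \
                    else morse_width
                ff.terms.append(MorseBond(i, j, depth, a, r0))
            else:
                ff.terms.append(HarmonicBond(i, j, k, r0, depth))
            ff.bond_order_pairs.append(
                BondOrderPair(i, j, n, r0, alpha))

        theta0 = {a.GetIdx(): _ideal_angle(mol, a) for a in mol.GetAtoms()
                  if a.GetDegree() >= 2}

        # 1-3 harmonic terms (angle surrogate via the law of cosines)
        pair13 = set()
        for atom in mol.GetAtoms():
            b = atom.GetIdx()
            nbrs = [n.GetIdx() for n in atom.GetNeighbors()]
            for x in range(len(nbrs)):
                for y in range(x + 1, len(nbrs)):
                    i, j = nbrs[x], nbrs[y]
                    r1 = r0_bond[(min(i, b), max(i, b))]
                    r2 = r0_bond[(min(j, b), max(j, b))]
                    th = theta0[b]
                    r13 = math.sqrt(
                        r1 * r1 + r2 * r2 - 2.0 * r1 * r2 * math.cos(th))
                    ff.terms.append(
                        HarmonicBond(i, j, k_angle, r13))
                    pair13.add((min(i, j), max(i, j)))

        # cosine torsions on all a-b-c-d chains (skipped around nearly
        # linear centres, where the dihedral is ill-defined)
        bonded = {tuple(sorted(k)) for k in r0_bond}
        for bond in mol.GetBonds():
            b, c = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if min(math.sin(theta0.get(b, 0.0)),
                   math.sin(theta0.get(c, 0.0))) < 0.1:
                continue
            central_order = order[(min(b, c), max(b, c))]
            for a_n in mol.GetAtomWithIdx(b).GetNeighbors():
                a = a_n.GetIdx()
                if a == c:
                    continue
                for d_n in mol.GetAtomWithIdx(c).GetNeighbors():
                    d = d_n.GetIdx()
                    if d == b or d == a:
                        continue
                    if central_order >= 2.0:
                        # keep double bonds planar (two-fold)
                        ff.torsions.append(CosineTorsion(
                            a, b, c, d, kt=0.5, n=2, phase=math.pi))
                    else:
                        kt = (k_torsion_heavy
                              if z[a] > 1 and z[d] > 1 else k_torsion_h)
                        ff.torsions.append(CosineTorsion(
                            a, b, c, d, kt=kt, n=3, phase=0.0))

        # nonbonded repulsion for all remaining pairs
        n = len(z)
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in bonded or (i, j) in pair13:
                    continue
                ff.terms.append(Repulsion(i, j, repulsion_amplitude,
                                          repulsion_rho))

        chi = np.array([_ELECTRONEGATIVITY.get(int(zz), 2.5) for zz in z])
        charges = np.zeros(n)
        for (i, j), nij in order.items():
            delta = 0.1 * nij * (chi[j] - chi[i])
            charges[i] += delta
            charges[j] -= delta
        ff.charges_ = charges
        return ff

    # --- evaluation -------------------------------------------------------

    def _check(self, s: Structure3D) -> None:
        if s.n_atoms != self.atomic_numbers.size or np.any(
                s.atomic_numbers != self.atomic_numbers):
            raise ValueError("structure does not match force-field topology")

    def energy_forces(self, positions: np.ndarray):
        x = np.asarray(positions, dtype=float)
        energy = 0.0
        forces = np.zeros_like(x)
        for t in self.terms:
            rij = x[t.i] - x[t.j]
            r = float(np.linalg.norm(rij))
            e, de, _ = t.value(r)
            energy += e
            f = -de * rij / r
            forces[t.i] += f
            forces[t.j] -= f
        for t in self.torsions:
            energy += t.energy(x)
            grad = t.gradient(x)
            for atom, gvec in zip(t.atoms, grad):
                forces[atom] -= gvec
        return energy, forces

    def evaluate(self, s: Structure3D) -> CalcResult:
        self._check(s)
        energy, forces = self.energy_forces(s.positions)
        if not (np.isfinite(energy) and np.all(np.isfinite(forces))):
            raise FloatingPointError("non-finite toy force field result")
        return CalcResult(
            energy=energy, forces=forces,
            bond_orders=self.bond_orders(s.positions),
            charges=None if self.charges_ is None else self.charges_.copy())

    def analytic_hessian(self, positions: np.ndarray) -> np.ndarray:
        """Exact second derivatives, assembled per pair term.

        Pair terms (E = f(r)) contribute closed-form blocks built from f',
        f'' and the unit separation vector. Torsion terms contribute blocks
        obtained by complex-step differentiation of their analytic gradient
        (step 1e-20, no truncation error — exact to machine precision).
        """
        x = np.asarray(positions, dtype=float)
        n = x.shape[0]
        hess = np.zeros((3 * n, 3 * n))
        eye = np.eye(3)
        for t in self.terms:
            rij = x[t.i] - x[t.j]
            r = float(np.linalg.norm(rij))
            _, de, d2e = t.value(r)
            u = rij / r
            block = d2e * np.outer(u, u) + (de / r) * (eye - np.outer(u, u))
            for (a, b, sign) in ((t.i, t.i, 1.0), (t.j, t.j, 1.0),
                                 (t.i, t.j, -1.0), (t.j, t.i, -1.0)):
                hess[3 * a:3 * a + 3, 3 * b:3 * b + 3] += sign * block
        h_step = 1e-20
        for t in self.torsions:
            xc = x.astype(complex)
            for atom in t.atoms:
                for axis in range(3):
                    xc[atom, axis] += 1j * h_step
                    dgrad = np.imag(t.gradient(xc)) / h_step
                    xc[atom, axis] -= 1j * h_step
                    col = 3 * atom + axis
                    for other, gvec in zip(t.atoms, dgrad):
                        hess[3 * other:3 * other + 3, col] += gvec
        return 0.5 * (hess + hess.T)

    def bond_orders(self, positions: np.ndarray) -> np.ndarray:
        x = np.asarray(positions, dtype=float)
        n = x.shape[0]
        bo = np.zeros((n, n))
        for p in self.bond_order_pairs:
            r = float(np.linalg.norm(x[p.i] - x[p.j]))
            bo[p.i, p.j] = bo[p.j, p.i] = p.order(r)
        return bo

    def isolated_atom_energy(self, z: int) -> float:
        """Toy reference energy of a free atom (no terms -> zero)."""
        return 0.0


class QuadraticCalculator(Calculator):
    """Exactly quadratic PES: E = e0 + 0.5 (x-x0)^T K (x-x0).

    The defining fixture for harmonic round-trip checks of the sampling
    scheme; K is typically a toy-force-field Hessian at its minimum.
    """

    capabilities = frozenset({"energy", "forces"})

    def __init__(self, atomic_numbers, x0: np.ndarray, hessian: np.ndarray,
                 e0: float = 0.0):
        self.atomic_numbers = np.asarray(atomic_numbers, dtype=int)
        self.x0 = np.asarray(x0, dtype=float).reshape(-1)
        self.hessian = np.asarray(hessian, dtype=float)
        self.e0 = e0
        n = self.x0.size
        if self.hessian.shape != (n, n):
            raise ValueError("hessian shape mismatch")

    def evaluate(self, s: Structure3D) -> CalcResult:
        dx = s.positions.reshape(-1) - self.x0
        g = self.hessian @ dx
        energy = self.e0 + 0.5 * float(dx @ g)
        return CalcResult(energy=energy, forces=-g.reshape(-1, 3))

    def analytic_hessian(self, positions) -> np.ndarray:
        return self.hessian.copy()


# ---------------------------------------------------------------------------
# plugin registry and consistency checks
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, type] = {}


def register_calculator(name: str, factory) -> None:
    _REGISTRY[name] = factory


def get_calculator_factory(name: str):
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown calculator: {name!r}; "
                       f"registered: {sorted(_REGISTRY)}") from None


register_calculator("toy", ToyForceField.from_graph)
register_calculator(
    "toy-morse", lambda g, **kw: ToyForceField.from_graph(g, morse=True, **kw))


def check_force_consistency(calc: Calculator, s: Structure3D,
                            step: float = 1e-5) -> float:
    """Max |F + dE/dx| via central differences; toy calculators must stay
    below 1e-4."""
    res = calc.evaluate(s)
    worst = 0.0
    flat = s.positions.reshape(-1).copy()
    for k in range(flat.size):
        xp = flat.copy()
        xm = flat.copy()
        xp[k] += step
        xm[k] -= step
        ep = calc.evaluate(Structure3D(
            s.atomic_numbers, xp.reshape(-1, 3), s.state)).energy
        em = calc.evaluate(Structure3D(
            s.atomic_numbers, xm.reshape(-1, 3), s.state)).energy
        num = -(ep - em) / (2.0 * step)
        worst = max(worst, abs(num - res.forces.reshape(-1)[k]))
    return worst
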