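"""Normal-mode analysis and off-equilibrium sampling.

Finite-difference Hessian (six-point stencil on forces), removal of rigid
translation/rotation modes, equipartition-based energy draws, random energy
partitioning over modes, and displacement application in mass-weighted
Cartesian or Z-matrix coordinates.

Conventions: force constants k_i are eigenvalues of the mass-weighted
Hessian (eV / (amu A^2)); displacements delta_i live in mass-weighted
coordinates (A * sqrt(amu)), so the Cartesian displacement is
M^(-1/2) sum_i delta_i q_i and the harmonic energy 0.5 k_i delta_i^2 is
exact on a quadratic surface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import constants, zmatrix
from .calculator import Calculator, Structure3D
from .conformer import Conformer

log = logging.getLogger(__name__)

# 6-point central first-derivative stencil: offsets and coefficients /(60 h)
_STENCIL_OFFSETS = (-3, -2, -1, 1, 2, 3)
_STENCIL_COEFFS = (-1.0, 9.0, -45.0, 45.0, -9.0, 1.0)

LINEAR_MOMENT_TOL = 1e-3  # amu A^2


class NotAMinimumError(RuntimeError):
    pass


@dataclass
class NormalModeSet:
    equilibrium: Structure3D
    masses: np.ndarray
    modes: np.ndarray            # (n_f, 3N), mass-weighted orthonormal rows
    force_constants: np.ndarray  # (n_f,), all positive
    n_f: int
    linear: bool


@dataclass
class SampleDraw:
    T: float
    E: float
    weights: np.ndarray
    mode_energies: np.ndarray
    displacements: np.ndarray
    coordinate_system: str

    def to_dict(self) -> dict:
        return {
            "T": self.T, "E": self.E,
            "weights": self.weights.tolist(),
            "mode_energies": self.mode_energies.tolist(),
            "displacements": self.displacements.tolist(),
            "coordinate_system": self.coordinate_system,
        }


def finite_difference_hessian(s: Structure3D, calc: Calculator,
                              h: float = constants.HESSIAN_STEP_A):
    """Hessian columns from the six-point stencil applied to forces.

    Returns ``(H, stencil_energies)`` where H is symmetrized as
    (H + H^T)/2 and ``stencil_energies`` has shape (3N, 6) holding the
    energy at every stencil point (used by the saddle check).
    """
    calc.require("energy", "forces")
    n3 = 3 * s.n_atoms
    flat = s.positions.reshape(-1)
    hess = np.zeros((n3, n3))
    energies = np.zeros((n3, len(_STENCIL_OFFSETS)))
    for k in range(n3):
        acc = np.zeros(n3)
        for col, (off, coeff) in enumerate(
                zip(_STENCIL_OFFSETS, _STENCIL_COEFFS)):
            x = flat.copy()
            x[k] += off * h
            res = calc.evaluate(Structure3D(
                s.atomic_numbers, x.reshape(-1, 3), s.state))
            energies[k, col] = res.energy
            acc += coeff * res.forces.reshape(-1)
        hess[:, k] = -acc / (60.0 * h)
    return 0.5 * (hess + hess.T), energies


def saddle_point_check(stencil_energies: np.ndarray, e0: float) -> bool:
    """True iff the energy strictly increases at every stencil point."""
    return bool(np.all(stencil_energies > e0))


def is_linear(s: Structure3D) -> bool:
    """Smallest principal moment of inertia below tolerance => linear."""
    m = s.masses
    x = s.positions - np.average(s.positions, axis=0, weights=m)
    inertia = np.zeros((3, 3))
    for mi, xi in zip(m, x):
        inertia += mi * ((xi @ xi) * np.eye(3) - np.outer(xi, xi))
    moments = np.linalg.eigvalsh(inertia)
    return bool(moments[0] < LINEAR_MOMENT_TOL)


def normal_mode_analysis(hessian: np.ndarray, masses: np.ndarray,
                         s: Structure3D,
                         min_force_constant: float = 1e-8) -> NormalModeSet:
    """Diagonalize the mass-weighted Hessian and drop rigid-body modes.

    The 6 (5 for linear structures) eigenpairs of smallest absolute
    eigenvalue are removed; any remaining non-positive eigenvalue means the
    input is not a minimum and raises NotAMinimumError.
    """
    n3 = hessian.shape[0]
    if hessian.shape != (n3, n3):
        raise ValueError("hessian must be square")
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(masses, 3))
    mw = hessian * np.outer(inv_sqrt_m, inv_sqrt_m)
    evals, evecs = np.linalg.eigh(0.5 * (mw + mw.T))
    linear = is_linear(s)
    n_rigid = 5 if linear else 6
    n_f = n3 - n_rigid
    if n_f < 1:
        raise NotAMinimumError("no internal degrees of freedom")
    keep = np.argsort(np.abs(evals))[n_rigid:]
    keep = keep[np.argsort(evals[keep])]
    k = evals[keep]
    if np.any(k <= min_force_constant):
        raise NotAMinimumError(
            f"non-positive internal force constant: min k = {k.min():.3g}")
    return NormalModeSet(
        equilibrium=s.copy(), masses=np.asarray(masses, dtype=float),
        modes=evecs[:, keep].T.copy(), force_constants=k,
        n_f=int(n_f), linear=linear)


def draw_sample_energy(n_f: int, rng: np.random.Generator,
                       t_max: float = constants.T_MAX_DEFAULT
                       ) -> tuple[float, float]:
    """T ~ Uniform(0, t_max); E = 0.5 n_f k_B T (equipartition)."""
    if n_f < 1:
        raise ValueError("n_f must be >= 1")
    temperature = rng.uniform(0.0, t_max)
    return temperature, 0.5 * n_f * constants.KB_EV * temperature


def partition_energy(energy: float, n_f: int, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Split E over modes: E_i = w_i^2 / sum(w^2) * E, w ~ N(0, 1).

    The largest share absorbs the floating-point residual so that the
    correctly-rounded sum (math.fsum) of the shares equals E exactly.
    """
    if energy < 0:
        raise ValueError("energy must be non-negative")
    while True:
        w = rng.standard_normal(n_f)
        ssq = float(np.sum(w * w))
        if ssq > 0.0:
            break
    e_vec = (w * w) * (energy / ssq)
    # cycle through shares (largest first) in case one index's achievable
    # sums straddle the target on rounding midpoints
    for idx in np.argsort(e_vec)[::-1]:
        done = False
        for _ in range(64):
            total = math.fsum(e_vec)
            diff = energy - total
            if diff == 0.0:
                done = True
                break
            if abs(diff) <= 8.0 * math.ulp(total):
                # walk in single ulps so no candidate value is skipped
                adjusted = math.nextafter(
                    e_vec[idx], math.inf if diff > 0 else -math.inf)
            else:
                adjusted = e_vec[idx] + diff
            if adjusted < 0.0:
                break
            e_vec[idx] = adjusted
        if done:
            break
    return w, e_vec


def mode_displacements(e_vec: np.ndarray, k_vec: np.ndarray,
                       w: np.ndarray) -> np.ndarray:
    """delta_i = sign(w_i) sqrt(2 E_i / k_i) (mass-weighted units)."""
    if np.any(k_vec <= 0):
        raise ValueError("force constants must be positive")
    signs = np.where(w >= 0, 1.0, -1.0)
    return signs * np.sqrt(2.0 * np.asarray(e_vec) / np.asarray(k_vec))


def _zmatrix_mode_increments(nms: NormalModeSet, tmpl, eps: float = 1e-4):
    """Two-sided finite-difference of the internal coordinates along each
    mass-weighted mode (dihedral block wrapped per difference)."""
    x0 = nms.equilibrium.positions
    inv_sqrt_m = 1.0 / np.sqrt(nms.masses)[:, None]
    rows = []
    n = nms.equilibrium.n_atoms
    for q in nms.modes:
        dx = q.reshape(-1, 3) * inv_sqrt_m
        zp = zmatrix.cart_to_internal(x0 + eps * dx, tmpl)
        zm = zmatrix.cart_to_internal(x0 - eps * dx, tmpl)
        rows.append(zmatrix.wrap_dihedrals(zp - zm, n) / (2.0 * eps))
    return np.array(rows)


def apply_displacements(nms: NormalModeSet, delta: np.ndarray,
                        mode: str = "cartesian") -> tuple[Structure3D, str]:
    """Displace the equilibrium geometry along all modes.

    Cartesian: x = x_eq + M^(-1/2) sum_i delta_i q_i. Z-matrix: per-mode
    internal-coordinate increments scaled by delta_i, summed, dihedrals
    wrapped, then rebuilt; falls back to Cartesian (with a logged flag) if
    Z-matrix construction or rebuild fails. Returns the structure and the
    coordinate system actually used.
    """
    delta = np.asarray(delta, dtype=float)
    if delta.size != nms.n_f:
        raise ValueError("need one displacement per internal mode")
    s0 = nms.equilibrium
    if mode == "zmatrix":
        try:
            adj = zmatrix.connectivity_from_distances(
                s0.atomic_numbers, s0.positions)
            tmpl = zmatrix.build_template(s0.atomic_numbers, adj)
            z_eq = zmatrix.cart_to_internal(s0.positions, tmpl)
            incr = _zmatrix_mode_increments(nms, tmpl)
            z_new = z_eq + delta @ incr
            z_new = z_eq + zmatrix.wrap_dihedrals(z_new - z_eq, s0.n_atoms)
            pos = zmatrix.internal_to_cart(z_new, tmpl)
            if not np.all(np.isfinite(pos)):
                raise zmatrix.ZMatrixError("non-finite rebuild")
            return (Structure3D(s0.atomic_numbers, pos, s0.state,
                                s0.graph_key, s0.conformer_key), "zmatrix")
        except zmatrix.ZMatrixError as exc:
            log.info("Z-matrix displacement failed (%s); "
                     "falling back to Cartesian", exc)
    elif mode != "cartesian":
        raise ValueError(f"unknown displacement mode: {mode!r}")
    dx = (nms.modes.T @ delta).reshape(-1, 3) / np.sqrt(nms.masses)[:, None]
    return (Structure3D(s0.atomic_numbers, s0.positions + dx, s0.state,
                        s0.graph_key, s0.conformer_key), "cartesian")


def sample_count_schedule(n_heavy: int, n_min: int = 100,
                          n_max: int = 1000, max_heavy: int = 8) -> int:
    """Linear ramp of samples per conformer vs heavy-atom count."""
    if n_heavy <= 1:
        return n_min
    frac = min(n_heavy - 1, max_heavy - 1) / (max_heavy - 1)
    return int(round(n_min + frac * (n_max - n_min)))


def sample_offequilibrium(conf: Conformer, calc: Calculator, n_samples: int,
                          rng: np.random.Generator,
                          t_max: float = constants.T_MAX_DEFAULT,
                          mode: str = "zmatrix",
                          h: float = constants.HESSIAN_STEP_A
                          ) -> list[tuple[Structure3D, SampleDraw]]:
    """Full sampling pipeline for one conformer.

    Hessian -> saddle check -> normal-mode analysis -> per-sample energy
    draw, partition, displacement. Raises NotAMinimumError if the conformer
    fails the saddle check or has non-positive internal force constants.
    """
    if n_samples == 0:
        return []
    s = conf.structure
    hessian, stencil_energies = finite_difference_hessian(s, calc, h=h)
    e0 = calc.evaluate(s).energy
    if not saddle_point_check(stencil_energies, e0):
        raise NotAMinimumError("energy does not increase in all stencil "
                               "directions (saddle point or flat mode)")
    nms_set = normal_mode_analysis(hessian, s.masses, s)
    out = []
    for _ in range(n_samples):
        temperature, energy = draw_sample_energy(nms_set.n_f, rng,
                                                 t_max=t_max)
        w, e_vec = partition_energy(energy, nms_set.n_f, rng)
        delta = mode_displacements(e_vec, nms_set.force_constants, w)
        displaced, used = apply_displacements(nms_set, delta, mode=mode)
        draw = SampleDraw(T=temperature, E=energy, weights=w,
                          mode_energies=e_vec, displacements=delta,
                          coordinate_system=used)
        out.append((displaced, draw))
    return out
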