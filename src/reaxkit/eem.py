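"""Taper switching function and EEM charge equilibration.

The electronegativity-equalization method (EEM) assigns partial charges by
minimizing the quadratic electrostatic energy

    E(q) = sum_i (chi_i q_i + eta_i q_i^2) + sum_{i<j} k(r_ij) q_i q_j

subject to ``sum_i q_i = Q``, where the pairwise kernel ``k`` is the tapered,
shielded Coulomb interaction used by the potential.  The constrained minimum
is the solution of a linear (KKT) system; at the solution every atom's
effective electronegativity equals the Lagrange multiplier.
"""

from __future__ import annotations

import numpy as np

from .forcefield import ForceField
from .neighbors import NeighborList, build_neighbor_list
from .structure import Structure
from .units import EV_TO_KCAL, KCAL_COULOMB

__all__ = ["taper_value", "taper_coefficients", "taper_derivative",
           "equilibrate_charges", "coulomb_kernel", "EEMSingularError"]


class EEMSingularError(np.linalg.LinAlgError):
    pass


def taper_coefficients(r_cut: float) -> np.ndarray:
    """Coefficients (constant term first) of the 7th-order taper polynomial.

    The polynomial satisfies T(0) = 1, T(r_cut) = 0, and has vanishing first,
    second, and third derivatives at both ends.
    """
    if r_cut <= 0:
        raise ValueError("taper cutoff must be positive")
    rc = float(r_cut)
    return np.array([1.0, 0.0, 0.0, 0.0,
                     -35.0 / rc**4, 84.0 / rc**5, -70.0 / rc**6, 20.0 / rc**7])


def taper_value(r, r_cut: float):
    """Smooth switching function; 1 at r = 0, 0 (with three vanishing
    derivatives) at r = r_cut, and exactly 0 beyond.

    Evaluated in the cancellation-free factored form
    ``(1-u)^4 (1 + 4u + 10u^2 + 20u^3)``, ``u = r/r_cut``, which equals the
    conventional 7th-order polynomial exactly.
    """
    if r_cut <= 0:
        raise ValueError("taper cutoff must be positive")
    r = np.asarray(r, dtype=float)
    u = np.clip(r / r_cut, 0.0, 1.0)
    out = (1.0 - u) ** 4 * (1.0 + 4.0 * u + 10.0 * u**2 + 20.0 * u**3)
    out = np.where(r < r_cut, out, 0.0)
    return float(out) if out.ndim == 0 else out


def taper_derivative(r, r_cut: float):
    """dT/dr; the factored form is -140 u^3 (1-u)^3 / r_cut."""
    if r_cut <= 0:
        raise ValueError("taper cutoff must be positive")
    r = np.asarray(r, dtype=float)
    u = np.clip(r / r_cut, 0.0, 1.0)
    out = -140.0 * u**3 * (1.0 - u) ** 3 / r_cut
    out = np.where(r < r_cut, out, 0.0)
    return float(out) if out.ndim == 0 else out


def coulomb_kernel(dist: np.ndarray, gamma3: np.ndarray, r_cut: float,
                   derivative: bool = False):
    """Tapered, shielded Coulomb kernel in kcal/mol per e^2.

    ``gamma3`` is (gamma_i * gamma_j)^(-3/2) per pair, in A^3.
    """
    tap = taper_value(dist, r_cut)
    denom = np.cbrt(dist**3 + gamma3)
    k = KCAL_COULOMB * tap / denom
    if not derivative:
        return k
    dtap = taper_derivative(dist, r_cut)
    dk = KCAL_COULOMB * (dtap / denom - tap * dist**2 / denom**4)
    return k, dk


def _eem_system(s: Structure, ff: ForceField, nl: NeighborList):
    n = len(s)
    eta = np.array([ff.elem(sym, "eta_eem") for sym in s.symbols])
    chi = np.array([ff.elem(sym, "chi_eem") for sym in s.symbols])
    gam = np.array([ff.elem(sym, "gamma_eem") for sym in s.symbols])
    h = np.zeros((n, n))
    h[np.diag_indices(n)] = 2.0 * eta * EV_TO_KCAL
    if nl.n_pairs:
        g3 = (gam[nl.i] * gam[nl.j]) ** -1.5
        k = coulomb_kernel(nl.dist, g3, nl.cutoff)
        same = nl.i == nl.j
        np.add.at(h, (nl.i[~same], nl.j[~same]), k[~same])
        np.add.at(h, (nl.j[~same], nl.i[~same]), k[~same])
        np.add.at(h, (nl.i[same], nl.i[same]), 2.0 * k[same])
    return h, chi * EV_TO_KCAL


def equilibrate_charges(s: Structure, ff: ForceField,
                        nl: NeighborList | None = None) -> np.ndarray:
    """Solve the constrained EEM minimization for per-atom charges (e).

    Charges sum to ``s.total_charge`` to linear-solver precision.  Raises
    :class:`EEMSingularError` if the EEM matrix is singular.
    """
    for sym in set(s.symbols):
        if sym not in ff.elements:
            raise KeyError(f"element {sym!r} missing from force field")
    if nl is None:
        nl = build_neighbor_list(s, ff)
    n = len(s)
    h, chi = _eem_system(s, ff, nl)
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = h
    a[:n, n] = -1.0
    a[n, :n] = 1.0
    b = np.concatenate([-chi, [s.total_charge]])
    try:
        sol = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise EEMSingularError(f"EEM system is singular: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise EEMSingularError("EEM solution is not finite")
    return sol[:n]


def eem_energy(s: Structure, ff: ForceField, q: np.ndarray,
               nl: NeighborList | None = None) -> float:
    """EEM objective (Coulomb + self energy) for given charges, kcal/mol.

    This is the quantity :func:`equilibrate_charges` minimizes; it is used by
    tests as an independent check against penalty-method optimization.
    """
    if nl is None:
        nl = build_neighbor_list(s, ff)
    h, chi = _eem_system(s, ff, nl)
    eta_diag = np.diag(np.diag(h))
    off = h - eta_diag
    return float(chi @ q + 0.5 * q @ eta_diag @ q + 0.5 * q @ off @ q)
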