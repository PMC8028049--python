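"""Potential-energy surface correctness: taper, neighbor lists, bond orders,
EEM charges, energy invariances, and analytic-force consistency."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from reaxkit import (Structure, build_neighbor_list, compute_bond_orders,
                     compute_energy, compute_forces, equilibrate_charges,
                     fixtures, taper_value)
from reaxkit.eem import eem_energy, taper_derivative
from reaxkit.neighbors import OverlapError
from reaxkit.potential import Evaluator

from conftest import jiggled


# ---------------------------------------------------------------------------
# taper
# ---------------------------------------------------------------------------

def test_taper_boundary_values():
    assert taper_value(0.0, 10.0) == pytest.approx(1.0, abs=1e-14)
    assert taper_value(10.0, 10.0) == pytest.approx(0.0, abs=1e-14)
    assert taper_value(12.0, 10.0) == 0.0
    with pytest.raises(ValueError):
        taper_value(1.0, -1.0)


@pytest.mark.parametrize("order", [1, 2, 3])
def test_taper_derivatives_vanish_at_cutoff(order):
    """Central-difference derivatives of order 1-3 vanish at the cutoff."""
    rc, h = 10.0, 1e-5
    stencils = {
        1: ([-1, 1], [-0.5, 0.5]),
        2: ([-1, 0, 1], [1.0, -2.0, 1.0]),
        3: ([-2, -1, 1, 2], [-0.5, 1.0, -1.0, 0.5]),
    }
    offs, coefs = stencils[order]
    val = sum(c * taper_value(rc + k * h, rc) for k, c in zip(offs, coefs))
    assert abs(val / h**order) < 1e-6


def test_taper_derivative_matches_finite_difference():
    rs = np.linspace(0.5, 9.5, 7)
    h = 1e-6
    num = (taper_value(rs + h, 10.0) - taper_value(rs - h, 10.0)) / (2 * h)
    np.testing.assert_allclose(taper_derivative(rs, 10.0), num, atol=1e-7)


# ---------------------------------------------------------------------------
# neighbor list
# ---------------------------------------------------------------------------

def test_neighbor_list_simple_pairs():
    s = Structure(["O", "O"], [[0, 0, 0], [5, 0, 0]])
    nl = build_neighbor_list(s, 10.0)
    assert nl.n_pairs == 1
    s = Structure(["O", "O"], [[0, 0, 0], [15, 0, 0]])
    assert build_neighbor_list(s, 10.0).n_pairs == 0


def test_neighbor_list_overlap_error():
    s = Structure(["O", "O"], [[0, 0, 0], [1e-8, 0, 0]])
    with pytest.raises(OverlapError):
        build_neighbor_list(s, 10.0)


def _brute_force_pairs(s, cutoff):
    """O(N^2 x images) oracle returning a multiset of (i, j, rounded dist)."""
    out = []
    x = s.coords
    if s.cell is None:
        for i in range(len(s)):
            for j in range(i + 1, len(s)):
                d = np.linalg.norm(x[j] - x[i])
                if d < cutoff:
                    out.append((i, j, round(d, 9)))
        return sorted(out)
    cell = s.cell
    frac = x / cell
    xw = (frac - np.floor(frac)) * cell
    m = (np.floor(cutoff / cell) + 1).astype(int)
    shifts = [(a, b, c)
              for a in range(-m[0], m[0] + 1)
              for b in range(-m[1], m[1] + 1)
              for c in range(-m[2], m[2] + 1)]
    for i in range(len(s)):
        for j in range(len(s)):
            for sh in shifts:
                if i == j and sh == (0, 0, 0):
                    continue
                if i > j or (i == j and sh < (0, 0, 0)):
                    continue
                d = np.linalg.norm(xw[j] + np.array(sh) * cell - xw[i])
                if d < cutoff:
                    out.append((i, j, round(d, 9)))
    return sorted(out)


@pytest.mark.parametrize("cell", [None, (7.0, 8.0, 9.0)])
def test_neighbor_list_matches_brute_force(cell):
    rng = np.random.default_rng(42)
    s = Structure(["O"] * 20, rng.uniform(0, 7, size=(20, 3)), cell=cell)
    nl = build_neighbor_list(s, 6.0)
    got = sorted((int(i), int(j), round(float(d), 9))
                 for i, j, d in zip(nl.i, nl.j, nl.dist))
    assert got == _brute_force_pairs(s, 6.0)


# ---------------------------------------------------------------------------
# bond orders
# ---------------------------------------------------------------------------

def test_bond_order_zero_beyond_cutoff(toy_ff):
    s = Structure(["O", "H"], [[0, 0, 0], [8.0, 0, 0]])
    g = compute_bond_orders(s, toy_ff)
    assert g.n_bonds == 0


def test_single_atom_graph(toy_ff):
    s = Structure(["O"], [[0, 0, 0]])
    g = compute_bond_orders(s, toy_ff)
    assert g.n_bonds == 0
    assert g.delta[0] == pytest.approx(-toy_ff.elem("O", "valency"))


def test_symmetric_bond_orders_equal(toy_ff):
    s = Structure(["O", "H", "O"],
                  [[-1.2, 0, 0], [0, 0, 0], [1.2, 0, 0]])
    g = compute_bond_orders(s, toy_ff)
    oh = sorted(float(b) for b in g.bo)
    assert oh[-1] == pytest.approx(oh[-2], abs=1e-12)


def test_corrected_not_above_uncorrected(toy_ff, fe2s2_w4):
    g = compute_bond_orders(jiggled(fe2s2_w4, seed=2), toy_ff)
    raw = g.bo_sigma_raw + g.bo_pi_raw + g.bo_pipi_raw
    assert np.all(g.bo <= raw + 1e-10)
    assert np.all(g.bo >= 0)


def test_missing_element_error(toy_ff):
    s = Structure(["O", "N"], [[0, 0, 0], [1.2, 0, 0]])
    with pytest.raises(KeyError, match="N"):
        compute_energy(s, toy_ff)


def test_missing_bond_parameters_error(toy_ff):
    ff = toy_ff.copy()
    del ff.bonds[("Fe", "H")]
    s = Structure(["Fe", "H"], [[0, 0, 0], [1.6, 0, 0]])
    with pytest.raises(KeyError, match="Fe"):
        compute_bond_orders(s, ff)


# ---------------------------------------------------------------------------
# EEM charges
# ---------------------------------------------------------------------------

def test_eem_identical_atoms_split_charge(toy_ff):
    s = Structure(["O", "O"], [[0, 0, 0], [1.3, 0, 0]], total_charge=0.0)
    np.testing.assert_allclose(equilibrate_charges(s, toy_ff), [0, 0], atol=1e-12)
    s = Structure(["O", "O"], [[0, 0, 0], [1.3, 0, 0]], total_charge=-1.0)
    np.testing.assert_allclose(equilibrate_charges(s, toy_ff), [-0.5, -0.5],
                               atol=1e-12)


def _penalty_method_charges(s, ff, mu=1e4):
    """Independent oracle: penalty-method minimization of the EEM objective
    (gradients by central differences; multiplier updates drive the
    total-charge violation to zero)."""
    from scipy.optimize import minimize

    nl = build_neighbor_list(s, ff)
    n = len(s)
    h = 1e-6

    def grad_e(q):
        g = np.empty(n)
        for a in range(n):
            qp = q.copy(); qp[a] += h
            qm = q.copy(); qm[a] -= h
            g[a] = (eem_energy(s, ff, qp, nl) - eem_energy(s, ff, qm, nl)) / (2 * h)
        return g

    lam = 0.0
    q = np.zeros(n)
    for _ in range(8):
        def f(qv):
            c = qv.sum() - s.total_charge
            return eem_energy(s, ff, qv, nl) - lam * c + mu * c * c

        def g(qv):
            c = qv.sum() - s.total_charge
            return grad_e(qv) + (-lam + 2 * mu * c)

        res = minimize(f, q, jac=g, method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 500})
        q = res.x
        c = q.sum() - s.total_charge
        if abs(c) < 1e-12:
            break
        lam -= 2 * mu * c
    return q


@pytest.mark.parametrize("builder,charge", [
    (fixtures.water, 0.0),
    (fixtures.water_dimer, 0.0),
    (fixtures.fe2s2, 0.0),
    (fixtures.fe2s2, 1.0),
    (fixtures.fe2s2_w4, 0.0),
])
def test_eem_matches_penalty_method_oracle(toy_ff, builder, charge):
    s = builder()
    s.total_charge = charge
    q = equilibrate_charges(s, toy_ff)
    assert abs(q.sum() - charge) < 1e-10
    q_ref = _penalty_method_charges(s, toy_ff)
    np.testing.assert_allclose(q, q_ref, atol=1e-6)


def test_eem_equal_effective_electronegativities(toy_ff, fe2s2_w4):
    """Lagrange condition: dE/dq_i identical across atoms at the solution."""
    s = fe2s2_w4
    q = equilibrate_charges(s, toy_ff)
    h = 1e-6
    mu = []
    for a in range(len(s)):
        qp = q.copy()
        qp[a] += h
        qm = q.copy()
        qm[a] -= h
        mu.append((eem_energy(s, toy_ff, qp) - eem_energy(s, toy_ff, qm)) / (2 * h))
    assert np.ptp(mu) < 1e-5


# ---------------------------------------------------------------------------
# energy invariants
# ---------------------------------------------------------------------------

def test_single_atom_energy_is_charge_term_only(toy_ff):
    s = Structure(["H"], [[0, 0, 0]], total_charge=0.0)
    br = compute_energy(s, toy_ff)
    assert br.total == pytest.approx(br.e_charge, abs=1e-12)
    assert br.e_bond == 0.0 and br.e_vdw == 0.0


def test_two_distant_identical_atoms_zero_energy(toy_ff):
    s = Structure(["H", "H"], [[0, 0, 0], [25.0, 0, 0]])
    assert compute_energy(s, toy_ff).total == pytest.approx(0.0, abs=1e-10)


def test_breakdown_sums_to_total(toy_ff, fe2s2_w4):
    br = compute_energy(jiggled(fe2s2_w4, seed=5), toy_ff)
    parts = sum(v for k, v in br.as_dict().items() if k != "total")
    assert br.total == pytest.approx(parts, abs=1e-8)


def test_energy_invariant_under_rigid_motion(toy_ff, water_dimer):
    s = jiggled(water_dimer, seed=1)
    e0 = compute_energy(s, toy_ff).total
    rot = Rotation.random(random_state=7).as_matrix()
    moved = s.with_coords(s.coords @ rot.T + np.array([3.0, -2.0, 11.0]))
    assert compute_energy(moved, toy_ff).total == pytest.approx(e0, abs=1e-6)


def test_energy_invariant_under_permutation(toy_ff, fe2s2_w4):
    s = jiggled(fe2s2_w4, seed=3)
    e0 = compute_energy(s, toy_ff).total
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(s))
    sp = Structure([s.symbols[p] for p in perm], s.coords[perm])
    assert compute_energy(sp, toy_ff).total == pytest.approx(e0, abs=1e-9)


def test_vacuum_matches_large_periodic_box(toy_ff, water_dimer):
    e0 = compute_energy(water_dimer, toy_ff).total
    boxed = Structure(water_dimer.symbols, water_dimer.coords + 20.0,
                      cell=(60.0, 60.0, 60.0))
    assert compute_energy(boxed, toy_ff).total == pytest.approx(e0, abs=1e-8)


def _bisect_crossing(e_of_r, lo, hi, tol=1e-12):
    """Locate a discontinuity candidate by bisecting on pair existence."""
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if e_of_r(mid):
            lo = mid
        else:
            hi = mid
    return lo, hi


def test_energy_continuous_across_bond_order_cutoff(toy_ff):
    """A stretched H-H pair leaves the bonded list with no energy jump."""
    def make(r):
        return Structure(["H", "H"], [[0, 0, 0], [r, 0, 0]])

    def has_bond(r):
        return compute_bond_orders(make(r), toy_ff).n_bonds > 0

    lo, hi = _bisect_crossing(has_bond, 1.5, 2.5)
    e_in = compute_energy(make(lo - 1e-9), toy_ff).total
    e_out = compute_energy(make(hi + 1e-9), toy_ff).total
    assert abs(e_in - e_out) < 1e-6


def test_energy_continuous_across_taper_radius(toy_ff):
    """Nonbonded terms vanish smoothly at the taper cutoff."""
    def make(r):
        return Structure(["O", "O"], [[0, 0, 0], [r, 0, 0]])

    rc = toy_ff.taper_radius
    e = [compute_energy(make(rc + dr), toy_ff).total
         for dr in (-1e-6, 1e-6)]
    assert abs(e[0] - e[1]) < 1e-6


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def test_diatomic_forces_equal_opposite(toy_ff):
    s = Structure(["O", "O"], [[0, 0, 0], [1.4, 0.3, -0.2]])
    f = compute_forces(s, toy_ff)
    np.testing.assert_allclose(f[0], -f[1], atol=1e-10)
    # force lies along the bond axis
    axis = s.coords[1] - s.coords[0]
    cross = np.cross(f[0], axis)
    assert np.linalg.norm(cross) < 1e-10


@pytest.mark.parametrize("seed", range(3))
def test_net_force_and_torque_vanish(toy_ff, fe2s2_w4, seed):
    s = jiggled(fe2s2_w4, sd=0.07, seed=seed)
    f = compute_forces(s, toy_ff)
    np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-6)
    torque = np.cross(s.coords - s.coords.mean(axis=0), f).sum(axis=0)
    np.testing.assert_allclose(torque, 0.0, atol=1e-6)


@pytest.mark.parametrize("builder,seed", [
    (fixtures.water, 0),
    (fixtures.water_dimer, 1),
    (fixtures.fe2s2, 2),
    (fixtures.fe2s2_w4, 3),
])
def test_analytic_forces_match_central_differences(toy_ff, builder, seed):
    s = jiggled(builder(), sd=0.05, seed=seed)
    fa = compute_forces(s, toy_ff, mode="analytic")
    fn = compute_forces(s, toy_ff, mode="numerical", step=1e-5)
    assert np.abs(fa - fn).max() < 1e-4


def test_forces_match_in_periodic_box(toy_ff):
    w = fixtures.water()
    s = Structure(w.symbols, w.coords + 2.0, cell=(7.5, 8.0, 8.5))
    fa = compute_forces(s, toy_ff, mode="analytic")
    fn = compute_forces(s, toy_ff, mode="numerical", step=1e-5)
    assert np.abs(fa - fn).max() < 1e-4


def test_charge_relaxation_force_contribution_is_negligible(toy_ff, water_dimer):
    """The analytic mode freezes EEM charges; because the charges minimize
    the electrostatic energy under the charge constraint, the neglected
    dq/dx term is bounded by solver precision."""
    s = jiggled(water_dimer, seed=9)
    ev = Evaluator(s, toy_ff)
    ev.energy()
    fa = ev.forces()
    # numerical gradient of the electrostatic part with charges re-solved
    fn_full = compute_forces(s, toy_ff, mode="numerical", step=1e-5,
                             terms={"coul", "charge"})
    fa_part = compute_forces(s, toy_ff, mode="analytic",
                             terms={"coul", "charge"})
    assert np.abs(fa_part - fn_full).max() < 1e-6
    assert np.all(np.isfinite(fa))
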