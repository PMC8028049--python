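"""Alignment, hydrogen-bond counting, trajectory statistics, and reports."""

from itertools import permutations, product

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from reaxkit import Structure, Frame, Trajectory, fixtures
from reaxkit.analysis import (HBondCriteria, aligned_rmsd, charge_report,
                              classify_fe_coordination, count_hbonds,
                              geometry_deviation_report, kabsch_rmsd,
                              prediction_correlation_report,
                              trajectory_statistics)
from reaxkit.potential import EnergyBreakdown
from reaxkit.training import ScanSpec


# ---------------------------------------------------------------------------
# aligned RMSD
# ---------------------------------------------------------------------------

def brute_force_min_rmsd(a: Structure, b: Structure) -> float:
    """Exhaustive oracle: all per-element permutations x both parities, with
    a Kabsch alignment for each candidate."""
    xa = a.coords - a.coords.mean(axis=0)
    classes: dict[str, list[int]] = {}
    for k, s in enumerate(a.symbols):
        classes.setdefault(s, []).append(k)
    idx_b: dict[str, list[int]] = {}
    for k, s in enumerate(b.symbols):
        idx_b.setdefault(s, []).append(k)
    syms = list(classes)
    pools = [list(permutations(idx_b[s])) for s in syms]
    best = np.inf
    for parity in (1.0, -1.0):
        xb = parity * (b.coords - b.coords.mean(axis=0))
        for combo in product(*pools):
            perm = np.empty(len(a.symbols), dtype=int)
            for s, pp in zip(syms, combo):
                for ai, bi in zip(classes[s], pp):
                    perm[ai] = bi
            best = min(best, kabsch_rmsd(xa, xb[perm]))
    return best


def test_rmsd_identity(fe2s2_w4):
    assert aligned_rmsd(fe2s2_w4, fe2s2_w4) == pytest.approx(0.0, abs=1e-10)


def test_rmsd_zero_on_transformed_copy(fe2s2_w4):
    rng = np.random.default_rng(1)
    rot = Rotation.random(random_state=5).as_matrix()
    perm = rng.permutation(len(fe2s2_w4))
    xb = (-fe2s2_w4.coords) @ rot.T + np.array([4.0, -1.0, 2.5])
    b = Structure([fe2s2_w4.symbols[p] for p in perm], xb[perm])
    assert aligned_rmsd(fe2s2_w4, b) == pytest.approx(0.0, abs=1e-8)


@pytest.mark.parametrize("seed", range(5))
def test_rmsd_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    syms = ["O", "O", "H", "H", "S", "Fe"]
    a = Structure(syms, rng.normal(size=(6, 3)) * 1.5)
    b = Structure(syms, rng.normal(size=(6, 3)) * 1.5)
    assert aligned_rmsd(a, b) == pytest.approx(brute_force_min_rmsd(a, b),
                                               abs=1e-8)


def test_rmsd_symmetric_and_motion_invariant():
    rng = np.random.default_rng(9)
    syms = ["O", "H", "H", "S"]
    a = Structure(syms, rng.normal(size=(4, 3)))
    b = Structure(syms, rng.normal(size=(4, 3)))
    v = aligned_rmsd(a, b)
    assert aligned_rmsd(b, a) == pytest.approx(v, abs=1e-8)
    rot = Rotation.random(random_state=2).as_matrix()
    b2 = b.with_coords(b.coords @ rot.T + 7.0)
    assert aligned_rmsd(a, b2) == pytest.approx(v, abs=1e-8)


def test_rmsd_element_mismatch_raises():
    a = Structure(["O", "H"], np.zeros((2, 3)) + [[0, 0, 0], [1, 0, 0]])
    b = Structure(["O", "O"], [[0, 0, 0], [1, 0, 0]])
    with pytest.raises(ValueError):
        aligned_rmsd(a, b)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _linear_hbond(r_da=2.9, deviation_deg=5.0):
    """O-H...O with the given donor-acceptor distance and deviation angle."""
    dev = np.radians(deviation_deg)
    return Structure(
        ["O", "H", "O", "H", "H"],
        [[0, 0, 0],
         [0.96 * np.cos(dev), 0.96 * np.sin(dev), 0],
         [r_da, 0, 0],
         [r_da + 0.3, 0.9, 0], [r_da + 0.3, -0.9, 0]])


def test_hbond_inside_both_cutoffs_counts():
    assert count_hbonds(_linear_hbond(2.9, 5.0)) == 1


def test_hbond_outside_distance_cutoff():
    assert count_hbonds(_linear_hbond(4.0, 5.0)) == 0


def test_hbond_outside_angle_cutoff():
    assert count_hbonds(_linear_hbond(2.9, 35.0)) == 0


def test_hbond_cluster_restriction():
    s = _linear_hbond()
    # both partners outside the cluster -> not counted
    assert count_hbonds(s, cluster={4}) == 0
    # exactly one partner in the cluster -> counted
    assert count_hbonds(s, cluster={0, 1}) == 1


def brute_force_hbonds(s, crit):
    from reaxkit.units import COVALENT_RADII
    x, syms = s.coords, s.symbols
    n = 0
    for d in range(len(s)):
        if syms[d] not in ("O", "S"):
            continue
        for h in range(len(s)):
            if syms[h] != "H":
                continue
            vdh = x[h] - x[d]
            if s.cell is not None:
                vdh -= np.round(vdh / s.cell) * s.cell
            if np.linalg.norm(vdh) > crit.dh_max * (
                    COVALENT_RADII[syms[d]] + COVALENT_RADII["H"]):
                continue
            for a in range(len(s)):
                if a == d or syms[a] not in ("O", "S"):
                    continue
                vda = x[a] - x[d]
                if s.cell is not None:
                    vda -= np.round(vda / s.cell) * s.cell
                r = np.linalg.norm(vda)
                if not 1e-6 < r <= crit.donor_acceptor_max_distance:
                    continue
                cosv = vdh @ vda / (np.linalg.norm(vdh) * r)
                if np.degrees(np.arccos(np.clip(cosv, -1, 1))) <= crit.angular_max:
                    n += 1
    return n


@pytest.mark.parametrize("seed,cell", [(0, None), (1, None),
                                       (2, (9.0, 9.0, 9.0))])
def test_hbond_count_matches_triple_loop(seed, cell):
    """Random 20-water frames agree exactly with the O(N^3) oracle."""
    rng = np.random.default_rng(seed)
    spec = fixtures.BoxSpec(cell=(9.0, 9.0, 9.0), n_waters=20, seed=seed)
    box = fixtures.build_solvated_box(spec)
    s = box if cell is not None else Structure(box.symbols, box.coords)
    crit = HBondCriteria()
    assert count_hbonds(s, crit=crit) == brute_force_hbonds(s, crit)


def test_hbond_invariant_under_rigid_motion():
    s = _linear_hbond()
    rot = Rotation.random(random_state=11).as_matrix()
    s2 = s.with_coords(s.coords @ rot.T + np.array([2.0, -3.0, 1.0]))
    assert count_hbonds(s2) == count_hbonds(s)


def test_fe_coordination_classification(fe2s2_w4):
    counts = classify_fe_coordination(fe2s2_w4, fe_indices=(0, 1))
    assert counts == {0: 2, 1: 2}


# ---------------------------------------------------------------------------
# trajectory statistics
# ---------------------------------------------------------------------------

def _traj_from_structures(structs, dt=1.0):
    frames = [Frame(time_fs=k * dt, structure=s,
                    breakdown=EnergyBreakdown())
              for k, s in enumerate(structs)]
    return Trajectory(frames)


def test_frozen_trajectory_zero_sd(fe2s2):
    traj = _traj_from_structures([fe2s2.copy() for _ in range(4)])
    st = trajectory_statistics(
        traj, (0.0, 10.0),
        distances={"FeS": [(0, 2), (0, 3), (1, 2), (1, 3)]},
        dihedrals={"theta": (0, 2, 1, 3)})
    assert st.sd("FeS") == 0.0
    assert st.mean("FeS") == pytest.approx(2.30, abs=1e-12)
    # planar ring: dihedral exactly zero
    assert st.mean("theta") == pytest.approx(0.0, abs=1e-9)


def test_two_frame_dihedral_mean_and_sd():
    base = Structure(["O", "O", "O", "O"],
                     [[0, 0, 0], [1.5, 0, 0], [1.5, 1.5, 0], [0.0, 1.5, 0.0]])
    rot = base.copy()
    # rotate the last atom 10 degrees about the central bond
    axis = (rot.coords[2] - rot.coords[1])
    axis /= np.linalg.norm(axis)
    r = Rotation.from_rotvec(np.radians(10.0) * axis).as_matrix()
    rot.coords[3] = (rot.coords[3] - rot.coords[1]) @ r.T + rot.coords[1]
    traj = _traj_from_structures([base, rot])
    st = trajectory_statistics(traj, (0.0, 2.0),
                               dihedrals={"w": (0, 1, 2, 3)})
    assert st.mean("w") == pytest.approx(5.0, abs=1e-6)
    assert st.sd("w") == pytest.approx(5.0, abs=1e-6)


def test_window_selection_and_errors(fe2s2):
    traj = _traj_from_structures([fe2s2.copy() for _ in range(10)])
    st = trajectory_statistics(traj, (5.0, 9.0), distances={"d": [(0, 1)]})
    assert st.n_frames == 5
    with pytest.raises(ValueError):
        trajectory_statistics(traj, (100.0, 200.0), distances={"d": [(0, 1)]})
    with pytest.raises(IndexError):
        trajectory_statistics(traj, (0.0, 9.0), distances={"d": [(0, 99)]})


# ---------------------------------------------------------------------------
# deviation report
# ---------------------------------------------------------------------------

def test_deviation_report_identity(fe2s2_w4):
    rep = geometry_deviation_report({"c": fe2s2_w4}, {"c": fe2s2_w4})
    assert rep.aggregate["bond"][0] == pytest.approx(0.0, abs=1e-12)
    assert rep.aggregate["angle"][0] == pytest.approx(0.0, abs=1e-12)


def test_deviation_report_single_stretched_bond(water):
    stretched = water.copy()
    oh = stretched.coords[1] - stretched.coords[0]
    stretched.coords[1] += 0.1 * oh / np.linalg.norm(oh)
    rep = geometry_deviation_report({"w": stretched}, {"w": water})
    dev = rep.deviations["w"]
    # stretching breaks the H/H symmetry: both O-H bonds are inequivalent in
    # the reference topology, but only one deviates
    assert max(dev["bond"]) == pytest.approx(0.1, abs=1e-9)
    assert rep.aggregate["torsion"][0] != rep.aggregate["torsion"][0] or \
        rep.aggregate["torsion"][0] == 0.0  # no torsions in water (NaN) or 0


def test_deviation_report_symmetry_unique_counting(water):
    """The two O-H bonds of water are equivalent under the topology
    automorphism that swaps the hydrogens, so only one is counted."""
    rep = geometry_deviation_report({"w": water}, {"w": water})
    assert rep.per_cluster.iloc[0]["bond_n"] == 1
    assert rep.per_cluster.iloc[0]["angle_n"] == 1


def test_deviation_report_three_atom_hand_computed():
    a = Structure(["O", "H", "S"], [[0, 0, 0], [1.0, 0, 0], [-0.3, 1.2, 0]])
    b = a.copy()
    b.coords[1] = [1.05, 0, 0]
    rep = geometry_deviation_report({"t": b}, {"t": a})
    bonds = sorted(rep.deviations["t"]["bond"])
    assert bonds[-1] == pytest.approx(0.05, abs=1e-9)


# ---------------------------------------------------------------------------
# correlation and charge reports
# ---------------------------------------------------------------------------

def test_correlation_identity_line(ho_ff, water):
    scans = [("w", ScanSpec(("bond", (0, 1)), 0.1, (-0.1, 0.4), (1,)))]
    ts = fixtures.make_synthetic_trainset(ho_ff, {"w": water}, scans,
                                          include_charges=False)
    rep = prediction_correlation_report(ts, ho_ff)
    s = rep["summary"]["train"]
    assert s["slope"] == pytest.approx(1.0, abs=1e-8)
    assert s["r2"] == pytest.approx(1.0, abs=1e-10)
    assert s["bias"] == pytest.approx(0.0, abs=1e-8)


def test_correlation_known_slope(ho_ff, water):
    scans = [("w", ScanSpec(("bond", (0, 1)), 0.1, (-0.1, 0.4), (1,)))]
    ts = fixtures.make_synthetic_trainset(ho_ff, {"w": water}, scans,
                                          include_charges=False)
    for e in ts.entries:
        e.reference_value *= 2.0   # y_ff = 0.5 * y_ref
    rep = prediction_correlation_report(ts, ho_ff)
    assert rep["summary"]["train"]["slope"] == pytest.approx(0.5, abs=1e-8)


def test_correlation_single_entry_slope_absent(ho_ff, water):
    from reaxkit.trainset import TrainingEntry, TrainingSet
    far = water.copy()
    far.coords[1] += 30.0
    ts = TrainingSet(
        entries=[TrainingEntry("a", "energy_difference", ("far", "w"), 1.0)],
        structures={"w": water, "far": far})
    rep = prediction_correlation_report(ts, ho_ff)
    assert rep["summary"]["train"]["slope"] is None
    assert len(rep["pairs"]) == 1


def test_charge_report_zero_error_against_eem(ho_ff, water):
    from reaxkit import equilibrate_charges
    q = equilibrate_charges(water, ho_ff)
    rep = charge_report({"w": water}, ho_ff, {"w": q})
    assert rep["table"]["abs_error"].max() == pytest.approx(0.0, abs=1e-12)
    # neutral homonuclear diatomic: EEM charges are exactly zero
    s2 = Structure(["O", "O"], [[0, 0, 0], [1.3, 0, 0]])
    rep2 = charge_report({"d": s2}, ho_ff, {"d": np.array([0.25, -0.25])})
    np.testing.assert_allclose(rep2["table"]["eem"], 0.0, atol=1e-12)
    np.testing.assert_allclose(rep2["table"]["abs_error"], 0.25, atol=1e-12)


def test_charge_report_mismatch_raises(ho_ff, water):
    with pytest.raises(ValueError):
        charge_report({"w": water}, ho_ff, {"w": np.zeros(2)})
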