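"""Scan generation, cost evaluation, and swarm training."""

import numpy as np
import pytest

from reaxkit import fixtures
from reaxkit.structure import Structure, angle, dihedral, distance
from reaxkit.training import (MaskEntry, ParameterMask, ScanSpec, SwarmConfig,
                              assemble_training_set, evaluate_cost,
                              generate_scan, guess_moving_set,
                              polish_nelder_mead, swarm_minimize, train_swarm,
                              COST_PENALTY)
from reaxkit.trainset import TrainingEntry, TrainingSet


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def test_bond_scan_offsets_exact(water):
    spec = ScanSpec(("bond", (0, 1)), 0.2, (0.2, 0.6), (1,))
    out = generate_scan(water, spec)
    assert len(out) == 3
    r0 = distance(water.coords, 0, 1)
    got = [distance(s.coords, 0, 1) - r0 for s in out]
    np.testing.assert_allclose(got, [0.2, 0.4, 0.6], atol=1e-8)
    # the untouched O-H bond is unchanged
    for s in out:
        assert distance(s.coords, 0, 2) == pytest.approx(
            distance(water.coords, 0, 2), abs=1e-8)


def test_angle_scan_offsets_and_bond_lengths(water):
    spec = ScanSpec(("angle", (1, 0, 2)), 10.0, (-20.0, 20.0), (2,))
    out = generate_scan(water, spec)
    a0 = angle(water.coords, 1, 0, 2)
    got = [angle(s.coords, 1, 0, 2) - a0 for s in out]
    np.testing.assert_allclose(got, [-20, -10, 10, 20], atol=1e-8)
    for s in out:
        for (i, j) in ((0, 1), (0, 2)):
            assert distance(s.coords, i, j) == pytest.approx(
                distance(water.coords, i, j), abs=1e-8)


def test_torsion_scan_offsets():
    h2o2 = Structure(["O", "O", "H", "H"], np.array([
        [0, 0, 0], [1.45, 0, 0], [-0.35, 0.9, 0.1], [1.8, -0.6, 0.65]]))
    spec = ScanSpec(("torsion", (2, 0, 1, 3)), 15.0, (-30.0, 30.0), (3,))
    out = generate_scan(h2o2, spec)
    d0 = dihedral(h2o2.coords, 2, 0, 1, 3)
    for s, want in zip(out, (-30, -15, 15, 30)):
        got = dihedral(s.coords, 2, 0, 1, 3) - d0
        got = (got + 180.0) % 360.0 - 180.0
        assert got == pytest.approx(want, abs=1e-8)
        assert distance(s.coords, 1, 3) == pytest.approx(
            distance(h2o2.coords, 1, 3), abs=1e-8)


def test_cluster_water_scan_keeps_water_rigid(fe2s2_w4):
    ms = guess_moving_set(fe2s2_w4, ("cluster_water_distance", (0, 4)))
    assert ms == (4, 5, 6)
    spec = ScanSpec(("cluster_water_distance", (0, 4)), 0.3, (-0.3, 0.9), ms)
    out = generate_scan(fe2s2_w4, spec)
    r0 = distance(fe2s2_w4.coords, 0, 4)
    np.testing.assert_allclose(
        [distance(s.coords, 0, 4) - r0 for s in out],
        [-0.3, 0.3, 0.6, 0.9], atol=1e-8)
    for s in out:
        assert distance(s.coords, 4, 5) == pytest.approx(
            distance(fe2s2_w4.coords, 4, 5), abs=1e-10)
        assert angle(s.coords, 5, 4, 6) == pytest.approx(
            angle(fe2s2_w4.coords, 5, 4, 6), abs=1e-8)


def test_scan_spec_validation():
    with pytest.raises(ValueError):
        ScanSpec(("bond", (0, 1)), -0.1, (0.1, 0.5), (1,))
    with pytest.raises(ValueError):
        ScanSpec(("bond", (0, 1)), 0.1, (0.5, 0.1), (1,))
    with pytest.raises(ValueError):
        ScanSpec(("angle", (0, 1, 2)), 5.0, (-10, 10), (1,))  # pivot moves


def test_collinear_angle_scan_rejected():
    s = Structure(["O", "O", "O"], [[0, 0, 0], [1, 0, 0], [2, 0, 0]])
    spec = ScanSpec(("angle", (0, 1, 2)), 5.0, (-10, 10), (2,))
    with pytest.raises(ValueError, match="collinear"):
        generate_scan(s, spec)


# ---------------------------------------------------------------------------
# training-set assembly and cost
# ---------------------------------------------------------------------------

def test_assemble_marks_validation_partition(water, fe2s2_w4):
    ts = assemble_training_set(
        {"w": water, "fe2s2w4": fe2s2_w4},
        energy_refs=[("w", "w", 0.0, 1.0), ("fe2s2w4", "fe2s2w4", 0.0, 1.0)],
        partition_rule=lambda sid: "validation" if "fe2s2" in sid else "train")
    parts = {e.structure_ids[0]: e.partition for e in ts.entries}
    assert parts["fe2s2w4"] == "validation"
    assert parts["w"] == "train"
    # self-referenced equilibrium pair has reference difference zero
    assert all(e.reference_value == 0.0 for e in ts.entries)


def test_cost_weighted_arithmetic(ho_ff, water):
    """Residuals 1 and 2 with weights 1 and 0.5 cost 1*1^2 + 0.5*2^2 = 3."""
    from reaxkit.potential import compute_energy
    e_w = compute_energy(water, ho_ff).total
    far = water.copy()
    far.coords[1] += 50.0
    e_far = compute_energy(far, ho_ff).total
    de = e_far - e_w
    ts = TrainingSet(
        entries=[
            TrainingEntry("a", "energy_difference", ("far", "w"), de - 1.0, 1.0),
            TrainingEntry("b", "energy_difference", ("far", "w"), de - 2.0, 0.5),
        ],
        structures={"w": water, "far": far})
    mask = ParameterMask([MaskEntry("bond", ("H", "O"), "De_sigma", 100, 200)])
    cost = evaluate_cost(mask.get(ho_ff), ts, ho_ff, mask)
    assert cost == pytest.approx(3.0, abs=1e-8)


def test_empty_training_set_costs_zero(ho_ff):
    ts = TrainingSet()
    mask = ParameterMask([MaskEntry("bond", ("H", "O"), "De_sigma", 100, 200)])
    assert evaluate_cost(mask.get(ho_ff), ts, ho_ff, mask) == 0.0


def test_self_consistent_trainset_costs_zero(ho_ff, water):
    scans = [("w", ScanSpec(("bond", (0, 1)), 0.1, (0.1, 0.4), (1,)))]
    ts = fixtures.make_synthetic_trainset(ho_ff, {"w": water}, scans)
    mask = ParameterMask([MaskEntry("bond", ("H", "O"), "De_sigma", 100, 200)])
    assert evaluate_cost(mask.get(ho_ff), ts, ho_ff, mask) == pytest.approx(0.0, abs=1e-12)
    # perturbing the parameter makes the cost strictly positive
    assert evaluate_cost(np.array([150.0]), ts, ho_ff, mask) > 1e-3


def test_validation_entries_excluded_from_cost(ho_ff, water):
    scans = [("w", ScanSpec(("bond", (0, 1)), 0.1, (0.1, 0.4), (1,)))]
    ts = fixtures.make_synthetic_trainset(
        ho_ff, {"w": water}, scans,
        partition_rule=lambda sid: "validation")
    mask = ParameterMask([MaskEntry("bond", ("H", "O"), "De_sigma", 100, 200)])
    # even a wrong parameter costs zero because nothing is in the train split
    assert evaluate_cost(np.array([150.0]), ts, ho_ff, mask) == 0.0


def test_cost_penalty_on_failure(ho_ff, water):
    ts = TrainingSet(
        entries=[TrainingEntry("a", "energy_difference", ("missing", "w"), 0.0)],
        structures={"w": water})
    mask = ParameterMask([MaskEntry("bond", ("H", "O"), "De_sigma", 100, 200)])
    assert evaluate_cost(mask.get(ho_ff), ts, ho_ff, mask) == COST_PENALTY


def test_mask_validation_and_bounds():
    with pytest.raises(ValueError):
        MaskEntry("bond", ("H", "O"), "De_sigma", 2.0, 1.0)
    ff = fixtures.make_toy_forcefield(elements=("H", "O"))
    mask = ParameterMask([MaskEntry("bond", ("H", "O"), "nonsense", 0, 1)])
    with pytest.raises(KeyError):
        mask.validate(ff)
    mask = ParameterMask([MaskEntry("angle", ("H", "Fe", "H"), "p_val1", 0, 1)])
    with pytest.raises(KeyError):
        mask.validate(ff)


def test_mask_apply_round_trip(ho_ff):
    mask = ParameterMask([
        MaskEntry("bond", ("H", "O"), "De_sigma", 100, 200),
        MaskEntry("element", "O", "chi_eem", 5, 12),
        MaskEntry("general", None, "p_vdw1", 1, 2),
    ])
    vec = np.array([175.0, 9.0, 1.7])
    ff2 = mask.apply(ho_ff, vec)
    np.testing.assert_allclose(mask.get(ff2), vec)
    # the template is untouched
    assert ho_ff.bond("H", "O", "De_sigma") != 175.0


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

def test_nelder_mead_quadratic_and_descent():
    bounds = np.array([[-5.0, 5.0]])
    out = polish_nelder_mead(lambda x: (x[0] - 1.2345) ** 2,
                             np.array([3.0]), bounds)
    assert out[0] == pytest.approx(1.2345, abs=1e-6)
    # already at the minimum: returned unchanged (within solver wobble)
    out2 = polish_nelder_mead(lambda x: (x[0] - 1.2345) ** 2, out, bounds)
    assert out2[0] == pytest.approx(out[0], abs=1e-6)
    # Rosenbrock from the origin: cost strictly decreases
    def rosen(x):
        return (1 - x[0]) ** 2 + 100 * (x[1] - x[0] ** 2) ** 2
    b2 = np.array([[-2.0, 2.0], [-2.0, 2.0]])
    out3 = polish_nelder_mead(rosen, np.zeros(2), b2)
    assert rosen(out3) < rosen(np.zeros(2))


def test_pso_sphere_recovers_optimum():
    """With respawn and polish disabled the trainer reduces to canonical
    gbest PSO, which locates the sphere minimum."""
    cfg = SwarmConfig(n_agents=20, max_iters=200, seed=1, polish_every=0,
                      respawn_fraction=0.0)
    res = swarm_minimize(lambda x: (x[0] - 0.3) ** 2 + (x[1] + 0.7) ** 2,
                         np.array([[-2.0, 2.0], [-2.0, 2.0]]), cfg)
    np.testing.assert_allclose(res.best_position, [0.3, -0.7], atol=1e-3)
    hist = res.history
    assert all(b <= a + 1e-15 for a, b in zip(hist, hist[1:]))


def test_pso_respawn_never_replaces_global_best():
    rng_costs = []

    def cost(x):
        c = float(np.sum(x**2))
        rng_costs.append(c)
        return c

    cfg = SwarmConfig(n_agents=6, max_iters=30, seed=2, polish_every=0,
                      respawn_fraction=0.5, gamma=0.3)
    res = swarm_minimize(cost, np.array([[-1.0, 1.0]] * 3), cfg)
    hist = res.history
    assert all(b <= a + 1e-15 for a, b in zip(hist, hist[1:]))


def test_swarm_positions_respect_bounds():
    seen = []

    def cost(x):
        seen.append(x.copy())
        return float(np.sum((x - 0.9) ** 2))

    bounds = np.array([[-1.0, 1.0], [0.0, 0.5]])
    cfg = SwarmConfig(n_agents=8, max_iters=25, seed=3, polish_every=0)
    swarm_minimize(cost, bounds, cfg)
    pts = np.array(seen)
    assert np.all(pts[:, 0] >= -1.0 - 1e-12) and np.all(pts[:, 0] <= 1.0 + 1e-12)
    assert np.all(pts[:, 1] >= -1e-12) and np.all(pts[:, 1] <= 0.5 + 1e-12)


def test_staged_charge_training_recovers_eem_parameter(ho_ff, water):
    """Stage 'charges_only' drives the cost of a synthetic charge-only
    training set to zero by recovering the generating electronegativity."""
    truth = ho_ff.elem("O", "chi_eem")
    ts = fixtures.make_synthetic_trainset(ho_ff, {"w": water}, scans=[])
    assert all(e.kind == "charge" for e in ts.entries)
    mask = ParameterMask([MaskEntry("element", "O", "chi_eem", 6.0, 11.0)])
    cfg = SwarmConfig(n_agents=8, max_iters=40, seed=5, polish_every=10,
                      nm_maxiter=40, target_cost=1e-16)
    res = train_swarm(ho_ff, mask, ts, cfg, stage="charges_only")
    assert res.best_position[0] == pytest.approx(truth, rel=1e-3)
    assert res.best_cost < 1e-10


def test_swarm_config_validation():
    with pytest.raises(ValueError):
        SwarmConfig(n_agents=1)
    with pytest.raises(ValueError):
        SwarmConfig(omega_start=0.4, omega_end=0.9)
    with pytest.raises(ValueError):
        SwarmConfig(respawn_fraction=1.0)
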