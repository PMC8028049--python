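"""Training-set construction by internal-coordinate scanning and force-field
parameter fitting with a particle-swarm optimizer.

The cost function is the weighted sum of squared residuals over the training
partition,

    C(p) = sum_m w_m (y_m^FF(p) - y_m^ref)^2,

with energy-difference entries evaluated as FF(distorted) - FF(equilibrium)
and charge entries as EEM charges.  The swarm is a gbest PSO with cognitive
and social coefficients c1 = c2 = 2.0, inertia decaying linearly from 0.9 to
0.4 over the run, Gaussian-mutation respawn of the worst-performing fraction
of agents around the global best (sigma = gamma * parameter range per
dimension, gamma = 0.1), and periodic Nelder-Mead relaxation of every agent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.transform import Rotation

from .forcefield import (ANGLE_PARAM_NAMES, BOND_PARAM_NAMES,
                         ELEMENT_PARAM_NAMES, GENERAL_PARAM_NAMES,
                         HBOND_PARAM_NAMES, OFFDIAG_PARAM_NAMES,
                         TORSION_PARAM_NAMES, ForceField)
from .structure import Structure, angle, dihedral, distance
from .trainset import TrainingEntry, TrainingSet
from .units import COVALENT_RADII

__all__ = ["ScanSpec", "generate_scan", "assemble_training_set",
           "ParameterMask", "MaskEntry", "SwarmConfig", "SwarmResult",
           "evaluate_cost", "train_swarm", "polish_nelder_mead",
           "guess_moving_set", "COST_PENALTY"]

#: cost assigned to a parameter vector whose evaluation fails
COST_PENALTY = 1e10


# ---------------------------------------------------------------------------
# internal-coordinate scans
# ---------------------------------------------------------------------------

@dataclass
class ScanSpec:
    """One scanned degree of freedom.

    ``coordinate`` is ``("bond", (i, j))``, ``("angle", (i, j, k))`` (centre
    j), ``("torsion", (i, j, k, l))`` (axis j-k) or
    ``("cluster_water_distance", (cluster_atom, water_oxygen))``.
    ``increment`` is in A (bonds, distances) or degrees (angles, torsions);
    the scan visits equilibrium value + k*increment for every nonzero offset
    in ``range_`` (inclusive).  ``moving_set`` lists the atoms displaced
    rigidly; it must not contain the pivot atoms.
    """
    coordinate: tuple
    increment: float
    range_: tuple[float, float]
    moving_set: tuple[int, ...]

    def __post_init__(self):
        if self.increment <= 0:
            raise ValueError("increment must be positive")
        lo, hi = self.range_
        if not lo < hi:
            raise ValueError("range minimum must be below maximum")
        if not self.moving_set:
            raise ValueError("moving_set must be nonempty")
        kind, atoms = self.coordinate
        if kind == "bond":
            pivots = {atoms[0]}
        elif kind == "angle":
            pivots = {atoms[0], atoms[1]}
        elif kind == "torsion":
            pivots = {atoms[1], atoms[2]}
        elif kind == "cluster_water_distance":
            pivots = {atoms[0]}
        else:
            raise ValueError(f"unknown scan coordinate kind {kind!r}")
        if pivots & set(self.moving_set):
            raise ValueError("moving_set must exclude the pivot atoms")

    def offsets(self) -> np.ndarray:
        lo, hi = self.range_
        k0 = math.ceil(lo / self.increment - 1e-9)
        k1 = math.floor(hi / self.increment + 1e-9)
        ks = [k for k in range(k0, k1 + 1) if k != 0]
        return np.array([k * self.increment for k in ks])


def _bond_graph(s: Structure, scale: float = 1.3) -> list[set[int]]:
    """Crude covalent bond graph from tabulated radii (scan fragments only)."""
    n = len(s)
    nbrs: list[set[int]] = [set() for _ in range(n)]
    r = np.array([COVALENT_RADII.get(sym, 1.0) for sym in s.symbols])
    for i in range(n):
        for j in range(i + 1, n):
            if distance(s.coords, i, j) < scale * (r[i] + r[j]):
                nbrs[i].add(j)
                nbrs[j].add(i)
    return nbrs


def _component(nbrs, start: int, blocked: set[int]) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        a = stack.pop()
        for b in nbrs[a]:
            if b not in seen and b not in blocked:
                seen.add(b)
                stack.append(b)
    return seen


def guess_moving_set(s: Structure, coordinate: tuple) -> tuple[int, ...]:
    """Default displaced fragment: the connected component on the far side of
    the scanned coordinate (the smaller fragment for bonds).  Raises if the
    bond is part of a cycle, in which case an explicit set is required."""
    kind, atoms = coordinate
    nbrs = _bond_graph(s)
    if kind == "bond":
        i, j = atoms
        side_j = _component(nbrs, j, {i})
        if i in side_j:
            raise ValueError("scanned bond lies in a cycle; supply moving_set")
        side_i = _component(nbrs, i, {j})
        moving = side_j if len(side_j) <= len(side_i) else side_i
        pivot = i if moving is side_j else j
        return tuple(sorted(moving - {pivot}))
    if kind == "angle":
        i, j, k = atoms
        side = _component(nbrs, k, {j}) - {j}
        if i in side:
            raise ValueError("angle arms are connected; supply moving_set")
        return tuple(sorted(side))
    if kind == "torsion":
        i, j, k, l = atoms
        side = _component(nbrs, k, {j}) - {k}
        if j in side or i in side:
            raise ValueError("torsion axis lies in a cycle; supply moving_set")
        return tuple(sorted(side))
    if kind == "cluster_water_distance":
        c, o = atoms
        side = _component(nbrs, o, {c})
        if c in side:
            raise ValueError("water is covalently fused to the cluster")
        return tuple(sorted(side))
    raise ValueError(f"unknown coordinate kind {kind!r}")


def _measure(s: Structure, coordinate: tuple) -> float:
    kind, atoms = coordinate
    if kind == "bond" or kind == "cluster_water_distance":
        return distance(s.coords, *atoms)
    if kind == "angle":
        return angle(s.coords, *atoms)
    if kind == "torsion":
        return dihedral(s.coords, *atoms)
    raise ValueError(kind)


def generate_scan(equilibrium: Structure, spec: ScanSpec) -> list[Structure]:
    """Generate distorted structures along one internal coordinate.

    The moving set is displaced rigidly: along the bond axis for bond and
    cluster-water scans, by rotation about the normal of the angle plane for
    angle scans, and about the j-k axis for torsion scans.  Every other
    internal coordinate of the moving and static fragments is untouched.
    """
    kind, atoms = spec.coordinate
    n = len(equilibrium)
    for a in list(atoms) + list(spec.moving_set):
        if not 0 <= a < n:
            raise IndexError(f"atom index {a} out of range")
    x0 = equilibrium.coords
    mov = list(spec.moving_set)
    out = []
    eq_val = _measure(equilibrium, spec.coordinate)

    if kind in ("bond", "cluster_water_distance"):
        i, j = atoms
        axis = x0[j] - x0[i]
        norm = np.linalg.norm(axis)
        if norm < 1e-8:
            raise ValueError("coincident scan atoms")
        axis = axis / norm
        for off in spec.offsets():
            x = x0.copy()
            x[mov] += off * axis
            out.append(equilibrium.with_coords(x))
        return out

    if kind == "angle":
        i, j, k = atoms
        u = x0[i] - x0[j]
        v = x0[k] - x0[j]
        nrm = np.cross(u, v)
        if np.linalg.norm(nrm) < 1e-8:
            raise ValueError("collinear atoms: angle scan axis undefined")
        nrm = nrm / np.linalg.norm(nrm)
        for off in spec.offsets():
            # rotating the k side about the plane normal by +off opens the
            # angle when the normal is u x v
            rot = Rotation.from_rotvec(np.radians(off) * nrm).as_matrix()
            x = x0.copy()
            x[mov] = (x0[mov] - x0[j]) @ rot.T + x0[j]
            got = angle(x, i, j, k)
            if abs(got - (eq_val + off)) > 1e-6:
                rot = Rotation.from_rotvec(-np.radians(off) * nrm).as_matrix()
                x = x0.copy()
                x[mov] = (x0[mov] - x0[j]) @ rot.T + x0[j]
            out.append(equilibrium.with_coords(x))
        return out

    if kind == "torsion":
        i, j, k, l = atoms
        axis = x0[k] - x0[j]
        if np.linalg.norm(axis) < 1e-8:
            raise ValueError("coincident torsion axis atoms")
        axis = axis / np.linalg.norm(axis)
        for b1, b2 in ((i, j), (k, l)):
            u = x0[b1] - x0[b2]
            if np.linalg.norm(np.cross(u, axis)) < 1e-8:
                raise ValueError("collinear atoms: torsion undefined")
        for off in spec.offsets():
            rot = Rotation.from_rotvec(np.radians(off) * axis).as_matrix()
            x = x0.copy()
            x[mov] = (x0[mov] - x0[j]) @ rot.T + x0[j]
            got = dihedral(x, i, j, k, l)
            want = eq_val + off
            if abs((got - want + 180.0) % 360.0 - 180.0) > 1e-6:
                rot = Rotation.from_rotvec(-np.radians(off) * axis).as_matrix()
                x = x0.copy()
                x[mov] = (x0[mov] - x0[j]) @ rot.T + x0[j]
            out.append(equilibrium.with_coords(x))
        return out

    raise ValueError(f"unknown coordinate kind {kind!r}")


# ---------------------------------------------------------------------------
# training-set assembly
# ---------------------------------------------------------------------------

def assemble_training_set(structures: dict[str, Structure],
                          energy_refs=(),
                          charge_refs=(),
                          geometry_refs=(),
                          partition_rule=None) -> TrainingSet:
    """Assemble weighted entries from reference data.

    ``energy_refs``: iterable of (distorted_id, equilibrium_id, value_kcal,
    weight); ``charge_refs``: (structure_id, atom_index, value_e, weight);
    ``geometry_refs``: (structure_id, atom_tuple, value, weight).
    ``partition_rule`` maps a structure id to "train" or "validation"
    (default: everything trains).
    """
    part = partition_rule or (lambda sid: "train")
    ts = TrainingSet(structures=dict(structures))
    for n, (did, eid, val, w) in enumerate(energy_refs):
        ts.entries.append(TrainingEntry(
            id=f"e{n}:{did}", kind="energy_difference",
            structure_ids=(did, eid), reference_value=float(val),
            weight=float(w), partition=part(did)))
    for n, (sid, a, val, w) in enumerate(charge_refs):
        ts.entries.append(TrainingEntry(
            id=f"q{n}:{sid}:{a}", kind="charge", structure_ids=(sid,),
            atoms=(int(a),), reference_value=float(val), weight=float(w),
            partition=part(sid)))
    for n, (sid, atoms, val, w) in enumerate(geometry_refs):
        ts.entries.append(TrainingEntry(
            id=f"g{n}:{sid}", kind="geometry_item", structure_ids=(sid,),
            atoms=tuple(int(a) for a in atoms), reference_value=float(val),
            weight=float(w), partition=part(sid)))
    ts.validate()
    return ts


# ---------------------------------------------------------------------------
# parameter masks
# ---------------------------------------------------------------------------

_SECTION_NAMES = {
    "general": None,
    "element": ELEMENT_PARAM_NAMES,
    "bond": BOND_PARAM_NAMES,
    "offdiag": OFFDIAG_PARAM_NAMES,
    "angle": ANGLE_PARAM_NAMES,
    "torsion": TORSION_PARAM_NAMES,
    "hbond": HBOND_PARAM_NAMES,
}


@dataclass
class MaskEntry:
    section: str
    key: object          # symbol, tuple of symbols, or None for general
    name: str            # parameter name within the record
    lower: float
    upper: float

    def __post_init__(self):
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)
                and self.lower < self.upper):
            raise ValueError(f"{self}: bounds must be finite with lower < upper")


@dataclass
class ParameterMask:
    """Selected force-field parameters with box bounds, exposed as a vector."""
    entries: list[MaskEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def bounds(self) -> np.ndarray:
        return np.array([[e.lower, e.upper] for e in self.entries])

    def _locate(self, ff: ForceField, e: MaskEntry):
        if e.section == "general":
            idx = [i for i, nm in GENERAL_PARAM_NAMES.items() if nm == e.name]
            if not idx:
                raise KeyError(f"unknown general parameter {e.name!r}")
            return ff.general, idx[0]
        names = _SECTION_NAMES.get(e.section)
        if names is None:
            raise KeyError(f"unknown section {e.section!r}")
        table = {"element": ff.elements, "bond": ff.bonds,
                 "offdiag": ff.offdiag, "angle": ff.angles,
                 "torsion": ff.torsions, "hbond": ff.hbonds}[e.section]
        from .forcefield import _canon_pair, _canon_quad, _canon_triple
        key = e.key
        if e.section in ("bond", "offdiag"):
            key = _canon_pair(*key)
        elif e.section == "angle":
            key = _canon_triple(*key)
        elif e.section == "torsion":
            key = _canon_quad(*key)
        elif e.section == "hbond":
            key = tuple(key)
        if key not in table:
            raise KeyError(f"no {e.section} record {key}")
        if e.name not in names:
            raise KeyError(f"no parameter {e.name!r} in section {e.section!r}")
        return table[key], names.index(e.name)

    def validate(self, ff: ForceField) -> None:
        for e in self.entries:
            self._locate(ff, e)

    def get(self, ff: ForceField) -> np.ndarray:
        return np.array([float(arr[i]) for arr, i in
                         (self._locate(ff, e) for e in self.entries)])

    def apply(self, ff: ForceField, vector: np.ndarray) -> ForceField:
        """Return a copy of *ff* with the masked parameters set to *vector*."""
        if len(vector) != len(self.entries):
            raise ValueError("vector length does not match the mask")
        out = ff.copy()
        for e, v in zip(self.entries, vector):
            arr, i = self._locate(out, e)
            arr[i] = float(v)
        return out


# ---------------------------------------------------------------------------
# cost function
# ---------------------------------------------------------------------------

def _entry_prediction(entry: TrainingEntry, ts: TrainingSet, ff: ForceField,
                      cache: dict) -> float:
    from .eem import equilibrate_charges
    from .potential import compute_energy

    def energy(sid: str) -> float:
        if ("E", sid) not in cache:
            cache[("E", sid)] = compute_energy(ts.structures[sid], ff).total
        return cache[("E", sid)]

    if entry.kind == "energy_difference":
        dist, eq = entry.structure_ids
        return energy(dist) - energy(eq)
    if entry.kind == "charge":
        sid = entry.structure_ids[0]
        if ("q", sid) not in cache:
            cache[("q", sid)] = equilibrate_charges(ts.structures[sid], ff)
        return float(cache[("q", sid)][entry.atoms[0]])
    if entry.kind == "geometry_item":
        from .dynamics import MinimizationError, minimize_structure
        sid = entry.structure_ids[0]
        if ("opt", sid) not in cache:
            try:
                cache[("opt", sid)] = minimize_structure(
                    ts.structures[sid], ff, rmsg_tol=1e-2, max_iter=300)
            except MinimizationError as exc:
                cache[("opt", sid)] = exc.best
        s = cache[("opt", sid)]
        kinds = {2: "bond", 3: "angle", 4: "torsion"}
        return _measure(s, (kinds[len(entry.atoms)], entry.atoms))
    raise ValueError(entry.kind)


def evaluate_cost(params: np.ndarray, trainset: TrainingSet,
                  ff_template: ForceField, mask: ParameterMask,
                  stage: str = "all") -> float:
    """Weighted squared-residual cost over the training partition.

    ``stage="charges_only"`` restricts the sum to charge entries (the first
    phase of the iterative protocol, in which only charge-related parameters
    are fitted); ``stage="all"`` includes every training entry.  A failed
    evaluation yields :data:`COST_PENALTY` instead of raising.
    """
    if stage not in ("all", "charges_only"):
        raise ValueError("stage must be 'all' or 'charges_only'")
    ff = mask.apply(ff_template, np.asarray(params, dtype=float))
    cache: dict = {}
    cost = 0.0
    try:
        for entry in trainset.training():
            if stage == "charges_only" and entry.kind != "charge":
                continue
            y = _entry_prediction(entry, trainset, ff, cache)
            cost += entry.weight * (y - entry.reference_value) ** 2
    except Exception:
        return COST_PENALTY
    return float(cost)


# ---------------------------------------------------------------------------
# swarm optimizer
# ---------------------------------------------------------------------------

@dataclass
class SwarmConfig:
    n_agents: int = 20
    c1: float = 2.0
    c2: float = 2.0
    omega_start: float = 0.9
    omega_end: float = 0.4
    gamma: float = 0.1
    respawn_fraction: float = 0.2
    polish_every: int = 20
    max_iters: int = 200
    seed: int = 0
    velocity_clamp: float = 0.5   # fraction of the bound range per dimension
    nm_maxiter: int = 60
    target_cost: float | None = None

    def __post_init__(self):
        if self.n_agents < 2:
            raise ValueError("need at least two agents")
        if not 0 < self.omega_end <= self.omega_start:
            raise ValueError("need 0 < omega_end <= omega_start")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0 <= self.respawn_fraction < 1:
            raise ValueError("respawn_fraction must be in [0, 1)")


@dataclass
class SwarmResult:
    forcefield: ForceField | None
    best_position: np.ndarray
    best_cost: float
    history: list[float]       # global-best cost per iteration (non-increasing)
    n_evaluations: int


def polish_nelder_mead(cost_fn, start: np.ndarray, bounds: np.ndarray,
                       maxiter: int = 200) -> np.ndarray:
    """Bounded Nelder-Mead relaxation; never returns a worse point than
    *start* (falls back to it on failure)."""
    lo, hi = bounds[:, 0], bounds[:, 1]
    start = np.clip(np.asarray(start, dtype=float), lo, hi)

    def f(x):
        return cost_fn(np.clip(x, lo, hi))

    try:
        res = _scipy_minimize(f, start, method="Nelder-Mead",
                              options={"maxiter": maxiter, "xatol": 1e-10,
                                       "fatol": 1e-12})
        x = np.clip(res.x, lo, hi)
        if cost_fn(x) <= cost_fn(start):
            return x
    except Exception:
        pass
    return start.copy()


def swarm_minimize(cost_fn, bounds: np.ndarray, cfg: SwarmConfig) -> SwarmResult:
    """Generic bounded gbest PSO with Gaussian respawn and NM polish."""
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    d = len(lo)
    rng = np.random.default_rng(cfg.seed)
    x = lo + rng.random((cfg.n_agents, d)) * span
    v = np.zeros_like(x)
    vmax = cfg.velocity_clamp * span
    nev = 0

    def ev(pt):
        nonlocal nev
        nev += 1
        return cost_fn(pt)

    cost = np.array([ev(xi) for xi in x])
    pbest = x.copy()
    pcost = cost.copy()
    g = int(np.argmin(pcost))
    gbest, gcost = pbest[g].copy(), float(pcost[g])
    history = [gcost]
    n_respawn = int(np.floor(cfg.respawn_fraction * cfg.n_agents))

    for it in range(cfg.max_iters):
        if cfg.target_cost is not None and gcost <= cfg.target_cost:
            break
        w = cfg.omega_start + (cfg.omega_end - cfg.omega_start) \
            * (it / max(cfg.max_iters - 1, 1))
        r1 = rng.random((cfg.n_agents, d))
        r2 = rng.random((cfg.n_agents, d))
        v = w * v + cfg.c1 * r1 * (pbest - x) + cfg.c2 * r2 * (gbest - x)
        v = np.clip(v, -vmax, vmax)
        x = np.clip(x + v, lo, hi)
        cost = np.array([ev(xi) for xi in x])

        # Gaussian-mutation respawn of the worst performers around the global
        # best; the best agent is never respawned
        if n_respawn:
            order = np.argsort(cost)
            worst = [a for a in order[::-1] if a != int(np.argmin(cost))][:n_respawn]
            for a in worst:
                x[a] = np.clip(gbest + rng.normal(0.0, cfg.gamma * span, d), lo, hi)
                v[a] = 0.0
                cost[a] = ev(x[a])

        # periodic local relaxation of every swarm member
        if cfg.polish_every and (it + 1) % cfg.polish_every == 0:
            for a in range(cfg.n_agents):
                xa = polish_nelder_mead(cost_fn, x[a], bounds,
                                        maxiter=cfg.nm_maxiter)
                ca = ev(xa)
                if ca <= cost[a]:
                    x[a], cost[a] = xa, ca

        improved = cost < pcost
        pbest[improved] = x[improved]
        pcost[improved] = cost[improved]
        g = int(np.argmin(pcost))
        if pcost[g] < gcost:
            gbest, gcost = pbest[g].copy(), float(pcost[g])
        history.append(gcost)
    return SwarmResult(None, gbest, gcost, history, nev)


def train_swarm(ff_template: ForceField, mask: ParameterMask,
                trainset: TrainingSet, cfg: SwarmConfig,
                stage: str = "all") -> SwarmResult:
    """Fit the masked parameters to the training set; returns the force field
    at the global-best position together with the cost history."""
    mask.validate(ff_template)

    def cost_fn(vec):
        return evaluate_cost(vec, trainset, ff_template, mask, stage=stage)

    res = swarm_minimize(cost_fn, mask.bounds, cfg)
    if not np.isfinite(res.best_cost) or res.best_cost >= COST_PENALTY:
        raise RuntimeError("all swarm evaluations failed; check the training set")
    res.forcefield = mask.apply(ff_template, res.best_position)
    return res
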