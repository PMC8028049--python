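"""Geometry optimization to an RMSG criterion and NVT molecular dynamics.

Optimization: L-BFGS with analytic gradients, converged on the
root-mean-square gradient over all 3N Cartesian components (RMSG),
the criterion used for cluster relaxation (1e-3 kcal/mol/A before MD,
1e-4 kcal/mol/A for equilibrium-geometry comparisons).

Dynamics: velocity-Verlet integration (0.1 fs production time step) with a
Berendsen weak-coupling thermostat,

    lambda = sqrt(1 + (dt/tau) (T0/T_inst - 1)),

applied to the velocities after each step (tau = 25 fs in the production
protocol; ``berendsen_tau=None`` disables the thermostat for NVE checks).
Initial velocities are Maxwell-Boltzmann at the target temperature, seeded,
with centre-of-mass motion removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .forcefield import ForceField
from .potential import Evaluator, PotentialSettings
from .structure import Frame, Structure, Trajectory
from .units import ATOMIC_MASSES, KB_KCAL, KCAL_TO_AMU_A2_FS2

__all__ = ["MDConfig", "MDState", "minimize_structure", "md_step", "run_md",
           "MinimizationError", "rmsg", "kinetic_temperature", "masses_of"]


class MinimizationError(RuntimeError):
    """Raised on non-convergence; carries the best structure found."""

    def __init__(self, msg: str, best: Structure, best_rmsg: float):
        super().__init__(msg)
        self.best = best
        self.best_rmsg = best_rmsg


def masses_of(s: Structure, ff: ForceField | None = None) -> np.ndarray:
    """Per-atom masses (amu); the force field's mass column takes precedence."""
    out = np.empty(len(s))
    for k, sym in enumerate(s.symbols):
        if ff is not None and sym in ff.elements:
            out[k] = ff.elem(sym, "mass")
        else:
            out[k] = ATOMIC_MASSES[sym]
    return out


def rmsg(forces: np.ndarray) -> float:
    """Root of the mean squared gradient component (kcal/mol/A)."""
    return float(np.sqrt(np.mean(forces**2)))


def _energy_grad(s: Structure, ff: ForceField, settings):
    ev = Evaluator(s, ff, settings=settings)
    e = ev.energy().total
    return e, -ev.forces()


def minimize_structure(s: Structure, ff: ForceField,
                       rmsg_tol: float = 1e-3,
                       max_iter: int = 2000,
                       settings: PotentialSettings | None = None) -> Structure:
    """Relax *s* until RMSG <= ``rmsg_tol`` (kcal/mol/A).

    Returns a new structure; the input is untouched.  The returned energy
    never exceeds the input energy.  Raises :class:`MinimizationError`
    (carrying the best structure) if the criterion is not met within
    ``max_iter`` L-BFGS iterations.
    """
    if rmsg_tol <= 0:
        raise ValueError("rmsg_tol must be positive")
    shape = s.coords.shape
    e0, g0 = _energy_grad(s, ff, settings)
    if rmsg(g0) <= rmsg_tol:
        return s.copy()

    def fun(x):
        e, g = _energy_grad(s.with_coords(x.reshape(shape)), ff, settings)
        return e, g.ravel()

    best = {"x": s.coords.ravel().copy(), "e": e0, "rmsg": rmsg(g0)}

    x = s.coords.ravel().copy()
    remaining = max_iter
    for _ in range(6):
        res = _scipy_minimize(
            fun, x, jac=True, method="L-BFGS-B",
            options={"maxiter": remaining, "ftol": 1e-14,
                     "gtol": rmsg_tol * 1e-2, "maxcor": 30})
        g = res.jac.reshape(shape)
        r = rmsg(g)
        if res.fun <= best["e"]:
            best = {"x": res.x.copy(), "e": res.fun, "rmsg": r}
        if r <= rmsg_tol and res.fun <= e0 + 1e-12:
            return s.with_coords(res.x.reshape(shape))
        remaining = max(remaining - res.nit, 50)
        x = res.x  # restart L-BFGS from the same point with fresh memory
        if res.nit == 0:
            break
    raise MinimizationError(
        f"RMSG {best['rmsg']:.3e} did not reach {rmsg_tol:.1e}",
        s.with_coords(best["x"].reshape(shape)), best["rmsg"])


# ---------------------------------------------------------------------------
# molecular dynamics
# ---------------------------------------------------------------------------

@dataclass
class MDConfig:
    timestep_fs: float = 0.1
    temperature: float = 300.0
    berendsen_tau_fs: float | None = 25.0   # None disables the thermostat
    n_steps: int = 1000
    seed: int = 0
    record_every: int = 10

    def __post_init__(self):
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.berendsen_tau_fs is not None and self.berendsen_tau_fs < self.timestep_fs:
            raise ValueError("berendsen_tau must be >= timestep")


@dataclass
class MDState:
    structure: Structure
    velocities: np.ndarray               # (N, 3) A/fs
    forces: np.ndarray | None = None     # (N, 3) kcal/mol/A
    breakdown: object = None
    masses: np.ndarray | None = None
    time_fs: float = 0.0
    info: dict = field(default_factory=dict)


def n_dof(s: Structure) -> int:
    """3N for periodic systems, 3N - 3 for isolated ones (COM removed)."""
    n = 3 * len(s)
    return n if s.cell is not None else max(n - 3, 1)


def kinetic_temperature(v: np.ndarray, m: np.ndarray, dof: int) -> float:
    ke = 0.5 * float(np.sum(m[:, None] * v**2)) / KCAL_TO_AMU_A2_FS2
    return 2.0 * ke / (dof * KB_KCAL)


def kinetic_energy(v: np.ndarray, m: np.ndarray) -> float:
    """Kinetic energy in kcal/mol."""
    return 0.5 * float(np.sum(m[:, None] * v**2)) / KCAL_TO_AMU_A2_FS2


def _eval(s: Structure, ff: ForceField, settings):
    ev = Evaluator(s, ff, settings=settings)
    br = ev.energy()
    return br, ev.forces()


def md_step(state: MDState, ff: ForceField, cfg: MDConfig,
            settings: PotentialSettings | None = None) -> MDState:
    """One velocity-Verlet step followed by the Berendsen velocity rescale."""
    s = state.structure
    m = state.masses if state.masses is not None else masses_of(s, ff)
    if state.forces is None:
        br, f = _eval(s, ff, settings)
    else:
        br, f = state.breakdown, state.forces
    dt = cfg.timestep_fs
    acc = f * KCAL_TO_AMU_A2_FS2 / m[:, None]          # A/fs^2
    v_half = state.velocities + 0.5 * dt * acc
    x_new = s.coords + dt * v_half
    if not np.all(np.isfinite(x_new)):
        raise FloatingPointError("non-finite coordinates: MD blow-up detected")
    s_new = s.with_coords(x_new)
    br_new, f_new = _eval(s_new, ff, settings)
    acc_new = f_new * KCAL_TO_AMU_A2_FS2 / m[:, None]
    v_new = v_half + 0.5 * dt * acc_new
    if cfg.berendsen_tau_fs is not None:
        t_inst = kinetic_temperature(v_new, m, n_dof(s))
        if t_inst > 0:
            lam = np.sqrt(1.0 + (dt / cfg.berendsen_tau_fs)
                          * (cfg.temperature / t_inst - 1.0))
            v_new = v_new * lam
    return MDState(structure=s_new, velocities=v_new, forces=f_new,
                   breakdown=br_new, masses=m, time_fs=state.time_fs + dt)


def init_velocities(s: Structure, m: np.ndarray, temperature: float,
                    seed: int) -> np.ndarray:
    """Maxwell-Boltzmann velocities with centre-of-mass motion removed."""
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(KB_KCAL * temperature * KCAL_TO_AMU_A2_FS2 / m)
    v = rng.normal(size=(len(s), 3)) * sigma[:, None]
    v -= (m[:, None] * v).sum(axis=0) / m.sum()
    return v


def run_md(s: Structure, ff: ForceField, cfg: MDConfig,
           settings: PotentialSettings | None = None,
           velocities: np.ndarray | None = None) -> Trajectory:
    """Run NVT (or NVE with the thermostat disabled) dynamics.

    Deterministic for a fixed ``cfg.seed``.  Frames (including the initial
    state) are recorded every ``cfg.record_every`` steps, plus the final step.
    """
    m = masses_of(s, ff)
    if velocities is None:
        velocities = init_velocities(s, m, cfg.temperature, cfg.seed)
    br, f = _eval(s, ff, settings)
    state = MDState(structure=s.copy(), velocities=velocities.copy(),
                    forces=f, breakdown=br, masses=m, time_fs=0.0)
    dof = n_dof(s)

    def frame(st: MDState) -> Frame:
        return Frame(time_fs=st.time_fs, structure=st.structure.copy(),
                     velocities=st.velocities.copy(),
                     temperature=kinetic_temperature(st.velocities, m, dof),
                     breakdown=st.breakdown)

    frames = [frame(state)]
    for step in range(1, cfg.n_steps + 1):
        state = md_step(state, ff, cfg, settings)
        if step % cfg.record_every == 0 or step == cfg.n_steps:
            frames.append(frame(state))
    return Trajectory(frames)
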