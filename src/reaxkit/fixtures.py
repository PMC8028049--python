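"""Deterministic synthetic inputs: toy force fields, reference geometries,
solvated boxes, and synthetic training sets.

The built-in H/O/Fe/S parameter set is a self-contained, physically plausible
toy force field assembled for testing and demonstration: water is a stable
bent molecule, Fe2S2 a planar rhombus, hydrogen bonds form between water and
O/S acceptors.  It makes no claim to quantitative accuracy against quantum
reference data; it exists so that every capability of the package can be
exercised without external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forcefield import (ANGLE_PARAM_NAMES, BOND_PARAM_NAMES,
                         ELEMENT_PARAM_NAMES, GENERAL_PARAM_NAMES,
                         HBOND_PARAM_NAMES, OFFDIAG_PARAM_NAMES,
                         TORSION_PARAM_NAMES, ForceField, _canon_pair,
                         _canon_quad, _canon_triple)
from .structure import Structure

__all__ = ["make_toy_forcefield", "water", "water_dimer", "fe2s2",
           "fe2s2_w4", "BoxSpec", "build_solvated_box",
           "make_synthetic_trainset", "PackingError"]

# --------------------------------------------------------------------------
# default parameter tables
# --------------------------------------------------------------------------

_GENERAL = [
    50.0000, 9.5469, 26.5405, 1.7224, 6.8702, 60.4850, 1.0588, 4.6000,
    12.1176, 13.3056, -70.5044, 0.0000, 10.0000, 2.8793, 33.8667, 6.0891,
    1.0563, 2.0384, 6.1431, 6.9290, 0.3989, 3.9954, -2.4837, 5.7796,
    10.0000, 1.9487, -1.2327, 2.1645, 1.5591, 0.1000, 2.1365, 0.6991,
    50.0000, 1.8512, 0.5000, 20.0000, 5.0000, 0.0000, 2.6962,
]

_ELEMENTS = {
    "H": [0.8930, 1.0000, 1.0080, 1.3550, 0.0930, 0.8203, -0.1000, 1.0000,
          8.2230, 33.2894, 1.0000, 0.0000, 121.1250, 3.7248, 9.6093, 1.0000,
          -0.1000, 0.0000, 61.6606, 3.0408, 2.4197, 0.0003, 1.0698, 0.0000,
          -19.4571, 4.2733, 1.0338, 1.0000, 2.8793, 0.0000, 0.0000, 0.0000],
    "O": [1.2450, 2.0000, 15.9990, 2.3890, 0.1000, 1.0898, 1.0548, 6.0000,
          9.7300, 13.8449, 4.0000, 37.5000, 116.0768, 8.5000, 8.3122, 2.0000,
          0.9049, 0.4056, 59.0626, 3.5027, 0.7640, 0.0021, 0.9745, 0.0000,
          -3.5500, 2.9000, 1.0493, 4.0000, 2.9225, 0.0000, 0.0000, 0.0000],
    "S": [1.9405, 2.0000, 32.0600, 1.9113, 0.2176, 1.0336, 1.5479, 6.0000,
          9.9575, 4.9055, 4.0000, 52.9998, 112.1416, 6.5745, 8.2545, 2.0000,
          1.4601, 9.7177, 71.1843, 5.7487, 23.2859, 12.7147, 0.9745, 0.0000,
          -11.0365, 2.7466, 1.0338, 6.2545, 2.9225, 0.0000, 0.0000, 0.0000],
    "Fe": [1.9306, 3.0000, 55.8450, 2.0308, 0.1181, 0.4744, -1.6836, 3.0000,
           10.8548, 2.6084, 3.0000, 0.0000, 18.6431, 1.7785, 8.6281, 0.0000,
           -1.2000, 0.0000, 66.4838, 30.0000, 1.0000, 0.0000, 0.9745, 0.0000,
           -16.0573, 2.6997, 1.0338, 6.0000, 2.5791, 0.0000, 0.0000, 0.0000],
}

_BONDS = {
    ("H", "H"): [153.3934, 0.0, 0.0, -0.4600, 0.0, 1.0, 6.0000, 0.7300,
                 6.2500, 1.0, 0.0, 1.0, -0.0790, 6.0552, 0.0, 0.0],
    ("H", "O"): [160.0000, 0.0, 0.0, -0.5725, 0.0, 1.0, 6.0000, 0.5626,
                 1.1150, 1.0, 0.0, 1.0, -0.0920, 4.2790, 0.0, 0.0],
    ("O", "O"): [142.2858, 145.0000, 50.8293, 0.2506, -0.1000, 1.0, 29.7503,
                 0.6051, 0.3451, -0.1055, 9.0000, 1.0, -0.1225, 5.5000, 1.0, 0.0],
    ("S", "S"): [86.8868, 70.0453, 0.0, 0.0955, -0.4721, 1.0, 17.8574, 0.6000,
                 0.2723, -0.1681, 8.1861, 1.0, -0.1131, 6.6539, 1.0, 0.0],
    ("H", "S"): [130.0000, 0.0, 0.0, -0.4721, 0.0, 1.0, 6.0000, 0.6000,
                 1.0000, 1.0, 0.0, 1.0, -0.0700, 5.0000, 0.0, 0.0],
    ("O", "S"): [115.0000, 60.0000, 0.0, -0.2000, 0.0, 1.0, 6.0000, 0.5000,
                 0.5000, -0.1200, 8.0000, 1.0, -0.1100, 5.8000, 1.0, 0.0],
    ("Fe", "Fe"): [41.4611, 0.0, 0.0, 0.2931, 0.0, 1.0, 6.0000, 0.2682,
                   1.0000, 1.0, 0.0, 1.0, -0.0512, 6.8013, 0.0, 0.0],
    ("Fe", "O"): [65.7713, 0.0, 0.0, 0.1366, 0.0, 1.0, 6.0000, 0.0494,
                  1.0000, 1.0, 0.0, 1.0, -0.0800, 7.5000, 0.0, 0.0],
    ("Fe", "S"): [75.0000, 0.0, 0.0, 0.1500, 0.0, 1.0, 6.0000, 0.1000,
                  0.5000, 1.0, 0.0, 1.0, -0.0750, 6.5000, 0.0, 0.0],
    ("Fe", "H"): [55.0000, 0.0, 0.0, -0.1000, 0.0, 1.0, 6.0000, 0.3000,
                  1.0000, 1.0, 0.0, 1.0, -0.0650, 6.0000, 0.0, 0.0],
}

_OFFDIAG = {
    ("H", "O"): [0.0283, 1.2885, 10.9190, 0.9215, -1.0, -1.0],
    ("H", "S"): [0.0500, 1.7025, 10.0000, 1.3500, -1.0, -1.0],
    ("Fe", "O"): [0.0846, 1.4284, 10.0308, 1.8000, -1.0, -1.0],
    ("Fe", "S"): [0.1500, 1.8500, 10.5000, 2.0000, -1.0, -1.0],
}

_ANGLES = {
    ("H", "O", "H"): [85.8000, 9.8453, 2.2720, 0.0, 2.8635, 0.0, 1.5800],
    ("H", "O", "O"): [75.6935, 50.0000, 2.0000, 0.0, 1.0000, 0.0, 1.1680],
    ("O", "O", "O"): [80.7324, 30.4554, 0.9953, 0.0, 1.6310, 50.0, 1.0783],
    ("S", "Fe", "S"): [75.0000, 25.0000, 2.0000, 0.0, 1.5000, 0.0, 1.5000],
    ("Fe", "S", "Fe"): [75.0000, 25.0000, 2.0000, 0.0, 1.5000, 0.0, 1.5000],
    ("O", "Fe", "O"): [80.0000, 20.0000, 2.0000, 0.0, 1.5000, 0.0, 1.2000],
    ("O", "Fe", "S"): [80.0000, 20.0000, 2.0000, 0.0, 1.5000, 0.0, 1.2000],
    ("Fe", "O", "H"): [90.0000, 15.0000, 2.0000, 0.0, 1.5000, 0.0, 1.2000],
    ("Fe", "O", "Fe"): [90.0000, 15.0000, 2.0000, 0.0, 1.5000, 0.0, 1.2000],
    ("H", "S", "H"): [85.0000, 15.0000, 2.0000, 0.0, 1.5000, 0.0, 1.2000],
    ("Fe", "S", "H"): [90.0000, 10.0000, 2.0000, 0.0, 1.5000, 0.0, 1.2000],
    ("S", "S", "Fe"): [85.0000, 15.0000, 2.0000, 0.0, 1.5000, 0.0, 1.2000],
    ("S", "S", "S"): [80.0000, 20.0000, 2.0000, 0.0, 1.5000, 0.0, 1.2000],
    # hydrogen-centred angles carry no three-body energy
    ("O", "H", "O"): [0.0, 0.0, 6.0000, 0.0, 0.0, 0.0, 1.0400],
    ("O", "H", "S"): [0.0, 0.0, 6.0000, 0.0, 0.0, 0.0, 1.0400],
    ("S", "H", "S"): [0.0, 0.0, 6.0000, 0.0, 0.0, 0.0, 1.0400],
    ("H", "H", "O"): [0.0, 0.0, 6.0000, 0.0, 0.0, 0.0, 1.0400],
    ("H", "H", "H"): [0.0, 0.0, 6.0000, 0.0, 0.0, 0.0, 1.0400],
    ("H", "H", "S"): [0.0, 0.0, 6.0000, 0.0, 0.0, 0.0, 1.0400],
    ("Fe", "H", "O"): [0.0, 0.0, 6.0000, 0.0, 0.0, 0.0, 1.0400],
}

_TORSIONS = {
    ("X", "O", "O", "X"): [0.5511, 25.4150, 1.1330, -5.1903, -1.0000, 0.0, 0.0],
    ("X", "S", "S", "X"): [2.4661, 35.0000, 0.2000, -8.0000, 0.0, 0.0, 0.0],
    ("X", "Fe", "S", "X"): [0.0, 5.0000, 0.0, -4.0000, 0.0, 0.0, 0.0],
    ("X", "Fe", "O", "X"): [0.0, 3.0000, 0.0, -4.0000, 0.0, 0.0, 0.0],
    ("X", "Fe", "Fe", "X"): [0.0, 2.0000, 0.0, -4.0000, 0.0, 0.0, 0.0],
}

_HBONDS = {
    ("O", "H", "O"): [2.1200, -3.5800, 1.4500, 19.5000],
    ("O", "H", "S"): [2.5000, -2.0000, 1.4500, 19.5000],
    ("S", "H", "O"): [2.5000, -2.0000, 1.4500, 19.5000],
    ("S", "H", "S"): [2.7500, -1.5000, 1.4500, 19.5000],
}

_SECTION_NAMES = {
    "general": list(GENERAL_PARAM_NAMES.values()),
    "element": ELEMENT_PARAM_NAMES,
    "bond": BOND_PARAM_NAMES,
    "offdiag": OFFDIAG_PARAM_NAMES,
    "angle": ANGLE_PARAM_NAMES,
    "torsion": TORSION_PARAM_NAMES,
    "hbond": HBOND_PARAM_NAMES,
}


def make_toy_forcefield(elements=("H", "O", "Fe", "S"), overrides=None) -> ForceField:
    """Assemble the built-in toy force field restricted to *elements*.

    ``overrides`` maps ``(section, key, param_name) -> value``; ``key`` is a
    symbol (element section), a tuple of symbols (bond/offdiag/angle/torsion/
    hbond) or ``None`` (general).  Targeting a nonexistent parameter raises
    ``KeyError``.
    """
    elements = list(elements)
    unknown = set(elements) - set(_ELEMENTS)
    if unknown:
        raise KeyError(f"no default parameters for elements {sorted(unknown)}")
    es = set(elements) | {"X"}
    ff = ForceField(general=np.array(_GENERAL, dtype=float), header="reaxkit toy H/O/Fe/S force field")
    for s in elements:
        ff.elements[s] = np.array(_ELEMENTS[s], dtype=float)
    ff.bonds = {_canon_pair(*k): np.array(v) for k, v in _BONDS.items() if set(k) <= es}
    ff.offdiag = {_canon_pair(*k): np.array(v) for k, v in _OFFDIAG.items() if set(k) <= es}
    ff.angles = {_canon_triple(*k): np.array(v) for k, v in _ANGLES.items() if set(k) <= es}
    ff.torsions = {_canon_quad(*k): np.array(v) for k, v in _TORSIONS.items() if set(k) <= es}
    ff.hbonds = {k: np.array(v) for k, v in _HBONDS.items() if set(k) <= es}

    for (section, key, name), value in (overrides or {}).items():
        names = _SECTION_NAMES.get(section)
        if names is None:
            raise KeyError(f"unknown force-field section {section!r}")
        if name not in names:
            raise KeyError(f"no parameter {name!r} in section {section!r}")
        if section == "general":
            idx = [i for i, nm in GENERAL_PARAM_NAMES.items() if nm == name][0]
            ff.general[idx] = value
            continue
        table = {"element": ff.elements, "bond": ff.bonds, "offdiag": ff.offdiag,
                 "angle": ff.angles, "torsion": ff.torsions, "hbond": ff.hbonds}[section]
        if section == "element":
            k = key
        elif section in ("bond", "offdiag"):
            k = _canon_pair(*key)
        elif section == "angle":
            k = _canon_triple(*key)
        elif section == "torsion":
            k = _canon_quad(*key)
        else:
            k = tuple(key)
        if k not in table:
            raise KeyError(f"no {section} record {k}")
        table[k][names.index(name)] = value
    ff.validate()
    return ff


# --------------------------------------------------------------------------
# reference geometries
# --------------------------------------------------------------------------

WATER_OH = 0.9572       # A
WATER_HOH = 104.52      # deg


def _water_coords(oh=WATER_OH, hoh=WATER_HOH) -> np.ndarray:
    a = np.radians(hoh / 2.0)
    return np.array([
        [0.0, 0.0, 0.0],
        [oh * np.sin(a), oh * np.cos(a), 0.0],
        [-oh * np.sin(a), oh * np.cos(a), 0.0],
    ])


def water() -> Structure:
    return Structure(["O", "H", "H"], _water_coords())


def water_dimer(r_oo: float = 2.95) -> Structure:
    """Hydrogen-bonded water dimer; donor O-H points at the acceptor O."""
    don = _water_coords()
    # orient so one O-H bond lies along +x
    oh = don[1] - don[0]
    c, s2 = oh[0] / np.linalg.norm(oh), oh[1] / np.linalg.norm(oh)
    rot = np.array([[c, s2, 0], [-s2, c, 0], [0, 0, 1.0]])
    don = don @ rot.T
    acc = _water_coords() @ np.array([[0, 0, 1.0], [0, 1.0, 0], [-1.0, 0, 0]]).T
    acc = acc + np.array([r_oo, 0.0, 0.0])
    return Structure(["O", "H", "H", "O", "H", "H"], np.vstack([don, acc]))


def fe2s2(d_fe_s: float = 2.30, d_fe_fe: float = 3.27) -> Structure:
    """Planar Fe2S2 rhombus with the given Fe-S and Fe-Fe distances."""
    half = d_fe_fe / 2.0
    y = np.sqrt(max(d_fe_s**2 - half**2, 1e-12))
    coords = np.array([
        [-half, 0.0, 0.0], [half, 0.0, 0.0],
        [0.0, y, 0.0], [0.0, -y, 0.0],
    ])
    return Structure(["Fe", "Fe", "S", "S"], coords)


def fe2s2_w4(d_fe_o: float = 2.1) -> Structure:
    """Tetrahedrally coordinated Fe2S2(H2O)4: two waters per iron site, with
    each water's hydrogens pointing away from the iron."""
    from scipy.spatial.transform import Rotation

    core = fe2s2()
    symbols = list(core.symbols)
    parts = [core.coords]
    wat = _water_coords()  # O at origin, hydrogens on the +y side
    bisector = np.array([[0.0, 1.0, 0.0]])
    for k, fe in enumerate(core.coords[:2]):
        sgn = -1.0 if k == 0 else 1.0
        for dz in (1.0, -1.0):
            direction = np.array([sgn, 0.0, 0.7 * dz])
            direction /= np.linalg.norm(direction)
            rot, _ = Rotation.align_vectors(direction[None, :], bisector)
            wc = wat @ rot.as_matrix().T + fe + d_fe_o * direction
            symbols += ["O", "H", "H"]
            parts.append(wc)
    return Structure(symbols, np.vstack(parts))


# --------------------------------------------------------------------------
# solvated boxes
# --------------------------------------------------------------------------

class PackingError(RuntimeError):
    pass


@dataclass
class BoxSpec:
    cell: tuple[float, float, float]
    n_waters: int
    solute: Structure | None = None
    min_separation: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_waters < 0:
            raise ValueError("n_waters must be nonnegative")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")


def _min_image_dists(a: np.ndarray, b: np.ndarray, cell: np.ndarray) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    d -= np.round(d / cell) * cell
    return np.linalg.norm(d, axis=-1)


def build_solvated_box(spec: BoxSpec) -> Structure:
    """Pack rigid waters around a centred solute on a jittered lattice with
    seeded random orientations; heavy-atom contacts below ``min_separation``
    (minimum image) are rejected."""
    cell = np.asarray(spec.cell, dtype=float)
    rng = np.random.default_rng(spec.seed)
    symbols: list[str] = []
    coords_parts = []
    heavy = []  # heavy-atom coordinates placed so far
    if spec.solute is not None:
        sol = spec.solute.coords - spec.solute.coords.mean(axis=0) + cell / 2.0
        symbols += list(spec.solute.symbols)
        coords_parts.append(sol)
        heavy = [sol[k] for k, s in enumerate(spec.solute.symbols) if s != "H"]
    total_charge = spec.solute.total_charge if spec.solute is not None else 0.0

    if spec.n_waters:
        # candidate lattice with enough head-room over the requested count
        k = np.maximum(np.floor(cell / 3.0).astype(int), 1)
        while np.prod(k) < 1.6 * spec.n_waters + len(heavy):
            k[np.argmin(k * 1.0 / cell)] += 1
        grid = []
        for ix in range(k[0]):
            for iy in range(k[1]):
                for iz in range(k[2]):
                    grid.append((np.array([ix, iy, iz]) + 0.5) / k * cell)
        grid = np.array(grid)
        if heavy:
            d = _min_image_dists(grid, np.array(heavy), cell)
            grid = grid[d.min(axis=1) >= spec.min_separation + 0.8]
        if len(grid) < spec.n_waters:
            raise PackingError(
                f"only {len(grid)} lattice sites available for {spec.n_waters} waters")
        wat = _water_coords()
        for attempt in range(25):
            order = rng.permutation(len(grid))
            sites = grid[order[:spec.n_waters]]
            jitter = rng.uniform(-0.3, 0.3, size=sites.shape)
            placed_o = []
            frames = []
            ok = True
            for site, jit in zip(sites, jitter):
                o_pos = site + jit
                from scipy.spatial.transform import Rotation
                rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
                frames.append((wat - wat[0]) @ rot.T + o_pos)
                placed_o.append(o_pos)
            placed_o = np.array(placed_o)
            others = np.array(heavy) if heavy else np.zeros((0, 3))
            all_ref = np.vstack([others, placed_o]) if len(others) else placed_o
            d = _min_image_dists(placed_o, all_ref, cell)
            # ignore each oxygen's zero distance to itself
            d[d < 1e-9] = np.inf
            if np.all(d.min(axis=1) >= spec.min_separation):
                for fr in frames:
                    symbols += ["O", "H", "H"]
                    coords_parts.append(fr)
                break
            ok = False
        else:
            raise PackingError("could not pack waters at the requested separation")
    coords = np.vstack(coords_parts) if coords_parts else np.zeros((0, 3))
    return Structure(symbols, coords, cell=cell, total_charge=total_charge)


# --------------------------------------------------------------------------
# synthetic training sets
# --------------------------------------------------------------------------

def make_synthetic_trainset(ff_truth, geometries: dict, scans,
                            noise_sd: float = 0.0, seed: int = 0,
                            include_charges: bool = True,
                            weight: float = 1.0,
                            partition_rule=None):
    """Build a training set whose reference values are the predictions of a
    known force field (optionally Gaussian-perturbed).

    ``geometries`` maps structure id -> equilibrium :class:`Structure`;
    ``scans`` is a list of ``(equilibrium_id, ScanSpec)`` pairs.  With
    ``noise_sd = 0`` the cost of the generating parameters is exactly zero,
    enabling parameter-recovery testing.
    """
    from .eem import equilibrate_charges
    from .potential import compute_energy
    from .trainset import TrainingEntry, TrainingSet
    from .training import generate_scan

    rng = np.random.default_rng(seed)
    part = partition_rule or (lambda sid: "train")
    ts = TrainingSet()
    eq_energy: dict[str, float] = {}
    for sid, s in geometries.items():
        ts.structures[sid] = s.copy()
        eq_energy[sid] = compute_energy(s, ff_truth).total
        if include_charges:
            q = equilibrate_charges(s, ff_truth)
            for a in range(len(s)):
                ref = q[a] + (rng.normal(0, noise_sd) if noise_sd else 0.0)
                ts.entries.append(TrainingEntry(
                    id=f"{sid}:q{a}", kind="charge", structure_ids=(sid,),
                    atoms=(a,), reference_value=float(ref), weight=weight,
                    partition=part(sid)))
    for eq_id, spec in scans:
        eq = geometries[eq_id]
        for k, dist in enumerate(generate_scan(eq, spec)):
            sid = f"{eq_id}:{spec.coordinate[0]}{k}"
            ts.structures[sid] = dist
            de = compute_energy(dist, ff_truth).total - eq_energy[eq_id]
            if noise_sd:
                de += rng.normal(0, noise_sd)
            ts.entries.append(TrainingEntry(
                id=f"e:{sid}", kind="energy_difference",
                structure_ids=(sid, eq_id), reference_value=float(de),
                weight=weight, partition=part(eq_id)))
    ts.validate()
    return ts
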