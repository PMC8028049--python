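"""Force-field quality metrics and solvation analysis.

Includes a MINPERMDIST-style aligned RMSD (minimum over translation, proper
rotation, per-element permutation, and overall inversion), hydrogen-bond
counting with donor-acceptor distance/linearity cutoffs (3.7 A and 20 deg by
default), windowed trajectory statistics, symmetry-unique geometry deviation
reports, and correlation/charge comparison tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation
from scipy.stats import linregress

from .structure import Structure, Trajectory, angle, dihedral, distance
from .trainset import TrainingSet
from .units import COVALENT_RADII

__all__ = ["aligned_rmsd", "HBondCriteria", "count_hbonds",
           "trajectory_statistics", "TrajectoryStats", "DeviationReport",
           "geometry_deviation_report", "prediction_correlation_report",
           "charge_report", "kabsch_rmsd", "classify_fe_coordination"]


# ---------------------------------------------------------------------------
# permutation-inversion RMSD
# ---------------------------------------------------------------------------

def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD after optimal proper rotation of centred coordinate sets."""
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    det = np.sign(np.linalg.det(u @ vt))
    s = s.copy()
    s[-1] *= det
    msd = (np.sum(a**2) + np.sum(b**2) - 2.0 * np.sum(s)) / len(a)
    return float(np.sqrt(max(msd, 0.0)))


def _kabsch_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing |a - b @ R.T| (rows of b rotated onto a)."""
    h = b.T @ a
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def aligned_rmsd(a: Structure, b: Structure, n_starts: int = 12,
                 seed: int = 0, return_permutation: bool = False):
    """Minimum RMSD over translation, rotation, per-element permutation, and
    inversion.

    Alternates optimal assignment (Hungarian algorithm on squared distances,
    within each element class) with optimal rotation until a fixed point,
    from ``n_starts`` initial orientations and for both parities, keeping the
    best result.  Raises ``ValueError`` if the element multisets differ.
    """
    if sorted(a.symbols) != sorted(b.symbols):
        raise ValueError("structures have different element compositions")
    xa = a.coords - a.coords.mean(axis=0)
    xb = b.coords - b.coords.mean(axis=0)
    n = len(xa)
    classes = {}
    for k, sym in enumerate(a.symbols):
        classes.setdefault(sym, [])
    idx_a = {sym: [k for k, s2 in enumerate(a.symbols) if s2 == sym]
             for sym in classes}
    idx_b = {sym: [k for k, s2 in enumerate(b.symbols) if s2 == sym]
             for sym in classes}

    rng = np.random.default_rng(seed)
    starts = [np.eye(3)]
    starts += [Rotation.random(random_state=rng).as_matrix()
               for _ in range(max(n_starts - 1, 0))]

    best = np.inf
    best_perm = None
    for parity in (1.0, -1.0):
        xb_p = parity * xb
        for r0 in starts:
            xr = xb_p @ r0.T
            perm = np.arange(n)
            for _ in range(60):
                new_perm = np.empty(n, dtype=int)
                for sym in idx_a:
                    ia = np.array(idx_a[sym])
                    ib = np.array(idx_b[sym])
                    cost = ((xa[ia][:, None, :] - xr[ib][None, :, :]) ** 2).sum(-1)
                    rows, cols = linear_sum_assignment(cost)
                    new_perm[ia[rows]] = ib[cols]
                # rotate the current orientation onto xa under the new matching
                rot = _kabsch_rotation(xa, xr[new_perm])
                xr_new = xr @ rot.T
                if np.array_equal(new_perm, perm) and np.allclose(
                        rot, np.eye(3), atol=1e-13):
                    break
                perm, xr = new_perm, xr_new
            val = np.sqrt(np.mean(np.sum((xa - xr[perm]) ** 2, axis=1)))
            if val < best:
                best = float(val)
                best_perm = perm.copy()
    if return_permutation:
        return best, best_perm
    return best


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass
class HBondCriteria:
    """Donor-acceptor cutoffs: D...A distance and deviation from linearity.

    The angular criterion is applied to the angle between the D->H and D->A
    directions (<= angular_max means a near-linear D-H...A arrangement).
    ``convention="dha_angle"`` switches to the D-H...A angle at the hydrogen
    vertex, with the cutoff interpreted as 180 deg - angular_max.
    """
    donor_acceptor_max_distance: float = 3.7
    angular_max: float = 20.0
    convention: str = "deviation"   # or "dha_angle"
    dh_max: float = 1.3             # covalent D-H assignment scale factor

    def __post_init__(self):
        if self.donor_acceptor_max_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.angular_max <= 180:
            raise ValueError("angular cutoff must be in (0, 180]")
        if self.convention not in ("deviation", "dha_angle"):
            raise ValueError("convention must be 'deviation' or 'dha_angle'")


def _mi_vec(a: np.ndarray, b: np.ndarray, cell) -> np.ndarray:
    d = b - a
    if cell is not None:
        d = d - np.round(d / cell) * cell
    return d


def count_hbonds(frame: Structure, cluster=None,
                 crit: HBondCriteria | None = None,
                 donor_elements=("O", "S"), acceptor_elements=("O", "S"),
                 count_pairs: bool = False):
    """Count D-H...A hydrogen bonds in a frame.

    Covalent D-H pairs are assigned by a distance heuristic (H within
    ``crit.dh_max`` times the covalent-radius sum of a donor heavy atom).
    When ``cluster`` (an index set) is given, only bonds with exactly one
    partner in the cluster are counted -- the cluster-water hydrogen bonds.
    Distances use the minimum image under periodic boundaries.
    """
    crit = crit or HBondCriteria()
    cell = frame.cell
    x = frame.coords
    syms = frame.symbols
    cluster = set() if cluster is None else set(cluster)
    donors = [k for k, s in enumerate(syms) if s in donor_elements]
    acceptors = [k for k, s in enumerate(syms) if s in acceptor_elements]
    hydrogens = [k for k, s in enumerate(syms) if s == "H"]
    if not donors or not acceptors:
        return 0

    count = 0
    pairs = []
    for d in donors:
        rd = COVALENT_RADII.get(syms[d], 1.0)
        for h in hydrogens:
            vdh = _mi_vec(x[d], x[h], cell)
            if np.linalg.norm(vdh) > crit.dh_max * (rd + COVALENT_RADII["H"]):
                continue
            for a in acceptors:
                if a == d:
                    continue
                if cluster and (d in cluster) == (a in cluster):
                    continue
                vda = _mi_vec(x[d], x[a], cell)
                rda = np.linalg.norm(vda)
                if rda > crit.donor_acceptor_max_distance or rda < 1e-6:
                    continue
                if crit.convention == "deviation":
                    c = float(vdh @ vda) / (np.linalg.norm(vdh) * rda)
                    dev = np.degrees(np.arccos(np.clip(c, -1, 1)))
                    if dev <= crit.angular_max:
                        count += 1
                        pairs.append((d, h, a))
                else:
                    vhd = -vdh
                    vha = _mi_vec(x[h], x[a], cell)
                    c = float(vhd @ vha) / (np.linalg.norm(vhd) * np.linalg.norm(vha))
                    ang = np.degrees(np.arccos(np.clip(c, -1, 1)))
                    if ang >= 180.0 - crit.angular_max:
                        count += 1
                        pairs.append((d, h, a))
    if count_pairs:
        return count, pairs
    return count


def classify_fe_coordination(frame: Structure, fe_indices,
                             cutoff: float = 2.8) -> dict[int, int]:
    """Number of oxygen atoms within ``cutoff`` of each iron site (3, 4, 5 =
    trigonal, tetrahedral, trigonal-bipyramidal water coordination)."""
    out = {}
    x = frame.coords
    oxy = [k for k, s in enumerate(frame.symbols) if s == "O"]
    for fe in fe_indices:
        c = 0
        for o in oxy:
            if np.linalg.norm(_mi_vec(x[fe], x[o], frame.cell)) <= cutoff:
                c += 1
        out[fe] = c
    return out


# ---------------------------------------------------------------------------
# trajectory statistics
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryStats:
    """Mean and population SD of named observables over an analysis window."""
    window: tuple[float, float]
    n_frames: int
    stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def mean(self, name: str) -> float:
        return self.stats[name][0]

    def sd(self, name: str) -> float:
        return self.stats[name][1]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, m, sd) for k, (m, sd) in self.stats.items()],
            columns=["observable", "mean", "sd"])


def _mi_distance(x, i, j, cell) -> float:
    return float(np.linalg.norm(_mi_vec(x[i], x[j], cell)))


def trajectory_statistics(traj: Trajectory, window: tuple[float, float],
                          distances: dict[str, list[tuple[int, int]]] | None = None,
                          dihedrals: dict[str, tuple[int, int, int, int]] | None = None,
                          hbond_cluster=None,
                          crit: HBondCriteria | None = None) -> TrajectoryStats:
    """Per-frame observables averaged over a time window.

    ``distances`` maps a name to a list of atom pairs whose (minimum-image)
    lengths are averaged within each frame -- e.g. the four symmetry-
    equivalent Fe-S pairs pooled into one mean.  Dihedral angles are folded
    to [0, 180] degrees.  If ``hbond_cluster`` is given, the cluster-water
    hydrogen-bond count is tracked as ``n_hbond``.
    """
    frames = [f for f in traj.frames if window[0] <= f.time_fs <= window[1]]
    if not frames:
        raise ValueError("analysis window contains no frames")
    series: dict[str, list[float]] = {}
    for fr in frames:
        s = fr.structure
        for name, pairs in (distances or {}).items():
            for (i, j) in pairs:
                if not (0 <= i < len(s) and 0 <= j < len(s)):
                    raise IndexError(f"named atoms out of range for {name!r}")
            val = float(np.mean([_mi_distance(s.coords, i, j, s.cell)
                                 for (i, j) in pairs]))
            series.setdefault(name, []).append(val)
        for name, (i, j, k, l) in (dihedrals or {}).items():
            val = abs(dihedral(s.coords, i, j, k, l))
            series.setdefault(name, []).append(val)
        if hbond_cluster is not None:
            series.setdefault("n_hbond", []).append(
                float(count_hbonds(s, cluster=hbond_cluster, crit=crit)))
    stats = {k: (float(np.mean(v)), float(np.std(v))) for k, v in series.items()}
    return TrajectoryStats(window=window, n_frames=len(frames), stats=stats)


# ---------------------------------------------------------------------------
# geometry deviation report
# ---------------------------------------------------------------------------

def _topology_graph(s: Structure, scale: float = 1.3):
    import networkx as nx
    g = nx.Graph()
    for k, sym in enumerate(s.symbols):
        g.add_node(k, element=sym)
    r = {k: COVALENT_RADII.get(sym, 1.0) for k, sym in enumerate(s.symbols)}
    for i in range(len(s)):
        for j in range(i + 1, len(s)):
            if distance(s.coords, i, j) < scale * (r[i] + r[j]):
                g.add_edge(i, j)
    return g


def _unique_coordinates(g):
    """Bonds, angles, torsions of the topology graph, one representative per
    orbit of the element-preserving automorphism group."""
    import networkx as nx
    gm = nx.algorithms.isomorphism.GraphMatcher(
        g, g, node_match=lambda a, b: a["element"] == b["element"])
    autos = []
    for n, mapping in enumerate(gm.isomorphisms_iter()):
        autos.append(mapping)
        if n >= 2000:
            break

    bonds = []
    for (i, j) in g.edges:
        bonds.append((i, j) if i < j else (j, i))
    angles = []
    for j in g.nodes:
        nbrs = sorted(g.neighbors(j))
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                angles.append((nbrs[a], j, nbrs[b]))
    torsions = []
    for (j, k) in g.edges:
        for i in g.neighbors(j):
            if i == k:
                continue
            for l in g.neighbors(k):
                if l == j or l == i:
                    continue
                torsions.append((i, j, k, l))

    def canon(t):
        rev = tuple(reversed(t))
        return t if t <= rev else rev

    def orbit_reps(items):
        items = {canon(tuple(t)) for t in items}
        seen = set()
        reps = []
        for t in sorted(items):
            if t in seen:
                continue
            reps.append(t)
            for m in autos:
                seen.add(canon(tuple(m[a] for a in t)))
        return reps

    return orbit_reps(bonds), orbit_reps(angles), orbit_reps(torsions)


@dataclass
class DeviationReport:
    """Per-cluster and aggregate mean +- SD of absolute deviations in bond
    lengths (A), valence angles (deg) and torsion angles (deg) over
    symmetry-unique internal coordinates."""
    per_cluster: pd.DataFrame
    aggregate: dict[str, tuple[float, float]]
    deviations: dict[str, dict[str, list[float]]]


def geometry_deviation_report(ff_structures: dict[str, Structure],
                              qm_structures: dict[str, Structure],
                              match_atoms: bool = False) -> DeviationReport:
    """Absolute internal-coordinate deviations between matched structure
    pairs, counting symmetry-equivalent coordinates once.

    With ``match_atoms=True`` the atom correspondence is taken from the
    permutation found by :func:`aligned_rmsd`; otherwise identical indexing
    is assumed.
    """
    if set(ff_structures) != set(qm_structures):
        raise ValueError("structure sets do not match")
    all_dev: dict[str, dict[str, list[float]]] = {}
    rows = []
    for name in sorted(qm_structures):
        qm = qm_structures[name]
        ffs = ff_structures[name]
        if sorted(qm.symbols) != sorted(ffs.symbols):
            raise ValueError(f"{name}: element mismatch between the two structures")
        if match_atoms:
            _, perm = aligned_rmsd(qm, ffs, return_permutation=True)
            ffs = Structure([ffs.symbols[p] for p in perm], ffs.coords[perm])
        elif qm.symbols != ffs.symbols:
            raise ValueError(f"{name}: atom order differs; use match_atoms=True")
        g = _topology_graph(qm)
        bonds, angles_u, torsions_u = _unique_coordinates(g)
        dev = {"bond": [], "angle": [], "torsion": []}
        for (i, j) in bonds:
            dev["bond"].append(abs(distance(ffs.coords, i, j)
                                   - distance(qm.coords, i, j)))
        for (i, j, k) in angles_u:
            dev["angle"].append(abs(angle(ffs.coords, i, j, k)
                                    - angle(qm.coords, i, j, k)))
        for (i, j, k, l) in torsions_u:
            d = abs(dihedral(ffs.coords, i, j, k, l)
                    - dihedral(qm.coords, i, j, k, l))
            dev["torsion"].append(min(d, 360.0 - d))
        all_dev[name] = dev
        row = {"cluster": name}
        for kind in ("bond", "angle", "torsion"):
            vals = dev[kind]
            row[f"{kind}_mean"] = float(np.mean(vals)) if vals else np.nan
            row[f"{kind}_sd"] = float(np.std(vals)) if vals else np.nan
            row[f"{kind}_n"] = len(vals)
        rows.append(row)
    aggregate = {}
    for kind in ("bond", "angle", "torsion"):
        pooled = [v for d in all_dev.values() for v in d[kind]]
        aggregate[kind] = ((float(np.mean(pooled)), float(np.std(pooled)))
                           if pooled else (np.nan, np.nan))
    return DeviationReport(pd.DataFrame(rows), aggregate, all_dev)


# ---------------------------------------------------------------------------
# correlation and charge reports
# ---------------------------------------------------------------------------

def prediction_correlation_report(trainset: TrainingSet, ff) -> dict:
    """(y_FF, y_ref) pairs for every energy entry plus per-partition linear
    statistics (slope, intercept, R^2, signed bias)."""
    from .training import _entry_prediction
    cache: dict = {}
    rows = []
    for e in trainset.entries:
        if e.kind != "energy_difference":
            continue
        y = _entry_prediction(e, trainset, ff, cache)
        rows.append({"id": e.id, "partition": e.partition,
                     "y_ref": e.reference_value, "y_ff": y,
                     "weight": e.weight})
    table = pd.DataFrame(rows)
    summary = {}
    for part, sub in table.groupby("partition"):
        if len(sub) >= 2 and np.std(sub["y_ref"]) > 0:
            fit = linregress(sub["y_ref"], sub["y_ff"])
            summary[part] = {
                "n": len(sub), "slope": fit.slope, "intercept": fit.intercept,
                "r2": fit.rvalue**2,
                "bias": float(np.mean(sub["y_ff"] - sub["y_ref"])),
                "rmse": float(np.sqrt(np.mean((sub["y_ff"] - sub["y_ref"])**2))),
            }
        else:
            summary[part] = {"n": len(sub), "slope": None, "intercept": None,
                             "r2": None,
                             "bias": float(np.mean(sub["y_ff"] - sub["y_ref"]))
                             if len(sub) else None,
                             "rmse": None}
    return {"pairs": table, "summary": summary}


def charge_report(structures: dict[str, Structure], ff,
                  reference_charges: dict[str, np.ndarray]) -> dict:
    """Per-atom EEM vs reference charge table and per-element MAE."""
    from .eem import equilibrate_charges
    rows = []
    for name in sorted(structures):
        s = structures[name]
        ref = np.asarray(reference_charges[name], dtype=float)
        if len(ref) != len(s):
            raise ValueError(f"{name}: reference charge count mismatch")
        q = equilibrate_charges(s, ff)
        for k, sym in enumerate(s.symbols):
            rows.append({"cluster": name, "atom": k, "element": sym,
                         "reference": float(ref[k]), "eem": float(q[k]),
                         "abs_error": float(abs(q[k] - ref[k]))})
    table = pd.DataFrame(rows)
    mae = table.groupby("element")["abs_error"].mean().to_dict()
    return {"table": table, "mae_by_element": mae}
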