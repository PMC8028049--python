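"""Molecular structures, trajectories, and (extended-)XYZ file I/O.

A :class:`Structure` is a set of element symbols and Cartesian coordinates in
Angstrom, optionally with an orthorhombic periodic cell, a total charge, and
per-atom partial charges.  Files are plain XYZ or extended-XYZ; the extended
comment line carries ``Lattice="ax 0 0 0 by 0 0 0 cz"`` (orthorhombic only),
``charge=Q`` and arbitrary scalar annotations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Structure",
    "Frame",
    "Trajectory",
    "read_structure_file",
    "write_structure_file",
    "read_trajectory",
    "write_trajectory",
    "distance",
    "angle",
    "dihedral",
]

_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


@dataclass
class Structure:
    symbols: list[str]
    coords: np.ndarray                    # (N, 3) Cartesian A
    cell: np.ndarray | None = None        # 3 orthorhombic edge lengths A
    total_charge: float = 0.0
    charges: np.ndarray | None = None     # per-atom charges (e)
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.symbols) != len(self.coords) or len(self.symbols) < 1:
            raise ValueError("symbols and coordinates must agree and N >= 1")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float).reshape(3)
            if np.any(self.cell <= 0):
                raise ValueError("cell edges must be strictly positive")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float).reshape(-1)
            if len(self.charges) != len(self.symbols):
                raise ValueError("one charge per atom required")
            if abs(self.charges.sum() - self.total_charge) > 1e-8:
                raise ValueError("per-atom charges must sum to the total charge")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def copy(self) -> "Structure":
        return replace(
            self,
            symbols=list(self.symbols),
            coords=self.coords.copy(),
            cell=None if self.cell is None else self.cell.copy(),
            charges=None if self.charges is None else self.charges.copy(),
            info=dict(self.info),
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        new = self.copy()
        new.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        return new


@dataclass
class Frame:
    """One MD snapshot: time (fs), positions/velocities, instantaneous
    temperature (K), and the energy breakdown at that configuration."""
    time_fs: float
    structure: Structure
    velocities: np.ndarray | None = None  # (N, 3) A/fs
    temperature: float | None = None
    breakdown: object | None = None       # potential.EnergyBreakdown

    @property
    def total_energy(self) -> float | None:
        return None if self.breakdown is None else self.breakdown.total


@dataclass
class Trajectory:
    frames: list[Frame] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def validate(self) -> None:
        times = [f.time_fs for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        ns = {f.structure.n_atoms for f in self.frames}
        if len(ns) > 1:
            raise ValueError("atom count must be constant along a trajectory")

    def window(self, t_min: float, t_max: float) -> "Trajectory":
        return Trajectory([f for f in self.frames if t_min <= f.time_fs <= t_max])


# ---------------------------------------------------------------------------
# geometry helpers (non-periodic; used on gas-phase clusters and scans)
# ---------------------------------------------------------------------------

def distance(coords: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(coords[j] - coords[i]))


def angle(coords: np.ndarray, i: int, j: int, k: int) -> float:
    """Valence angle i-j-k in degrees."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed dihedral i-j-k-l in degrees, in (-180, 180]."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


# ---------------------------------------------------------------------------
# (extended-)XYZ
# ---------------------------------------------------------------------------

def _parse_comment(comment: str) -> dict:
    out = {}
    for m in _KV_RE.finditer(comment):
        key = m.group(1)
        val = m.group(2) if m.group(2) is not None else m.group(3)
        out[key] = val
    return out


def _parse_lattice(text: str) -> np.ndarray:
    vals = np.array([float(t) for t in text.split()], dtype=float)
    if vals.size != 9:
        raise ValueError("Lattice must contain 9 numbers")
    mat = vals.reshape(3, 3)
    off = mat - np.diag(np.diag(mat))
    if np.any(np.abs(off) > 1e-10):
        raise ValueError("only orthorhombic (diagonal) cells are supported")
    return np.diag(mat).copy()


def _properties_columns(props: str) -> list[tuple[str, str, int]]:
    tok = props.split(":")
    return [(tok[i], tok[i + 1], int(tok[i + 2])) for i in range(0, len(tok), 3)]


def read_structure_file(path) -> list[Structure]:
    """Read all frames of an (extended-)XYZ file."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: list[Structure] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path}: line {pos + 1}: expected atom count") from exc
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        body = lines[pos + 2:pos + 2 + n]
        if len(body) != n:
            raise ValueError(f"{path}: line {pos + 1}: header declares {n} atoms, "
                             f"only {len(body)} atom lines present")
        meta = _parse_comment(comment)
        cell = _parse_lattice(meta["Lattice"]) if "Lattice" in meta else None
        cols = _properties_columns(meta["Properties"]) if "Properties" in meta else [
            ("species", "S", 1), ("pos", "R", 3)]
        symbols, coords, charges, velocities = [], [], [], []
        for k, line in enumerate(body):
            tok = line.split()
            ptr = 0
            row = {}
            for name, _, width in cols:
                if ptr + width > len(tok):
                    raise ValueError(f"{path}: atom line {pos + 3 + k}: too few columns")
                row[name] = tok[ptr:ptr + width]
                ptr += width
            symbols.append(row["species"][0])
            coords.append([float(x) for x in row["pos"]])
            if "charge" in row:
                charges.append(float(row["charge"][0]))
            if "vel" in row:
                velocities.append([float(x) for x in row["vel"]])
        total_charge = float(meta.get("charge", 0.0))
        qs = np.array(charges) if charges else None
        if qs is not None and "charge" not in meta:
            total_charge = float(qs.sum())
        info = {k: v for k, v in meta.items() if k not in ("Lattice", "Properties", "charge")}
        if velocities:
            info["_velocities"] = np.array(velocities, dtype=float)
        frames.append(Structure(symbols, np.array(coords), cell=cell,
                                total_charge=total_charge, charges=qs, info=info))
        pos += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return frames


def _comment_line(s: Structure, extra: dict | None = None, velocities: bool = False) -> str:
    parts = []
    if s.cell is not None:
        a, b, c = s.cell
        parts.append(f'Lattice="{a:.10g} 0.0 0.0 0.0 {b:.10g} 0.0 0.0 0.0 {c:.10g}"')
    props = "species:S:1:pos:R:3"
    if s.charges is not None:
        props += ":charge:R:1"
    if velocities:
        props += ":vel:R:3"
    parts.append(f"Properties={props}")
    parts.append(f"charge={s.total_charge:.10g}")
    for k, v in (extra or {}).items():
        parts.append(f"{k}={v}")
    return " ".join(parts)


def write_structure_file(structures, path) -> None:
    """Write one or more structures as multi-frame extended XYZ."""
    if isinstance(structures, Structure):
        structures = [structures]
    out = []
    for s in structures:
        out.append(str(s.n_atoms))
        extra = {k: v for k, v in s.info.items()
                 if not k.startswith("_") and isinstance(v, (str, int, float))}
        out.append(_comment_line(s, extra))
        for i, sym in enumerate(s.symbols):
            line = f"{sym:<2s} " + " ".join(f"{x:18.10f}" for x in s.coords[i])
            if s.charges is not None:
                line += f" {s.charges[i]:14.10f}"
            out.append(line)
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as multi-frame extended XYZ.

    The comment line of each frame carries ``Time`` (fs), ``Temperature`` (K)
    and ``Energy`` (total potential energy, kcal/mol) verbatim from the frame.
    """
    if len(traj) < 1:
        raise ValueError("trajectory must contain at least one frame")
    traj.validate()
    out = []
    for fr in traj.frames:
        s = fr.structure
        out.append(str(s.n_atoms))
        extra = {"Time": f"{fr.time_fs:.6f}"}
        if fr.temperature is not None:
            extra["Temperature"] = f"{fr.temperature:.6f}"
        if fr.total_energy is not None:
            extra["Energy"] = f"{fr.total_energy:.8f}"
        has_vel = fr.velocities is not None
        out.append(_comment_line(s, extra, velocities=has_vel))
        for i, sym in enumerate(s.symbols):
            line = f"{sym:<2s} " + " ".join(f"{x:18.10f}" for x in s.coords[i])
            if s.charges is not None:
                line += f" {s.charges[i]:14.10f}"
            if has_vel:
                line += " " + " ".join(f"{v:18.10f}" for v in fr.velocities[i])
            out.append(line)
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def read_trajectory(path) -> Trajectory:
    frames = []
    for s in read_structure_file(path):
        vel = s.info.pop("_velocities", None)
        t = float(s.info.get("Time", 0.0))
        temp = float(s.info["Temperature"]) if "Temperature" in s.info else None
        frames.append(Frame(time_fs=t, structure=s, velocities=vel, temperature=temp))
    return Trajectory(frames)
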