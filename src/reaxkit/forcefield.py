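"""ReaxFF force-field container and fixed-format ``ffield`` file I/O.

The on-disk layout is the community-standard fixed-format ``ffield`` text
file consumed by mainstream reactive-MD codes: a header comment, a counted
block of general (global) parameters, 4-line element blocks, 2-line bond
blocks, and single-line off-diagonal, valence-angle, torsion, and
hydrogen-bond records.  Reading then writing reproduces every numeric field
at the printed precision (4 decimal places).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ForceField",
    "read_ffield",
    "write_ffield",
    "FfieldParseError",
    "GENERAL_PARAM_NAMES",
    "ELEMENT_PARAM_NAMES",
    "BOND_PARAM_NAMES",
    "OFFDIAG_PARAM_NAMES",
    "ANGLE_PARAM_NAMES",
    "TORSION_PARAM_NAMES",
    "HBOND_PARAM_NAMES",
]

N_GENERAL = 39
N_ELEMENT_PARAMS = 32
N_BOND_PARAMS = 16
N_OFFDIAG_PARAMS = 6
N_ANGLE_PARAMS = 7
N_TORSION_PARAMS = 7
N_HBOND_PARAMS = 4

#: Names for the general-parameter slots that the potential actually uses.
#: Indices are 0-based positions in the 39-entry general block.
GENERAL_PARAM_NAMES = {
    0: "p_boc1",
    1: "p_boc2",
    2: "p_coa2",
    6: "p_ovun6",
    8: "p_ovun7",
    9: "p_ovun8",
    11: "swa",           # lower taper radius (A); 0 in every supported file
    12: "swb",           # upper taper radius (A) = nonbonded cutoff
    14: "p_val6",
    15: "p_lp1",
    16: "p_val9",
    17: "p_val10",
    19: "p_pen2",
    20: "p_pen3",
    21: "p_pen4",
    23: "p_tor2",
    24: "p_tor3",
    25: "p_tor4",
    27: "p_cot2",
    28: "p_vdw1",
    29: "bo_cutoff_x100",  # bond-order cutoff scaled by 100
    30: "p_coa4",
    31: "p_ovun4",
    32: "p_ovun3",
    33: "p_coa3",
    38: "p_val8",
}

ELEMENT_PARAM_NAMES = [
    # line 1
    "r_sigma", "valency", "mass", "r_vdw", "epsilon", "gamma_eem",
    "r_pi", "n_val_electrons",
    # line 2
    "alpha_vdw", "gamma_w", "valency_boc", "p_ovun5", "unused13",
    "chi_eem", "eta_eem", "hbond_role",
    # line 3
    "r_pipi", "p_lp2", "heat_increment", "p_boc4", "p_boc3", "p_boc5",
    "unused23", "unused24",
    # line 4
    "p_ovun2", "p_val3", "unused27", "valency_ang", "p_val5",
    "unused30", "unused31", "unused32",
]

BOND_PARAM_NAMES = [
    "De_sigma", "De_pi", "De_pipi", "p_be1", "p_bo5", "v13corr",
    "p_bo6", "p_ovun1",
    "p_be2", "p_bo3", "p_bo4", "unused12", "p_bo1", "p_bo2",
    "ovcorr", "unused16",
]

OFFDIAG_PARAM_NAMES = ["epsilon", "r_vdw", "alpha_vdw", "r_sigma", "r_pi", "r_pipi"]
ANGLE_PARAM_NAMES = ["theta00", "p_val1", "p_val2", "p_coa1", "p_val7", "p_pen1", "p_val4"]
TORSION_PARAM_NAMES = ["V1", "V2", "V3", "p_tor1", "p_cot1", "unused6", "unused7"]
HBOND_PARAM_NAMES = ["r0_hb", "p_hb1", "p_hb2", "p_hb3"]

#: Wildcard element symbol in torsion records (index 0 in the file).
WILDCARD = "X"


class FfieldParseError(ValueError):
    """Raised when an ffield file violates the fixed-format layout."""


def _canon_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _canon_triple(a: str, b: str, c: str) -> tuple[str, str, str]:
    """Canonical valence-angle key: centre fixed, outer atoms sorted."""
    return (a, b, c) if a <= c else (c, b, a)


def _canon_quad(a: str, b: str, c: str, d: str) -> tuple[str, str, str, str]:
    """Canonical torsion key: the lexicographically smaller direction."""
    fwd = (a, b, c, d)
    rev = (d, c, b, a)
    return fwd if fwd <= rev else rev


@dataclass
class ForceField:
    """Complete ReaxFF parameter set.

    Attributes
    ----------
    general:
        The 39 global constants (taper radii, bond-order cutoff scale,
        over/under-coordination constants, ...), in file order.
    elements:
        Per-element 32-parameter vectors keyed by symbol; insertion order is
        the file's element order and is preserved on write.
    bonds / offdiag:
        Pairwise records keyed by the sorted element pair.
    angles:
        Valence-angle records keyed by ``(outer, centre, outer)`` with the
        outer atoms sorted.
    torsions:
        Four-body records; outer positions may be the wildcard ``"X"``.
    hbonds:
        Donor - H - acceptor records.
    """

    general: np.ndarray
    elements: dict[str, np.ndarray] = field(default_factory=dict)
    bonds: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    offdiag: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    angles: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)
    torsions: dict[tuple[str, str, str, str], np.ndarray] = field(default_factory=dict)
    hbonds: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)
    header: str = "Reactive force field"
    general_comments: list[str] = field(default_factory=list)

    # -- named access -----------------------------------------------------

    def gp(self, name: str) -> float:
        """Look up a general parameter by its conventional name."""
        for idx, nm in GENERAL_PARAM_NAMES.items():
            if nm == name:
                return float(self.general[idx])
        raise KeyError(name)

    @property
    def taper_radius(self) -> float:
        return self.gp("swb")

    @property
    def bo_cutoff(self) -> float:
        """Bond-order cutoff (the file stores it multiplied by 100)."""
        return self.gp("bo_cutoff_x100") * 0.01

    def elem(self, symbol: str, name: str) -> float:
        return float(self.elements[symbol][ELEMENT_PARAM_NAMES.index(name)])

    def bond(self, a: str, b: str, name: str) -> float:
        return float(self.bonds[_canon_pair(a, b)][BOND_PARAM_NAMES.index(name)])

    def has_bond(self, a: str, b: str) -> bool:
        return _canon_pair(a, b) in self.bonds

    def get_offdiag(self, a: str, b: str) -> np.ndarray | None:
        return self.offdiag.get(_canon_pair(a, b))

    def get_angle(self, a: str, b: str, c: str) -> np.ndarray | None:
        return self.angles.get(_canon_triple(a, b, c))

    def get_torsion(self, a: str, b: str, c: str, d: str) -> np.ndarray | None:
        """Torsion record lookup: exact match first, then X-b-c-X wildcard."""
        rec = self.torsions.get(_canon_quad(a, b, c, d))
        if rec is None:
            rec = self.torsions.get(_canon_quad(WILDCARD, b, c, WILDCARD))
        return rec

    def get_hbond(self, donor: str, h: str, acceptor: str) -> np.ndarray | None:
        return self.hbonds.get((donor, h, acceptor))

    def copy(self) -> "ForceField":
        return copy.deepcopy(self)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if len(self.general) != N_GENERAL:
            raise ValueError(f"expected {N_GENERAL} general parameters, got {len(self.general)}")
        syms = set(self.elements)
        for key, n in [
            (self.bonds, N_BOND_PARAMS),
            (self.offdiag, N_OFFDIAG_PARAMS),
            (self.angles, N_ANGLE_PARAMS),
            (self.torsions, N_TORSION_PARAMS),
            (self.hbonds, N_HBOND_PARAMS),
        ]:
            for k, vals in key.items():
                if len(vals) != n:
                    raise ValueError(f"record {k} has {len(vals)} parameters, expected {n}")
                for s in k:
                    if s != WILDCARD and s not in syms:
                        raise ValueError(f"record {k} references undeclared element {s!r}")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _floats(tokens: list[str], n: int, lineno: int, what: str) -> np.ndarray:
    if len(tokens) < n:
        raise FfieldParseError(f"line {lineno}: expected {n} values for {what}, got {len(tokens)}")
    try:
        return np.array([float(t) for t in tokens[:n]], dtype=float)
    except ValueError as exc:
        raise FfieldParseError(f"line {lineno}: non-numeric value in {what}: {exc}") from exc


def _int(line: str, lineno: int, what: str) -> int:
    try:
        return int(line.split()[0])
    except (IndexError, ValueError) as exc:
        raise FfieldParseError(f"line {lineno}: expected {what} count") from exc


class _Lines:
    def __init__(self, path):
        with open(path) as fh:
            self.lines = fh.read().splitlines()
        self.pos = 0

    def next(self) -> tuple[str, int]:
        if self.pos >= len(self.lines):
            raise FfieldParseError(f"line {self.pos + 1}: unexpected end of file")
        line = self.lines[self.pos]
        self.pos += 1
        return line, self.pos


def read_ffield(path) -> ForceField:
    """Parse a fixed-format ReaxFF ``ffield`` file.

    Raises :class:`FfieldParseError` (naming the offending line) when a block
    count disagrees with the records present or a record is malformed.
    """
    src = _Lines(path)
    header, _ = src.next()

    line, ln = src.next()
    n_general = _int(line, ln, "general-parameter")
    general = np.zeros(n_general)
    comments: list[str] = []
    for i in range(n_general):
        line, ln = src.next()
        tok = line.split()
        general[i] = _floats(tok, 1, ln, "general parameter")[0]
        comments.append(line.split("!", 1)[1].strip() if "!" in line else "")
    if n_general != N_GENERAL:
        raise FfieldParseError(
            f"line {ln}: expected {N_GENERAL} general parameters, file declares {n_general}"
        )

    # element block: count line plus 3 continuation comment lines
    line, ln = src.next()
    n_el = _int(line, ln, "element")
    for _ in range(3):
        src.next()
    ff = ForceField(general=general, header=header.strip(), general_comments=comments)
    order: list[str] = []
    for _ in range(n_el):
        line, ln = src.next()
        tok = line.split()
        if not tok or tok[0][0].isdigit() or tok[0][0] in "-.":
            raise FfieldParseError(f"line {ln}: expected element symbol at start of atom record")
        sym = tok[0]
        vals = list(_floats(tok[1:], 8, ln, f"element {sym} line 1"))
        for k in range(3):
            line, ln = src.next()
            vals.extend(_floats(line.split(), 8, ln, f"element {sym} line {k + 2}"))
        ff.elements[sym] = np.array(vals)
        order.append(sym)

    def sym_of(idx: int, lineno: int, allow_wild: bool = False) -> str:
        if idx == 0 and allow_wild:
            return WILDCARD
        if not 1 <= idx <= len(order):
            raise FfieldParseError(f"line {lineno}: element index {idx} out of range")
        return order[idx - 1]

    # bonds: 2 lines per record
    line, ln = src.next()
    n_bonds = _int(line, ln, "bond")
    src.next()  # continuation comment line
    for _ in range(n_bonds):
        line, ln = src.next()
        tok = line.split()
        try:
            i, j = int(tok[0]), int(tok[1])
        except ValueError as exc:
            raise FfieldParseError(f"line {ln}: expected element indices") from exc
        vals = list(_floats(tok[2:], 8, ln, "bond record line 1"))
        line, ln = src.next()
        vals.extend(_floats(line.split(), 8, ln, "bond record line 2"))
        ff.bonds[_canon_pair(sym_of(i, ln), sym_of(j, ln))] = np.array(vals)

    line, ln = src.next()
    n_off = _int(line, ln, "off-diagonal")
    for _ in range(n_off):
        line, ln = src.next()
        tok = line.split()
        i, j = int(tok[0]), int(tok[1])
        ff.offdiag[_canon_pair(sym_of(i, ln), sym_of(j, ln))] = _floats(
            tok[2:], N_OFFDIAG_PARAMS, ln, "off-diagonal record")

    line, ln = src.next()
    n_ang = _int(line, ln, "angle")
    for _ in range(n_ang):
        line, ln = src.next()
        tok = line.split()
        i, j, k = int(tok[0]), int(tok[1]), int(tok[2])
        key = _canon_triple(sym_of(i, ln), sym_of(j, ln), sym_of(k, ln))
        ff.angles[key] = _floats(tok[3:], N_ANGLE_PARAMS, ln, "angle record")

    line, ln = src.next()
    n_tor = _int(line, ln, "torsion")
    for _ in range(n_tor):
        line, ln = src.next()
        tok = line.split()
        i, j, k, l = (int(t) for t in tok[:4])
        key = _canon_quad(sym_of(i, ln, True), sym_of(j, ln), sym_of(k, ln), sym_of(l, ln, True))
        ff.torsions[key] = _floats(tok[4:], N_TORSION_PARAMS, ln, "torsion record")

    line, ln = src.next()
    n_hb = _int(line, ln, "hydrogen-bond")
    for _ in range(n_hb):
        line, ln = src.next()
        tok = line.split()
        i, j, k = int(tok[0]), int(tok[1]), int(tok[2])
        key = (sym_of(i, ln), sym_of(j, ln), sym_of(k, ln))
        ff.hbonds[key] = _floats(tok[3:], N_HBOND_PARAMS, ln, "hydrogen-bond record")

    ff.validate()
    return ff


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    return f"{v:9.4f}"


def write_ffield(ff: ForceField, path) -> None:
    """Write *ff* in the fixed-format layout accepted by :func:`read_ffield`."""
    ff.validate()
    order = list(ff.elements)
    index = {s: i + 1 for i, s in enumerate(order)}
    index[WILDCARD] = 0
    out: list[str] = [ff.header]
    out.append(f" {len(ff.general)}       ! Number of general parameters")
    for i, v in enumerate(ff.general):
        comment = ff.general_comments[i] if i < len(ff.general_comments) else ""
        comment = comment or GENERAL_PARAM_NAMES.get(i, "n.u.")
        out.append(f"{v:10.4f} !{comment}")
    out.append(f" {len(order)}    ! Nr of atoms; cov.r; valency;a.m;Rvdw;Evdw;gammaEEM;cov.r2;#el")
    out.append("            alfa;gammavdW;valency;Eunder;n.u.;chiEEM;etaEEM;hbond")
    out.append("            cov r3;Elp;Heat inc.;13BO1;13BO2;13BO3;n.u.;n.u.")
    out.append("            ov/un;val1;n.u.;val3,vval4;n.u.;n.u.;n.u.")
    for sym in order:
        v = ff.elements[sym]
        out.append(f" {sym:<2s}" + "".join(_fmt(x) for x in v[:8]))
        for k in range(1, 4):
            out.append("   " + "".join(_fmt(x) for x in v[8 * k:8 * k + 8]))
    out.append(f" {len(ff.bonds)}      ! Nr of bonds; Edis1;LPpen;n.u.;pbe1;pbo5;13corr;pbo6")
    out.append("                         pbe2;pbo3;pbo4;n.u.;pbo1;pbo2;ovcorr")
    for (a, b), v in ff.bonds.items():
        out.append(f"{index[a]:3d}{index[b]:3d}" + "".join(_fmt(x) for x in v[:8]))
        out.append("      " + "".join(_fmt(x) for x in v[8:16]))
    out.append(f" {len(ff.offdiag)}    ! Nr of off-diagonal terms; Ediss;Ro;gamma;rsigma;rpi;rpi2")
    for (a, b), v in ff.offdiag.items():
        out.append(f"{index[a]:3d}{index[b]:3d}" + "".join(_fmt(x) for x in v))
    out.append(f" {len(ff.angles)}    ! Nr of angles;at1;at2;at3;Thetao,o;ka;kb;pv1;pv2")
    for (a, b, c), v in ff.angles.items():
        out.append(f"{index[a]:3d}{index[b]:3d}{index[c]:3d}" + "".join(_fmt(x) for x in v))
    out.append(f" {len(ff.torsions)}    ! Nr of torsions;at1;at2;at3;at4;;V1;V2;V3;V2(BO);vconj")
    for (a, b, c, d), v in ff.torsions.items():
        out.append(
            f"{index[a]:3d}{index[b]:3d}{index[c]:3d}{index[d]:3d}"
            + "".join(_fmt(x) for x in v))
    out.append(f" {len(ff.hbonds)}    ! Nr of hydrogen bonds;at1;at2;at3;Rhb;Dehb;vhb1")
    for (a, b, c), v in ff.hbonds.items():
        out.append(f"{index[a]:3d}{index[b]:3d}{index[c]:3d}" + "".join(_fmt(x) for x in v))
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")
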