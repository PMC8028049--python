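"""Pair neighbor lists with periodic-image enumeration.

For orthorhombic cells whose edges may be *smaller* than twice the nonbonded
cutoff (true for the 13.0 x 16.4 x 15.24 A solvated-cluster box with a 10 A
taper radius), the minimum-image convention is insufficient: an atom interacts
with several images of the same neighbor.  The list therefore enumerates all
lattice translations within the cutoff sphere, including an atom's own
periodic images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forcefield import ForceField
from .structure import Structure

__all__ = ["NeighborList", "build_neighbor_list", "OverlapError"]

#: distance (A) below which two atoms are considered unphysically overlapping
OVERLAP_TOL = 1e-6

#: bonded-candidate pair cutoff (A); uncorrected bond orders are negligible
#: beyond this distance for any published parameterization
BOND_CUTOFF = 5.0


class OverlapError(ValueError):
    pass


@dataclass
class NeighborList:
    """Symmetric pair list; each interacting (pair, image) combination is
    represented exactly once.

    ``vec[p] = coords[j[p]] + shift[p] * cell - coords[i[p]]``.
    """
    i: np.ndarray            # (P,) int
    j: np.ndarray            # (P,) int
    vec: np.ndarray          # (P, 3) A
    dist: np.ndarray         # (P,) A
    cutoff: float            # nonbonded cutoff used (A)
    bond_cutoff: float       # bonded-candidate cutoff (A)

    @property
    def n_pairs(self) -> int:
        return len(self.i)

    @property
    def bonded_mask(self) -> np.ndarray:
        return self.dist <= self.bond_cutoff


def _check_overlap(dist: np.ndarray, i, j) -> None:
    bad = dist < OVERLAP_TOL
    if np.any(bad):
        k = int(np.argmax(bad))
        raise OverlapError(
            f"atoms {int(i[k])} and {int(j[k])} overlap (r = {dist[k]:.2e} A)")


def build_neighbor_list(
    s: Structure,
    ff: ForceField | float,
    bond_cutoff: float = BOND_CUTOFF,
) -> NeighborList:
    """Build the pair list within the nonbonded cutoff.

    ``ff`` may be a :class:`ForceField` (the cutoff is its taper radius) or a
    plain cutoff in Angstrom.
    """
    cutoff = ff if isinstance(ff, (int, float)) else ff.taper_radius
    x = s.coords
    n = len(s)
    if s.cell is None:
        if n == 1:
            empty = np.zeros(0)
            return NeighborList(empty.astype(int), empty.astype(int),
                                np.zeros((0, 3)), empty, cutoff, bond_cutoff)
        d = x[None, :, :] - x[:, None, :]
        dist = np.linalg.norm(d, axis=-1)
        iu, ju = np.triu_indices(n, k=1)
        _check_overlap(dist[iu, ju], iu, ju)
        keep = dist[iu, ju] < cutoff
        iu, ju = iu[keep], ju[keep]
        return NeighborList(iu, ju, d[iu, ju], dist[iu, ju], cutoff, bond_cutoff)

    cell = s.cell
    # wrap into the primary cell; image vectors remain valid lattice
    # translations of the true pair vectors
    frac = x / cell
    xw = (frac - np.floor(frac)) * cell
    mmax = (np.floor(cutoff / cell) + 1).astype(int)
    shifts = []
    for nx in range(-mmax[0], mmax[0] + 1):
        for ny in range(-mmax[1], mmax[1] + 1):
            for nz in range(-mmax[2], mmax[2] + 1):
                shifts.append((nx, ny, nz))
    ii, jj, vecs, dists = [], [], [], []
    iu, ju = np.triu_indices(n, k=1)
    for shift in shifts:
        t = np.asarray(shift, dtype=float) * cell
        is_zero = shift == (0, 0, 0)
        # distinct atom pairs, this image
        d = xw[ju] + t - xw[iu]
        dist = np.linalg.norm(d, axis=-1)
        _check_overlap(dist, iu, ju)
        keep = dist < cutoff
        ii.append(iu[keep]); jj.append(ju[keep])
        vecs.append(d[keep]); dists.append(dist[keep])
        # self-image pairs: count each unordered image pair once (positive
        # half-space of shifts)
        if not is_zero and shift > (0, 0, 0):
            dist_self = float(np.linalg.norm(t))
            if dist_self < cutoff:
                idx = np.arange(n)
                if dist_self < OVERLAP_TOL:
                    raise OverlapError("cell translation shorter than overlap tolerance")
                ii.append(idx); jj.append(idx)
                vecs.append(np.tile(t, (n, 1)))
                dists.append(np.full(n, dist_self))
    i = np.concatenate(ii) if ii else np.zeros(0, dtype=int)
    j = np.concatenate(jj) if jj else np.zeros(0, dtype=int)
    vec = np.concatenate(vecs) if vecs else np.zeros((0, 3))
    dist = np.concatenate(dists) if dists else np.zeros(0)
    return NeighborList(i, j, vec, dist, cutoff, bond_cutoff)
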