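"""Rigid-body superposition, r.m.s.d. and backbone torsion arithmetic.

Two distinct r.m.s.d.s are exposed on purpose: :func:`superpose_kabsch`
returns the deviation *after* a least-squares fit (used when comparing two
different crystals), while :func:`rmsd_in_frame` compares coordinates as they
stand (used for alternate conformers modelled in one crystal frame, where
refitting would artificially shrink the difference).
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .models import Residue, Superposition

__all__ = [
    "superpose_kabsch",
    "rmsd_in_frame",
    "dihedral",
    "phi_psi",
    "TorsionSet",
    "PEPTIDE_BOND_MAX",
]

#: Maximum C(i)-N(i+1) distance for two residues to count as bonded, in Å.
PEPTIDE_BOND_MAX = 2.0


def _as_points(x, min_len: int, label: str) -> np.ndarray:
    pts = np.asarray(x, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"{label}: expected an (n, 3) coordinate array")
    if len(pts) < min_len:
        raise ValueError(f"{label}: need at least {min_len} points, got {len(pts)}")
    if not np.all(np.isfinite(pts)):
        raise ValueError(f"{label}: non-finite coordinates")
    return pts


def superpose_kabsch(mobile, reference) -> Superposition:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference`` (Kabsch).

    Correspondence is by position in the two equal-length lists; reflections
    are excluded (the returned rotation is proper). The r.m.s.d. is computed
    after applying the optimal transform.
    """
    mob = _as_points(mobile, 3, "mobile")
    ref = _as_points(reference, 3, "reference")
    if len(mob) != len(ref):
        raise ValueError(f"length mismatch: {len(mob)} vs {len(ref)}")

    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    m0, r0 = mob - mc, ref - rc

    # Collinear (or coincident) point sets leave the rotation underdetermined.
    for pts, label in ((m0, "mobile"), (r0, "reference")):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise ValueError(f"degenerate (collinear) {label} point set")

    h = m0.T @ r0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc

    moved = m0 @ rot.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=len(mob))


def rmsd_in_frame(set_a, set_b) -> float:
    """r.m.s.d. between paired coordinates with **no** fitting.

    sqrt(mean over pairs of squared Euclidean distance); appropriate for
    conformers sharing one crystal frame.
    """
    a = _as_points(set_a, 1, "set_a")
    b = _as_points(set_b, 1, "set_b")
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees on (-180, 180].

    IUPAC convention: cis = 0, trans = 180. The sign is that of the rotation
    of the p3->p4 bond relative to p1->p2 when looking down p2->p3.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for name, b in (("p1-p2", b1), ("p2-p3", b2), ("p3-p4", b3)):
        if np.linalg.norm(b) < 1e-9:
            raise ValueError(f"coincident consecutive points on bond {name}")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("colinear atoms: torsion undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = -float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0 + 1e-12:
        ang = 180.0
    return ang


class TorsionSet:
    """Per-residue backbone torsions of one chain, in author numbering.

    ``phi[i]`` / ``psi[i]`` are keyed by residue seq_number and are None where
    undefined (termini, chain breaks, missing backbone atoms).
    """

    def __init__(self, order: list, phi: dict, psi: dict, altloc: Optional[str] = None):
        self.order = list(order)
        self.phi = dict(phi)
        self.psi = dict(psi)
        self.altloc = altloc
        for d in (self.phi, self.psi):
            for v in d.values():
                if v is not None and not (-180.0 < v <= 180.0):
                    raise ValueError(f"torsion {v} outside (-180, 180]")

    def at_position(self, pos: int):
        """(phi, psi) of the ``pos``-th residue (1-based chain position)."""
        if not (1 <= pos <= len(self.order)):
            raise IndexError(f"position {pos} outside chain of {len(self.order)} residues")
        seq = self.order[pos - 1]
        return self.phi.get(seq), self.psi.get(seq)

    def __len__(self) -> int:
        return len(self.order)


def _backbone(res: Residue, name: str, altloc: Optional[str]):
    atom = res.get_atom(name, altloc)
    return None if atom is None else atom.coords


def phi_psi(residues: list, altloc: Optional[str] = None) -> TorsionSet:
    """Backbone ϕ/ψ along a residue list, one conformer label at a time.

    ϕ(i) = C(i-1)-N(i)-CA(i)-C(i);  ψ(i) = N(i)-CA(i)-C(i)-N(i+1).
    Blank-altloc atoms are shared by every conformer. Chain breaks
    (C-N distance above ``PEPTIDE_BOND_MAX``) and missing backbone atoms
    yield undefined entries, not errors.
    """
    order = [r.seq_number for r in residues]
    phi: dict = {s: None for s in order}
    psi: dict = {s: None for s in order}

    coords = []
    for r in residues:
        n, ca, c = (_backbone(r, nm, altloc) for nm in ("N", "CA", "C"))
        if n is None or ca is None or c is None:
            warnings.warn(
                f"residue {r.res_name}{r.seq_number}: missing backbone atom; torsions undefined"
            )
        coords.append((n, ca, c))

    def bonded(i: int) -> bool:
        c_prev = coords[i - 1][2]
        n_cur = coords[i][0]
        if c_prev is None or n_cur is None:
            return False
        return float(np.linalg.norm(n_cur - c_prev)) < PEPTIDE_BOND_MAX

    for i, r in enumerate(residues):
        n, ca, c = coords[i]
        complete = n is not None and ca is not None and c is not None
        if i > 0 and complete and coords[i - 1][2] is not None and bonded(i):
            try:
                phi[r.seq_number] = dihedral(coords[i - 1][2], n, ca, c)
            except ValueError:
                pass
        if (
            i + 1 < len(residues)
            and complete
            and coords[i + 1][0] is not None
            and bonded(i + 1)
        ):
            try:
                psi[r.seq_number] = dihedral(n, ca, c, coords[i + 1][0])
            except ValueError:
                pass
    return TorsionSet(order, phi, psi, altloc=altloc)
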