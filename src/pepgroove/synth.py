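"""Synthetic class-I-like structures and ensembles with known answers.

Everything downstream is validated against fixtures built here: a groove-like
scaffold (two helical walls standing in for the α1/α2 helices plus a short
light-chain helix) holding a 9-mer peptide whose backbone is built from ideal
bond geometry at requested (ϕ, ψ), with dual conformers at chosen occupancies,
donor-acceptor pairs planted at exact distances, bridging waters, and
multi-model ensembles with per-residue Gaussian jitter. Every planted
quantity is recovered by the corresponding analysis operation — that closed
loop is the core test of the package.

Side chains beyond Cβ are deliberately minimal; where a planted contact needs
a named atom (Tyr OH, Glu OE2, ...), exactly that atom is placed. The
scaffold is a geometric stand-in, not chemistry: planted atoms sit where the
plan puts them, unconstrained by their residue's covalent structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .io import write_structure
from .models import (
    AA1_TO_3,
    Atom,
    CrystalCell,
    Ensemble,
    Residue,
    StructureModel,
)

__all__ = [
    "GrooveSpec",
    "EnsembleSpec",
    "DualSite",
    "PlantedContact",
    "PlantedWater",
    "build_groove",
    "build_ensemble",
    "fixture_suite",
    "place_atom",
    "build_backbone",
]

# ideal backbone geometry (lengths in Å, angles in degrees)
N_CA, CA_C, C_N, C_O = 1.458, 1.525, 1.329, 1.231
ANG_N_CA_C, ANG_CA_C_N, ANG_C_N_CA, ANG_CA_C_O = 111.2, 116.2, 121.7, 120.8
CA_CB, ANG_N_CA_CB, TOR_C_N_CA_CB = 1.530, 110.5, -122.6
OMEGA = 180.0

HC_CHAIN, LIGHT_CHAIN, PEP_CHAIN, WATER_CHAIN = "A", "B", "C", "W"

EIGHT_PI_SQ = 8.0 * math.pi ** 2


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond_length: float, bond_angle: float, torsion: float) -> np.ndarray:
    """Position atom d bonded to c with angle(b,c,d)=bond_angle and
    dihedral(a,b,c,d)=torsion (degrees). Natural-extension reference frame."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise ValueError("collinear frame atoms")
    n = n / nn
    m = np.cross(n, bc)
    theta = math.radians(bond_angle)
    chi = math.radians(torsion)
    d_local = np.array([
        -bond_length * math.cos(theta),
        bond_length * math.sin(theta) * math.cos(chi),
        bond_length * math.sin(theta) * math.sin(chi),
    ])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


@dataclass
class _BB:
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    cb: Optional[np.ndarray]


def build_backbone(phi_psi: Sequence[tuple], with_cb: Sequence[bool]) -> list:
    """Backbone trace at the requested torsions; ϕ of residue 1 and ψ of the
    last residue only orient terminal atoms. Returns one :class:`_BB` per
    residue."""
    n_res = len(phi_psi)
    out = []
    # residue 1 laid flat in the xy-plane
    n1 = np.array([0.0, 0.0, 0.0])
    ca1 = np.array([N_CA, 0.0, 0.0])
    th = math.radians(180.0 - ANG_N_CA_C)
    c1 = ca1 + CA_C * np.array([math.cos(th), math.sin(th), 0.0])
    prev = (n1, ca1, c1)
    for i in range(n_res):
        n_i, ca_i, c_i = prev
        psi = phi_psi[i][1]
        psi_eff = psi if psi is not None else 150.0
        o_i = place_atom(n_i, ca_i, c_i, C_O, ANG_CA_C_O, psi_eff - 180.0)
        cb_i = None
        if with_cb[i]:
            cb_i = place_atom(c_i, n_i, ca_i, CA_CB, ANG_N_CA_CB, TOR_C_N_CA_CB)
        out.append(_BB(n_i, ca_i, c_i, o_i, cb_i))
        if i + 1 < n_res:
            n_next = place_atom(n_i, ca_i, c_i, C_N, ANG_CA_C_N, psi_eff)
            ca_next = place_atom(ca_i, c_i, n_next, N_CA, ANG_C_N_CA, OMEGA)
            phi_next = phi_psi[i + 1][0]
            phi_eff = phi_next if phi_next is not None else -120.0
            c_next = place_atom(c_i, n_next, ca_next, CA_C, ANG_N_CA_C, phi_eff)
            prev = (n_next, ca_next, c_next)
    return out


def _principal_align(points: np.ndarray) -> np.ndarray:
    """Centre a point cloud and rotate its principal axis onto +x.

    Signs are fixed deterministically (chain start at negative x, det +1) so
    that the same build always yields the same coordinates.
    """
    mean = points.mean(axis=0)
    x = points - mean
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    if vt.shape[0] < 3:
        vt = np.vstack([vt, np.cross(vt[0], vt[1])[None, :]])
    frame = vt.copy()
    if np.linalg.det(frame) < 0:
        frame[2] = -frame[2]
    new = x @ frame.T
    if new[0, 0] > new[-1, 0]:  # run the chain toward +x
        new[:, 0] = -new[:, 0]
        new[:, 1] = -new[:, 1]
    return new


@dataclass
class DualSite:
    """Residue carrying an A/B alternate conformation.

    ``atoms``: "backbone" (N, CA, C, O), "sidechain" (CB and any planted
    side-chain atoms), or "all". ``displacement`` is the A→B offset in Å.
    """

    position: int               # 1-based peptide position
    displacement: tuple
    atoms: str = "all"

    def __post_init__(self) -> None:
        if self.atoms not in ("backbone", "sidechain", "all"):
            raise ValueError(f"unknown dual-site atom set {self.atoms!r}")
        self.displacement = tuple(float(x) for x in self.displacement)


@dataclass
class PlantedContact:
    peptide_pos: int
    peptide_atom: str
    groove_seq: int
    groove_res_name: str
    groove_atom: str
    distance: float
    kind: str = "HB"            # intended kind, for bookkeeping only

    def __post_init__(self) -> None:
        if self.distance <= 1.5:
            raise ValueError(f"planted distance {self.distance} must exceed 1.5 Å")

    def label(self) -> str:
        return (f"p{self.peptide_pos}.{self.peptide_atom} - "
                f"{self.groove_res_name}{self.groove_seq}.{self.groove_atom} "
                f"@ {self.distance} Å")


@dataclass
class PlantedWater:
    """Water oxygen bridging a peptide atom and a groove atom at the given
    leg distances."""

    peptide_pos: int
    peptide_atom: str
    groove_seq: int
    groove_atom: str
    leg1: float = 3.0
    leg2: float = 3.0


@dataclass
class GrooveSpec:
    sequence: str = "RRRWHRWRL"
    phi_psi: Optional[Sequence[tuple]] = None   # default: extended everywhere
    dual_sites: list = field(default_factory=list)
    occupancies: tuple = (0.7, 0.3)
    planted_contacts: list = field(default_factory=list)
    planted_waters: list = field(default_factory=list)
    groove_size: int = 180
    light_chain_size: int = 30
    wall_offset: float = 8.0    # lateral distance of the helix walls, Å
    cell: Optional[CrystalCell] = None
    spacegroup: Optional[str] = None
    b_iso: float = 15.0
    water_b: float = 30.0
    aniso_peptide: bool = False   # attach isotropic U tensors to peptide atoms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if abs(sum(self.occupancies) - 1.0) > 1e-9:
            raise ValueError("conformer occupancies must sum to 1")
        for s in self.sequence:
            if s not in AA1_TO_3:
                raise ValueError(f"unknown one-letter code {s!r}")

    def resolved_phi_psi(self) -> list:
        if self.phi_psi is None:
            return [(-120.0, 130.0)] * len(self.sequence)
        if len(self.phi_psi) != len(self.sequence):
            raise ValueError("phi_psi length must match sequence length")
        return [tuple(p) for p in self.phi_psi]


@dataclass
class EnsembleSpec:
    base: Union[GrooveSpec, StructureModel]
    n_models: int = 50
    sigma_default: float = 0.0
    sigma_overrides: dict = field(default_factory=dict)  # (chain_id, seq) -> σ
    peptide_sigma: Optional[float] = None                # shorthand for chain C
    rigid_rot_deg: float = 0.0
    rigid_trans: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 2:
            raise ValueError("an ensemble needs at least 2 models")
        if self.sigma_default < 0 or any(v < 0 for v in self.sigma_overrides.values()):
            raise ValueError("jitter sd must be non-negative")


# ---------------------------------------------------------------------------
# builders

def _helix_chain(chain_id: str, n_res: int, start_seq: int, origin: np.ndarray,
                 b_iso: float, serial_start: int) -> tuple:
    """Poly-Ala α-helix used as scaffolding wall, axis along x through
    ``origin``; returns (residues, next_serial)."""
    bbs = build_backbone([(-60.0, -45.0)] * n_res, [True] * n_res)
    raw = [(i, name, el, pos)
           for i, bb in enumerate(bbs)
           for name, el, pos in (("N", "N", bb.n), ("CA", "C", bb.ca),
                                 ("C", "C", bb.c), ("O", "O", bb.o),
                                 ("CB", "C", bb.cb))]
    aligned = _principal_align(np.vstack([pos for *_, pos in raw]))
    residues = []
    serial = serial_start
    current: Optional[Residue] = None
    for (i, name, el, _), pos in zip(raw, aligned):
        if current is None or current.seq_number != start_seq + i:
            current = Residue(chain_id, start_seq + i, "ALA")
            residues.append(current)
        serial += 1
        current.atoms.append(Atom(serial, name, el, pos + origin, b_iso=b_iso))
    return residues, serial


def _element_of(atom_name: str) -> str:
    head = atom_name.strip()
    return head[0] if head and head[0].isalpha() else "C"


def _plant_position(anchor: np.ndarray, distance: float, obstacles: np.ndarray,
                    rng: np.random.Generator, label: str) -> np.ndarray:
    """Point at ``distance`` from ``anchor`` maximising clearance from other
    atoms; raises when every direction clashes with the scaffold."""
    dirs = [np.eye(3)[i] * s for i in range(3) for s in (1.0, -1.0)]
    v = rng.normal(size=(60, 3))
    dirs.extend(v / np.linalg.norm(v, axis=1, keepdims=True))
    best, best_clear = None, -1.0
    for u in dirs:
        cand = anchor + distance * np.asarray(u)
        clear = float(np.min(np.linalg.norm(obstacles - cand, axis=1))) if len(obstacles) else np.inf
        if clear > best_clear:
            best, best_clear = cand, clear
    if best_clear < 2.2:
        raise ValueError(f"unsatisfiable planted contact {label}: clashes with scaffold")
    return best


def build_groove(spec: GrooveSpec) -> StructureModel:
    """Deterministic synthetic groove complex from a fully specified plan."""
    rng = np.random.default_rng(spec.seed)
    n_pep = len(spec.sequence)

    # peptide backbone at the requested torsions, principal axis on x,
    # centred at the origin
    bbs = build_backbone(spec.resolved_phi_psi(), [s != "G" for s in spec.sequence])
    raw = []
    for i, (bb, letter) in enumerate(zip(bbs, spec.sequence)):
        entries = [("N", "N", bb.n), ("CA", "C", bb.ca), ("C", "C", bb.c), ("O", "O", bb.o)]
        if bb.cb is not None:
            entries.append(("CB", "C", bb.cb))
        for name, el, pos in entries:
            raw.append((i, letter, name, el, pos))
    aligned = _principal_align(np.vstack([pos for *_, pos in raw]))

    serial = 0
    pep_residues = []
    current = None
    for (i, letter, name, el, _), pos in zip(raw, aligned):
        if current is None or current.seq_number != i + 1:
            current = Residue(PEP_CHAIN, i + 1, AA1_TO_3[letter])
            pep_residues.append(current)
        serial += 1
        current.atoms.append(Atom(serial, name, el, pos, b_iso=spec.b_iso))

    # scaffold walls flanking the peptide, and a light-chain helix below
    half = spec.groove_size // 2
    wall1, serial = _helix_chain(HC_CHAIN, half, 1,
                                 np.array([-15.0, spec.wall_offset, 0.0]),
                                 spec.b_iso, serial)
    wall2, serial = _helix_chain(HC_CHAIN, spec.groove_size - half, half + 1,
                                 np.array([-15.0, -spec.wall_offset, 0.0]),
                                 spec.b_iso, serial)
    hc_residues = wall1 + wall2
    light, serial = _helix_chain(LIGHT_CHAIN, spec.light_chain_size, 1,
                                 np.array([-10.0, 0.0, -15.0]), spec.b_iso, serial)

    hc_by_seq = {r.seq_number: r for r in hc_residues}
    pep_by_pos = {i + 1: r for i, r in enumerate(pep_residues)}

    def all_coords(exclude=()) -> np.ndarray:
        pts = []
        for res in pep_residues + hc_residues + light:
            for a in res.atoms:
                if a not in exclude:
                    pts.append(a.coords)
        return np.vstack(pts) if pts else np.empty((0, 3))

    # planted contacts: the named groove atom is placed exactly at distance
    for pc in spec.planted_contacts:
        pres = pep_by_pos.get(pc.peptide_pos)
        if pres is None:
            raise ValueError(f"planted contact references peptide position {pc.peptide_pos}")
        anchor_atom = pres.get_atom(pc.peptide_atom)
        if anchor_atom is None:
            # a named peptide side-chain atom: hang it off CB (or CA) first
            base = pres.get_atom("CB") or pres.get_atom("CA")
            pos = _plant_position(base.coords, 1.8, all_coords(exclude=(base,)),
                                  rng, pc.label())
            serial += 1
            anchor_atom = Atom(serial, pc.peptide_atom, _element_of(pc.peptide_atom),
                               pos, b_iso=spec.b_iso)
            pres.atoms.append(anchor_atom)
        gres = hc_by_seq.get(pc.groove_seq)
        if gres is None:
            raise ValueError(f"planted contact references groove residue {pc.groove_seq}")
        gres.res_name = pc.groove_res_name
        pos = _plant_position(anchor_atom.coords, pc.distance,
                              all_coords(exclude=(anchor_atom,)), rng, pc.label())
        serial += 1
        gres.atoms.append(Atom(serial, pc.groove_atom, _element_of(pc.groove_atom),
                               pos, b_iso=spec.b_iso))

    # bridging waters: oxygen placed to satisfy both leg distances
    waters = []
    for i, pw in enumerate(spec.planted_waters):
        pres = pep_by_pos[pw.peptide_pos]
        p_atom = pres.get_atom(pw.peptide_atom)
        gres = hc_by_seq[pw.groove_seq]
        g_atom = gres.get_atom(pw.groove_atom)
        if p_atom is None or g_atom is None:
            raise ValueError("planted water references a missing atom")
        p, g = p_atom.coords, g_atom.coords
        gap = float(np.linalg.norm(g - p))
        if gap > pw.leg1 + pw.leg2 or gap < abs(pw.leg1 - pw.leg2):
            raise ValueError(
                f"water bridge p{pw.peptide_pos}-{pw.groove_seq}: legs "
                f"{pw.leg1}/{pw.leg2} cannot span gap {gap:.2f} Å"
            )
        # circle of intersection of the two spheres; pick the most clash-free
        # of two deterministic points on it
        u = (g - p) / gap
        x = (gap ** 2 + pw.leg1 ** 2 - pw.leg2 ** 2) / (2 * gap)
        h = math.sqrt(max(pw.leg1 ** 2 - x ** 2, 0.0))
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, u)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        v1 = np.cross(u, ref)
        v1 /= np.linalg.norm(v1)
        obstacles = all_coords(exclude=(p_atom, g_atom))
        cands = [p + x * u + h * s * v1 for s in (1.0, -1.0)]
        pos = max(cands, key=lambda c: float(np.min(np.linalg.norm(obstacles - c, axis=1))))
        serial += 1
        wres = Residue(WATER_CHAIN, i + 1, "HOH")
        wres.atoms.append(Atom(serial, "O", "O", pos, b_iso=spec.water_b))
        waters.append(wres)

    # dual conformers: duplicate the planned atoms as altloc A/B
    occ_a, occ_b = spec.occupancies
    for site in spec.dual_sites:
        res = pep_by_pos.get(site.position)
        if res is None:
            raise ValueError(f"dual site at unknown peptide position {site.position}")
        disp = np.asarray(site.displacement, dtype=float)
        new_atoms = []
        for a in res.atoms:
            is_bb = a.name in ("N", "CA", "C", "O", "OXT")
            selected = (
                site.atoms == "all"
                or (site.atoms == "backbone" and is_bb)
                or (site.atoms == "sidechain" and not is_bb)
            )
            if not selected:
                new_atoms.append(a)
                continue
            serial += 1
            a_copy = Atom(a.serial, a.name, a.element, a.coords.copy(), "A",
                          occ_a, a.b_iso, a.u_aniso)
            b_copy = Atom(serial, a.name, a.element, a.coords + disp, "B",
                          occ_b, a.b_iso, a.u_aniso)
            new_atoms.extend([a_copy, b_copy])
        res.atoms = new_atoms

    if spec.aniso_peptide:
        for res in pep_residues:
            for a in res.atoms:
                u = a.b_iso / EIGHT_PI_SQ
                a.u_aniso = (u, u, u, 0.0, 0.0, 0.0)

    chains = {
        HC_CHAIN: hc_residues,
        LIGHT_CHAIN: light,
        PEP_CHAIN: pep_residues,
    }
    if waters:
        chains[WATER_CHAIN] = waters
    return StructureModel(model_number=1, chains=chains, cell=spec.cell,
                          spacegroup=spec.spacegroup)


def build_ensemble(spec: EnsembleSpec) -> Ensemble:
    """Base model plus per-atom i.i.d. Gaussian jitter (per-residue sd) and an
    optional global rigid motion per model; fully seeded."""
    base = spec.base if isinstance(spec.base, StructureModel) else build_groove(spec.base)
    rng = np.random.default_rng(spec.seed)

    def sigma_of(res: Residue) -> float:
        if (res.chain_id, res.seq_number) in spec.sigma_overrides:
            return spec.sigma_overrides[(res.chain_id, res.seq_number)]
        if spec.peptide_sigma is not None and res.chain_id == PEP_CHAIN:
            return spec.peptide_sigma
        return spec.sigma_default

    models = []
    for m in range(1, spec.n_models + 1):
        model = base.copy()
        model.model_number = m
        if spec.rigid_rot_deg > 0 or spec.rigid_trans > 0:
            ang = math.radians(rng.normal(0.0, max(spec.rigid_rot_deg, 1e-12)))
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            k = np.array([
                [0, -axis[2], axis[1]],
                [axis[2], 0, -axis[0]],
                [-axis[1], axis[0], 0],
            ])
            rot = np.eye(3) + math.sin(ang) * k + (1 - math.cos(ang)) * (k @ k)
            trans = rng.normal(0.0, max(spec.rigid_trans, 1e-12), size=3)
        else:
            rot, trans = np.eye(3), np.zeros(3)
        for res in model.all_residues():
            s = sigma_of(res)
            for a in res.atoms:
                pos = a.coords
                if s > 0:
                    pos = pos + rng.normal(0.0, s, size=3)
                a.coords = rot @ pos + trans
        models.append(model)
    return Ensemble(models)


def fixture_suite(seed: int, out_dir: Union[str, Path]) -> dict:
    """Write the standing named fixtures and return {name: path}.

    * ``pgr_like``  - 9-mer RRRWHRWRL, α-helical torsions at p6 (NC mode),
      A/B conformers at 70:30 with a 0.4 Å backbone split at p6-p8 and dual
      side chains at p4/p6/p7/p8, published-table-style planted contacts and
      one bridging water.
    * ``cc_like``   - same scaffold, extended torsions throughout (CC mode),
      single conformer, no planted contacts.
    * ``stiff`` / ``floppy`` - 200-model ensembles with peptide jitter sd
      0.1 / 0.9 Å.
    * ``regional``  - ensemble with extra jitter on groove residues 106-108.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng_seed = int(seed)

    nc_phi_psi = [(-120.0, 130.0)] * 9
    nc_phi_psi[5] = (-60.0, -45.0)  # p6 in the α basin

    pgr = GrooveSpec(
        sequence="RRRWHRWRL",
        phi_psi=nc_phi_psi,
        dual_sites=[
            DualSite(4, (0.25, 0.0, 0.0), atoms="sidechain"),
            DualSite(6, (0.0, 0.28, 0.28), atoms="all"),
            DualSite(7, (0.0, 0.28, 0.28), atoms="all"),
            DualSite(8, (0.0, 0.28, 0.28), atoms="all"),
        ],
        occupancies=(0.7, 0.3),
        planted_contacts=[
            PlantedContact(3, "N", 99, "TYR", "OH", 3.1, "HB"),
            PlantedContact(8, "O", 147, "TRP", "NE1", 2.9, "HB"),
            PlantedContact(8, "NE", 76, "GLU", "OE2", 3.0, "SB"),
            PlantedContact(7, "CB", 152, "VAL", "CG1", 3.8, "vdW"),
            # carboxylate oxygen brought near the peptide solely to anchor
            # the water bridge below (5.5 Å: outside every direct window)
            PlantedContact(5, "O", 77, "ASP", "OD1", 5.5, "none"),
        ],
        planted_waters=[PlantedWater(5, "O", 77, "OD1", 3.0, 3.0)],
        cell=CrystalCell(51.0, 81.9, 65.4, 90.0, 108.9, 90.0, z_value=2),
        spacegroup="P 1 21 1",
        aniso_peptide=True,
        seed=rng_seed,
    )
    cc = GrooveSpec(sequence="RRKWRRWHL", seed=rng_seed + 1)

    single = GrooveSpec(sequence="RRRWHRWRL", phi_psi=nc_phi_psi, seed=rng_seed + 2)
    stiff = EnsembleSpec(base=single, n_models=200, sigma_default=0.02,
                         peptide_sigma=0.1, seed=rng_seed + 3)
    floppy = EnsembleSpec(base=single, n_models=200, sigma_default=0.02,
                          peptide_sigma=0.9, rigid_rot_deg=1.0, rigid_trans=0.3,
                          seed=rng_seed + 4)
    regional = EnsembleSpec(
        base=single, n_models=100, sigma_default=0.1,
        sigma_overrides={(HC_CHAIN, s): 0.7 for s in (106, 107, 108)},
        seed=rng_seed + 5,
    )

    paths = {}
    for name, obj in (
        ("pgr_like", Ensemble([build_groove(pgr)])),
        ("cc_like", Ensemble([build_groove(cc)])),
        ("stiff", build_ensemble(stiff)),
        ("floppy", build_ensemble(floppy)),
        ("regional", build_ensemble(regional)),
    ):
        path = out_dir / f"{name}.pdb"
        write_structure(obj, path)
        paths[name] = path
    return paths
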