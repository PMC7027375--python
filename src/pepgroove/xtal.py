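"""Crystal-content and displacement-parameter bookkeeping.

Implements the classic Matthews analysis (volume per dalton of protein in the
cell and the solvent fraction it implies), triclinic cell volume, conversion
of anisotropic U tensors to equivalent isotropic B, and selection-averaged B
factors as printed in refinement tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils import molecular_weight
import gemmi

from .models import AA3_TO_1, CrystalCell, Selection, StructureModel
from .io import resolve_selection

__all__ = [
    "MatthewsResult",
    "cell_volume",
    "molecular_mass",
    "matthews",
    "b_eq_from_aniso",
    "average_b",
    "MATTHEWS_CONSTANT",
]

#: 1.23 = (N_A * v_bar)^-1 in ų/Da for a protein partial specific volume of
#: 0.74 cm³/g — the constant in solvent_fraction = 1 - 1.23 / V_M.
MATTHEWS_CONSTANT = 1.23

#: Average mass of one water molecule, Da (lost per peptide bond).
WATER_MASS = 18.02


@dataclass
class MatthewsResult:
    cell_volume: float      # ų
    v_m: float              # ų / Da
    solvent_fraction: float  # dimensionless, clipped to (0, 1)
    mass_used: float        # Da
    z_used: int

    def __post_init__(self) -> None:
        if self.v_m <= 0:
            raise ValueError("v_m must be positive")


def cell_volume(cell: CrystalCell) -> float:
    """Unit-cell volume V = abc·sqrt(1 - cos²α - cos²β - cos²γ + 2cosαcosβcosγ).

    Reduces to abc·sinβ for a monoclinic cell.
    """
    ca, cb, cg = (math.cos(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if disc <= 0:
        raise ValueError(
            f"impossible cell: angle combination ({cell.alpha}, {cell.beta}, {cell.gamma}) "
            "gives non-positive metric discriminant"
        )
    return cell.a * cell.b * cell.c * math.sqrt(disc)


def _free_residue_mass(res) -> float:
    """Mass of one residue as a free amino acid, Da.

    Standard residues come from the average-isotopic protein weight table;
    nonstandard ones fall back to the element sum of the atoms present (one
    conformer) plus one water, an approximation adequate for Matthews-level
    bookkeeping.
    """
    if res.res_name in AA3_TO_1:
        return float(molecular_weight(AA3_TO_1[res.res_name], seq_type="protein"))
    if not res.atoms:
        raise ValueError(f"unknown residue {res.res_name}{res.seq_number} with no atoms")
    seen = set()
    total = 0.0
    for a in res.atoms:
        if a.altloc not in ("", "A") or a.name in seen:
            continue
        seen.add(a.name)
        total += gemmi.Element(a.element).weight
    return total + WATER_MASS


def _chain_mass(residues: list) -> float:
    """Chain mass: free residue masses minus one water per peptide bond."""
    total = sum(_free_residue_mass(r) for r in residues)
    return total - WATER_MASS * (len(residues) - 1)


def molecular_mass(model: StructureModel) -> float:
    """Protein mass of the asymmetric-unit content, in Da.

    Sums residue masses minus one water per peptide bond over every polymer
    chain; waters and non-polymer heteroatoms are excluded (they count as
    solvent in the Matthews convention).
    """
    poly = model.polymer_chains()
    if not poly:
        raise ValueError("model has no polymer chains")
    return float(sum(_chain_mass(res) for res in poly.values()))


def matthews(cell: CrystalCell, z: int, mass: float) -> MatthewsResult:
    """Matthews coefficient V_M = V_cell / (z·mass) and implied solvent content.

    ``z`` is the number of copies of ``mass`` in the full cell: space-group
    general-position multiplicity × complexes per asymmetric unit (P2₁ with
    one complex per a.s.u. → z = 2).
    """
    if z < 1:
        raise ValueError("z must be >= 1")
    if mass <= 0:
        raise ValueError("mass must be positive")
    vol = cell_volume(cell)
    v_m = vol / (z * mass)
    if v_m <= MATTHEWS_CONSTANT:
        warnings.warn(
            f"V_M = {v_m:.2f} ų/Da implies non-physical solvent content"
        )
    solvent = 1.0 - MATTHEWS_CONSTANT / v_m
    solvent = min(max(solvent, 1e-9), 1.0 - 1e-9)
    return MatthewsResult(cell_volume=vol, v_m=v_m, solvent_fraction=solvent,
                          mass_used=float(mass), z_used=int(z))


def b_eq_from_aniso(u_aniso) -> float:
    """Equivalent isotropic B from a U tensor: B_eq = 8π²·(U11+U22+U33)/3."""
    if u_aniso is None:
        raise ValueError("no anisotropic tensor present")
    m = np.asarray(u_aniso, dtype=float)
    if m.shape == (3, 3):
        trace = float(np.trace(m))
    elif m.shape == (6,):
        trace = float(m[0] + m[1] + m[2])
    else:
        raise ValueError("u_aniso must be a 6-tuple or 3x3 matrix")
    return 8.0 * math.pi ** 2 * trace / 3.0


def average_b(model: StructureModel, selection: Selection,
              occupancy_weighted: bool = False) -> float:
    """Mean isotropic B over a selection, in Å².

    Uses B_eq when an atom carries an anisotropic tensor, else b_iso. Every
    altloc copy counts separately (matching refinement-table conventions);
    occupancy weighting is optional and off by default.
    """
    atoms = resolve_selection(model, selection)
    if not atoms:
        raise ValueError("empty selection: average B undefined")
    bs = np.array([
        b_eq_from_aniso(a.u_aniso) if a.u_aniso is not None else a.b_iso
        for a in atoms
    ])
    if occupancy_weighted:
        w = np.array([a.occupancy for a in atoms])
        if w.sum() <= 0:
            raise ValueError("zero total occupancy in selection")
        return float(np.average(bs, weights=w))
    return float(bs.mean())
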