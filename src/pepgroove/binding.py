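"""Peptide binding-mode classification and alternate-conformation analysis.

Class-I nonamers are bound either in the canonical extended conformation (CC)
or in a non-canonical mode with α-helical backbone torsions at peptide
position 6 ("p6α", NC). The call is made purely from (ϕ6, ψ6) against a
configurable α-helical box; dual conformations and their occupancy split are
read from the deposited altloc labels and occupancies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import TorsionSet, rmsd_in_frame
from .models import BACKBONE_NAMES, Residue

__all__ = [
    "AlphaBox",
    "BindingModeCall",
    "ConformerReport",
    "classify_binding_mode",
    "conformer_report",
    "per_residue_conformer_rmsd",
    "DEFAULT_ALPHA_BOX",
]


@dataclass(frozen=True)
class AlphaBox:
    """ϕ/ψ rectangle regarded as α-helical, degrees."""

    phi_lo: float = -100.0
    phi_hi: float = -30.0
    psi_lo: float = -80.0
    psi_hi: float = -5.0

    def contains(self, phi: float, psi: float) -> bool:
        return self.phi_lo <= phi <= self.phi_hi and self.psi_lo <= psi <= self.psi_hi


#: Default α box: covers the classical α basin of the Ramachandran map.
DEFAULT_ALPHA_BOX = AlphaBox()


@dataclass
class BindingModeCall:
    mode: str                 # "CC" | "NC_p6alpha"
    phi6: float
    psi6: float
    conformer: Optional[str]  # altloc label the torsions were computed for
    evidence: AlphaBox

    def __post_init__(self) -> None:
        inside = self.evidence.contains(self.phi6, self.psi6)
        if (self.mode == "NC_p6alpha") != inside:
            raise ValueError("mode label inconsistent with the ϕ/ψ box evidence")


@dataclass
class ConformerReport:
    labels: list = field(default_factory=list)
    backbone_dual: list = field(default_factory=list)   # residue seq numbers
    sidechain_dual: list = field(default_factory=list)  # residue seq numbers
    occupancy_ratio: tuple = (1.0, 0.0)

    def __post_init__(self) -> None:
        lo, hi = min(self.occupancy_ratio), max(self.occupancy_ratio)
        if not (0.0 <= lo and hi <= 1.0):
            raise ValueError("occupancy ratio components must lie in [0, 1]")

    def ratio_percent(self, step: int = 5) -> tuple:
        """Occupancy split rounded to the nearest ``step`` percent, for
        summaries mirroring crystallographic usage ("about 70-30%")."""
        major = round(self.occupancy_ratio[0] * 100 / step) * step
        return (major, 100 - major)


def classify_binding_mode(torsions: TorsionSet, conformer: Optional[str] = None,
                          alpha_box: AlphaBox = DEFAULT_ALPHA_BOX,
                          position: int = 6) -> BindingModeCall:
    """Classify a peptide conformer as canonical (CC) or p6α non-canonical.

    NC_p6alpha iff both ϕ and ψ at peptide position ``position`` (1-based,
    default p6) fall inside ``alpha_box``. A pure function of (ϕ6, ψ6, box).
    """
    phi6, psi6 = torsions.at_position(position)
    if phi6 is None or psi6 is None:
        raise ValueError(
            f"cannot classify: ϕ/ψ undefined at peptide position {position}"
        )
    mode = "NC_p6alpha" if alpha_box.contains(phi6, psi6) else "CC"
    return BindingModeCall(mode=mode, phi6=phi6, psi6=psi6,
                           conformer=conformer if conformer is not None else torsions.altloc,
                           evidence=alpha_box)


def conformer_report(peptide_residues: list) -> ConformerReport:
    """Flag dual-conformation residues and estimate the occupancy split.

    ``backbone_dual`` lists residues whose CA carries two or more altlocs;
    ``sidechain_dual`` those with any split side-chain heavy atom. The ratio
    is the mean occupancy of the majority conformer over all dual atoms,
    paired with its complement.
    """
    labels: set = set()
    backbone, sidechain = [], []
    major_occ: list = []

    for res in peptide_residues:
        by_name: dict = {}
        for a in res.atoms:
            if a.element == "H":
                continue
            by_name.setdefault(a.name, []).append(a)
        res_labels = res.altlocs()
        labels.update(res_labels)
        is_bb_dual = len({a.altloc for a in by_name.get("CA", []) if a.altloc}) >= 2
        is_sc_dual = False
        for name, atoms in by_name.items():
            alts = {a.altloc for a in atoms if a.altloc}
            if len(alts) >= 2:
                occs = sorted((a.occupancy for a in atoms if a.altloc), reverse=True)
                major_occ.append(occs[0])
                if name not in BACKBONE_NAMES:
                    is_sc_dual = True
        if is_bb_dual:
            backbone.append(res.seq_number)
        if is_sc_dual:
            sidechain.append(res.seq_number)

    if major_occ:
        p = float(np.mean(major_occ))
        ratio = (p, 1.0 - p)
    else:
        ratio = (1.0, 0.0)
    return ConformerReport(labels=sorted(labels), backbone_dual=backbone,
                           sidechain_dual=sidechain, occupancy_ratio=ratio)


def per_residue_conformer_rmsd(peptide_residues: list, label_a: str = "A",
                               label_b: str = "B",
                               atom_names=("CA",),
                               residue_window: Optional[tuple] = None):
    """In-frame distance between two conformers, per residue and pooled.

    Conformers modelled in one crystal share the frame, so no refit is done.
    ``residue_window`` restricts to an inclusive (first, last) range of
    1-based peptide positions. Residues lacking one label (and no blank
    fallback) are skipped with a warning.

    Returns (per_residue: dict seq_number -> Å, pooled: float).
    """
    atom_names = tuple(atom_names)
    per_res: dict = {}
    pooled_a, pooled_b = [], []
    for pos, res in enumerate(peptide_residues, start=1):
        if residue_window is not None and not (residue_window[0] <= pos <= residue_window[1]):
            continue
        ca_list, cb_list = [], []
        missing = False
        for name in atom_names:
            a = res.get_atom(name, label_a)
            b = res.get_atom(name, label_b)
            if a is None or b is None:
                missing = True
                continue
            ca_list.append(a.coords)
            cb_list.append(b.coords)
        if missing and not ca_list:
            warnings.warn(
                f"residue {res.res_name}{res.seq_number}: conformer atoms missing; skipped"
            )
            continue
        if not ca_list:
            continue
        per_res[res.seq_number] = rmsd_in_frame(np.vstack(ca_list), np.vstack(cb_list))
        pooled_a.extend(ca_list)
        pooled_b.extend(cb_list)
    if not pooled_a:
        raise ValueError("no residue carries both requested conformer labels")
    pooled = rmsd_in_frame(np.vstack(pooled_a), np.vstack(pooled_b))
    return per_res, pooled
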