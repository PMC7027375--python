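"""Core in-memory model: atoms, residues, models, ensembles, cells, selections.

The hierarchy mirrors a crystallographic coordinate file: an :class:`Ensemble`
holds one :class:`StructureModel` per MODEL block; each model maps chain ids to
ordered lists of :class:`Residue`; each residue carries :class:`Atom` records
including alternate-location copies. Author (deposited) residue numbering is
kept throughout — positions such as His116 or p1..p9 are always quoted in
author numbering, so nothing is ever renumbered.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

#: Residue names treated as water (kept for bridge analysis, never polymer).
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: Standard amino-acid 3-letter codes recognised as polymer residues.
AMINO3 = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL MSE".split()
)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items() if k != "MSE"}

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass
class Atom:
    """One coordinate record.

    ``u_aniso`` stores the anisotropic displacement tensor as the 6-tuple
    (U11, U22, U33, U12, U13, U23) in Å²; ``b_iso`` is the isotropic B in Å².
    A blank ``altloc`` means the atom is shared by all conformers of its
    residue.
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    b_iso: float = 0.0
    u_aniso: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.name}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(
                f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]"
            )
        if self.u_aniso is not None:
            u = tuple(float(x) for x in self.u_aniso)
            if len(u) != 6:
                raise ValueError("u_aniso must have 6 components (U11,U22,U33,U12,U13,U23)")
            if min(u[:3]) <= 0:
                raise ValueError(f"atom {self.name}: non-positive U diagonal")
            self.u_aniso = u

    def copy(self) -> "Atom":
        return dataclasses.replace(self, coords=self.coords.copy())


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    res_name: str
    insertion_code: str = ""
    atoms: list = field(default_factory=list)

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    @property
    def is_amino_acid(self) -> bool:
        return self.res_name in AMINO3

    def key(self) -> tuple:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def altlocs(self) -> list:
        """Sorted non-blank altloc labels present on this residue."""
        return sorted({a.altloc for a in self.atoms if a.altloc})

    def find_atoms(self, name: str) -> list:
        return [a for a in self.atoms if a.name == name]

    def get_atom(self, name: str, altloc: Optional[str] = None):
        """Return the atom ``name`` for conformer ``altloc``.

        A blank-altloc atom is shared by every conformer, so it satisfies any
        requested label. Returns None when absent.
        """
        exact, blank = None, None
        for a in self.atoms:
            if a.name != name:
                continue
            if a.altloc == "":
                blank = a
            if altloc is not None and a.altloc == altloc:
                exact = a
            elif altloc is None and exact is None:
                exact = a
        return exact if exact is not None else blank

    def sidechain_atoms(self, altloc: Optional[str] = None) -> list:
        out = []
        for a in self.atoms:
            if a.name in BACKBONE_NAMES or a.element == "H":
                continue
            if altloc is None or a.altloc in ("", altloc):
                out.append(a)
        return out

    def copy(self) -> "Residue":
        return Residue(
            self.chain_id, self.seq_number, self.res_name, self.insertion_code,
            [a.copy() for a in self.atoms],
        )


@dataclass
class CrystalCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    z_value: int = 1

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not (0.0 < ang < 180.0):
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.z_value < 1:
            raise ValueError("z_value must be >= 1")


@dataclass
class StructureModel:
    """One model: chain id -> ordered residue list, plus crystal header."""

    model_number: int = 1
    chains: dict = field(default_factory=dict)
    cell: Optional[CrystalCell] = None
    spacegroup: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.chains) != len(set(self.chains)):
            raise ValueError("duplicate chain ids")

    def polymer_chains(self) -> dict:
        """Chains restricted to polymer residues: standard amino acids plus
        modified residues carrying a CA atom. Waters and CA-less ligands
        (glycerol, ions) are dropped."""
        out = {}
        for cid, residues in self.chains.items():
            poly = [
                r for r in residues
                if r.is_amino_acid or (not r.is_water and r.find_atoms("CA"))
            ]
            if poly:
                out[cid] = poly
        return out

    def waters(self) -> list:
        return [r for residues in self.chains.values() for r in residues if r.is_water]

    def all_residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def all_atoms(self) -> Iterator[Atom]:
        for r in self.all_residues():
            yield from r.atoms

    def atom_count(self) -> int:
        return sum(1 for _ in self.all_atoms())

    def copy(self) -> "StructureModel":
        return StructureModel(
            self.model_number,
            {cid: [r.copy() for r in residues] for cid, residues in self.chains.items()},
            dataclasses.replace(self.cell) if self.cell else None,
            self.spacegroup,
        )


@dataclass
class Ensemble:
    """Ordered models sharing residue topology (altloc presence may differ)."""

    models: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.models:
            ref = self._residue_inventory(self.models[0])
            for m in self.models[1:]:
                if self._residue_inventory(m) != ref:
                    raise ValueError("ensemble models have differing residue inventories")

    @staticmethod
    def _residue_inventory(model: StructureModel) -> tuple:
        return tuple(
            (cid, r.seq_number, r.insertion_code, r.res_name)
            for cid, residues in model.chains.items()
            for r in residues
        )

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self) -> Iterator[StructureModel]:
        return iter(self.models)

    def __getitem__(self, i):
        return self.models[i]

    @property
    def first(self) -> StructureModel:
        return self.models[0]

    def single(self) -> StructureModel:
        """The sole model; raises if the ensemble is not single-model."""
        if len(self.models) != 1:
            raise ValueError(f"expected a single model, found {len(self.models)}")
        return self.models[0]


@dataclass
class Selection:
    """Declarative atom selection resolving to a deterministic ordered list.

    ``altloc`` is one of ``"all"`` (every copy), a specific label such as
    ``"A"`` (that label plus blank-altloc atoms), or ``"occupancy"``
    (highest-occupancy copy per atom name, ties broken by altloc label).
    ``residues`` is a sequence of (first, last) author-number ranges,
    inclusive; None selects all residues.
    """

    chain_id: Optional[str] = None
    residues: Optional[Sequence[tuple]] = None
    atom_names: Optional[frozenset] = None
    altloc: str = "all"
    include_waters: bool = False
    heavy_only: bool = True

    def __post_init__(self) -> None:
        if self.atom_names is not None:
            self.atom_names = frozenset(self.atom_names)
        if self.residues is not None:
            self.residues = tuple((int(a), int(b)) for a, b in self.residues)

    def wants_residue(self, res: Residue) -> bool:
        if self.chain_id is not None and res.chain_id != self.chain_id:
            return False
        if res.is_water and not self.include_waters:
            return False
        if self.residues is not None:
            if not any(lo <= res.seq_number <= hi for lo, hi in self.residues):
                return False
        return True

    @classmethod
    def parse(cls, text: str) -> "Selection":
        """Parse ``chain:resrange:atomnames:altloc`` (fields may be empty).

        Example: ``"C:1-9:CA:A"`` or ``"A:1-180::occupancy"``.
        """
        parts = (text.split(":") + ["", "", "", ""])[:4]
        chain = parts[0] or None
        ranges = None
        if parts[1]:
            ranges = []
            for piece in parts[1].split(","):
                if "-" in piece[1:]:  # allow negative start, not expected
                    lo, hi = piece.split("-", 1)
                    ranges.append((int(lo), int(hi)))
                else:
                    ranges.append((int(piece), int(piece)))
        names = frozenset(parts[2].split(",")) if parts[2] else None
        altloc = parts[3] or "all"
        return cls(chain_id=chain, residues=ranges, atom_names=names, altloc=altloc)


@dataclass
class Superposition:
    """Result of a least-squares rigid-body fit (proper rotation only)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        det = float(np.linalg.det(self.rotation))
        if abs(det - 1.0) > 1e-9:
            raise ValueError(f"rotation determinant {det} is not +1")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


def coords_of(atoms: Iterable[Atom]) -> np.ndarray:
    """Stack atom coordinates into an (n, 3) array."""
    pts = [a.coords for a in atoms]
    if not pts:
        return np.empty((0, 3))
    return np.vstack(pts)
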