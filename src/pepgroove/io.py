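"""Reading and writing coordinate files.

Parsing and serialisation of the PDB / mmCIF formats are delegated to gemmi;
this module converts between gemmi's structure hierarchy and the package's
own :class:`~pepgroove.models.Ensemble`, preserving alternate locations,
multi-model blocks, anisotropic displacement tensors and the crystal header.
PDB fixed-width is the reference dialect (bit-exact round trips at format
precision); mmCIF is a read-only convenience.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Union

import gemmi
import numpy as np

from .models import (
    Atom,
    CrystalCell,
    Ensemble,
    Residue,
    Selection,
    StructureModel,
)

__all__ = [
    "ParseError",
    "parse_structure",
    "write_structure",
    "resolve_selection",
    "identify_peptide_chain",
    "identify_heavy_chain",
]


class ParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


def _prevalidate_pdb(path: Path) -> None:
    """Light fixed-width sanity pass: fail with the offending line number.

    gemmi is lenient about some malformed records; the analyses downstream
    must not be. Coordinates, occupancy and B are required to parse as floats
    in their canonical columns, and every ANISOU must follow a matching ATOM.
    """
    n_atoms = 0
    serials = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                n_atoms += 1
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                    float(line[54:60]); float(line[60:66])
                    serials.add(int(line[6:11]))
                except ValueError as exc:
                    raise ParseError(
                        f"{path.name}, line {lineno}: malformed fixed-width field in {rec.strip()} record"
                    ) from exc
            elif rec == "ANISOU":
                try:
                    serial = int(line[6:11])
                except ValueError as exc:
                    raise ParseError(
                        f"{path.name}, line {lineno}: malformed ANISOU serial"
                    ) from exc
                if serial not in serials:
                    warnings.warn(
                        f"{path.name}, line {lineno}: ANISOU without matching ATOM; record dropped"
                    )
    if n_atoms == 0:
        raise ParseError(f"{path}: no ATOM/HETATM records")


def _convert_gemmi_model(gm: gemmi.Model, cell: Optional[CrystalCell],
                         spacegroup: Optional[str]) -> StructureModel:
    chains: dict = {}
    serial = 0
    for gchain in gm:
        residues = []
        for gres in gchain:
            res = Residue(
                chain_id=gchain.name,
                seq_number=gres.seqid.num,
                res_name=gres.name,
                insertion_code=(gres.seqid.icode or "").strip(),
            )
            for ga in gres:
                serial += 1
                u = None
                if ga.aniso.nonzero():
                    a = ga.aniso
                    u = (a.u11, a.u22, a.u33, a.u12, a.u13, a.u23)
                res.atoms.append(
                    Atom(
                        serial=ga.serial if ga.serial else serial,
                        name=ga.name,
                        element=ga.element.name,
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        altloc=(ga.altloc or "").strip("\x00"),
                        occupancy=float(ga.occ),
                        b_iso=float(ga.b_iso),
                        u_aniso=u,
                    )
                )
            residues.append(res)
        if gchain.name in chains:
            chains[gchain.name].extend(residues)
        else:
            chains[gchain.name] = residues
    try:
        number = int(gm.name) if hasattr(gm, "name") else int(gm.num)
    except (TypeError, ValueError):
        number = getattr(gm, "num", 1)
    return StructureModel(model_number=number, chains=chains, cell=cell,
                          spacegroup=spacegroup)


def _occupancy_sum_check(model: StructureModel) -> None:
    for res in model.all_residues():
        by_name: dict = {}
        for a in res.atoms:
            if a.altloc:
                by_name.setdefault(a.name, 0.0)
                by_name[a.name] += a.occupancy
        for name, total in by_name.items():
            if total > 1.01:
                warnings.warn(
                    f"{res.res_name}{res.seq_number} {name}: altloc occupancies sum to {total:.2f} > 1"
                )


def parse_structure(path: Union[str, Path], dialect: str = "pdb") -> Ensemble:
    """Read a coordinate file into an :class:`Ensemble`.

    Every MODEL block becomes one ensemble member. ANISOU tensors are attached
    to their atoms, blank and lettered altlocs coexist, and CRYST1 populates
    the crystal cell of every model.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if dialect not in ("pdb", "mmcif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "pdb":
        _prevalidate_pdb(path)
        st = gemmi.read_pdb(str(path))
    else:
        st = gemmi.read_structure(str(path))

    cell = None
    gc = st.cell
    if gc and gc.a > 1.0:  # gemmi uses a 1 Å dummy cell when CRYST1 is absent
        z = 1
        if dialect == "pdb":
            with open(path) as fh:
                for line in fh:
                    if line.startswith("CRYST1"):
                        zfield = line[66:70].strip()
                        if zfield.isdigit():
                            z = max(1, int(zfield))
                        break
        cell = CrystalCell(gc.a, gc.b, gc.c, gc.alpha, gc.beta, gc.gamma, z_value=z)
    spacegroup = st.spacegroup_hm or None

    models = [_convert_gemmi_model(gm, cell, spacegroup) for gm in st]
    models = [m for m in models if m.atom_count() > 0]
    if not models:
        raise ParseError(f"{path}: no atoms parsed")
    ens = Ensemble(models)
    _occupancy_sum_check(ens.first)
    return ens


def _to_gemmi(ensemble: Ensemble) -> gemmi.Structure:
    st = gemmi.Structure()
    first = ensemble.first
    if first.cell is not None:
        c = first.cell
        st.cell = gemmi.UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    if first.spacegroup:
        st.spacegroup_hm = first.spacegroup
    for model in ensemble:
        gm = gemmi.Model(model.model_number)
        for cid, residues in model.chains.items():
            gchain = gemmi.Chain(cid)
            for res in residues:
                gres = gemmi.Residue()
                gres.name = res.res_name
                gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
                if res.is_water:
                    gres.het_flag = "H"
                for atom in res.atoms:
                    if len(atom.name) > 4:
                        raise ValueError(
                            f"atom name {atom.name!r} exceeds PDB field width"
                        )
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element)
                    ga.pos = gemmi.Position(*atom.coords)
                    ga.occ = atom.occupancy
                    ga.b_iso = atom.b_iso
                    if atom.altloc:
                        ga.altloc = atom.altloc
                    if atom.u_aniso is not None:
                        ga.aniso = gemmi.SMat33f(*atom.u_aniso)
                    gres.add_atom(ga)
                gchain.add_residue(gres)
            gm.add_chain(gchain)
        st.add_model(gm)
    return st


def write_structure(ensemble: Ensemble, path: Union[str, Path],
                    dialect: str = "pdb") -> None:
    """Serialise an ensemble; the output re-parses to an equivalent ensemble
    (coordinates to 3 decimals, occupancy/B to 2)."""
    if not ensemble.models:
        raise ValueError("cannot write an empty ensemble")
    st = _to_gemmi(ensemble)
    path = Path(path)
    if dialect == "pdb":
        st.write_pdb(str(path))
    elif dialect == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _altloc_filter(res: Residue, atoms: list, mode: str) -> list:
    if mode == "all":
        return atoms
    if mode == "occupancy":
        by_name: dict = {}
        for a in atoms:
            by_name.setdefault(a.name, []).append(a)
        picked = []
        for name in by_name:
            # highest occupancy; ties: blank altloc first, then label order
            best = sorted(by_name[name], key=lambda a: (-a.occupancy, a.altloc))[0]
            picked.append(best)
        return picked
    # specific conformer label: that label plus shared blank-altloc atoms,
    # but a blank copy is dropped when a lettered copy of the same name won
    out = []
    names_with_label = {a.name for a in atoms if a.altloc == mode}
    for a in atoms:
        if a.altloc == mode:
            out.append(a)
        elif a.altloc == "" and a.name not in names_with_label:
            out.append(a)
    return out


def resolve_selection_pairs(model: StructureModel, selection: Selection) -> list:
    """Like :func:`resolve_selection` but yields (residue, atom) pairs."""
    picked = []
    for cid in sorted(model.chains):
        for res in model.chains[cid]:
            if not selection.wants_residue(res):
                continue
            atoms = res.atoms
            if selection.heavy_only:
                atoms = [a for a in atoms if a.element != "H"]
            if selection.atom_names is not None:
                atoms = [a for a in atoms if a.name in selection.atom_names]
            atoms = _altloc_filter(res, atoms, selection.altloc)
            picked.extend((res, a) for a in atoms)
    picked.sort(key=lambda pair: (pair[0].chain_id, pair[0].seq_number,
                                  pair[0].insertion_code, pair[1].name,
                                  pair[1].altloc))
    return picked


def resolve_selection(model: StructureModel, selection: Selection) -> list:
    """Resolve a :class:`Selection` to a deterministically ordered atom list.

    Order: (chain id, residue number, insertion code, atom name, altloc).
    An empty result is valid.
    """
    return [a for _, a in resolve_selection_pairs(model, selection)]


def identify_peptide_chain(model: StructureModel,
                           min_len: int = 8, max_len: int = 12) -> str:
    """Identify the bound peptide: the shortest polymer chain of 8-12 residues.

    Chain labels of deposited entries vary, so the ligand is found by length,
    the convention for class-I nonamer complexes. Ties break on chain id.
    """
    poly = model.polymer_chains()
    if len(poly) < 2:
        raise ValueError("need at least two polymer chains to identify a peptide")
    candidates = [
        (len(res), cid) for cid, res in poly.items() if min_len <= len(res) <= max_len
    ]
    if not candidates:
        raise ValueError("no peptide chain found (no polymer chain of 8-12 residues)")
    candidates.sort()
    return candidates[0][1]


def identify_heavy_chain(model: StructureModel) -> str:
    """The MHC heavy chain: the longest polymer chain (ties: chain id)."""
    poly = model.polymer_chains()
    if not poly:
        raise ValueError("no polymer chains present")
    return max(sorted(poly), key=lambda cid: len(poly[cid]))
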