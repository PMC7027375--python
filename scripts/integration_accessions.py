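#!/usr/bin/env python
"""Optional integration checks against deposited crystal structures.

The regular test suite and acceptance script are fully synthetic and
self-contained. This script adds spot checks against real deposited entries
of peptide-HLA-B27 complexes — bookkeeping totals, conformer r.m.s.d.s and
contact distances published for them — and therefore needs the coordinate
files on disk. It is NOT run by the test suite: fetch the entries yourself
(e.g. ``wget https://files.rcsb.org/download/3CZF.pdb``) into a directory
and point the script at it.

Usage:  python scripts/integration_accessions.py --dir <dir with 3CZF.pdb [2A83.pdb]>
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import numpy as np

from pepgroove import (
    Selection,
    average_b,
    conformer_report,
    contact_table,
    identify_heavy_chain,
    identify_peptide_chain,
    matthews,
    molecular_mass,
    parse_structure,
    per_residue_conformer_rmsd,
    superpose_kabsch,
)

CHECKS = []


def check(name, got, want, tol):
    ok = abs(got - want) <= tol
    CHECKS.append(ok)
    status = "PASS" if ok else "FAIL"
    print(f"[{status}] {name}: got {got:.3f}, expected {want} ± {tol}")


def run_3czf(path: Path) -> None:
    model = parse_structure(path).single()
    heavy = [a for a in model.all_atoms() if a.element != "H"]
    print(f"-- {path.name}")
    check("non-hydrogen atoms", len(heavy), 4243, 0)
    n_waters = len(model.waters())
    check("water molecules", n_waters, 712, 0)

    pep = identify_peptide_chain(model)
    pep_sel = Selection(chain_id=pep)
    n_pep = sum(
        1 for r in model.polymer_chains()[pep] for a in r.atoms if a.element != "H"
    )
    check("peptide atoms (all altlocs)", n_pep, 149, 0)
    check("peptide average B (Ų)", average_b(model, pep_sel), 12.2, 0.3)

    if model.cell is not None:
        mres = matthews(model.cell, 2, molecular_mass(model))
        check("Matthews V_M (ų/Da)", mres.v_m, 2.8, 0.05)
        check("solvent content (%)", 100 * mres.solvent_fraction, 55.0, 2.0)

    # conformer split of the bound peptide
    residues = model.polymer_chains()[pep]
    rep = conformer_report(residues)
    print(f"     occupancy split: {rep.ratio_percent()} (published: about 70-30)")
    _, pooled = per_residue_conformer_rmsd(residues)
    check("peptide Cα A/B in-frame r.m.s.d. (Å)", pooled, 0.2, 0.05)

    df = contact_table(model)

    def spot(pos, catom_re, want, kind):
        hit = df[(df.peptide_pos == pos) & df.contact_atom.str.match(catom_re)
                 & (df.kind == kind)]
        if len(hit):
            check(f"{pos} - {catom_re} ({kind}, Å)", float(hit.iloc[0].distance),
                  want, 0.1)
        else:
            CHECKS.append(False)
            print(f"[FAIL] {pos} - {catom_re}: no {kind} row found")

    spot("p3", "OH", 3.1, "HB")       # pArg3 N - Tyr99 OH
    spot("p8", "NE1", 2.9, "HB")      # pArg8 O - Trp147 NE1
    spot("p8", "OE2", 3.0, "SB")      # pArg8 NE(A) - Glu76 OE2(A)


def run_pair(path_a: Path, path_b: Path) -> None:
    """Cross-entry checks requiring both subtype structures."""
    ma = parse_structure(path_a).single()
    mb = parse_structure(path_b).single()
    print(f"-- {path_a.name} vs {path_b.name}")

    def frame_ca(model):
        pep = identify_peptide_chain(model)
        poly = model.polymer_chains()
        out = {}
        for cid in sorted(poly, key=lambda c: -len(poly[c])):
            if cid == pep:
                continue
            for r in poly[cid]:
                ca = r.get_atom("CA")
                if ca is not None:
                    out[(cid, r.seq_number)] = ca.coords
        return out

    fa, fb = frame_ca(ma), frame_ca(mb)
    # match by per-chain rank and residue number
    ra = {k[1]: v for k, v in fa.items() if k[0] == identify_heavy_chain(ma)}
    rb = {k[1]: v for k, v in fb.items() if k[0] == identify_heavy_chain(mb)}
    shared = sorted(set(ra) & set(rb))
    sup = superpose_kabsch(np.vstack([rb[s] for s in shared]),
                           np.vstack([ra[s] for s in shared]))
    check("HC Cα superposition r.m.s.d. (Å)", sup.rmsd, 0.3, 0.05)

    pep_b = identify_peptide_chain(mb)
    _, pooled = per_residue_conformer_rmsd(
        mb.polymer_chains()[pep_b], residue_window=(3, 8))
    check("2A83 peptide Cα p3-p8 A/B r.m.s.d. (Å)", pooled, 0.5, 0.05)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--dir", type=Path, required=True,
                    help="directory containing 3CZF.pdb (and optionally 2A83.pdb)")
    args = ap.parse_args()

    p3czf = args.dir / "3CZF.pdb"
    p2a83 = args.dir / "2A83.pdb"
    if not p3czf.exists():
        sys.exit(f"{p3czf} not found; download it first (no network use here)")
    run_3czf(p3czf)
    if p2a83.exists():
        run_pair(p3czf, p2a83)
    else:
        print(f"note: {p2a83} absent; cross-entry checks skipped")

    print(f"\n{sum(CHECKS)}/{len(CHECKS)} checks passed")
    sys.exit(0 if all(CHECKS) else 1)


if __name__ == "__main__":
    main()
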