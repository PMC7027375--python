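"""Per-entry analysis, cross-entry comparison and run configuration.

`analyze_entry` ties the pipeline together for one complex: binding-mode
calls per conformer, dual-conformation bookkeeping, the full contact table,
crystal metrics, and (when an ensemble is supplied) plasticity profiles and
flexibility classes. Every classification in the output carries the
parameter values that produced it, so reports are reproducible byte for
byte from the same config and inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import (
    AlphaBox,
    classify_binding_mode,
    conformer_report,
    per_residue_conformer_rmsd,
)
from .contacts import ContactCriteria, contact_table
from .geometry import phi_psi, superpose_kabsch
from .io import identify_heavy_chain, identify_peptide_chain, parse_structure
from .models import AA3_TO_1, Ensemble, Selection, StructureModel
from .plasticity import (
    FlexibilityThresholds,
    classify_flexibility,
    ensemble_rmsf,
    groove_profile,
    mimicry_overlap,
)
from .xtal import average_b, matthews, molecular_mass

__all__ = ["RunConfig", "ComplexSummary", "analyze_entry", "compare_entries"]


@dataclass
class RunConfig:
    """All tunable parameters of a run, serialised into every output."""

    contacts: ContactCriteria = field(default_factory=ContactCriteria)
    alpha_box: AlphaBox = field(default_factory=AlphaBox)
    flexibility: FlexibilityThresholds = field(default_factory=FlexibilityThresholds)
    mimicry_d0: float = 1.0
    mimicry_positions: tuple = (4, 5, 6, 7, 8)
    complexes_per_asu: int = 1
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contacts"]["vdw_window"] = list(self.contacts.vdw_window)
        d["mimicry_positions"] = list(self.mimicry_positions)
        return d

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "contacts" in raw:
            c = dict(raw["contacts"])
            if "vdw_window" in c:
                c["vdw_window"] = tuple(c["vdw_window"])
            kwargs["contacts"] = ContactCriteria(**c)
        if "alpha_box" in raw:
            kwargs["alpha_box"] = AlphaBox(**raw["alpha_box"])
        if "flexibility" in raw:
            kwargs["flexibility"] = FlexibilityThresholds(**raw["flexibility"])
        for key in ("mimicry_d0", "complexes_per_asu", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "mimicry_positions" in raw:
            kwargs["mimicry_positions"] = tuple(raw["mimicry_positions"])
        return cls(**kwargs)


@dataclass
class ComplexSummary:
    entry_id: str
    peptide_sequence: str
    binding_modes: dict            # conformer label -> mode string
    backbone_dual: list
    sidechain_dual: list
    occupancy_ratio: tuple
    contact_counts: dict           # kind -> count
    peptide_flexibility: Optional[str] = None
    hc_flexibility: Optional[str] = None
    peptide_mean_rmsf: Optional[float] = None
    hc_mean_rmsf: Optional[float] = None
    average_b_peptide: Optional[float] = None
    matthews_v_m: Optional[float] = None
    solvent_fraction: Optional[float] = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)

        def clean(x):
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, float):
                return round(x, 6)
            return x
        return clean(d)


def _peptide_sequence(model: StructureModel, chain_id: str) -> str:
    return "".join(
        AA3_TO_1.get(r.res_name, "X") for r in model.polymer_chains()[chain_id]
    )


def analyze_entry(structure_path, ensemble_path=None,
                  config: RunConfig = RunConfig(),
                  entry_id: Optional[str] = None,
                  out_dir=None) -> ComplexSummary:
    """Analyse one complex; optionally write summary.json / contacts.tsv /
    plasticity.tsv into ``out_dir``."""
    structure_path = Path(structure_path)
    ens = parse_structure(structure_path)
    model = ens.first
    entry_id = entry_id or structure_path.stem

    pep_chain = identify_peptide_chain(model)
    pep_residues = model.polymer_chains()[pep_chain]

    rep = conformer_report(pep_residues)
    conformers = rep.labels or [""]
    modes = {}
    for lab in conformers:
        ts = phi_psi(pep_residues, lab or None)
        try:
            call = classify_binding_mode(ts, lab or None, config.alpha_box)
            modes[lab or "single"] = call.mode
        except ValueError as exc:
            modes[lab or "single"] = f"undefined ({exc})"

    table = contact_table(model, config.contacts)
    counts = table["kind"].value_counts().to_dict() if len(table) else {}

    avg_b = average_b(model, Selection(chain_id=pep_chain))
    v_m = solvent = None
    if model.cell is not None:
        try:
            mass = molecular_mass(model)
            z = model.cell.z_value * config.complexes_per_asu
            mres = matthews(model.cell, z, mass)
            v_m, solvent = mres.v_m, mres.solvent_fraction
        except ValueError as exc:
            warnings.warn(f"{entry_id}: Matthews analysis skipped ({exc})")

    pep_class = hc_class = None
    pep_rmsf = hc_rmsf = None
    plast_df = None
    if ensemble_path is not None:
        ens2 = parse_structure(ensemble_path)
        prof = ensemble_rmsf(ens2)
        pep_rmsf = prof.mean_rmsf
        pep_class = classify_flexibility(pep_rmsf, config.flexibility)
        gprof = groove_profile(ens2)
        hc_rmsf = gprof.mean_rmsf
        hc_class = classify_flexibility(hc_rmsf, config.flexibility)
        plast_df = pd.concat([prof.residues, gprof.residues], ignore_index=True)

    summary = ComplexSummary(
        entry_id=entry_id,
        peptide_sequence=_peptide_sequence(model, pep_chain),
        binding_modes=modes,
        backbone_dual=rep.backbone_dual,
        sidechain_dual=rep.sidechain_dual,
        occupancy_ratio=tuple(round(float(x), 4) for x in rep.occupancy_ratio),
        contact_counts={k: int(v) for k, v in sorted(counts.items())},
        peptide_flexibility=pep_class,
        hc_flexibility=hc_class,
        peptide_mean_rmsf=pep_rmsf,
        hc_mean_rmsf=hc_rmsf,
        average_b_peptide=avg_b,
        matthews_v_m=v_m,
        solvent_fraction=solvent,
        provenance={
            "package_version": __version__,
            "config": config.to_dict(),
            "config_digest": config.digest(),
            "structure": structure_path.name,
            "ensemble": Path(ensemble_path).name if ensemble_path else None,
        },
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        table.to_csv(out_dir / "contacts.tsv", sep="\t", index=False)
        if plast_df is not None:
            plast_df.to_csv(out_dir / "plasticity.tsv", sep="\t", index=False,
                            float_format="%.4f")
    return summary


def _matched_frame_ca(model_a: StructureModel, model_b: StructureModel):
    """Cα coordinate pairs of the non-peptide polymer chains of two models,
    matched by chain role (descending length) and author residue number."""
    def frame_chains(model):
        pep = identify_peptide_chain(model)
        poly = model.polymer_chains()
        return [cid for cid in sorted(poly, key=lambda c: (-len(poly[c]), c))
                if cid != pep]

    ca_of = lambda model, cid: {
        r.seq_number: r.get_atom("CA")
        for r in model.polymer_chains()[cid]
        if r.get_atom("CA") is not None
    }
    chains_a, chains_b = frame_chains(model_a), frame_chains(model_b)
    pts_a, pts_b = [], []
    for ca_id, cb_id in zip(chains_a, chains_b):
        da, db = ca_of(model_a, ca_id), ca_of(model_b, cb_id)
        for seq in sorted(set(da) & set(db)):
            pts_a.append(da[seq].coords)
            pts_b.append(db[seq].coords)
    if len(pts_a) < 3:
        raise ValueError("fewer than 3 matched frame Cα atoms between entries")
    return np.vstack(pts_a), np.vstack(pts_b)


def _peptide_ca(model: StructureModel):
    pep = identify_peptide_chain(model)
    return np.vstack([
        r.get_atom("CA").coords
        for r in model.polymer_chains()[pep] if r.get_atom("CA") is not None
    ])


def compare_entries(entries: list, config: RunConfig = RunConfig(),
                    out_dir=None):
    """Pairwise comparison grid for ≥2 entries.

    ``entries``: list of (entry_id, structure_path, ensemble_path_or_None).
    Returns (comparison DataFrame, {pair: MimicryOverlap}). The grid holds
    the frame r.m.s.d. (non-peptide Cα, fitted), the peptide Cα r.m.s.d. in
    that frame, and the flexibility classes computed here — labelled as this
    package's calibration, not quoted values.
    """
    if len(entries) < 2:
        raise ValueError("need at least two entries to compare")
    loaded = []
    for entry_id, spath, epath in entries:
        summary = analyze_entry(spath, epath, config, entry_id=entry_id)
        model = parse_structure(spath).first
        ens = parse_structure(epath) if epath else None
        loaded.append((entry_id, model, ens, summary))

    rows = []
    mimicry = {}
    for i in range(len(loaded)):
        for j in range(i + 1, len(loaded)):
            id_a, model_a, ens_a, sum_a = loaded[i]
            id_b, model_b, ens_b, sum_b = loaded[j]
            fa, fb = _matched_frame_ca(model_a, model_b)
            sup = superpose_kabsch(fb, fa)
            pa, pb = _peptide_ca(model_a), _peptide_ca(model_b)
            pep_rmsd = None
            if len(pa) == len(pb):
                moved = sup.apply(pb)
                pep_rmsd = float(np.sqrt(np.mean(np.sum((pa - moved) ** 2, axis=1))))
            row = {
                "entry_a": id_a, "entry_b": id_b,
                "frame_ca_rmsd": sup.rmsd,
                "peptide_ca_rmsd_after_frame_fit": pep_rmsd,
                "peptide_flex_a": sum_a.peptide_flexibility,
                "peptide_flex_b": sum_b.peptide_flexibility,
                "hc_flex_a": sum_a.hc_flexibility,
                "hc_flex_b": sum_b.hc_flexibility,
                "mimicry_pooled": None,
            }
            if ens_a is not None and ens_b is not None:
                try:
                    ov = mimicry_overlap(ens_a, ens_b, config.mimicry_positions,
                                         config.mimicry_d0)
                    mimicry[(id_a, id_b)] = ov
                    row["mimicry_pooled"] = ov.pooled
                except ValueError as exc:
                    warnings.warn(f"mimicry {id_a}/{id_b} omitted: {exc}")
            rows.append(row)
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "comparison.tsv", sep="\t", index=False,
                  float_format="%.4f")
    return df, mimicry
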