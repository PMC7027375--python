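"""Per-residue conformational plasticity from multi-model ensembles.

An ensemble-refined crystal structure is a set of models whose spread about
the mean reports conformational mobility more faithfully than B factors
(which also absorb lattice defects, rigid-body motion and occupancy errors).
This module superposes all models into a common frame (Cα of the heavy chain
plus the light chain, peptide excluded), computes per-atom root-mean-square
fluctuations about the ensemble mean, aggregates them per residue, and maps
summary fluctuation levels onto an ordinal marginal / intermediate / high
flexibility vocabulary. The numeric thresholds of that mapping are a package
calibration — published flexibility labels of this kind are qualitative — and
are therefore configurable and recorded in every output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import superpose_kabsch
from .io import identify_heavy_chain, identify_peptide_chain, resolve_selection_pairs
from .models import BACKBONE_NAMES, Ensemble, Selection, StructureModel

__all__ = [
    "PlasticityProfile",
    "MimicryOverlap",
    "FlexibilityThresholds",
    "ensemble_rmsf",
    "sidechain_heterogeneity",
    "classify_flexibility",
    "groove_profile",
    "mimicry_overlap",
    "GROOVE_REGIONS",
]

#: Named binding-groove regions (author numbering on the heavy chain) whose
#: mobility is summarised separately: loops below the α1-helix, the groove
#: ends, and the 106-108 loop.
GROOVE_REGIONS = {
    "13-18": (13, 18),
    "54-58": (54, 58),
    "86-90": (86, 90),
    "106-108": (106, 108),
    "175-181": (175, 181),
}


@dataclass(frozen=True)
class FlexibilityThresholds:
    """Mean-Cα-rmsf boundaries (Å) between the ordinal flexibility classes.

    A value equal to a boundary is assigned the *higher* class.
    """

    marginal_max: float = 0.3
    intermediate_max: float = 0.7


@dataclass
class PlasticityProfile:
    """Per-residue fluctuation table plus summary statistics.

    ``residues`` columns: chain_id, seq_number, res_name, rmsf_ca,
    rmsf_allatom, sidechain_heterogeneity (NaN unless requested).
    """

    residues: pd.DataFrame
    selection_name: str
    mean_rmsf: float
    max_rmsf: float
    n_models: int
    flexibility_class: Optional[str] = None
    thresholds: Optional[FlexibilityThresholds] = None
    region_summaries: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("rmsf_ca", "rmsf_allatom"):
            if col in self.residues and len(self.residues):
                vals = self.residues[col].dropna()
                if len(vals) and (vals < 0).any():
                    raise ValueError("fluctuations must be non-negative")


@dataclass
class MimicryOverlap:
    """Per-position similarity of two ensembles seen from above the groove.

    score(p) = exp(-d_p / d0) * J(p) where d_p is the mean-structure Cα
    distance at peptide position p after a common heavy-chain fit and J is
    the Jaccard overlap of the two fluctuation intervals [r/2, 3r/2].
    """

    per_position: dict
    pooled: float
    d0: float
    positions: tuple


# ---------------------------------------------------------------------------
# superposition frame

def _atom_table(model: StructureModel) -> dict:
    """(chain, seq, icode, name) -> coords for one heavy-atom copy per name."""
    sel = Selection(altloc="occupancy", heavy_only=True)
    return {
        (res.chain_id, res.seq_number, res.insertion_code, atom.name): atom.coords
        for res, atom in resolve_selection_pairs(model, sel)
    }


def _frame_keys(ensemble: Ensemble, tables: list) -> list:
    """Cα of every polymer chain except the peptide, present in all models."""
    model = ensemble.first
    try:
        pep = identify_peptide_chain(model)
    except ValueError:
        pep = None
    keys = [
        k for k in tables[0]
        if k[3] == "CA" and k[0] != pep
    ]
    poly = set()
    for cid, residues in model.polymer_chains().items():
        for r in residues:
            poly.add((r.chain_id, r.seq_number, r.insertion_code))
    keys = [k for k in keys if k[:3] in poly]
    keys = [k for k in keys if all(k in t for t in tables)]
    if len(keys) < 3:
        raise ValueError("fewer than 3 shared frame Cα atoms; cannot superpose")
    return sorted(keys)


def superposed_atom_tables(ensemble: Ensemble) -> list:
    """Atom tables of every model after fitting into the common frame.

    Each model is Kabsch-fitted on the frame Cα set onto the running
    reference; the reference starts as the first model and is replaced once
    by the ensemble mean (one re-iteration).
    """
    if len(ensemble) < 2:
        raise ValueError("plasticity undefined for a single-model ensemble")
    tables = [_atom_table(m) for m in ensemble]
    keys = _frame_keys(ensemble, tables)

    def frame_coords(table: dict) -> np.ndarray:
        return np.vstack([table[k] for k in keys])

    ref = frame_coords(tables[0])
    for _ in range(2):  # fit, recompute mean once, refit
        fitted = []
        for t in tables:
            sup = superpose_kabsch(frame_coords(t), ref)
            fitted.append({k: sup.apply(v) for k, v in t.items()})
        ref = np.mean([frame_coords(t) for t in fitted], axis=0)
        tables = fitted
    return tables


def _shared_keys(tables: list) -> list:
    keys = set(tables[0])
    for t in tables[1:]:
        keys &= set(t)
    return sorted(keys)


def _rmsf_by_key(tables: list) -> dict:
    keys = _shared_keys(tables)
    out = {}
    for k in keys:
        pts = np.vstack([t[k] for t in tables])
        mean = pts.mean(axis=0)
        out[k] = float(np.sqrt(np.mean(np.sum((pts - mean) ** 2, axis=1))))
    return out


# ---------------------------------------------------------------------------
# public operations

def ensemble_rmsf(ensemble: Ensemble, selection: Optional[Selection] = None,
                  reference: str = "mean",
                  selection_name: str = "peptide") -> PlasticityProfile:
    """Per-residue r.m.s. fluctuation about the ensemble mean position.

    All models are superposed on the heavy-chain + light-chain Cα frame
    first, so rigid-body spread does not masquerade as plasticity. The
    per-residue ``rmsf_ca`` is the CA atom's fluctuation; ``rmsf_allatom``
    averages over the residue's heavy atoms. ``reference`` may be ``"mean"``
    (default, iterated once) or ``"first-model"``.
    """
    if len(ensemble) < 2:
        raise ValueError("plasticity undefined for a single-model ensemble")
    if reference not in ("mean", "first-model"):
        raise ValueError(f"unknown reference {reference!r}")
    tables = superposed_atom_tables(ensemble)
    if reference == "first-model":
        # fluctuations about model 1 instead of the mean
        rmsf = {}
        for k in _shared_keys(tables):
            pts = np.vstack([t[k] for t in tables])
            rmsf[k] = float(np.sqrt(np.mean(np.sum((pts - tables[0][k]) ** 2, axis=1))))
    else:
        rmsf = _rmsf_by_key(tables)

    model = ensemble.first
    if selection is None:
        pep = identify_peptide_chain(model)
        selection = Selection(chain_id=pep)

    rows = []
    for cid in sorted(model.chains):
        for res in model.chains[cid]:
            if not selection.wants_residue(res) or not res.is_amino_acid:
                continue
            res_keys = [
                (res.chain_id, res.seq_number, res.insertion_code, a)
                for a in {at.name for at in res.atoms if at.element != "H"}
            ]
            vals = [rmsf[k] for k in res_keys if k in rmsf]
            ca_key = (res.chain_id, res.seq_number, res.insertion_code, "CA")
            rows.append({
                "chain_id": res.chain_id,
                "seq_number": res.seq_number,
                "res_name": res.res_name,
                "rmsf_ca": rmsf.get(ca_key, np.nan),
                "rmsf_allatom": float(np.mean(vals)) if vals else np.nan,
                "sidechain_heterogeneity": np.nan,
            })
    df = pd.DataFrame(rows)
    ca = df["rmsf_ca"].dropna()
    if ca.empty:
        raise ValueError("selection resolves to no Cα atoms")
    return PlasticityProfile(
        residues=df, selection_name=selection_name,
        mean_rmsf=float(ca.mean()), max_rmsf=float(ca.max()),
        n_models=len(ensemble),
    )


def sidechain_heterogeneity(ensemble: Ensemble, chain_id: str, seq_number: int,
                            insertion_code: str = ""):
    """Mean pairwise r.m.s.d. (Å) of one residue's side-chain heavy atoms
    across models, after superposing each model's local backbone (N, CA, C of
    the residue and its two neighbours).

    Returns (value, flag); glycine yields (0.0, "no side chain").
    """
    if len(ensemble) < 2:
        raise ValueError("heterogeneity undefined for a single-model ensemble")
    model = ensemble.first
    target_chain = model.chains.get(chain_id)
    if target_chain is None:
        raise ValueError(f"no chain {chain_id!r}")
    idx = next(
        (i for i, r in enumerate(target_chain)
         if r.seq_number == seq_number and r.insertion_code == insertion_code),
        None,
    )
    if idx is None:
        raise ValueError(f"no residue {chain_id}/{seq_number}{insertion_code}")

    res0 = target_chain[idx]
    sc_names = sorted({a.name for a in res0.sidechain_atoms()})
    if not sc_names:
        return 0.0, "no side chain"

    lo, hi = max(0, idx - 1), min(len(target_chain), idx + 2)
    bb_keys = [
        (r.seq_number, r.insertion_code, n)
        for r in target_chain[lo:hi] for n in ("N", "CA", "C")
    ]

    def coords(m: StructureModel, names, residue_filter):
        chain = m.chains[chain_id]
        table = {}
        for r in chain[lo:hi] if residue_filter else chain:
            for a in r.atoms:
                if a.element == "H":
                    continue
                key = (r.seq_number, r.insertion_code, a.name)
                if key not in table or a.occupancy > table[key][1]:
                    table[key] = (a.coords, a.occupancy)
        return table

    sc_sets = []
    for m in ensemble:
        table = coords(m, sc_names, residue_filter=True)
        bb = [table[k][0] for k in bb_keys if k in table]
        if len(bb) < 3:
            raise ValueError("local backbone incomplete; cannot superpose")
        ref_table = coords(ensemble.first, sc_names, residue_filter=True)
        ref_bb = [ref_table[k][0] for k in bb_keys if k in ref_table]
        sup = superpose_kabsch(np.vstack(bb), np.vstack(ref_bb))
        sc = [
            sup.apply(table[(seq_number, insertion_code, n)][0])
            for n in sc_names if (seq_number, insertion_code, n) in table
        ]
        sc_sets.append(np.vstack(sc))

    n = len(sc_sets)
    dists = [
        float(np.sqrt(np.mean(np.sum((sc_sets[i] - sc_sets[j]) ** 2, axis=1))))
        for i in range(n) for j in range(i + 1, n)
        if sc_sets[i].shape == sc_sets[j].shape
    ]
    if not dists:
        raise ValueError("side-chain atom sets differ between models")
    return float(np.mean(dists)), ""


def classify_flexibility(mean_rmsf: float,
                         thresholds: FlexibilityThresholds = FlexibilityThresholds()) -> str:
    """Ordinal flexibility class from a mean Cα rmsf; ties go to the higher
    class. Monotone in ``mean_rmsf`` by construction."""
    if mean_rmsf < 0:
        raise ValueError("mean rmsf must be non-negative")
    if mean_rmsf >= thresholds.intermediate_max:
        return "high"
    if mean_rmsf >= thresholds.marginal_max:
        return "intermediate"
    return "marginal"


def groove_profile(ensemble: Ensemble, last_residue: int = 180) -> PlasticityProfile:
    """Plasticity profile of the binding-groove domains of the heavy chain
    (author residues 1-``last_residue``), with named-region summaries."""
    model = ensemble.first
    hc = identify_heavy_chain(model)
    hc_residues = model.polymer_chains()[hc]
    max_seq = max(r.seq_number for r in hc_residues)
    if max_seq < last_residue:
        warnings.warn(
            f"heavy chain ends at residue {max_seq} < {last_residue}; "
            "profiling the available range"
        )
    sel = Selection(chain_id=hc, residues=[(min(r.seq_number for r in hc_residues),
                                            min(last_residue, max_seq))])
    profile = ensemble_rmsf(ensemble, sel, selection_name=f"HC groove 1-{last_residue}")
    df = profile.residues
    for name, (lo, hi) in GROOVE_REGIONS.items():
        sub = df[(df.seq_number >= lo) & (df.seq_number <= hi)]["rmsf_ca"].dropna()
        if len(sub):
            profile.region_summaries[name] = float(sub.mean())
    return profile


def _interval_overlap(r_a: float, r_b: float) -> float:
    """Jaccard overlap of the fluctuation intervals [r/2, 3r/2]."""
    lo_a, hi_a = r_a / 2.0, 1.5 * r_a
    lo_b, hi_b = r_b / 2.0, 1.5 * r_b
    if hi_a == lo_a and hi_b == lo_b:  # both rigid
        return 1.0 if abs(r_a - r_b) < 1e-12 else 0.0
    inter = max(0.0, min(hi_a, hi_b) - max(lo_a, lo_b))
    union = max(hi_a, hi_b) - min(lo_a, lo_b)
    return inter / union if union > 0 else 0.0


def mimicry_overlap(ensemble_a: Ensemble, ensemble_b: Ensemble,
                    positions: tuple = (4, 5, 6, 7, 8),
                    d0: float = 1.0) -> MimicryOverlap:
    """Quantify how similar the collection of peptide surfaces shown to a
    T-cell receptor is between two complexes.

    Both ensembles are reduced to mean structures in a common frame (the
    second complex is fitted onto the first on the shared-length heavy-chain
    Cα trace); at each peptide position the score combines mean-structure
    proximity, exp(-d_p/d0), with the overlap of the two rmsf intervals.
    The pooled score is the mean over the solvent-exposed positions
    (default p4-p8). This functional form is a package convention for an
    otherwise qualitative notion.
    """
    prof_a = ensemble_rmsf(ensemble_a)
    prof_b = ensemble_rmsf(ensemble_b)

    tables_a = superposed_atom_tables(ensemble_a)
    tables_b = superposed_atom_tables(ensemble_b)
    mean_a = {k: np.mean([t[k] for t in tables_a], axis=0) for k in _shared_keys(tables_a)}
    mean_b = {k: np.mean([t[k] for t in tables_b], axis=0) for k in _shared_keys(tables_b)}

    pep_a = identify_peptide_chain(ensemble_a.first)
    pep_b = identify_peptide_chain(ensemble_b.first)
    res_a = ensemble_a.first.polymer_chains()[pep_a]
    res_b = ensemble_b.first.polymer_chains()[pep_b]
    if len(res_a) != len(res_b):
        raise ValueError(
            f"peptide length mismatch: {len(res_a)} vs {len(res_b)}"
        )

    # common frame: fit B's heavy-chain mean Cα trace onto A's, matching by
    # author residue number
    hc_a, hc_b = identify_heavy_chain(ensemble_a.first), identify_heavy_chain(ensemble_b.first)
    ca_a = {k[1]: v for k, v in mean_a.items() if k[0] == hc_a and k[3] == "CA"}
    ca_b = {k[1]: v for k, v in mean_b.items() if k[0] == hc_b and k[3] == "CA"}
    shared = sorted(set(ca_a) & set(ca_b))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared heavy-chain Cα positions")
    sup = superpose_kabsch(np.vstack([ca_b[s] for s in shared]),
                           np.vstack([ca_a[s] for s in shared]))

    rmsf_a = dict(zip(prof_a.residues.seq_number, prof_a.residues.rmsf_ca))
    rmsf_b = dict(zip(prof_b.residues.seq_number, prof_b.residues.rmsf_ca))

    per_pos = {}
    for pos in positions:
        ra, rb = res_a[pos - 1], res_b[pos - 1]
        key_a = (pep_a, ra.seq_number, ra.insertion_code, "CA")
        key_b = (pep_b, rb.seq_number, rb.insertion_code, "CA")
        if key_a not in mean_a or key_b not in mean_b:
            continue
        d_p = float(np.linalg.norm(mean_a[key_a] - sup.apply(mean_b[key_b])))
        j = _interval_overlap(float(rmsf_a.get(ra.seq_number, 0.0)),
                              float(rmsf_b.get(rb.seq_number, 0.0)))
        per_pos[pos] = float(np.exp(-d_p / d0) * j)
    if not per_pos:
        raise ValueError("no comparable peptide positions")
    return MimicryOverlap(per_position=per_pos,
                          pooled=float(np.mean(list(per_pos.values()))),
                          d0=d0, positions=tuple(positions))
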