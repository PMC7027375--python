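"""Quantify per-residue plasticity from multi-model ensembles.

Two ensembles share one mean structure but differ in peptide jitter
(sd 0.1 Å vs 0.9 Å). After superposition on the heavy-chain frame, the
per-residue rmsf recovers the planted sd via rmsf = σ·√3, the ordinal
flexibility classes separate, and the mimicry score between the two drops
to zero because their fluctuation intervals are disjoint.
"""

import numpy as np

from pepgroove import (
    EnsembleSpec,
    GrooveSpec,
    build_ensemble,
    build_groove,
    classify_flexibility,
    ensemble_rmsf,
    mimicry_overlap,
)

base = build_groove(GrooveSpec(seed=3))
quiet = build_ensemble(EnsembleSpec(base=base, n_models=200, peptide_sigma=0.1, seed=4))
wild = build_ensemble(EnsembleSpec(base=base, n_models=200, peptide_sigma=0.9,
                                   rigid_rot_deg=1.0, rigid_trans=0.3, seed=5))

for name, ens, sigma in (("quiet", quiet, 0.1), ("wild", wild, 0.9)):
    prof = ensemble_rmsf(ens)
    est = prof.mean_rmsf / np.sqrt(3)
    cls = classify_flexibility(prof.mean_rmsf)
    print(f"{name}: mean Cα rmsf {prof.mean_rmsf:.3f} Å -> σ estimate "
          f"{est:.3f} Å (planted {sigma}), class {cls}")

ov = mimicry_overlap(quiet, wild)
print(f"mimicry score quiet vs wild: {ov.pooled:.4f} over positions {ov.positions}")
ov_self = mimicry_overlap(quiet, quiet)
print(f"mimicry score quiet vs itself: {ov_self.pooled:.4f}")
# The rigid-motion noise added to the wild ensemble does not inflate its
# rmsf — the common-frame superposition removes it before fluctuations are
# measured, which is exactly why ensemble spread is a better mobility readout
# than B factors.
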