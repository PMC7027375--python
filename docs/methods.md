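# Methods

## Scope and model of the data

`pepgroove` analyses crystallographic models of class-I peptide-MHC
complexes: a heavy chain (HC) whose α1/α2 domains (residues 1–180) form the
peptide-binding groove, an invariant light chain (β₂-microglobulin), and a
short bound peptide, conventionally numbered p1–p9 for a nonamer. The
package consumes standard coordinate files — single models with alternate
locations (altlocs) and anisotropic displacement tensors, or multi-model
ensembles as produced by ensemble refinement — and computes four families of
quantities: peptide binding-mode calls, alternate-conformation statistics,
typed contact networks, and per-residue conformational plasticity, plus
crystal-content bookkeeping.

All residue numbering is author (deposited) numbering; nothing is ever
renumbered. Blank-altloc atoms are treated as shared by every conformer of
their residue, the standard PDB semantics, which is what lets a backbone
split confined to p6–p8 coexist with a common backbone elsewhere.

## Binding-mode classification

A peptide conformer is called non-canonical ("p6α", NC) when its main-chain
ϕ/ψ at peptide position 6 falls inside a configurable α-helical rectangle,
and canonical (CC) otherwise. The default box, ϕ ∈ [−100°, −30°],
ψ ∈ [−80°, −5°], covers the classical α basin of the Ramachandran map. The
literature names the α-helical criterion but publishes no numeric bounds, so
the box is a package default, recorded in every output, not a claim about
any author's cut-off. The call is a pure function of (ϕ6, ψ6, box):
shrinking the box can only move calls from NC to CC.

Torsions follow the IUPAC sign convention (cis = 0°, trans = 180°),
validated against Biopython's `calc_dihedral`. ϕ/ψ are computed per
conformer label; chain breaks (C–N > 2.0 Å) and missing backbone atoms give
undefined values rather than errors.

## Conformer analysis

Dual conformations are read from deposited altloc labels: a residue is
backbone-dual when its CA carries ≥2 labels and side-chain-dual when any
side-chain heavy atom does. The occupancy ratio is the mean occupancy of
the majority conformer over all dual atoms, paired with its complement, and
is reported rounded to 5% in summaries (mirroring crystallographic usage:
"about 70–30%").

Conformer r.m.s.d.s (A vs B within one entry) are computed **in frame** —
no refitting — because both conformers are modelled in a single crystal
frame; a Kabsch refit would artificially shrink the difference. Whole-entry
comparisons between different crystals instead use a least-squares fit on
the Cα of HC + light chain with the peptide excluded; the fitted r.m.s.d. is
never larger than the in-frame value for the same correspondence.
Superposition correspondence is by selection order, never distance matching.

## Contact typing

Contacts are heavy-atom and distance-only. Deposited models at this
resolution carry no hydrogens and published contact tables quote heavy-atom
distances, so donors/acceptors are typed from a per-residue chemistry table
(backbone N donor except proline, backbone O/OXT acceptor, the usual
side-chain assignments) and no angle criterion is applied. Defaults:
hydrogen bond ≤ 3.5 Å; salt bridge ≤ 4.0 Å between a positive group
(Arg NE/NH1/NH2, Lys NZ, His ND1/NE2) and a negative one (Asp OD1/OD2,
Glu OE1/OE2, C-terminal carboxylate); van-der-Waals window 3.6–4.0 Å;
water-bridge leg ≤ 3.5 Å. Classification is a strict partition with
precedence SB > HB > vdW — no atom pair is reported twice. His is treated
as potentially charged; His-carboxylate pairs are typed SB with an explicit
note. vdW contacts are aggregated residue-to-residue keeping the minimum
distance (per-atom records behind a flag). Altloc consistency is enforced:
partners share a label or one is blank. Same-residue pairs and
covalently-adjacent backbone-backbone pairs are excluded. A water bridge is
one water oxygen within the leg cut-off of a polar atom on each side; the
record's single distance field holds the longer leg, with both legs kept in
the record note.

## Plasticity from ensembles

Multi-model ensembles are superposed into a common frame: Kabsch on the Cα
of HC + light chain (peptide excluded), first onto model 1, then once more
onto the recomputed ensemble mean. Per-atom r.m.s. fluctuation (rmsf) is the
root-mean-square deviation from the ensemble mean position; per-residue
values are the CA atom's rmsf and the mean over the residue's heavy atoms.
Because the frame removes global rigid motion, lattice-wide displacements do
not masquerade as plasticity — the reason ensemble spread is a better
mobility readout than B factors, which also absorb lattice defects,
rigid-body motion and occupancy error. For isotropic per-coordinate Gaussian
jitter of sd σ the expected rmsf is σ·√3; the test suite plants σ and
requires recovery within 5% at 200 models.

Side-chain heterogeneity of a residue is the mean pairwise r.m.s.d. of its
side-chain heavy atoms across models after superposing each model's local
backbone (N/CA/C of the residue ± 1); glycine returns 0 with a
"no side chain" flag.

Flexibility classes (marginal / intermediate / high) are ordinal cuts on
the mean Cα rmsf at configurable thresholds, default 0.3 Å and 0.7 Å, with
ties going to the higher class. Published flexibility labels of this kind
are qualitative; these thresholds are a package calibration chosen to
separate the synthetic calibration ensembles (σ = 0.1 / 0.4 / 0.9 Å), are
never hard-coded claims about any experiment, and are carried in every
output's provenance block.

Groove profiles restrict to HC residues 1–180 and summarise named regions
(13–18, 54–58, 86–90, 106–108, 175–181 — the loops below the α1 helix, the
groove ends and the 106–108 loop) by their mean Cα rmsf.

### Mimicry score

How similar is the collection of peptide surfaces two complexes show a
T-cell receptor? The package quantifies this otherwise qualitative notion
with an artifact-defined score: after fitting the second complex onto the
first on shared HC Cα positions, each peptide position p gets
score(p) = exp(−d_p/d0) · J(p), where d_p is the mean-structure Cα distance
(d0 = 1.0 Å by default) and J is the Jaccard overlap of the two fluctuation
intervals [r/2, 3r/2] built from the positional rmsf values. Identical mean
structures with identical fluctuations score 1; means further apart than a
few d0 saturate to 0; rmsf values differing by ≥3× have disjoint intervals
and also score 0. The pooled score averages the solvent-exposed positions
(p4–p8 by default). The half-width r/2 is a package choice: it makes the
factor scale-free in r and gives the 3× disjointness property.

## Crystal metrics

Cell volume uses the triclinic closed form
V = abc·√(1 − cos²α − cos²β − cos²γ + 2cosα·cosβ·cosγ), which reduces to
abc·sinβ for monoclinic cells. The Matthews coefficient is
V_M = V/(z·M) with z = space-group multiplicity × complexes per asymmetric
unit; solvent fraction is 1 − 1.23/V_M, the convention constant for a
protein partial specific volume of 0.74 cm³/g. Note that this convention
yields ≈56% solvent at V_M = 2.8 ų/Da where crystallographic papers often
round to 55%; outputs carry the computed value. Protein mass sums free
residue masses (Biopython's average-isotopic table) minus one water per
peptide bond; nonstandard residues fall back to the element sum of their
atoms plus one water — adequate for Matthews-level bookkeeping, not for mass
spectrometry. B_eq = 8π²·(U11+U22+U33)/3 converts anisotropic tensors;
selection-averaged B uses B_eq when a tensor is present, counts every altloc
copy separately, and offers optional occupancy weighting (off by default —
refinement-table conventions vary and the difference is within 0.3 Ų for
the fixtures).

## The synthetic generator

The generator is the package's test surface, built so that every planted
quantity is recovered by the corresponding analysis operation:

* **Backbone**: NeRF-style chain extension with ideal geometry (N–CA 1.458,
  CA–C 1.525, C–N 1.329, C=O 1.231 Å; standard angles; ω = 180°) at
  requested (ϕ, ψ). Torsion recovery is exact to machine precision; the
  tests require 0.5°.
* **Scaffold**: two poly-Ala α-helix walls (axis-aligned by principal
  component, flanking the peptide at a configurable lateral offset, default
  8 Å) stand in for the α1/α2 helices; a short helix below stands in for the
  light chain. Side chains stop at Cβ except where a planted contact names
  an atom, which is then placed explicitly at the exact target distance in
  the most clash-free direction (error if every direction clashes).
  Planted atoms are positioned by the plan, not by their residue's covalent
  chemistry — the scaffold is geometry, not a force field.
* **Conformers**: dual sites duplicate the planned atoms as altloc A/B with
  a fixed displacement and the requested occupancies.
* **Waters**: bridging waters are placed on the two-sphere intersection
  satisfying both leg distances.
* **Ensembles**: per-atom i.i.d. Gaussian jitter with per-residue sd, plus
  optional global rigid motion per model (which the analysis must and does
  remove). Everything is seeded; the same spec and seed reproduce the same
  file byte for byte.

What the generator does **not** emulate: real rotamer chemistry, correlated
motions, crystal packing, solvent structure beyond planted waters, and the
actual output of stochastic ensemble-refinement protocols. Passing the
closed-loop tests therefore demonstrates that the analysis operations
measure what they claim on known inputs — it does not certify agreement
with any particular deposited entry. Spot checks against deposited
structures live in `scripts/integration_accessions.py` and require the
coordinate files on disk.

## Problem sizes and numerics

Test and acceptance runs use a 180-residue scaffold, 9-mer peptides and
200-model ensembles — the size at which the σ-recovery bound (5%) is
comfortably met while the whole suite stays within a couple of minutes.
Kabsch uses SVD with the determinant correction (reflections excluded);
collinear point sets are rejected rather than silently fitted. Degenerate
torsions (coincident or collinear points) raise; chain breaks yield
undefined torsions. Flexibility ties go to the higher class. Occupancy sums
over altlocs exceeding 1.01 warn but do not fail, since deposited files
occasionally contain them.
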