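"""Ensemble fluctuation analysis: recovery of planted jitter, invariances,
flexibility classes and the mimicry score."""

import numpy as np
import pytest

from pepgroove import (
    Ensemble,
    EnsembleSpec,
    FlexibilityThresholds,
    GrooveSpec,
    build_ensemble,
    build_groove,
    classify_flexibility,
    ensemble_rmsf,
    groove_profile,
    identify_peptide_chain,
    mimicry_overlap,
    sidechain_heterogeneity,
)
from pepgroove.plasticity import _interval_overlap, superposed_atom_tables

SQRT3 = np.sqrt(3.0)


def _small_spec(seed):
    return GrooveSpec(groove_size=40, light_chain_size=10, seed=seed)


class TestRmsf:
    def test_identical_models_have_zero_rmsf(self, base_groove):
        ens = build_ensemble(EnsembleSpec(base=base_groove, n_models=5,
                                          sigma_default=0.0, seed=1))
        prof = ensemble_rmsf(ens)
        assert prof.mean_rmsf == pytest.approx(0.0, abs=1e-9)
        assert prof.max_rmsf == pytest.approx(0.0, abs=1e-9)

    def test_isotropic_jitter_gives_sigma_times_sqrt3(self, halfsigma_ensemble):
        prof = ensemble_rmsf(halfsigma_ensemble)
        expected = 0.5 * SQRT3
        assert prof.mean_rmsf == pytest.approx(expected, rel=0.05)

    def test_rmsf_ordering_follows_planted_sigmas(self, base_groove):
        ens = build_ensemble(EnsembleSpec(
            base=base_groove, n_models=80,
            sigma_overrides={("C", 2): 0.2, ("C", 7): 0.8},
            seed=2,
        ))
        prof = ensemble_rmsf(ens)
        df = prof.residues.set_index("seq_number")
        assert df.loc[7, "rmsf_ca"] > df.loc[2, "rmsf_ca"]

    def test_rigid_motion_noise_does_not_inflate_rmsf(self, base_groove):
        """Per-model rigid motions are removed by the superposition step."""
        quiet = build_ensemble(EnsembleSpec(base=base_groove, n_models=20,
                                            peptide_sigma=0.3, seed=3))
        rng = np.random.default_rng(30)
        shaken = []
        for m in quiet:
            mm = m.copy()
            ang = rng.normal(0, np.radians(2.0))
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            rot = np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)
            shift = rng.normal(0, 0.5, size=3)
            for atom in mm.all_atoms():
                atom.coords = rot @ atom.coords + shift
            shaken.append(mm)
        a = ensemble_rmsf(quiet).mean_rmsf
        b = ensemble_rmsf(Ensemble(shaken)).mean_rmsf
        assert b == pytest.approx(a, abs=1e-6)

    def test_global_rigid_motion_invariance_exact(self, base_groove):
        ens = build_ensemble(EnsembleSpec(base=base_groove, n_models=10,
                                          peptide_sigma=0.4, seed=4))
        prof = ensemble_rmsf(ens)
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved_models = []
        for m in ens:
            mm = m.copy()
            for atom in mm.all_atoms():
                atom.coords = rot @ atom.coords + np.array([10.0, -4.0, 2.0])
            moved_models.append(mm)
        prof2 = ensemble_rmsf(Ensemble(moved_models))
        a = prof.residues.set_index("seq_number")["rmsf_ca"]
        b = prof2.residues.set_index("seq_number")["rmsf_ca"]
        assert np.allclose(a.values, b.values, atol=1e-6)

    def test_single_model_ensemble_is_an_error(self, base_groove):
        with pytest.raises(ValueError, match="single-model"):
            ensemble_rmsf(Ensemble([base_groove]))


class TestSidechainHeterogeneity:
    def test_identical_models_give_zero(self, base_groove):
        ens = build_ensemble(EnsembleSpec(base=base_groove, n_models=4,
                                          sigma_default=0.0, seed=5))
        val, flag = sidechain_heterogeneity(ens, "C", 4)
        assert val == pytest.approx(0.0, abs=1e-9)
        assert flag == ""

    def test_two_rotamer_alternation_matches_closed_form(self):
        """CB flips between two sites 1.0 Å apart in alternate models: the
        mean pairwise distance of a balanced two-point distribution is half
        the site separation."""
        base = build_groove(_small_spec(6))
        models = []
        shift = np.array([0.0, 0.0, 1.0])
        for i in range(6):
            m = base.copy()
            m.model_number = i + 1
            if i % 2 == 1:
                res = m.chains["C"][3]
                cb = res.get_atom("CB")
                cb.coords = cb.coords + shift
            models.append(m)
        val, _ = sidechain_heterogeneity(Ensemble(models), "C", 4)
        # 6 models, 3+3 split: 9 of 15 pairs differ by 1.0 -> mean 0.6
        assert val == pytest.approx(9 / 15, abs=1e-6)

    def test_glycine_is_flagged(self):
        spec = GrooveSpec(sequence="RRGWHRWRL", groove_size=40,
                          light_chain_size=10, seed=7)
        ens = build_ensemble(EnsembleSpec(base=spec, n_models=3, seed=8))
        val, flag = sidechain_heterogeneity(ens, "C", 3)
        assert val == 0.0 and flag == "no side chain"


class TestClassification:
    def test_threshold_bands_and_tie_rule(self):
        th = FlexibilityThresholds(0.3, 0.7)
        assert classify_flexibility(0.1, th) == "marginal"
        assert classify_flexibility(0.5, th) == "intermediate"
        assert classify_flexibility(0.9, th) == "high"
        assert classify_flexibility(0.3, th) == "intermediate"  # tie -> higher
        assert classify_flexibility(0.7, th) == "high"

    def test_monotone_in_mean_rmsf(self):
        th = FlexibilityThresholds()
        order = {"marginal": 0, "intermediate": 1, "high": 2}
        values = [classify_flexibility(x, th) for x in np.linspace(0, 1.5, 40)]
        ranks = [order[v] for v in values]
        assert ranks == sorted(ranks)

    def test_calibration_ensembles_span_the_classes(self, stiff_ensemble,
                                                    floppy_ensemble, base_groove):
        stiff = ensemble_rmsf(stiff_ensemble)
        floppy = ensemble_rmsf(floppy_ensemble)
        mid = ensemble_rmsf(build_ensemble(EnsembleSpec(
            base=base_groove, n_models=200, peptide_sigma=0.4, seed=13)))
        assert classify_flexibility(stiff.mean_rmsf) == "marginal"
        assert classify_flexibility(mid.mean_rmsf) == "intermediate"
        assert classify_flexibility(floppy.mean_rmsf) == "high"

    def test_sigma_recovery_within_tolerance(self, stiff_ensemble, floppy_ensemble):
        for ens, sigma in ((stiff_ensemble, 0.1), (floppy_ensemble, 0.9)):
            prof = ensemble_rmsf(ens)
            assert prof.mean_rmsf / SQRT3 == pytest.approx(sigma, rel=0.05)


class TestGrooveProfile:
    def test_planted_regional_jitter_stands_out(self, regional_ensemble):
        prof = groove_profile(regional_ensemble)
        assert prof.region_summaries["106-108"] > 2 * prof.mean_rmsf
        for name in ("13-18", "54-58", "86-90"):
            assert prof.region_summaries[name] < prof.region_summaries["106-108"]

    def test_identical_models_give_zero_everywhere(self, base_groove):
        ens = build_ensemble(EnsembleSpec(base=base_groove, n_models=3,
                                          sigma_default=0.0, seed=9))
        prof = groove_profile(ens)
        assert all(v == pytest.approx(0.0, abs=1e-9)
                   for v in prof.region_summaries.values())

    def test_short_heavy_chain_warns(self):
        ens = build_ensemble(EnsembleSpec(base=_small_spec(10), n_models=3, seed=10))
        with pytest.warns(UserWarning, match="ends at residue"):
            groove_profile(ens)

    def test_region_means_match_independent_averaging_oracle(self, regional_ensemble):
        prof = groove_profile(regional_ensemble)
        # oracle: recompute per-atom rmsf directly from superposed tables and
        # average Cα values per region by hand
        tables = superposed_atom_tables(regional_ensemble)
        keys = [k for k in tables[0] if k[0] == "A" and k[3] == "CA"
                and all(k in t for t in tables)]
        rmsf = {}
        for k in keys:
            pts = np.vstack([t[k] for t in tables])
            mu = pts.mean(axis=0)
            rmsf[k[1]] = np.sqrt(np.mean(np.sum((pts - mu) ** 2, axis=1)))
        for name, (lo, hi) in (("106-108", (106, 108)), ("13-18", (13, 18))):
            oracle = np.mean([v for s, v in rmsf.items() if lo <= s <= hi])
            assert prof.region_summaries[name] == pytest.approx(oracle, abs=1e-9)


class TestMimicry:
    def test_self_comparison_scores_one(self, stiff_ensemble):
        ov = mimicry_overlap(stiff_ensemble, stiff_ensemble)
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in ov.per_position.values())
        assert ov.pooled == pytest.approx(1.0, abs=1e-9)

    def test_distant_mean_structures_saturate_to_zero(self, base_groove):
        ens_a = build_ensemble(EnsembleSpec(base=base_groove, n_models=5,
                                            peptide_sigma=0.2, seed=14))
        moved = []
        for m in ens_a:
            mm = m.copy()
            for res in mm.chains["C"]:
                for atom in res.atoms:
                    atom.coords = atom.coords + np.array([0.0, 0.0, 10.0])
            moved.append(mm)
        ov = mimicry_overlap(ens_a, Ensemble(moved), d0=1.0)
        assert ov.pooled < 0.001

    def test_disjoint_fluctuation_intervals_zero_the_score(self, base_groove):
        quiet = build_ensemble(EnsembleSpec(base=base_groove, n_models=60,
                                            peptide_sigma=0.05, seed=15))
        wild = build_ensemble(EnsembleSpec(base=base_groove, n_models=60,
                                           peptide_sigma=0.9, seed=16))
        ov = mimicry_overlap(quiet, wild)
        # identical mean structures, rmsf differing by far more than 3x:
        # the interval factor alone must null every position
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in ov.per_position.values())

    def test_interval_overlap_definition(self):
        assert _interval_overlap(0.5, 0.5) == 1.0
        assert _interval_overlap(0.1, 0.9) == 0.0   # 3x apart: disjoint
        assert _interval_overlap(0.0, 0.0) == 1.0
        assert 0.0 < _interval_overlap(0.4, 0.6) < 1.0

    def test_length_mismatch_is_an_error(self, stiff_ensemble):
        spec = GrooveSpec(sequence="RRRWHRWR", groove_size=40,
                          light_chain_size=10, seed=17)
        other = build_ensemble(EnsembleSpec(base=spec, n_models=3, seed=18))
        with pytest.raises(ValueError, match="length mismatch"):
            mimicry_overlap(stiff_ensemble, other)
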