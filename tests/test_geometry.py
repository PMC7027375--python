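"""Superposition, r.m.s.d. and torsion arithmetic against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepgroove import (
    GrooveSpec,
    build_groove,
    dihedral,
    identify_peptide_chain,
    phi_psi,
    rmsd_in_frame,
    superpose_kabsch,
)
from pepgroove.models import Atom, Residue
from pepgroove.synth import build_backbone


def _random_points(seed, n=12, scale=5.0):
    return np.random.default_rng(seed).normal(size=(n, 3)) * scale


def _rotation(axis, deg):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def oracle_dihedral(p1, p2, p3, p4):
    """Independent formulation: arccos of normalised normals, signed by the
    triple product."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1 /= np.linalg.norm(n1)
    n2 /= np.linalg.norm(n2)
    cosang = np.clip(np.dot(n1, n2), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    if ang <= -180.0 + 1e-12:
        ang = 180.0
    return ang


class TestKabsch:
    def test_self_superposition_is_identity(self):
        pts = _random_points(0)
        sup = superpose_kabsch(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_recovers_a_planted_rigid_motion(self):
        ref = _random_points(1)
        rot = _rotation([0, 0, 1], 90.0)
        mobile = ref @ rot.T + np.array([5.0, 0.0, 0.0])
        sup = superpose_kabsch(mobile, ref)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.apply(mobile), ref, atol=1e-8)

    def test_reflection_never_returned(self):
        # mirrored set: best proper rotation leaves residual, det stays +1
        ref = _random_points(2)
        mirrored = ref * np.array([1.0, 1.0, -1.0])
        sup = superpose_kabsch(mirrored, ref)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
        assert sup.rmsd > 0.1

    def test_too_few_points_and_collinear_raise(self):
        pts = _random_points(3)
        with pytest.raises(ValueError, match="at least 3"):
            superpose_kabsch(pts[:2], pts[:2])
        line = np.outer(np.arange(5.0), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="collinear"):
            superpose_kabsch(line, _random_points(4, n=5))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rmsd_symmetry_and_rigid_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(8, 3)) * 4
        b = a + rng.normal(size=(8, 3))
        r_ab = superpose_kabsch(a, b).rmsd
        assert superpose_kabsch(b, a).rmsd == pytest.approx(r_ab, abs=1e-9)
        rot = _rotation(rng.normal(size=3), rng.uniform(0, 180))
        shift = rng.normal(size=3) * 10
        r_moved = superpose_kabsch(a @ rot.T + shift, b @ rot.T + shift).rmsd
        assert r_moved == pytest.approx(r_ab, abs=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_fitted_never_exceeds_in_frame(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(10, 3)) * 3
        b = a + rng.normal(size=(10, 3)) * 0.5
        assert superpose_kabsch(a, b).rmsd <= rmsd_in_frame(a, b) + 1e-12


class TestInFrameRmsd:
    def test_identical_sets_are_zero(self):
        pts = _random_points(5)
        assert rmsd_in_frame(pts, pts) == 0.0

    def test_uniform_unit_displacement_closed_form(self):
        a = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        b = a + np.array([0.0, 1.0, 0.0])
        assert rmsd_in_frame(a, b) == pytest.approx(1.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmsd_in_frame(np.zeros((3, 3)), np.zeros((4, 3)))


class TestDihedral:
    def test_planar_trans_and_cis(self):
        p1, p2, p3 = np.array([0.0, 1, 0]), np.array([0.0, 0, 0]), np.array([1.0, 0, 0])
        trans = np.array([1.0, 1.0, 0.0])  # same side as p1? check both
        assert abs(dihedral(p1, p2, p3, np.array([1.0, -1.0, 0.0]))) == pytest.approx(180.0)
        assert dihedral(p1, p2, p3, trans) == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_oracle_on_random_quadruples(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            pts = rng.normal(size=(4, 3)) * 3
            try:
                ours = dihedral(*pts)
            except ValueError:
                continue
            assert ours == pytest.approx(oracle_dihedral(*pts), abs=1e-6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_reversal_leaves_angle_unchanged(self, seed):
        pts = np.random.default_rng(seed).normal(size=(4, 3)) * 3
        try:
            fwd = dihedral(*pts)
        except ValueError:
            return
        assert dihedral(*pts[::-1]) == pytest.approx(fwd, abs=1e-9)

    def test_degenerate_inputs_raise(self):
        p = np.zeros(3)
        with pytest.raises(ValueError, match="coincident"):
            dihedral(p, p, np.array([1.0, 0, 0]), np.array([1.0, 1, 0]))
        with pytest.raises(ValueError, match="colinear"):
            dihedral(np.array([0.0, 0, 0]), np.array([1.0, 0, 0]),
                     np.array([2.0, 0, 0]), np.array([3.0, 1, 0]))


def _residues_from_backbone(phi_psi_list):
    bbs = build_backbone(phi_psi_list, [False] * len(phi_psi_list))
    out = []
    for i, bb in enumerate(bbs):
        r = Residue("C", i + 1, "GLY")
        for j, (nm, el, pos) in enumerate(
            (("N", "N", bb.n), ("CA", "C", bb.ca), ("C", "C", bb.c), ("O", "O", bb.o))
        ):
            r.atoms.append(Atom(i * 4 + j + 1, nm, el, pos))
        out.append(r)
    return out


class TestPhiPsi:
    def test_ideal_helix_angles_recovered(self):
        residues = _residues_from_backbone([(-60.0, -45.0)] * 6)
        ts = phi_psi(residues)
        for seq in range(2, 6):
            assert ts.phi[seq] == pytest.approx(-60.0, abs=0.5)
        for seq in range(1, 6):
            assert ts.psi[seq] == pytest.approx(-45.0, abs=0.5)

    def test_termini_are_undefined(self):
        residues = _residues_from_backbone([(-120.0, 130.0)] * 2)
        ts = phi_psi(residues)
        assert ts.phi[1] is None and ts.phi[2] is not None
        assert ts.psi[1] is not None and ts.psi[2] is None

    def test_chain_break_yields_undefined_not_error(self):
        residues = _residues_from_backbone([(-120.0, 130.0)] * 4)
        for atom in residues[2].atoms:  # move residue 3 far away
            atom.coords = atom.coords + np.array([50.0, 0.0, 0.0])
        ts = phi_psi(residues)
        assert ts.phi[3] is None and ts.psi[2] is None
        assert ts.phi[2] is not None

    def test_missing_backbone_atom_warns_and_undefines(self):
        residues = _residues_from_backbone([(-120.0, 130.0)] * 3)
        residues[1].atoms = [a for a in residues[1].atoms if a.name != "CA"]
        with pytest.warns(UserWarning, match="missing backbone"):
            ts = phi_psi(residues)
        assert ts.phi[2] is None and ts.psi[2] is None

    def test_peptide_torsions_per_conformer_in_groove(self, pgr_model):
        pep = identify_peptide_chain(pgr_model)
        residues = pgr_model.polymer_chains()[pep]
        for lab in ("A", "B"):
            ts = phi_psi(residues, lab)
            phi6, psi6 = ts.at_position(6)
            assert phi6 is not None and psi6 is not None
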