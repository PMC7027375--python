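"""Contact typing, precedence, water bridges, and the brute-force oracle."""

import itertools

import numpy as np
import pytest

from pepgroove import (
    ContactCriteria,
    GrooveSpec,
    Selection,
    contact_table,
    hydrogen_bonds,
    identify_peptide_chain,
    salt_bridges,
    vdw_contacts,
    water_bridges,
    build_groove,
)
from pepgroove.contacts import classify_pair, _candidate_pairs
from pepgroove.models import Atom, Residue, StructureModel
from pepgroove.synth import PlantedContact


def _mini_model(*residue_specs, waters=()):
    """Model from (chain, seq, res_name, [(atom, element, xyz), ...]) tuples."""
    chains = {}
    serial = 0
    for chain_id, seq, name, atoms in residue_specs:
        res = Residue(chain_id, seq, name)
        for an, el, xyz in atoms:
            serial += 1
            res.atoms.append(Atom(serial, an, el, np.asarray(xyz, float)))
        chains.setdefault(chain_id, []).append(res)
    for i, xyz in enumerate(waters):
        serial += 1
        res = Residue("W", i + 1, "HOH")
        res.atoms.append(Atom(serial, "O", "O", np.asarray(xyz, float)))
        chains.setdefault("W", []).append(res)
    return StructureModel(chains=chains)


SEL_A = Selection(chain_id="A")
SEL_B = Selection(chain_id="B")


class TestTyping:
    def test_donor_acceptor_within_cutoff_is_reported(self):
        model = _mini_model(
            ("A", 1, "ARG", [("N", "N", (0, 0, 0))]),
            ("B", 99, "TYR", [("OH", "O", (3.1, 0, 0))]),
        )
        (rec,) = hydrogen_bonds(model, SEL_A, SEL_B)
        assert rec.kind == "HB"
        assert rec.distance == pytest.approx(3.1)

    def test_pair_beyond_cutoff_is_silent(self):
        model = _mini_model(
            ("A", 1, "ARG", [("N", "N", (0, 0, 0))]),
            ("B", 99, "TYR", [("OH", "O", (4.5, 0, 0))]),
        )
        assert hydrogen_bonds(model, SEL_A, SEL_B) == []

    def test_lys_asp_pair_is_salt_bridge_not_hydrogen_bond(self):
        model = _mini_model(
            ("A", 1, "LYS", [("NZ", "N", (0, 0, 0))]),
            ("B", 2, "ASP", [("OD1", "O", (3.2, 0, 0))]),
        )
        assert hydrogen_bonds(model, SEL_A, SEL_B) == []
        (rec,) = salt_bridges(model, SEL_A, SEL_B)
        assert rec.kind == "SB" and rec.distance == pytest.approx(3.2)

    def test_arg_ser_pair_is_hydrogen_bond_not_salt_bridge(self):
        model = _mini_model(
            ("A", 1, "ARG", [("NH1", "N", (0, 0, 0))]),
            ("B", 2, "SER", [("OG", "O", (3.0, 0, 0))]),
        )
        assert salt_bridges(model, SEL_A, SEL_B) == []
        (rec,) = hydrogen_bonds(model, SEL_A, SEL_B)
        assert rec.kind == "HB"

    def test_his_carboxylate_is_flagged_salt_bridge(self):
        model = _mini_model(
            ("A", 1, "HIS", [("NE2", "N", (0, 0, 0))]),
            ("B", 2, "GLU", [("OE2", "O", (3.4, 0, 0))]),
        )
        (rec,) = salt_bridges(model, SEL_A, SEL_B)
        assert "His" in rec.note

    def test_carbon_pair_in_window_is_vdw_and_far_pair_is_nothing(self):
        model = _mini_model(
            ("A", 1, "TRP", [("CB", "C", (0, 0, 0))]),
            ("B", 2, "VAL", [("CG1", "C", (3.8, 0, 0)), ("CG2", "C", (5.0, 5.0, 0))]),
        )
        recs = vdw_contacts(model, SEL_A, SEL_B)
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(3.8)

    def test_altloc_inconsistent_pairs_are_skipped(self):
        model = _mini_model(
            ("A", 1, "ARG", [("N", "N", (0, 0, 0))]),
        )
        res_b = Residue("B", 2, "TYR")
        res_b.atoms.append(Atom(10, "OH", "O", np.array([3.1, 0.0, 0.0]), "B", 0.5))
        model.chains["B"] = [res_b]
        model.chains["A"][0].atoms[0].altloc = "A"
        model.chains["A"][0].atoms[0].occupancy = 0.5
        assert hydrogen_bonds(model, SEL_A, SEL_B) == []


class TestPrecedencePartition:
    def test_no_pair_is_reported_under_two_kinds(self, pgr_model):
        pep = identify_peptide_chain(pgr_model)
        sel_pep, sel_all = Selection(chain_id=pep), Selection()
        crit = ContactCriteria()
        seen = {}
        for kind, recs in (
            ("SB", salt_bridges(pgr_model, sel_pep, sel_all, crit)),
            ("HB", hydrogen_bonds(pgr_model, sel_pep, sel_all, crit)),
            ("vdW", vdw_contacts(pgr_model, sel_pep, sel_all, crit, per_atom=True)),
        ):
            for rec in recs:
                key = tuple(sorted((str(rec.atom1), str(rec.atom2))))
                assert key not in seen, f"{key} typed {seen.get(key)} and {kind}"
                seen[key] = kind
        assert seen  # the fixture plants contacts of every kind

    def test_enlarging_hb_cutoff_never_removes_a_bond(self, pgr_model):
        pep = identify_peptide_chain(pgr_model)
        sel_pep, sel_all = Selection(chain_id=pep), Selection()
        small = hydrogen_bonds(pgr_model, sel_pep, sel_all, ContactCriteria(hb_max=3.0))
        large = hydrogen_bonds(pgr_model, sel_pep, sel_all, ContactCriteria(hb_max=3.5))
        small_keys = {(str(r.atom1), str(r.atom2)) for r in small}
        large_keys = {(str(r.atom1), str(r.atom2)) for r in large}
        assert small_keys <= large_keys


class TestWaterBridges:
    def test_bridge_within_both_legs_is_reported(self):
        model = _mini_model(
            ("A", 1, "SER", [("OG", "O", (0, 0, 0))]),
            ("B", 2, "ASP", [("OD1", "O", (6.0, 0, 0))]),
            waters=[(3.0, 0.0, 0.0)],
        )
        (rec,) = water_bridges(model, SEL_A, SEL_B)
        assert rec.kind == "water_bridge"
        assert rec.via_water is not None

    def test_one_long_leg_kills_the_bridge(self):
        model = _mini_model(
            ("A", 1, "SER", [("OG", "O", (0, 0, 0))]),
            ("B", 2, "ASP", [("OD1", "O", (8.0, 0, 0))]),
            waters=[(3.0, 0.0, 0.0)],  # 5.0 Å from the Asp oxygen
        )
        assert water_bridges(model, SEL_A, SEL_B) == []

    def test_model_without_waters_warns_and_returns_empty(self):
        model = _mini_model(
            ("A", 1, "SER", [("OG", "O", (0, 0, 0))]),
            ("B", 2, "ASP", [("OD1", "O", (6.0, 0, 0))]),
        )
        with pytest.warns(UserWarning, match="no waters"):
            assert water_bridges(model, SEL_A, SEL_B) == []

    def test_planted_bridge_recovered_in_groove(self, pgr_model):
        df = contact_table(pgr_model)
        bridges = df[df.kind == "water_bridge"]
        assert len(bridges) >= 1
        row = bridges.iloc[0]
        assert row.peptide_pos == "p5" and row.contact_residue == "ASP77"


class TestContactTable:
    def test_planted_contacts_appear_with_type_and_distance(self, pgr_model):
        df = contact_table(pgr_model)
        def row(pos, cres, catom, alt=""):
            hit = df[(df.peptide_pos == pos) & (df.contact_residue == cres)
                     & (df.contact_atom == catom)]
            if alt:
                hit = hit[hit.altloc_p.isin(["", alt])]
            assert len(hit) >= 1, f"missing {pos}-{cres}.{catom}"
            return hit.iloc[0]

        hb = row("p3", "TYR99", "OH")
        assert hb.kind == "HB" and hb.distance == pytest.approx(3.1, abs=0.05)
        hb2 = row("p8", "TRP147", "NE1", alt="A")
        assert hb2.kind == "HB" and hb2.distance == pytest.approx(2.9, abs=0.05)
        sb = row("p8", "GLU76", "OE2", alt="A")
        assert sb.kind == "SB" and sb.distance == pytest.approx(3.0, abs=0.05)
        vdw = row("p7", "VAL152", "CG1")
        assert vdw.kind == "vdW"
        assert 3.6 <= vdw.distance <= 4.0

    def test_far_wall_glycine_groove_has_empty_table(self):
        spec = GrooveSpec(sequence="GGGGGGGGG", wall_offset=25.0,
                          groove_size=40, light_chain_size=10, seed=9)
        df = contact_table(build_groove(spec))
        assert len(df) == 0

    def test_ordering_is_deterministic(self, pgr_model):
        a = contact_table(pgr_model)
        b = contact_table(pgr_model)
        assert a.equals(b)


class TestBruteForceOracle:
    def test_all_reported_pairs_match_exhaustive_enumeration(self, pgr_model):
        """Independent O(n²) oracle over a ≤500-atom subset: every qualifying
        pair is found, with exactly the same distance, and none is missed."""
        pep = identify_peptide_chain(pgr_model)
        sel_pep = Selection(chain_id=pep)
        sel_env = Selection(chain_id="A", residues=[(60, 160)])
        crit = ContactCriteria()

        from pepgroove.io import resolve_selection_pairs
        pairs_p = resolve_selection_pairs(pgr_model, sel_pep)
        pairs_e = resolve_selection_pairs(pgr_model, sel_env)
        assert len(pairs_p) + len(pairs_e) <= 500 + 200  # small instance

        oracle = {}
        for (r1, a1), (r2, a2) in itertools.product(pairs_p, pairs_e):
            if a1 is a2:
                continue
            if not (a1.altloc == "" or a2.altloc == "" or a1.altloc == a2.altloc):
                continue
            if r1.key() == r2.key():
                continue
            d = float(np.sqrt(np.sum((a1.coords - a2.coords) ** 2)))
            kind, _ = classify_pair(r1, a1, r2, a2, d, crit)
            if kind is not None:
                oracle[(str(r1.seq_number), a1.name, a1.altloc,
                        str(r2.seq_number), a2.name, a2.altloc)] = (kind, d)

        ours = {}
        for kind in ("SB", "HB"):
            recs = (salt_bridges if kind == "SB" else hydrogen_bonds)(
                pgr_model, sel_pep, sel_env, crit)
            for rec in recs:
                ours[(str(rec.atom1.seq_number), rec.atom1.atom_name, rec.atom1.altloc,
                      str(rec.atom2.seq_number), rec.atom2.atom_name, rec.atom2.altloc)] = (
                    rec.kind, rec.distance)
        for rec in vdw_contacts(pgr_model, sel_pep, sel_env, crit, per_atom=True):
            ours[(str(rec.atom1.seq_number), rec.atom1.atom_name, rec.atom1.altloc,
                  str(rec.atom2.seq_number), rec.atom2.atom_name, rec.atom2.altloc)] = (
                rec.kind, rec.distance)

        assert set(ours) == set(oracle)
        for key in oracle:
            assert ours[key][0] == oracle[key][0]
            assert ours[key][1] == pytest.approx(oracle[key][1], abs=1e-12)
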