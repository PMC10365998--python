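"""The two-distance-criterion screen, stacking geometry, and tier triage."""

import math

import numpy as np
import pytest

from allosite import synthetic
from allosite.model import Atom, LigandInstance, Residue, StructureModel
from allosite.screen import (
    AromaticContact,
    CriterionInapplicableError,
    ScreenCriteria,
    assess_stacking,
    classify_site,
    find_arginine_gamma_contacts,
    find_aromatic_contacts,
    screen_library,
    screen_model,
)
from conftest import brute_force_arg_contacts, brute_force_contacts, random_rotation


def _bare_model_with_ligand(code="ANP", with_pg=True):
    """Minimal hand-built model: a ligand at the origin region."""
    model = StructureModel("HAND")
    res = Residue(code, 900, "A", category="ligand")
    ade = synthetic.adenine_coords()
    for name in ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"):
        res.atoms.append(Atom(name, "C" if name.startswith("C") else "N", ade[name]))
    if with_pg:
        res.atoms.append(Atom("PG", "P", [8.0, 0.0, 0.0]))
    model.add_residue(res)
    ring = [a for a in res.atoms if a.name != "PG"]
    lig = LigandInstance(res, code, ring, res.atom("C5"),
                         res.atom("PG") if code not in ("ADP", "AMP") else None)
    return model, lig


def _add_aromatic(model, comp, chain, seq, cg_pos):
    res = Residue(comp, seq, chain)
    res.atoms.append(Atom("CG", "C", cg_pos))
    model.add_residue(res)
    return res


def _add_arg(model, chain, seq, cz_pos):
    res = Residue("ARG", seq, chain)
    res.atoms.append(Atom("CZ", "C", cz_pos))
    model.add_residue(res)
    return res


class TestAromaticContacts:
    def test_two_contacts_sorted_by_distance(self):
        model, lig = _bare_model_with_ligand()
        c5 = lig.c5.position
        _add_aromatic(model, "HIS", "A", 10, c5 + [4.5, 0, 0])
        _add_aromatic(model, "TYR", "B", 20, c5 + [0, 4.0, 0])
        contacts = find_aromatic_contacts(model, lig)
        assert [(c.residue.comp_id, round(c.distance_c5_cg, 6)) for c in contacts] == [
            ("TYR", 4.0), ("HIS", 4.5),
        ]

    def test_cutoff_boundary_inclusive(self):
        """A CG at exactly 5.0 Å is inside the <= cutoff."""
        model, lig = _bare_model_with_ligand()
        _add_aromatic(model, "PHE", "A", 10, lig.c5.position + [5.0, 0, 0])
        assert len(find_aromatic_contacts(model, lig)) == 1

    def test_beyond_cutoff_empty(self):
        model, lig = _bare_model_with_ligand()
        _add_aromatic(model, "PHE", "A", 10, lig.c5.position + [5.2, 0, 0])
        assert find_aromatic_contacts(model, lig) == []

    def test_non_aromatic_and_missing_cg_skipped(self, caplog):
        model, lig = _bare_model_with_ligand()
        res = Residue("TYR", 11, "A")
        res.atoms.append(Atom("CB", "C", lig.c5.position + [1.0, 0, 0]))
        model.add_residue(res)  # aromatic but no CG
        _add_arg(model, "A", 12, lig.c5.position + [1.0, 0, 0])  # not aromatic
        with caplog.at_level("WARNING"):
            assert find_aromatic_contacts(model, lig) == []
        assert "lacks atom CG" in caplog.text

    def test_ligand_without_c5_raises(self):
        model, lig = _bare_model_with_ligand()
        lig.c5 = None
        with pytest.raises(CriterionInapplicableError):
            find_aromatic_contacts(model, lig)

    def test_matches_brute_force_oracle_random_sites(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            model, lig = _bare_model_with_ligand()
            c5 = lig.c5.position
            for k in range(rng.integers(1, 6)):
                comp = ["TYR", "TRP", "PHE", "HIS", "ARG", "GLY"][rng.integers(6)]
                pos = c5 + rng.uniform(-7, 7, 3)
                res = Residue(comp, 10 + k, "AB"[rng.integers(2)])
                res.atoms.append(Atom("CG", "C", pos))
                model.add_residue(res)
            got = [(c.chain_id, c.residue.seq_num, round(c.distance_c5_cg, 9))
                   for c in find_aromatic_contacts(model, lig)]
            assert got == brute_force_contacts(model, lig)


class TestArginineContacts:
    def test_single_contact(self):
        model, lig = _bare_model_with_ligand()
        _add_arg(model, "B", 30, lig.pg.position + [3.8, 0, 0])
        (hit,) = find_arginine_gamma_contacts(model, lig)
        assert hit[0].seq_num == 30 and hit[1] == pytest.approx(3.8)

    def test_adp_always_empty(self):
        model, lig = _bare_model_with_ligand(code="ADP", with_pg=False)
        _add_arg(model, "A", 30, lig.c5.position + [1.0, 0, 0])
        assert find_arginine_gamma_contacts(model, lig) == []

    def test_two_contacts_sorted_ascending(self):
        model, lig = _bare_model_with_ligand()
        pg = lig.pg.position
        _add_arg(model, "A", 30, pg + [4.9, 0, 0])
        _add_arg(model, "B", 31, pg + [0, 4.0, 0])
        hits = find_arginine_gamma_contacts(model, lig)
        assert [round(d, 6) for _, d in hits] == [4.0, 4.9]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            model, lig = _bare_model_with_ligand()
            for k in range(rng.integers(1, 5)):
                _add_arg(model, "AB"[rng.integers(2)], 30 + k,
                         lig.pg.position + rng.uniform(-7, 7, 3))
            got = [(r.chain_id, r.seq_num, round(d, 9))
                   for r, d in find_arginine_gamma_contacts(model, lig)]
            assert got == brute_force_arg_contacts(model, lig)


def _ring_residue(comp, chain, seq, rotation, translation):
    """Aromatic residue whose ring is a rigid transform of its flat template."""
    names, local = synthetic._ring_template(comp)
    res = Residue(comp, seq, chain)
    for name, v in zip(names, local):
        res.atoms.append(Atom(name, "C", rotation @ v + translation))
    return res


class TestStacking:
    def _ligand(self):
        return _bare_model_with_ligand()[1]

    def test_parallel_rings_stacked(self):
        lig = self._ligand()
        pcen = lig.purine_coords().mean(axis=0)
        res = _ring_residue("TYR", "A", 10, np.eye(3), pcen + [0, 0, 3.6])
        contact = AromaticContact(res, "A", 4.0)
        out = assess_stacking(lig, contact)
        assert out.stacked
        assert out.stacking_angle == pytest.approx(0.0, abs=1e-6)
        assert out.centroid_distance == pytest.approx(3.6, abs=1e-6)

    def test_perpendicular_rings_not_stacked(self):
        lig = self._ligand()
        pcen = lig.purine_coords().mean(axis=0)
        Rx = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], float)
        res = _ring_residue("TYR", "A", 10, Rx, pcen + [0, 0, 3.6])
        out = assess_stacking(lig, AromaticContact(res, "A", 4.0))
        assert not out.stacked
        assert out.stacking_angle == pytest.approx(90.0, abs=1e-6)

    def test_parallel_but_distant_not_stacked(self):
        lig = self._ligand()
        pcen = lig.purine_coords().mean(axis=0)
        res = _ring_residue("TYR", "A", 10, np.eye(3), pcen + [0, 0, 6.0])
        out = assess_stacking(lig, AromaticContact(res, "A", 4.0))
        assert not out.stacked
        assert out.centroid_distance == pytest.approx(6.0, abs=1e-6)

    def test_angle_folded_into_quadrant(self):
        """A 150-degree tilt reads as 30 degrees between planes."""
        lig = self._ligand()
        pcen = lig.purine_coords().mean(axis=0)
        th = math.radians(150.0)
        Ry = np.array([[math.cos(th), 0, math.sin(th)], [0, 1, 0],
                       [-math.sin(th), 0, math.cos(th)]])
        res = _ring_residue("TYR", "A", 10, Ry, pcen + [0, 0, 3.6])
        out = assess_stacking(lig, AromaticContact(res, "A", 4.0))
        assert out.stacking_angle == pytest.approx(30.0, abs=1e-6)

    def test_missing_ring_atoms_reported(self):
        lig = self._ligand()
        res = Residue("TYR", 10, "A")
        res.atoms.append(Atom("CG", "C", [0.0, 0.0, 3.6]))
        out = assess_stacking(lig, AromaticContact(res, "A", 4.0))
        assert not out.stacked
        assert out.no_stack_reason == "missing ring atoms"


class TestClassify:
    def _contact(self, chain, seq, d, stacked):
        res = Residue("TYR", seq, chain)
        res.atoms.append(Atom("CG", "C", [0.0, 0.0, 0.0]))
        return AromaticContact(res, chain, d, stacked=stacked)

    @pytest.mark.parametrize(
        "chains,stacked,args,expected",
        [
            (("A", "A"), (True, False), [], "T1_pair_contact"),
            (("A", "A"), (True, True), ["arg"], "T1_pair_contact"),
            (("A", "B"), (False, False), ["arg"], "T2_cross_subunit"),
            (("A", "B"), (True, False), [], "T2_cross_subunit"),
            (("A", "B"), (True, True), [], "T3_dual_stacking"),
            (("A", "B"), (True, True), ["arg"], "T4_full"),
        ],
    )
    def test_tier_truth_table(self, chains, stacked, args, expected):
        _, lig = _bare_model_with_ligand()
        contacts = [self._contact(chains[0], 10, 4.0, stacked[0]),
                    self._contact(chains[1], 20, 4.5, stacked[1])]
        arg_contacts = [(Residue("ARG", 30, "B"), 3.8)] if args else []
        hit = classify_site(contacts, arg_contacts, lig)
        assert hit.tier == expected

    def test_single_contact_returns_none(self):
        _, lig = _bare_model_with_ligand()
        assert classify_site([self._contact("A", 10, 4.0, True)], [], lig) is None

    def test_arg_without_gamma_phosphate_cannot_reach_t4(self):
        _, lig = _bare_model_with_ligand(code="ADP", with_pg=False)
        contacts = [self._contact("A", 10, 4.0, True),
                    self._contact("B", 20, 4.5, True)]
        hit = classify_site(contacts, [(Residue("ARG", 30, "B"), 3.8)], lig)
        assert hit.tier == "T3_dual_stacking"

    def test_best_pair_prefers_higher_tier_over_distance(self):
        """A farther cross-chain stacked pair beats a closer same-chain pair."""
        _, lig = _bare_model_with_ligand()
        contacts = [self._contact("A", 10, 3.0, True),
                    self._contact("A", 11, 3.1, True),
                    self._contact("B", 20, 4.9, True)]
        hit = classify_site(contacts, [], lig)
        assert hit.cross_subunit
        assert {c.residue.seq_num for c in hit.aromatic_pair} == {10, 20}


class TestScreenLibrary:
    def test_planted_tier_counts(self, tmp_path):
        labels = synthetic.make_structure_library(18, str(tmp_path), seed=4)
        paths = sorted(str(tmp_path / p) for p in labels["pdb"])
        hits = screen_library(paths)
        expected = labels["tier"].value_counts().to_dict()
        got = {k: v for k, v in hits.tier_counts.items() if v}
        assert got == expected

    def test_empty_library(self):
        hits = screen_library([])
        assert len(hits.table) == 0
        assert all(v == 0 for v in hits.tier_counts.values())

    def test_unreadable_file_becomes_error_row(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("this is not a structure\n")
        labels = synthetic.make_structure_library(1, str(tmp_path), seed=1)
        hits = screen_library([str(bad), str(tmp_path / labels["pdb"][0])])
        assert len(hits.errors) == 1
        assert len(hits.table) == 1

    def test_criterion1_only_never_t4(self, tmp_path):
        synthetic.make_structure_library(12, str(tmp_path), seed=2)
        paths = sorted(str(p) for p in tmp_path.glob("*.pdb"))
        hits = screen_library(paths, mode="criterion1_only")
        assert hits.tier_counts["T4_full"] == 0

    def test_entry_tier_is_max_over_ligands(self, tmp_path):
        labels = synthetic.make_structure_library(6, str(tmp_path), seed=3)
        paths = sorted(str(tmp_path / p) for p in labels["pdb"])
        hits = screen_library(paths)
        per_entry = hits.entry_tiers()
        assert set(per_entry.index) == set(labels["entry_id"])


class TestInvariances:
    def test_rigid_transform_invariance(self, t4_geometry):
        """Tiers, distances, and stacking flags survive rotation+translation."""
        model, _ = synthetic.make_binding_site_structure(t4_geometry)
        base = screen_model(model)
        rng = np.random.default_rng(5)
        for _ in range(5):
            R = random_rotation(rng)
            t = rng.uniform(-30, 30, 3)
            rows = screen_model(model.transformed(R, t))
            for a, b in zip(base, rows):
                assert a["tier"] == b["tier"]
                assert a["n_stacked"] == b["n_stacked"]
                assert b["d1"] == pytest.approx(a["d1"], abs=1e-6)
                assert b["d2"] == pytest.approx(a["d2"], abs=1e-6)

    def test_tier_monotone_under_cutoffs(self, t4_geometry):
        """Tightening cutoffs never raises a tier; loosening never lowers it."""
        from allosite.screen import TIER_ORDER

        model, _ = synthetic.make_binding_site_structure(t4_geometry)

        def tier_at(d_arom, d_arg, cen, ang):
            rows = screen_model(model, ScreenCriteria(
                d_aromatic=d_arom, d_arg=d_arg,
                stacking_centroid_max=cen, stacking_angle_max=ang))
            t = rows[0]["tier"]
            return TIER_ORDER[None if t == "none" else t]

        base = (5.0, 5.0, 5.0, 30.0)
        loose = (6.0, 6.0, 6.0, 45.0)
        tight_sets = [(4.1, 5.0, 5.0, 30.0), (5.0, 3.0, 5.0, 30.0),
                      (5.0, 5.0, 4.0, 30.0), (5.0, 5.0, 5.0, 5.0),
                      (3.9, 3.0, 3.0, 5.0)]
        t0 = tier_at(*base)
        assert tier_at(*loose) >= t0
        for ts in tight_sets:
            assert tier_at(*ts) <= t0
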