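"""Knowledge-based pocket filter and pocket-collapse profiles."""

import numpy as np
import pytest

from dockassess.pocket_filter import (
    PocketDefinition,
    apply_pocket_filter,
    build_pocket,
    cap_by_energy,
    derive_cutoffs,
    derive_pocket_columns,
    pocket_collapse,
)
from dockassess.structio import AlignmentMap, AtomRecord, ReceptorModel
from dockassess.synthetic import FamilyConfig, gen_model_ensemble, gen_receptor_family


def _mini_model(tag, ca_list, lig=None, res_names=None, cb_list=None,
                energy=float("nan")):
    atoms = []
    for i, ca in enumerate(ca_list):
        name = (res_names or ["ALA"] * len(ca_list))[i]
        atoms.append(AtomRecord("CA", "C", name, str(i + 1), "A", ca))
        if cb_list is not None and cb_list[i] is not None:
            atoms.append(AtomRecord("CB", "C", name, str(i + 1), "A", cb_list[i]))
    het = [AtomRecord(f"C{j+1}", "C", "LIG", "1", "L", p, record="HETATM")
           for j, p in enumerate(lig)] if lig is not None else []
    return ReceptorModel(atoms, het, energy=energy, tag=tag)


class TestDerivePocketColumns:
    def test_contact_in_one_member_suffices(self):
        lig = np.array([[0.0, 0.0, 0.0]])
        m = _mini_model("s1", [np.array([3.5, 0, 0]), np.array([20.0, 0, 0])],
                        lig=lig)
        aln = AlignmentMap({"s1": "AA"})
        assert derive_pocket_columns([m], aln) == {1}

    def test_no_contact_gives_empty(self):
        lig = np.array([[0.0, 0.0, 0.0]])
        m = _mini_model("s1", [np.array([4.0, 0, 0]), np.array([9.0, 0, 0])],
                        lig=lig)   # 4.0 is not < 4.0 (strict)
        aln = AlignmentMap({"s1": "AA"})
        assert derive_pocket_columns([m], aln) == set()

    def test_member_without_ligand_rejected(self):
        m = _mini_model("s1", [np.zeros(3), np.ones(3) * 5])
        aln = AlignmentMap({"s1": "AA"})
        with pytest.raises(ValueError, match="no ligand"):
            derive_pocket_columns([m], aln)

    def test_exclusion_list_subtracted(self, family):
        full = derive_pocket_columns(family.members, family.alignment)
        excl = {min(full)}
        assert derive_pocket_columns(family.members, family.alignment,
                                     exclude=excl) == full - excl

    def test_matches_brute_force_scan(self, family):
        got = derive_pocket_columns(family.members, family.alignment)
        expected = set()
        for m in family.members:                      # exhaustive all-pairs scan
            lig = m.ligand_coords()
            for chain, rid in m.residue_ids():
                for lp in lig:
                    if np.linalg.norm(m.ca(rid, chain) - lp) < 4.0:
                        expected.add(family.alignment.column_for(m.tag, rid))
        assert got == expected


class TestDeriveCutoffs:
    def test_pairwise_distance(self):
        a = _mini_model("a", [np.zeros(3)], lig=np.zeros((1, 3)))
        b = _mini_model("b", [np.array([1.7, 0, 0])], lig=np.zeros((1, 3)))
        aln = AlignmentMap({"a": "A", "b": "A"})
        cutoffs, skipped = derive_cutoffs([a, b], aln, {1})
        assert cutoffs[1] == pytest.approx(1.7)
        assert not skipped

    def test_identical_members_zero(self):
        fam = gen_receptor_family(FamilyConfig(sigma_family=0.0, seed=3))
        cutoffs, _ = derive_cutoffs(fam.members, fam.alignment,
                                    set(fam.pocket_columns))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in cutoffs.values())

    def test_matches_brute_force_max(self, family):
        cols = set(family.pocket_columns)
        cutoffs, _ = derive_cutoffs(family.members, family.alignment, cols)
        for c in cols:
            cas = [m.ca(family.alignment.residue_at(m.tag, c))
                   for m in family.members]
            expected = max(np.linalg.norm(x - y) for x in cas for y in cas)
            assert cutoffs[c] == pytest.approx(expected)

    def test_underoccupied_column_flagged(self):
        a = _mini_model("a", [np.zeros(3)], lig=np.zeros((1, 3)))
        b = _mini_model("b", [np.zeros(3)], lig=np.zeros((1, 3)))
        aln = AlignmentMap({"a": "A-", "b": "A-"})
        _, skipped = derive_cutoffs([a, b], aln, {2})
        assert skipped == {2}


class TestApplyFilter:
    def test_copy_of_nonself_member_passes(self, family, pocket):
        twin = family.members[1]            # identical to member S1
        report = apply_pocket_filter([twin], family.members, "S0", pocket,
                                     family.alignment, model_row="S1")
        assert report["passed"].all()

    def test_displacement_beyond_every_cutoff_fails(self, family, pocket):
        ref = family.members[0]
        col = min(pocket.columns)
        res = family.alignment.residue_at("S0", col)
        worst = max(pocket.cutoffs.values())
        atoms = []
        for a in ref.atoms:
            pos = a.position + (0 if a.res_id != str(res)
                                else np.array([worst + 5.0, 0, 0]))
            atoms.append(AtomRecord(a.name, a.element, a.res_name, a.res_id,
                                    a.chain, pos))
        bad = ReceptorModel(atoms, tag="bad")
        report = apply_pocket_filter([bad], family.members, "S0", pocket,
                                     family.alignment, model_row="S0")
        assert not report["passed"].any()

    def test_missing_pocket_residue_fails_with_reason(self, family, pocket):
        ref = family.members[0]
        col = min(pocket.columns)
        res = str(family.alignment.residue_at("S0", col))
        trimmed = ReceptorModel([a for a in ref.atoms if a.res_id != res],
                                tag="trimmed")
        report = apply_pocket_filter([trimmed], family.members, "S0", pocket,
                                     family.alignment, model_row="S0")
        assert not report["passed"][0]
        assert "missing" in report["reason"][0]

    def test_matches_brute_force_oracle(self, family, pocket):
        models, _ = gen_model_ensemble(family, "S0", n_good=40, sigma_good=0.5,
                                       n_bad=60, sigma_bad=4.0, seed=9)
        report = apply_pocket_filter(models, family.members, "S0", pocket,
                                     family.alignment)
        aln = family.alignment
        others = [m for m in family.members if m.tag != "S0"]
        for model, got in zip(models, report["passed"]):
            expect = True
            for col in pocket.columns:          # independent nested-loop check
                res = aln.residue_at("S0", col)
                ca = model.ca(res)
                ok = False
                for o in others:
                    r2 = aln.residue_at(o.tag, col)
                    if r2 is not None and np.linalg.norm(o.ca(r2) - ca) <= pocket.cutoffs[col]:
                        ok = True
                if not ok:
                    expect = False
            assert got == expect

    def test_self_exclusion_invariant(self, family, pocket):
        # adding the self structure to the family changes no verdict as
        # long as self_id is honored
        models, _ = gen_model_ensemble(family, "S0", n_good=20, sigma_good=0.5,
                                       n_bad=30, sigma_bad=4.0, seed=21)
        without_self = [m for m in family.members if m.tag != "S0"]
        r1 = apply_pocket_filter(models, family.members, "S0", pocket,
                                 family.alignment)
        r2 = apply_pocket_filter(models, without_self, "S0", pocket,
                                 family.alignment, model_row="S0")
        assert (r1["passed"] == r2["passed"]).all()

    def test_anti_monotone_in_distortion(self, family, pocket):
        rates = []
        for sigma in (0.25, 1.0, 2.5, 5.0):
            models, _ = gen_model_ensemble(family, "S0", n_good=60,
                                           sigma_good=sigma, n_bad=1,
                                           sigma_bad=sigma + 10, seed=31)
            rep = apply_pocket_filter(models[:60], family.members, "S0",
                                      pocket, family.alignment)
            rates.append(rep["passed"].mean())
        assert all(a >= b for a, b in zip(rates, rates[1:]))


class TestCapByEnergy:
    def _models(self, energies, tags=None):
        return [
            ReceptorModel([AtomRecord("CA", "C", "ALA", "1", "A", np.zeros(3))],
                          energy=e, tag=t)
            for e, t in zip(energies, tags or [f"m{i}" for i in range(len(energies))])
        ]

    def test_under_cap_keeps_all(self):
        assert len(cap_by_energy(self._models(range(50)), cap=100)) == 50

    def test_lowest_energies_kept(self, rng):
        e = rng.permutation(200).astype(float)
        kept = cap_by_energy(self._models(e), cap=100)
        assert sorted(m.energy for m in kept) == sorted(e)[:100]

    def test_boundary_ties_are_id_ordered(self):
        models = self._models([1.0, 2.0, 2.0, 2.0, 3.0],
                              tags=["e", "d", "c", "b", "a"])
        kept = cap_by_energy(models, cap=3)
        oracle = sorted(models, key=lambda m: (m.energy, m.tag))[:3]
        assert [m.tag for m in kept] == [m.tag for m in oracle] == ["e", "b", "c"]


class TestPocketCollapse:
    def _pair(self, cb_shift=None):
        # ligand atom at origin plus a far second atom; residue 1 has
        # CB at (3, 0, 0) so the origin atom is closest by construction
        lig = np.array([[0.0, 0.0, 0.0], [12.0, 0.0, 0.0]])
        ca = [np.array([4.0, 0, 0]), np.array([0.0, 8.0, 0])]
        cb = [np.array([3.0, 0, 0]), None]
        ref = _mini_model("ref", ca, lig=lig, cb_list=cb,
                          res_names=["ALA", "GLY"])
        cb2 = [cb[0] + cb_shift if cb_shift is not None else cb[0], None]
        mod = _mini_model("mod", ca, lig=lig, cb_list=cb2,
                          res_names=["ALA", "GLY"])
        aln = AlignmentMap({"ref": "AG", "mod": "AG"})
        pocket = PocketDefinition(columns=frozenset({1, 2}),
                                  cutoffs={1: 1.0, 2: 1.0})
        return ref, mod, pocket, aln

    def test_self_profile_is_zero(self, family, pocket):
        ref = family.members[0]
        profile = pocket_collapse(ref, ref, pocket, family.alignment,
                                  model_row="S0", reference_row="S0")
        assert profile.values
        assert all(v == pytest.approx(0.0, abs=1e-12)
                   for v in profile.values.values())

    def test_outward_shift_gives_minus_one(self):
        ref, mod, pocket, aln = self._pair(cb_shift=np.array([1.0, 0, 0]))
        profile = pocket_collapse(mod, ref, pocket, aln)
        assert profile.values[1] == pytest.approx(-1.0, abs=1e-9)

    def test_inward_shift_gives_plus_one(self):
        ref, mod, pocket, aln = self._pair(cb_shift=np.array([-1.0, 0, 0]))
        profile = pocket_collapse(mod, ref, pocket, aln)
        assert profile.values[1] == pytest.approx(1.0, abs=1e-9)

    def test_closest_atom_switch_matches_brute_force(self, rng):
        ref, _, pocket, aln = self._pair()
        lig = ref.ligand_coords()
        for _ in range(20):
            shift = rng.normal(0, 6, 3)
            mod = _mini_model("mod", [ref.ca(1), ref.ca(2)], lig=lig,
                              cb_list=[ref.cb(1) + shift, None],
                              res_names=["ALA", "GLY"])
            profile = pocket_collapse(mod, ref, pocket, aln)
            d_ref = min(np.linalg.norm(lig - ref.cb(1), axis=1))
            d_mod = min(np.linalg.norm(lig - mod.cb(1), axis=1))
            assert profile.values[1] == pytest.approx(d_ref - d_mod, abs=1e-12)

    def test_glycine_uses_ca(self):
        ref, mod, pocket, aln = self._pair()
        profile = pocket_collapse(mod, ref, pocket, aln)
        assert profile.values[2] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_noise_spread_grows_with_sigma(self, family, pocket):
        # spread of the collapse distribution is monotone in the noise,
        # and the mean vanishes in the small-noise limit (at larger noise
        # the min-distance functional biases the mean negative: isotropic
        # displacement moves a residue away from its nearest ligand atom
        # on average)
        rng = np.random.default_rng(17)
        ref = family.members[0]
        stats = []
        for sigma in (0.2, 1.0, 3.0):
            vals = []
            for _ in range(30):
                atoms = [AtomRecord(a.name, a.element, a.res_name, a.res_id,
                                    a.chain, a.position + rng.normal(0, sigma, 3))
                         for a in ref.atoms]
                mod = ReceptorModel(atoms, tag="S0")
                prof = pocket_collapse(mod, ref, pocket, family.alignment,
                                       model_row="S0", reference_row="S0")
                vals.extend(prof.values.values())
            vals = np.array(vals)
            stats.append((vals.mean(), vals.std()))
        assert abs(stats[0][0]) < 0.1          # small-noise mean near zero
        assert stats[0][1] < stats[1][1] < stats[2][1]


class TestBuildPocket:
    def test_excludes_overlap_rejected(self):
        with pytest.raises(ValueError):
            PocketDefinition(columns=frozenset({1}), cutoffs={1: 1.0},
                             excluded_columns=frozenset({1}))

    def test_roundtrip_on_family(self, family):
        p = build_pocket(family.members, family.alignment)
        assert p.columns == frozenset(family.pocket_columns)
        assert set(p.cutoffs) == set(p.columns)
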