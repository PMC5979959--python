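"""Crosslink constraints on structural models: distances, ranking, export."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xlassist import datasets, structmap, synth
from xlassist.structmap import (
    ConstraintPolicy,
    CrosslinkConstraint,
    DomainMap,
    ca_distance,
    classify_topology,
    evaluate_constraint,
    evaluate_model,
    export_restraints_air,
    export_restraints_tsv,
    load_structure,
    rank_models,
    rank_models_from_distances,
    read_constraints_tsv,
    structure_to_pdb,
)

PDB_3RES = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  LYS A   2       3.000   4.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   3       6.000   8.000   1.000  1.00  0.00           C
TER
END
"""


def _random_rotation(rng):
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


class TestLoad:
    def test_handcrafted_three_residues(self):
        m = load_structure(PDB_3RES)
        assert m.n_residues == 3
        assert np.allclose(m.ca("A", 2), [3.0, 4.0, 0.0])

    def test_two_chains_addressable(self):
        text = PDB_3RES.replace("END", "") + PDB_3RES.replace(" A ", " B ")
        m = load_structure(text)
        assert set(m.chain_ids) == {"A", "B"}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            load_structure("")

    def test_pdb_round_trip(self):
        m = synth.make_structure(12, "helix", 0)
        back = load_structure(structure_to_pdb(m))
        assert np.allclose(back.coords(), m.coords(), atol=1e-3)


class TestDistance:
    def test_3_4_5_triangle(self):
        m = load_structure(PDB_3RES)
        assert ca_distance(m, 1, 2) == pytest.approx(5.0)

    def test_symmetry(self):
        m = load_structure(PDB_3RES)
        assert ca_distance(m, 1, 3) == ca_distance(m, 3, 1)

    def test_missing_residue_reported(self):
        m = load_structure(PDB_3RES)
        with pytest.raises(KeyError, match="9"):
            ca_distance(m, 1, 9)

    @given(st.integers(0, 10_000))
    def test_metric_against_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-50, 50, size=(8, 3))
        m = synth.make_structure(8, "helix", 0).with_coords(coords)
        for i in range(1, 9):
            for j in range(1, 9):
                expected = float(np.sqrt(np.sum((coords[i - 1] - coords[j - 1]) ** 2)))
                assert ca_distance(m, i, j) == pytest.approx(expected, abs=1e-9)
                assert ca_distance(m, i, j) >= 0


class TestClassification:
    @pytest.mark.parametrize(
        "d,expected", [(22.4, "satisfied"), (30.0, "satisfied"), (36.2, "ambiguous"),
                       (40.0, "ambiguous"), (40.01, "violated"), (66.6, "violated")]
    )
    def test_thresholds(self, d, expected):
        assert ConstraintPolicy().classify(d) == expected

    def test_policy_invariant(self):
        with pytest.raises(ValueError):
            ConstraintPolicy(40.0, 30.0)

    @given(st.floats(5, 60), st.floats(1, 29), st.floats(41, 80))
    def test_monotonicity(self, d, sat, viol):
        """Loosening satisfied threshold never loses satisfied; tightening the
        violation threshold never loses violations."""
        base = ConstraintPolicy(sat, viol)
        looser = ConstraintPolicy(min(sat + 5, viol - 0.5), viol)
        tighter_viol = ConstraintPolicy(min(sat, viol - 1.5), viol - 1)
        def count(policy, klass):
            return policy.classify(d) == klass
        assert count(looser, "satisfied") >= count(base, "satisfied")
        assert count(tighter_viol, "violated") >= count(base, "violated")


class TestEvaluate:
    def test_same_residue_needs_two_chains(self):
        mono = synth.make_structure(30, "hairpin", 1)
        c = CrosslinkConstraint(13, 13)
        ev = evaluate_constraint(mono, c)
        assert ev.klass == "unevaluable"
        assert ev.realization == "inter-only, unevaluable"
        dimer = synth.make_oligomer(mono, 2, radius=16.0)
        ev2 = evaluate_constraint(dimer, c)
        assert ev2.distance is not None and ev2.realization.startswith("inter-chain")

    def test_min_over_chain_assignments(self):
        mono = synth.make_structure(30, "hairpin", 1)
        dimer = synth.make_oligomer(mono, 2, radius=16.0)
        for a, b in [(3, 8), (3, 28), (8, 18), (13, 23)]:
            c = CrosslinkConstraint(a, b)
            d_dimer = evaluate_constraint(dimer, c).distance
            d_mono = ca_distance(dimer, a, b, "A", "A")
            assert d_dimer <= d_mono + 1e-9


class TestRanking:
    @staticmethod
    def _table1_frame():
        df = datasets.monomer_interdomain_distances()
        df["constraint"] = "K" + df.lys_a.astype(str) + "xK" + df.lys_b.astype(str)
        return df[["constraint", "model_1", "model_2", "model_3", "model_4", "model_5"]]

    def test_published_matrix_selects_model_5(self):
        selected, ranking = rank_models_from_distances(self._table1_frame())
        assert selected.model_id == "model_5"
        assert selected.n_satisfied == 2
        assert selected.n_violated == 0
        # every other model has at least one violating crosslink
        assert all(r.n_violated > 0 for r in ranking[1:])

    def test_single_model_selected(self):
        m = synth.make_structure(40, "coil", 3)
        lys = synth.lysine_positions(m)
        cons, _ = synth.sample_crosslinks(m, lys, dmax=25.0, count=5, seed=3)
        sel, ranking = rank_models([m], cons)
        assert sel.model_id == m.model_id and len(ranking) == 1
        assert sel.n_satisfied == len(cons)

    def test_no_constraints_warns(self):
        m = synth.make_structure(10, "helix", 0)
        with pytest.warns(UserWarning):
            rank_models([m], [])

    def test_rigid_motion_invariance(self, rng):
        models = synth.make_decoys(synth.make_structure(40, "coil", 5), [15.0, 20.0], seed=6)
        lys = synth.lysine_positions(models[0])
        cons, _ = synth.sample_crosslinks(models[0], lys, dmax=25.0, count=8, seed=5)
        sel, ranking = rank_models(models, cons)
        R = _random_rotation(rng)
        t = rng.uniform(-100, 100, 3)
        moved = [m.transformed(R, t) for m in models]
        sel2, ranking2 = rank_models(moved, cons)
        assert sel2.model_id == sel.model_id
        for r1, r2 in zip(ranking, ranking2):
            assert r1.model_id == r2.model_id
            for e1, e2 in zip(r1.evaluations, r2.evaluations):
                assert e2.distance == pytest.approx(e1.distance, abs=1e-6)

    def test_selection_recovery_over_seeded_replicates(self):
        """True structure beats >=15 A RMSD decoys in >=95/100 replicates."""
        wins = 0
        for seed in range(100):
            model = synth.make_structure(80, "coil", seed)
            lys = synth.lysine_positions(model)
            cons, _ = synth.sample_crosslinks(model, lys, dmax=25.0, count=8, seed=seed)
            ensemble = synth.make_decoys(model, [15.0, 18.0, 22.0, 26.0], seed=seed + 1000)
            sel, _ = rank_models(ensemble, cons)
            wins += sel.model_id.endswith("-true")
        assert wins >= 95


class TestTopology:
    def test_same_residue_is_inter_only(self):
        dom, sub = classify_topology(CrosslinkConstraint(189, 189))
        assert sub == "inter-only"

    def test_intra_ntd(self):
        dom, sub = classify_topology(CrosslinkConstraint(20, 25))
        assert dom == "intra-domain (NTD)" and sub == "intra-possible"

    def test_inter_domain_ctd_ntd(self):
        dom, _ = classify_topology(CrosslinkConstraint(225, 60))
        assert dom == "inter-domain (CTD-NTD)"

    def test_unassigned_position(self):
        small = DomainMap({"NTD": (1, 10)})
        dom, _ = classify_topology(CrosslinkConstraint(3, 50), small)
        assert dom == "linker/unassigned"

    def test_domain_overlap_rejected(self):
        with pytest.raises(ValueError):
            DomainMap({"a": (1, 10), "b": (5, 20)})


class TestRestraints:
    CONS = [CrosslinkConstraint(189, 189), CrosslinkConstraint(232, 232)]

    def test_tsv_round_trip(self):
        text = export_restraints_tsv(self.CONS)
        back = read_constraints_tsv(text)
        assert [(c.pos_a, c.pos_b) for c in back] == [(189, 189), (232, 232)]
        assert "30" in text

    def test_air_block(self):
        air = export_restraints_air(self.CONS)
        assert air.count("assign") == 2
        assert "resid 189 and name CA" in air
        assert "30.0 30.0 0.0" in air

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            export_restraints_tsv([])
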