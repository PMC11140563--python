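"""SCM and SAP scoring: brute-force oracles, score algebra, ensembles."""
import math

import numpy as np
import pytest

import abspatial as ab
from abspatial.sap import HydrophobicityScale, ReferenceSasa
from conftest import random_cluster


def brute_force_scm(snapshot, exposed, radius=10.0):
    """O(n^2) direct summation of Eq.-style atomic SCM (self excluded)."""
    atoms = snapshot.atoms
    keys = snapshot.residue_keys()
    res_idx = snapshot.atom_residue_index()
    out = np.zeros(len(atoms))
    for i, ai in enumerate(atoms):
        for j, aj in enumerate(atoms):
            if i == j or keys[res_idx[j]] not in exposed:
                continue
            if np.linalg.norm(ai.coords - aj.coords) <= radius:
                out[i] += aj.charge
    return out


def brute_force_sap(snapshot, sasa, radius=10.0):
    """Residue-by-residue direct summation of the atomic SAP definition."""
    scale, ref = HydrophobicityScale.bundled(), ReferenceSasa.bundled()
    atoms = snapshot.atoms
    out = np.zeros(len(atoms))
    for i, ai in enumerate(atoms):
        pos = 0
        for res in snapshot.residues:
            n = len(res.atoms)
            in_range_sasa = 0.0
            any_in = False
            for k, atom in enumerate(res.atoms):
                if not atom.is_side_chain:
                    continue
                if np.linalg.norm(ai.coords - atom.coords) <= radius:
                    any_in = True
                    in_range_sasa += sasa.per_atom[pos + k]
            if any_in:
                out[i] += in_range_sasa / ref(res.resname) * scale(res.resname)
            pos += n
    return out


def all_exposed(snapshot):
    return set(snapshot.residue_keys())


# ---------------------------------------------------------------------------
# SCM
# ---------------------------------------------------------------------------

class TestAtomicScm:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_matches_all_pairs_oracle_exactly(self, seed):
        snap = random_cluster(20, seed=seed, box=15.0)
        exposed = all_exposed(snap)
        engine = ab.atomic_scm(snap, exposed).values
        oracle = brute_force_scm(snap, exposed)
        np.testing.assert_allclose(engine, oracle, atol=1e-12)

    def test_single_neighbour_contributes_its_charge(self, toy_structures):
        st, sheet = toy_structures["pair_5A"]
        field = ab.atomic_scm(st.snapshots[0], all_exposed(st.snapshots[0]))
        np.testing.assert_allclose(field.values, [-0.5, 0.5])

    def test_out_of_radius_scores_zero(self, toy_structures):
        st, _ = toy_structures["pair_20A"]
        field = ab.atomic_scm(st.snapshots[0], all_exposed(st.snapshots[0]))
        np.testing.assert_allclose(field.values, 0.0)

    def test_empty_exposed_set_warns_and_zeroes(self, toy_structures, caplog):
        st, _ = toy_structures["pair_5A"]
        with caplog.at_level("WARNING", logger="abspatial"):
            field = ab.atomic_scm(st.snapshots[0], set())
        assert np.all(field.values == 0)
        assert any("empty exposed" in m for m in caplog.messages)

    def test_only_exposed_residues_contribute(self):
        snap = random_cluster(10, seed=9)
        exposed = set(list(all_exposed(snap))[:4])
        engine = ab.atomic_scm(snap, exposed).values
        oracle = brute_force_scm(snap, exposed)
        np.testing.assert_allclose(engine, oracle, atol=1e-12)


class TestDomainScm:
    def test_positive_negative_split(self):
        snap = random_cluster(6, seed=2)
        field = ab.AtomicScoreField(np.array([0.5, -0.2, 0.1, 0.0, -0.3, 0.4]), "SCM")
        dm = ab.assign_domains(snap)
        scores = ab.domain_scm(field, snap, dm)
        pos, neg = scores["Fv"]
        assert pos == pytest.approx(1.0)
        assert neg == pytest.approx(0.5)

    def test_identity_pos_minus_neg_is_signed_sum(self):
        snap = random_cluster(14, seed=6)
        exposed = all_exposed(snap)
        field = ab.atomic_scm(snap, exposed)
        dm = ab.assign_domains(snap)
        scores = ab.domain_scm(field, snap, dm)
        idx = dm.atom_indices(snap)
        for region, (pos, neg) in scores.items():
            assert pos - neg == pytest.approx(field.values[idx[region]].sum())

    def test_additivity_fv_and_cdr(self):
        snap = random_cluster(16, seed=8)
        field = ab.atomic_scm(snap, all_exposed(snap))
        dm = ab.assign_domains(snap)
        scores = ab.domain_scm(field, snap, dm)
        for part in (0, 1):  # pos then neg
            assert scores["Fv"][part] == pytest.approx(
                scores["Hv"][part] + scores["Lv"][part])
            assert scores["CDR"][part] == pytest.approx(
                sum(scores[c][part] for c in ab.CDR_REGIONS))

    def test_rigid_motion_invariance(self):
        snap = random_cluster(12, seed=3)
        field0 = ab.atomic_scm(snap, all_exposed(snap)).values
        # rotate + translate every atom
        theta = 0.7
        R = np.array([[math.cos(theta), -math.sin(theta), 0],
                      [math.sin(theta), math.cos(theta), 0],
                      [0, 0, 1.0]])
        for atom in snap.atoms:
            atom.coords = R @ atom.coords + np.array([10.0, -4.0, 2.0])
        field1 = ab.atomic_scm(snap, all_exposed(snap)).values
        np.testing.assert_allclose(field0, field1, atol=1e-9)

    def test_charge_doubling_doubles_both_parts(self):
        snap = random_cluster(10, seed=12)
        dm = ab.assign_domains(snap)
        s1 = ab.domain_scm(ab.atomic_scm(snap, all_exposed(snap)), snap, dm)
        for atom in snap.atoms:
            atom.charge *= 2
        s2 = ab.domain_scm(ab.atomic_scm(snap, all_exposed(snap)), snap, dm)
        for region in s1:
            assert s2[region][0] == pytest.approx(2 * s1[region][0])
            assert s2[region][1] == pytest.approx(2 * s1[region][1])


class TestEnsembleStats:
    def test_two_point_series(self):
        stats = ab.ensemble_stats([{"Fv": 1.0}, {"Fv": 3.0}], "SCM_pos")
        ds = stats[0]
        assert (ds.mean, ds.std, ds.rel_std) == (2.0, 1.0, 0.5)

    def test_single_snapshot_zero_std(self):
        ds = ab.ensemble_stats([{"Fv": 4.2}], "SAP_pos")[0]
        assert ds.std == 0.0 and ds.rel_std == 0.0

    def test_constant_series_zero_rel_std(self):
        ds = ab.ensemble_stats([{"Fv": 2.0}] * 5, "SCM_neg")[0]
        assert ds.rel_std == 0.0

    def test_zero_mean_with_spread_gives_nan_sentinel(self):
        ds = ab.ensemble_stats([{"Fv": -1.0}, {"Fv": 1.0}], "SCM_pos")[0]
        assert ds.mean == 0.0 and math.isnan(ds.rel_std)


# ---------------------------------------------------------------------------
# SAP
# ---------------------------------------------------------------------------

class TestAtomicSap:
    @pytest.mark.parametrize("seed", [5, 6])
    def test_matches_direct_summation_oracle(self, seed):
        snap = random_cluster(12, seed=seed)
        sasa = ab.shrake_rupley(snap)
        engine = ab.atomic_sap(snap, sasa).values
        oracle = brute_force_sap(snap, sasa)
        np.testing.assert_allclose(engine, oracle, atol=1e-9)

    def test_isolated_pair_closed_form(self, toy_structures):
        st, sheet = toy_structures["pair_20A"]
        snap = st.snapshots[0]
        sasa = ab.shrake_rupley(snap)
        field = ab.atomic_sap(snap, sasa)
        np.testing.assert_allclose(field.values, sheet["sap_per_atom"], rtol=1e-6)

    def test_zero_hydrophobicity_contributes_nothing(self):
        snap = random_cluster(4, seed=1)
        for res in snap.residues:
            res.aa = "G"  # glycine: hydrophobicity 0 by construction
        sasa = ab.shrake_rupley(snap)
        field = ab.atomic_sap(snap, sasa)
        np.testing.assert_allclose(field.values, 0.0, atol=1e-12)

    def test_hydrophobicity_scaling_scales_sap_pos(self):
        snap = random_cluster(10, seed=2)
        sasa = ab.shrake_rupley(snap)
        dm = ab.assign_domains(snap)
        base = ab.domain_sap_pos(ab.atomic_sap(snap, sasa), snap, dm)
        scale = HydrophobicityScale.bundled()
        tripled = HydrophobicityScale({k: 3 * v for k, v in scale.values.items()})
        scaled = ab.domain_sap_pos(
            ab.atomic_sap(snap, sasa, scale=tripled), snap, dm)
        for region in base:
            assert scaled[region] == pytest.approx(3 * base[region])

    def test_buried_side_chains_give_zero_sap_pos(self):
        snap = random_cluster(6, seed=4)
        sasa = ab.SasaResult(np.zeros(6), 1.4, 960)
        dm = ab.assign_domains(snap)
        scores = ab.domain_sap_pos(ab.atomic_sap(snap, sasa), snap, dm)
        assert all(v == 0.0 for v in scores.values())

    def test_missing_residue_in_tables_rejected(self):
        snap = random_cluster(3, seed=1)
        sasa = ab.shrake_rupley(snap)
        scale = HydrophobicityScale({"GLY": 0.0})
        with pytest.raises(KeyError):
            ab.atomic_sap(snap, sasa, scale=scale)


class TestDomainSapPos:
    def test_positive_part_only(self):
        snap = random_cluster(4, seed=3)
        dm = ab.assign_domains(snap)
        field = ab.AtomicScoreField(np.array([0.3, -0.1, 0.0, 0.2]), "SAP")
        scores = ab.domain_sap_pos(field, snap, dm)
        assert scores["Fv"] == pytest.approx(0.5)

    def test_zeroing_negatives_changes_nothing(self):
        snap = random_cluster(10, seed=10)
        sasa = ab.shrake_rupley(snap)
        dm = ab.assign_domains(snap)
        field = ab.atomic_sap(snap, sasa)
        clipped = ab.AtomicScoreField(np.maximum(field.values, 0.0), "SAP")
        assert ab.domain_sap_pos(field, snap, dm) == \
            ab.domain_sap_pos(clipped, snap, dm)

    def test_additivity_matches_scm_convention(self):
        snap = random_cluster(14, seed=13)
        sasa = ab.shrake_rupley(snap)
        dm = ab.assign_domains(snap)
        scores = ab.domain_sap_pos(ab.atomic_sap(snap, sasa), snap, dm)
        assert scores["Fv"] == pytest.approx(scores["Hv"] + scores["Lv"])
        assert scores["CDR"] == pytest.approx(
            sum(scores[c] for c in ab.CDR_REGIONS))
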