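import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from wsilk.io import Model
from wsilk.metrics import (
    alpha_fraction,
    assign_ss,
    dihedrals,
    ensemble_alpha_fraction,
    ensemble_rmsd,
    sasa_ranking,
    shrake_rupley_sasa,
    ss_fractions,
    superpose,
)
from wsilk.synthetic import _build_backbone, gen_beads_on_string_ensemble

from conftest import backbone_model


def rigid_move(model, seed=0, angle=0.9):
    rot = Rotation.from_rotvec(angle * np.array([0.3, -0.5, 0.8])).as_matrix()
    coords = model.coords @ rot.T + np.array([4.0, -7.0, 2.0])
    return Model(coords, model.atom_name, model.residue_number,
                 model.residue_name, model.chain_id, model.element)


class TestSuperposition:
    def test_model_onto_itself(self, ideal_helix_model):
        result = superpose(ideal_helix_model, ideal_helix_model)
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(result.rotation, np.eye(3), atol=1e-9)

    def test_translated_copy_recovered(self, ideal_helix_model):
        shift = np.array([3.0, -2.0, 7.0])
        moved = Model(
            ideal_helix_model.coords + shift,
            ideal_helix_model.atom_name,
            ideal_helix_model.residue_number,
            ideal_helix_model.residue_name,
            ideal_helix_model.chain_id,
            ideal_helix_model.element,
        )
        result = superpose(moved, ideal_helix_model)
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(result.rotation, np.eye(3), atol=1e-8)
        assert np.allclose(result.translation, -shift, atol=1e-8)

    def test_against_independent_kabsch(self):
        # scipy's quaternion-based align_vectors is an independent solver
        rng = np.random.default_rng(1)
        ref = rng.normal(scale=5.0, size=(7, 3))
        mob = rng.normal(scale=5.0, size=(7, 3))
        names = np.array(["CA"] * 7)
        resnum = np.arange(1, 8)
        other = np.array(["C"] * 7)
        model_m = Model(mob, names, resnum, np.array(["GLY"] * 7), other, other)
        model_r = Model(ref, names, resnum, np.array(["GLY"] * 7), other, other)
        ours = superpose(model_m, model_r, atom_class="heavy")
        rot, rssd = Rotation.align_vectors(ref - ref.mean(0), mob - mob.mean(0))
        expected_rmsd = rssd / math.sqrt(len(ref))
        assert ours.rmsd == pytest.approx(expected_rmsd, abs=1e-3)

    def test_collinear_selection_rejected(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        names = np.array(["CA"] * 4)
        model = Model(coords, names, np.arange(1, 5), np.array(["GLY"] * 4),
                      np.array(["A"] * 4), np.array(["C"] * 4))
        with pytest.raises(ValueError, match="collinear"):
            superpose(model, model, atom_class="heavy")


class TestEnsembleRmsd:
    def test_identical_models_zero(self, small_ensemble):
        coords = np.repeat(small_ensemble.coords[:1], 3, axis=0)
        from wsilk.io import Ensemble

        clones = Ensemble(coords, small_ensemble.atom_name,
                          small_ensemble.residue_number, small_ensemble.residue_name,
                          small_ensemble.chain_id, small_ensemble.element)
        mean, sd = ensemble_rmsd(clones)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_pairwise_mean_matches_manual_enumeration(self, small_ensemble):
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        values = []
        for i, j in pairs:
            values.append(
                superpose(small_ensemble.model(j), small_ensemble.model(i)).rmsd
            )
        mean, sd = ensemble_rmsd(small_ensemble)
        assert mean == pytest.approx(np.mean(values), rel=1e-9)
        assert sd == pytest.approx(np.std(values), rel=1e-9)

    def test_core_much_tighter_than_full_chain(self, small_ensemble):
        core, _ = ensemble_rmsd(small_ensemble, residue_range=(12, 149))
        full, _ = ensemble_rmsd(small_ensemble)
        assert core < 0.1 * full

    def test_empty_selection_rejected(self, small_ensemble):
        with pytest.raises(ValueError):
            ensemble_rmsd(small_ensemble, residue_range=(500, 600))


class TestSecondaryStructure:
    def test_ideal_helix_mostly_H(self, ideal_helix_model):
        ss = assign_ss(ideal_helix_model)
        assert (ss == "H").sum() >= 16

    def test_extended_chain_has_no_helix(self, extended_model):
        ss = assign_ss(extended_model)
        assert (ss == "H").sum() == 0

    def test_parallel_ladder_labelled_strand(self):
        # two extended strands placed side by side at sheet spacing form a
        # ladder whose central residues are assigned E
        n = 8
        strand = _build_backbone(np.full(n, -120.0), np.full(n, 130.0))
        shifted = strand + np.array([-2.0, 4.6, 0.0])
        coords = np.concatenate([strand.reshape(-1, 3), shifted.reshape(-1, 3)])
        atom_name = np.tile(np.array(["N", "CA", "C", "O"]), 2 * n)
        residue_number = np.concatenate(
            [np.repeat(np.arange(1, n + 1), 4), np.repeat(np.arange(21, 21 + n), 4)]
        )
        model = Model(coords, atom_name, residue_number,
                      np.array(["GLY"] * 8 * n), np.array(["A"] * 8 * n),
                      np.tile(np.array(["N", "C", "C", "O"]), 2 * n))
        ss = assign_ss(model)
        assert (ss.loc[[5, 6, 25, 26]] == "E").all()

    def test_rigid_motion_invariance(self, ideal_helix_model):
        moved = rigid_move(ideal_helix_model)
        assert assign_ss(moved).equals(assign_ss(ideal_helix_model))

    def test_generated_helices_recovered(self, small_ensemble):
        from wsilk.synthetic import DEFAULT_HELIX_TABLE

        ss = assign_ss(small_ensemble.model(0))
        for start, end in DEFAULT_HELIX_TABLE:
            interior = ss.loc[start + 1 : end - 1]
            assert (interior == "H").all()

    def test_fractions_sum_to_100(self, small_ensemble):
        fractions = ss_fractions(small_ensemble)
        assert sum(fractions.values()) == pytest.approx(100.0)

    def test_all_helix_ensemble(self, ideal_helix_model):
        from wsilk.io import Ensemble

        ensemble = Ensemble(
            ideal_helix_model.coords[None], ideal_helix_model.atom_name,
            ideal_helix_model.residue_number, ideal_helix_model.residue_name,
            ideal_helix_model.chain_id, ideal_helix_model.element,
        )
        fractions = ss_fractions(ensemble)
        # 10-residue helix in a 20-residue chain would be ~40-50% with end
        # effects; a full-length ideal helix is 90%
        assert fractions["H"] == pytest.approx(90.0, abs=10.0)
        assert fractions["E"] == 0.0

    def test_cross_check_against_mdtraj_dssp(self, small_ensemble, tmp_path):
        mdtraj = pytest.importorskip("mdtraj")
        from wsilk.io import write_pdb_ensemble

        path = tmp_path / "ensemble.pdb"
        write_pdb_ensemble(small_ensemble, path)
        traj = mdtraj.load(str(path))
        ref = mdtraj.compute_dssp(traj, simplified=True)[0]
        ours = assign_ss(small_ensemble.model(0)).values
        agreement = np.mean(ref == ours)
        assert agreement > 0.85


class TestDihedrals:
    def test_ideal_helix_angles(self, ideal_helix_model):
        table = dihedrals(ideal_helix_model)
        interior = table.iloc[1:-1]
        assert np.allclose(interior["phi"], -57.0, atol=1.0)
        assert np.allclose(interior["psi"], -47.0, atol=1.0)

    def test_termini_undefined(self, ideal_helix_model):
        table = dihedrals(ideal_helix_model)
        assert np.isnan(table.iloc[0]["phi"])
        assert np.isnan(table.iloc[-1]["psi"])

    def test_helix_alpha_fraction_is_100(self, ideal_helix_model):
        table = dihedrals(ideal_helix_model)
        assert alpha_fraction(table, (2, 19)) == pytest.approx(100.0)

    def test_widening_window_is_monotone(self, small_ensemble):
        table = dihedrals(small_ensemble.model(0))
        narrow = alpha_fraction(table, (12, 149), (-70, -45), (-60, -35))
        default = alpha_fraction(table, (12, 149))
        wide = alpha_fraction(table, (12, 149), (-180, 0), (-120, 60))
        assert narrow <= default <= wide

    def test_empty_window_rejected(self, ideal_helix_model):
        table = dihedrals(ideal_helix_model)
        with pytest.raises(ValueError):
            alpha_fraction(table, (500, 600))

    def test_ensemble_average(self, small_ensemble):
        value = ensemble_alpha_fraction(small_ensemble, (12, 149))
        assert 0.0 <= value <= 100.0


class TestSasa:
    def test_fully_caged_atom_is_buried(self):
        # central atom surrounded by 12 neighbours at contact distance
        golden = (1 + math.sqrt(5)) / 2
        verts = []
        for a in (-1, 1):
            for b in (-golden, golden):
                verts += [[0, a, b], [a, b, 0], [b, 0, a]]
        verts = np.array(verts)
        verts = verts / np.linalg.norm(verts[0]) * 3.0
        coords = np.vstack([[0.0, 0, 0], verts])
        n = len(coords)
        model = Model(coords, np.array(["C"] * n), np.arange(1, n + 1),
                      np.array(["ALA"] * n), np.array(["A"] * n), np.array(["C"] * n))
        sasa = shrake_rupley_sasa(model)
        assert sasa[0] == pytest.approx(0.0, abs=1.0)

    def test_quadrature_convergence(self, ideal_helix_model):
        # doubling the sphere sampling changes per-residue areas by < 2%
        import pandas as pd

        coarse = shrake_rupley_sasa(ideal_helix_model, n_points=960)
        fine = shrake_rupley_sasa(ideal_helix_model, n_points=1920)
        per_res = pd.DataFrame(
            {"res": ideal_helix_model.residue_number, "c": coarse, "f": fine}
        ).groupby("res").sum()
        rel = (per_res["f"] - per_res["c"]).abs() / per_res["c"]
        assert rel.max() < 0.02

    def test_isolated_residue_relative_exposure(self):
        # with nothing to occlude it, a lone residue exceeds the extended
        # tripeptide reference but stays within ~2x of it
        coords = _build_backbone(np.array([180.0]), np.array([180.0]))
        model = backbone_model(coords)
        ranking = sasa_ranking(model)
        assert 1.0 <= ranking["rel_exposure"].iloc[0] <= 2.0

    def test_ranking_descends(self, small_ensemble):
        ranking = sasa_ranking(small_ensemble.model(0))
        ordered = ranking.sort_values("rank")["rel_exposure"].to_numpy()
        assert np.all(np.diff(ordered) <= 1e-12)
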