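import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wsilk.restraints import (
    DihedralRestraint,
    DistanceRestraint,
    HBondRestraint,
    RestraintSet,
    RgRestraintSpec,
    categorize,
    hbonds_from_hdx,
    make_rg_restraint,
    propagate,
    read_restraints,
    rg_penalty,
    score_violations,
    write_restraints,
)
from wsilk.synthetic import gen_beads_on_string_ensemble, gen_restraints_from_ensemble


def dist(i, j, lower=0.0, upper=5.0):
    return DistanceRestraint.simple(i, "CA", j, "CA", lower, upper)


pair_sets = st.lists(
    st.tuples(st.integers(1, 180), st.integers(0, 19)), min_size=1, max_size=60
)


class TestCategorize:
    @pytest.mark.parametrize(
        "i,j,expected",
        [(5, 5, "intra"), (5, 6, "sequential"), (5, 8, "medium"),
         (5, 9, "medium"), (5, 10, "long"), (5, 30, "long")],
    )
    def test_span_classes(self, i, j, expected):
        counts = categorize([dist(i, j)])
        assert counts[expected] == 1

    def test_ambiguous_counted_separately(self):
        r = DistanceRestraint(((1, "CA", 2, "CA"), (1, "CA", 50, "CA")), 0.0, 5.0)
        counts = categorize([r])
        assert counts["ambiguous"] == 1
        assert counts["long"] == 0

    @settings(max_examples=50, derandomize=True)
    @given(pair_sets)
    def test_partition_property(self, spans):
        restraints = [dist(i, i + d) for i, d in spans]
        counts = categorize(restraints)
        assert counts["total"] == len(restraints)
        assert (
            counts["intra"] + counts["sequential"] + counts["medium"]
            + counts["long"] + counts["ambiguous"]
        ) == len(restraints)


class TestHbondsFromHdx:
    def test_protected_residue_inside_helix(self):
        out = hbonds_from_hdx({20}, [(12, 39)])
        assert len(out) == 1
        assert (out[0].donor, out[0].acceptor) == (20, 16)

    def test_outside_helix_emits_nothing(self):
        assert hbonds_from_hdx({5}, [(12, 39)]) == []

    def test_near_helix_start_needs_room_for_i_minus_4(self):
        assert hbonds_from_hdx({14}, [(12, 39)]) == []

    def test_empty_retained_set(self):
        assert hbonds_from_hdx(set(), [(12, 39)]) == []

    def test_output_bounded_by_retained(self):
        retained = set(range(1, 200))
        out = hbonds_from_hdx(retained, [(12, 39), (135, 149)])
        assert len(out) <= len(retained)


class TestPropagate:
    def base_set(self):
        return RestraintSet(
            distances=[dist(20, 80), dist(5, 5), dist(100, 104)],
            dihedrals=[DihedralRestraint(150, "phi", -57.0, 10.0)],
            hbonds=[HBondRestraint(20, 16)],
        )

    def test_offsets_applied_per_unit(self):
        out = propagate(self.base_set(), repeat_length=200, n_units=2)
        second_unit = out.distances[3]
        assert second_unit.pairs[0][0] == 220
        assert second_unit.pairs[0][2] == 280
        assert out.dihedrals[1].residue == 350

    def test_third_unit_dihedral(self):
        out = propagate(
            RestraintSet(dihedrals=[DihedralRestraint(150, "psi", -47.0, 5.0)]),
            repeat_length=200, n_units=3,
        )
        assert out.dihedrals[2].residue == 550

    def test_cardinality_scales(self):
        base = self.base_set()
        out = propagate(base, repeat_length=200, n_units=2)
        assert len(out) == 2 * len(base)

    def test_restraint_exceeding_repeat_rejected(self):
        with pytest.raises(ValueError):
            propagate(RestraintSet(distances=[dist(10, 250)]), repeat_length=200)

    @settings(max_examples=30, derandomize=True)
    @given(pair_sets, st.integers(1, 4))
    def test_category_counts_scale_exactly(self, spans, n_units):
        restraints = RestraintSet(
            distances=[dist(i, min(i + d, 199)) for i, d in spans]
        )
        base_counts = categorize(restraints)
        out = propagate(restraints, repeat_length=200, n_units=n_units)
        out_counts = categorize(out)
        for key in ("intra", "sequential", "medium", "long", "ambiguous", "total"):
            assert out_counts[key] == n_units * base_counts[key]


class TestScoreViolations:
    def test_satisfied_ensemble_scores_zero(self, small_ensemble):
        restraints = gen_restraints_from_ensemble(small_ensemble, cutoff=6.0)
        report = score_violations(small_ensemble, restraints)
        assert report.distance_mean == 0.0
        assert report.distance_max_mean == 0.0
        assert report.dihedral_mean == 0.0

    def test_simple_overshoot(self, small_ensemble):
        model = small_ensemble.model(0)
        a = model.atom_coord(20, "CA")
        b = model.atom_coord(21, "CA")
        d = float(np.linalg.norm(a - b))
        single = small_ensemble.subset(np.ones(small_ensemble.n_atoms, bool))
        restraints = RestraintSet(distances=[dist(20, 21, 0.0, d - 0.5)])
        report = score_violations(single, restraints)
        assert report.distance_max_mean == pytest.approx(0.5, abs=1e-6)

    def test_ambiguous_r6_sum(self, small_ensemble):
        # pairs at ~d1 and a remote pair: effective distance ≈ min distance
        model = small_ensemble.model(0)
        d_near = float(
            np.linalg.norm(model.atom_coord(20, "CA") - model.atom_coord(21, "CA"))
        )
        amb = DistanceRestraint(
            ((20, "CA", 21, "CA"), (20, "CA", 120, "CA")), 0.0, d_near + 0.01
        )
        report = score_violations(small_ensemble, RestraintSet(distances=[amb]))
        assert report.distance_mean == pytest.approx(0.0, abs=1e-3)

    def test_rigid_motion_invariance(self, small_ensemble):
        from scipy.spatial.transform import Rotation

        from wsilk.io import Ensemble

        restraints = gen_restraints_from_ensemble(small_ensemble, cutoff=6.0)
        rot = Rotation.from_rotvec([0.4, 0.1, -0.8]).as_matrix()
        moved = Ensemble(
            small_ensemble.coords @ rot.T + np.array([3.0, 4.0, 5.0]),
            small_ensemble.atom_name, small_ensemble.residue_number,
            small_ensemble.residue_name, small_ensemble.chain_id,
            small_ensemble.element,
        )
        a = score_violations(small_ensemble, restraints)
        b = score_violations(moved, restraints)
        assert a.distance_mean == pytest.approx(b.distance_mean, abs=1e-9)
        assert a.dihedral_mean == pytest.approx(b.dihedral_mean, abs=1e-6)

    def test_unresolvable_restraints_rejected(self, small_ensemble):
        restraints = RestraintSet(
            distances=[DistanceRestraint.simple(1, "ZZ", 2, "ZZ", 0.0, 5.0)]
        )
        with pytest.raises(ValueError):
            score_violations(small_ensemble, restraints)


class TestRgRestraint:
    def test_serialisation_round_trip(self):
        spec = make_rg_restraint(25.0, weight_scale=2.0, residue_selection=(12, 149))
        back = RgRestraintSpec.from_json(spec.to_json())
        assert back == spec

    def test_negative_rg_rejected(self):
        with pytest.raises(ValueError):
            make_rg_restraint(-1.0)

    def test_matching_ensemble_scores_zero(self, small_ensemble):
        from wsilk.hydro import rg_from_coordinates

        rg = rg_from_coordinates(small_ensemble.model(0).coords)
        single_model = small_ensemble.coords[:1]
        from wsilk.io import Ensemble

        one = Ensemble(single_model, small_ensemble.atom_name,
                       small_ensemble.residue_number, small_ensemble.residue_name,
                       small_ensemble.chain_id, small_ensemble.element)
        assert rg_penalty(one, make_rg_restraint(rg)) == pytest.approx(0.0, abs=1e-9)


class TestSerialisation:
    def test_tabular_round_trip(self):
        rset = RestraintSet(
            distances=[
                dist(5, 30, 1.8, 5.0),
                DistanceRestraint(((1, "HA", 9, "HB"), (1, "HA", 40, "HB")), 0.0, 6.0),
            ],
            dihedrals=[DihedralRestraint(7, "phi", -57.0, 10.0)],
            hbonds=[HBondRestraint(20, 16)],
        )
        buf = io.StringIO()
        write_restraints(rset, buf)
        buf.seek(0)
        back = read_restraints(buf)
        assert categorize(back) == categorize(rset)
        assert back.dihedrals == rset.dihedrals
        assert back.hbonds == rset.hbonds
        assert sorted(len(r.pairs) for r in back.distances) == [1, 2]

    def test_bad_line_reports_number(self):
        with pytest.raises(ValueError, match="line 2"):
            read_restraints(io.StringIO("dist 0 1 CA 2 CA 0 5\nnonsense record\n"))
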