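"""Lattice construction, screw geometry, and superposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mthelix.lattice import (AtomModel, HelicalSymmetry, LatticeSpec,
                             SpiralSpec, build_microtubule,
                             build_protofilament_spiral, compose_screw,
                             default_symmetry, measure_intersubunit_transform,
                             rmsd_after_superposition, screw_decompose)

SYM_DECORATED_MT = HelicalSymmetry(168.083, 5.50)


class TestScrewDecomposition:
    def test_identity_transform(self):
        p = screw_decompose(np.eye(3), np.zeros(3))
        assert p.angle_deg == 0.0
        assert p.rise_A == 0.0
        assert p.shear_A == 0.0

    def test_pure_rotation_about_z(self):
        R = Rotation.from_euler("z", 12.0, degrees=True).as_matrix()
        p = screw_decompose(R, np.zeros(3))
        assert p.angle_deg == pytest.approx(12.0, abs=1e-9)
        assert abs(p.axis[2]) == pytest.approx(1.0, abs=1e-12)
        assert p.rise_A == pytest.approx(0.0, abs=1e-12)
        assert p.shear_A == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_random_screws(self, rng):
        """Decompose-then-compose reproduces 1000 random rigid transforms."""
        worst = 0.0
        for _ in range(1000):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-50, 50, 3)
            p = screw_decompose(R, t)
            R2, t2 = compose_screw(p)
            worst = max(worst, np.abs(R2 - R).max(), np.abs(t2 - t).max())
            assert 0.0 <= p.angle_deg <= 180.0
            assert p.shear_A >= 0.0
        assert worst < 1e-8

    def test_improper_rotation_rejected(self):
        M = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="improper"):
            screw_decompose(M, np.zeros(3))

    def test_zero_angle_uses_translation_direction(self):
        p = screw_decompose(np.eye(3), np.array([0.0, 3.0, 4.0]))
        assert p.rise_A == pytest.approx(5.0)
        assert p.shear_A == 0.0
        assert p.axis @ [0, 3, 4] == pytest.approx(5.0)


class TestMicrotubuleLattice:
    def test_consecutive_units_related_by_screw(self):
        model = build_microtubule(LatticeSpec(15, "R", n_dimers_per_pf=2), SYM_DECORATED_MT)
        p = measure_intersubunit_transform(model, (0, 0), (1, 0))
        assert p.angle_deg == pytest.approx(168.083, abs=1e-6)
        assert p.rise_A == pytest.approx(5.50, abs=1e-6)
        assert p.shear_A == pytest.approx(0.0, abs=1e-6)

    def test_all_twelve_types_distinct(self):
        seen = set()
        for n in range(11, 17):
            for hand in "RL":
                spec = LatticeSpec(n, hand, n_dimers_per_pf=2)
                sym = default_symmetry(spec)
                model = build_microtubule(spec, sym)
                assert len(model) > 0
                seen.add((round(sym.twist_deg, 4), round(sym.rise_A, 4)))
        assert len(seen) == 12

    def test_recovered_symmetry_matches_input_for_all_types(self):
        for n in (11, 13, 16):
            for hand in "RL":
                spec = LatticeSpec(n, hand, n_dimers_per_pf=2)
                sym = default_symmetry(spec)
                model = build_microtubule(spec, sym)
                p = measure_intersubunit_transform(model, (0, 0), (1, 0))
                assert p.signed_twist_about() == pytest.approx(sym.twist_deg,
                                                               abs=1e-8)
                assert abs(p.rise_A) == pytest.approx(sym.rise_A, abs=1e-8)

    def test_pf_count_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="11-16"):
            LatticeSpec(10, "R")
        with pytest.raises(ValueError, match="11-16"):
            LatticeSpec(17, "L")

    def test_inconsistent_rise_flags_warning(self):
        spec = LatticeSpec(15, "R", n_dimers_per_pf=1)
        bad = HelicalSymmetry(168.083, 4.1)  # 15 x 4.1 far from 2 spacings
        with pytest.warns(UserWarning, match="monomer spacings"):
            model = build_microtubule(spec, bad)
        assert model.meta["spacing_warning"]

    def test_handedness_flips_under_mirror(self):
        """Mirroring through a plane containing the axis flips the twist sign."""
        model = build_microtubule(LatticeSpec(15, "R", n_dimers_per_pf=2), SYM_DECORATED_MT)
        mirrored = AtomModel(model.positions * [1.0, -1.0, 1.0], model.weights,
                             model.pf_index, model.dimer_index,
                             model.monomer_kind)
        p = measure_intersubunit_transform(model, (0, 0), (1, 0))
        pm = measure_intersubunit_transform(mirrored, (0, 0), (1, 0))
        assert pm.signed_twist_about() == pytest.approx(
            -p.signed_twist_about(), abs=1e-8)


class TestProtofilamentSpiral:
    def test_ring_closes_at_24_degrees(self):
        ring = build_protofilament_spiral(SpiralSpec(24.0, 0.0, 15))
        closure = measure_intersubunit_transform(ring, (0, 14), (0, 0))
        assert closure.angle_deg == pytest.approx(24.0, abs=1e-9)
        assert abs(closure.rise_A) == pytest.approx(0.0, abs=1e-9)
        # dimer centroids average to the ring centre
        tub = ring.monomer_kind != "kinesin"
        centroid = ring.positions[tub].mean(axis=0)
        assert np.linalg.norm(centroid[:2]) < 1e-9

    def test_helical_path_screw(self):
        spiral = build_protofilament_spiral(SpiralSpec(23.82, 11.1, 20))
        p = measure_intersubunit_transform(spiral, (0, 0), (0, 1))
        assert p.angle_deg == pytest.approx(23.82, abs=1e-9)
        assert abs(p.rise_A) == pytest.approx(11.1, abs=1e-9)

    def test_even_intra_dimer_split(self):
        ring = build_protofilament_spiral(SpiralSpec(24.0, 0.0, 15))
        p = measure_intersubunit_transform(ring, (0, 0, "alpha"), (0, 0, "beta"))
        assert p.angle_deg == pytest.approx(12.0, abs=1e-9)

    def test_single_dimer_degenerate(self):
        model = build_protofilament_spiral(SpiralSpec(24.0, 0.0, 1))
        assert set(zip(model.pf_index, model.dimer_index)) == {(0, 0)}

    def test_every_other_dimer_odd_flagged(self):
        model = build_protofilament_spiral(
            SpiralSpec(24.0, 0.0, 15, decoration="every_other_dimer"))
        assert model.meta["odd_dimer_bare"]
        kin_dimers = set(model.dimer_index[model.monomer_kind == "kinesin"])
        assert kin_dimers == set(range(0, 15, 2))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SpiralSpec(0.0, 0.0, 15)
        with pytest.raises(ValueError):
            SpiralSpec(24.0, 0.0, 0)


class TestSuperposition:
    def test_rigid_copy_has_zero_rmsd(self, rng):
        pts = rng.normal(size=(50, 3)) * 30
        R = Rotation.random(rng=rng).as_matrix()
        assert rmsd_after_superposition(pts, pts @ R.T + [1, 2, 3]) < 1e-9

    def test_gaussian_displacement_closed_form(self, rng):
        """RMSD of an iid-displaced copy approaches sigma * sqrt(3)."""
        sigma = 2.0
        pts = rng.normal(size=(10_000, 3)) * 50
        noisy = pts + rng.normal(0.0, sigma, pts.shape)
        r = rmsd_after_superposition(pts, noisy)
        assert r == pytest.approx(sigma * np.sqrt(3), rel=0.02)

    def test_order_invariance(self, rng):
        a = rng.normal(size=(20, 3))
        b = a + rng.normal(0, 0.5, a.shape)
        assert rmsd_after_superposition(a, b) == pytest.approx(
            rmsd_after_superposition(b, a), abs=1e-9)

    def test_empty_pairing_rejected(self, rng):
        a = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            rmsd_after_superposition(a, a, (np.array([]), np.array([])))


class TestModelIO:
    def test_pdb_round_trip(self, tmp_path):
        model = build_microtubule(LatticeSpec(13, "L", n_dimers_per_pf=1,
                                              decorate_kinesin="every_dimer"))
        path = tmp_path / "model.pdb"
        model.to_pdb(path)
        back = AtomModel.from_pdb(path)
        assert len(back) == len(model)
        assert np.allclose(back.positions, model.positions, atol=1e-2)
        assert list(back.monomer_kind) == list(model.monomer_kind)

    def test_tsv_round_trip(self, tmp_path):
        model = build_protofilament_spiral(SpiralSpec(24.0, 0.0, 5))
        path = tmp_path / "model.tsv"
        model.to_tsv(path)
        back = AtomModel.from_tsv(path)
        assert np.allclose(back.positions, model.positions)
        assert np.allclose(back.weights, model.weights)
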