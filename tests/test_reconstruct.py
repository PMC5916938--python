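"""Back-projection, helical symmetry imposition and estimation."""

import numpy as np
import pandas as pd
import pytest

from mthelix.imaging import (DensityVolume, ImageStack, fsc_curve,
                             lowpass_filter, project, render_density)
from mthelix.lattice import (AtomModel, HelicalSymmetry, LatticeSpec,
                             build_microtubule)
from mthelix.reconstruct import (backproject, estimate_symmetry,
                                 gold_standard_fsc, impose_helical_symmetry)

SYM_DECORATED_MT = HelicalSymmetry(168.083, 5.50)


def _table(rows):
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def phantom():
    model = build_microtubule(LatticeSpec(13, "R", n_dimers_per_pf=2))
    return render_density(model, 4.0, 72)


class TestBackprojection:
    def test_phantom_self_consistency(self, phantom):
        """Reconstruction from its own projections agrees with the phantom
        to FSC >= 0.99 up to 2/3 Nyquist."""
        rng = np.random.default_rng(0)
        rows, imgs = [], []
        for i in range(500):
            phi = rng.uniform(0, 360)
            theta = np.degrees(np.arccos(rng.uniform(-1, 1)))
            psi = rng.uniform(0, 360)
            imgs.append(project(phantom, (phi, theta, psi)).data)
            rows.append(dict(filament_id=0, segment_idx=i, phi=phi,
                             theta=theta, psi=psi, sx=0.0, sy=0.0, half_set=1))
        rec = backproject(ImageStack(np.stack(imgs), 4.0), _table(rows))
        curve = fsc_curve(rec, phantom)
        cutoff = int(len(curve.fsc) * 2 / 3)
        assert curve.fsc[:cutoff].min() >= 0.99

    def test_central_slice_property(self, phantom):
        """Re-projecting the reconstruction at a used orientation reproduces
        that image (Fourier-slice theorem)."""
        rng = np.random.default_rng(1)
        rows, imgs = [], []
        for i in range(150):
            e = (rng.uniform(0, 360), 90.0, rng.uniform(0, 360))
            imgs.append(project(phantom, e).data)
            rows.append(dict(filament_id=0, segment_idx=i, phi=e[0],
                             theta=e[1], psi=e[2], sx=0.0, sy=0.0, half_set=1))
        rec = backproject(ImageStack(np.stack(imgs), 4.0), _table(rows))
        reproj = project(rec, (rows[0]["phi"], 90.0, rows[0]["psi"])).data
        r = np.corrcoef(reproj.ravel(), imgs[0].ravel())[0, 1]
        assert r > 0.99

    def test_shifts_are_removed_before_insertion(self, phantom):
        rows, imgs = [], []
        rng = np.random.default_rng(2)
        for i in range(100):
            e = (rng.uniform(0, 360), 90.0, rng.uniform(0, 360))
            s = rng.uniform(-3, 3, 2)
            imgs.append(project(phantom, e, shift_px=s).data)
            rows.append(dict(filament_id=0, segment_idx=i, phi=e[0],
                             theta=e[1], psi=e[2], sx=s[0], sy=s[1],
                             half_set=1))
        rec = backproject(ImageStack(np.stack(imgs), 4.0), _table(rows))
        # oracle: the same orientations without shifts
        clean = [dict(r, sx=0.0, sy=0.0) for r in rows]
        imgs0 = [project(phantom, (r["phi"], r["theta"], r["psi"])).data
                 for r in rows]
        rec0 = backproject(ImageStack(np.stack(imgs0), 4.0), _table(clean))
        curve = fsc_curve(rec, rec0)
        assert curve.fsc[:int(len(curve.fsc) * 0.8)].min() > 0.98

    def test_no_particles_rejected(self):
        with pytest.raises(ValueError):
            backproject(ImageStack(np.zeros((0, 32, 32)), 4.0), _table([]))

    def test_missing_columns_rejected(self, phantom):
        img = project(phantom, (0, 90, 0)).data
        with pytest.raises(ValueError, match="missing columns"):
            backproject(ImageStack(img[None], 4.0),
                        _table([{"filament_id": 0}]))


@pytest.fixture(scope="module")
def symmetrized_unit(single_dimer_unit):
    vol = render_density(single_dimer_unit, 4.0, 96)
    return impose_helical_symmetry(vol, SYM_DECORATED_MT, z_fraction=0.8)


class TestImposeSymmetry:
    def test_single_unit_becomes_lattice(self, symmetrized_unit,
                                         single_dimer_unit):
        """Symmetrizing one rendered dimer reproduces a directly rendered
        lattice built by explicit screw copies of the same unit."""
        from mthelix.lattice import _rot_z

        pos, wts, kinds = [], [], []
        for k in range(-30, 31):
            R = _rot_z(k * SYM_DECORATED_MT.twist_deg)
            pos.append(single_dimer_unit.positions @ R.T
                       + [0, 0, k * SYM_DECORATED_MT.rise_A])
            wts.append(single_dimer_unit.weights)
            kinds.append(single_dimer_unit.monomer_kind)
        n_at = len(single_dimer_unit)
        model = AtomModel(np.vstack(pos), np.concatenate(wts),
                          np.zeros(61 * n_at, int),
                          np.repeat(np.arange(61), n_at),
                          np.concatenate(kinds))
        keep = np.abs(model.positions[:, 2]) < 160.0
        model = AtomModel(model.positions[keep], model.weights[keep],
                          model.pf_index[keep], model.dimer_index[keep],
                          model.monomer_kind[keep])
        oracle = render_density(model, 4.0, 96)
        c = slice(24, 72)
        r = np.corrcoef(symmetrized_unit.data[c].ravel(),
                        oracle.data[c].ravel())[0, 1]
        assert r > 0.98

    def test_undersampled_rise_rejected(self, symmetrized_unit):
        with pytest.raises(ValueError, match="undersampled"):
            impose_helical_symmetry(symmetrized_unit,
                                    HelicalSymmetry(10.0, 1.0))

    def test_symmetrization_raises_snr(self, symmetrized_unit, rng):
        """Averaging over screw copies suppresses white noise against truth."""
        noisy = DensityVolume(
            symmetrized_unit.data
            + rng.normal(0, symmetrized_unit.data.std(),
                         symmetrized_unit.data.shape), 4.0)
        cleaned = impose_helical_symmetry(noisy, SYM_DECORATED_MT, 0.8)
        f_noisy = fsc_curve(noisy, symmetrized_unit).fsc
        f_clean = fsc_curve(cleaned, symmetrized_unit).fsc
        mid = slice(2, 30)
        assert np.mean(f_clean[mid]) > np.mean(f_noisy[mid])


class TestEstimateSymmetry:
    def test_featureless_volume_flagged_low_confidence(self, rng):
        blob = DensityVolume(lowpass_filter(rng.normal(size=(64, 64, 64)),
                                            30.0, 4.0), 4.0)
        est = estimate_symmetry(blob, (160, 175), (4, 7), grid_steps=(1.0, 0.5))
        assert est.low_confidence

    def test_scaling_invariance(self, symmetrized_unit):
        a = estimate_symmetry(symmetrized_unit, (166, 170), (5, 6),
                              grid_steps=(0.5, 0.25), polish=False)
        b = estimate_symmetry(
            DensityVolume(symmetrized_unit.data * 13.7, 4.0), (166, 170),
            (5, 6), grid_steps=(0.5, 0.25), polish=False)
        assert a.symmetry.twist_deg == pytest.approx(b.symmetry.twist_deg,
                                                     abs=1e-9)
        assert a.symmetry.rise_A == pytest.approx(b.symmetry.rise_A, abs=1e-9)


def test_gold_standard_fsc_refuses_same_half_tag(symmetrized_unit):
    from mthelix.reconstruct import ReconstructionState

    v1 = symmetrized_unit.copy()
    v2 = symmetrized_unit.copy()
    v1.meta["half_set"] = 1
    v2.meta["half_set"] = 1
    state = ReconstructionState((v1, v2), SYM_DECORATED_MT)
    with pytest.raises(ValueError, match="half-set"):
        gold_standard_fsc(state)
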