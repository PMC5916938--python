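"""Rendering, projection, alignment, FSC and spectral filters."""

import numpy as np
import pytest
from scipy import ndimage

from mthelix.imaging import (DensityVolume, FSCCurve, ImageStack,
                             align_to_references, fourier_shift, fsc_curve,
                             lowpass_filter, make_fsc_mask, normalize_image,
                             project, randomize_phases, render_density,
                             resolution_at, sharpen)
from mthelix.lattice import AtomModel, LatticeSpec, build_microtubule
from mthelix.mrcio import read_mrc, write_mrc


def _point_model(positions, weights=None):
    positions = np.atleast_2d(positions)
    n = len(positions)
    return AtomModel(positions, np.ones(n) if weights is None else weights,
                     np.zeros(n, int), np.arange(n), ["alpha"] * n)


class TestRendering:
    def test_single_atom_centred_and_normalized(self):
        vol = render_density(_point_model([0.0, 0.0, 0.0]), 4.0, 32)
        assert np.unravel_index(np.argmax(vol.data), vol.data.shape) == (16, 16, 16)
        assert vol.data.sum() == pytest.approx(1.0, rel=0.01)

    def test_voxel_shift_equivariance(self):
        a = render_density(_point_model([0.0, 0.0, 0.0]), 4.0, 32).data
        b = render_density(_point_model([4.0, 0.0, 0.0]), 4.0, 32).data
        assert np.allclose(np.roll(a, 1, axis=2), b, atol=1e-12)

    def test_linearity(self):
        both = render_density(_point_model([[0, 0, 0], [12, 0, 0]]), 4.0, 32).data
        a = render_density(_point_model([0, 0, 0]), 4.0, 32).data
        b = render_density(_point_model([12, 0, 0]), 4.0, 32).data
        assert np.allclose(both, a + b, atol=1e-12)

    def test_lattice_support_diameter_matches_geometry(self, volume_15r):
        """Nonzero support diameter ~ (2*radius + kernel reach) in voxels."""
        proj = volume_15r.data.sum(axis=0)
        cols = np.flatnonzero(proj.sum(axis=0) > 1e-6 * proj.max())
        measured = cols[-1] - cols[0] + 1
        expected = (2 * 110.0 + 2 * (8.0 + 4 * 4.0)) / 4.0
        assert measured == pytest.approx(expected, rel=0.15)

    def test_model_exceeding_box_names_subunit(self):
        with pytest.raises(ValueError, match=r"pf=0, dimer=1"):
            render_density(_point_model([[0, 0, 0], [100, 0, 0]]), 4.0, 32)


class TestProjection:
    def test_identity_projection_is_axis_sum(self, volume_15r):
        img = project(volume_15r, (0.0, 0.0, 0.0))
        assert np.allclose(img.data, volume_15r.data.sum(axis=0), atol=1e-12)

    def test_ray_conservation(self, volume_15r, rng):
        total = volume_15r.data.sum()
        for _ in range(3):
            euler = rng.uniform(0, 360, 3)
            img = project(volume_15r, euler)
            assert img.data.sum() == pytest.approx(total, rel=1e-3)

    def test_spherical_blob_is_view_invariant(self, rng):
        c = np.arange(48) - 24
        zz, yy, xx = np.meshgrid(c, c, c, indexing="ij")
        blob = DensityVolume(np.exp(-(xx**2 + yy**2 + zz**2) / 50.0), 4.0)
        base = project(blob, (0.0, 0.0, 0.0)).data
        for _ in range(5):
            img = project(blob, rng.uniform(0, 360, 3)).data
            # linear interpolation bounds the view dependence at the ~1% level
            assert np.abs(img - base).max() < 0.01 * base.max()


class TestAlignment:
    def test_self_match(self, volume_15r):
        ref = project(volume_15r, (30.0, 90.0, 0.0)).data
        refs = np.stack([np.roll(ref, 9, axis=0), ref])
        res = align_to_references(ref, refs, rot_step_deg=4.0)
        assert res.best_reference_index == 1
        assert res.in_plane_rotation_deg == 0.0
        assert np.allclose(res.shift_px, 0.0, atol=0.1)
        assert res.score > 0.999

    def test_recovers_constructed_rotation_and_shift(self, volume_15r, rng):
        ref = project(volume_15r, (30.0, 90.0, 0.0)).data
        refs = np.stack([rng.normal(size=ref.shape), ref,
                         np.roll(ref, 5, axis=1)])
        img = fourier_shift(ndimage.rotate(ref, 10.0, reshape=False, order=1),
                            (2.0, 3.0))
        res = align_to_references(img, refs, rot_step_deg=2.0, max_shift_px=5)
        assert res.best_reference_index == 1
        assert res.in_plane_rotation_deg == pytest.approx(10.0, abs=1.0)
        assert res.shift_px == pytest.approx((2.0, 3.0), abs=0.5)

    def test_empty_reference_stack_rejected(self, rng):
        img = rng.normal(size=(32, 32))
        with pytest.raises(ValueError, match="empty"):
            align_to_references(img, np.zeros((0, 32, 32)))

    def test_noise_image_shows_no_reference_preference(self, volume_15r, rng):
        """Best-matching reference for pure noise is uniform over the stack."""
        refs = np.stack([project(volume_15r, (p, 90.0, 0.0)).data
                         for p in (0.0, 90.0, 180.0, 270.0)])
        hits = np.zeros(4)
        for _ in range(60):
            res = align_to_references(rng.normal(size=refs.shape[1:]), refs,
                                      rot_step_deg=30.0, max_shift_px=2)
            hits[res.best_reference_index] += 1
        # chi-square against uniform: 3 dof, 99.9% quantile ~ 16.3
        chi2 = ((hits - 15.0) ** 2 / 15.0).sum()
        assert chi2 < 16.3


class TestFSC:
    def test_self_correlation_is_one(self, rng):
        vol = DensityVolume(rng.normal(size=(32, 32, 32)), 4.0)
        curve = fsc_curve(vol, vol)
        assert np.all(curve.fsc > 0.999)
        assert np.all(np.diff(curve.freq) > 0)

    def test_symmetry_in_arguments(self, rng):
        a = DensityVolume(rng.normal(size=(32, 32, 32)), 4.0)
        b = DensityVolume(rng.normal(size=(32, 32, 32)), 4.0)
        assert np.allclose(fsc_curve(a, b).fsc, fsc_curve(b, a).fsc, atol=1e-12)

    def test_independent_noise_is_null(self, rng):
        a = DensityVolume(rng.normal(size=(64, 64, 64)), 4.0)
        b = DensityVolume(rng.normal(size=(64, 64, 64)), 4.0)
        curve = fsc_curve(a, b)
        assert np.all(np.abs(curve.fsc) < 3.0 / np.sqrt(curve.counts))

    def test_fsc_matches_ssnr_closed_form(self, rng):
        """Half-maps with per-shell SSNR s give FSC = s/(s+1)."""
        sig = rng.normal(size=(64, 64, 64))
        for ssnr in (0.5, 2.0):
            a = DensityVolume(sig + rng.normal(size=sig.shape) / np.sqrt(ssnr), 4.0)
            b = DensityVolume(sig + rng.normal(size=sig.shape) / np.sqrt(ssnr), 4.0)
            curve = fsc_curve(a, b)
            good = curve.counts > 2000
            expected = ssnr / (ssnr + 1.0)
            assert np.abs(curve.fsc[good] - expected).max() < 0.05

    def test_all_zero_volume_rejected(self):
        z = DensityVolume(np.zeros((16, 16, 16)), 4.0)
        with pytest.raises(ValueError):
            fsc_curve(z, z)

    def test_resolution_linear_interpolation(self):
        curve = FSCCurve(np.array([0.01, 0.02, 0.03]),
                         np.array([1.0, 0.5, 0.0]), np.ones(3))
        # 0.143 crossing between 0.02 and 0.03: f = 0.02 + (0.357/0.5)*0.01
        assert resolution_at(curve, 0.143) == pytest.approx(
            1.0 / (0.02 + (0.5 - 0.143) / 0.5 * 0.01))

    def test_resolution_never_crossing_returns_nyquist(self):
        curve = FSCCurve(np.array([0.01, 0.125]), np.array([1.0, 0.9]),
                         np.ones(2))
        assert resolution_at(curve, 0.143) == pytest.approx(8.0)


class TestMask:
    def test_sphere_mask_hard_core_and_soft_shell(self):
        c = np.arange(64) - 32
        zz, yy, xx = np.meshgrid(c, c, c, indexing="ij")
        rr = np.sqrt(xx**2 + yy**2 + zz**2)
        vol = DensityVolume((rr <= 10).astype(float), 4.0)
        mask = make_fsc_mask(vol, dilate_px=2, soft_px=5)
        # hard core: support + 2 px dilation all at 1
        assert mask.data[rr <= 11].min() > 0.99
        # soft cosine shell decays to 0 beyond dilation + 5 px
        assert mask.data[rr >= 21].max() < 0.01
        assert 0.0 <= mask.data.min() and mask.data.max() <= 1.0

    def test_empty_support_rejected(self):
        vol = DensityVolume(np.zeros((16, 16, 16)), 4.0)
        with pytest.raises(ValueError):
            make_fsc_mask(vol)


class TestSpectral:
    def test_phase_randomization_preserves_power(self, volume_15r, rng):
        out = randomize_phases(volume_15r, 20.0, rng)
        p_in = np.abs(np.fft.fftn(volume_15r.data)) ** 2
        p_out = np.abs(np.fft.fftn(out.data)) ** 2
        assert np.abs(p_in - p_out).max() < 1e-6 * p_in.max()

    def test_low_frequencies_untouched_high_decorrelated(self, volume_15r, rng):
        out = randomize_phases(volume_15r, 20.0, rng)
        curve = fsc_curve(volume_15r, out)
        assert curve.fsc[curve.freq < 1.0 / 20.5].min() > 0.999
        assert np.abs(curve.fsc[curve.freq > 1.0 / 15.0]).mean() < 0.1

    def test_two_seeds_give_independent_references(self, volume_15r):
        rng = np.random.default_rng(7)
        a = randomize_phases(volume_15r, 20.0, rng)
        b = randomize_phases(volume_15r, 20.0, rng)
        curve = fsc_curve(a, b)
        assert np.abs(curve.fsc[curve.freq > 1.0 / 15.0]).mean() < 0.1

    def test_sharpen_identity_and_inverse(self, volume_15r):
        assert np.allclose(sharpen(volume_15r, 0.0).data, volume_15r.data,
                           atol=1e-9)
        round_trip = sharpen(sharpen(volume_15r, -130.0), 130.0)
        assert np.abs(round_trip.data - volume_15r.data).max() < 1e-9

    def test_sharpen_amplitude_ratio_formula(self, volume_15r):
        """B = -130 boosts each shell by exp(130 s^2 / 4)."""
        out = sharpen(volume_15r, -130.0)
        fa = np.abs(np.fft.fftn(volume_15r.data))
        fb = np.abs(np.fft.fftn(out.data))
        n = volume_15r.box
        freqs = np.fft.fftfreq(n, d=4.0)
        for shell in (5, 10, 15):
            s = freqs[shell]
            ratio = fb[0, 0, shell] / fa[0, 0, shell]
            assert ratio == pytest.approx(np.exp(130.0 * s**2 / 4.0), rel=1e-9)

    def test_parseval_preserved_by_b0_and_phase_randomization(self, volume_15r,
                                                              rng):
        power = (volume_15r.data ** 2).sum()
        assert (sharpen(volume_15r, 0.0).data ** 2).sum() == pytest.approx(power)
        assert (randomize_phases(volume_15r, 20.0, rng).data ** 2).sum() == \
            pytest.approx(power, rel=1e-9)

    def test_lowpass_removes_high_frequency_power(self, rng):
        img = rng.normal(size=(64, 64))
        out = lowpass_filter(img, 15.0, 4.0)
        f = np.fft.fftfreq(64, d=4.0)
        s = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)
        p = np.abs(np.fft.fft2(out)) ** 2
        assert p[s > 1.1 / 15.0].sum() < 0.01 * p.sum()


class TestMRC:
    def test_volume_round_trip(self, tmp_path, rng):
        data = rng.normal(size=(24, 24, 24)).astype(np.float32)
        path = tmp_path / "vol.mrc"
        write_mrc(path, data, 4.0)
        back, voxel = read_mrc(path)
        assert voxel == pytest.approx(4.0)
        assert np.allclose(back, data, atol=1e-6)

    def test_stack_round_trip(self, tmp_path, rng):
        data = rng.normal(size=(5, 16, 16)).astype(np.float32)
        path = tmp_path / "stack.mrcs"
        stack = ImageStack(data, 4.0)
        stack.write(path)
        back = ImageStack.read(path)
        assert back.pixel_size_A == pytest.approx(4.0)
        assert np.allclose(back.data, data, atol=1e-6)

    def test_garbage_rejected(self, tmp_path):
        path = tmp_path / "bad.mrc"
        path.write_bytes(b"\x00" * 2048)
        with pytest.raises(ValueError):
            read_mrc(path)


def test_normalize_image_support_statistics(rng):
    img = rng.normal(5.0, 3.0, size=(64, 64))
    from mthelix.imaging import circular_support

    sup = circular_support(64)
    out = normalize_image(img, sup)
    assert out[sup].mean() == pytest.approx(0.0, abs=1e-12)
    assert out[sup].std() == pytest.approx(1.0, abs=1e-12)
    assert np.all(out[~sup] == 0.0)
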