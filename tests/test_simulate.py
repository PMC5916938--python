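"""Synthetic data generators: determinism, SNR contract, CTF physics."""

import numpy as np
import pytest
from scipy import optimize

from mthelix.imaging import Image2D, circular_support, project
from mthelix.lattice import HelicalSymmetry, LatticeSpec, SpiralSpec
from mthelix.simulate import (CTFParams, FilamentTypeMix, RingMix, SimConfig,
                              apply_ctf, ctf_transfer,
                              generate_filament_dataset, generate_micrograph,
                              generate_ring_dataset, render_reference_volume)

SYM_15R = HelicalSymmetry(168.083, 5.50)


def _filament_config(seed=7, snr=0.5, n_seg=8):
    return SimConfig(seed=seed, filament_types=[
        FilamentTypeMix(LatticeSpec(15, "R"), 2, SYM_15R),
        FilamentTypeMix(LatticeSpec(13, "L"), 1)],
        n_segments_per_filament=n_seg, snr=snr)


class TestFilamentDataset:
    def test_same_seed_is_byte_identical(self):
        a = generate_filament_dataset(_filament_config())
        b = generate_filament_dataset(_filament_config())
        assert np.array_equal(a[0].data, b[0].data)
        assert a[1].equals(b[1])
        assert a[2].filaments == b[2].filaments

    def test_type_counts_match_config(self):
        _, table, manifest = generate_filament_dataset(_filament_config())
        counts = table["true_type"].value_counts().to_dict()
        assert counts == {"15R": 16, "13L": 8}
        assert len(manifest.filaments) == 3
        assert all(len(f["segments"]) == 8 for f in manifest.filaments)

    def test_requested_snr_is_delivered(self):
        """Measured signal/noise variance ratio in the support tracks config."""
        noisy = generate_filament_dataset(_filament_config(seed=3, snr=0.5,
                                                           n_seg=20))[0]
        clean = generate_filament_dataset(_filament_config(seed=3, snr=None,
                                                           n_seg=20))[0]
        sup = circular_support(noisy.data.shape[1])
        noise = noisy.data - clean.data
        ratios = [clean.data[i][sup].var() / noise[i][sup].var()
                  for i in range(len(noisy))]
        assert np.mean(ratios) == pytest.approx(0.5, rel=0.10)

    def test_manifest_orientations_are_exact(self):
        """Projecting the canonical model at the recorded parameters
        reproduces each noiseless segment."""
        cfg = SimConfig(seed=21, filament_types=[
            FilamentTypeMix(LatticeSpec(15, "R"), 1, SYM_15R)],
            n_segments_per_filament=4, snr=None, axis_wobble_amp_px=0.0,
            pick_jitter_px=0.0)
        stack, table, manifest = generate_filament_dataset(cfg)
        vol = render_reference_volume(manifest.filaments[0], 96)
        lo = (96 - 64) // 2
        from mthelix.imaging import align_to_references

        for i, (_, row) in enumerate(table.iterrows()):
            ref = project(vol, (row.phi, 90.0, row.psi)).data[lo:lo + 64,
                                                              lo:lo + 64]
            res = align_to_references(stack.data[i], ref[None],
                                      rot_step_deg=1.0, rot_range=(-1, 1.5),
                                      max_shift_px=4)
            assert res.score > 0.9
            assert res.shift_px == pytest.approx((row.sx, row.sy), abs=0.3)

    def test_half_sets_split_filaments(self):
        _, table, _ = generate_filament_dataset(_filament_config())
        for _, grp in table.groupby("filament_id"):
            assert set(grp["half_set"]) == {1, 2}
            # halves are contiguous filament halves
            h1 = grp[grp.half_set == 1]["segment_idx"]
            assert h1.max() < grp[grp.half_set == 2]["segment_idx"].min()


class TestRingDataset:
    def test_decoration_blob_counts(self):
        """every_other on 14 dimers -> 7 kinesins; every on 15 -> 15."""
        cfg = SimConfig(seed=5, ring_types=[
            RingMix(SpiralSpec(360 / 14, 0.0, 14,
                               decoration="every_other_dimer"), 1),
            RingMix(SpiralSpec(24.0, 0.0, 15, decoration="every_dimer"), 1)],
            snr=None)
        stack, manifest = generate_ring_dataset(cfg)
        from mthelix.rings import _angular_profile, _kinesin_radius, _radial_profile

        for img, rec, expected in zip(stack.data, manifest.rings, (7, 15)):
            prof = _radial_profile(img)
            rt = float(np.argmax(prof[:69]))
            rk = _kinesin_radius(img, rt)
            ang = _angular_profile(img, rk)
            spec = np.abs(np.fft.rfft(ang - ang.mean()))
            assert np.argmax(spec[3:25]) + 3 == expected

    def test_determinism(self):
        cfg = SimConfig(seed=9, ring_types=[RingMix(SpiralSpec(24.0, 0.0, 15), 3)],
                        snr=0.3)
        a, _ = generate_ring_dataset(cfg)
        b, _ = generate_ring_dataset(cfg)
        assert np.array_equal(a.data, b.data)

    def test_blob_angular_spacing(self):
        """15 dimers -> 24 degree spacing of kinesin blobs."""
        cfg = SimConfig(seed=5, ring_types=[
            RingMix(SpiralSpec(24.0, 0.0, 15, decoration="every_dimer"), 1)],
            snr=None)
        stack, _ = generate_ring_dataset(cfg)
        from mthelix.rings import _angular_profile, _kinesin_radius, _radial_profile

        img = stack.data[0]
        prof = _radial_profile(img)
        rt = float(np.argmax(prof[:69]))
        ang = _angular_profile(img, _kinesin_radius(img, rt), n_samples=3600)
        spec = np.abs(np.fft.rfft(ang - ang.mean()))
        k = int(np.argmax(spec[3:40])) + 3
        assert 360.0 / k == pytest.approx(24.0, abs=0.1)


class TestCTF:
    def test_zero_frequency_is_amplitude_contrast(self):
        ctf = CTFParams(defocus_um=1.6)
        assert ctf_transfer(np.array([0.0]), ctf)[0] == pytest.approx(-0.07)

    def test_phase_flip_after_full_ctf_is_nonnegative(self, rng):
        ctf = CTFParams(defocus_um=1.6, pixel_size_A=4.0)
        img = Image2D(rng.normal(size=(64, 64)), 4.0)
        full = apply_ctf(img, ctf, "full")
        flipped = apply_ctf(full, ctf, "phase_flip_correct")
        # effective transfer = |CTF|: check on the Fourier plane directly
        f = np.fft.fftfreq(64, d=4.0)
        s = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)
        h_eff = np.fft.fft2(flipped.data) / np.where(
            np.abs(np.fft.fft2(img.data)) > 1e-12, np.fft.fft2(img.data), 1.0)
        assert np.all(np.real(h_eff) > -1e-9)
        assert np.allclose(np.real(h_eff), np.abs(ctf_transfer(s, ctf)),
                           atol=1e-9)

    def test_first_zero_matches_numeric_root(self):
        """First sign change of the transfer at 1.6 um / 300 kV equals the
        root of the phase equation found independently by bisection."""
        ctf = CTFParams(defocus_um=1.6, voltage_kV=300.0)
        s = np.linspace(1e-4, 0.1, 20000)
        vals = ctf_transfer(s, ctf)
        scan_root = s[np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]]

        lam, dz, cs = ctf.wavelength_A, 1.6e4, 2.7e7
        a = ctf.amplitude_contrast
        # analytic zero condition: tan(chi) = -A / sqrt(1 - A^2), first branch
        chi_star = np.pi - np.arctan(a / np.sqrt(1 - a**2))

        def chi_of(si):
            return np.pi * lam * dz * si**2 - 0.5 * np.pi * cs * lam**3 * si**4

        bisect_root = optimize.brentq(lambda si: chi_of(si) - chi_star,
                                      1e-4, 0.1)
        assert scan_root == pytest.approx(bisect_root, abs=1.0 / (64 * 4.0))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CTFParams(defocus_um=-1.0)
        with pytest.raises(ValueError):
            CTFParams(amplitude_contrast=1.5)


def test_micrograph_contains_filament_on_true_axis():
    from scipy import ndimage

    cfg = SimConfig(seed=5, snr=None)
    mix = FilamentTypeMix(LatticeSpec(15, "R"), 1, SYM_15R)
    micro, picks, truth = generate_micrograph(cfg, mix, 512)
    vals = ndimage.map_coordinates(micro.data, [truth[:, 1], truth[:, 0]],
                                   order=1)
    assert vals.mean() > 5 * np.abs(micro.data).mean()
    assert len(picks) == len(truth)
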