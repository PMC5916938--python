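"""Density rendering, projection, 2D alignment, spectral filters, and FSC.

Numerical kernels shared by every pipeline stage. Conventions, used
everywhere in the package:

* Volumes are (nz, ny, nx) grids; images are (ny, nx). The coordinate origin
  sits at the box centre voxel ``n // 2``.
* Euler angles are ZYZ intrinsic, ``R = Rz(phi) @ Ry(theta) @ Rz(psi)``; a
  projection integrates the volume along the viewing axis ``R @ z``, and psi
  is the in-plane rotation of the projection.
* Real-space rotations/shifts use linear interpolation; pure translations may
  be applied as exact Fourier phase ramps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .mrcio import read_mrc, write_mrc

__all__ = [
    "DensityVolume", "Image2D", "ImageStack", "AlignmentResult", "FSCCurve",
    "euler_to_matrix", "render_density", "project", "normalize_image",
    "align_to_references", "fsc_curve", "resolution_at", "make_fsc_mask",
    "randomize_phases", "sharpen", "lowpass_filter", "fourier_shift",
]


@dataclass
class DensityVolume:
    """3D scalar grid with physical voxel size (Angstrom)."""

    data: np.ndarray
    voxel_size_A: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("DensityVolume needs a 3D grid")
        if not self.voxel_size_A > 0:
            raise ValueError("voxel_size_A must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("DensityVolume must be finite")

    @property
    def box(self) -> int:
        return self.data.shape[0]

    def copy(self, data=None) -> "DensityVolume":
        return DensityVolume(self.data.copy() if data is None else data,
                             self.voxel_size_A, dict(self.meta))

    def write(self, path) -> None:
        write_mrc(path, self.data, self.voxel_size_A)

    @classmethod
    def read(cls, path) -> "DensityVolume":
        data, voxel = read_mrc(path)
        return cls(data, voxel)


@dataclass
class Image2D:
    """2D scalar grid with physical pixel size (Angstrom)."""

    data: np.ndarray
    pixel_size_A: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError("Image2D must be a square 2D grid")
        if not self.pixel_size_A > 0:
            raise ValueError("pixel_size_A must be > 0")


@dataclass
class ImageStack:
    """Stack of same-size square images with shared pixel size."""

    data: np.ndarray
    pixel_size_A: float
    meta: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != self.data.shape[2]:
            raise ValueError("ImageStack must be (n, box, box)")
        if not self.pixel_size_A > 0:
            raise ValueError("pixel_size_A must be > 0")

    def __len__(self):
        return len(self.data)

    def __getitem__(self, i) -> Image2D:
        meta = self.meta[i] if i < len(self.meta) else {}
        return Image2D(self.data[i], self.pixel_size_A, dict(meta))

    def write(self, path) -> None:
        write_mrc(path, self.data, self.pixel_size_A, is_stack=True)

    @classmethod
    def read(cls, path) -> "ImageStack":
        data, pixel = read_mrc(path)
        if data.ndim == 2:
            data = data[None]
        return cls(data, pixel)


@dataclass
class AlignmentResult:
    best_reference_index: int
    in_plane_rotation_deg: float
    shift_px: np.ndarray  # (sx, sy)
    score: float


@dataclass
class FSCCurve:
    """Fourier shell correlation: per-shell frequency (1/A), correlation, count."""

    freq: np.ndarray
    fsc: np.ndarray
    counts: np.ndarray

    def to_tsv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.freq, self.fsc]),
                   delimiter="\t", header="freq_invA\tfsc", comments="")


# ---- geometry helpers -------------------------------------------------------


def euler_to_matrix(phi_deg: float, theta_deg: float, psi_deg: float) -> np.ndarray:
    """ZYZ intrinsic rotation matrix Rz(phi) @ Ry(theta) @ Rz(psi)."""
    from scipy.spatial.transform import Rotation

    return Rotation.from_euler("ZYZ", [phi_deg, theta_deg, psi_deg],
                               degrees=True).as_matrix()


def _centered_coords(n: int) -> np.ndarray:
    return np.arange(n, dtype=float) - n // 2


def fourier_shift(img: np.ndarray, shift_xy) -> np.ndarray:
    """Translate an image by (sx, sy) pixels via an exact Fourier phase ramp."""
    sx, sy = shift_xy
    ny, nx = img.shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    ramp = np.exp(-2j * np.pi * (fx * sx + fy * sy))
    return np.real(np.fft.ifft2(np.fft.fft2(img) * ramp))


# ---- rendering & projection -------------------------------------------------


def render_density(model, voxel_size_A: float, box_px: int,
                   sigma_vox: float = 1.0) -> DensityVolume:
    """Render a pseudo-atomic model as a sum of isotropic Gaussian kernels.

    Each atom contributes a Gaussian of width ``sigma_vox`` voxels whose
    discrete sum equals the atom's mass weight, so the grid total equals the
    model's total weight. Atoms whose kernel support leaves the box raise an
    error naming the offending subunit.
    """
    half = box_px // 2
    reach = int(np.ceil(4.0 * sigma_vox))
    grid = np.zeros((box_px, box_px, box_px))
    # voxel index of each atom (x, y, z order -> ix, iy, iz)
    vox = model.positions / voxel_size_A + half
    centers = np.round(vox).astype(int)
    lo = centers - reach
    hi = centers + reach
    bad = np.any(lo < 0, axis=1) | np.any(hi > box_px - 1, axis=1)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValueError(
            "model exceeds render box at subunit "
            f"(pf={model.pf_index[i]}, dimer={model.dimer_index[i]}, "
            f"kind={model.monomer_kind[i]})")
    offsets = np.arange(-reach, reach + 1, dtype=float)
    for (cx, cy, cz), (vx, vy, vz), w in zip(centers, vox, model.weights):
        gx = np.exp(-((cx + offsets - vx) ** 2) / (2 * sigma_vox**2))
        gy = np.exp(-((cy + offsets - vy) ** 2) / (2 * sigma_vox**2))
        gz = np.exp(-((cz + offsets - vz) ** 2) / (2 * sigma_vox**2))
        kernel = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        kernel *= w / kernel.sum()
        grid[cz - reach:cz + reach + 1,
             cy - reach:cy + reach + 1,
             cx - reach:cx + reach + 1] += kernel
    return DensityVolume(grid, voxel_size_A, {"render_sigma_vox": sigma_vox})


def project(vol: DensityVolume, euler_deg=(0.0, 0.0, 0.0), shift_px=(0.0, 0.0)
            ) -> Image2D:
    """Parallel-beam projection of a volume at a ZYZ-intrinsic orientation.

    The image value at (x, y) is the line integral of the volume along the
    rotated viewing axis; an optional in-plane shift is applied afterwards as
    an exact Fourier phase ramp.
    """
    n = vol.box
    R = euler_to_matrix(*euler_deg)
    c = _centered_coords(n)
    # image-frame coordinates (x, y, z'), world = R @ r
    zz, yy, xx = np.meshgrid(c, c, c, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()])
    world = R @ pts
    half = n // 2
    idx = np.stack([world[2] + half, world[1] + half, world[0] + half])
    samples = ndimage.map_coordinates(vol.data, idx, order=1, cval=0.0)
    img = samples.reshape(n, n, n).sum(axis=0)
    if shift_px[0] != 0 or shift_px[1] != 0:
        img = fourier_shift(img, shift_px)
    return Image2D(img, vol.voxel_size_A,
                   {"euler_deg": tuple(euler_deg), "shift_px": tuple(shift_px)})


# ---- alignment --------------------------------------------------------------


def circular_support(box: int, radius_px: float | None = None) -> np.ndarray:
    if radius_px is None:
        radius_px = box / 2.0 - 1.0
    c = _centered_coords(box)
    rr = np.hypot(c[:, None], c[None, :])
    return rr <= radius_px


def normalize_image(img: np.ndarray, support: np.ndarray | None = None
                    ) -> np.ndarray:
    """Zero-mean, unit-variance within a circular support; zero outside."""
    if support is None:
        support = circular_support(img.shape[0])
    out = np.zeros_like(img, dtype=float)
    vals = img[support]
    sd = vals.std()
    if sd == 0:
        return out
    out[support] = (vals - vals.mean()) / sd
    return out


def _rotate_image(img: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate an image counter-clockwise (in x-y coordinates) about its centre."""
    if angle_deg == 0:
        return img
    return ndimage.rotate(img, angle_deg, reshape=False, order=1, mode="constant")


def _shift_window_peak(corr: np.ndarray, max_shift: int):
    """Best circular-correlation peak within |dx|,|dy| <= max_shift.

    Returns (score, (dx, dy)) with sub-pixel parabolic refinement.
    """
    n = corr.shape[0]
    offs = np.r_[np.arange(0, max_shift + 1), np.arange(-max_shift, 0)]
    window = corr[np.ix_(offs % n, offs % n)]
    iy, ix = np.unravel_index(np.argmax(window), window.shape)
    dy, dx = float(offs[iy]), float(offs[ix])
    score = window[iy, ix]

    def parabolic(fm, f0, fp):
        denom = fm - 2 * f0 + fp
        return 0.0 if denom >= 0 else float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))

    dym = corr[int(dy - 1) % n, int(dx) % n]
    dyp = corr[int(dy + 1) % n, int(dx) % n]
    dxm = corr[int(dy) % n, int(dx - 1) % n]
    dxp = corr[int(dy) % n, int(dx + 1) % n]
    dy += parabolic(dym, score, dyp)
    dx += parabolic(dxm, score, dxp)
    return float(score), (dx, dy)


def align_to_references(img, refs, rot_step_deg: float = 2.0,
                        max_shift_px: int = 5, rot_range=(0.0, 360.0),
                        return_scores: bool = False):
    """Exhaustive rotation x FFT-translation alignment against a reference stack.

    Finds the reference and in-plane (rotation, shift) such that
    ``img ~ shift(rotate(ref, rot), shift_px)``. Both image and references are
    normalized to zero mean / unit variance inside a circular support before
    correlation, so the score approximates a correlation coefficient. Ties are
    broken deterministically: lowest reference index, then smallest rotation.
    """
    img_arr = img.data if isinstance(img, Image2D) else np.asarray(img, float)
    ref_arr = refs.data if isinstance(refs, ImageStack) else np.asarray(refs, float)
    if ref_arr.ndim == 2:
        ref_arr = ref_arr[None]
    if len(ref_arr) == 0:
        raise ValueError("empty reference stack")
    if ref_arr.shape[1:] != img_arr.shape:
        raise ValueError("image and references must have the same box size")
    if (isinstance(img, Image2D) and isinstance(refs, ImageStack)
            and img.pixel_size_A != refs.pixel_size_A):
        raise ValueError("image and reference pixel sizes differ")

    box = img_arr.shape[0]
    support = circular_support(box)
    nsup = support.sum()
    refs_n = np.stack([normalize_image(r, support) for r in ref_arr])
    refs_f_conj = np.conj(np.fft.fft2(refs_n))

    angles = np.arange(rot_range[0], rot_range[1], rot_step_deg)
    n_ref = len(ref_arr)
    scores = np.full((n_ref, len(angles)), -np.inf)
    shifts = np.zeros((n_ref, len(angles), 2))
    for ia, ang in enumerate(angles):
        # if img = rotate(ref, ang) + shift, then rotate(img, -ang) matches ref
        rot = normalize_image(_rotate_image(img_arr, -ang), support)
        rot_f = np.fft.fft2(rot)
        corr = np.real(np.fft.ifft2(rot_f[None] * refs_f_conj)) / nsup
        for ir in range(n_ref):
            s, (dx, dy) = _shift_window_peak(corr[ir], max_shift_px)
            scores[ir, ia] = s
            # peak (dx, dy): rotate(img, -ang) ~ ref shifted by (dx, dy);
            # un-rotating maps the shift back into the image frame. ndimage
            # rotates CCW in (row, col), i.e. CW in (x, y), hence the signs.
            ca, sa = np.cos(np.radians(ang)), np.sin(np.radians(ang))
            shifts[ir, ia] = (ca * dx + sa * dy, -sa * dx + ca * dy)
    flat = int(np.argmax(scores))  # C-order argmax: lowest ref, then smallest angle
    ir, ia = np.unravel_index(flat, scores.shape)
    best_rot = float(angles[ia])
    if 0 < ia < len(angles) - 1:
        # sub-grid rotation refinement on the correlation parabola
        fm, f0, fp = scores[ir, ia - 1], scores[ir, ia], scores[ir, ia + 1]
        d = fm - 2 * f0 + fp
        if d < 0:
            best_rot += float(np.clip(0.5 * (fm - fp) / d, -0.5, 0.5)) \
                * rot_step_deg
    result = AlignmentResult(int(ir), best_rot, shifts[ir, ia].copy(),
                             float(np.clip(scores[ir, ia], -1.0, 1.0)))
    if return_scores:
        return result, scores
    return result


# ---- spectral operations ----------------------------------------------------


def _freq_grid(shape, voxel_size_A: float):
    """|s| in 1/A on the full FFT grid."""
    axes = [np.fft.fftfreq(n, d=voxel_size_A) for n in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(sum(g**2 for g in grids))


def lowpass_filter(arr: np.ndarray, cutoff_A: float, voxel_size_A: float,
                   edge_frac: float = 0.1) -> np.ndarray:
    """Radial low-pass with a raised-cosine edge around 1/cutoff_A."""
    s = _freq_grid(arr.shape, voxel_size_A)
    sc = 1.0 / cutoff_A
    width = max(edge_frac * sc, 1.0 / (arr.shape[0] * voxel_size_A))
    t = np.clip((s - sc) / width, 0.0, 1.0)
    mask = 0.5 * (1.0 + np.cos(np.pi * t))
    return np.real(np.fft.ifftn(np.fft.fftn(arr) * mask))


def fsc_curve(vol_a, vol_b, mask: DensityVolume | None = None) -> FSCCurve:
    """Fourier shell correlation between two volumes on identical grids."""
    a = vol_a.data if isinstance(vol_a, DensityVolume) else np.asarray(vol_a, float)
    b = vol_b.data if isinstance(vol_b, DensityVolume) else np.asarray(vol_b, float)
    voxel = vol_a.voxel_size_A if isinstance(vol_a, DensityVolume) else 1.0
    if a.shape != b.shape:
        raise ValueError("FSC requires identical grids")
    if not a.any() or not b.any():
        raise ValueError("FSC of an all-zero volume is undefined")
    if mask is not None:
        m = mask.data if isinstance(mask, DensityVolume) else np.asarray(mask)
        a = a * m
        b = b * m
    n = a.shape[0]
    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    # integer shell index = rounded |k| in index units
    axes = [np.fft.fftfreq(dim) * dim for dim in a.shape]
    kk = np.sqrt(sum(g**2 for g in np.meshgrid(*axes, indexing="ij")))
    shell = np.minimum(np.round(kk).astype(int), n // 2)
    nshell = n // 2 + 1
    cross = np.bincount(shell.ravel(), np.real(fa * np.conj(fb)).ravel(), nshell)
    pa = np.bincount(shell.ravel(), np.abs(fa).ravel() ** 2, nshell)
    pb = np.bincount(shell.ravel(), np.abs(fb).ravel() ** 2, nshell)
    counts = np.bincount(shell.ravel(), minlength=nshell)
    denom = np.sqrt(pa * pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        fsc = np.where(denom > 0, cross / denom, 0.0)
    freq = np.arange(1, nshell) / (n * voxel)
    return FSCCurve(freq, np.clip(fsc[1:], -1.0, 1.0), counts[1:])


def resolution_at(curve: FSCCurve, threshold: float = 0.143) -> float:
    """Resolution (A) at the first downward threshold crossing of an FSC curve.

    Linear interpolation between shells; if the curve never drops below the
    threshold the Nyquist resolution (finest measurable) is returned.
    """
    fsc, freq = curve.fsc, curve.freq
    below = np.nonzero(fsc < threshold)[0]
    if len(below) == 0:
        return float(1.0 / freq[-1])
    i = below[0]
    if i == 0:
        return float(1.0 / freq[0])
    f0, f1 = fsc[i - 1], fsc[i]
    frac = (f0 - threshold) / (f0 - f1)
    crossing = freq[i - 1] + frac * (freq[i] - freq[i - 1])
    return float(1.0 / crossing)


def make_fsc_mask(vol: DensityVolume, lowpass_A: float = 12.0,
                  threshold_frac: float = 0.1, dilate_px: int = 2,
                  soft_px: int = 5) -> DensityVolume:
    """Soft solvent mask: 12 A low-pass, threshold, 2 px dilation, 5 px cosine edge."""
    lp = lowpass_filter(vol.data, lowpass_A, vol.voxel_size_A)
    support = lp > threshold_frac * lp.max()
    if not support.any():
        raise ValueError("mask threshold leaves empty support")
    dist = ndimage.distance_transform_edt(~support)
    t = np.clip((dist - dilate_px) / soft_px, 0.0, 1.0)
    mask = 0.5 * (1.0 + np.cos(np.pi * t))
    return DensityVolume(mask, vol.voxel_size_A, {"mask_of": vol.meta.get("name")})


def randomize_phases(vol: DensityVolume, beyond_A: float,
                     rng: np.random.Generator) -> DensityVolume:
    """Replace Fourier phases beyond 1/beyond_A with random ones.

    Amplitudes are preserved at every frequency and Friedel symmetry is
    enforced, so the output is real with an unchanged power spectrum.
    """
    if beyond_A < 2.0 * vol.voxel_size_A:
        raise ValueError("phase randomization cutoff finer than Nyquist")
    F = np.fft.fftn(vol.data)
    s = _freq_grid(vol.data.shape, vol.voxel_size_A)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=F.shape)
    rev = phases
    for ax in range(phases.ndim):
        rev = np.roll(np.flip(rev, axis=ax), 1, axis=ax)
    anti = phases - rev  # antisymmetric under k -> -k, keeps output real
    beyond = s > 1.0 / beyond_A
    F_new = np.where(beyond, np.abs(F) * np.exp(1j * anti), F)
    out = np.real(np.fft.ifftn(F_new))
    return DensityVolume(out, vol.voxel_size_A, dict(vol.meta))


def sharpen(vol: DensityVolume, b_factor_A2: float) -> DensityVolume:
    """B-factor amplitude correction exp(-B s^2 / 4); negative B sharpens."""
    s = _freq_grid(vol.data.shape, vol.voxel_size_A)
    F = np.fft.fftn(vol.data) * np.exp(-b_factor_A2 * s**2 / 4.0)
    return DensityVolume(np.real(np.fft.ifftn(F)), vol.voxel_size_A, dict(vol.meta))
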