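"""Helical 3D reconstruction: back-projection, symmetry search/imposition,
and independent half-set (gold-standard) refinement.

The reconstruction engine follows the classic filament single-particle
scheme: Fourier-slice back-projection of aligned segment images, real-space
imposition of the per-dimer helical screw, and projection-matching refinement
run completely independently on two data halves (split by filament half)
whose starting references are decorrelated by phase randomization beyond
20 A. Per-round reference filtering uses the resolution estimated from a
further quarter split of each half, and the data entering alignment are
limited to 10 A then 8 A as refinement proceeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .imaging import (DensityVolume, ImageStack, align_to_references,
                      fourier_shift, fsc_curve, lowpass_filter, project,
                      randomize_phases, resolution_at)
from .lattice import HelicalSymmetry

__all__ = [
    "ReconstructionState", "SymmetryEstimate", "backproject",
    "impose_helical_symmetry", "estimate_symmetry", "refine_gold_standard",
    "gold_standard_fsc",
]

REQUIRED_COLUMNS = ("filament_id", "segment_idx", "phi", "theta", "psi",
                    "sx", "sy", "half_set")


@dataclass
class SymmetryEstimate:
    symmetry: HelicalSymmetry
    correlation: float
    confidence: float
    low_confidence: bool


@dataclass
class ReconstructionState:
    half_volumes: tuple
    symmetry: HelicalSymmetry
    resolution_history: list = field(default_factory=list)
    rounds_run: int = 0
    data_limit_A: float | None = None
    tables: tuple | None = None


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"particle table missing columns: {missing}")


# ---- back-projection --------------------------------------------------------


def backproject(stack: ImageStack, table: pd.DataFrame,
                voxel_size_A: float | None = None) -> DensityVolume:
    """Fourier-slice back-projection of aligned segment images.

    Each image's centred 2D transform is inserted as a central slice at its
    ZYZ orientation with trilinear spreading and per-voxel weight
    normalization; shifts are removed beforehand by exact phase ramps.
    Empty Fourier regions stay zero.
    """
    _check_table(table)
    if len(stack) == 0:
        raise ValueError("no particles to backproject")
    if len(table) != len(stack):
        raise ValueError("particle table and stack length differ")
    voxel = voxel_size_A or stack.pixel_size_A
    if abs(voxel - stack.pixel_size_A) > 1e-9:
        raise ValueError("image pixel size does not match requested voxel size")
    acc, wts = _fourier_insert(stack, table)
    return _grid_to_volume(acc, wts, voxel, stack.data.shape[1])


_OVERSAMPLE = 2  # Fourier oversampling factor for slice insertion


def _fourier_insert(stack: ImageStack, table: pd.DataFrame):
    from .imaging import euler_to_matrix

    n0 = stack.data.shape[1]
    n = _OVERSAMPLE * n0
    half = n // 2
    pad = (n - n0) // 2
    acc = np.zeros((n, n, n), dtype=complex)
    wts = np.zeros((n, n, n))
    c = np.arange(n) - half
    ky, kx = np.meshgrid(c, c, indexing="ij")
    k2 = np.stack([kx.ravel(), ky.ravel(), np.zeros(n * n)])

    for img, (_, row) in zip(stack.data, table.iterrows()):
        recentred = fourier_shift(img, (-row["sx"], -row["sy"]))
        padded = np.zeros((n, n))
        padded[pad:pad + n0, pad:pad + n0] = recentred
        F = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(padded))).ravel()
        R = euler_to_matrix(row["phi"], row["theta"], row["psi"])
        coords = (R @ k2) + half  # (3, n*n) in x, y, z index order
        x, y, z = coords
        inside = ((x >= 0) & (x <= n - 1 - 1e-9) & (y >= 0) & (y <= n - 1 - 1e-9)
                  & (z >= 0) & (z <= n - 1 - 1e-9))
        x, y, z, Fv = x[inside], y[inside], z[inside], F[inside]
        x0, y0, z0 = np.floor(x).astype(int), np.floor(y).astype(int), \
            np.floor(z).astype(int)
        fx, fy, fz = x - x0, y - y0, z - z0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (np.where(dx, fx, 1 - fx) * np.where(dy, fy, 1 - fy)
                         * np.where(dz, fz, 1 - fz))
                    idx = np.ravel_multi_index(
                        (z0 + dz, y0 + dy, x0 + dx), (n, n, n), mode="clip")
                    np.add.at(acc.ravel(), idx, w * Fv)
                    np.add.at(wts.ravel(), idx, w)
    return acc, wts


def _grid_to_volume(acc: np.ndarray, wts: np.ndarray, voxel: float,
                    out_box: int) -> DensityVolume:
    with np.errstate(invalid="ignore"):
        V = np.where(wts > 1e-6, acc / np.maximum(wts, 1e-6), 0.0)
    V = np.fft.ifftshift(V)
    rev = V
    for ax in range(3):
        rev = np.roll(np.flip(rev, axis=ax), 1, axis=ax)
    V = 0.5 * (V + np.conj(rev))  # enforce Friedel symmetry
    vol = np.real(np.fft.fftshift(np.fft.ifftn(V)))
    n = vol.shape[0]
    lo = (n - out_box) // 2
    vol = vol[lo:lo + out_box, lo:lo + out_box, lo:lo + out_box]
    return DensityVolume(np.ascontiguousarray(vol), voxel)


# ---- helical symmetry -------------------------------------------------------


def impose_helical_symmetry(vol: DensityVolume, sym: HelicalSymmetry,
                            z_fraction: float = 0.8, order: int = 3
                            ) -> DensityVolume:
    """Average a volume over its helical screw operations.

    Source samples are drawn only from the central ``z_fraction`` of the box
    (whose density is fully surrounded by lattice and, after one pass,
    exactly screw-symmetric — making the operation idempotent there); every
    output voxel averages over all screw powers that map it into that window.
    ``order`` picks the interpolation spline: 3 is fast and adequate inside
    refinement loops, 5 minimizes resampling loss on final band-limited maps.
    """
    if sym.rise_A < 0.5 * vol.voxel_size_A:
        raise ValueError("rise below half a voxel: symmetrization undersampled")
    n = vol.box
    half_A = n * vol.voxel_size_A / 2.0
    # every screw power that can source a voxel inside the central z_fraction
    kmax = int(np.ceil((1.0 + z_fraction) * half_A / sym.rise_A))
    half = n // 2
    lo_src = half - z_fraction * half
    hi_src = half + z_fraction * half
    c = np.arange(n, dtype=float) - half
    yy, xx = np.meshgrid(c, c, indexing="ij")
    rr_ok = np.hypot(xx, yy) <= half  # rotation keeps this disc inside the box
    acc = np.zeros_like(vol.data)
    cnt = np.zeros_like(vol.data)
    rise_vox = sym.rise_A / vol.voxel_size_A
    filtered = ndimage.spline_filter(vol.data, order=order)
    for k in range(-kmax, kmax + 1):
        # output z-slices whose source slice lies inside the central window
        z0 = max(0, int(np.ceil(lo_src + k * rise_vox)))
        z1 = min(n - 1, int(np.floor(hi_src + k * rise_vox)))
        if z0 > z1:
            continue
        th = np.radians(-k * sym.twist_deg)
        ct, st = np.cos(th), np.sin(th)
        ix = ct * xx - st * yy + half
        iy = st * xx + ct * yy + half
        nz = z1 - z0 + 1
        iz = (np.arange(z0, z1 + 1, dtype=float) - k * rise_vox)[:, None, None]
        coords = [np.broadcast_to(iz, (nz, n, n)),
                  np.broadcast_to(iy[None], (nz, n, n)),
                  np.broadcast_to(ix[None], (nz, n, n))]
        samp = ndimage.map_coordinates(filtered, coords, order=order,
                                       prefilter=False, cval=0.0)
        acc[z0:z1 + 1] += np.where(rr_ok[None], samp, 0.0)
        cnt[z0:z1 + 1] += rr_ok[None]
    out = np.where(cnt > 0, acc / np.maximum(cnt, 1), vol.data)
    return DensityVolume(out, vol.voxel_size_A, dict(vol.meta))


def _screw_correlation_factory(vol: DensityVolume, rise_max_A: float,
                               subsample: int = 2):
    """Closure evaluating real-space self-correlation under a screw."""
    n = vol.box
    half = n // 2
    margin = int(np.ceil(rise_max_A / vol.voxel_size_A)) + 2
    c = np.arange(margin, n - margin, subsample) - half
    cxy = np.arange(0, n, subsample) - half
    zz, yy, xx = np.meshgrid(c, cxy, cxy, indexing="ij")
    rr = np.hypot(xx, yy)
    keep = rr <= (half - 2)
    xx, yy, zz = xx[keep], yy[keep], zz[keep]
    filtered = ndimage.spline_filter(vol.data, order=3)
    ref = ndimage.map_coordinates(
        filtered, [zz + half, yy + half, xx + half], order=3, prefilter=False)
    ref = ref - ref.mean()
    ref_sd = ref.std()

    def corr(twist_deg: float, rise_A: float) -> float:
        th = np.radians(-twist_deg)
        ct, st = np.cos(th), np.sin(th)
        xs = ct * xx - st * yy + half
        ys = st * xx + ct * yy + half
        zs = zz - rise_A / vol.voxel_size_A + half
        samp = ndimage.map_coordinates(filtered, [zs, ys, xs], order=3,
                                       prefilter=False)
        samp = samp - samp.mean()
        sd = samp.std()
        if sd == 0 or ref_sd == 0:
            return 0.0
        return float(np.dot(ref, samp) / (len(ref) * ref_sd * sd))

    return corr


def estimate_symmetry(vol: DensityVolume, twist_range_deg=(160.0, 175.0),
                      rise_range_A=(4.0, 7.0), grid_steps=(0.1, 0.1),
                      polish: bool = True, subsample: int = 2
                      ) -> SymmetryEstimate:
    """Grid search for the helical screw maximizing real-space self-correlation.

    Correlates the central region of the volume with its screw-transformed
    copy over a (twist, rise) grid (``grid_steps`` in degrees / Angstrom),
    refines the best node by separable parabolic interpolation and an
    optional simplex polish. Confidence is the peak's prominence over the
    landscape median in median-absolute-deviation units; a flat landscape is
    flagged low-confidence.
    """
    corr = _screw_correlation_factory(vol, rise_range_A[1], subsample)
    twists = np.arange(twist_range_deg[0], twist_range_deg[1] + 1e-9,
                       grid_steps[0])
    rises = np.arange(rise_range_A[0], rise_range_A[1] + 1e-9, grid_steps[1])
    scores = np.array([[corr(t, r) for r in rises] for t in twists])
    it, ir = np.unravel_index(np.argmax(scores), scores.shape)

    def parab(values, idx, coords):
        if 0 < idx < len(values) - 1:
            fm, f0, fp = values[idx - 1], values[idx], values[idx + 1]
            d = fm - 2 * f0 + fp
            if d < 0:
                return coords[idx] + 0.5 * (fm - fp) / d * (coords[1] - coords[0])
        return coords[idx]

    best_t = parab(scores[:, ir], it, twists)
    best_r = parab(scores[it, :], ir, rises)
    if polish:
        def objective(p):
            t, r = p
            if not (twist_range_deg[0] <= t <= twist_range_deg[1]
                    and rise_range_A[0] <= r <= rise_range_A[1]):
                return 1.0
            return -corr(t, r)

        res = optimize.minimize(objective, [best_t, best_r],
                                method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-8,
                                         "maxiter": 200})
        if -res.fun >= scores[it, ir]:
            best_t, best_r = res.x
    peak = corr(best_t, best_r)
    # a genuine screw optimum stands far above the landscape median; a
    # featureless volume correlates (weakly) everywhere
    confidence = peak - float(np.median(scores))
    low = bool(confidence < 0.1 or peak < 0.2)
    return SymmetryEstimate(HelicalSymmetry(float(best_t), float(best_r)),
                            peak, float(confidence), low)


# ---- gold-standard refinement -----------------------------------------------


def _project_library(ref: DensityVolume, box_px: int, az_step_deg: float,
                     tilt_offsets=(0.0,)):
    """Projections of a reference over the azimuth (and small tilts)."""
    phis = np.arange(0.0, 360.0, az_step_deg)
    lo = (ref.box - box_px) // 2
    imgs, eulers = [], []
    for tilt in tilt_offsets:
        for phi in phis:
            img = project(ref, (phi, 90.0 + tilt, 0.0)).data
            if lo > 0:
                img = img[lo:lo + box_px, lo:lo + box_px]
            imgs.append(img)
            eulers.append((phi, 90.0 + tilt))
    return np.stack(imgs), eulers


def _align_half(stack_data, table, refs, eulers, pix, limit_A, rot_window,
                rot_step, max_shift, az_step_deg):
    refs_lp = np.stack([lowpass_filter(r, limit_A, pix) for r in refs])
    n_phi = int(round(360.0 / az_step_deg))
    out = table.copy()
    for i, (_, row) in enumerate(table.iterrows()):
        img = lowpass_filter(stack_data[i], limit_A, pix)
        psi0 = row["psi"]
        res, scores = align_to_references(
            img, refs_lp, rot_step_deg=rot_step, max_shift_px=max_shift,
            rot_range=(psi0 - rot_window, psi0 + rot_window + 1e-9),
            return_scores=True)
        phi, theta = eulers[res.best_reference_index]
        # sub-grid azimuth refinement: parabola over the neighbouring
        # references of the same tilt row (circular in phi)
        ir = res.best_reference_index
        block = ir // n_phi
        p = ir % n_phi
        col = scores.max(axis=1)
        fm = col[block * n_phi + (p - 1) % n_phi]
        f0 = col[ir]
        fp = col[block * n_phi + (p + 1) % n_phi]
        d = fm - 2 * f0 + fp
        if d < 0:
            phi += float(np.clip(0.5 * (fm - fp) / d, -0.5, 0.5)) * az_step_deg
        out.iloc[i, out.columns.get_loc("phi")] = phi
        out.iloc[i, out.columns.get_loc("theta")] = theta
        out.iloc[i, out.columns.get_loc("psi")] = res.in_plane_rotation_deg
        out.iloc[i, out.columns.get_loc("sx")] = res.shift_px[0]
        out.iloc[i, out.columns.get_loc("sy")] = res.shift_px[1]
        if "score" in out.columns:
            out.iloc[i, out.columns.get_loc("score")] = res.score
    return out


def refine_gold_standard(stack: ImageStack, table: pd.DataFrame,
                         init_vol: DensityVolume, sym: HelicalSymmetry,
                         n_rounds: int = 4, limit_schedule_A=(10.0, 8.0),
                         az_step_deg: float = 4.0, rot_window_deg: float = 6.0,
                         rot_step_deg: float = 2.0, max_shift_px: int = 5,
                         tilt_offsets=(0.0,), z_fraction: float = 0.8,
                         seed: int = 0, improvement_tol_A: float = 0.0
                         ) -> ReconstructionState:
    """Projection-matching refinement run independently on two data halves.

    The halves (pre-assigned by filament half in the particle table) start
    from two phase-randomized copies of ``init_vol`` (beyond 20 A, different
    seeds). Per round and half: project the current reference over the
    azimuth, align every segment (in-plane search windowed around the axis
    direction), back-project, impose helical symmetry, and low-pass the new
    reference to the resolution estimated from the half's two quarter sets.
    The resolution limit applied to the alignment data follows
    ``limit_schedule_A`` (last entry repeats). Stops early when the mean
    quarter-set resolution stops improving, or after two consecutive
    worsening rounds (divergence; best round is reported).
    """
    _check_table(table)
    if "quarter_set" not in table.columns:
        raise ValueError("gold-standard refinement needs a quarter_set column")
    pix = stack.pixel_size_A
    box = stack.data.shape[1]
    rng = np.random.default_rng(seed)
    halves = {}
    for h in (1, 2):
        sel = table["half_set"] == h
        if not sel.any():
            raise ValueError(f"half-set {h} is empty")
        ref = randomize_phases(init_vol, 20.0, rng)
        ref.meta["half_set"] = h
        halves[h] = {"table": table[sel].reset_index(drop=True),
                     "index": np.flatnonzero(sel.to_numpy()), "ref": ref,
                     "vol": None}

    history = []
    best = {"res": np.inf, "round": -1, "vols": None, "tables": None}
    worse_streak = 0
    for rnd in range(n_rounds):
        limit = limit_schedule_A[min(rnd, len(limit_schedule_A) - 1)]
        round_res = []
        for h in (1, 2):
            H = halves[h]
            refs, eulers = _project_library(H["ref"], box, az_step_deg,
                                            tilt_offsets)
            H["table"] = _align_half(stack.data[H["index"]], H["table"], refs,
                                     eulers, pix, limit, rot_window_deg,
                                     rot_step_deg, max_shift_px, az_step_deg)
            sub = ImageStack(stack.data[H["index"]], pix)
            vol = backproject(sub, H["table"])
            vol = impose_helical_symmetry(vol, sym, z_fraction)
            vol.meta["half_set"] = h
            H["vol"] = vol
            # quarter-split resolution -> filter for the next reference
            q_res = _quarter_resolution(sub, H["table"], sym, z_fraction)
            round_res.append(q_res)
            filtered = DensityVolume(
                lowpass_filter(vol.data, max(q_res, 2 * pix), pix), pix,
                dict(vol.meta))
            H["ref"] = filtered
        mean_res = float(np.mean(round_res))
        history.append({"round": rnd, "limit_A": limit,
                        "quarter_res_A": [float(r) for r in round_res],
                        "mean_res_A": mean_res})
        if mean_res < best["res"] - improvement_tol_A:
            best = {"res": mean_res, "round": rnd,
                    "vols": (halves[1]["vol"], halves[2]["vol"]),
                    "tables": (halves[1]["table"].copy(),
                               halves[2]["table"].copy())}
            worse_streak = 0
        else:
            worse_streak += 1
            if worse_streak >= 2:
                break
    vols = best["vols"] or (halves[1]["vol"], halves[2]["vol"])
    tables = best["tables"] or (halves[1]["table"], halves[2]["table"])
    return ReconstructionState(vols, sym, history, len(history),
                               limit_schedule_A[-1], tables)


def _quarter_resolution(sub: ImageStack, table: pd.DataFrame,
                        sym: HelicalSymmetry, z_fraction: float) -> float:
    quarters = sorted(table["quarter_set"].unique())
    if len(quarters) < 2:
        return 2 * sub.pixel_size_A
    qa = table["quarter_set"] == quarters[0]
    vols = []
    for mask in (qa, ~qa):
        qs = ImageStack(sub.data[mask.to_numpy()], sub.pixel_size_A)
        v = backproject(qs, table[mask].reset_index(drop=True))
        vols.append(impose_helical_symmetry(v, sym, z_fraction))
    return resolution_at(fsc_curve(vols[0], vols[1]), 0.143)


def gold_standard_fsc(state: ReconstructionState, mask=None):
    """Final FSC between the two independently refined half-maps.

    The only place half-set data meet; refuses volumes carrying the same
    half-set tag.
    """
    v1, v2 = state.half_volumes
    if v1.meta.get("half_set") == v2.meta.get("half_set"):
        raise ValueError("both volumes carry the same half-set tag")
    return fsc_curve(v1, v2, mask=mask)
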