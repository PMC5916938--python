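"""Iterative spline refinement of filament axis coordinates.

Manually picked filament coordinates are noisy; before orientation refinement
the axis is smoothed by fitting a low-order curve and iteratively re-centred
by translation-only alignment of boxed segments against reference
projections. The refined axis bounds the translations allowed downstream.

The "low-order curve" is a quadratic polynomial per lateral coordinate as a
function of arc length: one curvature degree of freedom beyond a straight
line per coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import (DensityVolume, Image2D, circular_support, lowpass_filter,
                      normalize_image, project)

__all__ = ["FilamentTrack", "AxisCurve", "fit_axis_spline", "refine_axis"]


@dataclass
class FilamentTrack:
    """Ordered axis sample points of one filament in the micrograph frame (A)."""

    filament_id: int
    points_A: np.ndarray  # (N, 2) x, y in Angstrom
    sampling_step_A: float

    def __post_init__(self):
        self.points_A = np.asarray(self.points_A, dtype=float).reshape(-1, 2)
        if len(self.points_A) < 2:
            raise ValueError("FilamentTrack needs at least 2 points")

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.points_A, columns=["x_A", "y_A"])
        df.insert(0, "point_idx", np.arange(len(df)))
        df.insert(0, "filament_id", self.filament_id)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class AxisCurve:
    """Quadratic parametric curve (x(t), y(t)), t = arc-length parameter."""

    coeff_x: np.ndarray
    coeff_y: np.ndarray
    t_range: tuple
    residual_A: float = 0.0
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, float))
        return np.column_stack([np.polyval(self.coeff_x, t),
                                np.polyval(self.coeff_y, t)])

    def tangent(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, float))
        dx = np.polyval(np.polyder(self.coeff_x), t)
        dy = np.polyval(np.polyder(self.coeff_y), t)
        v = np.column_stack([dx, dy])
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    def resample(self, step: float) -> np.ndarray:
        """Points spaced ``step`` apart in arc length (numeric reparametrization)."""
        t0, t1 = self.t_range
        tt = np.linspace(t0, t1, 512)
        pts = self(tt)
        arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0),
                                                              axis=1))])
        targets = np.arange(0.0, arc[-1] + 1e-9, step)
        return self(np.interp(targets, arc, tt))


def fit_axis_spline(points: np.ndarray, max_dof: int = 2) -> AxisCurve:
    """Least-squares smooth curve through picked axis points.

    Fits a polynomial of degree ``max_dof`` (default quadratic) to each
    coordinate against the projection of the points onto their principal
    direction (tracks progress monotonically along the dominant axis, so the
    parameter is monotone and a quadratic arc is fitted exactly). Reports the
    RMS residual of the points about the fit.
    """
    pts = np.asarray(points, float).reshape(-1, 2)
    if len(pts) < 3:
        raise ValueError("need at least 3 points to fit an axis curve")
    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    t = centred @ vt[0]
    if t[-1] < t[0]:
        t = -t
    cx = np.polyfit(t, pts[:, 0], max_dof)
    cy = np.polyfit(t, pts[:, 1], max_dof)
    fit = np.column_stack([np.polyval(cx, t), np.polyval(cy, t)])
    res = np.linalg.norm(fit - pts, axis=1)
    return AxisCurve(cx, cy, (t.min(), t.max()),
                     float(np.sqrt(np.mean(res**2))), res)


def _extract_box(micro: np.ndarray, center_xy: np.ndarray, box: int) -> np.ndarray:
    """Sub-pixel box extraction centred on center_xy (x, y in pixels)."""
    half = box // 2
    cy, cx = center_xy[1], center_xy[0]
    yy = np.arange(box) - half + cy
    xx = np.arange(box) - half + cx
    return ndimage.map_coordinates(micro, np.meshgrid(yy, xx, indexing="ij"),
                                   order=1, cval=0.0)


def _translation_align(img: np.ndarray, refs: np.ndarray, max_shift: int,
                       support) -> tuple[np.ndarray, float]:
    """Best translation against the best of several references."""
    from .imaging import _shift_window_peak  # shared peak finder

    imgn = normalize_image(img, support)
    f = np.fft.fft2(imgn)
    best = (-np.inf, (0.0, 0.0))
    for ref in refs:
        refn = normalize_image(ref, support)
        corr = np.real(np.fft.ifft2(f * np.conj(np.fft.fft2(refn)))) / support.sum()
        score, shift = _shift_window_peak(corr, max_shift)
        if score > best[0]:
            best = (score, shift)
    return np.asarray(best[1]), best[0]


def refine_axis(track: FilamentTrack, micrograph: Image2D,
                reference: DensityVolume, n_cycles: int = 4,
                step_A: float = 82.0, box_px: int = 64,
                lowpass_A: float = 15.0, max_shift_px: int = 8,
                n_ref_azimuths: int = 4, log: list | None = None
                ) -> FilamentTrack:
    """Iterative centring of a filament axis against reference projections.

    Per cycle: fit the current points with a quadratic curve, resample every
    ``step_A``, extract low-pass-filtered boxes at the samples, align each by
    translation only against reference projections rotated to the local axis
    direction, keep the shift component perpendicular to the axis, correct
    the coordinates, and refit. Aborts if more than half the segments fail to
    align in a cycle. ``log`` (optional list) collects per-cycle RMS
    corrections.
    """
    pix = micrograph.pixel_size_A
    micro = lowpass_filter(micrograph.data, lowpass_A, pix)
    support = circular_support(box_px)
    phis = np.linspace(0.0, 360.0, n_ref_azimuths, endpoint=False)
    base_refs = [project(reference, (phi, 90.0, 0.0)).data for phi in phis]
    # reference box must match extraction box
    rb = base_refs[0].shape[0]
    if rb != box_px:
        lo = (rb - box_px) // 2
        base_refs = [r[lo:lo + box_px, lo:lo + box_px] for r in base_refs]
    base_refs = [lowpass_filter(r, lowpass_A, pix) for r in base_refs]

    points = track.points_A.copy()
    for cycle in range(n_cycles):
        curve = fit_axis_spline(points / pix)
        samples = curve.resample(step_A / pix)
        tangents = _tangents_of(samples)
        corrections = np.zeros_like(samples)
        n_fail = 0
        for i, (pt, tg) in enumerate(zip(samples, tangents)):
            seg = _extract_box(micro, pt, box_px)
            # the psi=0 reference filament runs along image x; rotate the
            # references onto the local tangent direction (both polarities,
            # since the filament direction along the track is ambiguous)
            ang = np.degrees(np.arctan2(tg[1], tg[0]))
            refs = [ndimage.rotate(r, a, reshape=False, order=1)
                    for r in base_refs for a in (-ang, -ang + 180.0)]
            shift, score = _translation_align(seg, np.stack(refs),
                                              max_shift_px, support)
            if not np.isfinite(score) or score < 0.05:
                n_fail += 1
                continue
            # seg ~ ref shifted by `shift`: the filament sits at +shift from
            # the box centre, so the axis point moves by the perpendicular
            # component of the shift
            perp = np.array([-tg[1], tg[0]])
            corrections[i] = float(np.dot(shift, perp)) * perp
        if n_fail > 0.5 * len(samples):
            raise RuntimeError(
                f"axis refinement cycle {cycle}: {n_fail}/{len(samples)} "
                "segments failed to align")
        points = (samples + corrections) * pix
        if log is not None:
            rms = float(np.sqrt(np.mean(np.sum(corrections**2, axis=1))))
            log.append({"cycle": cycle, "rms_correction_px": rms,
                        "n_failed": n_fail, "n_samples": len(samples)})
    return FilamentTrack(track.filament_id, points, step_A)


def _tangents_of(points: np.ndarray) -> np.ndarray:
    grad = np.gradient(points, axis=0)
    return grad / np.linalg.norm(grad, axis=1, keepdims=True)
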