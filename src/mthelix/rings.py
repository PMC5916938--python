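"""2D classification of curved-protofilament ring particles.

Kinesin-13 bends tubulin protofilaments into rings and spirals of 13-15
dimers. This stage aligns and classifies picked ring images iteratively
(re-centring particle coordinates each round), counts tubulin dimers per
class average by angular harmonic analysis, and calls the kinesin decoration
pattern (one motor per dimer vs one per two dimers) from two-dimer
sub-particles extracted at inter-dimer interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import (Image2D, ImageStack, align_to_references,
                      circular_support, fourier_shift, normalize_image)

__all__ = [
    "RingClass", "DecorationCall", "DimerCount", "classify_rings",
    "count_dimers", "analyze_decoration", "curvature_from_count",
]


@dataclass
class RingClass:
    class_id: int
    average: Image2D
    member_ids: list
    dimer_count: int | None = None
    count_confidence: float = 0.0
    ring_radius_px: float = 0.0
    quality: float = 0.0
    member_rotations_deg: list = field(default_factory=list)
    member_shifts_px: list = field(default_factory=list)


@dataclass
class DecorationCall:
    class_id: int
    pattern: str  # every_dimer | every_other_dimer | undetermined
    kinesin_per_dimer: float
    site_counts: dict = field(default_factory=dict)


@dataclass
class DimerCount:
    count: int | None
    confidence: float
    ring_radius_px: float


# ---- dimer counting ---------------------------------------------------------


def _radial_profile(img: np.ndarray, r_min_px: int = 6):
    n = img.shape[0]
    c = np.arange(n) - n // 2
    rr = np.hypot(c[:, None], c[None, :])
    rbin = np.round(rr).astype(int)
    nmax = n // 2
    prof = np.bincount(rbin.ravel(), img.ravel(), nmax + 1)
    cnt = np.bincount(rbin.ravel(), minlength=nmax + 1)
    prof = prof / np.maximum(cnt, 1)
    prof[:r_min_px] = -np.inf
    return prof


def _angular_profile(img: np.ndarray, radius_px: float, n_samples: int = 720,
                     radial_avg_px: int = 2):
    n = img.shape[0]
    half = n // 2
    th = np.linspace(0.0, 2.0 * np.pi, n_samples, endpoint=False)
    prof = np.zeros(n_samples)
    for dr in range(-radial_avg_px, radial_avg_px + 1):
        r = radius_px + dr
        xs = half + r * np.cos(th)
        ys = half + r * np.sin(th)
        prof += ndimage.map_coordinates(img, [ys, xs], order=1)
    return prof / (2 * radial_avg_px + 1)


def count_dimers(class_avg: Image2D, harmonic_range=(10, 20),
                 min_ratio: float = 2.0) -> DimerCount:
    """Count tubulin dimers on a centred ring image.

    Detects the tubulin annulus radius from the radial intensity profile,
    extracts the angular intensity on the annulus, and picks the dominant
    angular harmonic in ``harmonic_range``; the count is undetermined when no
    harmonic stands out by ``min_ratio`` over the runner-up.
    """
    img = class_avg.data
    prof = _radial_profile(img)
    radius = float(np.argmax(prof[: int(img.shape[0] / 2 - 3)]))
    ang = _angular_profile(img, radius)
    spec = np.abs(np.fft.rfft(ang - ang.mean()))
    lo, hi = harmonic_range
    band = spec[lo:hi + 1]
    order = np.argsort(band)[::-1]
    best, second = band[order[0]], band[order[1]] if len(band) > 1 else 0.0
    ratio = best / (second + 1e-12)
    count = int(lo + order[0])
    if ratio < min_ratio:
        return DimerCount(None, float(ratio), radius)
    return DimerCount(count, float(ratio), radius)


def curvature_from_count(n_dimers: int) -> float:
    """Per-dimer curvature (degrees) of a closed ring of ``n_dimers``."""
    if n_dimers < 3:
        raise ValueError("a closed ring needs at least 3 dimers")
    return 360.0 / n_dimers


# ---- iterative classification ----------------------------------------------


def _apply_mask(data: np.ndarray, diameter_px: float) -> np.ndarray:
    sup = circular_support(data.shape[-1], diameter_px / 2.0)
    return data * sup


def _inverse_align(img: np.ndarray, rot_deg: float, shift_px) -> np.ndarray:
    """Undo img ~ shift(rotate(avg, rot), s): recentre then derotate."""
    out = fourier_shift(img, (-shift_px[0], -shift_px[1]))
    if rot_deg:
        out = ndimage.rotate(out, -rot_deg, reshape=False, order=1)
    return out


def ring_quality(avg: np.ndarray) -> tuple[float, float]:
    """(quality, ring radius): annular signal prominence of a class average.

    Quality is the mean annulus intensity at the detected ring radius in
    units of the image's robust scale; featureless (noise) averages score
    near zero.
    """
    prof = _radial_profile(avg)
    radius = float(np.argmax(prof[: int(avg.shape[0] / 2 - 3)]))
    annulus = prof[int(radius) - 1:int(radius) + 2].mean()
    scale = np.median(np.abs(avg - np.median(avg))) + 1e-12
    return float(annulus / scale), radius


def classify_rings(stack: ImageStack, k_classes: int = 12, n_rounds: int = 3,
                   mask_diameter_A: float = 540.0, seed: int = 0,
                   rot_step_deg: float = 3.0, rot_max_deg: float = 30.0,
                   max_shift_px: int = 4, quality_threshold: float = 2.0
                   ) -> tuple[list[RingClass], np.ndarray]:
    """Iterative alignment / classification / averaging of ring particles.

    Per round: align every particle to each class average (in-plane rotation
    up to ``rot_max_deg`` -- one ring period is enough since a ring is nearly
    invariant under rotation by 360/n -- plus translation), reassign to the
    best-correlating class, re-centre the particle coordinates by the inverse
    transform, and recompute averages. Classes whose final average lacks a
    ring (annular quality below ``quality_threshold``) are dropped with their
    particles. Returns surviving classes and the per-particle accumulated
    centre corrections (px).
    """
    n = len(stack)
    if k_classes > n:
        raise ValueError(f"k_classes={k_classes} exceeds {n} particles")
    rng = np.random.default_rng(seed)
    pix = stack.pixel_size_A
    mask_px = mask_diameter_A / pix
    data = _apply_mask(stack.data.copy(), mask_px)
    assign = rng.integers(0, k_classes, size=n)
    rotations = np.zeros(n)
    total_shift = np.zeros((n, 2))

    averages = np.stack([
        data[assign == k].mean(axis=0) if (assign == k).any()
        else rng.normal(size=data.shape[1:]) for k in range(k_classes)])
    for _ in range(n_rounds):
        refs = np.stack([normalize_image(a) for a in averages])
        new_avg = np.zeros_like(averages)
        counts = np.zeros(k_classes)
        for i in range(n):
            res = align_to_references(
                data[i], refs, rot_step_deg=rot_step_deg,
                max_shift_px=max_shift_px, rot_range=(0.0, rot_max_deg))
            assign[i] = res.best_reference_index
            rotations[i] = res.in_plane_rotation_deg
            total_shift[i] += res.shift_px
            # re-centre the particle itself (stand-in for re-extraction)
            data[i] = fourier_shift(data[i], (-res.shift_px[0], -res.shift_px[1]))
            aligned = _inverse_align(data[i], res.in_plane_rotation_deg, (0, 0))
            new_avg[res.best_reference_index] += aligned
            counts[res.best_reference_index] += 1
        keep = counts > 0
        new_avg[keep] /= counts[keep, None, None]
        new_avg[~keep] = averages[~keep]
        averages = new_avg

    classes = []
    for k in range(k_classes):
        members = np.flatnonzero(assign == k)
        if len(members) == 0:
            continue
        q, radius = ring_quality(averages[k])
        if q < quality_threshold:
            continue
        dc = count_dimers(Image2D(averages[k], pix))
        classes.append(RingClass(
            class_id=k, average=Image2D(averages[k], pix),
            member_ids=members.tolist(), dimer_count=dc.count,
            count_confidence=dc.confidence, ring_radius_px=dc.ring_radius_px,
            quality=q,
            member_rotations_deg=rotations[members].tolist(),
            member_shifts_px=total_shift[members].tolist()))
    return classes, total_shift


# ---- decoration analysis ----------------------------------------------------


def _kinesin_radius(avg: np.ndarray, ring_radius_px: float,
                    min_peak_frac: float = 0.08) -> float | None:
    """Outer (kinesin) annulus radius: first radial peak beyond the valley
    outside the tubulin ring; None when no convincing outer density exists."""
    prof = _radial_profile(avg)
    start = int(ring_radius_px) + 2
    stop = int(avg.shape[0] / 2 - 3)
    if stop <= start + 2:
        return None
    seg = prof[start:stop]
    rising = np.flatnonzero(np.diff(seg) > 0)
    if len(rising) == 0:
        return None
    valley = rising[0] + 1
    peak = valley + int(np.argmax(seg[valley:]))
    if seg[peak] < min_peak_frac * prof[int(ring_radius_px)]:
        return None
    return float(start + peak)


def analyze_decoration(ring_class: RingClass, stack: ImageStack,
                       mask_diameter_A: float = 176.0,
                       occupancy_threshold: float = 0.35) -> DecorationCall:
    """Call the kinesin decoration pattern of one ring class.

    For every member particle, two-dimer sub-particles are extracted centred
    on each inter-dimer interface (the ring geometry comes from the class
    average; each member is first de-rotated into the class frame). Within
    each sub-particle the two flanking dimer-centre sites on the kinesin
    annulus are probed; a site counts as occupied when its local mean exceeds
    ``occupancy_threshold`` of the particle's tubulin-annulus level. Two
    occupied sites per sub-particle means one motor per dimer; one means the
    skipping pattern (one motor per two dimers).
    """
    nd = ring_class.dimer_count
    if nd is None:
        raise ValueError("ring class has no determined dimer count")
    pix = stack.pixel_size_A
    avg = ring_class.average.data
    r_tub = ring_class.ring_radius_px
    r_kin = _kinesin_radius(avg, r_tub)
    box = avg.shape[0]
    half = box // 2
    sub_half_px = mask_diameter_A / pix / 2.0

    # the tubulin harmonic peaks on the (heavier) beta monomers; the dimer
    # centre -- where kinesin binds -- sits a quarter dimer-period earlier
    ang0 = _dimer_phase(avg, r_tub, nd) - (2 * np.pi / nd) / 4.0
    interface = ang0 + (np.arange(nd) + 0.5) * 2 * np.pi / nd
    dimer_off = np.pi / nd  # interface +- half a dimer
    probe_px = max(2.0, 8.0 / pix)

    site_counts = {0: 0, 1: 0, 2: 0}
    n_sub = 0
    for m, rot, sh in zip(ring_class.member_ids,
                          ring_class.member_rotations_deg,
                          ring_class.member_shifts_px):
        centred = fourier_shift(stack.data[m], (-sh[0], -sh[1]))
        img = ndimage.rotate(centred, -rot, reshape=False, order=1)
        tub_level = _annulus_level(img, r_tub, probe_px)
        if tub_level <= 0:
            continue
        for a in interface:
            occupied = 0
            for s in (-dimer_off, dimer_off):
                if r_kin is None:
                    break
                x = half + r_kin * np.cos(a + s)
                y = half + r_kin * np.sin(a + s)
                # probe stays inside the two-dimer sub-particle mask
                ix = half + r_tub * np.cos(a)
                iy = half + r_tub * np.sin(a)
                if np.hypot(x - ix, y - iy) > sub_half_px:
                    continue
                level = _disk_mean(img, x, y, probe_px)
                if level > occupancy_threshold * tub_level:
                    occupied += 1
            site_counts[occupied] += 1
            n_sub += 1
    if n_sub == 0:
        return DecorationCall(ring_class.class_id, "undetermined", 0.0,
                              site_counts)
    total_kin = site_counts[1] + 2 * site_counts[2]
    ratio = total_kin / (2.0 * n_sub)
    if site_counts[2] > 0.5 * n_sub:
        pattern = "every_dimer"
    elif site_counts[1] > 0.5 * n_sub:
        pattern = "every_other_dimer"
    else:
        pattern = "undetermined"
    return DecorationCall(ring_class.class_id, pattern, float(ratio),
                         dict(site_counts))


def _dimer_phase(avg: np.ndarray, radius_px: float, n_dimers: int) -> float:
    """Angular offset of the dimer centres from the x axis (class frame)."""
    ang = _angular_profile(avg, radius_px)
    spec = np.fft.rfft(ang - ang.mean())
    return float(-np.angle(spec[n_dimers]) / n_dimers)


def _annulus_level(img: np.ndarray, radius_px: float, width_px: float) -> float:
    prof = _angular_profile(img, radius_px, radial_avg_px=int(width_px))
    return float(prof.mean())


def _disk_mean(img: np.ndarray, x: float, y: float, r_px: float) -> float:
    n = img.shape[0]
    xx, yy = np.meshgrid(np.arange(n), np.arange(n))
    m = (xx - x) ** 2 + (yy - y) ** 2 <= r_px**2
    if not m.any():
        return 0.0
    return float(img[m].mean())
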