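"""Synthetic decorated-microtubule and tubulin-ring data with full ground truth.

Every input the pipeline consumes is generated here: filament segment stacks
(with particle tables and manifests), face-on curved-protofilament ring
images, synthetic micrographs for axis refinement, and CTF corruption.

Segment and ring images are rendered by projecting the pseudo-atom model
analytically -- each atom becomes a 2D Gaussian at its projected position,
which is the exact line integral of the 3D Gaussian kernel used by
``imaging.render_density``. The simulator therefore shares no code with the
volume-projection path it is used to validate.

Noise is additive white Gaussian; SNR is defined as the variance of the
noiseless signal inside the circular particle support divided by the noise
variance. CTF simulation uses the standard weak-phase transfer function with
defocus defaults drawn from the 1.3-2.2 um underfocus range of the source
data collection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import Image2D, ImageStack, circular_support, euler_to_matrix
from .lattice import (AtomModel, HelicalSymmetry, LatticeSpec, SpiralSpec,
                      build_microtubule, build_protofilament_spiral,
                      default_symmetry)

__all__ = [
    "CTFParams", "SimConfig", "FilamentTypeMix", "RingMix", "GroundTruthManifest",
    "splat_projection", "apply_ctf", "ctf_transfer",
    "generate_filament_dataset", "generate_ring_dataset", "generate_micrograph",
    "reference_model_for", "render_reference_volume",
]


@dataclass
class CTFParams:
    """Microscope contrast transfer function parameters."""

    voltage_kV: float = 300.0
    cs_mm: float = 2.7
    defocus_um: float = 1.6  # positive = underfocus
    amplitude_contrast: float = 0.07
    pixel_size_A: float = 4.0

    def __post_init__(self):
        if self.defocus_um <= 0:
            raise ValueError("defocus_um must be > 0 (underfocus) for simulation")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude_contrast must be in [0, 1]")

    @property
    def wavelength_A(self) -> float:
        v = self.voltage_kV * 1e3
        return 12.2643 / np.sqrt(v * (1.0 + 0.97845e-6 * v))


def ctf_transfer(s_invA: np.ndarray, ctf: CTFParams) -> np.ndarray:
    """CTF(s) = -[sqrt(1-A^2) sin(chi) + A cos(chi)] with
    chi(s) = pi lambda dz s^2 - (pi/2) Cs lambda^3 s^4."""
    lam = ctf.wavelength_A
    dz = ctf.defocus_um * 1e4
    cs = ctf.cs_mm * 1e7
    chi = np.pi * lam * dz * s_invA**2 - 0.5 * np.pi * cs * lam**3 * s_invA**4
    a = ctf.amplitude_contrast
    return -(np.sqrt(1.0 - a**2) * np.sin(chi) + a * np.cos(chi))


def apply_ctf(img: Image2D, ctf: CTFParams, mode: str = "full") -> Image2D:
    """Multiply an image's Fourier transform by the CTF or by its sign.

    mode 'full' simulates the microscope; 'phase_flip_correct' multiplies by
    sign(CTF), the phase-flipping correction applied before alignment.
    """
    if mode not in ("full", "phase_flip_correct"):
        raise ValueError(f"unknown CTF mode {mode!r}")
    n = img.data.shape[0]
    f = np.fft.fftfreq(n, d=img.pixel_size_A)
    s = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)
    h = ctf_transfer(s, ctf)
    if mode == "phase_flip_correct":
        h = np.sign(h)
        h[h == 0] = 1.0
    out = np.real(np.fft.ifft2(np.fft.fft2(img.data) * h))
    meta = dict(img.meta)
    meta.setdefault("ctf", []).append((mode, ctf.defocus_um))
    return Image2D(out, img.pixel_size_A, meta)


@dataclass
class FilamentTypeMix:
    """How many filaments of one lattice type to simulate."""

    spec: LatticeSpec
    n_filaments: int
    symmetry: HelicalSymmetry | None = None

    def sym(self) -> HelicalSymmetry:
        return self.symmetry or default_symmetry(self.spec)

    @property
    def type_name(self) -> str:
        return f"{self.spec.n_protofilaments}{self.spec.handedness}"


@dataclass
class RingMix:
    """How many rings of one spiral geometry to simulate."""

    spec: SpiralSpec
    n_rings: int


@dataclass
class SimConfig:
    """Study conditions for the synthetic datasets.

    Defaults mirror the desk-scale geometry used throughout the package:
    4 A/pixel, 64 px segment boxes, segments every 82 A along the filament,
    smooth sinusoidal axis perturbation of 2 px amplitude emulating manual
    picking error. The seed is mandatory; every stochastic draw flows from it.
    """

    seed: int
    filament_types: list = field(default_factory=list)
    ring_types: list = field(default_factory=list)
    n_segments_per_filament: int = 20
    segment_step_A: float = 82.0
    box_px: int = 64
    pixel_size_A: float = 4.0
    ring_box_px: int = 144
    snr: float | None = 0.5
    ctf: CTFParams | None = None
    axis_wobble_amp_px: float = 2.0
    axis_wobble_wavelength_A: float = 2500.0
    pick_jitter_px: float = 0.5
    splat_sigma_px: float = 1.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.snr is not None and not self.snr > 0:
            raise ValueError("snr must be > 0 (or None for noiseless)")


@dataclass
class GroundTruthManifest:
    """Maps every emitted image to the parameters that generated it."""

    config_summary: dict
    filaments: list = field(default_factory=list)
    rings: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config_summary, "filaments": self.filaments,
                       "rings": self.rings}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["config"], d["filaments"], d["rings"])


# ---- analytic projection ----------------------------------------------------


def splat_projection(model: AtomModel, euler_deg, box_px: int,
                     pixel_size_A: float, shift_px=(0.0, 0.0),
                     sigma_px: float = 1.0, z_window_A: float | None = None,
                     z_center_A: float = 0.0) -> np.ndarray:
    """Exact projection of a Gaussian pseudo-atom model onto an image.

    Each atom lands at the first two components of ``R^T q`` (the adjoint of
    the volume-projection geometry) as a 2D Gaussian whose discrete sum is the
    atom weight; atoms partially outside the box lose the out-of-box part of
    their kernel, like a real boxed projection. ``z_window_A`` keeps only
    atoms within a slab |z - z_center| < window/2 in model coordinates
    (segment extraction along a filament axis).
    """
    pos = model.positions
    wts = model.weights
    if z_window_A is not None:
        sel = np.abs(pos[:, 2] - z_center_A) < z_window_A / 2.0
        pos, wts = pos[sel], wts[sel]
    R = euler_to_matrix(*euler_deg)
    proj = (pos - [0.0, 0.0, 0.0]) @ R  # row-vectors: q @ R == R.T @ q
    half = box_px // 2
    px = proj[:, 0] / pixel_size_A + half + shift_px[0]
    py = proj[:, 1] / pixel_size_A + half + shift_px[1]

    img = np.zeros((box_px, box_px))
    reach = int(np.ceil(4.0 * sigma_px))
    offs = np.arange(-reach, reach + 1, dtype=float)
    for x, y, w in zip(px, py, wts):
        cx, cy = int(round(x)), int(round(y))
        if cx + reach < 0 or cx - reach > box_px - 1:
            continue
        if cy + reach < 0 or cy - reach > box_px - 1:
            continue
        gx = np.exp(-((cx + offs - x) ** 2) / (2 * sigma_px**2))
        gy = np.exp(-((cy + offs - y) ** 2) / (2 * sigma_px**2))
        kern = (w / (gx.sum() * gy.sum())) * gy[:, None] * gx[None, :]
        x0, x1 = max(cx - reach, 0), min(cx + reach + 1, box_px)
        y0, y1 = max(cy - reach, 0), min(cy + reach + 1, box_px)
        img[y0:y1, x0:x1] += kern[y0 - (cy - reach):y1 - (cy - reach),
                                  x0 - (cx - reach):x1 - (cx - reach)]
    return img


def _spawn_rngs(seed: int):
    geom, noise = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(geom), np.random.default_rng(noise)


def _add_noise(img: np.ndarray, snr: float | None, rng, support) -> np.ndarray:
    if snr is None:
        return img
    sig_var = img[support].var()
    if sig_var == 0:
        return img
    return img + rng.normal(0.0, np.sqrt(sig_var / snr), size=img.shape)


# ---- filament segments ------------------------------------------------------


def generate_filament_dataset(config: SimConfig):
    """Simulate decorated-microtubule filament segments.

    Returns (ImageStack, particle table DataFrame, GroundTruthManifest). Each
    filament has a fixed viewing azimuth and in-plane angle; segments are cut
    every ``segment_step_A`` along the axis, displaced perpendicular to the
    axis by a smooth sinusoid plus per-pick jitter (the recorded true shift),
    then noise and optional CTF are applied. Deterministic given the seed.
    """
    if not config.filament_types:
        raise ValueError("config.filament_types is empty")
    # separate geometry and noise streams: the same seed generates the same
    # underlying particles whether or not noise/CTF is switched on
    rng, rng_noise = _spawn_rngs(config.seed)
    box, pix = config.box_px, config.pixel_size_A
    support = circular_support(box)
    slab_A = box * pix * 1.5  # cover the box diagonal at any in-plane angle

    images, rows, fil_records = [], [], []
    models: dict[str, AtomModel] = {}
    fid = 0
    for mix in config.filament_types:
        length_A = (config.n_segments_per_filament * config.segment_step_A
                    + slab_A)
        sym = mix.sym()
        n_dimers = int(np.ceil(length_A / (2 * mix.spec.monomer_spacing_A))) + 2
        key = mix.type_name
        if key not in models:
            spec = LatticeSpec(mix.spec.n_protofilaments, mix.spec.handedness,
                               mix.spec.monomer_spacing_A, mix.spec.lattice_radius_A,
                               n_dimers, mix.spec.decorate_kinesin)
            models[key] = build_microtubule(spec, sym)
        model = models[key]
        zlo = model.positions[:, 2].min()
        model_n_dimers = int(model.dimer_index.max()) + 1

        for _ in range(mix.n_filaments):
            phi0 = float(rng.uniform(0.0, 360.0))
            psi = float(rng.uniform(0.0, 360.0))
            wobble_phase = float(rng.uniform(0.0, 2.0 * np.pi))
            seg_records = []
            n_seg = config.n_segments_per_filament
            for k in range(n_seg):
                s_k = zlo + slab_A / 2.0 + k * config.segment_step_A
                perp = (config.axis_wobble_amp_px
                        * np.sin(2 * np.pi * s_k / config.axis_wobble_wavelength_A
                                 + wobble_phase)
                        + rng.normal(0.0, config.pick_jitter_px))
                along = float(rng.normal(0.0, config.pick_jitter_px))
                # axis direction in the image plane and its perpendicular
                Rm = euler_to_matrix(phi0, 90.0, psi)
                axis_im = (Rm.T @ np.array([0.0, 0.0, 1.0]))[:2]
                perp_im = np.array([-axis_im[1], axis_im[0]])
                shift = perp * perp_im + along * axis_im
                model_shifted = AtomModel(
                    model.positions - [0.0, 0.0, s_k], model.weights,
                    model.pf_index, model.dimer_index, model.monomer_kind)
                img = splat_projection(model_shifted, (phi0, 90.0, psi), box, pix,
                                       shift_px=tuple(shift),
                                       sigma_px=config.splat_sigma_px,
                                       z_window_A=slab_A)
                defocus = None
                if config.ctf is not None:
                    defocus = float(rng.uniform(1.3, 2.2)) \
                        if config.ctf.defocus_um is None else config.ctf.defocus_um
                    ctf = CTFParams(config.ctf.voltage_kV, config.ctf.cs_mm,
                                    defocus, config.ctf.amplitude_contrast, pix)
                    img = apply_ctf(Image2D(img, pix), ctf, "full").data
                img = _add_noise(img, config.snr, rng_noise, support)
                images.append(img)
                half_set = 1 if k < n_seg // 2 else 2
                quarter = (half_set - 1) * 2 + (k % 2) + 1
                # exact orientation of this segment relative to the canonical
                # centred model (see reference_model_for): translating the
                # filament by s along its axis equals rotating the model by
                # -round(s/rise) twists; the sub-rise remainder shows up as an
                # axial image shift
                k_units = round(s_k / sym.rise_A)
                phi_eff = (phi0 - k_units * sym.twist_deg) % 360.0
                delta_A = s_k - k_units * sym.rise_A
                Re = euler_to_matrix(phi_eff, 90.0, psi)
                ax_eff = (Re.T @ np.array([0.0, 0.0, 1.0]))[:2]
                axial_shift = -(delta_A / pix) * ax_eff
                total_shift = shift + axial_shift
                rows.append({
                    "filament_id": fid, "segment_idx": k,
                    "x": 0.0, "y": s_k, "psi": psi, "theta": 90.0,
                    "phi": phi_eff,
                    "sx": total_shift[0], "sy": total_shift[1],
                    "half_set": half_set, "quarter_set": quarter,
                    "true_type": key,
                })
                seg_records.append({
                    "segment_idx": k, "axial_pos_A": s_k,
                    "euler_deg": [phi_eff, 90.0, psi],
                    "shift_px": [float(total_shift[0]), float(total_shift[1])],
                    "pick_shift_px": [float(shift[0]), float(shift[1])],
                    "half_set": half_set, "defocus_um": defocus,
                })
            fil_records.append({
                "filament_id": fid, "type": key,
                "n_pf": mix.spec.n_protofilaments,
                "handedness": mix.spec.handedness,
                "twist_deg": sym.twist_deg, "rise_A": sym.rise_A,
                "monomer_spacing_A": mix.spec.monomer_spacing_A,
                "lattice_radius_A": mix.spec.lattice_radius_A,
                "decorate_kinesin": mix.spec.decorate_kinesin,
                "model_n_dimers": model_n_dimers,
                "psi_deg": psi, "phi0_deg": phi0,
                "segments": seg_records,
            })
            fid += 1

    stack = ImageStack(np.stack(images), pix,
                       [{"filament_id": r["filament_id"],
                         "segment_idx": r["segment_idx"]} for r in rows])
    table = pd.DataFrame(rows)
    manifest = GroundTruthManifest(
        {"seed": config.seed, "snr": config.snr, "box_px": box,
         "pixel_size_A": pix, "kind": "filament"},
        filaments=fil_records)
    return stack, table, manifest


# ---- rings ------------------------------------------------------------------


def generate_ring_dataset(config: SimConfig):
    """Simulate face-on curved-protofilament ring images.

    Each ring is a closed (or near-closed) protofilament spiral viewed down
    its axis at a random in-plane angle with sub-pixel centre jitter.
    Returns (ImageStack, GroundTruthManifest).
    """
    if not config.ring_types:
        raise ValueError("config.ring_types is empty")
    rng, rng_noise = _spawn_rngs(config.seed)
    box, pix = config.ring_box_px, config.pixel_size_A
    support = circular_support(box)

    images, records = [], []
    rid = 0
    for mix in config.ring_types:
        model = build_protofilament_spiral(mix.spec)
        for _ in range(mix.n_rings):
            angle = float(rng.uniform(0.0, 360.0))
            jitter = rng.uniform(-1.5, 1.5, size=2)
            img = splat_projection(model, (0.0, 0.0, angle), box, pix,
                                   shift_px=tuple(jitter),
                                   sigma_px=config.splat_sigma_px)
            img = _add_noise(img, config.snr, rng_noise, support)
            images.append(img)
            records.append({
                "ring_id": rid, "n_dimers": mix.spec.n_dimers,
                "curvature_per_dimer_deg": mix.spec.curvature_per_dimer_deg,
                "decoration": mix.spec.decoration,
                "in_plane_deg": angle,
                "center_jitter_px": [float(jitter[0]), float(jitter[1])],
                "ring_radius_A": mix.spec.ring_radius_A,
            })
            rid += 1
    stack = ImageStack(np.stack(images), pix,
                       [{"ring_id": r["ring_id"]} for r in records])
    manifest = GroundTruthManifest(
        {"seed": config.seed, "snr": config.snr, "box_px": box,
         "pixel_size_A": pix, "kind": "ring"},
        rings=records)
    return stack, manifest


# ---- micrographs for axis refinement ---------------------------------------


def generate_micrograph(config: SimConfig, mix: FilamentTypeMix,
                        micrograph_px: int = 1024, bend_px: float = 3.0):
    """One synthetic micrograph with a gently curved filament plus its picks.

    The filament axis follows a quadratic arc (sag ``bend_px`` at the ends);
    picked coordinates are axis samples corrupted by the configured sinusoid
    and jitter. Returns (Image2D micrograph, picked points (N,2) px,
    true axis points (N,2) px).
    """
    rng, rng_noise = _spawn_rngs(config.seed)
    pix = config.pixel_size_A
    length_A = micrograph_px * pix * 0.8
    n_dimers = int(np.ceil(length_A / (2 * mix.spec.monomer_spacing_A))) + 2
    spec = LatticeSpec(mix.spec.n_protofilaments, mix.spec.handedness,
                       mix.spec.monomer_spacing_A, mix.spec.lattice_radius_A,
                       n_dimers, mix.spec.decorate_kinesin)
    model = build_microtubule(spec, mix.sym())

    # bend: perpendicular offset (world y, which survives the projection)
    # quadratic in axial position
    pos = model.positions.copy()
    z = pos[:, 2]
    zmax = np.abs(z).max()
    pos[:, 1] += bend_px * pix * (z / zmax) ** 2
    bent = AtomModel(pos, model.weights, model.pf_index, model.dimer_index,
                     model.monomer_kind)

    # place filament along the micrograph y axis through the centre
    img = splat_projection(bent, (0.0, 90.0, 90.0), micrograph_px, pix,
                           sigma_px=config.splat_sigma_px)
    if config.snr is not None:
        sig_var = img[img != 0].var()
        img = img + rng_noise.normal(0.0, np.sqrt(sig_var / config.snr), img.shape)

    half = micrograph_px // 2
    step_px = config.segment_step_A / pix
    n_pick = int((0.7 * micrograph_px) / step_px)
    t = (np.arange(n_pick) - n_pick / 2) * step_px
    # euler (0,90,90) maps model +z to image +y and world +y to image +x
    true_y = half + t
    true_x = half + bend_px * (t * pix / zmax) ** 2
    wob = (config.axis_wobble_amp_px
           * np.sin(2 * np.pi * t * pix / config.axis_wobble_wavelength_A)
           + rng.normal(0.0, config.pick_jitter_px, n_pick))
    picks = np.column_stack([true_x + wob, true_y])
    truth = np.column_stack([true_x, true_y])
    return Image2D(img, pix, {"kind": "micrograph"}), picks, truth


def reference_model_for(filament_record: dict) -> AtomModel:
    """Rebuild the exact centred lattice model behind a simulated filament.

    The per-segment orientations in the manifest/particle table are defined
    relative to this model's coordinate frame, so rendering it (slab-trimmed
    to the box) gives the ground-truth reference volume for the filament.
    """
    r = filament_record
    spec = LatticeSpec(r["n_pf"], r["handedness"], r["monomer_spacing_A"],
                       r["lattice_radius_A"], r["model_n_dimers"],
                       r.get("decorate_kinesin", "none"))
    return build_microtubule(spec, HelicalSymmetry(r["twist_deg"], r["rise_A"]))


def render_reference_volume(filament_record: dict, box_px: int,
                            voxel_size_A: float = 4.0, margin_px: int = 6):
    """Ground-truth reference volume for a simulated filament type.

    Renders the canonical model trimmed to the box (atoms whose kernel would
    leave the grid are dropped; the coordinate frame is unchanged, so the
    manifest orientations remain exact).
    """
    from .imaging import render_density

    model = reference_model_for(filament_record)
    z_safe = (box_px / 2 - margin_px) * voxel_size_A
    r_safe = np.sqrt(np.sum(model.positions[:, :2] ** 2, axis=1))
    keep = (np.abs(model.positions[:, 2]) <= z_safe) & (r_safe <= z_safe * 10)
    trimmed = AtomModel(model.positions[keep], model.weights[keep],
                        model.pf_index[keep], model.dimer_index[keep],
                        model.monomer_kind[keep])
    return render_density(trimmed, voxel_size_A, box_px)
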