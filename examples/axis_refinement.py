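"""Refine noisy filament picks against reference projections.

A synthetic micrograph holds one gently bent filament; picked coordinates
carry a 2 px sinusoidal wobble plus jitter. Four centring cycles of
quadratic-curve fitting and translation-only projection matching bring the
axis to sub-half-pixel accuracy. Takes ~10 seconds.
"""

import numpy as np

from mthelix.axis import FilamentTrack, refine_axis
from mthelix.lattice import HelicalSymmetry, LatticeSpec
from mthelix.simulate import (FilamentTypeMix, SimConfig,
                              generate_filament_dataset, generate_micrograph,
                              render_reference_volume)

mix = FilamentTypeMix(LatticeSpec(15, "R"), 1, HelicalSymmetry(168.083, 5.50))
sim = SimConfig(seed=5, snr=1.0, axis_wobble_amp_px=2.0, pick_jitter_px=0.5,
                filament_types=[mix], n_segments_per_filament=4)
micrograph, picks, truth = generate_micrograph(sim, mix, 768)
_, _, manifest = generate_filament_dataset(sim)
reference = render_reference_volume(manifest.filaments[0], 96)

pix = micrograph.pixel_size_A
initial = np.sqrt(np.mean(np.sum((picks - truth) ** 2, axis=1)))
print(f"picked-coordinate RMS error: {initial:.2f} px")

log = []
track = refine_axis(FilamentTrack(0, picks * pix, 82.0), micrograph,
                    reference, n_cycles=4, log=log)
for entry in log:
    print(f"cycle {entry['cycle']}: RMS correction "
          f"{entry['rms_correction_px']:.2f} px")

pts = track.points_A / pix
fx = np.interp(pts[:, 1], truth[:, 1], truth[:, 0])
print(f"residual to the true axis after 4 cycles: "
      f"{np.sqrt(np.mean((pts[:, 0] - fx) ** 2)):.2f} px "
      f"(samples every {np.linalg.norm(np.diff(track.points_A, axis=0), axis=1).mean():.0f} A)")
# corrections shrink cycle over cycle; the refined axis sits well under half
# a pixel from the truth, sampled every ~82 A (15 helical rises)
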