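"""Recover helical twist/rise from a map by real-space self-correlation search.

One tubulin-dimer asymmetric unit is rendered and expanded into a full
lattice by the screw, then the symmetry is searched blind over a
twist x rise grid with parabolic + simplex refinement. Takes ~1 minute.
"""

from mthelix.imaging import render_density
from mthelix.lattice import (AtomModel, HelicalSymmetry, LatticeSpec,
                             build_microtubule)
from mthelix.reconstruct import estimate_symmetry, impose_helical_symmetry

TRUE = HelicalSymmetry(168.083, 5.50)

model = build_microtubule(LatticeSpec(15, "R", n_dimers_per_pf=1), TRUE)
keep = (model.pf_index == 0) & (model.dimer_index == 0)
unit = AtomModel(model.positions[keep], model.weights[keep],
                 model.pf_index[keep], model.dimer_index[keep],
                 model.monomer_kind[keep])
volume = impose_helical_symmetry(render_density(unit, 4.0, 96), TRUE, 0.8)

est = estimate_symmetry(volume, (160.0, 175.0), (4.0, 7.0),
                        grid_steps=(0.5, 0.25))
print(f"recovered twist {est.symmetry.twist_deg:.4f} deg "
      f"(true {TRUE.twist_deg}), rise {est.symmetry.rise_A:.4f} A "
      f"(true {TRUE.rise_A})")
print(f"peak correlation {est.correlation:.4f}, "
      f"confidence {est.confidence:.2f}, low_confidence={est.low_confidence}")
# twist recovers to a few thousandths of a degree, rise to ~0.01 A; a
# featureless map would be flagged low_confidence instead
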