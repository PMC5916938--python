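"""Build microtubule lattices and curved protofilaments; measure their screws.

Constructs a 15-protofilament right-handed lattice with the per-dimer screw
observed for kinesin-decorated microtubules and a curved protofilament with
the published helical path, then recovers both geometries by least-squares
superposition + screw decomposition.
"""

from mthelix.curvature import profile_protofilament
from mthelix.lattice import (HelicalSymmetry, LatticeSpec, SpiralSpec,
                             build_microtubule, build_protofilament_spiral,
                             measure_intersubunit_transform)

lattice = build_microtubule(LatticeSpec(15, "R", n_dimers_per_pf=3),
                            HelicalSymmetry(168.083, 5.50))
screw = measure_intersubunit_transform(lattice, (0, 0), (1, 0))
print(f"lattice inter-unit screw: twist {screw.angle_deg:.3f} deg, "
      f"rise {screw.rise_A:.2f} A, shear {screw.shear_A:.2e} A")
# -> exactly the (168.083, 5.50) screw the lattice was built with; shear ~ 0

spiral = build_protofilament_spiral(SpiralSpec(23.82, 11.1, 20))
summary = profile_protofilament(spiral, 0).summary()
print(f"curved protofilament: {summary['dimer_angle_mean_deg']:.2f} deg and "
      f"{summary['dimer_rise_mean_A']:.1f} A per dimer, "
      f"{summary['monomer_angle_mean_deg']:.2f} deg per monomer")
# -> the 23.82 deg / 11.1 A helical path, split 11.91 deg per monomer step

ring = build_protofilament_spiral(SpiralSpec(24.0, 0.0, 15))
mono = measure_intersubunit_transform(ring, (0, 0, "alpha"), (0, 0, "beta"))
print(f"closed 15-dimer ring: {mono.angle_deg:.1f} deg between monomers "
      f"(24 deg per dimer, curvature split evenly inside the dimer)")
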