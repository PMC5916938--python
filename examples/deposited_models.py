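"""Optional cross-check against deposited atomic models (needs network).

Downloads the curved-tubulin model PDB 6B0C and the straight-lattice models
6B0I and 6B0L from the PDB, and measures the C-alpha RMSD of straight vs
curved tubulin after superposition. Which straight model anchors the
published per-subunit values is not recorded, so both pairings are printed.

Everything else in this package runs fully offline; this script is the one
deliberate exception.
"""

import urllib.request
from pathlib import Path

import numpy as np

from mthelix.curvature import load_calpha
from mthelix.lattice import rmsd_after_superposition

CACHE = Path("scratch/pdb")


def fetch(code: str) -> Path:
    CACHE.mkdir(parents=True, exist_ok=True)
    path = CACHE / f"{code}.pdb"
    if not path.exists():
        urllib.request.urlretrieve(
            f"https://files.rcsb.org/download/{code}.pdb", path)
    return path


curved = fetch("6b0c")
for straight_code in ("6b0i", "6b0l"):
    straight = fetch(straight_code)
    for chain_curved, chain_straight, label in (("B", "B", "alpha-tubulin"),
                                                ("C", "C", "beta-tubulin")):
        a = load_calpha(curved, chain_curved)
        b = load_calpha(straight, chain_straight)
        n = min(len(a), len(b))
        if n < 3:
            continue
        r = rmsd_after_superposition(a[:n], b[:n])
        print(f"{straight_code.upper()} vs 6B0C, {label}: "
              f"Calpha RMSD {r:.2f} A over {n} residues")
# values around 2 A reflect the internal rearrangement of tubulin between
# the straight lattice and the kinesin-13-bent conformation
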