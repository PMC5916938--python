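"""Curvature statistics of protofilament models.

Turns fitted or constructed models into per-junction screw parameters: the
rotation between successive tubulin monomers and dimers along a
protofilament, the rise along and shear perpendicular to the screw axis, and
straight-vs-curved RMSD comparisons (including deposited atomic models read
from PDB/mmCIF when available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .lattice import (AtomModel, ScrewParams, measure_intersubunit_transform,
                      rmsd_after_superposition)

__all__ = ["CurvatureProfile", "profile_protofilament",
           "compare_straight_vs_curved", "load_calpha"]


@dataclass
class CurvatureProfile:
    pf_index: int
    monomer_screws: list  # ScrewParams per monomer junction, chain order
    dimer_screws: list  # ScrewParams per dimer junction
    skipped_junctions: list = field(default_factory=list)

    def summary(self) -> dict:
        mono = np.array([s.angle_deg for s in self.monomer_screws])
        dim = np.array([s.angle_deg for s in self.dimer_screws])
        dim_rise = np.array([s.rise_A for s in self.dimer_screws])
        dim_shear = np.array([s.shear_A for s in self.dimer_screws])
        out = {}
        if len(mono):
            out["monomer_angle_mean_deg"] = float(mono.mean())
            out["monomer_angle_sd_deg"] = float(mono.std())
        if len(dim):
            out.update(dimer_angle_mean_deg=float(dim.mean()),
                       dimer_angle_sd_deg=float(dim.std()),
                       dimer_rise_mean_A=float(np.abs(dim_rise).mean()),
                       dimer_shear_mean_A=float(dim_shear.mean()))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for level, screws in (("monomer", self.monomer_screws),
                              ("dimer", self.dimer_screws)):
            for j, s in enumerate(screws):
                rows.append({"pf": self.pf_index, "level": level, "junction": j,
                             "angle_deg": s.angle_deg, "rise_A": s.rise_A,
                             "shear_A": s.shear_A})
        return pd.DataFrame(rows)


def _chain_subunits(model: AtomModel, pf: int):
    """(dimer, kind) pairs along the protofilament in chain order."""
    sel = model.pf_index == pf
    dimers = np.unique(model.dimer_index[sel])
    out = []
    for d in sorted(dimers):
        for kind in ("alpha", "beta"):
            mask = sel & (model.dimer_index == d) & (model.monomer_kind == kind)
            out.append(((int(d), kind), bool(mask.any())))
    return out


def profile_protofilament(model: AtomModel, pf_index: int = 0
                          ) -> CurvatureProfile:
    """Measure the screw between successive subunits along one protofilament.

    Monomer junctions chain alpha -> beta -> alpha' ...; dimer junctions use
    whole-dimer superpositions. Missing subunits are skipped with the gap
    recorded.
    """
    chain = _chain_subunits(model, pf_index)
    present = [s for s, ok in chain if ok]
    if len(present) < 2:
        raise ValueError(f"protofilament {pf_index} has fewer than 2 subunits")
    skipped = [s for s, ok in chain if not ok
               and chain[0][0] <= s <= chain[-1][0]]
    mono = []
    for a, b in zip(present[:-1], present[1:]):
        expected_next = (a[0] + (a[1] == "beta"), "beta" if a[1] == "alpha"
                         else "alpha")
        if b != expected_next:
            skipped.append(b)
            continue
        mono.append(measure_intersubunit_transform(
            model, (pf_index, a[0], a[1]), (pf_index, b[0], b[1])))
    dimers = sorted({d for (d, _k) in present})
    dim = []
    for a, b in zip(dimers[:-1], dimers[1:]):
        if b != a + 1:
            continue
        dim.append(measure_intersubunit_transform(model, (pf_index, a),
                                                  (pf_index, b)))
    return CurvatureProfile(pf_index, mono, dim, skipped)


def compare_straight_vs_curved(model_straight, model_curved,
                               pairing: dict | None = None) -> pd.DataFrame:
    """Per-subunit-kind RMSD between straight and curved models.

    ``pairing`` optionally maps subunit kind -> (indices_straight,
    indices_curved); by default every common (pf, dimer, kind) subunit is
    superposed individually. Returns a table with one row per kind
    (alpha / beta / kinesin) carrying the mean per-subunit RMSD.
    """
    rows = []
    for kind in ("alpha", "beta", "kinesin"):
        if pairing is not None and kind not in pairing:
            continue
        if pairing is not None:
            ia, ib = pairing[kind]
            r = rmsd_after_superposition(model_straight.positions,
                                         model_curved.positions, (ia, ib))
            rows.append({"kind": kind, "n_subunits": len(ia), "rmsd_A": r})
            continue
        keys_s = {(p, d) for p, d, k in zip(model_straight.pf_index,
                                            model_straight.dimer_index,
                                            model_straight.monomer_kind)
                  if k == kind}
        keys_c = {(p, d) for p, d, k in zip(model_curved.pf_index,
                                            model_curved.dimer_index,
                                            model_curved.monomer_kind)
                  if k == kind}
        common = sorted(keys_s & keys_c)
        if not common:
            warnings.warn(f"no common {kind} subunits; row omitted",
                          stacklevel=2)
            continue
        vals = [rmsd_after_superposition(
            model_straight.subunit(p, d, kind),
            model_curved.subunit(p, d, kind)) for p, d in common]
        rows.append({"kind": kind, "n_subunits": len(common),
                     "rmsd_A": float(np.mean(vals))})
    return pd.DataFrame(rows)


def load_calpha(path, chain: str | None = None) -> np.ndarray:
    """C-alpha coordinates from a PDB/mmCIF file (deposited-model cross-checks)."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    coords = []
    for ch in st[0]:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            atom = res.find_atom("CA", "*")
            if atom is not None:
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    return np.asarray(coords)
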