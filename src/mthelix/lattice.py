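"""Pseudo-atomic microtubule lattices, curved-protofilament spirals, and screw geometry.

The model system is a kinesin-decorated microtubule: 11-16 protofilaments of
alpha/beta-tubulin dimers arranged on a helical lattice, with one kinesin
motor domain bound per dimer (or per two dimers on curved protofilaments).
The asymmetric unit of the helical symmetry is one tubulin dimer plus any
bound kinesin density; successive units along the 1-start helix are related
by a screw of (twist_deg, rise_A).

Subunits are small rigid clusters of non-coplanar pseudo-atoms rather than
single points so that least-squares superposition between subunits is
well-posed and yields the exact inter-subunit screw transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "HelicalSymmetry", "LatticeSpec", "SpiralSpec", "AtomModel", "ScrewParams",
    "default_symmetry", "build_microtubule", "build_protofilament_spiral",
    "screw_decompose", "compose_screw", "kabsch", "measure_intersubunit_transform",
    "rmsd_after_superposition",
]

# Pseudo-atom cluster for one tubulin monomer (Angstrom offsets from the
# monomer centre). Non-coplanar and chirality-bearing so superposition is
# unambiguous; extent ~20 A matches a coarse tubulin monomer footprint.
MONOMER_TEMPLATE = np.array([
    [0.0, 0.0, 0.0],
    [8.0, 0.0, 0.0],
    [0.0, 7.0, 0.0],
    [0.0, 0.0, 9.0],
    [-6.0, 5.0, 4.0],
    [5.0, -6.0, -7.0],
])
MONOMER_WEIGHTS = np.array([1.5, 1.0, 1.0, 1.0, 1.0, 1.0])
# beta-tubulin carries more density than alpha in the coarse model, giving the
# lattice a per-dimer (not just per-monomer) density periodicity, as in real
# tubulin; geometry is identical so screw measurements are unaffected
BETA_WEIGHT_SCALE = 1.3

# Kinesin motor domain: slightly smaller cluster, sits radially outward.
KINESIN_TEMPLATE = np.array([
    [0.0, 0.0, 0.0],
    [6.0, 0.0, 0.0],
    [0.0, 6.0, 0.0],
    [0.0, 0.0, 6.0],
    [-4.0, -4.0, 3.0],
])
KINESIN_WEIGHTS = np.array([1.2, 0.9, 0.9, 0.9, 0.9])

KINESIN_RADIAL_OFFSET_A = 38.0

_DEFAULT_MONOMER_SPACING_A = 40.95
_DEFAULT_LATTICE_RADIUS_A = 110.0

# Start number of the dimer 1-start helix for each protofilament count,
# chosen coprime with n so the helix visits every protofilament.
_START_NUMBER = {11: 5, 12: 5, 13: 6, 14: 5, 15: 7, 16: 7}
_DEFAULT_SUPERTWIST_DEG = 0.3


@dataclass(frozen=True)
class HelicalSymmetry:
    """Per-asymmetric-unit screw of a helical lattice.

    twist_deg is signed: positive means a right-handed screw when advancing
    along the +z filament axis.
    """

    twist_deg: float
    rise_A: float

    def __post_init__(self):
        if not self.rise_A > 0:
            raise ValueError(f"rise_A must be > 0, got {self.rise_A}")
        if not (-180.0 < self.twist_deg <= 180.0):
            raise ValueError(f"twist_deg must be in (-180, 180], got {self.twist_deg}")


@dataclass
class LatticeSpec:
    """Geometry of a straight microtubule lattice."""

    n_protofilaments: int
    handedness: str = "R"
    monomer_spacing_A: float = _DEFAULT_MONOMER_SPACING_A
    lattice_radius_A: float = _DEFAULT_LATTICE_RADIUS_A
    n_dimers_per_pf: int = 4
    decorate_kinesin: str = "none"  # none | every_dimer

    def __post_init__(self):
        if not 11 <= self.n_protofilaments <= 16:
            raise ValueError(
                f"n_protofilaments must be 11-16, got {self.n_protofilaments}")
        if self.handedness not in ("R", "L"):
            raise ValueError(f"handedness must be 'R' or 'L', got {self.handedness!r}")
        if self.lattice_radius_A <= 0:
            raise ValueError("lattice_radius_A must be > 0")
        if self.n_dimers_per_pf < 1:
            raise ValueError("n_dimers_per_pf must be >= 1")
        if self.decorate_kinesin not in ("none", "every_dimer"):
            raise ValueError(f"unknown decoration {self.decorate_kinesin!r}")


@dataclass
class SpiralSpec:
    """Geometry of a curved protofilament spiral or closed ring.

    The dimer centres lie on a helix of per-dimer rotation
    curvature_per_dimer_deg and per-dimer axial rise rise_per_dimer_A (zero
    for a planar closed ring). Curvature is split evenly between the two
    monomer steps inside each dimer.
    """

    curvature_per_dimer_deg: float
    rise_per_dimer_A: float
    n_dimers: int
    decoration: str = "none"  # none | every_dimer | every_other_dimer
    monomer_spacing_A: float = _DEFAULT_MONOMER_SPACING_A

    def __post_init__(self):
        if not 0 < self.curvature_per_dimer_deg < 180:
            raise ValueError("curvature_per_dimer_deg must be in (0, 180)")
        if self.n_dimers < 1:
            raise ValueError("n_dimers must be >= 1")
        if self.decoration not in ("none", "every_dimer", "every_other_dimer"):
            raise ValueError(f"unknown decoration {self.decoration!r}")

    @property
    def ring_radius_A(self) -> float:
        """Radius of the circle of monomer centres.

        Consecutive monomer centres are one monomer spacing apart (chord),
        separated by half the per-dimer curvature.
        """
        half_step = np.radians(self.curvature_per_dimer_deg / 4.0)
        return self.monomer_spacing_A / (2.0 * np.sin(half_step))

    @property
    def is_closed_ring(self) -> bool:
        total = self.n_dimers * self.curvature_per_dimer_deg
        return self.rise_per_dimer_A == 0 and abs(total - 360.0) < 0.01 * 360.0


@dataclass
class ScrewParams:
    """Screw decomposition of a rigid transform x -> R x + t.

    angle about a unit axis through the origin, translation split into a
    component along the axis (rise) and a perpendicular component of
    magnitude shear along shear_dir. angle is reported in [0, 180] with the
    handedness carried by the axis direction.
    """

    angle_deg: float
    axis: np.ndarray
    rise_A: float
    shear_A: float
    shear_dir: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def signed_twist_about(self, ref_axis=(0.0, 0.0, 1.0)) -> float:
        """Rotation angle signed by the axis component along ref_axis."""
        s = float(np.dot(self.axis, ref_axis))
        return self.angle_deg * (1.0 if s >= 0 else -1.0)


class AtomModel:
    """Labeled pseudo-atomic coordinates.

    positions: (N, 3) Angstrom; weights: (N,) mass weights; labels are three
    parallel arrays (pf_index, dimer_index, monomer_kind) with monomer_kind in
    {'alpha', 'beta', 'kinesin'}. Atoms of one subunit are stored contiguously
    in template order, so same-kind subunits correspond atom-by-atom.
    """

    def __init__(self, positions, weights, pf_index, dimer_index, monomer_kind,
                 meta=None):
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        self.weights = np.asarray(weights, dtype=float)
        self.pf_index = np.asarray(pf_index, dtype=int)
        self.dimer_index = np.asarray(dimer_index, dtype=int)
        self.monomer_kind = np.asarray(monomer_kind, dtype="U7")
        self.meta = dict(meta or {})
        n = len(self.positions)
        if n == 0:
            raise ValueError("AtomModel must be non-empty")
        if not (len(self.weights) == len(self.pf_index) == len(self.dimer_index)
                == len(self.monomer_kind) == n):
            raise ValueError("label arrays must match number of atoms")

    def __len__(self):
        return len(self.positions)

    def subunit(self, pf: int, dimer: int, kind: str | None = None) -> np.ndarray:
        """Coordinates of one labeled subunit (monomer, kinesin, or whole dimer)."""
        mask = (self.pf_index == pf) & (self.dimer_index == dimer)
        if kind is not None:
            mask &= self.monomer_kind == kind
        coords = self.positions[mask]
        if len(coords) == 0:
            raise KeyError(f"no atoms for subunit (pf={pf}, dimer={dimer}, kind={kind})")
        return coords

    def concat(self, other: "AtomModel") -> "AtomModel":
        return AtomModel(
            np.vstack([self.positions, other.positions]),
            np.concatenate([self.weights, other.weights]),
            np.concatenate([self.pf_index, other.pf_index]),
            np.concatenate([self.dimer_index, other.dimer_index]),
            np.concatenate([self.monomer_kind, other.monomer_kind]),
            meta={**other.meta, **self.meta},
        )

    def transformed(self, rotation: np.ndarray, translation=(0, 0, 0)) -> "AtomModel":
        """Copy with positions mapped through x -> R x + t."""
        pos = self.positions @ np.asarray(rotation).T + np.asarray(translation, float)
        return AtomModel(pos, self.weights, self.pf_index, self.dimer_index,
                         self.monomer_kind, meta=self.meta)

    # ---- I/O ----------------------------------------------------------------

    _KIND_CODE = {"alpha": "A", "beta": "B", "kinesin": "K"}
    _CODE_KIND = {v: k for k, v in _KIND_CODE.items()}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pf": self.pf_index, "dimer": self.dimer_index,
            "monomer": self.monomer_kind, "x_A": self.positions[:, 0],
            "y_A": self.positions[:, 1], "z_A": self.positions[:, 2],
            "weight": self.weights,
        })

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AtomModel":
        df = pd.read_csv(path, sep="\t")
        return cls(df[["x_A", "y_A", "z_A"]].to_numpy(), df["weight"].to_numpy(),
                   df["pf"].to_numpy(), df["dimer"].to_numpy(), df["monomer"].to_numpy())

    def to_pdb(self, path) -> None:
        """Write as PDB: one chain per protofilament, residue number = dimer
        index, atom name = monomer-kind letter + atom ordinal, weight stored
        in the occupancy column."""
        import gemmi

        st = gemmi.Structure()
        st.name = "mthelix-model"
        model = gemmi.Model("1")
        chain_ids = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        for pf in np.unique(self.pf_index):
            chain = gemmi.Chain(chain_ids[int(pf) % len(chain_ids)])
            for dimer in np.unique(self.dimer_index[self.pf_index == pf]):
                res = gemmi.Residue()
                res.name = "TUB"
                res.seqid = gemmi.SeqId(int(dimer) + 1, " ")
                sel = (self.pf_index == pf) & (self.dimer_index == dimer)
                counters: dict[str, int] = {}
                for pos, w, kind in zip(self.positions[sel], self.weights[sel],
                                        self.monomer_kind[sel]):
                    code = self._KIND_CODE[str(kind)]
                    counters[code] = counters.get(code, 0) + 1
                    atom = gemmi.Atom()
                    atom.name = f"{code}{counters[code]}"
                    atom.element = gemmi.Element("C")
                    atom.pos = gemmi.Position(*pos)
                    atom.occ = float(w)
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        st.write_pdb(str(path))

    @classmethod
    def from_pdb(cls, path) -> "AtomModel":
        import gemmi

        st = gemmi.read_structure(str(path))
        pos, wts, pfs, dimers, kinds = [], [], [], [], []
        chain_ids = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        for chain in st[0]:
            pf = chain_ids.index(chain.name[0])
            for res in chain:
                for atom in res:
                    pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    wts.append(atom.occ)
                    pfs.append(pf)
                    dimers.append(res.seqid.num - 1)
                    kinds.append(cls._CODE_KIND.get(atom.name[0], "alpha"))
        return cls(np.array(pos), np.array(wts), np.array(pfs), np.array(dimers),
                   np.array(kinds))


# ---- construction -----------------------------------------------------------


def default_symmetry(spec: LatticeSpec) -> HelicalSymmetry:
    """Canonical per-dimer helical symmetry for a lattice type.

    The dimer 1-start helix advances by h/n turns per subunit (h a start
    number coprime with n) plus a small supertwist whose sign encodes the
    protofilament handedness; the rise is two monomer spacings divided by n.
    """
    n = spec.n_protofilaments
    h = _START_NUMBER[n]
    sign = 1.0 if spec.handedness == "R" else -1.0
    twist = 360.0 * h / n + sign * _DEFAULT_SUPERTWIST_DEG
    if twist > 180.0:
        twist -= 360.0
    rise = 2.0 * spec.monomer_spacing_A / n
    return HelicalSymmetry(twist, rise)


def _center_axially(pos: np.ndarray) -> np.ndarray:
    """Shift positions so the axial (z) midrange sits at the origin.

    A pure z-shift, so it changes no inter-subunit screw relationship but
    lets the model sit centred in an origin-centred render box.
    """
    z = pos[:, 2]
    return pos - [0.0, 0.0, 0.5 * (z.min() + z.max())]


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _dimer_unit(radius_A, monomer_spacing_A, decorate: bool):
    """One asymmetric unit at azimuth 0: alpha below beta along +z, kinesin
    (optional) radially outward between them. Returns (pos, w, kinds)."""
    alpha = MONOMER_TEMPLATE + [radius_A, 0.0, 0.0]
    beta = MONOMER_TEMPLATE + [radius_A, 0.0, monomer_spacing_A]
    pos = [alpha, beta]
    wts = [MONOMER_WEIGHTS, BETA_WEIGHT_SCALE * MONOMER_WEIGHTS]
    kinds = ["alpha"] * len(alpha) + ["beta"] * len(beta)
    if decorate:
        kin = KINESIN_TEMPLATE + [radius_A + KINESIN_RADIAL_OFFSET_A, 0.0,
                                  monomer_spacing_A / 2.0]
        pos.append(kin)
        wts.append(KINESIN_WEIGHTS)
        kinds += ["kinesin"] * len(kin)
    return np.vstack(pos), np.concatenate(wts), np.array(kinds)


def build_microtubule(spec: LatticeSpec, sym: HelicalSymmetry | None = None
                      ) -> AtomModel:
    """Build a straight microtubule lattice from its per-dimer screw.

    Unit k of the 1-start helix is the reference dimer transformed by the
    k-th power of the screw (rotate k*twist about z, translate k*rise along
    z); protofilament index is k mod n_protofilaments. If the accumulated
    rise around one turn is not close to a whole number of monomer spacings
    the model is flagged (meta['spacing_warning']) and a warning is issued.
    """
    if sym is None:
        sym = default_symmetry(spec)
    n_pf = spec.n_protofilaments
    n_units = n_pf * spec.n_dimers_per_pf

    spacing_ratio = sym.rise_A * n_pf / spec.monomer_spacing_A
    spacing_ok = abs(spacing_ratio - round(spacing_ratio)) <= 0.05 * spacing_ratio
    if not spacing_ok:
        warnings.warn(
            f"rise*n_pf = {sym.rise_A * n_pf:.2f} A is not close to a whole "
            f"number of monomer spacings ({spec.monomer_spacing_A} A)",
            stacklevel=2)

    upos, uw, ukinds = _dimer_unit(spec.lattice_radius_A, spec.monomer_spacing_A,
                                   spec.decorate_kinesin == "every_dimer")
    pos, wts, pfs, dimers, kinds = [], [], [], [], []
    for k in range(n_units):
        R = _rot_z(k * sym.twist_deg)
        pos.append(upos @ R.T + [0.0, 0.0, k * sym.rise_A])
        wts.append(uw)
        pfs.append(np.full(len(upos), k % n_pf))
        dimers.append(np.full(len(upos), k // n_pf))
        kinds.append(ukinds)
    meta = {"spec": spec, "symmetry": sym, "spacing_warning": not spacing_ok}
    return AtomModel(_center_axially(np.vstack(pos)), np.concatenate(wts),
                     np.concatenate(pfs), np.concatenate(dimers),
                     np.concatenate(kinds), meta=meta)


def build_protofilament_spiral(spec: SpiralSpec) -> AtomModel:
    """Build a curved protofilament spiral (or closed planar ring).

    Monomer m sits on the spiral axis (z) helix: rotated m * curvature/2
    about z and raised m * rise/2, starting from a reference monomer at
    ring_radius on the +x axis. Consecutive-dimer screws therefore equal
    (curvature_per_dimer_deg, rise_per_dimer_A) exactly, with the intra-dimer
    curvature split evenly between the two monomer steps. Kinesin decoration
    places one motor-domain cluster per decorated dimer at larger radius.
    """
    step_deg = spec.curvature_per_dimer_deg / 2.0
    step_rise = spec.rise_per_dimer_A / 2.0
    radius = spec.ring_radius_A
    base = MONOMER_TEMPLATE + [radius, 0.0, 0.0]

    pos, wts, pfs, dimers, kinds = [], [], [], [], []
    n_monomers = 2 * spec.n_dimers
    for m in range(n_monomers):
        R = _rot_z(m * step_deg)
        pos.append(base @ R.T + [0.0, 0.0, m * step_rise])
        wts.append(MONOMER_WEIGHTS if m % 2 == 0
                   else BETA_WEIGHT_SCALE * MONOMER_WEIGHTS)
        pfs.append(np.zeros(len(base), dtype=int))
        dimers.append(np.full(len(base), m // 2))
        kinds.append(np.array(["alpha" if m % 2 == 0 else "beta"] * len(base)))

    odd_skip_flag = False
    if spec.decoration != "none":
        decorated = range(0, spec.n_dimers,
                          1 if spec.decoration == "every_dimer" else 2)
        kin_base = KINESIN_TEMPLATE + [radius + KINESIN_RADIAL_OFFSET_A, 0.0, 0.0]
        for d in decorated:
            # between the dimer's two monomers: phase (2d + 0.5) monomer steps
            phase = 2 * d + 0.5
            R = _rot_z(phase * step_deg)
            pos.append(kin_base @ R.T + [0.0, 0.0, phase * step_rise])
            wts.append(KINESIN_WEIGHTS)
            pfs.append(np.zeros(len(kin_base), dtype=int))
            dimers.append(np.full(len(kin_base), d))
            kinds.append(np.array(["kinesin"] * len(kin_base)))
        if spec.decoration == "every_other_dimer" and spec.n_dimers % 2 == 1:
            odd_skip_flag = True  # last dimer bare: skipping pattern wraps oddly

    meta = {"spec": spec, "odd_dimer_bare": odd_skip_flag}
    return AtomModel(_center_axially(np.vstack(pos)), np.concatenate(wts),
                     np.concatenate(pfs), np.concatenate(dimers),
                     np.concatenate(kinds), meta=meta)


# ---- screw geometry ---------------------------------------------------------

_ANGLE_EPS_DEG = 1e-9


def screw_decompose(rotation: np.ndarray, translation: np.ndarray) -> ScrewParams:
    """Decompose a proper rigid transform x -> R x + t into screw parameters.

    Returns the rotation angle in [0, 180] about a unit axis (handedness in
    the axis sign), the translation component along the axis (rise, signed)
    and perpendicular to it (shear >= 0, direction in shear_dir). For a
    near-zero rotation the axis is undefined; the translation direction is
    used with rise = |t| and shear = 0.
    """
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float).reshape(3)
    det = np.linalg.det(rotation)
    if det < 0:
        raise ValueError(f"improper rotation (det = {det:.6f})")
    rot = Rotation.from_matrix(rotation)
    rotvec = rot.as_rotvec()
    angle = np.linalg.norm(rotvec)
    if np.degrees(angle) < _ANGLE_EPS_DEG:
        tnorm = np.linalg.norm(translation)
        axis = translation / tnorm if tnorm > 0 else np.array([0.0, 0.0, 1.0])
        return ScrewParams(0.0, axis, float(tnorm), 0.0)
    axis = rotvec / angle
    rise = float(axis @ translation)
    perp = translation - rise * axis
    shear = float(np.linalg.norm(perp))
    shear_dir = perp / shear if shear > 1e-15 else np.zeros(3)
    return ScrewParams(float(np.degrees(angle)), axis, rise, shear, shear_dir)


def compose_screw(params: ScrewParams) -> tuple[np.ndarray, np.ndarray]:
    """Rebuild the (R, t) pair encoded by a ScrewParams."""
    axis = np.asarray(params.axis, dtype=float)
    R = Rotation.from_rotvec(np.radians(params.angle_deg) * axis).as_matrix()
    t = params.rise_A * axis + params.shear_A * np.asarray(params.shear_dir, float)
    return R, t


def kabsch(source: np.ndarray, target: np.ndarray, weights=None
           ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) with target ~ R @ source + t."""
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    if source.shape != target.shape or len(source) < 3:
        raise ValueError("need two equal coordinate sets of >= 3 points")
    w = np.ones(len(source)) if weights is None else np.asarray(weights, float)
    cs = np.average(source, axis=0, weights=w)
    ct = np.average(target, axis=0, weights=w)
    rot, rssd = Rotation.align_vectors(target - ct, source - cs, weights=w)
    R = rot.as_matrix()
    return R, ct - R @ cs


def measure_intersubunit_transform(model: AtomModel, subunit_a, subunit_b
                                   ) -> ScrewParams:
    """Screw transform relating two labeled subunits of a model.

    Subunits are (pf, dimer) for a whole dimer or (pf, dimer, kind) for a
    single monomer/kinesin; atom correspondence follows template order.
    """
    a = model.subunit(*subunit_a)
    b = model.subunit(*subunit_b)
    if a.shape != b.shape:
        raise ValueError("subunits have different atom counts; cannot pair")
    if len(a) < 3 or np.linalg.matrix_rank(a - a.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("subunit is degenerate (collinear or < 3 atoms)")
    R, t = kabsch(a, b)
    return screw_decompose(R, t)


def rmsd_after_superposition(coords_a: np.ndarray, coords_b: np.ndarray,
                             pairing=None) -> float:
    """RMSD between paired coordinates after optimal rigid superposition.

    ``pairing``: optional (idx_a, idx_b) index arrays selecting equal-size
    subsets; defaults to identity pairing of equal-length sets.
    """
    A = np.asarray(coords_a, float)
    B = np.asarray(coords_b, float)
    if pairing is not None:
        ia, ib = pairing
        if len(ia) != len(ib) or len(ia) == 0:
            raise ValueError("pairing must map equal-size, non-empty subsets")
        A, B = A[np.asarray(ia)], B[np.asarray(ib)]
    if A.shape != B.shape or len(A) == 0:
        raise ValueError("paired coordinate sets must be equal-size and non-empty")
    R, t = kabsch(A, B)
    diff = (A @ R.T + t) - B
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
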