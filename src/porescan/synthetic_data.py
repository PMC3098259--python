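"""Generators with analytically known answers for every analysis stage.

Three families of synthetic inputs:

* **Pores** — walls of pseudo-atoms arranged in rings around an axis, with
  a closed-form inscribed-radius profile r(z) (constant for a cylinder,
  linear for a cone, piecewise for an hourglass constriction).  The wall
  construction guarantees that the discrete wall's inscribed radius
  deviates from the closed form by less than 0.02 Å, which makes these
  structures a rigorous oracle for the plane-marching profiler.

* **Scripted site ensembles** — frames in which one water holds ideal
  hydrogen-bond geometry (2.8 Å donor–acceptor, 0° deviation) to exactly a
  scripted set of partners from an active-site template (two backbone
  carbonyl acceptors, a donor hydroxyl, and an exit hydroxyl), or is
  parked outside the site for vacancy segments.  The state sequence the
  detector should recover is known exactly.

* **Ideal lysine** — a (optionally Nζ-methylated) lysine with ideal
  covalent geometry (C–C 1.52 Å, C–H 1.09 Å, tetrahedral angles) and
  explicit hydrogens, for substrate cross-section arithmetic.

All generators are deterministic; optional positional jitter requires an
explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import Atom, Structure, Ensemble
from .hbond_dynamics import (
    StateRules,
    STATE_TRIAD_BOUND,
    STATE_EXIT_CAPTURED,
    STATE_TRANSIT,
    STATE_VACANT,
)

__all__ = [
    "PoreSpec",
    "make_pore",
    "OccupancyScript",
    "Segment",
    "make_site_ensemble",
    "site_template",
    "make_lysine",
]

_TETRA = np.arccos(-1.0 / 3.0)          # 109.471°
_HOH_ANGLE = np.deg2rad(104.52)
_OH_BOND = 0.96
_HB_IDEAL = 2.8                          # ideal donor–acceptor distance


# ---------------------------------------------------------------------------
# Pores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoreSpec:
    """Geometry of a synthetic pore with a known inscribed-radius profile.

    ``ring_spacing`` should equal the profiler's plane spacing so that wall
    rings sit exactly on station planes; the construction refuses spacings
    too coarse for the 0.02 Å oracle guarantee.
    """

    shape: str = "cylinder"              # cylinder | cone | constricted
    inner_radius: float = 2.3            # cylinder radius / constricted bulk radius
    r_start: float = 1.5                 # cone entry radius
    r_end: float = 3.4                   # cone exit radius (< end-of-pore 3.5)
    neck_radius: float = 1.45
    neck_halfwidth: float = 2.0
    length: float = 12.0
    wall_vdw: float = 1.5
    ring_spacing: float = 0.25
    n_ring_atoms: int = 24
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_shells: int = 3                    # outer padding shells (kill spurious optima)
    shell_spacing: float = 1.5

    def nominal_radius(self, z: float | np.ndarray):
        """Wall radius (before VDW subtraction effects) as a function of z."""
        z = np.asarray(z, dtype=float)
        if self.shape == "cylinder":
            return np.full_like(z, self.inner_radius)
        if self.shape == "cone":
            return self.r_start + (self.r_end - self.r_start) * z / self.length
        if self.shape == "constricted":
            zc = 0.5 * self.length
            dip = 1.0 - ((z - zc) / self.neck_halfwidth) ** 2
            return self.inner_radius - (self.inner_radius - self.neck_radius) * np.clip(
                dip, 0.0, None
            )
        raise ValueError(f"unknown pore shape {self.shape!r}")

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        u = np.asarray(self.axis, dtype=float)
        u = u / np.linalg.norm(u)
        helper = np.zeros(3)
        helper[int(np.argmin(np.abs(u)))] = 1.0
        v = np.cross(u, helper)
        v /= np.linalg.norm(v)
        return u, v, np.cross(u, v)

    def seed_hint(self) -> np.ndarray:
        u, _, _ = self.frame()
        return np.asarray(self.origin, dtype=float) + 0.5 * self.length * u


def _required_ring_spacing(spec: PoreSpec) -> float:
    """Largest ring spacing keeping the between-ring overshoot below 0.015 Å."""
    zs = np.arange(0.0, spec.length + 1e-9, min(spec.ring_spacing, 0.05))
    d_min = float(np.min(spec.nominal_radius(zs))) + spec.wall_vdw
    # sqrt(d^2 + (dz/2)^2) - d <= e  =>  dz <= 2*sqrt(2*d*e + e^2)
    e = 0.015
    return 2.0 * np.sqrt(2.0 * d_min * e + e * e)


def make_pore(spec: PoreSpec):
    """Build the pseudo-atom wall and return ``(structure, analytic_profile)``.

    ``analytic_profile(z)`` is the exact on-axis inscribed radius of the
    constructed wall: ``min over rings m of sqrt(d_m^2 + (z - z_m)^2) -
    vdw``, which coincides with the closed-form r(z) at ring planes (and,
    for slanted walls, with the slope-corrected perpendicular clearance).
    """
    dz_max = _required_ring_spacing(spec)
    if spec.ring_spacing > dz_max:
        raise ValueError(
            f"ring_spacing {spec.ring_spacing} too coarse for the 0.02 Å "
            f"guarantee; use <= {dz_max:.3f} Å"
        )
    # wall gap check: the chord between adjacent ring atoms must be closed
    # by their VDW spheres, or the optimizer could tunnel between them
    zs = np.arange(0.0, spec.length + 1e-9, spec.ring_spacing)
    d_wall = spec.nominal_radius(zs) + spec.wall_vdw
    d_max = float(np.max(d_wall))
    if d_max * np.sin(np.pi / spec.n_ring_atoms) > spec.wall_vdw:
        needed = int(np.ceil(np.pi / np.arcsin(spec.wall_vdw / d_max)))
        raise ValueError(f"n_ring_atoms too small; use >= {needed}")

    u, v, w = spec.frame()
    origin = np.asarray(spec.origin, dtype=float)
    coords = []
    for z, d in zip(zs, d_wall):
        ring_center = origin + z * u
        # wall ring plus concentric padding shells
        for m in range(spec.n_shells + 1):
            radius = d + m * spec.shell_spacing
            if m == 0:
                n_atoms = spec.n_ring_atoms
                phase = 0.0
            else:
                # arc spacing <= vdw keeps the inter-shell space blocked
                n_atoms = max(
                    spec.n_ring_atoms, int(np.ceil(2 * np.pi * radius / spec.wall_vdw))
                )
                phase = 0.5 * m  # stagger shells deterministically
            angles = phase + 2 * np.pi * np.arange(n_atoms) / n_atoms
            ring = (
                ring_center[None, :]
                + radius * np.cos(angles)[:, None] * v[None, :]
                + radius * np.sin(angles)[:, None] * w[None, :]
            )
            coords.append(ring)
    coords = np.vstack(coords)
    n = len(coords)
    structure = Structure(
        serial=np.arange(1, n + 1),
        name=np.array(["X"] * n, dtype=object),
        residue_name=np.array(["POR"] * n, dtype=object),
        chain=np.array(["W"] * n, dtype=object),
        residue_number=np.ones(n, dtype=int),
        element=np.array(["C"] * n, dtype=object),
        coords=coords,
        vdw=np.full(n, spec.wall_vdw),
        source=f"synthetic:{spec.shape}",
    )

    z_rings = zs.copy()
    d_rings = d_wall.copy()
    axial_origin = float(origin @ u)

    def analytic_profile(axial: float | np.ndarray) -> np.ndarray:
        """Inscribed radius at absolute axial coordinate(s) along the axis."""
        z = np.atleast_1d(np.asarray(axial, dtype=float)) - axial_origin
        dist = np.sqrt(
            d_rings[None, :] ** 2 + (z[:, None] - z_rings[None, :]) ** 2
        )
        out = dist.min(axis=1) - spec.wall_vdw
        return out if out.size > 1 else float(out[0])

    return structure, analytic_profile


# ---------------------------------------------------------------------------
# Scripted active-site ensembles
# ---------------------------------------------------------------------------

# bond-set vocabulary of one segment (labels refer to the template residues)
TRIAD = frozenset({"G292", "A295", "Y305"})
A295_ONLY = frozenset({"A295"})
Y335_ONLY = frozenset({"Y335"})
MIXED_A295_Y335 = frozenset({"A295", "Y335"})
UNBONDED = frozenset()

_SUPPORTED_BOND_SETS = {TRIAD, A295_ONLY, Y335_ONLY, MIXED_A295_Y335, UNBONDED}


@dataclass(frozen=True)
class Segment:
    """``bonds=None`` means no water occupies the site (vacancy)."""

    n_frames: int
    bonds: frozenset | None
    water_serial: int = 9001

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("segment frame counts must be >= 1")


@dataclass
class OccupancyScript:
    segments: list[Segment]
    stride_ps: float = 10.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("script needs at least one segment")

    @property
    def n_frames(self) -> int:
        return sum(s.n_frames for s in self.segments)

    def expected_states(self, rules: StateRules | None = None) -> list[str]:
        """The state sequence a correct detector must recover."""
        rules = rules or StateRules()
        out: list[str] = []
        for seg in self.segments:
            if seg.bonds is None:
                state = STATE_VACANT
            else:
                counts = {lbl: 1 for lbl in seg.bonds}
                state = rules.classify(counts, water_present=True)
            out.extend([state] * seg.n_frames)
        return out

    def expected_counts(self, labels: tuple[str, ...] = ("G292", "A295", "Y305", "Y335")) -> np.ndarray:
        rows = []
        for seg in self.segments:
            bonds = seg.bonds or frozenset()
            row = [1 if lbl in bonds else 0 for lbl in labels]
            rows.extend([row] * seg.n_frames)
        return np.array(rows, dtype=int)


def _unit(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x / np.linalg.norm(x)


def _site_layout() -> dict:
    """Fixed template geometry and the scripted water placements.

    The triad sits on the −x side (two carbonyl oxygens splayed in ±y, the
    donor hydroxyl above in +z); the exit hydroxyl lies on +x.  Each water
    placement realises exactly its scripted bond set under the 3.5 Å / 35°
    criterion — verified arithmetically in the test suite.
    """
    half = 0.5 * _HOH_ANGLE
    u1 = np.array([-np.cos(half), np.sin(half), 0.0])     # toward G292 O
    u2 = np.array([-np.cos(half), -np.sin(half), 0.0])    # toward A295 O
    u3 = _unit([-0.3, 0.0, 0.954])                        # toward Y305 O
    g292_o = _HB_IDEAL * u1
    a295_o = _HB_IDEAL * u2
    y305_o = _HB_IDEAL * u3
    y335_o = np.array([4.8, 0.0, 0.0])
    exit_water = np.array([2.0, 0.0, 0.0])

    # TRANSIT water donating only to A295
    w_dir = _unit([0.0, -0.35, 0.937])
    transit_o = a295_o + _HB_IDEAL * w_dir
    transit_h1 = transit_o + _OH_BOND * (-w_dir)
    perp = np.array([-1.0, 0.0, 0.0])
    h2_dir = np.cos(_HOH_ANGLE) * (-w_dir) + np.sin(_HOH_ANGLE) * perp
    transit_h2 = transit_o + _OH_BOND * _unit(h2_dir)

    # mixed A295 + Y335 water on the segment between the two oxygens
    seg_dir = _unit(y335_o - a295_o)
    mixed_o = a295_o + 3.42 * seg_dir
    mixed_h1 = mixed_o + _OH_BOND * (-seg_dir)
    perp_m = _unit(np.cross(np.cross(seg_dir, [0, 0, 1.0]), seg_dir))
    mixed_h2_dir = np.cos(_HOH_ANGLE) * (-seg_dir) + np.sin(_HOH_ANGLE) * perp_m
    mixed_h2 = mixed_o + _OH_BOND * _unit(mixed_h2_dir)

    unbonded_o = np.array([0.8, 0.0, -1.8])
    parked_o = np.array([30.0, 0.0, 0.0])

    def water(o, h1_dir, h2_dir):
        o = np.asarray(o, dtype=float)
        return {
            "O": o,
            "H1": o + _OH_BOND * _unit(h1_dir),
            "H2": o + _OH_BOND * _unit(h2_dir),
        }

    return {
        "residues": {
            "G292": {
                "resname": "GLY",
                "resnum": 292,
                "atoms": {"C": g292_o + 1.23 * u1, "O": g292_o},
            },
            "A295": {
                "resname": "ALA",
                "resnum": 295,
                "atoms": {"C": a295_o + 1.23 * u2, "O": a295_o},
            },
            "Y305": {
                "resname": "TYR",
                "resnum": 305,
                "atoms": {
                    "CZ": y305_o + 1.38 * u3,
                    "OH": y305_o,
                    "HH": y305_o - _OH_BOND * u3,   # donating toward the triad water
                },
            },
            "Y335": {
                "resname": "TYR",
                "resnum": 335,
                "atoms": {
                    "CZ": y335_o + np.array([1.38, 0.0, 0.0]),
                    "OH": y335_o,
                    "HH": y335_o + _OH_BOND * _unit(exit_water - y335_o),
                },
            },
        },
        "waters": {
            TRIAD: water(np.zeros(3), u1, u2),
            A295_ONLY: {"O": transit_o, "H1": transit_h1, "H2": transit_h2},
            MIXED_A295_Y335: {"O": mixed_o, "H1": mixed_h1, "H2": mixed_h2},
            Y335_ONLY: water(exit_water, u1, u2),
            UNBONDED: water(unbonded_o, u1, u2),
            None: water(parked_o, [0, 1.0, 0], [0.399, -0.917, 0]),
        },
    }


def site_template() -> Structure:
    """The fixed four-residue active-site template (no water)."""
    layout = _site_layout()
    atoms = []
    serial = 1
    for res in layout["residues"].values():
        for name, pos in res["atoms"].items():
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    residue_name=res["resname"],
                    chain="A",
                    residue_number=res["resnum"],
                    element="H" if name.startswith("H") else name[0],
                    position=np.asarray(pos, dtype=float),
                )
            )
            serial += 1
    return Structure.from_atoms(atoms, source="synthetic:site_template")


def make_site_ensemble(
    script: OccupancyScript,
    jitter: float = 0.0,
    seed: int | None = None,
) -> Ensemble:
    """Frames realising a scripted water-occupancy sequence.

    Every frame contains the four-residue template plus one water; during
    vacancy segments the water is parked far outside the site so that frame
    atom counts stay constant.  ``jitter`` adds isotropic Gaussian noise
    (Å) to every coordinate and requires ``seed``.
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    if jitter > 0 and seed is None:
        raise ValueError("jitter requires an explicit seed")
    rng = np.random.default_rng(seed) if jitter > 0 else None
    layout = _site_layout()

    for idx, seg in enumerate(script.segments):
        if seg.bonds is not None and seg.bonds not in _SUPPORTED_BOND_SETS:
            raise ValueError(
                f"segment {idx}: bond set {set(seg.bonds)} is not geometrically "
                "realizable with a single water in this template"
            )

    template = site_template()
    frames: list[Structure] = []
    for seg in script.segments:
        placement = layout["waters"][seg.bonds if seg.bonds is not None else None]
        for _ in range(seg.n_frames):
            atoms = list(template)
            base_serial = seg.water_serial
            for j, name in enumerate(("O", "H1", "H2")):
                pos = np.asarray(placement[name], dtype=float)
                atoms.append(
                    Atom(
                        serial=base_serial + j,
                        name=name,
                        residue_name="HOH",
                        chain="S",
                        residue_number=999,
                        element="O" if name == "O" else "H",
                        position=pos,
                    )
                )
            frame = Structure.from_atoms(atoms, source="synthetic:site_frame")
            if rng is not None:
                frame.coords = frame.coords + rng.normal(0.0, jitter, frame.coords.shape)
            frames.append(frame)
    times = script.stride_ps * np.arange(script.n_frames, dtype=float)
    return Ensemble(frames=frames, frame_times=times)


# ---------------------------------------------------------------------------
# Ideal lysine
# ---------------------------------------------------------------------------

def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Internal-coordinate (NeRF) placement of the atom bonded to ``c``."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


_TETRA_DEG = float(np.degrees(_TETRA))


def make_lysine(methylated: bool = False) -> Structure:
    """A lysine residue with ideal covalent geometry and explicit hydrogens.

    C–C 1.52 Å, C–N 1.47 Å, C–H 1.09 Å, tetrahedral angles, all-anti
    backbone-to-Nζ chain.  ``methylated=True`` adds the Nζ methyl (atom
    ``CM`` with hydrogens ``HM1..3``) of a monomethyl-lysine.  Residue
    number 372, chain P; synthetic stand-in for a crystallographic
    substrate lysine.
    """
    cc, cn, ch, nh = 1.52, 1.47, 1.09, 1.01
    pos: dict[str, np.ndarray] = {}
    pos["N"] = np.array([0.0, 0.0, 0.0])
    pos["CA"] = np.array([1.47, 0.0, 0.0])
    pos["CB"] = _place(
        np.array([1.47, 1.0, 0.0]), pos["N"], pos["CA"], cc, _TETRA_DEG, 180.0
    )
    pos["C"] = _place(pos["CB"], pos["N"], pos["CA"], 1.52, _TETRA_DEG, 120.0)
    pos["O"] = _place(pos["N"], pos["CA"], pos["C"], 1.23, 120.0, 0.0)
    chain = ["N", "CA", "CB", "CG", "CD", "CE", "NZ"]
    bonds = {"CG": cc, "CD": cc, "CE": cc, "NZ": cn}
    for prev3, prev2, prev1, name in zip(chain, chain[1:], chain[2:], chain[3:]):
        pos[name] = _place(
            pos[prev3], pos[prev2], pos[prev1], bonds[name], _TETRA_DEG, 180.0
        )

    def methylene_hydrogens(center: str, nb1: str, nb2: str) -> list[np.ndarray]:
        x = pos[center]
        n1, n2 = _unit(pos[nb1] - x), _unit(pos[nb2] - x)
        bis = -_unit(n1 + n2)
        perp = _unit(np.cross(n1, n2))
        alpha = 0.5 * _TETRA
        return [
            x + ch * (np.cos(alpha) * bis + np.sin(alpha) * perp),
            x + ch * (np.cos(alpha) * bis - np.sin(alpha) * perp),
        ]

    atoms: list[tuple[str, np.ndarray]] = [(n, pos[n]) for n in
                                           ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ")]
    for center, nb1, nb2 in (("CB", "CA", "CG"), ("CG", "CB", "CD"),
                             ("CD", "CG", "CE"), ("CE", "CD", "NZ")):
        for k, hpos in enumerate(methylene_hydrogens(center, nb1, nb2), start=2):
            atoms.append((f"H{center[1]}{k}", hpos))

    if methylated:
        pos["CM"] = _place(pos["CD"], pos["CE"], pos["NZ"], cn, _TETRA_DEG, 180.0)
        atoms.append(("CM", pos["CM"]))
        # staggered methyl hydrogens about the NZ->CM axis
        axis = _unit(pos["CM"] - pos["NZ"])
        helper = np.zeros(3)
        helper[int(np.argmin(np.abs(axis)))] = 1.0
        v = _unit(np.cross(axis, helper))
        w = np.cross(axis, v)
        tilt = np.pi - _TETRA
        for k, phi in enumerate((0.0, 2 * np.pi / 3, 4 * np.pi / 3), start=1):
            direction = np.cos(tilt) * axis + np.sin(tilt) * (
                np.cos(phi) * v + np.sin(phi) * w
            )
            atoms.append((f"HM{k}", pos["CM"] + ch * direction))
        atoms.append(("HZ1", pos["NZ"] + nh * _unit(np.cross(axis, w) + 0.5 * axis)))
        resname = "MLZ"
    else:
        # NZ hydrogens (ammonium-like, staggered about CE->NZ)
        axis = _unit(pos["NZ"] - pos["CE"])
        helper = np.zeros(3)
        helper[int(np.argmin(np.abs(axis)))] = 1.0
        v = _unit(np.cross(axis, helper))
        w = np.cross(axis, v)
        tilt = np.pi - _TETRA
        for k, phi in enumerate((0.0, 2 * np.pi / 3, 4 * np.pi / 3), start=1):
            direction = np.cos(tilt) * axis + np.sin(tilt) * (
                np.cos(phi) * v + np.sin(phi) * w
            )
            atoms.append((f"HZ{k}", pos["NZ"] + nh * direction))
        resname = "LYS"

    return Structure.from_atoms(
        [
            Atom(
                serial=i + 1,
                name=name,
                residue_name=resname,
                chain="P",
                residue_number=372,
                element="H" if name.startswith("H") else name[0],
                position=p,
            )
            for i, (name, p) in enumerate(atoms)
        ],
        source="synthetic:ideal_lysine",
    )
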