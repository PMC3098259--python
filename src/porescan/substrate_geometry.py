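"""Substrate cross-section radii from three-atom geometry.

The effective radius of a substrate cross-section is estimated from the
triangle formed by three of its atoms plus a van der Waals term:

    R(j) = h (or h/2) + VDW

where ``h`` is the height of the triangle (perpendicular distance from an
apex atom to the line through the two base atoms) and VDW is the van der
Waals radius of the atom class that lines that cross-section.  Two sections
of the substrate lysine are measured by default: the terminal methyl region
(CM — apex carbon over its hydrogen pair, hydrogen VDW, full height) and
the third side-chain carbon region (CD — the Cγ–Cδ–Cε triple, carbon VDW,
half height).  Subtracting the smallest substrate radius from the channel
radii gives the annular clearance available to a probe such as water
(effective radius 1.9 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .structure_io import Structure, VdwTable, selection_mask
from .channel_profiler import RadiusProfile

__all__ = [
    "HeightMode",
    "SectionSpec",
    "CrossSection",
    "SubstrateRadiusRange",
    "triangle_height",
    "cross_section_radius",
    "substrate_radius_range",
    "clearance",
    "default_lysine_sections",
]


class HeightMode(str, Enum):
    FULL = "full_height"
    HALF = "half_height"


@dataclass(frozen=True)
class SectionSpec:
    """Named recipe for building a cross-section from residue atom names.

    ``apex_name`` is the apex atom; ``base_names`` the two base atoms, or
    ``("@H", "@H")`` meaning "two hydrogens bonded to the apex" (constructed
    at ideal tetrahedral positions if the structure carries none, as crystal
    structures usually don't).  ``vdw_element`` names the atom class whose
    VDW radius enters R(j).
    """

    label: str
    apex_name: str
    base_names: tuple[str, str]
    vdw_element: str
    height_mode: HeightMode = HeightMode.FULL


@dataclass(frozen=True)
class CrossSection:
    """A concrete cross-section: three positioned atoms plus the VDW choice."""

    label: str
    apex: np.ndarray
    base1: np.ndarray
    base2: np.ndarray
    vdw_element: str
    height_mode: HeightMode = HeightMode.FULL
    constructed_hydrogens: bool = False


@dataclass
class SubstrateRadiusRange:
    """Per-section radii and their envelope."""

    values: dict[str, float]
    flags: dict[str, str] = field(default_factory=dict)

    @property
    def min(self) -> float:
        return min(self.values.values())

    @property
    def max(self) -> float:
        return max(self.values.values())


def default_lysine_sections(methyl_carbon: str = "CM") -> list[SectionSpec]:
    """CM/CD sections of a (methylated) lysine side chain.

    ``methyl_carbon`` is the atom name of the terminal methyl carbon — for a
    monomethylated lysine the carbon bonded to Nζ ("CM" here, "CM" or "CH3"
    in various dictionaries).
    """
    return [
        SectionSpec(
            label="CM",
            apex_name=methyl_carbon,
            base_names=("@H", "@H"),
            vdw_element="H",
            height_mode=HeightMode.FULL,
        ),
        SectionSpec(
            label="CD",
            apex_name="CD",
            base_names=("CG", "CE"),
            vdw_element="C",
            height_mode=HeightMode.HALF,
        ),
    ]


def triangle_height(apex: np.ndarray, base1: np.ndarray, base2: np.ndarray) -> float:
    """Perpendicular distance from ``apex`` to the line through the base atoms."""
    apex = np.asarray(apex, dtype=float)
    base1 = np.asarray(base1, dtype=float)
    base2 = np.asarray(base2, dtype=float)
    base_vec = base2 - base1
    base_len = np.linalg.norm(base_vec)
    if base_len == 0:
        raise ValueError("degenerate base: base1 and base2 coincide")
    return float(np.linalg.norm(np.cross(base_vec, apex - base1)) / base_len)


def cross_section_radius(section: CrossSection, vdw: VdwTable | None = None) -> float:
    """R(j) of one cross-section: triangle height (full or half) plus VDW."""
    vdw = vdw or VdwTable.default()
    r = vdw.lookup(section.vdw_element)
    if r is None:
        raise ValueError(f"no VDW radius for element {section.vdw_element!r}")
    h = triangle_height(section.apex, section.base1, section.base2)
    if section.height_mode == HeightMode.HALF:
        h = 0.5 * h
    return h + r


# --- hydrogen construction for hydrogen-free (crystal) structures ----------

_TETRAHEDRAL = np.arccos(-1.0 / 3.0)  # 109.471°
_CH_BOND = 1.09


def _ideal_methyl_hydrogens(apex: np.ndarray, heavy_neighbor: np.ndarray) -> np.ndarray:
    """Three H positions of an ideal methyl on ``apex`` bonded to ``heavy_neighbor``.

    Staggered placement about the neighbor→apex axis; deterministic.
    """
    axis = apex - heavy_neighbor
    axis = axis / np.linalg.norm(axis)
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(axis)))] = 1.0
    v = np.cross(axis, helper)
    v /= np.linalg.norm(v)
    w = np.cross(axis, v)
    hs = []
    # tetrahedral angle is measured from the neighbor bond, so each H
    # direction makes (180° - 109.47°) with the neighbor→apex axis
    tilt = np.pi - _TETRAHEDRAL
    for phi in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
        direction = np.cos(tilt) * axis + np.sin(tilt) * (np.cos(phi) * v + np.sin(phi) * w)
        hs.append(apex + _CH_BOND * direction)
    return np.array(hs)


def _resolve_section(
    structure: Structure, spec: SectionSpec
) -> CrossSection:
    names = np.char.upper(structure.name.astype(str))

    def find(atom_name: str) -> np.ndarray:
        sel = names == atom_name.upper()
        if not sel.any():
            raise ValueError(
                f"section {spec.label}: atom {atom_name!r} not found in residue"
            )
        return structure.coords[np.flatnonzero(sel)[0]]

    apex = find(spec.apex_name)
    constructed = False
    if spec.base_names == ("@H", "@H"):
        elements = np.char.upper(structure.element.astype(str))
        h_idx = np.flatnonzero(elements == "H")
        if h_idx.size:
            d = np.linalg.norm(structure.coords[h_idx] - apex, axis=1)
            h_idx = h_idx[d <= 1.2]
        if h_idx.size >= 2:
            base1, base2 = structure.coords[h_idx[0]], structure.coords[h_idx[1]]
        else:
            heavy_idx = np.flatnonzero(elements != "H")
            d = np.linalg.norm(structure.coords[heavy_idx] - apex, axis=1)
            bonded = heavy_idx[(d > 1e-6) & (d <= 1.8)]
            if bonded.size == 0:
                raise ValueError(
                    f"section {spec.label}: apex {spec.apex_name!r} has no bonded "
                    "heavy neighbor from which to construct hydrogens"
                )
            neighbor = structure.coords[bonded[np.argmin(d[(d > 1e-6) & (d <= 1.8)])]]
            hs = _ideal_methyl_hydrogens(apex, neighbor)
            base1, base2 = hs[0], hs[1]
            constructed = True
    else:
        base1 = find(spec.base_names[0])
        base2 = find(spec.base_names[1])
    return CrossSection(
        label=spec.label,
        apex=apex,
        base1=base1,
        base2=base2,
        vdw_element=spec.vdw_element,
        height_mode=spec.height_mode,
        constructed_hydrogens=constructed,
    )


def substrate_radius_range(
    structure: Structure,
    residue: str,
    sections: list[SectionSpec] | None = None,
    vdw: VdwTable | None = None,
) -> SubstrateRadiusRange:
    """Evaluate R(j) for each section of the selected residue.

    ``residue`` is a selection expression (e.g. ``"chain P and resnum 372"``).
    Section order does not affect the resulting range.
    """
    mask = selection_mask(structure, residue)
    if not mask.any():
        raise ValueError(f"residue selection {residue!r} matched no atoms")
    res = structure.subset(mask)
    sections = sections if sections is not None else default_lysine_sections()
    vdw = vdw or VdwTable.default()
    values: dict[str, float] = {}
    flags: dict[str, str] = {}
    for spec in sections:
        cs = _resolve_section(res, spec)
        values[spec.label] = cross_section_radius(cs, vdw)
        if cs.constructed_hydrogens:
            flags[spec.label] = "ideal_hydrogens_constructed"
    return SubstrateRadiusRange(values=values, flags=flags)


def clearance(
    channel: RadiusProfile,
    substrate: SubstrateRadiusRange | float,
    occupied_window: tuple[float, float],
    probe_radius: float | None = None,
):
    """Per-station clearance: channel radius minus the substrate's minimum radius.

    Returns a DataFrame with one row per interior station in the window and,
    when ``probe_radius`` is given, a pass flag (clearance ≥ probe).
    """
    import pandas as pd

    sub_min = substrate if isinstance(substrate, (int, float)) else substrate.min
    lo, hi = float(occupied_window[0]), float(occupied_window[1])
    if hi < lo:
        lo, hi = hi, lo
    rows = [
        s for s in channel.interior() if lo - 1e-9 <= s.axial_coordinate <= hi + 1e-9
    ]
    if not rows:
        raise ValueError("occupied_window does not intersect the profile")
    df = pd.DataFrame(
        {
            "axial_coordinate": [s.axial_coordinate for s in rows],
            "channel_radius": [s.radius for s in rows],
            "clearance": [s.radius - sub_min for s in rows],
        }
    )
    if probe_radius is not None:
        df["passes_probe"] = df["clearance"] >= probe_radius
    return df
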