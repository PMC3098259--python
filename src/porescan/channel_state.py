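"""Open/closed channel verdicts and equilibrium-phase radius reports.

A channel is open to a probe (water: 1.9 Å effective radius) when every
interior station of its radius profile clears the probe and no blocker
atom (substrate, cofactor) intrudes into the profiled pore.  Equilibrium
reports tabulate per-frame minimum and mean radii for two channels — the
substrate-bearing "first" channel and the tyrosine-gated "new" water
channel — in the shape of a per-time-point radius table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .structure_io import Structure, Ensemble, selection_mask
from .channel_profiler import (
    ProfilerParams,
    RadiusProfile,
    profile_channel,
    profile_stats,
    seed_point,
)

__all__ = [
    "ChannelSpec",
    "ChannelVerdict",
    "EquilibriumReport",
    "classify_channel",
    "equilibrium_report",
    "verdict_summary",
    "new_channel_geometry",
    "WATER_PROBE_RADIUS",
]

WATER_PROBE_RADIUS = 1.9  # Å: effective radial sphere of a protein-bound water


def new_channel_geometry(
    structure: Structure,
    lining_resnums: tuple[int, int, int] = (292, 295, 305),
    exit_resnum: int = 335,
) -> tuple[np.ndarray, np.ndarray]:
    """Seed and axis for a channel defined only by its lining residues.

    Seed: centroid of the lining residues' N/O atoms (where a key water
    would sit); axis: from that centroid toward the exit residue's hydroxyl
    oxygen (or its N/O centroid).
    """
    elements = np.char.upper(structure.element.astype(str))
    no_mask = np.isin(elements, ["N", "O"])
    lining = np.zeros(len(structure), dtype=bool)
    for rn in lining_resnums:
        lining |= structure.residue_number == rn
    lining &= no_mask
    if not lining.any():
        raise ValueError("no N/O atoms found in the lining residues")
    seed = structure.coords[lining].mean(axis=0)
    exit_mask = (structure.residue_number == exit_resnum) & no_mask
    names = np.char.upper(structure.name.astype(str))
    oh = exit_mask & (names == "OH")
    target_mask = oh if oh.any() else exit_mask
    if not target_mask.any():
        raise ValueError(f"exit residue {exit_resnum} has no N/O atom")
    target = structure.coords[target_mask].mean(axis=0)
    axis = target - seed
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("degenerate channel axis: exit coincides with seed")
    return seed, axis / norm


@dataclass(frozen=True)
class ChannelSpec:
    """A named channel: profiling parameters plus the atoms to exclude."""

    name: str
    params: ProfilerParams = field(default_factory=ProfilerParams)
    exclude: str = ""
    lining_residues: tuple[int, ...] = ()
    seed_mode: str = "explicit"  # "explicit" | "substrate" | "lining"
    substrate_resnum: int = 372

    def resolve_params(self, frame: Structure) -> ProfilerParams:
        """Fill in the seed (and, for lining mode, the axis) from the frame."""
        if self.seed_mode == "explicit":
            if self.params.seed is None:
                raise ValueError(f"channel {self.name!r}: explicit seed missing")
            return self.params
        if self.seed_mode == "substrate":
            seed = seed_point(frame, residue_number=self.substrate_resnum)
            return replace(self.params, seed=tuple(seed))
        if self.seed_mode == "lining":
            lining = self.lining_residues or (292, 295, 305, 335)
            seed, axis = new_channel_geometry(
                frame, lining_resnums=tuple(lining[:3]), exit_resnum=lining[-1]
            )
            return replace(self.params, seed=tuple(seed), axis=tuple(axis))
        raise ValueError(f"unknown seed_mode {self.seed_mode!r}")


@dataclass(frozen=True)
class ChannelVerdict:
    channel: str
    min_radius: float
    mean_radius: float
    limiting_station: float  # axial coordinate of the narrowest station
    open: bool
    blocked: bool
    frame: int | None = None


@dataclass
class EquilibriumReport:
    """Per-frame min/mean radii for the first and new channels."""

    table: pd.DataFrame  # columns: time_ns, R_Fmin, R_Favg, R_Nmin, R_Navg, flags

    def __post_init__(self) -> None:
        for lo, hi in (("R_Fmin", "R_Favg"), ("R_Nmin", "R_Navg")):
            rows = self.table.dropna(subset=[lo, hi])
            if (rows[lo] > rows[hi] + 1e-9).any():
                raise ValueError(f"{lo} exceeds {hi} in the report")


def classify_channel(
    profile: RadiusProfile,
    probe_radius: float = WATER_PROBE_RADIUS,
    blockers: Structure | None = None,
    frame: int | None = None,
    channel: str = "",
) -> ChannelVerdict:
    """Open/closed verdict for a profiled channel against a probe radius.

    Open iff the minimum interior station radius clears the probe and no
    blocker VDW sphere intersects any station sphere.
    """
    interior = profile.interior()
    if not interior:
        raise ValueError("profile has no interior stations")
    radii = np.array([s.radius for s in interior])
    i_min = int(np.argmin(radii))
    blocked = False
    if blockers is not None:
        if not blockers.has_vdw:
            raise ValueError("blockers need VDW radii for the intersection test")
        centers = np.array([s.center for s in interior])
        for st_center, st_radius in zip(centers, radii):
            d = np.linalg.norm(blockers.coords - st_center, axis=1)
            if np.any(d < blockers.vdw + st_radius):
                blocked = True
                break
    min_r = float(radii[i_min])
    return ChannelVerdict(
        channel=channel,
        min_radius=min_r,
        mean_radius=float(radii.mean()),
        limiting_station=float(interior[i_min].axial_coordinate),
        open=bool(min_r >= probe_radius and not blocked),
        blocked=blocked,
        frame=frame,
    )


def equilibrium_report(
    ensemble: Ensemble,
    frames: list[int] | None,
    first: ChannelSpec,
    new: ChannelSpec,
    stats_window: tuple[float, float] | str = "all",
) -> EquilibriumReport:
    """Profile both channels on selected frames and tabulate min/mean radii.

    ``frames`` are 0-based frame indices (``None`` = all frames).  A frame
    where a channel's seed cannot be resolved is flagged, not dropped.
    """
    if frames is None:
        frames = list(range(len(ensemble)))
    for k in frames:
        if not 0 <= k < len(ensemble):
            raise IndexError(f"frame {k} out of range")
    rows = []
    for k in frames:
        frame = ensemble.frames[k]
        row: dict[str, float | str] = {
            "frame": k,
            "time_ns": ensemble.frame_times[k] / 1000.0,
        }
        flags = []
        for spec, mn_col, avg_col in (
            (first, "R_Fmin", "R_Favg"),
            (new, "R_Nmin", "R_Navg"),
        ):
            try:
                params = spec.resolve_params(frame)
                profile = profile_channel(frame, params=params, exclude=spec.exclude)
                mn, avg = profile_stats(profile, stats_window)
                row[mn_col], row[avg_col] = mn, avg
            except (ValueError, IndexError) as err:
                row[mn_col] = row[avg_col] = np.nan
                flags.append(f"{spec.name}: {err}")
        row["flags"] = "; ".join(flags)
        rows.append(row)
    return EquilibriumReport(table=pd.DataFrame(rows))


def verdict_summary(
    report: EquilibriumReport,
    probe: float = WATER_PROBE_RADIUS,
    substrate_min: float | None = None,
) -> pd.DataFrame:
    """Fraction of frames each channel is open, plus substrate clearance.

    For the first (substrate-bearing) channel the effective aperture is the
    clearance R − substrate_min, which is what a water probe would actually
    see with the substrate in place.
    """
    t = report.table
    rows = []
    for name, mn_col, avg_col in (("first", "R_Fmin", "R_Favg"), ("new", "R_Nmin", "R_Navg")):
        valid = t.dropna(subset=[mn_col])
        frac_open = float((valid[mn_col] >= probe).mean()) if len(valid) else np.nan
        row = {
            "channel": name,
            "n_frames": len(valid),
            "fraction_open": frac_open,
            "min_radius": float(valid[mn_col].min()) if len(valid) else np.nan,
            "max_mean_radius": float(valid[avg_col].max()) if len(valid) else np.nan,
        }
        if name == "first" and substrate_min is not None and len(valid):
            max_clearance = float(valid[avg_col].max()) - substrate_min
            row["max_clearance"] = max_clearance
            row["clearance_passes_probe"] = bool(max_clearance >= probe)
        rows.append(row)
    return pd.DataFrame(rows)
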