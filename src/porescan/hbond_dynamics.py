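"""Geometric hydrogen-bond detection and active-site water state tracking.

A hydrogen bond is recorded for a donor–hydrogen–acceptor triple when the
donor–acceptor distance is below 3.5 Å and the angle at the donor between
the D→H and D→A vectors is below 35° (both configurable).  The angle
convention is the donor-centred deviation form common in trajectory
analysis; the supplementary D–H···A form can be selected instead.

On an ensemble, the tracked quantity is the occupancy of a binding site:
per frame, the water nearest the site centre (within a site radius) is
identified and its hydrogen bonds to a set of tracked residues counted.
The default tracking set is the active-site triad of a SET-domain
methyltransferase (G292 and A295 backbone carbonyl oxygens as acceptors,
the Y305 hydroxyl as donor) plus the exit-lining Y335 hydroxyl.  Bond
patterns map onto discrete states: triad-bound, exit-captured, transiting,
or vacant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import Ensemble, Structure, selection_mask, WATER_RESIDUE_NAMES

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "StateRules",
    "OccupancySeries",
    "find_hbonds",
    "water_site_series",
    "vacancy_intervals",
    "STATE_TRIAD_BOUND",
    "STATE_EXIT_CAPTURED",
    "STATE_TRANSIT",
    "STATE_VACANT",
]

STATE_TRIAD_BOUND = "TRIAD_BOUND"
STATE_EXIT_CAPTURED = "EXIT_CAPTURED"
STATE_TRANSIT = "TRANSIT"
STATE_VACANT = "VACANT"

COVALENT_H_CUTOFF = 1.2  # Å: hydrogens within this distance belong to the donor


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric cutoffs: distance < 3.5 Å, donor-angle deviation ≤ 35°."""

    max_donor_acceptor_distance: float = 3.5
    max_angle: float = 35.0
    angle_convention: str = "donor"  # "donor" (H–D–A at D) or "dha" (D–H···A at H)

    def __post_init__(self) -> None:
        if self.max_donor_acceptor_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.max_angle < 90:
            raise ValueError("angle cutoff must lie in (0, 90) degrees")
        if self.angle_convention not in ("donor", "dha"):
            raise ValueError("angle_convention must be 'donor' or 'dha'")


@dataclass(frozen=True)
class HBondRecord:
    frame_index: int
    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    distance: float
    angle: float


@dataclass(frozen=True)
class StateRules:
    """Total mapping from per-residue bond patterns to site states.

    With tracked residues (triad..., exit): all three triad bonds present →
    TRIAD_BOUND; a bond to the exit residue with no remaining triad bond →
    EXIT_CAPTURED (the water has been handed off to the outlet tyrosine);
    any other pattern while a water is present (a single triad bond, a
    mixed triad+exit pattern, or no bonds at all) → TRANSIT; no water
    within the site radius → VACANT.  The mapping is total.
    """

    triad_labels: tuple[str, ...] = ("G292", "A295", "Y305")
    exit_label: str = "Y335"

    def classify(self, counts: dict[str, int], water_present: bool) -> str:
        if not water_present:
            return STATE_VACANT
        triad = [counts.get(lbl, 0) for lbl in self.triad_labels]
        if all(n >= 1 for n in triad):
            return STATE_TRIAD_BOUND
        if counts.get(self.exit_label, 0) >= 1 and not any(triad):
            return STATE_EXIT_CAPTURED
        return STATE_TRANSIT


@dataclass
class OccupancySeries:
    """Per-frame bond counts, states and water identity over an ensemble."""

    frame_times: np.ndarray          # ps
    labels: list[str]
    counts: np.ndarray               # (n_frames, n_labels) int
    states: list[str]
    water_serial: np.ndarray         # -1 where no water occupies the site
    identity_change: np.ndarray      # True where the occupying water changed

    @property
    def total(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            {"frame": np.arange(len(self.states)), "time_ps": self.frame_times}
        )
        for j, lbl in enumerate(self.labels):
            df[f"n_{lbl}"] = self.counts[:, j]
        df["total"] = self.total
        df["state"] = self.states
        df["water_serial"] = self.water_serial
        df["identity_change"] = self.identity_change
        return df


def _attached_hydrogens(frame: Structure, donor_indices: np.ndarray) -> dict[int, np.ndarray]:
    """Map each donor heavy atom to the hydrogens covalently attached to it."""
    elements = np.char.upper(frame.element.astype(str))
    h_idx = np.flatnonzero(elements == "H")
    out: dict[int, np.ndarray] = {}
    if h_idx.size == 0:
        return {int(d): np.empty(0, dtype=int) for d in donor_indices}
    h_coords = frame.coords[h_idx]
    for d in donor_indices:
        dist = np.linalg.norm(h_coords - frame.coords[d], axis=1)
        out[int(d)] = h_idx[dist <= COVALENT_H_CUTOFF]
    return out


def find_hbonds(
    frame: Structure,
    donors: np.ndarray | None = None,
    acceptors: np.ndarray | None = None,
    criteria: HBondCriteria | None = None,
    frame_index: int = 0,
    require_hydrogens: bool = True,
) -> list[HBondRecord]:
    """Detect hydrogen bonds in one frame by the geometric criterion.

    ``donors``/``acceptors`` are index arrays of heavy atoms; by default all
    N and O atoms act as both (water therefore evaluated in both roles).
    Returns one record per donor–hydrogen–acceptor triple that satisfies
    the criterion.
    """
    criteria = criteria or HBondCriteria()
    elements = np.char.upper(frame.element.astype(str))
    if donors is None:
        donors = np.flatnonzero(np.isin(elements, ["N", "O"]))
    if acceptors is None:
        acceptors = np.flatnonzero(np.isin(elements, ["N", "O"]))
    donors = np.asarray(donors, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    hydrogens = _attached_hydrogens(frame, donors)
    if require_hydrogens and donors.size and all(
        hydrogens[int(d)].size == 0 for d in donors
    ):
        raise ValueError(
            "no donor carries an attached hydrogen (within "
            f"{COVALENT_H_CUTOFF} Å); construct hydrogens before detection"
        )

    records: list[HBondRecord] = []
    acc_coords = frame.coords[acceptors]
    cos_max = np.cos(np.deg2rad(criteria.max_angle))
    for d in donors:
        hs = hydrogens[int(d)]
        if hs.size == 0:
            continue
        d_pos = frame.coords[d]
        da = acc_coords - d_pos
        dist = np.linalg.norm(da, axis=1)
        ok = (dist < criteria.max_donor_acceptor_distance) & (acceptors != d) & (dist > 1e-9)
        for a_local in np.flatnonzero(ok):
            a = int(acceptors[a_local])
            for h in hs:
                if criteria.angle_convention == "donor":
                    v1 = frame.coords[h] - d_pos
                    v2 = da[a_local]
                    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                    if denom == 0:
                        continue
                    cos_dev = float(np.dot(v1, v2) / denom)
                else:
                    # deviation of D–H···A from linearity, measured at H:
                    # dev = 180° - angle(H→D, H→A)
                    v1 = d_pos - frame.coords[h]
                    v2 = acc_coords[a_local] - frame.coords[h]
                    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                    if denom == 0:
                        continue
                    cos_dev = -float(np.dot(v1, v2) / denom)
                if cos_dev >= cos_max - 1e-12:
                    angle = float(np.degrees(np.arccos(np.clip(cos_dev, -1.0, 1.0))))
                    records.append(
                        HBondRecord(
                            frame_index=frame_index,
                            donor_index=int(d),
                            hydrogen_index=int(h),
                            acceptor_index=int(a),
                            distance=float(dist[a_local]),
                            angle=angle,
                        )
                    )
    return records


def _heavy_no_indices(frame: Structure, mask: np.ndarray) -> np.ndarray:
    elements = np.char.upper(frame.element.astype(str))
    return np.flatnonzero(mask & np.isin(elements, ["N", "O"]))


def water_site_series(
    ensemble: Ensemble,
    site_residues: list[str] | None = None,
    labels: list[str] | None = None,
    rules: StateRules | None = None,
    site_center: np.ndarray | None = None,
    site_radius: float = 4.0,
    criteria: HBondCriteria | None = None,
) -> OccupancySeries:
    """Classify the active-site water's binding state frame by frame.

    ``site_residues`` are selection expressions for the tracked residues, in
    the order (triad..., exit); defaults to residue numbers 292, 295, 305
    and 335.  The site centre defaults to the centroid of the triad's N/O
    atoms in each frame; the water oxygen nearest the centre within
    ``site_radius`` is the tracked occupant.  Waters are followed by serial
    number; a change of occupant raises the identity-change flag.
    """
    import warnings

    criteria = criteria or HBondCriteria()
    rules = rules or StateRules()
    if site_residues is None:
        site_residues = ["resnum 292", "resnum 295", "resnum 305", "resnum 335"]
    if labels is None:
        labels = list(rules.triad_labels) + [rules.exit_label]
    if len(labels) != len(site_residues):
        raise ValueError("labels and site_residues must align")
    n_triad = len(rules.triad_labels)

    frame0 = ensemble.frames[0]
    res_masks = [selection_mask(frame0, expr) for expr in site_residues]
    for expr, m in zip(site_residues, res_masks):
        if not m.any():
            raise ValueError(f"site residue selection {expr!r} matched no atoms")
    water_mask = selection_mask(frame0, "water") if any(
        rn in WATER_RESIDUE_NAMES for rn in frame0.residue_name
    ) else np.zeros(len(frame0), dtype=bool)
    if not water_mask.any():
        warnings.warn("ensemble contains no waters; every frame will be VACANT")
    elements0 = np.char.upper(frame0.element.astype(str))
    water_o = np.flatnonzero(water_mask & (elements0 == "O"))

    n_frames = len(ensemble)
    counts = np.zeros((n_frames, len(labels)), dtype=int)
    states: list[str] = []
    serial = np.full(n_frames, -1, dtype=int)
    ident = np.zeros(n_frames, dtype=bool)
    prev_serial = -1

    for k, frame in enumerate(ensemble.frames):
        if site_center is None:
            triad_heavy = np.concatenate(
                [_heavy_no_indices(frame, res_masks[j]) for j in range(n_triad)]
            )
            center = frame.coords[triad_heavy].mean(axis=0)
        else:
            center = np.asarray(site_center, dtype=float)

        occupant = -1
        if water_o.size:
            d = np.linalg.norm(frame.coords[water_o] - center, axis=1)
            j = int(np.argmin(d))
            if d[j] <= site_radius:
                occupant = int(water_o[j])

        if occupant < 0:
            states.append(rules.classify({}, water_present=False))
            continue

        serial[k] = int(frame.serial[occupant])
        if prev_serial >= 0 and serial[k] != prev_serial:
            ident[k] = True
        prev_serial = serial[k]

        # candidate donors/acceptors: the water plus the tracked residues
        water_res_mask = (frame.residue_number == frame.residue_number[occupant]) & (
            frame.chain == frame.chain[occupant]
        ) & water_mask
        water_heavy = _heavy_no_indices(frame, water_res_mask)
        tracked_heavy = [ _heavy_no_indices(frame, m) for m in res_masks ]
        all_heavy = np.concatenate([water_heavy] + tracked_heavy)
        bonds = find_hbonds(
            frame,
            donors=all_heavy,
            acceptors=all_heavy,
            criteria=criteria,
            frame_index=k,
            require_hydrogens=False,
        )
        water_set = set(int(i) for i in water_heavy)
        for j, heavy in enumerate(tracked_heavy):
            res_set = set(int(i) for i in heavy)
            n = sum(
                1
                for b in bonds
                if (b.donor_index in water_set and b.acceptor_index in res_set)
                or (b.donor_index in res_set and b.acceptor_index in water_set)
            )
            counts[k, j] = n
        states.append(
            rules.classify(dict(zip(labels, counts[k])), water_present=True)
        )

    return OccupancySeries(
        frame_times=np.asarray(ensemble.frame_times, dtype=float),
        labels=list(labels),
        counts=counts,
        states=states,
        water_serial=serial,
        identity_change=ident,
    )


def vacancy_intervals(
    series: OccupancySeries, frame_times: np.ndarray | None = None
) -> list[tuple[float, float, float]]:
    """Maximal runs of VACANT frames as (start_ps, end_ps, duration_ps).

    A run covering frames i..j is charged the time up to the next occupied
    frame (j+1); a run at the end of the series is extended by the median
    frame stride, so an n-frame vacancy at stride dt always lasts n*dt.
    """
    times = np.asarray(
        series.frame_times if frame_times is None else frame_times, dtype=float
    )
    vacant = np.array([s == STATE_VACANT for s in series.states], dtype=bool)
    if times.shape[0] != vacant.shape[0]:
        raise ValueError("series and frame_times are not aligned")
    stride = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    intervals: list[tuple[float, float, float]] = []
    i = 0
    n = len(vacant)
    while i < n:
        if not vacant[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and vacant[j + 1]:
            j += 1
        start = float(times[i])
        end = float(times[j + 1]) if j + 1 < n else float(times[j]) + stride
        intervals.append((start, end, end - start))
        i = j + 1
    return intervals
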