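"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from porescan import ProfilerParams, profile_channel
from porescan.structure_io import Structure
from porescan.synthetic_data import PoreSpec, make_pore, make_lysine


def brute_force_plane_radius(
    coords: np.ndarray,
    vdw: np.ndarray,
    plane_x: float,
    bound: float,
    step: float = 0.01,
    cap: float = 3.5,
) -> float:
    """Exhaustive grid maximization of min_i(|c - x_i| - vdw_i) in the plane
    x = plane_x, over the disc of radius ``bound`` around (plane_x, 0, 0).

    Independent of the production optimizer: dense grid, no refinement.
    """
    ticks = np.arange(-bound, bound + 0.5 * step, step)
    yy, zz = np.meshgrid(ticks, ticks, indexing="ij")
    mask = yy**2 + zz**2 <= bound**2
    pts = np.column_stack(
        [np.full(mask.sum(), plane_x), yy[mask], zz[mask]]
    )
    from scipy.spatial.distance import cdist

    # exact prefilter: an atom farther than cap + vdw from every candidate
    # point cannot bind the (capped) optimum
    reach = cap + vdw
    axial_ok = np.abs(coords[:, 0] - plane_x) <= reach
    radial = np.hypot(coords[:, 1], coords[:, 2])
    keep = axial_ok & (radial <= bound + reach)
    if keep.any():
        coords, vdw = coords[keep], vdw[keep]
    best = np.full(len(pts), np.inf)
    chunk = max(1, 10_000_000 // max(len(coords), 1))
    for i in range(0, len(pts), chunk):
        block = pts[i : i + chunk]
        d = cdist(block, coords) - vdw[None, :]
        best[i : i + chunk] = d.min(axis=1)
    return min(float(best.max()), cap)


def structure_from_arrays(coords: np.ndarray, vdw: np.ndarray) -> Structure:
    n = len(coords)
    return Structure(
        serial=np.arange(1, n + 1),
        name=np.array(["X"] * n, dtype=object),
        residue_name=np.array(["DUM"] * n, dtype=object),
        chain=np.array(["A"] * n, dtype=object),
        residue_number=np.ones(n, dtype=int),
        element=np.array(["C"] * n, dtype=object),
        coords=np.asarray(coords, dtype=float),
        vdw=np.asarray(vdw, dtype=float),
    )


def brute_force_hbonds(frame, donors, acceptors, criteria) -> set[tuple[int, int, int]]:
    """All-triples hydrogen-bond checker (donor-angle convention).

    Plain Python loops over every (donor, attached hydrogen, acceptor)
    triple; returns the set of index triples satisfying the criterion.
    """
    elements = [str(e).upper() for e in frame.element]
    h_indices = [i for i, e in enumerate(elements) if e == "H"]
    found = set()
    for d in donors:
        d = int(d)
        d_pos = frame.coords[d]
        hs = [
            h for h in h_indices
            if np.linalg.norm(frame.coords[h] - d_pos) <= 1.2
        ]
        for a in acceptors:
            a = int(a)
            if a == d:
                continue
            a_pos = frame.coords[a]
            dist = float(np.linalg.norm(a_pos - d_pos))
            if not 1e-9 < dist < criteria.max_donor_acceptor_distance:
                continue
            for h in hs:
                v1 = frame.coords[h] - d_pos
                v2 = a_pos - d_pos
                cosang = float(
                    np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                )
                angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if angle <= criteria.max_angle + 1e-9:
                    found.add((d, h, a))
    return found


@pytest.fixture(scope="session")
def ideal_lysine():
    return make_lysine(methylated=False)


@pytest.fixture(scope="session")
def methyl_lysine():
    return make_lysine(methylated=True)


@pytest.fixture(scope="session")
def cylinder_pore():
    spec = PoreSpec(shape="cylinder", inner_radius=2.3, length=10.0)
    structure, analytic = make_pore(spec)
    return spec, structure, analytic


@pytest.fixture(scope="session")
def cylinder_profile(cylinder_pore):
    spec, structure, _ = cylinder_pore
    params = ProfilerParams(seed=tuple(spec.seed_hint()))
    return profile_channel(structure, params=params)
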