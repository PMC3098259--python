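# Methods

## Channel radius profiles

The profile is the classic pore-radius construction: at each axial station
the radius of the largest sphere, centred in the plane perpendicular to the
exploring axis, that touches no atom's van der Waals sphere.  The
objective

    f(c) = min_i ( |c − x_i| − VDW_i ),   c constrained to the plane,

is maximised per plane, and planes are marched in `plane_spacing` steps
(default 0.25 Å) from a seed point in both directions.  A direction
terminates when a station's value exceeds `end_radius` (default 3.5 Å,
interpreted as "the pore has opened into bulk"); the triggering station is
kept but flagged, and flagged stations are excluded from min/mean
statistics because their capped radii are sentinels, not measurements.
The default seed for a substrate-bearing channel is the midpoint of the
substrate lysine's Cα and Nζ atoms; the default axis is +x, matching the
usual convention of aligning the crystal frame before profiling.

**Optimiser.**  Classic pore-profiling tools solve the per-plane problem
with Monte-Carlo simulated annealing.  This package uses a deterministic
three-stage search instead: a coarse grid (`grid_step`, default 0.2 Å)
over the in-plane search disc (`in_plane_search_bound`, default 10 Å,
centred on the seed's in-plane projection), a 0.02 Å fine grid around every
near-optimal coarse point (the objective is 1-Lipschitz, so the basin of
the true optimum always contains a coarse point within `grid_step/√2` of
the optimal value; near-optimal candidates are de-duplicated at 2·grid_step
separation and capped at eight, preferring candidates near the warm start),
and a Nelder–Mead polish to `refine_tolerance` (default 1e-4 Å).
Candidates outside the search disc are projected onto it, which keeps the
simplex well behaved at the boundary.  Determinism buys reproducibility
and lets a dense-grid brute force serve as an oracle in the tests; the
measured agreement is within 0.02 Å on random 50-atom instances and within
numerical noise on analytic pores.

Each plane's search warm-starts from the previous station's centre, so the
centre path follows the pore rather than jumping to unrelated voids.
Plane normals stay fixed along the chosen axis for every station; there is
no adaptive re-orientation of the exploring vector, so strongly curved
channels are measured along a straight axis by construction.  Waters are
excluded from profiling by default (the profile measures the protein
channel), as are any atoms matched by the caller's exclusion expression —
for the substrate channel, the substrate peptide and the cofactor.

**Performance.**  The objective is evaluated through per-radius-class
KD-trees built once per profile, so a station costs a few thousand
nearest-neighbour queries; a full profile of a ~5000-atom structure takes
well under a second.

## Substrate cross-section radii

The occupied radius of a substrate cross-section is `R(j) = h + VDW` or
`h/2 + VDW`, where `h` is the height of the triangle formed by three atoms
of the section and VDW is the van der Waals radius of the atom class
lining the section.  Which triangle, which height mode and which VDW enter
each section are explicit per-section parameters, because the construction
admits several natural readings.  The shipped lysine defaults are:

| section | atoms (apex / base)      | height | VDW | ideal-geometry value |
|---------|--------------------------|--------|-----|----------------------|
| CM      | methyl C / two methyl H  | full   | H (1.09 Å) | 1.72 Å |
| CD      | Cδ / Cγ, Cε              | half   | C (1.70 Å) | 2.14 Å |

The CM section uses the full apex height because the methyl hydrogens
splay around the apex carbon and the hydrogen shell defines the narrowest
lobe of the side chain; the CD section uses the half height because the
backbone-side methylenes are staggered and only half the zig-zag
amplitude protrudes per side.  With ideal covalent geometry these defaults
give 1.72 and 2.14 Å, bracketing the 1.76–2.19 Å range reported for the
crystallographic substrate lysine within the 0.05 Å one expects between
idealised and crystal coordinates.  Crystal structures carry no hydrogens;
for hydrogen-dependent sections ideal tetrahedral hydrogens are
constructed at 1.09 Å from the apex (staggered about the bond to the
heavy neighbour) and the result is flagged.

Clearance is the per-station difference between channel radius and the
substrate's smallest section radius; comparison against a probe radius
(water: 1.9 Å effective radius when interacting with protein) yields the
pass/fail annotation.

## Hydrogen bonds and water-site states

A bond is recorded for a donor–hydrogen–acceptor triple when the
donor–acceptor distance is < 3.5 Å and the angle at the donor between
D→H and D→A is ≤ 35°.  The angle convention is donor-centred, the common
trajectory-analysis form; the D–H···A deviation-from-linearity form can be
selected instead (`angle_convention="dha"`) since published criteria do not
always say which is meant.  N and O carry donor/acceptor roles; hydrogens
are associated to their donor by a 1.2 Å covalent cutoff.  CH···O bonds
are not detected by default (carbon is not in the donor set) but the donor
set is configurable.

The tracked quantity over an ensemble is site occupancy, not the fate of
one particular water: per frame the water oxygen nearest the triad
centroid (within `site_radius`, default 4 Å — the bond criterion itself
reaches 3.5 Å, so any bonded water is inside) is the occupant, and a
change of occupant serial raises an identity-change flag so hand-off
events remain visible.  Bond patterns map to states with the precedence:
all three triad bonds → `TRIAD_BOUND`; exit-residue bond with no triad
bond → `EXIT_CAPTURED`; any other pattern with a water present →
`TRANSIT` (this includes mixed triad+exit contact, which is an
in-passage configuration, not a completed hand-off); no water →
`VACANT`.  The mapping is total.  Vacancy intervals are maximal `VACANT`
runs; a run of *n* frames at stride *dt* is charged *n·dt* (the run is
closed by the next occupied frame, or extended by the median stride at the
series end).  Raw per-frame counts are emitted; any smoothing is left to
reporting.

## Channel verdicts and equilibrium reports

A channel is open to a probe when the minimum interior station radius
clears the probe radius and no blocker atom's VDW sphere intersects any
station sphere (sphere–sphere test; the simplest reading of "the cofactor
blocks the pore").  Verdicts are monotone in the probe by construction.
Equilibrium reports run the profiler per frame for two channel
specifications and tabulate per-frame min/mean radii; a frame whose seed
cannot be resolved is flagged and kept, not dropped.  The second
("new") channel has no substrate to define a seed, so its default seed is
the centroid of the lining residues' N/O atoms (where the key water sits)
and its axis points toward the exit tyrosine's hydroxyl; both are
overridable.  Whether waters are present during profiling is a caller
choice; the default removes them.

## Synthetic generators

`make_pore` builds pseudo-atom walls as rings around an axis: wall radius
`r(z) + vdw` so the on-axis clearance is `r(z)`.  Ring spacing defaults to
the profiler's plane spacing, so wall rings coincide with station planes
and interior stations recover the closed form exactly; the constructor
refuses spacings whose between-ring overshoot `sqrt(d² + (Δz/2)²) − d`
exceeds 0.015 Å, which enforces the advertised 0.02 Å oracle guarantee at
arbitrary planes.  It also refuses ring populations sparse enough for the
optimiser to tunnel between adjacent wall atoms, and surrounds the wall
with concentric padding shells (arc spacing ≤ vdw) so the coarse grid
cannot find spurious optima outside the pore.  For slanted walls the true
in-plane clearance is the perpendicular distance to the wall, so the
analytic profile returned with the structure is the exact on-axis formula
`min_m sqrt(d_m² + (z − z_m)²) − vdw` over wall rings — constant for the
cylinder, slope-corrected linear for the cone, piecewise for the
hourglass.

`make_site_ensemble` realises scripted water states with ideal bond
geometry (2.8 Å donor–acceptor, 0° deviation) against a fixed four-residue
template: two backbone carbonyl oxygens splayed at the water H–O–H angle
(so one water donates to both), a donor hydroxyl above, an exit hydroxyl
on the outlet axis.  Supported per-segment bond sets are the full triad,
A295 only, Y335 only, A295+Y335 (in-passage), unbonded-in-site, and
vacancy; geometrically inconsistent requests are rejected naming the
segment.  During vacancy segments the water is parked ~30 Å away rather
than deleted, keeping frame atom counts constant as ensembles require.
Placements were chosen so every scripted bond is satisfied with ≥0.02 Å /
several-degree margin and every non-scripted pair fails its criterion by a
clear margin; the test suite verifies both with independent arithmetic.
Optional Gaussian jitter (σ in Å, explicit seed required) tests criterion
robustness; at σ = 0.03 Å all scripted states survive.

`make_lysine` builds a lysine (optionally Nζ-methylated) by internal
coordinates: C–C 1.52 Å, C–N 1.47 Å, C–H 1.09 Å, tetrahedral angles,
all-anti chain, explicit hydrogens.  It is the stand-in for the
crystallographic substrate residue wherever the real coordinates are not
available.

What the generators do **not** emulate: thermal disorder beyond the
optional jitter, correlated protein motions, realistic water exchange
kinetics, crystallographic anisotropy or alternate conformers.  Passing
the round-trip tests therefore demonstrates correctness of the geometry
and bookkeeping, not agreement with any particular simulation.

## Structure I/O

PDB parsing and writing go through biotite; on top of that sit element
inference from atom names when the element column is blank, first-altloc
reduction (downstream geometry assumes one conformer), water recognition
by residue name (HOH/WAT/TIP3/TIP/SOL), VDW assignment from a Bondi table
with hydrogen at 1.09 Å (name-level overrides win over element entries),
and per-model times for ensembles carried in `REMARK 100 FRAME k TIME_PS
t` header lines (absent remarks default to frame-index × stride).  Author
residue numbering is authoritative throughout.  Units are Å and ps
everywhere; no operation converts units.

## Problem sizes

The test suite and the acceptance script run entirely on generated
inputs: 100 random ≤50-atom instances for the inscribed-sphere oracle,
8–10 Å pores of ~5000 wall atoms, ensembles of up to 750 frames with a
15-atom template.  These sizes exercise every code path while keeping the
whole suite under a few minutes on one core.

## Known limitations

* Straight-axis profiling only; no curved centre-line tracing, adaptive
  plane normals, capsule options or conductance estimates.
* The cross-section construction is calibrated for lysine-like side
  chains; other substrates need explicit section specifications.
* Hydrogen-bond detection is purely geometric; no energetic definition.
* Binary trajectory formats (DCD/XTC) and mmCIF are out of scope; convert
  to multi-model PDB first.
* Crystal-structure reproduction tests require the user to supply the PDB
  entry (`data/1XQH.pdb`); it is not redistributed with the package.
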