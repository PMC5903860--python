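# Methods

This note records the operational definitions, parameter choices and known
limitations behind each analysis, and what the synthetic-data generators do
and do not emulate.

## Bilayer reference geometry

All metrics are expressed relative to the bilayer midplane. Per frame,
phosphate z coordinates are split into two leaflets by a deterministic 1-D
two-means clustering (centres initialised at the min and max); a split whose
leaflet means are closer than 1 nm is rejected as "not a planar bilayer"
(e.g. tubulated or micellar configurations). **Thickness** is defined
phosphate-to-phosphate (distance between the leaflet phosphate means): the
underlying experimental convention never pins down which atoms define the
thickness, and phosphate means are the common operational choice available
in both all-atom and coarse-grained templates. The **midplane** is the
midpoint of the two leaflet means (robust to asymmetric water boxes, unlike
a centre of mass). The **hydrophobic slab** is the band centred on the
midplane spanning `slab_fraction` × thickness; the default fraction is 0.65,
the value used to score water visits to the membrane core. Slab bounds are
computed **per frame** so that membrane drift or undulation does not smear
the slab over a trajectory; a trajectory-averaged variant can be had by
passing a fixed reference list. Lipids whose phosphate sits exactly on the
midplane are assigned by glycerol z and logged.

Density profiles are histograms of midplane-relative z, averaged over
frames, defaulting to 100 bins over [−thickness, +thickness]. The profile
integral equals the mean in-range selected-atom count per frame; selections
outside the range (e.g. bulk water far from the membrane) are excluded, so
the normalisation identity holds for any range that covers the selection.

## Water permeation

A **visit** is a maximal contiguous run of frames with the water oxygen
strictly inside the slab; one frame suffices (no minimum dwell time — visits
are counted, not filtered). Sides are evaluated on minimum-image wrapped,
midplane-relative z. Classification: **crossing** when the exit side differs
from the entry side, **rebound** when they coincide, **unresolved** when the
trajectory ends with the water inside. A water already inside at frame 0 has
no observable entry side; if it later exits, the visit is scored as a
rebound from the exit side (logged), otherwise it stays unresolved.
Re-entrant waters produce one record per maximal run — deterministic,
order-independent bookkeeping.

Summaries assign events to blocks (default 100 ns) by entry time, after an
optional equilibration discard (default 0 here; a 100 ns discard mirrors
common practice and is one flag away). The headline percentage counts
**distinct molecules** per block ("number of water molecules that visited"),
while the crossing/rebound tallies count events; both are reported. Standard
deviations are sample SDs over blocks (0 for a single block).

`unwrap_z` removes periodic jumps by minimum-image correction of successive
displacements. Since the corrected step is bounded by half the box height by
construction, a literal "≥ box_z/2" untrackability test can never fire;
instead an atom is flagged untrackable when a corrected step reaches
`max_step_fraction` × box_z (default 0.25), which cleanly separates genuine
wrap events (small corrected steps) from motion too fast for the frame
spacing.

## Chain dynamics

**Velocity**: displacements of each chain's terminal carbon are taken over
fixed 10 ps steps (per-axis minimum image); `velocity_z = Σ|Δz|/T` and
`velocity_xy = Σ√(Δx²+Δy²)/T` in nm/ns, averaged over chains of the same
label. The per-axis sums Σ|Δx|, Σ|Δy| are also emitted: descriptions of this
metric conflict between a per-axis and an in-plane reading, so the in-plane
Euclidean step is the headline (matching the usual "x-y velocity" panel
label) with the per-axis variant available.

**Torsion**: the angle at carbon *n* subtended by carbons *n−2* and *n+2*
(vertex at *n*, positions in degrees), counted when **strictly** below the
100° threshold; this is a 3-point bend, deliberately not a 4-atom dihedral.
Chains shorter than 5 carbons carry no triplet and are excluded (logged).
Frequencies are averaged within frame over chains, then over frames, with
SDs over 100 ns blocks.

**Protrusion**: a chain is protruded when its terminal carbon lies outward
of its own lipid's glycerol central carbon along the leaflet normal (upper
leaflet: above; lower: below). An **event** is a non-protruded → protruded
transition between consecutive frames — transition counting is the only
reading that makes "number of events" finite; no minimum duration is
applied. A hysteresis band (default 0 nm) is available for noisy all-atom
data: with hysteresis *h*, the terminal must retreat *h* nm inward before a
new event can fire.

## Packing defects

The interface scan is a reconstruction: the published description delegates
details to a prior method, so the procedure here is fully specified and
deterministic. Each leaflet is scanned on a 0.1 nm x-y grid; from the
solvent side a vertical ray is cast at every grid point and the first lipid
heavy atom whose van der Waals sphere it intersects is the contact (default
radii in nm: C 0.17, O 0.152, N 0.155, P 0.18, S 0.18, H 0.12, generic bead
0.26; hydrogens are skipped as contacts). A cell is a defect when the
contact atom is in the template's aliphatic set (acyl carbons minus the two
carbonyl carbons). Depth is the nearest glycerol central carbon's z minus
the contact z along the outward normal, with "nearest" meaning smallest
lateral distance within a 1.0 nm neighbourhood (falling back to the global
nearest). Shallow ⇔ depth ≤ 0.1 nm, deep ⇔ depth > 0.1 nm; exactly 1 Å is
left unassigned by the "<1 Å / >1 Å" convention and is classified shallow
here. Grid points with no lipid contact at all are voids, counted separately.
Contiguous defect cells merge by 4-connectivity, periodic in x-y; areas are
cell counts × spacing².

## Tubes, rigidity, scission

Tube measurements are an operational choice (the source convention for
measuring *L* and *R* on coarse-grained tethers is unstated): `base_z` is
the median headgroup height of the flat region's solvent-facing leaflet
(base candidates = headgroups within one bilayer thickness, 4.5 nm, of the
lowest headgroup — robust even when tube headgroups outnumber the base);
tube headgroups are those above `base_z + max(2×roughness, 0.5 nm)`; *L* is
the maximum tube headgroup height above `base_z` (a configurable
`base_offset` subtracts a base bulge if desired); *R* is the mean of the
inner- and outer-leaflet headgroup radii about the axis (two-means split of
radial distances), measured on the tube body with the cap and junction
excluded (bottom margin 1.0 nm, top margin 3.5 nm). A configuration with no
headgroups above threshold is *flat* (L = 0, R undefined), not an error.

Relative rigidity follows from `E_b = πK_b·L/R` with equal stored energy at
equal force and time: `K_b(c)/K_b(ref) = (L/R)_ref/(L/R)_c`, reported in
percent. Force/time labels, when supplied, must match across compositions.
On the reference L/R table (6, 12, 16, 20 nm/nm) the formula yields 100, 50,
37.5 and 30%; the middle value is reported as computed (37.5%) — published
roundings of the same quantity (35%) presumably used unrounded L/R, and the
module does not force agreement.

Scission: single-linkage connected components over all lipid beads at a
1.2 nm cutoff (periodic in x-y, via a KD-tree; an O(n²) pairwise search is
kept in the test suite as the exact oracle). One component ⇒ intact. With
several, the component holding the majority of the pulled patch decides:
**breakage** when it contains at most `margin` (default 10) non-patch lipids
(rupture right at the force application point), otherwise **fission** (the
patch left together with tube-body lipids: neck rupture).

## Assay quantification

* Quenching: `(F_i − F_0)/(F_T − F_0) × 100` with `F_0` the mean
  fluorescence over the pre-dithionite window (default 0–30 s, configurable)
  and `F_T` the post-Triton value (given, or the mean after a stated Triton
  time). `F_0 = F_T` has no dynamic range and is an error. The quench
  percentage is invariant under affine rescaling of the fluorescence axis.
* GUV permeability `100 × I_in/I_ex`; shrinkage `100 × A_0/A_i` exactly as
  conventionally printed — note this rises **above** 100% as vesicles
  shrink, so the consumed-area alternative `100 × (1 − A_i/A_0)` is also
  provided; both conventions are emitted because the printed form's intent
  is not resolvable from its source.
* Apparent radius `√(A/π)` in the unit of √area.
* GTPase rate: absorbances are calibrated to µM phosphate by a least-squares
  line through the standards **with a free intercept** (the intercept
  absorbs background; nothing constrains the line through the origin);
  non-monotone standards are rejected. The rate is the least-squares slope
  of phosphate vs time over the fit window, divided by the enzyme
  concentration. The default window 15–120 s covers the early linear phase
  of the 15/45/75/120/180/240/360 s sampling grid; the exact window is not
  specified anywhere upstream and is configurable.

## Synthetic data

The generators are **fixture factories, not simulators**: no forces,
thermostats or force-field physics anywhere. They emulate the *statistical
structure* the analyses consume — two leaflets of rigid idealized lipids
(phosphate, glycerol, sn1/sn2 carbon strings at 0.125 nm spacing) around a
midplane, aqueous slabs above and below, 4.0 nm default thickness and
0.64 nm² area per lipid (typical PC values), ~30 waters per lipid — and
plant exact, scripted features:

* waters realizing exactly `n_cross` crossings and `n_rebound` rebounds
  (piecewise-linear slab transits with 0.1 nm margins), one water per event,
  against background waters performing bounded random walks that never enter
  the slab;
* terminal-bead motion as constant steps (analytic velocity) or Gaussian
  steps of SD σ (mean |Δz| = σ√(2/π));
* chain bends placing the *n−2/n/n+2* angle at an exact planted value by a
  single lateral carbon displacement of 2a·cot(θ/2) (flanking angles stay at
  90° + θ/2, safely above the 100° threshold for θ > 20°), bends ≥5 carbons
  apart so no two share a triplet;
* protrusion square waves with a known number of outward transitions;
* coarse-grained tubes of exact midsurface radius and length built from
  6-bead lipids (half-thickness 1.5 nm), optionally severed mid-tube (axial
  gap > 1.5 nm) or with the pulled patch displaced beyond the linkage
  cutoff;
* defect patches whose exposed aliphatic bead tops sit exactly `depth` nm
  below the glycerol level inside a window of known area;
* assay traces with planted plateau, permeability/shrinkage and turnover
  rate.

The default system size is 2 × 144 lipids (the all-atom study scale); tests
use the 2 × 16-lipid preset with 500 waters and 1000 frames at 10 ps — small
enough that the full suite runs in well under a minute while every planted
event remains individually recoverable. Because lipids are rigid and waters
scripted, passing tests demonstrate the *correctness of the bookkeeping and
formulas* (event detection, classification, normalisation, geometry), not
robustness to thermal noise, undulations, curved midplanes or genuinely
diffusive permeation; those belong to real-trajectory validation.

Every generator is a pure function of (config, seed); ground truth is
serialized as JSON next to any written dataset and round-trips exactly.

## Numerical choices and degenerate inputs

Strict inequalities at every classification boundary (slab membership,
torsion threshold, protrusion crossing); depth exactly 0.1 nm → shallow.
Two-means clustering is deterministic (min/max initialisation). Sample SDs
use ddof = 1, reported as 0 for a single block. A single-frame trajectory
has undefined dt (flagged); velocity and block statistics require more than
one frame. Trajectory times must be strictly increasing and uniform to 1e-6
relative. Empty selections, zero blocks, zero external intensity, zero areas
and non-monotone standards are errors, not silent zeros.

## Limitations

Planar-bilayer analyses assume an approximately flat membrane with its
normal along z (no local-patch midplane fitting). Binary trajectory formats
(XTC/TRR/DCD) are out of scope — convert upstream or use the frame-text
format. Permeability is reported as normalised visit percentages, not as a
physical permeability coefficient. Tube analysis assumes one tube along a
known axis. The defect scan's ray-cast geometry is a reconstruction and not
guaranteed to match any particular prior implementation cell-for-cell.
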