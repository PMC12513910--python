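# Methods

## Coordinate and annotation model

All coordinates are nanometres.  Within a section the origin is the lower
left corner with y up; the z of section *i* is the cumulative sum of the
thicknesses of the sections listed before it, so sections lost at the
microtome should be kept in the file as empty `S` records.  Per-section
thickness is stored individually (not as one global constant) because real
ultrathin series jitter around their nominal thickness and that jitter is
part of any honest error budget.

A closed contour traces a full membrane (bouton, mitochondrion); an open
contour traces a membrane specialization (PreAZ, PSD) along part of a
membrane.  Validation enforces: ≥ 3 points, nonzero area and simplicity
(shapely's robust predicates, shared endpoint exempt) for closed contours;
≥ 2 points for open ones; finite coordinates; consecutive duplicate points
removed on construction.  Vesicle marks are circles (center + diameter);
clear-vesicle diameters outside 20–80 nm are accepted with a warning because
sliced profiles are chords and legitimately fall below the anatomical range.
A vesicle mark's `object_id` names its parent bouton; the identity of one
physical vesicle across sections is *not* encoded, matching real annotation,
and is recovered spatially where needed (dense-core dedup).

## Surface reconstruction

One closed contour per section (branching rejected in v1).  Both contours of
each consecutive pair are resampled by arc length to a common vertex count
`max(32, ceil(perimeter / pixel_size))` — mesh resolution follows
acquisition resolution — oriented counter-clockwise, and joined by the
cyclic vertex correspondence that minimizes total band area (evaluated
exhaustively over all offsets).  First and last contours are capped with
planar centroid fans at their section planes, giving a watertight,
consistently oriented mesh.  Sections where the object was not traced are
bridged directly: the band simply spans the larger z gap.  Surface area is
the triangle-area sum; volume is the divergence-theorem signed sum,
orientation-corrected, and requires watertightness.

Known error terms, measured against analytic solids in the test suite: flat
end caps truncate the half-section crowns (volume deficit ≲ 1.5% on a
500 nm-radius sphere at 55 nm sections); the band overestimates doubly
curved area slightly (≲ 3%); both shrink as thickness decreases
(convergence is tested).

Completeness: an object touching the first or last section is `incomplete`.
Strictly inside the stack, an end counts as tapered when its contour area is
below 25% of the object's maximum cross-section; two tapered ends give
`complete_en_passant`, exactly one gives `complete_end_terminal`, and none
is reported `incomplete` because completeness cannot be certified from the
trace run alone.

## Active-zone measurement

**PreAZ.**  On every section carrying the density outline, the sub-arc of
the bouton membrane covered by the density is extracted: membrane samples
(step = min(pixel, 2) nm) whose perpendicular foot lies *on* the outline
(not beyond its ends) within the coincidence distance, default 30 nm.  The
end-of-outline condition matters: without it the 30 nm halo around the
outline tips recruits membrane laterally beyond the density and inflates the
area by ~2 × 30 nm of arc.  Covered sub-arcs of consecutive sections are
stitched into a ruled band (fragmented densities fall back to the trapezoid
rule) and the two end sections contribute half-thickness flanges, which is
unbiased when the density's true edge is uniformly positioned within its end
section.  The per-AZ area therefore carries a ±half-thickness uncertainty at
each z end — about ±10% for a patch spanning five 55 nm sections.  `l_PreAZ`
is the summed trace length of the outlines (fragments summed); traces are
planar, so 2D and 3D lengths coincide.

**PSD.**  Estimated, not reconstructed: `SA_PSD = SA_PreAZ · l_PSD /
l_PreAZ`, valid under the assumption that both specializations run parallel
across the cleft.  The record's cross-product identity
`sa_psd · l_preaz = sa_preaz · l_psd` holds to machine precision by
construction and is property-tested.

**Shape.**  Outlines embedded at their section z are projected onto their
best-fit (PCA) plane — the en-face view.  Projecting onto the xy plane
instead would let the curvature of the bouton wall masquerade as concavity
(a plainly macular patch on the default synthetic bouton classifies as
horseshoe under z-projection; en face it is macular).  Each projected
outline is dilated by half its section thickness plus one pixel (so
adjacent-section footprints fuse) and unioned.  Classification: fragmented
union → perforated; exactly one enclosed hole larger than 25% of the filled
patch → ring; other holes → perforated; simply connected with convex-hull
solidity < 0.6 → horseshoe; otherwise macular.  The two thresholds are
package constants exposed as function arguments — the source vocabulary is
qualitative, so they are calibration points, not measurements.

**Cleft.**  Width triples (two lateral edges, center) are taken by the
annotator on perpendicularly cut synapses; that inclusion criterion is
visual and stays with the annotator.  Per synapse: lateral mean, then mean
and sample SD of {lateral mean, center}; across synapses: mean and sample SD
of the per-synapse means (SD reported 0 with a warning at n = 1).  Sample
(n−1) SD is used throughout the package.

## Vesicle pools

Distance is measured in-plane on the vesicle's own section: max(0, distance
from mark center to the nearest PreAZ outline − radius).  When that section
carries no outline of the bouton's AZs, the nearest outline within ±1
section is used with the out-of-plane offset added in quadrature (section
mid-plane z), and the record is flagged `cross_section`; with no outline in
reach the distance is undefined and the vesicle is excluded from the
histogram (counted as `n_undefined`).  With several AZs per bouton a vesicle
is assigned to its nearest one.  AZ–bouton association is automatic (outline
within 30 nm of the membrane on a shared section) or explicit via `az_ids`.

Bins are 10 nm wide and closed below (a vesicle exactly at 10 nm belongs to
the RRP); the histogram runs to 500 nm with an overflow bin.  Pool mapping:
≤ 10 RRP(p10); ≤ 20 RRP(p20), reported cumulatively so p20 ≥ p10 always;
20–60 an explicit interzone column (the published pool bands leave it
unassigned, so it is never silently merged into the RP); 60–200 RP; > 200
resting.  Clear vesicle marks are trusted once per vesicle — no dedup and no
count corrections.  Dense-core vesicles, marked only where they appear
largest, are deduplicated by clustering marks on adjacent sections whose
centers lie within the larger mark's radius in-plane (maximal connected
components, which makes the operation idempotent); each cluster keeps its
largest-diameter mark, ties broken toward the lower section.

Docked vesicles: explicitly flagged records count regardless of distance;
unflagged records within ε = 2 nm (below the 5 nm pixel) are recruited.  On
thin-section (tomogram) stacks, one vesicle yields marks on many consecutive
sections; `count_docked_in_stack` clusters marks with the dense-core rule
first so each vesicle counts once.

## The synthetic scene generator

The generator is the package's ground-truth instrument, not a rendering
engine.  A scene is an ellipsoid bouton (default semi-axes 700 × 600 ×
500 nm, ≈ 4.5 µm² — mid-range for cortical boutons of ~2.5–15 µm²) with one
to three AZ patches (default one 60° × 280 nm band near the equator,
≈ 0.18 µm², in the reported 0.2–0.3 µm² range), a 22 ± 1 nm cleft read at
the two lateral edges and the center of each AZ, a 500-vesicle cloud
(diameters 40 ± 5 nm, clipped to 20–80), five dense-core vesicles (50–90 nm,
mutually separated ≥ 150 nm so dedup can never merge two real DCVs), four
docked vesicles touching the AZ, and one mitochondrion.  Exact truth is
recorded at build time: ellipsoid area by high-order Gauss–Legendre
quadrature (matches the closed form for a sphere to 1e-9), volume in closed
form, patch area by quadrature, each vesicle's membrane-to-PreAZ distance in
its own mid-plane, pool labels (counts assigned exactly by largest-remainder
rounding of the fractions 0.02/0.03/0.10/0.35/0.50), and DCV/docked
identities.

Undocked vesicles keep a minimum membrane distance of 4 nm: docking is a
discrete attachment state in the model, so an unflagged vesicle inside the
2 nm docked criterion would be a contradiction of the scene, not a test of
the pipeline.

Slicing emulates acquisition: per-section thickness drawn from
N(55, 5²) nm (TEM default; 50 nm z / 5 nm xy for FIB-SEM; 2 nm virtual
sections restricted to a ~300 nm window for the tomogram mode), a random
grid phase, surfaces intersected with each section's central plane, contours
polygonized at the pixel size and quantized to the pixel grid.  A vesicle
yields a mark on each section whose central plane cuts it, with the chord
diameter at that plane; profiles with chords below 10 nm (two pixels) are
considered undetectable and are dropped.  Central-plane cutting is the
simplest model consistent with contour-tracing practice; it deliberately
loses ~1 − d/t of the vesicles (≈ 27% at d = 40, t = 55 nm), which is why
recovery tests compare counted identities against *visible* ground truth and
fractions against binomial sampling expectations.  What the generator does
not emulate: image noise and blur, membrane-contrast differences between TEM
and FIB-SEM, registration error, annotator disagreement, and
projection-through-thickness effects.  Passing recovery tests therefore
demonstrate the correctness of the measurement code under ideal annotation,
not robustness to segmentation error.

## Statistics

Kruskal–Wallis H with tie correction (scipy), pairwise two-sided
Mann–Whitney U post hoc — exact distribution when both groups have n ≤ 20
and the pooled sample is tie-free, tie-corrected normal approximation
otherwise — with Holm adjustment across the pairwise family (the omnibus
test's source protocol names no correction; Holm controls FWER without
independence assumptions).  All-identical values across groups degenerate
the rank statistic and return H = 0, p = 1 with a warning.  Calibration is
simulated in the acceptance suite: null rejection 0.05 ± 0.02 over 500
three-group datasets, power > 0.8 at 1 SD shifts between adjacent group
means at n = 30.

## Reproducibility and problem sizes

Every CLI output embeds toolkit version, input SHA-256, seed, and the
parameter set; no timestamps, so identical inputs and seeds give identical
bytes.  All randomness flows through seeded `numpy` generators.  The test
suite and `scripts/acceptance.py` use desk-scale problem sizes chosen to
make sampling error small relative to the tested tolerances: 20 recovery
boutons × ~500 vesicles, 500 null simulations, 1,000 formula draws, 200
distance-oracle cases, 10,000 binning draws.
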