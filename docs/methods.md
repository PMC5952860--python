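# Methods

This note records the models, conventions and parameter choices behind
`cortigap`, and what the synthetic phantom does and does not establish about
real data.

## Spatial conventions

Arrays are `(z, y, x)`, 0-based, with `z` the scan axis; voxels must be
isotropic and anisotropic inputs are rejected at load time, because every
diameter and depth threshold of the algorithm is defined in voxel units at
82 μm and silently resampling would corrupt them. Physical thresholds are
stored in mm and converted exactly once through `mm_to_voxels`
(nearest-integer). Foreground connectivity is 26-neighbour, background
6-neighbour, everywhere — the standard complementary pair that avoids
topological paradoxes.

All structuring elements are *digitized Euclidean balls* realized by
thresholding distance transforms, not iterated 3×3×3 crosses: an erosion by
radius *r* keeps voxels whose distance to the background exceeds *r*; a
dilation reaches voxels within *r* of the set. Iterated crosses would grow
octahedra, and a 48-step dilation must produce a sphere, not an octahedron.

## Segmentation

The clinical protocol's Laplace–Hamming filter coefficients are proprietary,
so the binarization here is a documented surrogate: a radial Hamming-window
low-pass in the frequency domain (transfer 0.54 + 0.46·cos(πu/cutoff) up to
the cutoff, as a fraction of Nyquist; a cutoff of 1 disables the filter
entirely), Laplacian sharpening `f − w·∇²f` with weight `w ∈ [0,1]`, and a
threshold at a fixed fraction of the filtered dynamic range. Defaults:
cutoff 0.8, weight 0.5, threshold fraction 0.4. With the filter disabled and
threshold 0.5 the operation reduces to a plain midpoint threshold, which is
the exact setting for two-level test volumes.

The periosteal auto-contour closes the bone mask with a ball of 2.5 mm
(bridging interruptions up to ~5 mm — larger defects require an external,
operator-corrected contour mask, which `segment_joint` accepts), fills
holes in 3D and keeps the largest 26-connected component. The cortical mask
is the contour minus its Euclidean erosion by the depth (4 voxels); on
curved surfaces digitization places the realized peel within ±half a voxel
of the nominal depth, which the tests bound explicitly.

## Interruption detection

A cortical interruption is a non-bone 26-component of the peel that spans
it: 26-adjacent both to the exterior of the outer contour and to the eroded
interior. Non-spanning cavities are cortical porosity and are reported by
the morphometry module instead — this prevents double counting. Components
cut by the image z-boundary cannot demonstrate contact with the missing
face, so boundary contact substitutes for it and the component is flagged
`truncated` (multi-stack acquisitions cut anatomy arbitrarily).

The diameter gate (≥ 0.41 mm) uses the maximum inscribed-sphere diameter
*measured against bone*: twice the largest EDT value of the full non-bone
space over the component's voxels. Measuring within the peel-clipped
component itself would cap every diameter at the 0.328 mm peel depth and no
interruption could ever pass the 0.41 mm gate.

Interruption surface is volumetric — component volume divided by peel
depth, i.e. the effective through-cortex cross-section — because mesh areas
are unstable on 4-voxel-thin structures. This is a surrogate for a quantity
whose original definition is not public.

## Void extension

The six stages and their defaults: ROI = Euclidean dilation of the
interruptions by 48 voxels (3.936 mm) ∧ outer contour; void selection =
morphological opening of the non-bone ROI space by a ball of half the
0.738 mm threshold (equivalently: the region of local thickness ≥ threshold);
erosion by 2 voxels (severing necks ≤ 0.328 mm); connectivity filter;
constrained restoration; union with the interruptions.

Two digitization decisions matter here:

* **Connectivity tolerance.** The erosion retracts every void surface by
  2 voxels, so a void that touched an interruption before erosion always
  ends exactly 2 voxels away from it afterwards; a literal adjacency test
  would then reject *every* void not reached through a channel wider than
  0.738 mm. The filter therefore widens the adjacency test by exactly the
  erosion radius — tolerating only the gap the erosion itself created.
  Genuinely detached cavities (e.g. the phantom's decoy void) remain
  rejected.
* **Restoration.** "Dilating back to original size" is reconstruction by
  dilation: `erode_voxels` iterations of 26-neighbour dilation, each
  intersected with the pre-erosion void mask. An isolated void is restored
  exactly (verified on digital balls of radius 6–12); severed thin necks
  regrow at most 2 voxels and never reconnect. A free dilation would undo
  the erosion's purpose.

Final components containing several interruptions are attributed once, with
all member ids listed, so total volume is conserved. The detectable void
depth is bounded by the ROI radius (~4 mm): deeper cavities contribute
nothing, by construction.

## Local thickness

Thickness at a voxel is the diameter of the largest inscribed sphere
containing it (direct method). The implementation prunes sphere centres
whose sphere lies inside a neighbour's (an exact reduction) and paints the
survivors in increasing radius order. Convention: a centre with EDT value
*d* covers voxels within *d* (so every voxel of a digital ball is covered
by its central sphere) but reports diameter 2(d − ½), compensating for the
EDT measuring to background voxel *centres* — half a voxel past the
physical interface. An n-voxel slab thus reports exactly n·v and a digital
ball of radius r reports ≈ 2r (−8% at r = 5). The same convention defines
the brute-force oracle the tests compare against on ≤ 32³ volumes.

## Morphometry surrogates

Tb.Th/Tb.Sp/Tb.SpSD are means/SDs of local thickness of trabecular bone and
marrow; thickness is always computed on the *full* structure and then
averaged over the compartment, so compartment borders never clip the
spheres (Ct.Th would otherwise saturate at the peel depth). Ct.Po is the
non-bone, non-spanning fraction of the peel; Ct.Po.Dm is the mean cavity
thickness bounded by the filled contour (open notches must not inherit
air-sized spheres). Tb.N is reported both ridge-based (inverse mean spacing
of the EDT medial axes) and via the plate model 1/(Tb.Th + Tb.Sp), with the
method flagged, since the scanner's definition for this anatomy is not
fixed. Densities in mg HA/cm³ require a scanner calibration phantom and are
deliberately not computed; BV/TV (exact voxel fraction) and mean
attenuation stand in so the precision pipeline stays exercisable end to
end.

## Precision statistics

ICC(2,1): single-measure, two-way random effects, absolute agreement,
(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n), with the F-based 95% CI
(Satterthwaite denominator df). Single-measure is the right form because
individual scans/operators are compared, not their mean. Rating bands:
< 0.40 poor, 0.40–0.60 fair, 0.60–0.75 good, ≥ 0.75 excellent; boundary
values go to the higher band (the source convention is ambiguous; this
choice is documented, not tunable). Glüer precision: SD_j = |x₁−x₂|/√2 per
duplicate pair, SD_RMS = √(mean SD_j²); CV_j = 100·SD_j/mean_j, suppressed
("n.a.") whenever a subject mean is zero — as for count outcomes.
LSC = 1.96·√2 × the precision error, identical in absolute and percent
form. Paired *t* is two-sided; subjects are treated as independent rows
(joints from the same patient are not modelled as correlated — a documented
caveat). Stack exclusion: grade > 3 on either scan excludes the stack
(union counted once); a joint is excluded only when all stacks are.

## The phantom

`make_joint_phantom` emulates the geometry the algorithm consumes, not CT
physics: a spherical cortical shell (bone ≈ 1000, marrow ≈ 0) of default
radius 4 mm and thickness 0.8 mm inside a 110³ grid at 82 μm, filled with a
cubic rod lattice, drilled radially with cylindrical channels and carved
with spherical voids whose top touches the bottom of the detection peel —
as a real erosion cavity replaces the cortex it destroyed. Gaussian blur
(σ = 0.055 mm, matching a ~0.13 mm FWHM point spread) and additive Gaussian
noise (σ = 50 gray units on the 0–1000 scale) model the imaging chain; a
seed fully determines the output.

Lattice realism is defined *post hoc* on the binary image, because that is
what the algorithm sees: the lattice's 3D pore diameter (what Tb.Sp
measures — the axis-aligned rod gap is spacing/√2) defaults to 0.63 mm,
safely below the 0.738 mm void threshold so normal marrow never qualifies
as a void; rods are drawn 3 voxels wide because thinner rods do not survive
the imaging blur. Consequences worth knowing: the apparent bone fraction
(~0.6) and Tb.Th are higher than in vivo trabecular bone, and segmentation
at the 0.4 threshold thickens rods further — the phantom is a geometric
test bed for the detection cascade, not a biomechanically realistic bone.
Whenever space allows, an unconnected *decoy* void is placed at the joint
centre so the connectivity filter is exercised negatively as well.

`rescan_variant` applies an integer rigid shift (default ≤ 3 voxels) and a
fresh noise draw to the clean volume — repositioning between scans. It does
not model motion streaking, rotation or beam hardening; visual motion
grades are inputs, never computed.

## Problem sizes and runtime

The reference phantom runs at full clinical scale (110³ voxels, 4 mm head).
Cohort-style checks (40 scan/re-scan pairs) use scaled-down 64³ joints
(2.2 mm radius, 0.6 mm cortex) — the package's chosen test scale, keeping a
full cohort to roughly a minute on one CPU while exercising every pipeline
stage. Phantom recovery at these conditions: exact interruption counts for
noise-free channels ≥ 0.5 mm, attached void volume within 15% of ground
truth for voids ≥ 2 mm³ (typically ~6%).

## Known limitations

* The segmentation filter is a surrogate; absolute agreement with the
  proprietary protocol is neither claimed nor testable here.
* The automatic contour reconstruction inside `detect_interruptions`
  (hole-filling the peel) assumes the object is not cut by the volume
  border; truncated anatomy needs an explicit outer contour mask.
* Interruption surface and Tb.N are defined by documented surrogates.
* The phantom's lattice is periodic and its voids spherical; pathology is
  messier, and passing tests demonstrate correctness of the morphological
  cascade, not clinical accuracy on patient scans.
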