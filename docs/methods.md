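# Methods

## Scope and data model

The package quantifies bone microarchitecture in 3D voxel volumes with
isotropic spacing (default 0.0607 mm, the second-generation HR-pQCT
voxel size).  All lengths, areas and volumes are reported in mm, mm²
and mm³; voxel indices are 0-based and physical position is
`origin + index × spacing`.  The limb long axis is metadata (default
the third array axis); every "axial" computation reads it rather than
assuming an orientation.  Foreground (bone or pore structures being
decomposed) uses 26-connectivity; complementary background and the pore
space inside the cortex use 6-connectivity, the standard pairing that
avoids digital-topology paradoxes.

## Binarization

Two methods segment mineralized bone from grayscale volumes.

*Laplace–Hamming* (primary): a frequency-domain low-pass with a radial
Hamming taper `H(f) = 0.54 + 0.46·cos(πf/f_c)` for `f ≤ f_c`, Laplacian
edge enhancement (`I − w·∇²I`, an unsharp-mask step), robust [0, 1]
normalization by the 0.1/99.9 intensity percentiles, a global threshold
at a fraction of that range, and removal of 26-connected components
below a voxel count.  Defaults: `f_c` = Nyquist (the taper spans the
full band — the data are already band-limited and the Laplacian term
supplies the detail emphasis), `w = 0.5`, threshold fraction 0.5,
minimum component 27 voxels.  The constants of the original instrument
implementation are not published; these defaults were chosen by a
design scan against the package's own phantom targets (exact recovery
of noiseless two-level phantoms; Dice ≥ 0.95 under 1-voxel blur and 10%
noise; retention of sub-voxel rods where plain thresholding loses them)
and are recorded in every output's metadata.

*Standard threshold*: Gaussian smoothing (σ = 0.5 voxel) followed by a
global absolute threshold, or a fraction of the robust range when no
absolute value is given.  A larger smoothing σ (e.g. 0.8) rounds off
corners of thin structures at the 0.5 iso-level and breaks exact
recovery of noiseless phantoms, which is why 0.5 is the default.

Robust normalization makes both methods exactly invariant to affine
intensity rescaling; raising the threshold can only remove voxels
(monotonicity).  A constant image returns an empty mask with a warning.

## Cortical segmentation

A 3-step algorithm on the binarized bone, slice by transverse slice:

1. **Contours.**  Morphological closing (disk, radius `r_close`,
   default 15 voxels, computed on a padded slice so the dilation is
   never clipped) bridges surface interruptions; hole filling gives the
   periosteal region (everything inside the outer contour).  The
   endosteal (marrow) region is the largest enclosed background
   component of the *original* bone — using the original rather than
   the closed bone avoids a one-voxel inward bias along the inner
   surface — with enclosed bone islands (trabeculae) filled in.  A
   marrow candidate must be bounded mostly (≥ 50%) by actual bone;
   slices whose closing inflates the section by more than 50% without
   producing enclosed marrow are rejected as "not a cortical shell",
   and an enclosed-looking but open shell raises an error suggesting a
   larger `r_close`.  The original interactive review step is replaced
   by these parameters plus the option to supply externally corrected
   contour masks.
2. **Pores.**  6-connected background components inside the cortical
   band that do not touch a 1-voxel in-plane band at either surface
   (erosion is in-plane so axially through-running canals survive) and
   contain at least `min_pore_voxels` (default 5) voxels.  Components
   touching a surface are concavities, not pores.
3. **Integration.**  `cortex = bone ∩ band`,
   `compartment = cortex ∪ pores`; the invariants (pores disjoint from
   cortex, compartment inside the band) are enforced programmatically.

Known discretization limit: a notch that removes an extreme boundary
voxel cannot be perfectly restored by any closing (the extreme point no
longer exists); bridging is exact up to that one voxel per slice.

## Skeletonization and plate/rod (slab/tube) decomposition

The decomposition machinery is shared by the trabecular analysis (on
bone) and the cortical pore analysis (on the pore space).

**Thinning.**  An isthmus-preserving directional thinning: six
directional subiterations per pass; each subiteration evaluates, on the
frozen state, (a) anchoring — a border voxel whose foreground
26-neighbourhood splits into ≥ 2 components (curve isthmus) or whose
background 6-neighbourhood splits into ≥ 2 components (surface isthmus)
is permanently anchored — and (b) deletion candidates (simple points,
by the standard 26/6 characterization, that are border in the current
direction and not curve endpoints); candidates are then deleted
sequentially in lexicographic order with a topological re-check.  This
preserves connectivity and the Euler characteristic, collapses rods to
medial axes and plates to medial surfaces.  Two refinements handle
discretization artifacts: connected components that are already
1-voxel-thin everywhere are their own skeleton (anchored at
initialization), and "ribbon" artifacts — sheet-like patches whose
interior (background-separating voxels with ≥ 6 neighbours) counts
fewer than 9 voxels, as arise when an elongated rod cross-section
passes through a w×1 intermediate — are re-thinned in curve-only mode.

**Classification.**  Per skeleton voxel, from the local 26-neighbourhood:
n = skeleton neighbours, c = foreground 26-components among them,
b = background 6-components of the 18-neighbourhood touching the voxel.
`n ≤ 1` → curve edge; `c ≥ 3` or `b ≥ 3` → junction; `b = 2` with
`c = 1` and `n ≥ 6` → surface interior; `n = 2` or `c = 2` → curve
interior; `b ≥ 2` with `n < 6` → junction (pinch points such as the
centre of a planar cross); otherwise surface edge.  Curve voxels that
touch surface voxels become junctions (surface–curve meetings), tiny
surface segments (< 9 skeleton voxels, below the sheet resolvability
limit) are absorbed into adjacent junctions or reclassified as curve,
and junctions grow by one skeleton ring — over curve voxels always,
over surface voxels only at raw topological junctions — because
branches can touch diagonally around a junction voxel.  Classification
is deterministic.

**Elements and propagation.**  Removing junction voxels splits the
skeleton into same-class segments (surface elements numbered before
curve elements).  Every structure voxel then receives the label of its
nearest segment by an iterative 26-connected wavefront restricted to
the structure; ties go to the lower element id, making the output
deterministic and the decomposition complete (element voxel counts sum
to the structure's foreground count — asserted in code, not only
tested).  Unreachable islands become their own elements, typed by local
shape, with a warning.  Per element: thickness = 2 × mean distance-to-
background over the element's skeleton voxels × spacing; orientation =
principal axis of the element's voxel cloud (SVD, deterministic sign);
curve length = total Euclidean edge length of the minimum spanning tree
over 26-adjacent skeleton voxels (+1 voxel end correction) × spacing;
surface area = element volume / thickness.  Elements touching the
volume boundary are kept and flagged.

**Junction semantics.**  Adjacent junction voxels form one junction
cluster.  A cluster joining ≥ 2 surface elements counts one
plate–plate (slab–slab) junction, ≥ 2 curve elements one rod–rod
(tube–tube), and ≥ 1 of each one plate–rod (slab–tube); a cluster
touching three rods is one junction, not three.  A consequence of the
junction-splitting contract is that a Y-branched canal is three tube
segments joined by one tube–tube junction, and a canal with a side-
connected void splits where the junction interrupts its skeleton.

## ITS parameters

Plates are surface-like elements, rods curve-like.  With bulk volume TV
(the trabecular mask volume): `pBV/TV`, `rBV/TV` (element volume over
TV), `pBV/BV + rBV/BV = 1`, `P–R ratio = pBV/rBV`; `aBV/TV` sums
elements whose principal axis is within 30° of the longitudinal axis
(the angle is a package choice, configurable and logged); plate/rod
number density is the literal cube root of count over bulk volume, per
its printed definition (the unit oddity is acknowledged); mean
thickness/length/area are volume-weighted element means (robust to
fragment elements; flagged in metadata).  Undefined quantities (e.g.
the P–R ratio with no rods) are reported missing rather than infinite.

## CPS parameters

The same decomposition applied to the pore space *within the cortical
compartment only* (never exterior background): slab count, tube count,
tube–tube and slab–tube junction counts, slabs/tubes, slab volume/tube
volume, mean slab and tube volumes, total pore volume.  Slab + tube
volumes sum exactly to the pore volume (conservation assertion).

## CLA

For every compartment voxel the normalized transmural depth is
`d = D_endo / (D_endo + D_peri)` with in-plane Euclidean distance
transforms to the endosteal region and to the space outside the
periosteal contour; layers are `d < 1/3` (endosteal), `1/3 ≤ d < 2/3`
(midcortical), `d ≥ 2/3` (periosteal).  Defining the layers by
normalized depth guarantees three equal-width bands whatever the local
cortical thickness.  For a solid section (no marrow) depth is measured
from the periosteal centroid as a medullary-axis surrogate, with a
warning.  Each pore element is assigned whole to the layer containing
its voxel centroid (a pore spanning layers counts once; a centroid
falling outside the compartment falls back to the majority layer of
the pore's voxels).  Total pore area is the per-slice mean (over the
slices containing compartment, the same slice set for every layer, so
layer values sum exactly to the entire-compartment value) of the summed
pore cross-sectional areas; average pore size is the mean over pores of
voxel count × voxel area / slices spanned; normalized area and number
divide by the layer's own per-slice mean area.  Both the raw per-slice
mean (the headline, unit mm²) and the normalized variant (mm²/mm²) are
emitted.

## Phantoms

Phantom elements are axis-aligned primitives — boxes for plates/slab
voids, cylinders for rods/canals — so counts, volumes, orientations and
depths have closed-form expectations.  Trabecular phantoms place
elements with a minimum clearance (default 3 voxels, verified by
dilation) under bounded rejection sampling; defaults (plate 16×16×2
voxels ≈ 120 µm thick, rod radius 1.6 voxels ≈ 190 µm diameter) sit in
the physiological trabecular range at 60.7 µm voxels.  Cortical
phantoms are annular shells with axial canals at controlled transmural
depths (evenly spaced angular slots with jitter guarantee separation),
planar voids, Y-branched canals (slim geometry — radius ≤ 1.5 voxels,
2-voxel tangential step — so the branch point is a clean curve junction
rather than a slab-like wedge), and "coalesced pairs" (two close canals
merged by a planar web), the degraded-bone motif that raises the
slabs/tubes ratio.  Canals keep ≥ 2 voxels of clearance from both
cortical surfaces; a requested depth is clipped into the feasible band,
and the ground truth records the realized depth.  Intensity volumes add
two-level contrast, Gaussian blur (a partial-volume surrogate) and
additive Gaussian noise.  A single integer seed drives all randomness.

What the phantoms do *not* emulate: real trabecular connectivity and
curvature, cortical thickness variation, beam hardening, scanner noise
texture, motion artifacts.  Passing the phantom suite therefore
demonstrates correctness of the measurement chain on known geometry,
not clinical accuracy on scans.

Cohorts: `make_cohort` draws covariates from distributions typical of a
late-middle-aged study population (age ≈ N(60, 7.5) yr, ~55% female,
~70% of females postmenopausal, height/weight normal, HbA1c ≈ N(8.0,
0.9)% in cases vs N(5.5, 0.3)% in controls, skin AGEs correlated 0.5
with HbA1c), with optional group offsets to inject confounding.  In
table mode, outcomes come from a linear model with a known conditional
group effect (the recorded ground truth separates conditional from
marginal effects under confounding); in phantom mode each subject
carries a trabecular and a cortical phantom specification whose
generator knobs are shifted in the case group, and the analyzers
produce the outcomes.

## Statistics

Adjusted differences use a linear mean model (outcome ~ group +
covariates).  The default error structure is GEE with identity link,
exchangeable working correlation over the matched-pair cluster id, and
robust sandwich standard errors; OLS is the `iid` alternative and the
automatic fallback when every cluster is a singleton.  CIs are
normal-theory (estimate ± 1.96·SE); p-values two-sided.  Sandwich SEs
are mildly anticonservative in small samples, so nominal 95% coverage
measures slightly below 95% (the calibration study at n = 60 + 30
typically lands at 90–95%).  Risk-factor models are OLS with the
exposure coefficient rescaled to a configurable unit (per 1% HbA1c, per
5 AGE units, per −20 or −30 mL/min/1.73 m² eGFR — the sign convention
lives in `per_units`).  Collinear designs are rejected with the null
space named; missing outcomes are dropped listwise with a logged count.
No multiple-testing adjustment is applied anywhere, by design.

## Problem sizes and determinism

The test and acceptance studies use phantoms of 64³–96³ voxels, 20–50
phantom replicates per property, 100 cohort replicates for CI coverage,
and a 30-vs-30 phantom cohort for the degradation-direction study —
sizes at which every closed-form expectation is still exact while a
full run completes in minutes on one core.  All randomness flows from a
single seed through `numpy.random.default_rng`; reruns are bit-identical
(asserted on serialized outputs).

## Known limitations

* Discrete medial decompositions are not unique: junction-splitting
  semantics make element counts sensitive to contact geometry (a rod
  crossing splits into four arms; a side-connected void splits its
  canal).  The contracts above pin one deterministic behavior.
* Sheets narrower than ~3 voxels and sheet fragments with < 9 interior
  voxels are classified as rods by construction (resolvability limit).
* The autocontour handles shell-like sections; heavily trabecularized
  endosteal zones (a transitional-zone problem) are out of scope.
* Binarization constants are package defaults, not the instrument
  vendor's; they are echoed into output metadata for provenance.
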