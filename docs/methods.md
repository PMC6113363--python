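# Methods

## The scene model

A scene lives in a world coordinate frame identical to the LM frame, in
nanometres, with the ventral plasma membrane at z = 0.  Each podosome is
described by:

| parameter | default | meaning |
|---|---|---|
| `core_diameter` | 700 nm | FWHM of the actin core blob |
| `core_height` | 600 nm | axial extent of the core |
| `vinculin_ring_radius` | 360 nm | radius of the vinculin ring |
| `vinculin_ring_z` | 50 nm | height of the ring (membrane-proximal) |
| `zyxin_cap_radius` | 200 nm | radius of the zyxin zone |
| `zyxin_cap_z` | 400 nm | height of the zyxin zone (toward the core top) |
| `n_radiating_filaments` | 8 | filaments per core, core top → membrane |

The type system enforces the two geometric orderings that carry the
biology: the vinculin ring is wider than the zyxin zone, and zyxin sits
axially above vinculin.

Vinculin rings are drawn as *capsule* (stadium) contours — the locus of
points at ring radius from the segment joining the member cores.  For an
isolated podosome the segment is degenerate and the ring is a circle; for
a closely associated pair the capsule produces exactly one continuous
ring around both cores, which is the defining signature of association.
Interpodosomal bundles are 2–4 parallel ridges spaced 25 nm (a compact
bundle of actin filaments; the spacing keeps the bundle a single thick
ridge at SEM resolution rather than resolvable separate lines).  Ventral
filaments form a Poisson-distributed mat at z ≈ 20 nm with a default
density of 3 filaments/µm²; podosome clusters sit on a conspicuously
dense actin carpet and a sparse mat would understate the clutter the
detectors must tolerate.  `cytoD_mode` emulates cytochalasin-D treatment:
ventral and radiating filaments are removed while cores and
interpodosomal bundles are retained.

Podosome centers keep a 3 µm margin to the field border (room for the
3 µm profiling line); non-pair cores keep ≥ 1.5 µm spacing and pair
members sit 1 µm apart (free parameters — typical cluster spacing, not
measured values).  Beads avoid core centers by one bead diameter and stay
0.5 µm from the field edge so their PSF is not edge-truncated.

## Rendering

**LM.** Sampling defaults are typical Airyscan acquisition: 40 nm/px
lateral, 150 nm z-steps, 140 nm lateral and 350 nm axial PSF FWHM (the
axial value is ~2.5× lateral, standard for the modality).  Filaments and
rings are deposited as weighted line samples and convolved with the
Gaussian PSF; cores and beads are added analytically as Gaussian blobs
(a point source deposited on the grid would inherit up to 0.25 px² of
spurious variance from the interpolation weights — analytically rendered
beads reproduce the PSF FWHM exactly, which the tests check by
least-squares Gaussian fitting).  Beads render into all four channels,
emulating multi-fluorescent Tetraspeck fiducials.  Noise is optional
Gaussian noise with variance proportional to the signal (shot-noise-like);
`noise_scale = 0` gives exact renders for geometry oracles.

**SEM.** The SEM image is a geometric sketch: 2D-projected filaments and
core outlines drawn as ridges of 50 nm FWHM, beads as bright discs,
mapped through the ground-truth affine, plus background and additive
noise.  No secondary-electron physics is modelled; only geometry and
contrast ordering (beads > core outlines > filaments) matter for the
pipeline.  The default ground-truth affine has ~20× scale relative to
the LM pixel grid (40 nm → 2 nm pixels), ±5° rotation, 0.5–1% shear and
slight (±0.5%) anisotropy — enough distortion that a similarity-only
registration visibly fails, as it does on real dehydrated samples.

## Registration

Bead localization is Gaussian smoothing matched to half the bead size,
median background subtraction, thresholding at 20% of the maximum,
connected components, then a *half-max center of mass*: the centroid is
computed with weights `(I − peak/2)₊` over a symmetric window, with
pixels claimed by other components masked out.  Weighting above the
half-maximum makes the weight decay smoothly to zero at the spot
boundary (no jagged-threshold bias) and excludes dimmer clutter such as
filament ridges brushing a bead; on rendered scenes with default noise
this localizes LM beads to ~1–3 nm and SEM beads to a few nm except
where a filament crosses the disc itself.

Control points are paired by mutual nearest neighbours after mapping SEM
detections through a coarse prior (stage metadata in practice, the known
acquisition geometry in simulations); spurious SEM detections of
filament junctions are dropped automatically because they have no LM
partner.  Fewer than three resulting pairs is an error — the same ≥ 3
bead rule used when selecting fields of view.

The SEM → LM fit is ordinary (unweighted) least squares, solved per
coordinate for the affine model and in the `a, b, tx, ty` parametrization
of `sR` for the similarity model.  No RANSAC: the matcher is clean on
synthetic data and the experimental workflow picks beads manually.
Residuals are Euclidean distances in nm of the LM frame.  With 6 beads
and 5 nm localization noise per modality the expected mean residual is
`σ√2 · √(1 − 6/2n) · √(π/2) ≈ 6.3 nm`, comfortably below the 10 nm
alignment budget; the acceptance script measures it directly.

Resampling (`apply_affine`) is inverse-mapping bilinear interpolation
(`mode="grid-constant"`, which interpolates rather than zeroes samples an
epsilon outside the grid — exactness on integer translations and 90°
rotations is tested against `np.rot90`).

## Overlay

Local statistics use a circular window of the stated radius, clipped at
image borders.  The mean method marks a pixel foreground when it exceeds
its window mean with a 1e-9 relative guard band, so exact ties are
background regardless of floating-point summation order; the mask is
invariant under positive affine intensity rescaling.  Phansalkar uses the
canonical constants k = 0.25, r = 0.5, p = 2, q = 10 on the min–max
rescaled image.  "Blur radius 10" is interpreted as Gaussian σ = 10 px
(the convention of the tool that popularized the recipe) with reflective
padding; the mask value 90 bounds the layer maximum.  Compositing is a
plain additive blend: gray SEM into all three RGB components, cyan into
G+B, green into G, magenta into R+B, clipped to the display maximum.

## Profiling

Core detection: difference-of-Gaussians band-pass (σ = 150/400 nm) of
the actin projection over all z-slices except the membrane-proximal one
(the ventral mat and interpodosomal bundles live there and blur core
peaks together), local maxima with a suppression window of half the
minimum separation, sub-pixel refinement by windowed centroid, and a
final pass that enforces the 700 nm pairwise minimum separation on the
refined centers (two cores closer than that merge into one detection —
a documented limitation matching the core size).  The `accepted` flag on
each detection supports the semi-automatic curation step.

The radial orthogonal view samples the stack by bilinear interpolation
along a 3 µm line through the core center at 36 angles of 10° and
averages the resulting (r, z) slices.  The radial grid has
`line_length / r_step + 1` samples (76 at the 40 nm default), symmetric
half-integer offsets about the center.  z-profiles are read as the view
column nearest the requested radial offset, averaging the ±r columns by
default (they coincide for rotationally symmetric input; `left`/`right`
policies are available).  A literal diagonal line through the (r, z)
view would conflate radius with depth; the vertical-at-offset reading is
the interpretation used throughout.

Normalization is min–max over *all* z-sections of one podosome/channel
jointly (per podosome, not per cell), so relative amplitudes between
sections are preserved; constant sets map to zeros with a `degenerate`
flag, and normalization is idempotent.  Aggregation reports pointwise
mean and SEM = sd/√n with ddof = 1.  Cytochalasin-D profiles are
compared to controls by pointwise division, with points where the
control is below 0.1% of its maximum flagged invalid rather than
divided.

## Association and bundle scoring

A vinculin mask component counts as a continuous ring when, after one
radius-1 closing step (vinculin is non-continuous at fine scale), its
filled footprint has an interior hole; an association event is an
interior region containing ≥ 2 core centers.  Broken rings have no
interior and produce no events; disjoint single rings hold one core
each.  Under cytochalasin D vinculin is absent and association falls
back to a core-distance criterion (centers within 1.5 µm).

The bundle score ridge-enhances the registered SEM image with a
difference of Gaussians tuned to the filament width, rectifies it, and
takes the **median** enhanced intensity along the inter-core segment
(core footprints excluded) over the median along two parallel control
segments offset by one core diameter (plus a small stabilizer of 1% of
the image maximum).  The median is the load-bearing choice: a true
bundle runs continuously along the whole segment, so its median is the
ridge level, whereas stray filaments crossing the segment touch only a
few samples and leave the median near zero.  The default decision
threshold is 2× background.  Isolated radiating filaments that happen to
run almost collinearly between two cores can still fool the score — on
real data the bundle call was visual, and this score is a synthetic-data
proxy, not a validated detector.

Percentages in event tallies round half up to integers (41/44 → 93%).

## What passing tests do and do not show

The generator reproduces the *geometry* of podosome clusters (radii,
axial ordering, ring topology, bundle connectivity, fiducial physics) and
realistic detection-level nuisances (shot noise, filament clutter,
sub-pixel positions, affine distortion with shear).  It does not emulate
labelling stochasticity, unroofing damage, PSF aberrations, SEM charging
or topographic contrast, or biological variability in podosome shape.
Tests passing on these scenes demonstrate that the *algorithms* recover
known ground truth under the stated noise — not that the biological
conclusions would survive on arbitrary real data.

## Problem sizes

Default test scenes use 7–12 µm fields (≈ 175–300 px LM, 10 z-slices)
with 1–5 podosomes, SEM rendered at 4–8 nm/px; the registration
benchmark uses pure point constellations (no rendering), 100 seeds of 6
beads each.  These sizes keep every scene's render under a few seconds
while leaving all spatial scales (PSF, ring radii, bundle width) at
their physical values.
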