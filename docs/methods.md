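# Methods

`nemorph` quantifies three morphological readouts of nuclear-envelope
(NE) reassembly from 3D electron-microscopy volumes: vesicle diameters,
NE-gap geometry with a vicinity vesicle-density statistic, and the in
situ curvature of the NE rim at nuclear pores. Because the measurements
target rare correlative events for which no public raw volumes exist,
every stage is validated by parameter recovery on ground-truthed
synthetic phantoms generated by the package itself.

## Conventions

Arrays are ordered (z, y, x), matching slice-stack acquisition; indices
are 0-based; all physical quantities are nm (areas nm², densities
µm⁻², curvature nm⁻¹). TIFF carries no trustworthy 3D voxel size, so
readers require an explicit voxel size for TIFF input rather than
assuming 1 nm; a nonzero MRC header cell spacing wins when present.
Binning is block-mean with trailing partial blocks dropped; 8-bit
windowing clips to the 0.5/99.5 intensity percentiles by default before
the linear map to [0, 255].

## Vesicle morphometry

Vesicles are the 26-connected components of the vesicle label in a
segmentation volume. Each component is summarised by its physical
bounding-box extents (dz, dy, dx); the working definition of a vesicle
— a roughly spherical membrane profile of similar x, y and z diameter —
is quantified as max(extent)/min(extent) ≤ `max_axis_ratio`
(default 1.5). The reported diameter is the arithmetic mean of the
three extents, the most direct reading of a caliper diameter measured
on micrographs; an equivalent-sphere diameter (from labelled volume) is
emitted as an extra column since the two conventions differ for
non-ideal shapes. For section stacks whose z pitch (50–70 nm) exceeds
the object size, the z extent of a ~57 nm vesicle is a single-section
artefact; `ignore_z_axis` restricts the sphericity test to the imaging
plane. Summary statistics are mean ± SEM with a 5 nm histogram; a
single accepted vesicle reports SEM 0 (undefined).

## Gap detection and vicinity statistics

A gap is a discontinuity of the reforming NE. Per z-slice, the NE's
in-plane trace is projected onto x; runs of membrane-free columns
strictly inside the NE's x support are candidate discontinuities, kept
when the edge separation is at most `max_edge_separation` (default
140 nm, read as the maximum x-separation at which two NE edges still
count as "converging"; an alternative reading as a z-extent cap is
selectable). Runs overlapping in x on consecutive slices merge into one
gap; dx is the minimum per-slice separation, dz the merged slice count
times the z pitch, and the vertical area is exactly dx·dz — no rounding
occurs before classification.

The three observed size classes (small 5,800–9,900; medium
11,000–82,000; large 100,000–350,000 nm²) leave dead zones between
their printed limits. Default classification closes them at the
midpoints (10,450 and 91,000 nm²), making the class a total, monotone
function of area; `strict=True` instead returns `unclassified` inside
the dead zones.

Vicinity fields are 1 µm-radius discs centred on gap endpoints or on
random NE control points (default 10, drawn reproducibly, pairwise
≥ 1 µm apart and by default ≥ 1 µm from any gap endpoint), subdivided
at 500 nm into a close disc and a far annulus. Counts use 3D Euclidean
distances from the centre (`projected_2d` reproduces strict
per-micrograph counting); densities are per area, in vesicles/µm².
Group comparisons of the densities use one-way ANOVA with Tukey HSD.

## Rim-curvature protocol

Per pore: a cubic clip (half-extent 120 nm by default) is cropped,
binned onto a ~3 nm working grid and windowed to 8 bit. The in-plane
orientation of the membrane is estimated from the principal axes of
below-Otsu voxels (the thin axis of a planar cloud is its normal) and
removed by a rotation about z, leaving the residual envelope tilt about
x. A planarity guard (thin/middle axis ratio ≤ 0.5) rejects clips
without a planar dark structure.

The en-face view is then searched on a 10° grid over [0°, 180°) of
rotations about x. The original protocol's by-eye judgement —
"rotate until the pore appears as near to a circle as possible" — is
automated as isoperimetric circularity 4πA/P² of the pore lumen in a
thin central slab, with the lumen boundary extracted at sub-pixel
precision as the Otsu-level iso-contour and scored as a polygon
(shoelace area, polyline perimeter). Two numerical details matter
here. First, a thin slab is far more discriminative than a thick
projection: off-angle, the slab cuts the rim obliquely and the dark
annulus opens or elongates, while a thick minimum-projection stays
deceptively circular tens of degrees from en face. Second, the view at
the true angle is grid-aligned and therefore crisply aliased, whereas
neighbouring angles are smoothed by interpolation; a small Gaussian
(1 px) before contouring equalises this, otherwise the true angle
systematically under-scores its neighbours. Scores within 10⁻⁴ are
treated as ties and break toward the smaller angle. The circularity
response is intrinsically flat within roughly ±10° of en face at small
tilts (oblique-cut outward shift of the lumen edge cancels the
projective foreshortening), which is harmless downstream: a residual
misalignment of θ biases the rim diameter only by 1/cos θ ≈ 1.5% at
10°. A finer local re-scan below the grid step is available
(`refine_step_deg`) but off by default, keeping the 10°-grid protocol.

From the best angle the clip is rotated back by 90° about x so the
pore axis lies in the viewing plane. The slice with the widest enclosed
lumen is located by classifying columns as membrane-free within a
±25 nm band around the midplane; bounding the lumen by membrane-free
columns (rather than by any dark pixel on the midplane row) keeps the
adjacent rim-junction blobs, not the torus outer equator further out,
as the pore edge. On that slice the two membrane centre-lines are
traced per column as sub-pixel (parabolic) intensity minima above and
below the midplane; their separation d(s) is followed outward from the
pore axis on each side. The rim diameter is read where d(s) has "just
become parallel": the first window of `parallel_window` (15 nm) whose
least-squares slope |dd/ds| falls below `parallel_tol` (0.05); a
regression slope is used rather than per-step differences, which pixel
noise would dominate. The pore diameter is the distance between the
sub-pixel junction minima bounding the lumen at the midplane
(midline-to-midline, consistent with the rim convention). Curvature is
κ = 2/RD per side; both sides (i, ii) enter downstream statistics as
separate data points by default (per-pore averaging is available, as
the original protocol does not state which was used).

Section shrinkage from beam exposure (~30% in z, 2–8% in-plane) is not
corrected numerically. Following the protocol, Pearson correlations of
the en-face angle against rim and pore diameter serve as the QC gate
for orientation-dependent bias.

## Statistics

Group comparisons pass a normality gate: Shapiro–Wilk per group at
α = 0.05; any rejection routes to Kruskal–Wallis with Dunn's pairwise
z-tests (summaries median ± IQR/2, type-7 linear-interpolation
quartiles), otherwise one-way ANOVA with Tukey HSD (mean ± SD). Dunn's
multiplicity adjustment is Holm by default (Bonferroni and none
selectable) and is recorded in every output, as the convention is not
standardised. Dunn's statistic is implemented directly (mean pooled
ranks, tie-corrected variance); for two groups it reduces exactly to
the Kruskal–Wallis χ²₁ p-value, which the tests use as an independent
cross-check. Sarle's bimodality coefficient is attached to each group
as a descriptive multimodality cue only — no inferential claim. Stars
map p as * ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001, **** ≤ 0.0001.

## Phantom generator

Telophase scenes render an NE double membrane (dark bands of 7 nm,
a typical stained bilayer; midline separation 40 nm away from pores —
both configurable, as neither is printed in the source data) as a
gently waved sheet (amplitude 15 nm, wavelength 2 µm; real post-fixation
membranes are more tortuous), carve rectangular gaps of specified
dx × dz, and place spherical vesicle shells with truncated-normal
diameters at 100–1,000 nm from the sheet, rejecting overlaps with a
one-voxel-diagonal margin so rasterised shells never touch. Labels mark
membrane voxels (NE) and shell voxels (vesicle); vesicle interiors stay
background-bright, as in stained EM.

Pore phantoms model the rim as a half-torus joining the two membrane
midline planes: tube diameter = rim diameter RD (the midline-to-midline
distance where the membranes become parallel, making ground-truth RD
well defined), centre-circle radius = pore radius + RD/2, so the
lumen-edge (junction) distance equals the ground-truth pore diameter.
The envelope is rotated by tilt (about x) and azimuth (about z) before
rasterisation on coordinates centred on the array centre — the same
pivot the measurement rotations use. Rendering is binary membrane/
background followed by Gaussian blur (σ 1.5 nm) and i.i.d. Gaussian
noise (sd 0.1 of the unit membrane–background contrast); there is no
missing wedge or anisotropic PSF, so phantom recovery demonstrates the
geometry and numerics of the pipeline, not robustness to reconstruction
artefacts. Rims narrower than one voxel are rendered but flagged
sub-resolution. Fixed seeds give byte-identical volumes.

## Problem sizes and reproduction

The recovery studies run at desk scale: vesicle scenes with 500 (and
30) vesicles at 4.5 nm voxels; pore cohorts of 40 phantoms per
condition (per-group n is not reported in the source system; 40 is an
arbitrary fixed choice), rendered at 1.5 nm pitch in ~240 nm cubes and
binned by 2 onto the 3 nm working grid, with tilts drawn uniformly up
to 40° and free azimuths. `scripts/acceptance.py` regenerates
everything from a single seed and reports the recovered vesicle means,
rim-curvature medians and the Dunn p-value for the two-cohort
comparison.

## Known limitations

- Gap detection assumes the NE sheet is transverse to x in each slice
  (the orientation the gap definition itself presumes); arbitrarily
  oriented envelopes would need a local-frame extension.
- The en-face search inherits the protocol's 10° grid; its flat
  response near the optimum means recorded angles at small true tilts
  scatter by ±10–15°, with negligible effect on rim diameters.
- Sub-pixel membrane minima are biased outward by ~1 nm at 26 nm
  separations (overlapping blurred profiles repel); this is visible as
  a ≤5% underestimate of κ in the worst case and is not corrected.
- Phantoms omit missing-wedge anisotropy, organelle clutter and
  membrane tortuosity beyond a gentle sinusoid; recovery results bound
  algorithmic error only.
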