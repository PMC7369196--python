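# Methods

`villistereo` quantifies segmented 3D label volumes of placental villous
microvessels of the kind produced by serial block-face scanning electron
microscopy (SBF SEM): stacks of a few hundred to a few thousand slices,
25–100 nm apart, with in-plane pixels of a few to a few tens of nanometres,
in which the lumen, individual endothelial cells, pericytes, stroma,
syncytiotrophoblast and intervillous space have been labelled.  The package
does not segment; it consumes label volumes (or annotation tables) and
measures them.  Because estimators of this kind are easy to get subtly
wrong at voxel resolution, every estimator here is validated by parameter
recovery on a synthetic phantom whose ground truth is known by
construction, with brute-force enumeration as the oracle wherever one
exists.

## Pericyte coverage by line-intercept stereology

The quantity of interest is the fraction of the capillary abluminal (basal)
surface covered by pericytes.  The estimator samples every
`slice_stride`-th slice (default 50) with a randomly offset grid of
`n_lines` equally spaced horizontal lines (default 4).  Walking each line
left to right, every transition between wall tissue (an endothelial cell,
or a protrusion enclosed within one) and an abluminal voxel — anything that
is neither wall nor lumen — is one capillary intersect; it is a pericyte
intersect when the first voxel on the abluminal side is pericyte.  The
estimate is the pooled ratio of pericyte to capillary intersects, with the
cumulative (running) ratio recorded per sampled slice as the usual
sampling-adequacy diagnostic.

Rules the source data do not fix, resolved here and exposed as options:

- **Intersect definition.** An intercept is a label transition along the
  line; tangential grazes count once per entry and once per exit.  This is
  the standard intercept-counting convention and is the only definition
  that makes the row-offset randomisation exactly uniform over boundary
  faces.
- **Pericyte attribution** uses only the single abluminal neighbour voxel
  at the crossing.  A pericyte one voxel away across a thin
  basement-membrane gap does not count by default;
  `abluminal_gap_voxels=1` enables that tolerance for sensitivity
  analysis.
- **One offset per sampled slice** rather than one for the whole stack;
  per-slice offsets reduce variance at no cost in bias.
- An undefined ratio (no capillary intersect sampled) propagates as
  missing, never as zero.

The ground-truth counterpart, `true_surface_coverage`, enumerates every
voxel face between wall and abluminal tissue and reports the pericyte-
covered fraction exhaustively.  Faces on the stack boundary are surface
truncated by the field of view and are excluded by both the oracle and the
estimator (a horizontal line cannot cross them), keeping the two measures
of "surface" identical.

## The synthetic phantom

The generator emulates the segmented stacks the estimators were designed
for.  A lumen tube of configurable per-slice radius runs the length of the
stack, wrapped by a closed endothelial ring of fixed wall thickness,
embedded in stroma inside a syncytiotrophoblast shell, with intervillous
space outside.  The default configuration is a 256 × 256 × 400 voxel stack
at (50, 25, 25) nm spacing — seconds-scale to generate while inside the
realistic acquisition envelope — carrying a 5.0 μm diameter capillary lined
by five endothelial cells with 15% pericyte coverage.

- **Endothelial cells** are angular sectors whose boundary (junction) lines
  wander sinusoidally along the vessel with amplitude at most 20% of the
  cell's angular width, giving longitudinally aligned cells with
  slice-to-slice junction movement.  An optional per-slice cell-count
  schedule changes the number of sectors in blocks, which is how the
  paired-vessel study phantoms realise non-integer mean cell counts.
- **Pericytes** are longitudinal, gently helical processes on the abluminal
  shell: `n_pericyte_processes` angular paths (default 8) at stratified
  starting angles twist by `pericyte_twist_rad` (default π) over the stack.
  All processes share one arc half-width, chosen as the quantile of the
  per-face arc distances at the target fraction, so the realised covered
  face fraction equals the target up to face-count granularity (and to
  within 0.01 by contract, else the truth record is flagged).  Modelling
  pericyte processes as longitudinal wrapping bands matches their anatomy
  on capillaries and makes the per-slice coverage stationary along the
  vessel — which is what a running-mean adequacy check presumes, and what
  compact isolated patches would violate at desk-scale stack lengths.
- **Interendothelial protrusions (IEPs)** are carved as capsules of
  requested length and width, rooted mid-wall on a junction line, running
  mostly axially with a slight tangential tilt (slope 0.15) into the
  neighbouring (acceptor) cell; the base is nudged half a width into the
  acceptor and the axis is pre-compensated for the radial drift of a
  straight chord in a curved wall.  Requests that cannot be realised (too
  long for the axial extent, or not fitting the wall) are rejected with the
  offending spec index.  The truth records realised, not requested,
  quantities: base/tip voxels, chord length, class.
- **Determinism.** One root seed is split into named sub-streams per
  feature (junction layout, pericyte placement), so identical
  configurations are bit-identical and adding protrusions does not perturb
  pericyte placement.

What the phantom does *not* emulate: electron-contrast greyscale, noise,
cutting artefacts and drift, syncytiotrophoblast microvilli, stromal cell
types beyond pericytes, non-circular lumina, and branching vessels.
Recovery on phantoms therefore demonstrates that the estimators measure
what they claim on clean geometry at realistic voxel anisotropy; it cannot
certify segmentation quality or biological variability of real stacks.

## Protrusion morphometry and density

Protrusions enter as per-structure records — tip and base voxel
coordinates plus width — from an annotation CSV (the machine form of a
manual marking workflow, with duplicate ids rejected) or from phantom
truth.  Length is the straight tip-to-base chord after scaling each axis by
its spacing; this deliberately underestimates curved protrusions.  Width is
measured from the label volume: voxels are projected onto the base→tip
axis (given, or estimated as the principal axis oriented so the donor-cell
contact is the base), positions within `neck_exclusion_nm` of the base
(default 100 nm, about the narrowest credible process) are excluded, and
the maximum perpendicular cross-section extent is returned, with the mean
in-plane spacing added to the centre-to-centre distance so a single-voxel
cross-section reports one pixel.

Protrusions are classified against wide-and-shallow complex-junction
regions by their length:width ratio with an inclusive threshold of 4.0 —
observed protrusion ratios start near 4.2 while typical complex-junction
regions sit near 2.4, so the boundary separates the two populations with
margin; it is exposed as an option.

Density is `n / V × 10^21` per cm³ of terminal villous tissue, where `V`
(nm³) is the non-intervillous-space voxel volume on phantoms and must be
supplied explicitly for annotation-only input.  The adjusted density
multiplies by `(1 − f_ivs) · f_tv`, the intervillous-space fraction of
placental volume and the terminal-villus fraction of villous volume.
Defaults are 0.35 and 0.39 (the values of the worked estimate this module
reproduces); the slightly different literature values 0.34 and 0.387 are
provided as constants, and both choices round to the same whole-million
figure.  Summaries report medians and (min, max) ranges; the per-placenta
summary takes per-placenta medians first and then the median of those
medians, which differs from the pooled median under unequal
representation.

## Cross-section profiles

Junctions per profile are counted as distinct endothelial cell ids in the
ring of wall voxels around the lumen; for a closed ring of k ≥ 2 cells
this equals the number of junction seams.  A single-cell ring reports 1
(its longitudinal seam, if any, is invisible to ids; real rings observed
have ≥ 2 cells).  A lumen touching a non-wall label or the image border
means the ring is not closed and the profile is not counted.

Diameter is the maximum Feret (caliper) extent of the outer abluminal
boundary in physical units, computed over convex-hull vertices with the
mean in-plane pixel added for voxel extent (a lumen-based variant exists).
Profiles strictly wider than 11 μm are classed as dilated; exactly 11 μm
is non-dilated, the threshold being configurable.

The full-profile guard excludes: the first and last slices (no
above/below context), slices whose lumen lacks an overlapping counterpart
in either neighbour, slices where the vessel touches the lateral image
border, and slices on a monotone run of lumen areas vanishing to zero
while below half the vessel's median positive area — the signature of the
edge taken off one side of a vessel rather than a true cross-section.

Vessel series (arteriole/venule) sample every 25th slice by default and
report mean ± sample SD of diameter and junction count with the
observation count.  Vessel identity is by label semantics; the convention
that the smaller vessel of a pair is the arteriole (higher resistance) and
the larger the venule is recorded by the caller, not inferred.

## Statistics

Group comparisons use the classical pooled-variance two-sample Student's
t-test (df = n₁ + n₂ − 2, two-sided); a Welch option exists.  Zero pooled
variance degenerates explicitly: equal means give t = 0, p = 1; unequal
means are flagged as significant beyond machine precision rather than
fabricating a finite statistic.  Spearman's rho uses average ranks for
ties and the t-approximation for its two-sided p, adequate at n of a few
dozen; an exact permutation p is available for n ≤ 10.  Means are
reported with sample (n − 1) SDs.  No multiple-testing correction is
applied, and capillary profiles from one placenta are treated as
independent observations — a simplification the report does not hide.

## Problem sizes and numerical choices

Recovery studies run at: the default 256 × 256 × 400 capillary phantom
(coverage, 50 grid seeds); a three-protrusion phantom spanning the
observed length/width range (0.2–5.2 μm / 0.15–0.50 μm); paired 540-slice
vessel phantoms at intermediate-villus magnification (50 nm pixels, 100 nm
slices — coarser than capillary stacks, as intermediate-villus stacks
are), whose diameters and cell counts alternate in 25-slice blocks around
means of 22.0 μm/10 cells and 11.7 μm/7.5 cells so that every-25th-slice
sampling recovers the construction means exactly with n = 22 per vessel;
and a 300-slice capillary whose cell count grows with its calibre for the
rank-correlation sign check.  Length/width recovery tolerances are one
voxel diagonal; diameter tolerances one pixel; the coverage recovery
tolerance is 0.02 absolute with an unbiasedness check at two standard
errors of the 50-seed mean.

Labels are 16-bit unsigned; stacks round-trip byte-exactly through
uncompressed multipage TIFF plus a JSON sidecar carrying spacing,
semantics and provenance (a stack without a sidecar is an error, never a
guessed default).  Coordinates are 0-based (z, y, x) voxel indices
throughout, converted to physical units only at measurement boundaries.

## Known limitations

Straight-chord protrusion lengths underestimate curved structures; no
geodesic alternative is offered.  Automated protrusion detection from
greyscale is out of scope.  The junction count conflates seams with
distinct ids for non-closed rings, which the full-profile rule excludes
rather than resolves.  Phantom vessels are circular tubes; estimator
performance on strongly non-convex real profiles is exercised only through
the Feret brute-force equivalence tests, not through realistic shape
models.  Placenta-level clustering is not modelled in the statistics.
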