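# Methods

`trichrome` implements the computational side of trichromatic serial
two-photon imaging: simultaneous excitation of three spectrally distinct
fluorescent proteins over whole mounted brains, acquired tile by tile and
section by section.  The toolkit covers five analyses — mosaic
preprocessing, linear spectral unmixing, chromatic-shift metrology,
multiplexed projection mapping, and astrocyte morphometry — together with a
synthetic phantom generator that supplies ground-truthed inputs for all of
them.  This note records the models, the defaults and why, the numerical
choices, and what the synthetic closures do and do not demonstrate.

## Linear unmixing

Measured channel intensities are modelled as a unit-diagonal linear mixture
of the true ("corrected") intensities:

```
R_raw = R_corr + a_GR·G_corr + a_BR·B_corr
G_raw = a_RG·R_corr + G_corr + a_BG·B_corr
B_raw = a_RB·R_corr + a_GB·G_corr + B_corr
```

`a_XY` is the dimensionless leak of fluorophore X into detection channel Y.
Unmixing solves this 3×3 system per pixel.  The coefficients are estimated
from reference ROIs: the ROI of maximal intensity per channel (suitable for
stochastic combinatorial labels, where some cells express a single protein
at high level) or the per-tracer barycentres of the ROI cloud (suitable for
viral tracers with unimodal colour distributions).  Anchors are normalised
to unit sum — projected onto the ternary diagram — before the matrix is
assembled, which makes estimation invariant to exposure differences between
anchors; the same projection defines the "stretch" of the measured colours
onto the full diagram.  Two conventions in the model are configurable:

* the B→G leak term is treated as a standard off-diagonal coefficient; a
  variant in which the green equation's third term multiplies G instead of
  B is available via `MixingModel(literal_green_equation=True)`;
* negative corrected intensities (a noise artifact) are clipped at zero by
  default; `negatives="keep"` preserves exact linearity.

Limits of the max-ROI anchor rule: it assumes each channel's brightest ROI
is dominated by that channel's fluorophore.  If per-channel exposures differ
by more than roughly one minus the largest coefficient, two channels can
elect the same ROI and the anchor system degenerates; the estimator then
raises rather than returning a bogus model.

Colorimetric outputs: ternary coordinates (channel over channel-sum,
scale-invariant), hue/saturation (standard HSV), and a colour-mode count by
single-linkage agglomeration at a caller-chosen radius in the ternary plane.

## Tile preprocessing and stitching

Tiles are cropped by a fixed margin to remove scan-turnaround artifacts.
The illumination profile of each channel is estimated by averaging all
tiles and Gaussian-blurring with a large kernel; the blur sigma defaults to
one eighth of the tile width — large against cell-scale structure, small
against the vignetting scale.  The blur uses edge replication
(`mode="nearest"`): reflected or zero padding bends the smoothed field at
the tile border, exactly where vignetting is strongest, and measurably
degrades the estimate.  Profiles are normalised to a maximum of one and
divided out (flat-field correction).

Tile placement is translation-only.  Pairwise offsets between grid
neighbours are refined by exhaustive normalised cross-correlation over an
integer window (default ±10 px) around the nominal offset.  Candidate
offsets whose overlap is thinner than 8 px along any axis are skipped: a
few-pixel sliver of two vignette-corrected background edges can correlate
perfectly by accident and hijack the placement.  Pairs scoring below 0.3
fall back to the nominal offset.  Global positions accumulate along a
maximum-correlation spanning tree rooted at the first tile; mosaics are
composited with overwrite, max, or feather (linear cross-fade) blending.
Sub-pixel registration is deliberately not attempted.  A known failure mode,
retained on purpose: long straight sparse filaments are
translation-ambiguous along their own axis, and correlation registration
cannot resolve them — the synthetic tests use curvy, dense content for this
reason, as does any real tissue.

## Chromatic-shift metrology

Dual-beam excitation requires both foci to coincide in 3D.
Second-harmonic-generating nanocrystals localise both beams at once; the
displacement (ΔX, ΔY, ΔZ) of the second focus relative to the first, as a
function of field position, is fitted with an affine model per lateral
component and a polynomial in the radial coordinate ρ = √(x²+y²) for the
axial component.  The axial polynomial degree defaults to 2 (field
curvature is quadratic to leading order) and is configurable; odd terms are
permitted since the underlying symmetry is not guaranteed by alignment.
The lateral shift magnitude √(ΔX²+ΔY²) is mapped over the field of view,
and a quality report flags whether it stays below 0.6 µm over a 350 µm
effective sub-field — the level at which colour ratios of submicron
structures remain trustworthy.  Standard errors come from the residual-based
least-squares covariance; an optional single pass drops beads with residuals
above 3× RMS (mislocalisations) and refits.

## Projection mapping

Per channel, after unmixing: square-root transform, then monotone
histogram matching to a reference section (quantile mapping; rank order is
preserved, and matching a section to its own histogram is the identity up
to binning).  Signal is separated from background by multi-Otsu
thresholding with connected-component filtering.  The multi-Otsu search is
implemented in-package as an exact float64 dynamic program over class
boundaries: the global maximiser of between-class variance is found over
all ways of cutting the histogram into contiguous non-empty classes, with
ties resolved to the lowest cuts.  (A widely used library implementation
accumulates class moments in float32 and returns a threshold one bin off
the true optimum on a few percent of random histograms, which the exactness
tests here do not tolerate.)  Defaults: 3 intensity classes with the top
class as signal — background / neuropil / axon trimodality is the common
case — and removal of 8-connected components under 4 px, which deletes
speckle while preserving thin diagonal axons.

Each channel's mask is made colour-exclusive by removing pixels detected
in any other channel.  Projection strength is the signal-pixel fraction per
non-overlapping super-pixel (30×30 px, 24×24 µm at 0.8 µm pixels; edge
blocks are normalised by their actual area).  The denominator is the block
area, keeping strengths in [0, 1]; a literal signal-to-nonsignal ratio
would be unbounded.  Confidence maps record exclusive over total signal per
super-pixel — 1 where channels never overlap — with signal-free blocks
flagged as no-data rather than zero.  The three strength maps merge into an
interdigitation map whose super-pixels are classified by normalising the
triple to relative contributions and taking the nearest of seven reference
points — [1 0 0], [0 1 0], [0 0 1], [0.5 0.5 0], [0 0.5 0.5], [0.5 0 0.5],
[0.33 0.33 0.33] — i.e. single, dual, and triple projection categories,
with deterministic tie-breaking in a fixed class order.  Region proportions
are computed over in-region, non-empty super-pixels.

When channels co-locate heavily at the pixel level (dense fiber tracts,
or phantoms generated with a high overlap fraction), exclusion discards
exactly the shared evidence and biases the strength maps — this is the
condition the confidence map flags, and the analysis should then run with
`exclusive=False`, which the pipeline exposes as a flag.  The closure tests
follow this rule: composition recovery under heavy overlap uses the
non-exclusive variant, while the exclusive path is validated on disjoint
populations and by its conservation properties (pairwise disjoint masks,
per-super-pixel exclusive strengths summing to at most 1).

## Astrocyte interface geometry

For a pair of somata A1, A2 the Voronoi axis is the unit vector A1→A2 and
the Voronoi plane passes through the segment midpoint perpendicular to the
axis — the interface expected of an equiparted tiling.  Two parameters
summarise a segmented interface point cloud:

* **bias** — percentage of points on the A2 side of the Voronoi plane
  ("above" is the A2 side, consistent with the axis orientation; any
  consistent convention satisfies the mirror symmetry bias ↔ 100 − bias
  under soma exchange).  Points exactly on the plane count half, which
  keeps the estimate unbiased under mirror symmetry.
* **orientation** — the angle between the fitted interface plane and the
  Voronoi plane, folded into [0°, 90°].

The degree-1 interface plane is fitted by orthogonal least squares
(principal components of the cloud) rather than by regressing the axial
offset on the in-plane coordinates: under isotropic point noise the graph
regression suffers errors-in-variables attenuation that biases steep tilts
by close to a degree at 60°, while the orthogonal fit is unbiased.  Higher
polynomial degrees, where requested, use the graph regression, and a
design-rank check rejects clouds that do not span two in-plane directions.

Residual relief is modelled in the interface frame by a biharmonic
(thin-plate spline) interpolant with zero smoothing, which reproduces every
input point exactly; amplitude maps sample the interpolant on a regular
grid over the footprint — the convex hull of the in-plane points, standing
in for the manual delimitation done on real data, overridable by a mask —
and gradient maps hold the slope magnitude from central differences.

## Morphometry

Colour clusters are connected components of the contact graph restricted to
same-colour edges (different-colour contacts cannot belong to one clone and
are ignored with a log message); isolated astrocytes are clusters of size 1.
The contacts-per-astrocyte ratio divides a cluster's contacted-cell count
by its member count.  Layer summaries include only clusters of size ≤ 3
contained entirely within one identified layer — larger clusters straddle
layers too often to be attributable — and report n, mean, s.d. (0 with a
flag for single observations), and median.  Soma positions, colour ids,
contact counts, layer labels and domain volumes enter as CSV tables; on
real data these are manual annotations, and no algorithm is provided to
produce them.  Inferential statistics across layers are intentionally out
of scope; any statistics package can consume the summary tables.

## Synthetic phantoms

The generator emulates the image-level statistics each analysis consumes;
it does not simulate optics (no PSF, no label-free contrasts).

* **Projection phantom** — three populations of smoothed random-walk tubes
  (default curvature 0.1 rad/step, radius 3 px, ~0.7× the image side long)
  rendered at constant amplitude.  Flat-top tubes, not Gaussian profiles,
  so that per-pixel membership is exact and noiseless closures are
  bit-exact.  At overlap fraction 0 the populations live in disjoint
  vertical strips; at fraction f, s = 6nf/(1+f) tube pairs are duplicated
  across two populations at one tube-radius offset, making the expected
  fraction of co-located signal pixels equal f (one-radius offsets keep
  each channel's exclusive crescent a full radius wide, robust to pixel
  quantisation; incidental crossings add a few percent).  Ground truth
  records per-pixel membership and per-super-pixel composition.
* **Territory phantom** — nearest-seed (Voronoi) partition of a volume,
  each territory filled with one of n colour combinations from a
  {0, 0.5, 1}³ palette; contacted cell bodies are dark spheres carved out
  at Poisson-distributed counts per territory (mean 12.8 by default, the
  density scale of contacted cells around cortical protoplasmic
  astrocytes).
* **Detector model** — forward mixing followed by Poisson noise on
  gain-scaled intensities plus Gaussian read noise, clipped at zero; gain 0
  disables shot noise so exactly noise-free forward mixes exist.
* **Bead fields** — uniform positions over a centred square field, shifts
  from a known affine+polynomial model plus isotropic localisation noise.
* **Tiling** — grid cut at pitch `tile·(1−overlap)` with the last
  row/column clamped flush to the image edge, each tile multiplied by a
  centred Gaussian illumination profile normalised to 1.
* **Interfaces** — somata 40 µm apart; a disc of points (default radius
  20 µm, n = 500) on a plane at a known offset and tilt, isotropic noise
  (default 0.5 µm), optionally moved by a random rigid motion to avoid
  axis-aligned special cases.  The 20 µm footprint makes the orientation
  standard error ≈ σ/(√n·R/2) ≈ 0.13°, so half-degree recovery holds with
  margin.
* **Colour combinations** — modes on the coarsest simplex lattice holding
  the requested count (minimum separation √2/resolution), sampled with
  Gaussian noise and renormalised.

What passing the closures shows: the algebra, the estimators, and the
bookkeeping are correct, and the pipeline is exact in the noise regimes it
claims.  What it does not show: performance on real tissue, where
background is structured, axon intensity spans decades, segmentation truth
is undefined at the resolution limit, and interfaces are segmented by hand.
The phantom's labelling density, noise levels, and geometry are plausible
but not calibrated to any dataset.

## Problem sizes in the test suite

The default suite and the acceptance script run phantoms at 1800×1800 px
(the projection and mosaic closures), 200-interface and 200-seed Monte
Carlo batches, and 64-bin histogram oracles — sizes at which every oracle
(exhaustive threshold search, brute-force component search, half-space
counts) is itself fast and exact, and the whole run completes in well under
a minute.
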