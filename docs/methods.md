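# Methods

This note documents the models, numerical choices and limitations of
`ffaleak` at the level a maintainer or reviewer needs to interpret its
output.  Units: pixel intensities are arbitrary fluorescence units (a.u.);
lengths are pixels; times are minutes post injection.

## Image model and assumptions

A frame is a nonnegative single-channel intensity grid with a roughly
circular illuminated field of view (ROI) on a dark surround.  Three signal
components are assumed: bright tubular vessels (high contrast, widths of a
few to ~10 px at 512×512), diffuse leakage (smooth, amorphous, no sharp
boundary, growing in amplitude and extent over minutes), and a roughly
constant background.  Inter-timepoint motion is modeled as rigid
(rotation + translation); fluorescein dose and camera gain may differ
between frames, which is why registration uses normalized cross-correlation
and quantification uses within-sequence relative values.

## Vessel removal

*Small vessels* are removed by the minimum over 8 oriented grayscale
openings with line elements of `l_sv` pixels.  The element must exceed the
*visible* width of the thickest vessel to be removed: for a soft
(Gaussian-profile) vessel the perpendicular opening leaves the profile's
value at the element end, so `l_sv` of roughly twice the FWHM is needed.
Default `l_sv = 21` for 512×512 frames (thickest phantom vessel FWHM 8 px);
scale linearly with frame width.  "Length" of a line element counts pixels
along the rasterized line (a 45° element of length 7 has 7 diagonal
pixels).  All morphology uses reflective (symmetric) border extension so
erosion does not drag the dark frame into the ROI; openings are computed on
a symmetrically padded copy and cropped, making the result exactly the
opening of the reflectively extended image (this is also what the
brute-force oracle in the tests computes, enabling bit-exact comparison).

*Large vessels* are detected on the original image by the maximum over
orientations of the opening residue (along minus perpendicular, `l_lv = 31`
px).  The angle set (multiples of π/8) is closed under perpendicularity, so
the maximum is provably nonnegative.  The residue is near zero on isotropic
structures; off-center on a smooth blob a small tangential-vs-radial
asymmetry survives (≲10 % of the blob peak for blobs 4× wider than the
element) — far below the ~90 % response on a matched bar, which is the
contrast the hysteresis step relies on.

The residue image is evened out with the quadrature vesselness filter
(below) and hysteresis-thresholded at quantiles (default q85/q97) of the
within-ROI vesselness values.  Quantile thresholds transfer across exposure
levels; q85 sits just above the background bulk of the vesselness
distribution when vessels occupy ≲10 % of the ROI.  Sensitivity is
one-sided: raising the thresholds a few points changes the mask little
(Jaccard ≥ 0.8 in the tests), while dropping the low threshold into the
background bulk lets noise clusters percolate into retained components.

Masked vessel pixels of the small-vessel-removed image are replaced by a
local background estimate — the grayscale opening with a disk of diameter
`l_lv` — so infilled values never exceed the surrounding leakage level and
the downstream mean-intensity readout is not biased toward zero.  Before
removal the pipeline closes the mask with a disk of radius 12 and dilates
by 2: the junction blob where the primary vessels converge at the optic
disk is isotropic and invisible to the directional residue, and closing
bridges it so the infill can replace it.  The raw (unclosed) mask feeds the
reference-point detector, whose skeleton benefits from the thinner mask.

## Log-Gabor quadrature vesselness

Frequency-domain filters: radial profile exp(−ln²(f/w₀)/(2·s²)) with s set
for a 2-octave FWHM bandwidth (s = ln 2 / √(2 ln 2) ≈ 0.589, i.e.
k/w₀ ≈ 0.555), zero gain at DC by construction; angular profile a Gaussian
in angular distance to the filter orientation with σ_θ = π/8, giving a
near-uniform folded orientation coverage (CoV < 0.2 across angles at fixed
radius).  Filters are single-lobed in the frequency plane, so each response
is a complex quadrature (analytic) signal.  Center frequencies are dyadic,
w₀ = 2⁻ˢ cycles/px; `enhance` uses scales s = 1..n_s (default n_s = 2).
Images are reflect-padded to the next power of two and cropped after the
inverse transform.

For the *large-vessel* mask the bank starts at s = 3 (center periods 8 and
16 px): the s = 1, 2 filters respond mostly to pixel noise and barely to
8-px-wide vessels, which in practice destroyed the residue image's
excellent vessel/background separation.  This is the same dyadic family,
starting coarser (`s_start` parameter).

Scale combination P = Σ qₙ|qₙ|³/Σ|qₙ|³ is defined as 0 where the
denominator vanishes (all responses zero ⇒ vesselness must be 0, not NaN).
The regularized map LP = Re{P|P|/(|P|²+σ²)} is bounded by 1 in magnitude;
σ = 3 by default, and any σ > 1 gives nearly identical maps (Pearson
r > 0.95 on phantoms), so σ is not a sensitive tuning knob.

## Chan–Vese segmentation

The two-phase piecewise-constant energy is
E = μ·|boundary| + λ₁·Σ_fg (v−c₁)² + λ₂·Σ_bg (v−c₂)², with the boundary
length discretized as the count of 4-neighbor label disagreements
(μ = 0.2, λ₁ = λ₂ = 1 by default; the output is invariant to affine
intensity rescaling v → a·v + b when μ is scaled by a²).  It is minimized
by exact alternating coordinate descent: closed-form mean updates and
checkerboard label sweeps (each half-sweep updates a set of mutually
non-adjacent pixels to their locally optimal label, ties keeping the
current label).  Every step is an exact coordinate minimization, so the
energy sequence is non-increasing by construction — the level-set solver of
the original formulation does not guarantee this discretely, which is why
the descent scheme was chosen; the energy, not the solver, defines the
output, and the tests cross-check against scikit-image's level-set solver
on disk fixtures.  Initialization is deterministic (hysteresis mask at the
default quantiles, Otsu fallback if trivial); iteration stops when fewer
than 10⁻⁴ of pixels change label or after 200 sweeps.  Constant input is a
defined error; `segment_vessels` converts it into an empty mask with a
warning (a blank ROI has no vessels).

## Reference point

Skeletonization uses topology-preserving thinning.  Graph rules: skeleton
pixels with ≥ 3 neighbors are bifurcations (8-adjacent bifurcation pixels
merge into one node at their centroid, since thinning emits 2×2 junction
blocks), exactly 1 neighbor are terminations; edges carry the ordered
medial-axis pixel chain.  A node-free cycle becomes a self-edge anchored at
its scan-order-first pixel.  Branch pruning deletes terminal edges with
chains shorter than T_b (default 20 px), re-thins, and repeats until stable
— re-thinning removes the bump pixels that branch deletion leaves at
ex-junction staircases, and deleting a terminal edge may legitimately
expose (and then remove) further short terminal segments.

Line voting: each chain pixel's direction is the principal axis
(total-least-squares, valid for vertical vessels) of the chain points
within Euclidean radius L₀ = 30 px; the full line through the window
centroid is rasterized across the frame, adding one vote per pixel (total
votes ≡ summed rasterized lengths, checked exactly).  The accumulator is
smoothed with a 2-px Gaussian before the argmax (raw vote maxima are
rasterization-sensitive); ties break by scan order.  Every chain pixel
votes (stride 1); a stride option exists for speed.

In the sequence pipeline, an outlier reference point is possible when
strong leakage edges contaminate a late frame's vessel mask; registration
therefore falls back to an identity-initialized run whenever the final
correlation is below 0.9, keeping the better-scoring transform
(deterministic).

## Registration

Rigid transform in (row, col) convention: f = R(angle)·(m − c) + c + t maps
moving-frame to fixed-frame points; the rotation center c is the fixed
frame's reference point (or the ROI centroid as fallback), which decouples
the angle and translation gradients.  The metric is normalized
cross-correlation over the fixed ROI mask; the optimizer is regular-step
gradient descent (learning rate 2, minimum step 10⁻⁴, ≤ 300 iterations,
relaxation 0.5) over two resolution levels (shrink 2/1, smoothing σ 1/0),
with full deterministic metric sampling, delegated to SimpleITK and
converted to the package convention at the boundary.  If the optimizer
ends below the initialization's correlation the initialization is returned,
so the final metric never falls below its starting value.  Registration
runs on raw frames (not vesselness maps); warping uses linear interpolation
for intensities and nearest-neighbor for the ROI, with out-of-source pixels
marked outside the ROI.  All later frames are registered to the first
timepoint (smallest leakage, least saturation), and quantification uses the
intersection of all registered ROIs so every timepoint covers the same
retinal area.

## Quantification

Otsu's threshold maximizes between-class variance over a 256-bin histogram
of the within-ROI leakage-image values; on the tie plateaus that arise in
empty inter-mode gaps the lowest maximizing bin is chosen, and the returned
threshold is that bin's upper edge (foreground = values ≥ T).  The
threshold is computed per frame independently (each frame's contrast
differs as dye accumulates).  Relative intensity subtracts the first
frame's in-ROI mean, making the series invariant to a shared constant
offset; a per-frame offset c_t shifts the series by c_t − c₀ — this is a
property of the readout, not removed.  Resampling is piecewise-linear onto
a 1-minute grid spanning the acquired range, with no extrapolation.  The
in-region intensity (sum inside the Otsu mask ÷ ROI area) is reported
alongside; the maskless relative intensity is the primary readout since it
needs no thresholding step.

## Synthetic phantoms: what they emulate, and what not

Defaults (the study conditions used by tests and the acceptance script):
512×512 frames, ROI radius 230 centered, optic-disk convergence point
offset (−35, +45) from center; 6 primary vessels of diameter 8 px
branching twice into children (×0.65 diameter, min 2 px), Gaussian
cross-sections with FWHM = diameter; heading noise 0.05 rad per 2-px step,
ramping from 0 at the disk to full at 0.3·ROI-radius (vessels leave the
disk radially and curve distally); background 25 a.u., vessel amplitude
130 a.u.; three raised-cosine leakage blobs with amplitudes 30→110 a.u.
and support radii 50→66 px over t = 1, 3, 5, 7, 9 min (visible leakage from
the first frame, occupying ~9–15 % of the ROI); rigid jitter ≤ 15 px /
≈ 3°; additive Gaussian noise σ = 3 a.u.  Raised-cosine blobs are smooth
(leakage has no sharp boundary) yet compactly supported, so a true support
mask exists for area-recovery tests.  Frame 0 is the canonical frame; each
later frame's stored truth transform maps its coordinates to frame-0
coordinates and is exactly what registration should recover.

Not emulated: choroidal background texture, vessel pulsation and focus
changes, saturation/blooming at late timepoints, capillary networks,
disease-specific structures, non-rigid distortion.  Passing the recovery
tests therefore shows the pipeline is internally consistent and recovers
known signals under the stated image model — not that it matches expert
annotations on real mouse data, which are not publicly available for this
protocol.

Synthetic annotators for the agreement analysis are morphological
perturbations of the true support: a conservative annotator tracing a
tight boundary (erosion by 0.5·R_t, near the half-intensity contour) and a
liberal one (erosion by 0.2·R_t, near the 10 %-intensity contour), each
with 1.5-px smooth boundary noise — modeling different intensity-cutoff
criteria as the source of inter-annotator differences.  The acceptance
check asks that the method's mean relative difference from each annotator
stay within 1.5× the annotator-vs-annotator difference.

## Problem sizes

The test suite runs phantoms at the full default 512×512 size: 10 seeds for
reference-point recovery, 10 two-frame sequences for registration recovery,
5 five-frame sequences plus one linear-amplitude phantom for end-to-end
quantification, and 1 sequence for the annotator analogue; oracle
comparisons use 64×64 random images.  The acceptance script uses 5 / 5 / 3
seeds for the same studies.  These sizes keep the full suite in the
single-digit minutes on one CPU while leaving every statistical margin
comfortable.

## Known limitations

* The rigid motion model cannot absorb non-rigid eye deformation.
* The directional residue misses isotropic vessel structures (junction
  blobs); the mask-closing step is a heuristic bridge with a fixed radius.
* Otsu's threshold degrades when leakage is very faint or occupies a tiny
  fraction of the ROI (first-timepoint regime); the relative-intensity
  readout does not share this weakness.
* Imaging artifacts or pathology that brightens non-leakage tissue would be
  counted as leakage; no artifact rejection is included.
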