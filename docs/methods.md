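# Methods

## Imaging model and coordinate conventions

A mirrored well plate places a 45° mirror in the well adjacent to each
specimen well, so one camera sees the specimen from above and, via the
mirror, from the side in the same frame. We model each view as a thin lens
(f = 25.05 mm) at a nominal object distance of 240 mm with transverse
magnification m(d) = f/(d − f); at the ±7 mm focus extremes this gives the
magnification range 0.1129–0.1205 that the geometry module reproduces to
four decimals. The mirror adds optical path to the side view; its default
extra path (pitch + depth/2 = 15 mm) is a configurable parameter because the
true value depends on where in the mirrored well the specimen sits.

World frame: x is the horizontal axis both views share, y the top-view-only
horizontal axis (the side camera looks along −y), z the height above the
well bottom. Pixels are 0-based with centers on integer coordinates; image
rows increase downward and are negated so y and z increase in world
directions. The sensor pixel pitch is not published for this design, so it
is a config value whose default makes the 28.5 mm field of view span the
4208-pixel sensor axis at the nominal distance.

A point's object distance depends on its position: height z in the top view,
y in the side view. Rendering applies this height-dependent magnification
exactly, and `reconstruct_skeleton` inverts it by fixed-point iteration
(the coupling is O(mm/240 mm) per pass, so 12 iterations are far beyond
machine precision; noise-free render→reconstruct round trips agree to
< 1e−6 mm). The two estimates of the shared x axis are averaged; a
disagreement beyond a tolerance (default: five object pixels) sets a
per-landmark QC flag.

## Quality control

Three filters, with deliberately strict inequalities:

- frame level: all 8 landmark likelihoods must exceed 0.7 (a landmark at
  exactly 0.7 fails);
- video level: a video is excluded when the failing-frame fraction strictly
  exceeds 1/3 (exactly one third still passes — "over one third" read
  literally);
- bladder visibility: frames whose projected-to-3D body-length ratio falls
  strictly below 0.5 in either view are excluded from bladder reconstruction
  only — kinematics keeps them, since the eye midpoint remains trackable.

The body length is the polyline nostril → eye midpoint → swim bladder →
tail 1–4 (the head-to-tail-tip alternative is available behind a `method`
switch). QC-dropped frames break the displacement chain rather than
bridging it; bridging would divide a multi-frame excursion by a single
frame interval and inflate speed.

## Kinematics

The reference point is the midpoint of the two eyes — the head is the only
rigid part of the body. Displacement is the Euclidean distance between
consecutive reference points; speed multiplies by the frame rate;
acceleration is the signed forward difference of speed (scalar, per the
definition of speed as a magnitude); total distance sums displacements.
2D mode drops z before the norm, exactly what a top-view tracker measures,
so per-frame 2D displacement ≤ 3D displacement holds identically (the
projection inequality, asserted on 1,000 random tracks). A movement bout
is a maximal run of ≥ 2 consecutive frames with speed > 2 mm/s; both
numbers are free parameters (no published bout definition exists for this
pipeline) and are exposed as arguments. The tail angle is measured at the
nostril between the forward vector (nostril → eye midpoint) and the
nostril → tail-tip vector; the 2D variant projects both vectors to x–y
first, which is what hides purely vertical tail bending from top-view-only
analysis.

## Swim-bladder reconstruction

Both silhouettes are fitted as ellipses (largest 8-connected component,
sub-pixel border following, direct least-squares conic fit) and expressed
as quadratic forms uᵀQᵀAQu = 1. The ellipsoid form is vᵀRᵀBRv = 1 with
R = Rx(φ)·Rz(ψ)·Ry(θ) — this specific matrix product is the one the
reconstruction defines and uses; the conventional Rx·Ry·Rz order is
available behind a flag. The orthographic silhouette of the ellipsoid
along axis k is the Schur complement M̃ = M_rr − M_rk M_kk⁻¹ M_kr of the
dropped axis (verified against a ray-fan sampling oracle that never forms
the complement). The fit minimizes the element-wise L1 error between the
two predicted silhouette forms and the two fitted ellipse forms over
(a, b, c, φ, ψ, θ). The objective is non-smooth, so Nelder–Mead is used
with a tolerance of 1e−10 and eight starts; restarts are warm-started by a
smooth Cholesky-parametrized least-squares pre-solve of the matching
problem.

**Identifiability.** The inverse ellipse forms are principal submatrices of
the inverse ellipsoid form W = M⁻¹, so two orthogonal silhouettes determine
every entry of W except W_yz — the coupling between the two axes never seen
together in one view. A one-parameter family of ellipsoids therefore
reproduces any consistent silhouette pair exactly, and the volume varies
along the family. The deterministic first start (and the returned solution
for consistent data) is the closed-form **maximum-volume member**
W_yz = W_xy·W_xz/W_xx: it is always feasible, coincides with the truth
whenever the bladder carries no tilt in the unobserved y–z plane, and is
the least-eccentric extrapolation of the unseen coupling. Near-ties between
starts resolve to this canonical member so silhouette noise cannot swap
family members between frames. The per-start objectives and volumes are
reported, and a multi-start volume spread above 2% raises an explicit
identifiability warning rather than silently returning one solution. For
larvae that keep a roughly upright posture (see the phantom's righting
dynamics) the unobserved tilt is small and phantom volumes are recovered
within a few percent.

Ellipse fits assume the nominal (focal-plane) pixel size, so the final
volume applies a height-based magnification factor
s = m(d_ref)/m(d(z)) cubed, with the focal-plane height as the reference
(the published procedure names no reference; the focal plane is the natural
zero of the correction). Both ellipses observe the same shared-axis extent
of the bladder; a relative mismatch above 10% raises a
`shared_extent_mismatch` warning while still returning the fit. Forms are
compared at raw scale (not determinant-normalized).

## Optics characterization

Refraction analysis uses the four-well equivalent model: two real wells and
their two mirror-image virtual counterparts, with the camera axis on the
2×2 block center. Chief rays are swept laterally in 0.1 mm steps out to the
farthest in-well point, √2·(pitch/2 + footprint/2) = 12.02 mm, giving a
maximum incidence of atan(12.02/240) = 2.87°. The apparent lateral shift of
a point behind flat layers is Σ tᵢ(tan θ − tan θᵢ′) with θᵢ′ from Snell's
law (water n = 1.33, plastic n = 1.5); the top view traverses the full
water depth (worst case, with a `target_depth` override), the side view a
default 1 mm plastic wall (thickness unpublished, configurable) plus the
well footprint of water. Marginal-ray analysis needs an aperture the design
does not publish; the default aperture radius is calibrated so the marginal
incidence at the field corner is the stated 5° worst case. At 5° through
12 mm of water the relative shift is 0.92% of the 28.5 mm field — under the
1% design bound.

Lateral resolution uses the slanted-edge spatial frequency response: per-row
edge localization (coarse smoothed-gradient peak, then a sub-pixel
squared-gradient centroid within ±8 px of the fitted straight edge — the
windowing keeps full-row pixel noise from biasing the centroid), projection
of all pixels onto the edge normal, a 4×-oversampled binned edge-spread
function, finite-difference line-spread, Hamming window, and normalized DFT
magnitude on 0–50 cycles/mm. The noise floor is the mean MTF over the top
20% of the frequency band; the decay region runs from the first nonzero
frequency to the first sample below twice the floor and is fitted
log-linearly as A·exp(−B·f); the cutoff solves A·exp(−B·f) = floor and the
resolution is its reciprocal (µm). Band fraction and the 2× region edge are
free parameters of this estimator. On Gaussian-blurred phantom edges the
measured MTF tracks exp(−2π²σ²f²) within 0.02 up to 30 cycles/mm and the
end-to-end cutoff agrees with the same fit applied to the analytic curve
within 15%.

## Synthetic phantoms

The simulated larva is an articulated rigid-length chain (nostril 1.5 mm,
eye midpoint 1.0 mm ahead of the bladder, eyes ±0.25 mm lateral, four
0.625 mm tail segments — a ~4 mm, 7 dpf body) whose tail bends sinusoidally
(2 Hz beat, amplitude growing toward the tip) in a body plane. The bladder
anchor moves at constant commanded speed with a freely wandering azimuth
(SD 0.05 rad/frame) and mean-reverting pitch and roll (stationary SDs 0.12
and 0.08 rad, reversion 0.05/frame, pitch capped at 0.6 rad) — zebrafish
larvae are dorsoventrally stable, so free random-walk posture would be
unphysical. Confinement is an inner box inset by the body reach with
reflective walls (reflection keeps speed statistics stationary, unlike
absorption). The body axis tracks the movement direction at a bounded
0.2 rad/frame so the rigid head turns smoothly through wall reflections,
and the per-frame anchor stride is solved so the eye midpoint advances by
exactly the commanded step; realized mean reference speed lands within ~2%
of the command (the residual comes from reflection folds).

Rendering projects landmarks through the same height-dependent pixel model
the reconstruction inverts, then adds i.i.d. Gaussian pixel noise (default
0.5 px) and likelihoods: dropout frames (per-view Bernoulli) draw all eight
likelihoods from U(0, 0.7), others from U(0.85, 1) — only the 0.7 threshold
matters downstream, so the shape of the likelihood distribution is
arbitrary. Bladder masks rasterize the exact Schur-complement silhouette as
a filled ellipse, by default on a 4× downsampled pixel grid. Edge targets
are analytic erf profiles with a 5° slant.

What the phantoms do **not** emulate: appearance (no photorealism, no
segmentation errors beyond ellipse rasterization), hydrodynamics, occlusion
or refraction of the specimen itself, lens blur on keypoints, and
likelihoods correlated with pose. Passing tests therefore validate the
geometry, QC logic, estimators and their numerics — not the upstream
networks' detection quality on real video.

## Problem sizes in the test suite

The default suite simulates single larvae at 600–10,000 frames, fits 500
ellipsoid round trips, checks the silhouette oracle on 100 random quadrics
at a 1° ray fan, and runs the projection inequality on 1,000 random
20-frame tracks; the whole suite completes in well under a minute on one
core. These sizes were chosen as the smallest that exercise every boundary
case and keep sampling noise irrelevant to the asserted tolerances.

## Known limitations

- Two orthogonal silhouettes cannot fully determine an ellipsoid (above);
  volumes for strongly tilted bladders are reported under the documented
  maximum-volume convention, with diagnostics, not as unique estimates.
- The refraction model treats interfaces as flat and ignores the meniscus,
  lens aberrations and defocus; the MTF estimator assumes a single straight
  high-contrast edge.
- Precision mAP/mAR-style keypoint metrics are not implemented (no fixed
  similarity convention exists for this landmark set); RMSE and a
  radius hit-rate are provided instead.
- The side-view extra optical path and plastic wall thickness are config
  estimates, not measured values.
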