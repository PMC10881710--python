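# Methods

This note documents the models behind `mvphantom`: what is simulated, which
parameters matter, the numerical choices, and what the synthetic world does
and does not establish.

## 1. Parametric anatomy

**Annulus.** The mitral annulus is the saddle curve
`p(θ) = c + a·cosθ·e₁ + b·sinθ·e₂ + h·cos2θ·e₃`, θ ∈ [0, 2π), with
semi-axes a ≥ b in the annular plane and saddle amplitude h along the valve
axis. The cos 2θ term is the standard first-order description of the
bileaflet saddle; the curve spans 2h along the axis, so the ground-truth
"height" of the default annulus (a, b, h) = (20, 15, 3) mm is 6 mm.
Defaults are mid-range adult values (D_max 40 mm, D_min 30 mm, annulus area
≈ 9.4 cm²).

**Leaflets.** Each leaflet is a quadrilateral sheet lofted from one annulus
half (anterior: θ ∈ [0, π]; posterior: θ ∈ [π, 2π]) to a free edge. In the
annular frame, with sheet coordinate s ∈ [0, 1]:

- x(θ, s) = a cosθ
- y(θ, s) = ((1−s)·b + s·g)·sinθ, where g = orifice_gap/2·(1−state)
- z(θ, s) = (1−s)·h cos2θ − s·(c₀ + (d − c₀)·|sinθ|)

with leaflet belly depth d (`leaflet_depth`, default 18 mm) and commissural
depth c₀ (`commissure_depth`, default 6 mm). Three properties of this
construction are load-bearing:

- the **annulus row (s = 0) lies exactly on the annulus curve** (vertex ids
  are recorded, so the attachment is known to machine precision);
- the **orifice** bounded by the two free edges projects to a smooth
  ellipse-like loop of semi-axes (a, g) — the anatomically realistic rounded
  shape; the default `orifice_gap` = 16 mm gives an open orifice area of
  ≈ 5.0 cm², in the normal range for diastole. A slit-shaped orifice would
  additionally be under-sampled by radial planes at its pointed ends;
- the **leaflet is long enough to close**: the annulus-to-free-edge chord at
  the leaflet center is √((b−g)² + (d−h)²) ≈ 16.6 mm > b = 15 mm, the
  minimum reach for the free edges to meet at the symmetry plane under
  edge-length-preserving motion. (With d = 12 mm the valve geometrically
  cannot coapt; this drove the 18 mm default.) Commissural depth 6 mm
  matches real commissural leaflet height (5–8 mm) and keeps the mesh free
  of near-degenerate elements at the commissures.

Mesh resolution is iterated until the mean triangle area is within 5% of
`target_face_area` (default 0.55 mm², the density of a segmentation-derived
valve surface at ~1 mm imaging resolution). Each leaflet is a manifold
topological disk; the two leaflets share no topology (coincident commissure
coordinates are duplicated vertices). Mesh generation requires h > 0: a
perfectly flat annulus collapses the commissure columns.

**Thorax.** Surrounding entities are ellipsoid/tube primitives with the
label set of the intensity table (left/right heart walls and cavities,
aorta, bones, liver, kidney, lungs, bronchi), 1 mm isotropic in a 160 mm
cube by default, annulus centered at the origin with the valve axis along
+z. An elliptic "ostium" channel of blood pool joins the LA and LV cavities
so the valve always sits in cavity voxels. Shapes are deliberately schematic
(realistic organ geometry is a non-goal); what matters downstream is correct
labeling and the valve's blood-pool environment.

**Landmark fusion.** Components are aligned by 10 named landmarks (four
valve centers, apex, septum center, four aortic-centerline markers). With
known correspondences the iterative-closest-point problem reduces to one
closed-form orthogonal Procrustes (Kabsch) step; reflections are corrected
to proper rotations, collinear or <3 landmarks are rejected.

**Rasterization.** A voxel receives the valve label when its center lies
within thickness/2 (default 1 mm surface thickness) of the leaflet surface,
using exact point–triangle distances rather than scan conversion —
correctness over speed at this scale. Overwrite policy: the valve wins over
background and blood-pool cavities and loses to everything else
(configurable), so the thin structure is never swallowed by walls.

## 2. Valve closure (position-based dynamics)

The closure is a deterministic PBD sequence of `n_frames` = 180 frames with
the annulus pinned exactly (a static heart with a fixed annulus). Per frame:

1. **Drive.** Free vertices move by `closing_drive` (mm/frame) along the
   tangent of a rotation about their own leaflet's annulus-attachment
   centroid, oriented toward the inter-leaflet mid-plane — the
   near-isometric swinging motion a closing leaflet actually performs
   (driving straight at the mid-plane fights the edge constraints). The
   magnitude is weighted per vertex by (sheet coordinate) × (local leaflet
   span), a pressure-like load that leaves the short commissural tissue
   nearly still, and gated off once a vertex reaches the mid-plane. The
   default drive is 1.3 × (initial free-edge gap)/(n_frames−1); the 1.3 arc
   factor accounts for the curved path.
2. **Projection.** `solver_iterations` = 30 Gauss–Seidel sweeps of distance
   constraints: mesh edges (stiffness 1.0) and opposite-vertex bending pairs
   (stiffness 0.05). Edges respond to stretch at full stiffness but to
   compression at `compression_factor` = 0.1 of it — thin tissue buckles
   rather than resisting compression; this is what lets the free edge fold
   as it flattens. Constraints are greedily edge-colored once, so each color
   class is projected exactly and vectorized while the sweep stays
   deterministic (fixed class order, no randomness anywhere in the solver).
3. **Barrier and pinning.** Free vertices may not cross the mid-plane
   (prevents interpenetration in the rasterized images), and fixed vertices
   are re-pinned bit-exactly.

With the defaults the closure is monotone (free-edge centroid separation
strictly non-increasing), ends with a 0.6 mm residual gap (under the 1 mm
coaptation tolerance; a warning is emitted if the tolerance is missed), and
peak edge stretch stays at 4.2%, within the 5% contract of the module. These
defaults were chosen by sweeping the solver/material parameters until that
contract held; they are not physiological constants.

**Temporal sampling** to imaging resolution (10 timesteps/closure) either
decimates (default: frames at round-spaced indices, endpoints kept) or
window-averages vertex positions over contiguous equal windows, which
emulates temporal partial-volume mixing. Frames are assumed uniform in time.

## 3. Synthetic image generation

Order of operations: temporal sampling → per-timeframe valve rasterization
into the thorax → intensity assignment → additive noise → smoothing → plane
definition → slab sampling → two-step in-plane resampling. (Temporal
sampling is applied to the motion sequence before rasterization; with
decimation this is frame-for-frame identical to rasterizing first and 18×
cheaper.)

- **Intensities.** Each voxel draws independently from
  Normal(mean_tissue, sd_tissue) with the observed cine-MRI table (mitral
  valve 266 ± 25, LA cavity 357 ± 14, myocardium 75 ± 8, …). A Rician
  variant is implemented for completeness but Gaussian is the default — the
  two fits differ only marginally on blood pool and myocardium at these
  SNRs. Unlabeled voxels are 0 ± 0 unless overridden.
- **Noise.** Additive zero-mean Gaussian with σ = 38, the largest per-tissue
  sd among the heart entities (the left atrial wall).
- **Smoothing.** Gaussian kernel specified in mm (converted per-axis for
  anisotropic voxels); default σ = 0.7 mm ≈ half the acquired pixel,
  emulating mild reconstruction filtering without destroying the 1 mm valve.
- **Planes.** The valve axis is the smallest principal component of the
  valve-surface vertex covariance (sign fixed toward the atrium); the valve
  center is the vertex centroid. SAX: parallel planes normal to the axis,
  6 mm thickness and 6 mm center-to-center spacing (contiguous cine stack —
  "gap" is read as center spacing, consistent with a slice spacing equal to
  the thickness). rLAX: n ∈ {6, 9, 18} planes containing the axis, rotated
  by 180°/n increments; the fan reference direction is offset by a quarter
  increment from the commissural axis so no plane is tangent to the valve at
  the commissures (both span and reference are configurable).
- **Slab sampling.** Pixel value = mean of 5 trilinear sub-plane samples
  across [−t/2, +t/2] (through-plane partial volume). Out-of-volume samples
  take a configurable background fill with a warning.
- **In-plane resampling.** Exact box averaging (integral image with linear
  interpolation at fractional box edges) down to the 1.4 mm acquired grid,
  then bilinear interpolation up to the 0.87 mm reconstructed grid.

All randomness descends from a single seed through per-timeframe
substreams; a fixed seed reproduces stacks bit-for-bit.

## 4. Simulated annotators

Ground truth for annotation is the exact mesh–plane cross-section of the
slice-center plane (marching-triangles polylines; open endpoints are tagged
by the mesh boundary they touch: annulus attachment, free edge = orifice, or
lateral leaflet boundary). An annotator is that ground truth plus:

- **in-plane Gaussian click noise** (σ = 1.5 mm by default) — annotation
  happens on 2D slices, so through-plane error is induced by the slice
  geometry, not by the noise model. On SAX slices the contour is first
  snapped to the displayed slice-center plane, which is exactly the
  through-plane quantization that penalizes SAX;
- optional independent **misses** of annulus/orifice points (rate < 1);
- on rLAX planes: 2 annulus points, 2 leaflet-end (orifice) points and a few
  leaflet-contour points per plane; on SAX: spline control points
  (resampled cross-section contours).

The default σ = 1.5 mm was chosen so simulated inter-annotator variation on
rLAX lands at ~2 mm mean contour distance, the magnitude reported for expert
readers on comparable data; it is a free parameter, not a measured quantity,
and sensitivity sweeps should vary it.

## 5. Quantification and metrics

- **annulus PCA**: principal components of the pooled annular points,
  ordered by descending eigenvalue (ties are extent-invariant). D_max/D_min
  = extent (max − min projection) along PC1/PC2; height = extent along PC3.
  "Height" as full extent matches the 2h ground truth of the saddle; an
  alternative (2·max|deviation|) would differ for asymmetric annuli.
- **areas**: points projected to the annular (PC1, PC2) plane, angular sort
  about the centroid when unordered, unsigned shoelace sum. Self-intersecting
  projections warn but still return the shoelace value.
- **SAX boundary estimates**: SAX contours carry no point labels, so the
  annulus (orifice) estimate is the radially outermost (innermost) contour
  point per angular sector about the valve axis (36 sectors).
- **bias** = mean signed difference over the N = 3 annotators.
- **contour distance**: asymmetric, annotation → ground truth, exact
  point-to-segment minimum over every segment of the dense GT polyline.
- **point-to-surface distance**: exact point–triangle minimum over all
  faces (vertex/edge/interior cases).
- **summaries**: min, quartiles, mean, sd, max; outliers by the standard
  1.5·IQR box-plot rule.

`replicate_study` runs the full loop (phantom → closure → sampling →
3 annotators per strategy → parameters, biases, contour and surface distance
tables) for SAX and rLAX6/9/18. The annotated timeframe defaults to the
first (open) frame so the orifice is non-degenerate. Image stacks can be
rendered as part of the study, but the distance metrics depend only on the
annotation geometry.

## 6. What a green test establishes — and what it does not

The synthetic world reproduces the *mechanism* that separates the sampling
strategies: through-plane quantization of a thin oblique structure by a
6 mm SAX stack versus in-plane visibility of annulus and leaflet ends on
radial planes. With default noise, SAX annulus contour error (~4.8 mm) vs
rLAX (~1.7–1.8 mm) reproduces the qualitative ordering and rough magnitudes
reported for human experts. It does **not** emulate: flow and motion
artifacts, k-space acquisition physics, field inhomogeneity, heart
contraction or annular motion (annulus fixed by design), chordae/papillary
apparatus, patient-specific anatomy, or human perceptual biases (the
annotator noise is isotropic and unbiased, real readers are neither). Exact
numeric agreement with expert-study tables is therefore out of scope.

## 7. Numerical details and edge cases

- Degenerate inputs raise typed errors: non-orthonormal annulus frames,
  collinear landmark/PCA point sets, <4 annular points, empty meshes or
  distance sets, negative noise/thickness, unknown config keys (named in the
  message), meshes outside the rasterization volume (offending vertex ids
  listed).
- Tie-breaks: PCA signs are fixed (largest-magnitude component positive);
  eigenvalue ties do not affect extents. Trilinear sampling at exact voxel
  boundaries follows the interpolator's lower-index convention.
- The PBD divergence check names the first non-finite frame.
- Rasterization pads each triangle's voxel search box by thickness/2 plus
  half a voxel diagonal, so no qualifying voxel center is missed.
- Determinism: closure is seed-free and bit-reproducible; image and
  annotation stages consume numpy Generators spawned from the study seed.
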