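# Methods

This note documents the models, conventions and numerical choices
behind `cardioshape`, in the spirit of a methods appendix: what each
component assumes, which knobs matter, and what the synthetic data can
and cannot tell you about behaviour on clinical images.

## The modeling problem

Biventricular shape modeling condenses a multi-view cine CMR study
into a patient-specific 3D surface model with a fixed topology, from
which global measures (volumes, masses, ejection fractions) and
statistical shape features (atlas Z-scores) follow. The automated
workflow runs five image-analysis stages in order — view
classification, short-axis (SAx) slice selection, end-systolic (ES)
phase selection, anatomical landmark localization, myocardial
segmentation — then extracts contour guide points, fits a template
mesh, and measures the result. Every stage output can be overridden by
user-supplied values before the next stage runs; overrides are tallied
in a ledger with per-landmark intervention rates.

## Synthetic phantom

The phantom supplies studies with complete ground truth so that every
stage is testable without patient data.

**Anatomy.** The LV is a thick-walled half-ellipsoid (base plane at
z = 0 in the heart frame, apex at z = −ℓ): endocardial semi-axes
(r, ℓ) default (25, 80) mm, wall 9 mm. The RV is a crescent wrapped
around the LV epicardium over an angular window (default 120°), with
depth profile d·cos(πθ̂/2)·√(1 − z²/ℓ_rv²) (d default 18 mm) and a
free wall (default 5 mm) that tapers to zero at the insertions. Valve
rings (MV, AV, TV, PV) are circles in the base plane; the MV ring is
the endocardial base boundary. An aortic root, a pulmonary trunk and
two atrial blood pools are rendered above the base plane — they give
the three-chamber, outflow-tract and two-/four-chamber views their
defining appearance, as in real anatomy, but are never part of the
segmentation ground truth or the fitted model.

**Contraction.** A piecewise raised-cosine weight w(t) rises from 0 at
frame 0 (ED) to exactly 1 at the chosen ES frame and returns to 0 at
the cycle's end. The LV cavity scales about the base-plane center by
λ(t) = 1 − (1 − (1 − EF)^{1/3}) w(t), so cavity volume is λ³·EDV and
the ejection fraction equals the target *exactly*; the epicardium is
static, so the wall thickens in systole. The RV crescent depth scales
by μ(t), with μ_ES solving the (analytically quadratic) crescent
volume law for the same EF. Cavity and wall volumes are closed-form up
to one 1D quadrature.

**Imaging.** Seven cardiac planes (2Ch LT/RT, 3Ch, 4Ch, LVOT, RVOT,
SAx stack spanning beyond apex and base) are prescribed in the heart
frame — as clinical view planning does — with per-series "operator"
jitter (±8° in-plane rotation, ±4 mm shift); two axial "other" series
cover the torso. Pixels are classified through the implicit anatomy at
their patient-space centers (LPS mm, 0-based row/col pixel centers,
DICOM-style affine); blood renders at 0.92, myocardium 0.55, torso
0.30, background 0.05, plus Gaussian noise (default sd 0.03). Default
in-plane spacing is 1.4 mm at 128², SAx spacing 8 mm, 30 frames.

**Ground truth.** View labels; optimal flags (a SAx plane is optimal
iff it crosses the LV cavity strictly between apex and base plane);
per-frame landmark pixel coordinates obtained by intersecting the
valve-ring circles with each view plane (so insert midpoints are ring
centers by construction); label masks following the per-view
annotation conventions (2Ch LT: LV only; 2Ch RT/RVOT: RV only;
3Ch/4Ch/SAx: all four structures; papillary-like islands belong to
the blood pool) plus full-anatomy masks; analytic volumes per frame;
and ED/ES surface meshes in patient coordinates.

**What the phantom does not emulate.** MRI physics (no k-space,
banding, flow or motion artifacts), trabeculation, pathology-specific
remodeling, arrhythmia (one global ES phase), through-plane motion of
the valve plane, and inter-vendor appearance differences. Passing
stage floors here demonstrates that the contracts, codecs, geometry
and training loops are correct — not that the small networks would
match their clinical counterparts on patient data.

## Stage models

Label codecs follow the conventions used for training such stages:
the ES phase label is a Gaussian over frames, peak-normalized to 1 at
ES with σ = 4 frames; landmark labels are per-landmark Gaussian
heatmaps with σ = 12 px, peak-normalized to 1 ("normalized" is read as
peak-normalized, since the label is described as reaching 1 at ES).
Cines shorter than 30 frames are zero-padded with a validity mask;
temporal context stacks use frames (t−2 … t+2) with cyclic indexing
(a cine is periodic; the boundary rule is ours). Decoding rules the
source material leaves open are fixed here: the ES frame is the argmax
of the slice-averaged curve over valid frames (ties toward the
earliest frame); a landmark is the intensity-weighted centroid of the
above-half-maximum connected component containing the global maximum,
with confidence = peak value. Slice selection is a binary
optimal/non-optimal decision with exact ties resolved non-optimal.

The networks are compact CPU-trainable models with the canonical
contracts: conv/pool classifiers with global average pooling and a
softmax head (view: 8 classes; slice: 2); a shared per-frame conv
encoder feeding a bidirectional Elman recurrence and a sigmoid head
for the phase curve (MSE loss on valid frames); and a half-resolution
encoder–decoder with skip connections plus a full-resolution output
head for heatmaps (weighted MSE; the peak neighbourhood is weighted
10×, since the background dominates the pixel count) and segmentation
(cross-entropy + soft Dice). Conv blocks throughout use instance
normalization with leaky ReLU — without normalization the deeper
stacks plateau at the trivial solution and the classifiers converge an
order of magnitude more slowly. The optimizer is SGD with momentum
0.9 throughout; default learning rates are per stage (0.05
classifier/phase/heatmaps, 0.1 segmentation; higher rates reach lower
training loss on some seeds but occasionally collapse the phase and
heatmap heads onto degenerate optima, so the stable setting is the
default) because the losses live on different
scales. Training is deterministic given the config seed.

One segmentation network serves all views: it is trained on
full-anatomy masks and the per-view class filter is applied at decode
time (masking disallowed logits), which keeps supervision consistent —
training on view-filtered labels would teach the net that the same LV
appearance is sometimes "background". Landmark networks are trained
*per landmark-bearing view* (3Ch, 4Ch, RVOT, SAx), with output
channels exactly that view's landmark set: a shared network would need
one channel (say, "first mitral insert") to mean different image
positions in different views, and in practice confidently localizes
the wrong insert. The landmark nets take two extra coordinate input
channels (a purely convolutional net has no notion of absolute image
position, which symmetric insert pairs require), use wider features
than the segmentation net (the crowded basal landmarks need separable
feature combinations), and are trained with best-of-k restarts scored
by the decoded landmark error on their own training samples — a run
that confuses two landmarks can reach *lower* regression loss than a
correct one, so training loss cannot select models, while the decoded
training error exposes the confusion immediately (no held-out data is
involved). Insert pairs are named along the pair's dominant image
axis, which is invariant to the plane-prescription jitter; naming by
image column alone flips randomly for the near-vertical short-axis RV
insert pairs.

Augmentations (rotation, zoom, translation, brightness, contrast,
noise, crop, mirror, time-roll) act jointly on images and spatial
labels; time-roll shifts a cine and its phase label together so ES can
fall anywhere in the padded input.

## Contour extraction and guide points

Masks are traced with sub-pixel marching squares after filling
cavity holes (papillary-like islands count as blood pool). Classes:
LV endocardium = LV-cavity boundary; epicardium = outer boundary of
the union of all labeled tissue; septum = the LV-side boundary
segments adjacent (within 1.8 px) to RV blood or muscle *and* not on
the outer outline (the septum is interior by definition); RV
endocardium = RV-cavity boundary excluding the septal interface. The
LV-side septum convention matches drawing a single septal contour.
Polylines are resampled to ≈2 mm arc length before fitting (balances
the least-squares system size against fidelity), lifted through each
plane's affine, and pooled into one guide-point set per phase: ED is
frame 0 (ECG-gated acquisitions start at end-diastole; no other ED
definition is given), ES comes from the phase stage.

A known artifact of slice-wise annotation is that long-axis masks are
cut off at the valve plane, so their traced boundaries include a
straight "cut line" that belongs to no anatomical surface. These
points are handled by robust trimming in the fitter (below) rather
than by ad-hoc filtering in the contourer.

## Template mesh and fitting

The template is built parametrically from the phantom's mean geometry
(there is no distributed reference template): latitude rings ×
azimuth columns, with the RV window always spanned by the same 12
columns so *every* mesh built by the generator shares vertex/face
topology. It carries four closed, outward-oriented regions (LV
endocardium, RV endocardium, global epicardium, LV epicardium — the
last shares the septal sheet's vertices with the RV region, so septal
guides move both), open "match" surfaces per contour class, valve-ring
vertex loops, and named landmark vertices (apex, ring centers).
Watertightness and consistent orientation of every region are enforced
by construction and by tests; cap faces (base plane, valve disks) are
excluded from contour matching.

Fitting is two-stage. (1) Closed-form similarity registration
(Umeyama) of the template's landmark points onto the guide set's
derived targets (valve-insert midpoints averaged across views, plus
the apex); requires ≥3 non-collinear landmarks. (2) Regularized
non-rigid ICP: each contour point is matched to the nearest point of
the same-class template surface (k-d-tree candidate pruning); insert
points match their valve-ring vertices and ring centers with a higher
landmark weight (default 10 — landmarks are sparse but control the
valve anatomy, to which the fit is most sensitive); a linear
least-squares displacement field is solved over all vertices with a
graph-Laplacian smoothness penalty (weight 1.0) and a tiny ridge
(1e-9) for the similarity nullspace of isolated valve disks;
per-vertex steps are capped at 2 mm per iteration, which keeps the
deformation gentle and fold-free in practice (no flipped normals are
observed, and tests assert positive region volumes after fitting).
Matches farther than max(4 × class-median, 3 mm) are dropped for that
iteration (robust trimming — this absorbs the valve-plane cut lines
and stray segmentation fragments). Default 20 iterations with early
stop when the mean vertex step falls below 0.01 mm.

The fit is equivariant under rigid motion of the inputs in exact
arithmetic; in floating point, re-matching and trimming amplify
rounding differences, so two runs related by a rigid transform agree
to ~0.02 mm (the property test asserts 0.05 mm).

Loop subdivision (with label propagation and watertightness checks) is
provided for single closed manifold meshes; the multi-region template,
whose coincident septal sheets are deliberately non-manifold as a
union, is built at its final resolution instead. Note Loop subdivision
shrinks a control icosahedron toward a smooth non-spherical limit, so
convergence is tested as smoothness (adjacent-normal angles), not as
distance to the circumscribed sphere.

## Measures and atlas

Region volumes are signed divergence-theorem sums over closed region
surfaces (error < 2% at template resolution against analytic solids).
LV mass = (LV-epicardial volume − LV cavity) × 1.05 g/mL at ED, septum
counted in the LV; RV mass = free-wall volume × 1.05 (1.05 g/mL is the
standard myocardial density; the septal assignment is the standard
convention). SV = EDV − ESV and EF = 100·SV/EDV hold by definition.
EDV ≤ ESV yields a warning, not an error — dysfunction must be
representable.

The ED/ES atlas aligns each subject's ED model to the evolving
population mean by rigid Procrustes *without scaling* (heart size is a
real shape feature), applies the same transform to the ES model,
concatenates ED+ES vertex coordinates into one shape vector, and runs
PCA with the 1/(n−1) covariance convention. Z-scores are mode
coefficients divided by √λ_k, so training scores have mean 0 and
sample sd 1 per mode by construction; modes with λ below 1e-12 are
excluded from projection with a warning. ED and ES live in one vector
(one atlas), matching the combined ED/ES reading; separate-phase
atlases can be built by passing identical phases.

## Evaluation toolbox

Dice (two empty masks define 1.0), exact symmetric Hausdorff (max
convention, with a percentile variant exposed since the max/95%
choice is often left unstated; 2D contour metrics stay in pixels, 3D
in mm), AAFD, rigid model alignment (proper rotations only), signed
point-to-surface projection distances (positive = outside the
reference surface along its outward normal; valve regions compare
ring vertices to the reference ring polyline; the global MAE is the
all-point mean, not the mean of regional means), plane angulation
errors in [0°, 90°], Bland–Altman summaries (bias, 1.96·sd limits,
regression r², paired-t p), and per-mode Z-score differences with
two-sample Kolmogorov–Smirnov tests under Holm–Bonferroni at α=0.05.
The point-to-surface query is exact: k-d-tree candidates are expanded
by a circumradius-guaranteed ball, and tests assert equality with the
brute-force minimum over triangles.

## Problem sizes in the shipped experiments

The test suite and the acceptance script run everything at desk scale,
chosen so a full pass stays comfortable on one CPU: populations of
10–30 phantoms at 128² / 1.4 mm, stage training on ~200 images for
8–25 epochs, atlas experiments on 12–30 oracle-fitted subjects, and
oracle round trips on 3–5 phantoms. These sizes are package defaults,
not statements about the method's limits; every experiment scales by
changing the population size and epochs in one place.

## Known limitations

- The stage networks are deliberately small; their scores on the
  phantom say nothing quantitative about clinical performance.
- The template's valve disks are held only by landmark terms and the
  ridge; with missing valve landmarks their pose regresses to the
  similarity registration.
- The RV free wall tapers to zero thickness at the insertions, so
  RV-myocardium Dice is intrinsically the hardest class (as it is in
  practice for thin RV walls).
- One global ES phase is assumed; ventricle-specific phase selection
  is out of scope.
- Subdivision-surface limit evaluation is not implemented; fitting
  operates on the control mesh.
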