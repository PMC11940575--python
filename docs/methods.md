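# Methods

`beakmorph` implements a generative-morphometrics pipeline for bill-like
3D shapes: a signed-distance-function (SDF) autodecoder learns a latent
shape space from watertight meshes, and the latent codes are then mined
for morphological, ecological and phylogenetic structure. This note
documents the models, the numerical choices, and what the synthetic data
does and does not establish.

## The shape model

A closed surface is represented implicitly by its signed distance
function `SDF(x)`: the distance from a 3D point `x` to the nearest
surface point, negative inside, positive outside. The surface is the
zero level set. A single decoder network approximates the SDFs of all
shapes at once,

    f_theta(z_i, x) ~ SDF_i(x),

where `z_i` is a latent code — a free parameter vector per shape with a
spherical Gaussian prior, optimized jointly with the weights `theta` by
maximum a posteriori (MAP) estimation. There is no encoder; this
"autodecoder" design lets minibatches mix SDF rows from any subset of
shapes. The training objective per batch is

    sum_rows | clamp(s, delta) - clamp(f_theta(z, x), delta) |
        + lambda * sum_shapes ||z_i||^2 ,

with `clamp(v, delta) = min(delta, max(-delta, v))`. Clamping (default
`delta = 0.1` in unit-sphere units) concentrates accuracy near the
surface, which is all the zero isosurface depends on; `lambda` is the
observation-to-prior variance ratio and shrinks codes toward the origin
(default `1e-4`).

**Architecture.** Two chained 3-layer perceptron modules. Module 1 maps
`[z, x]` (latent_dim + 3 inputs) through three ReLU layers of
`hidden_size` units; module 2 receives module 1's output concatenated
again with `[z, x]` (skip connection) and emits one value through tanh.
Full-scale defaults are 64 latent dimensions and 512 hidden units; the
desk-scale experiments in this repository use 8 and 128.

**Numerics that matter.**
- The output layer is initialized at 1% of the usual scale so that
  initial predictions lie inside the clamp band. The clamped-L1 gradient
  is identically zero outside the band; with a default-scale start, some
  seeds begin saturated and training never moves at all.
- Optimization is Adam with separate learning rates for weights and
  codes (desk scale: 1e-3 and 1e-2; code moments are kept per shape row).
  Codes initialize from N(0, 0.01^2).
- Everything is float64 numpy with seeded generators; a training run is
  bit-reproducible on one thread.

## Mesh preprocessing

Scanned bills arrive in arbitrary pose, attached to part of the head,
open at the back. Four steps make them comparable and watertight:

1. **Clean** — weld duplicate vertices, drop degenerate and duplicate
   faces, remove connected components below 1% of total faces (scanner
   debris is small).
2. **Reorient** — rigid motion into the canonical frame defined by three
   landmarks: +x from the bill-base center (midpoint of the base-top and
   base-bottom landmarks) to the tip, +z the dorsal component of the
   base bottom-to-top line orthogonal to x, y = z x x. Only rotation and
   translation; reflections are impossible by construction.
3. **Trim and cap** — compute the minimal sphere enclosing five hull
   points (tip; base top and bottom from landmarks; base left/right as
   the extreme +-y vertices in a slab of 5% of the base-to-tip span).
   "Minimal" is the natural reading of a perfectly enclosing sphere and
   is computed exactly by case analysis over support subsets of up to
   four points. Faces crossing the sphere are cut at the exact
   edge-sphere intersections; every boundary loop is projected onto the
   sphere and closed by a fan to its centroid direction, giving a
   standardized curved back surface. Trimming that would discard more
   than 90% of faces aborts with an error.
4. **Normalize** — center at the bounding-box midpoint and scale so the
   farthest vertex has norm 1; scale and center are recorded so
   reconstructions map back to model units.

Trim-and-cap is not mathematically idempotent — the cap lies *on* the
enclosing sphere, so a second pass would compute a slightly different
sphere through cap points. The pipeline therefore returns a mesh
unchanged when it is watertight and already inside (to tolerance) its
enclosing sphere, or when its provenance records a prior trim; pipeline
idempotency to 1e-6 is a tested property.

## SDF computation and sampling

Distances are exact point-to-triangle distances minimized over faces
(vectorized barycentric region analysis). Candidate faces come from a
KD-tree over face centroids; a radius bound certifies when the candidate
minimum is globally optimal and a ball re-query handles the rest, so
acceleration never changes the result. The inside/outside sign uses the
nearest face's outward normal where the geometry makes that unambiguous
and the generalized winding number where it does not (closest feature on
an edge or vertex). Signing requires watertightness and raises otherwise.

Training data per shape is the two-part Monte-Carlo sample: `n` points
uniform in the unit ball (radius-inversion sampling, no rejection) plus
an equal number of area-uniform surface draws jittered by isotropic
Gaussian noise (default SD 0.01 in unit-sphere units; offsets leaving the
unit ball are redrawn). The equal split and the noise scale are
package defaults: desk-scale runs use 1,000–1,500 points per part; a
full-scale run would use tens of thousands.

## Reconstruction and fidelity

Any code decodes to a mesh by evaluating `f_theta(code, .)` on a
cell-centered lattice over [-1, 1]^3 (site `i` at `lo + (i + 0.5) *
cell`; recorded so extraction is bit-reproducible) and contouring the
zero level with marching cubes. Desk-scale grids are 64^3 in the
fidelity checks and 48^3 in traversal experiments; a full-scale run
would use 128^3.

Fidelity is symmetric chamfer distance between area-uniform surface
samples. Both meshes are sampled with the *same* seed and the two
directional means averaged, which makes the metric exactly symmetric in
its arguments.

## Stage-2 conditional VAE

MAP codes conform only loosely to their spherical prior (heavy tails per
dimension — the "prior hole"), so decoding prior draws directly produces
unrepresentative shapes. A small conditional VAE fit on the codes
repairs this: encoder and decoder are 2x128 ReLU MLPs, the latent space
has 15 dimensions, conditioning is by one-hot concatenation to both
encoder and decoder inputs, and the Gaussian reconstruction variance
`gamma` is a single trainable scalar (log-parameterized), which lets the
model balance reconstruction against the KL pull on its own. The ELBO
and KL are the standard closed forms; sampling is reparameterized.
Class-conditional generation chains prior draw -> CVAE decoder -> SDF
decoder -> marching cubes.

Gaussianization is verified operationally: heavy-tailed synthetic codes
(Student-t, df 4) go in; the encoded stage-2 means show substantially
smaller mean |excess kurtosis| than the inputs.

## Morphospace analysis

Shape indices on a canonically posed mesh: length = x-extent; width and
depth = y/z extents within the rear 10% of the x-extent (the in-silico
analogue of caliper measurements at the bill base); elongation =
length / mean(width, depth); broadness = width / depth. Both indices are
scale-invariant. Decoded meshes carry no landmarks, so callers that know
the pose pass `assume_canonical=True`; measurements of decoded shapes
use the largest connected component, since off-data codes occasionally
decode with small satellite blobs.

A latent direction "meaning" an index is the coefficient vector of the
no-intercept least-squares regression of the index on the codes,
reported with uncentered R^2. Directions — not coordinates — are the
meaningful objects in this space: recovery is exactly equivariant under
orthogonal rotation of the codes (a tested property).

**Traversal experiments.** Starting shapes are random pairwise
interpolations of trained codes rather than spherical prior draws: at
desk scale the aggregate posterior deviates far enough from the prior
that prior draws mostly decode to empty space (the prior-hole problem
above, amplified by a training set 10–100x smaller than a full-scale
run). The direction is discovered from codes and responses centered at
their means — a desk-scale MAP code cloud has a substantial mean, and an
uncentered no-intercept fit spends part of its coefficient vector
reproducing the mean elongation through it, a component with no
morphological effect. Steps along the unit direction are in units of the SD of code
projections onto that direction — one SD of the morphological gradient
as the cloud expresses it. Monotonicity of measured elongation along the
ladder allows 0.02 slack for sub-voxel marching-cubes noise. The
substrate is a model trained on bills spanning the parametric family
continuously; a decoder memorizing a few tight clusters is locally flat
between them, and no global linear direction has a realized effect
there.

2-d visualization delegates to UMAP (default 25 neighbors) and t-SNE;
only parameter plumbing and seeding are owned here. The latent tour is a
natural cubic spline through waypoint codes, sampled evenly in
parameter.

## Niche classification

Classes are imbalanced, so each member of class j gets case weight
`1/n_j` — every class contributes unit total weight. The protocol:
stratified holdout (per-class test count = round(n_j * test_prop),
clamped to [1, n_j - 1]); hyperparameter choice by Monte-Carlo
cross-validation (20 random stratified validation splits by default),
scoring mean validation balanced accuracy and refitting the winner on
all training rows. Balanced accuracy is the macro average over classes
of (sensitivity + specificity)/2 in one-vs-rest form; classes absent
from both truth and prediction are excluded with a warning. Random
forest and elastic-net multinomial regression come from scikit-learn;
the weighting, splitting, selection and evaluation protocol is owned
here. An optional QC mask drops specimens whose meshes failed manual
inspection.

## Phylogenetic signal

Under Brownian motion the among-species trait covariance is proportional
to C, the matrix of shared root-to-ancestor branch lengths; C is
computed from tip depths and patristic distances. Statistics:

- **Blomberg's K**: `[MSE0/MSE] / [(tr C - n / (1'C^-1 1)) / (n-1)]`
  with the GLS phylogenetic mean; ~1 under BM. The simulation
  calibration (200 replicates, 64-tip pure-birth trees) recovers a mean
  within [0.9, 1.1], and the implementation matches an independently
  coded direct-formula oracle to 1e-10.
- **Multivariate K**: the trace generalization (squared deviations
  summed over trait dimensions in numerator and C-weighted denominator);
  reduces exactly to K at p = 1.
- **Phylogenetic PCA**: eigenanalysis of the GLS-estimated evolutionary
  covariance `(X - 1a)' C^-1 (X - 1a) / (n-1)`; on a star tree this is
  ordinary PCA.
- **PACA**: eigenvectors of `(X - 1a)' C (X - 1a)` — orthonormal
  directions ordered by covariation with the phylogeny, so axis 1
  concentrates as much phylogenetic signal as a rotation can.

Newick ingestion bumps non-positive branch lengths to 1e-8 with a
warning (C must be positive definite for GLS). All statistics are
invariant to tip-order permutation.

The axis-removal experiment computes PACA scores, drops the leading
axis, and reruns the full classification protocol — probing whether
class prediction rides on phylogenetically structured variation.

## Synthetic data: what it emulates, what it does not

The mesh family is a tapered solid with elliptical cross-sections
shrinking from base (profile `(1 - t^1.8)^(1/1.8)`) to a point at the
tip, an optional dorsal bend and tip downturn, and an ellipsoidal cap
closing the base — watertight by construction, in canonical pose, with
analytic landmarks, and with bounding extents equal to the requested
length/width/depth (enforced by a final per-axis rescale). Class
structure comes from per-class normal parameter distributions with
arbitrary counts (imbalance included); size draws that land non-positive
are redrawn, so specs should keep means several SDs above zero.

Clades are pure-birth (Yule) trees grown to `n` tips with exponential
waiting times; traits evolve by Brownian motion along branches, sizes on
the log scale (exponentiated at the tips, keeping positivity the way
comparative methods usually do). One seed fixes topology and traits
bit-for-bit. `simulate_phylo_latents` adds iid Gaussian noise to BM
dimensions so that a chosen fraction (default 0.3) of per-tip variance
is phylogenetic — emulating a latent space whose signal is spread evenly
across dimensions at a realistic (well below 1) per-axis K.

What passing tests show: the pipeline's operations are correct on
smooth, watertight, landmark-true geometry, and its statistical stages
behave as designed when their assumptions hold by construction. What
they do not show: robustness to scanner artifacts (holes, self-
intersections beyond simple duplicates, misplaced landmarks), to fine
surface detail (nares, ornaments — deliberately out of scope), or
performance at the scale of thousands of species; desk-scale models
memorize rather than generalize, and the generalization smoke tests
(held-out embedding) are exactly that.

## Desk-scale problem sizes

Chosen so the full suite and the reproduction script each run in
minutes on one CPU: 10-bill memorization runs (latent 8, hidden 128,
2,000 Adam steps, 3,000 SDF rows/shape), a 60-bill continuous-variation
model for direction work, a 135-bill three-class model (45 per class,
30% holdout) for classification, 64^3 reconstruction grids, 200-replicate
K calibrations on 64-tip trees, and 20-replicate signal-profile
comparisons on 96-tip trees.
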