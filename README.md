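# beakmorph

Generative 3D morphometrics of bird-bill-like shapes: learn a continuous
latent space of bill meshes with a signed-distance-function (SDF)
autodecoder, then extract morphological, ecological and phylogenetic
meaning from the latent codes.

Classical 3D morphometrics needs landmarks, alignment and linear
dimension reduction before any downstream analysis. This package takes
the generative route instead: every bill `i` is represented by a latent
vector `z_i`, and a single decoder network `f_theta(z, x)` maps a code
and a 3D coordinate to the signed distance of that bill's surface
(negative inside, positive outside; the surface is the zero level set).
Codes and weights are fit jointly by MAP estimation of

    sum_ij | clamp(s_ij, delta) - clamp(f_theta(z_i, x_ij), delta) |
        + lambda * sum_i ||z_i||^2,        delta = 0.1,

over Monte-Carlo samples `(x_ij, s_ij)` of each bill's signed distance
field. Any code then decodes back to a mesh via dense SDF evaluation and
marching cubes. On top of the latent space the package provides:

- interpretable latent directions (elongation, broadness) by
  no-intercept regression of measured shape indices on the codes;
- a second-stage conditional VAE with trainable reconstruction variance,
  which Gaussianizes the code distribution and generates bills
  conditioned on a trophic niche;
- niche classification with inverse-class-size case weights, stratified
  holdout, Monte-Carlo cross-validation and balanced accuracy (the
  macro average of per-class sensitivity and specificity);
- phylogenetic-signal analysis: Blomberg's K (univariate and
  multivariate), phylogenetic PCA, phylogenetically aligned components
  (PACA), per-axis signal profiles, and the first-axis-removal
  classification experiment.

Because real bill scans are not bundled, a first-class synthetic module
generates watertight parametric bills (length, width, depth, curvature,
hook), class-structured parameter tables with controllable imbalance,
and pure-birth clades whose traits evolve by Brownian motion — so every
claim is testable against truth known by construction.

## Worked example

Train a desk-scale model on ten synthetic bills, reconstruct one, and
measure it:

```python
from beakmorph import pipeline, reconstruct, morphospace

model = pipeline.train_desk_model(
    pipeline.random_beak_table(10, seed=0),
    latent_dim=8, hidden_size=128, n_sdf=1500,
    epochs=100, steps_per_epoch=20, seed=0,
)
print(f"final training loss {model.result.history[-1]:.4f}")

sid = model.codes.shape_ids[0]
grid = reconstruct.predict_sdf_grid(model.params, model.codes[sid], resolution=64)
mesh = reconstruct.extract_mesh(grid)
chamfer = reconstruct.chamfer_distance(model.dataset.meshes[sid], mesh,
                                       n_points=4000, seed=7)
idx = morphospace.measure_beak(mesh, assume_canonical=True)
print(f"{sid}: chamfer {chamfer:.4f}, elongation {idx.elongation:.2f}, "
      f"broadness {idx.broadness:.2f}")
```

Output:

```
final training loss 0.0016
s000: chamfer 0.0113, elongation 6.04, broadness 1.45
```

The loss is the mean per-row clamped-L1 error (unit-sphere units), so
0.0016 means the decoder reproduces each bill's near-surface distance
field to about 2/1000 of the enclosing sphere's radius. The chamfer
distance of 0.011 between the input mesh and its reconstruction is the
mesh-level counterpart ("captures the overall shape"). Elongation is
length over mean girth; broadness is width over depth — this bill is
long and slender, a bit wider than deep.

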