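"""SDF autodecoder: decoder network, clamped-L1 MAP objective, training.

The model approximates each shape's signed distance function with a single
decoder ``f_theta(z_i, x)`` where ``z_i`` is a free latent code per shape.
There is no encoder: codes are parameters, jointly optimized with the
decoder weights by maximum a posteriori estimation under a spherical
Gaussian prior on the codes.  Up to constants, the negative log posterior
for a batch of SDF rows is::

    sum |clamp(s, delta) - clamp(f_theta(z, x), delta)|  +  lambda * sum_i ||z_i||^2

The clamp (delta defaults to 0.1) concentrates accuracy near the surface,
which is all that matters for the zero isosurface; ``lambda`` is the ratio
of observation to prior variance and controls code shrinkage.

Architecture: two chained 3-layer perceptron modules.  Module 1 maps
``[z, x]`` through three hidden layers; module 2 receives module 1's
output concatenated again with ``[z, x]`` (a skip connection) and produces
the scalar SDF prediction through a tanh.  Hidden width defaults to 512,
latent dimension to 64.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import MLP, Adam, RowAdam
from .core import InvalidParameterError, TrainingDivergedError
from .sdf import SDFSampleSet


def clamp(value, delta: float):
    """Truncate to the band [-delta, delta] (elementwise)."""
    if delta <= 0:
        raise InvalidParameterError("delta must be positive")
    return np.minimum(delta, np.maximum(-delta, value))


@dataclass
class TrainConfig:
    """Hyperparameters of MAP training.

    ``lam`` is the prior-penalty weight (the observation/prior variance
    ratio); ``delta`` the SDF clamp half-width in unit-sphere units.
    Learning rates follow the convention of faster code than weight
    updates.
    """

    latent_dim: int = 64
    hidden_size: int = 512
    delta: float = 0.1
    lam: float = 1e-4
    epochs: int = 100
    steps_per_epoch: int = 20
    batch_size: int = 512
    learning_rate_theta: float = 1e-4
    learning_rate_z: float = 1e-3
    code_init_sd: float = 0.01
    seed: int = 0
    checkpoint_interval: int = 0  # epochs; 0 = only at the end

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise InvalidParameterError("delta must be positive")
        if self.lam < 0:
            raise InvalidParameterError("lambda must be non-negative")


@dataclass
class DecoderParams:
    """Weights of the two chained MLP modules."""

    module1: MLP
    module2: MLP
    latent_dim: int
    hidden_size: int

    @property
    def params(self) -> list[np.ndarray]:
        return self.module1.params + self.module2.params


@dataclass
class LatentCodes:
    """Table of per-shape latent vectors."""

    shape_ids: list[str]
    codes: np.ndarray  # (n_shapes, latent_dim)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if not np.isfinite(self.codes).all():
            raise InvalidParameterError("latent codes must be finite")

    @property
    def latent_dim(self) -> int:
        return self.codes.shape[1]

    def __getitem__(self, shape_id: str) -> np.ndarray:
        return self.codes[self.shape_ids.index(shape_id)]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"z_{i + 1}" for i in range(self.latent_dim)]
        return pd.DataFrame(self.codes, index=self.shape_ids, columns=cols).rename_axis(
            "shape_id"
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "LatentCodes":
        df = pd.read_csv(path, index_col="shape_id")
        return cls(shape_ids=[str(i) for i in df.index], codes=df.to_numpy())


def build_decoder(
    latent_dim: int = 64, hidden_size: int = 512, seed: int = 0
) -> DecoderParams:
    """Initialize decoder weights (seeded; same seed, same weights)."""
    if latent_dim < 1 or hidden_size < 1:
        raise InvalidParameterError("latent_dim and hidden_size must be >= 1")
    rng = np.random.default_rng(seed)
    d_in = latent_dim + 3
    m1 = MLP(
        [d_in, hidden_size, hidden_size, hidden_size],
        ["relu", "relu", "relu"],
        rng,
    )
    m2 = MLP(
        [hidden_size + d_in, hidden_size, hidden_size, 1],
        ["relu", "relu", "tanh"],
        rng,
    )
    # small output-layer init keeps initial predictions inside the clamp
    # band; the clamped-L1 gradient is zero outside it, so a saturated
    # start would never train at all
    m2.layers[-1].W *= 0.01
    return DecoderParams(m1, m2, latent_dim, hidden_size)


def decoder_forward(
    params: DecoderParams,
    z: np.ndarray,
    x: np.ndarray,
    want_cache: bool = False,
):
    """Predict SDF values for (code, coordinate) rows; returns (B,) array."""
    z = np.atleast_2d(z)
    x = np.atleast_2d(x)
    if z.shape[0] == 1 and x.shape[0] > 1:
        z = np.broadcast_to(z, (x.shape[0], z.shape[1]))
    in1 = np.hstack([z, x])
    h, c1 = params.module1.forward(in1, want_cache=True)
    in2 = np.hstack([h, in1])
    out, c2 = params.module2.forward(in2, want_cache=True)
    pred = out[:, 0]
    if want_cache:
        return pred, (in1, c1, c2)
    return pred


def decoder_backward(
    params: DecoderParams, cache, grad_pred: np.ndarray
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Backprop d(loss)/d(pred) to code gradients and weight gradients."""
    in1, c1, c2 = cache
    g2_in, grads2 = params.module2.backward(c2, grad_pred[:, None])
    h_width = params.hidden_size
    g_h = g2_in[:, :h_width]
    g_in1_skip = g2_in[:, h_width:]
    g_in1, grads1 = params.module1.backward(c1, g_h)
    g_in1 = g_in1 + g_in1_skip
    g_z = g_in1[:, : params.latent_dim]
    return g_z, grads1 + grads2


def clamped_l1(observed, predicted, delta: float) -> float:
    """Sum of |clamp(s, delta) - clamp(s_hat, delta)| — the reconstruction loss."""
    return float(
        np.abs(clamp(np.asarray(observed, float), delta) - clamp(np.asarray(predicted, float), delta)).sum()
    )


def map_loss(
    batch_points: np.ndarray,
    batch_dists: np.ndarray,
    batch_shape_idx: np.ndarray,
    codes: np.ndarray,
    params: DecoderParams,
    config: TrainConfig,
) -> float:
    """The MAP objective on one batch (penalty once per shape present)."""
    z = codes[batch_shape_idx]
    pred = decoder_forward(params, z, batch_points)
    if not np.isfinite(pred).all():
        raise TrainingDivergedError("NaN/inf in decoder forward pass")
    recon = np.abs(
        clamp(batch_dists, config.delta) - clamp(pred, config.delta)
    ).sum()
    shapes = np.unique(batch_shape_idx)
    penalty = config.lam * (codes[shapes] ** 2).sum()
    return float(recon + penalty)


@dataclass
class TrainResult:
    params: DecoderParams
    codes: LatentCodes
    history: list[float] = field(default_factory=list)


def _loss_and_grads(
    params: DecoderParams,
    codes: np.ndarray,
    pts: np.ndarray,
    dists: np.ndarray,
    sidx: np.ndarray,
    config: TrainConfig,
):
    z = codes[sidx]
    pred, cache = decoder_forward(params, z, pts, want_cache=True)
    if not np.isfinite(pred).all():
        raise TrainingDivergedError("NaN/inf in decoder forward pass")
    cs = clamp(dists, config.delta)
    cp = clamp(pred, config.delta)
    err = cp - cs
    loss = np.abs(err).sum()
    # d|cp - cs|/dpred: sign through the clamp's active band
    grad_pred = np.sign(err) * (np.abs(pred) < config.delta)
    g_z_rows, w_grads = decoder_backward(params, cache, grad_pred)
    # accumulate per-shape code gradients + prior term (once per batch)
    shapes, inv = np.unique(sidx, return_inverse=True)
    g_codes = np.zeros((len(shapes), codes.shape[1]))
    np.add.at(g_codes, inv, g_z_rows)
    g_codes += 2.0 * config.lam * codes[shapes]
    loss += config.lam * (codes[shapes] ** 2).sum()
    return float(loss), w_grads, shapes, g_codes


def train(
    samples: list[SDFSampleSet],
    config: TrainConfig,
    checkpoint_path: str | Path | None = None,
    resampler=None,
) -> TrainResult:
    """Jointly optimize decoder weights and per-shape codes.

    ``samples`` is one SDF sample set per shape (>= 2 shapes, >= 100 rows
    each).  Optimization is Adam with separate learning rates for weights
    and codes; each step draws ``batch_size`` random rows from the pooled
    table.  ``resampler(shape_id, epoch) -> SDFSampleSet``, if given,
    refreshes the Monte-Carlo sample at the start of each epoch.  History
    records the mean per-row batch loss per epoch.  On divergence the last
    finite checkpoint is saved (if a path is given) before raising.
    """
    if len(samples) < 2:
        raise InvalidParameterError("need at least 2 shapes")
    if any(len(s) < 100 for s in samples):
        raise InvalidParameterError("each shape needs at least 100 SDF rows")
    rng = np.random.default_rng(config.seed)
    params = build_decoder(config.latent_dim, config.hidden_size, seed=config.seed)
    shape_ids = [s.shape_id for s in samples]
    codes = rng.normal(0.0, config.code_init_sd, size=(len(samples), config.latent_dim))

    opt_theta = Adam(params.params, lr=config.learning_rate_theta)
    opt_z = RowAdam(codes, lr=config.learning_rate_z)

    def pool(sample_list):
        pts = np.vstack([s.points for s in sample_list])
        dst = np.concatenate([s.distances for s in sample_list])
        idx = np.concatenate(
            [np.full(len(s), i, dtype=np.int64) for i, s in enumerate(sample_list)]
        )
        return pts, dst, idx

    pts, dst, idx = pool(samples)
    history: list[float] = []
    last_good = None
    try:
        for epoch in range(config.epochs):
            if resampler is not None:
                samples = [
                    resampler(sid, epoch) for sid in shape_ids
                ]
                pts, dst, idx = pool(samples)
            epoch_losses = []
            for _ in range(config.steps_per_epoch):
                take = rng.integers(0, len(pts), size=config.batch_size)
                loss, w_grads, shapes, g_codes = _loss_and_grads(
                    params, codes, pts[take], dst[take], idx[take], config
                )
                opt_theta.step(w_grads)
                opt_z.step(shapes, g_codes)
                epoch_losses.append(loss / config.batch_size)
            history.append(float(np.mean(epoch_losses)))
            last_good = (params, codes.copy())
            if (
                checkpoint_path is not None
                and config.checkpoint_interval
                and (epoch + 1) % config.checkpoint_interval == 0
            ):
                save_checkpoint(
                    checkpoint_path, params, LatentCodes(shape_ids, codes), config
                )
    except TrainingDivergedError:
        if checkpoint_path is not None and last_good is not None:
            save_checkpoint(
                checkpoint_path,
                last_good[0],
                LatentCodes(shape_ids, last_good[1]),
                config,
            )
        raise
    result = TrainResult(params, LatentCodes(shape_ids, codes), history)
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, params, result.codes, config)
    return result


def mean_clamped_error(
    params: DecoderParams,
    codes: LatentCodes,
    samples: list[SDFSampleSet],
    delta: float = 0.1,
) -> float:
    """Mean per-row |clamped truth - clamped prediction| over all shapes."""
    errs = []
    for s in samples:
        z = codes[s.shape_id]
        pred = decoder_forward(params, z[None, :], s.points)
        errs.append(np.abs(clamp(s.distances, delta) - clamp(pred, delta)))
    return float(np.concatenate(errs).mean())


def embed_new_shape(
    params: DecoderParams,
    sample: SDFSampleSet,
    config: TrainConfig,
    freeze_decoder: bool = True,
    n_steps: int = 500,
):
    """Optimize a latent code for one new shape against a trained decoder.

    Starts from a small random code and minimizes the clamped-L1 MAP loss
    for this shape alone.  With ``freeze_decoder=True`` (the default) only
    the code moves; otherwise decoder weights are fine-tuned too and the
    updated params are returned as a third element.  ``n_steps == 0``
    returns the random initialization unchanged.
    """
    rng = np.random.default_rng(config.seed)
    code = rng.normal(0.0, config.code_init_sd, size=(1, config.latent_dim))
    opt_z = RowAdam(code, lr=config.learning_rate_z)
    opt_theta = Adam(params.params, lr=config.learning_rate_theta) if not freeze_decoder else None
    final = np.nan
    for _ in range(n_steps):
        take = rng.integers(0, len(sample.points), size=min(config.batch_size, len(sample.points)))
        loss, w_grads, shapes, g_codes = _loss_and_grads(
            params,
            code,
            sample.points[take],
            sample.distances[take],
            np.zeros(len(take), dtype=np.int64),
            config,
        )
        if opt_theta is not None:
            opt_theta.step(w_grads)
        opt_z.step(shapes, g_codes)
    pred = decoder_forward(params, code, sample.points)
    final = float(
        np.abs(
            clamp(sample.distances, config.delta) - clamp(pred, config.delta)
        ).mean()
    )
    if freeze_decoder:
        return code[0], final
    return code[0], final, params


# ---------------------------------------------------------------------------
# checkpoints: named numeric arrays + JSON config sidecar
# ---------------------------------------------------------------------------

def save_checkpoint(
    path: str | Path,
    params: DecoderParams,
    codes: LatentCodes,
    config: TrainConfig,
) -> None:
    path = Path(path)
    arrays = {}
    for mi, mod in enumerate((params.module1, params.module2), start=1):
        for li, layer in enumerate(mod.layers):
            arrays[f"m{mi}_l{li}_W"] = layer.W
            arrays[f"m{mi}_l{li}_b"] = layer.b
    arrays["codes"] = codes.codes
    arrays["shape_ids"] = np.array(codes.shape_ids)
    np.savez(path, **arrays)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(config.__dict__, indent=2))


def load_checkpoint(path: str | Path) -> tuple[DecoderParams, LatentCodes, TrainConfig]:
    path = Path(path)
    config = TrainConfig(**json.loads(path.with_suffix(path.suffix + ".json").read_text()))
    params = build_decoder(config.latent_dim, config.hidden_size, seed=config.seed)
    with np.load(path) as z:
        for mi, mod in enumerate((params.module1, params.module2), start=1):
            for li, layer in enumerate(mod.layers):
                layer.W[...] = z[f"m{mi}_l{li}_W"]
                layer.b[...] = z[f"m{mi}_l{li}_b"]
        codes = LatentCodes(
            shape_ids=[str(s) for s in z["shape_ids"]], codes=z["codes"]
        )
    return params, codes, config
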