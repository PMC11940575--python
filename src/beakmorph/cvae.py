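"""Stage-2 conditional VAE on the autodecoder's latent codes.

MAP-estimated autodecoder codes typically deviate from their spherical
Gaussian prior ("prior holes", visible as heavy tails per dimension), so
sampling the prior directly produces unrepresentative shapes.  A second,
small conditional VAE fit *on the codes* repairs this: its own latent
space conforms much more closely to an independent Gaussian, and
conditioning on a niche label gives a class-conditional generator
(prior draw -> CVAE decoder -> SDF decoder -> mesh).

The ELBO is the usual reconstruction-minus-KL bound with one twist
following the two-stage-VAE literature: the Gaussian reconstruction
variance ``gamma`` is a single trainable scalar, which lets the model
balance reconstruction accuracy against the KL pull to the prior on its
own.  Conditioning is by one-hot concatenation to both encoder and
decoder inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from ._nn import MLP, Adam
from .core import InvalidParameterError, TrainingDivergedError


@dataclass
class CVAEConfig:
    cvae_latent_dim: int = 15
    hidden_size: int = 128
    epochs: int = 500
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0
    init_log_gamma: float = 0.0


@dataclass
class CVAEParams:
    """Encoder/decoder weights, the trainable log reconstruction variance,
    and the declared label set."""

    encoder: MLP
    decoder: MLP
    log_gamma: np.ndarray  # shape-() array so the optimizer can update it
    labels: tuple[str, ...]
    input_dim: int
    cvae_latent_dim: int

    @property
    def gamma(self) -> float:
        return float(np.exp(self.log_gamma))

    def one_hot(self, labels) -> np.ndarray:
        labels = np.asarray(labels, dtype=object)
        out = np.zeros((len(labels), len(self.labels)))
        for i, lab in enumerate(labels):
            if str(lab) not in self.labels:
                raise InvalidParameterError(
                    f"unknown label {lab!r}; declared set is {self.labels}"
                )
            out[i, self.labels.index(str(lab))] = 1.0
        return out

    def encode(self, x: np.ndarray, labels) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and log-variance for each input row."""
        inp = np.hstack([np.atleast_2d(x), self.one_hot(labels)])
        out = self.encoder.forward(inp)
        d = self.cvae_latent_dim
        return out[:, :d], out[:, d:]

    def decode(self, z: np.ndarray, labels) -> np.ndarray:
        inp = np.hstack([np.atleast_2d(z), self.one_hot(labels)])
        return self.decoder.forward(inp)


def build_cvae(
    input_dim: int, labels, config: CVAEConfig | None = None
) -> CVAEParams:
    config = config or CVAEConfig()
    rng = np.random.default_rng(config.seed)
    labels = tuple(sorted({str(l) for l in labels}))
    c = len(labels)
    d = config.cvae_latent_dim
    h = config.hidden_size
    enc = MLP([input_dim + c, h, h, 2 * d], ["relu", "relu", "linear"], rng)
    dec = MLP([d + c, h, h, input_dim], ["relu", "relu", "linear"], rng)
    return CVAEParams(
        enc, dec, np.array(config.init_log_gamma, dtype=float), labels, input_dim, d
    )


# -- closed forms -----------------------------------------------------------

def gaussian_kl(mu: np.ndarray, logvar: np.ndarray) -> np.ndarray:
    """Per-row KL( N(mu, diag(exp(logvar))) || N(0, I) ), closed form."""
    mu = np.atleast_2d(mu)
    logvar = np.atleast_2d(logvar)
    return 0.5 * (mu**2 + np.exp(logvar) - 1.0 - logvar).sum(axis=1)


def gaussian_recon_logp(
    x: np.ndarray, xhat: np.ndarray, gamma: float
) -> np.ndarray:
    """Per-row log N(x | xhat, gamma I)."""
    x = np.atleast_2d(x)
    xhat = np.atleast_2d(xhat)
    d = x.shape[1]
    sq = ((x - xhat) ** 2).sum(axis=1)
    return -0.5 * d * np.log(2.0 * np.pi * gamma) - sq / (2.0 * gamma)


def elbo_loss(
    x: np.ndarray,
    condition,
    params: CVAEParams,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Monte-Carlo ELBO of a batch: (total loss, reconstruction, KL).

    ``total = -(reconstruction - KL)`` averaged over rows; reconstruction
    uses a single reparameterized posterior draw (pass ``rng`` to seed it).
    """
    rng = rng or np.random.default_rng(0)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    mu, logvar = params.encode(x, condition)
    eps = rng.standard_normal(mu.shape)
    z = mu + np.exp(0.5 * logvar) * eps
    xhat = params.decode(z, condition)
    recon = gaussian_recon_logp(x, xhat, params.gamma).mean()
    kl = gaussian_kl(mu, logvar).mean()
    return float(-(recon - kl)), float(recon), float(kl)


# -- training ---------------------------------------------------------------

def _cvae_step(params: CVAEParams, x, onehot, rng):
    """One forward/backward pass; returns (loss, grads aligned to params)."""
    B, D = x.shape
    d = params.cvae_latent_dim
    enc_in = np.hstack([x, onehot])
    enc_out, enc_cache = params.encoder.forward(enc_in, want_cache=True)
    mu, logvar = enc_out[:, :d], enc_out[:, d:]
    eps = rng.standard_normal(mu.shape)
    sd = np.exp(0.5 * logvar)
    z = mu + sd * eps
    dec_in = np.hstack([z, onehot])
    xhat, dec_cache = params.decoder.forward(dec_in, want_cache=True)
    gamma = params.gamma

    resid = xhat - x
    sq = (resid**2).sum(axis=1)
    recon = -0.5 * D * np.log(2 * np.pi * gamma) - sq / (2 * gamma)
    kl = 0.5 * (mu**2 + np.exp(logvar) - 1.0 - logvar).sum(axis=1)
    loss = float((-recon + kl).mean())
    if not np.isfinite(loss):
        raise TrainingDivergedError("CVAE loss is not finite")

    # backward (all gradients of the mean loss)
    g_xhat = resid / (gamma * B)
    g_dec_in, dec_grads = params.decoder.backward(dec_cache, g_xhat)
    g_z = g_dec_in[:, :d]
    g_mu = g_z + mu / B
    g_logvar = g_z * eps * 0.5 * sd + 0.5 * (np.exp(logvar) - 1.0) / B
    g_enc_out = np.hstack([g_mu, g_logvar])
    _, enc_grads = params.encoder.backward(enc_cache, g_enc_out)
    g_log_gamma = np.array((0.5 * D - sq / (2 * gamma)).mean())
    return loss, enc_grads + dec_grads + [g_log_gamma]


def train_cvae(
    codes: np.ndarray,
    labels,
    config: CVAEConfig | None = None,
) -> tuple[CVAEParams, list[float]]:
    """Fit the conditional VAE; returns (params, per-epoch loss history).

    ``codes`` is the (n, d) table of stage-1 latent codes (or any feature
    matrix); ``labels`` the per-row niche labels (>= 2 classes).
    """
    config = config or CVAEConfig()
    x = np.atleast_2d(np.asarray(codes, dtype=float))
    labels = [str(l) for l in np.asarray(labels, dtype=object)]
    if len(set(labels)) < 2:
        raise InvalidParameterError("need at least 2 label classes")
    if len(labels) != len(x):
        raise InvalidParameterError("labels and codes must align")
    params = build_cvae(x.shape[1], labels, config)
    onehot_all = params.one_hot(labels)
    rng = np.random.default_rng(config.seed)
    all_params = params.encoder.params + params.decoder.params + [params.log_gamma]
    opt = Adam(all_params, lr=config.learning_rate)
    history: list[float] = []
    n = len(x)
    for _ in range(config.epochs):
        take = rng.integers(0, n, size=min(config.batch_size, n))
        loss, grads = _cvae_step(params, x[take], onehot_all[take], rng)
        opt.step(grads)
        history.append(loss)
    return params, history


def sample_conditional(
    params: CVAEParams, label: str, n: int, seed: int = 0
) -> np.ndarray:
    """Draw n codes from the learned conditional distribution of a label."""
    params.one_hot([label])  # validates the label
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty((0, params.input_dim))
    z = rng.standard_normal((n, params.cvae_latent_dim))
    return params.decode(z, [label] * n)


# -- Gaussianity diagnostics ------------------------------------------------

@dataclass
class NormalityReport:
    """Per-dimension excess kurtosis and max |QQ deviation| vs N(0,1)."""

    excess_kurtosis: np.ndarray
    qq_max_deviation: np.ndarray
    degenerate: np.ndarray = field(default_factory=lambda: np.array([], bool))


def normality_diagnostics(matrix: np.ndarray) -> NormalityReport:
    """How Gaussian is each column? (columns standardized first).

    Zero-variance columns are flagged degenerate (NaN statistics) rather
    than raising.
    """
    x = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, p = x.shape
    if n < 20:
        raise InvalidParameterError("need at least 20 rows")
    sd = x.std(axis=0, ddof=1)
    degenerate = sd < 1e-300
    kurt = np.full(p, np.nan)
    qq = np.full(p, np.nan)
    probs = (np.arange(n) + 0.5) / n
    theo = _stats.norm.ppf(probs)
    for j in range(p):
        if degenerate[j]:
            continue
        col = (x[:, j] - x[:, j].mean()) / sd[j]
        kurt[j] = _stats.kurtosis(col, fisher=True, bias=False)
        qq[j] = np.abs(np.sort(col) - theo).max()
    return NormalityReport(kurt, qq, degenerate)
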