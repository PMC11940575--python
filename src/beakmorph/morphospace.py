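"""Meaning in the latent space: shape indices, directions, paths, embeddings.

Two unitless bill-shape indices anchor the interpretation:

* elongation = length / mean(width, depth) — how long the bill is
  relative to its girth;
* broadness = width / depth — how wide relative to its height.

Length is the x-extent of a canonically posed mesh; width and depth are
the y/z extents inside a slab covering the rear 10% of the x-extent (the
in-silico analogue of caliper measurements at the bill base).

A direction in latent space "meaning" one of these indices is found by
no-intercept least squares of the index on the codes: the coefficient
vector points along the direction of maximum increase under a linear
model, and is what gets traversed to visualize the effect.  Only
directions are meaningful in this latent space — any orthogonal rotation
of the codes is an equally valid fit, and the recovered direction rotates
with them (tested as an equivariance property).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .core import InvalidParameterError, OrientationError, TriangleMesh

#: rear fraction of the x-extent treated as the bill base for width/depth
BASE_SLAB = 0.10


@dataclass(frozen=True)
class ShapeIndices:
    length: float
    width: float
    depth: float

    @property
    def elongation(self) -> float:
        return self.length / (0.5 * (self.width + self.depth))

    @property
    def broadness(self) -> float:
        return self.width / self.depth


@dataclass(frozen=True)
class LatentDirection:
    """A regression-derived direction with its fit quality."""

    vector: np.ndarray
    response_name: str
    r_squared: float


def measure_beak(
    mesh: TriangleMesh, assume_canonical: bool = False
) -> ShapeIndices:
    """Measure length/width/depth (and the derived indices) of a mesh.

    Requires canonical pose (tip along +x).  Pose is vouched for by the
    orientation landmarks; reconstructed meshes carry no landmarks, so
    callers that know the pose (decoder output is trained in canonical
    pose) pass ``assume_canonical=True``.
    """
    if not assume_canonical:
        mesh.require_landmarks()
    v = mesh.vertices
    if len(v) == 0:
        raise InvalidParameterError("empty mesh")
    x = v[:, 0]
    length = float(x.max() - x.min())
    if length <= 0:
        raise OrientationError("mesh has zero x-extent")
    slab = x <= x.min() + BASE_SLAB * length
    sv = v[slab]
    width = float(sv[:, 1].max() - sv[:, 1].min())
    depth = float(sv[:, 2].max() - sv[:, 2].min())
    if width <= 0 or depth <= 0:
        raise OrientationError("degenerate base slab")
    return ShapeIndices(length=length, width=width, depth=depth)


def discover_vector(
    codes: np.ndarray, response: np.ndarray, response_name: str = "response"
) -> LatentDirection:
    """No-intercept least squares of a response on the latent codes.

    Returns the coefficient vector together with the uncentered R^2
    (consistent with the absence of an intercept).
    """
    Z = np.atleast_2d(np.asarray(codes, dtype=float))
    y = np.asarray(response, dtype=float)
    n, d = Z.shape
    if n < d + 5:
        raise InvalidParameterError(
            f"need at least latent_dim + 5 = {d + 5} shapes, got {n}"
        )
    if not np.isfinite(y).all():
        raise InvalidParameterError("response must be finite")
    rank = np.linalg.matrix_rank(Z)
    if rank < d:
        s = np.linalg.svd(Z, compute_uv=False)
        small = np.where(s < s[0] * 1e-10)[0]
        raise InvalidParameterError(
            f"code matrix is rank deficient (rank {rank} < {d}; "
            f"near-null singular values at positions {small.tolist()})"
        )
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    denom = float(y @ y)
    r2 = 1.0 - float(resid @ resid) / denom if denom > 0 else 0.0
    return LatentDirection(vector=beta, response_name=response_name, r_squared=r2)


def apply_vector(
    code: np.ndarray, direction: LatentDirection, steps
) -> list[np.ndarray]:
    """Codes at ``code + step * unit(direction)`` for each step.

    Steps are in units of the unit-normalized direction; symmetric +-t
    steps land symmetrically about the input.
    """
    code = np.asarray(code, dtype=float)
    v = np.asarray(direction.vector, dtype=float)
    norm = np.linalg.norm(v)
    if norm < 1e-300:
        raise InvalidParameterError("direction vector is zero")
    if v.shape != code.shape:
        raise InvalidParameterError("dimension mismatch")
    u = v / norm
    return [code + float(t) * u for t in np.asarray(steps, dtype=float)]


def sample_prior_codes(
    n: int, latent_dim: int, seed: int = 0, scale: float = 1.0
) -> np.ndarray:
    """IID spherical Gaussian draws matching the autodecoder's code prior."""
    if n < 0:
        raise InvalidParameterError("n must be >= 0")
    rng = np.random.default_rng(seed)
    return scale * rng.standard_normal((n, latent_dim))


def latent_path(waypoints: np.ndarray, n_frames: int) -> np.ndarray:
    """Natural cubic spline through latent waypoints, sampled evenly.

    The tour device: passes through each waypoint exactly; with two
    waypoints it degenerates to straight-line interpolation.
    """
    W = np.atleast_2d(np.asarray(waypoints, dtype=float))
    if len(W) < 2:
        raise InvalidParameterError("need at least 2 waypoints")
    if (np.linalg.norm(np.diff(W, axis=0), axis=1) < 1e-300).any():
        raise InvalidParameterError("duplicate consecutive waypoints")
    t = np.arange(len(W), dtype=float)
    spline = CubicSpline(t, W, axis=0, bc_type="natural")
    return spline(np.linspace(0.0, t[-1], n_frames))


def embed_2d(
    codes: np.ndarray,
    method: str = "umap",
    n_neighbors: int = 25,
    seed: int = 0,
) -> np.ndarray:
    """2-D embedding of the codes via UMAP or t-SNE (delegated).

    Thin parameter/seeding plumbing over the established implementations;
    determinism follows their fixed-seed contracts.
    """
    Z = np.atleast_2d(np.asarray(codes, dtype=float))
    n = len(Z)
    if n < 10:
        raise InvalidParameterError("need at least 10 shapes")
    if n_neighbors >= n:
        raise InvalidParameterError("n_neighbors must be < number of shapes")
    if method == "umap":
        import umap

        reducer = umap.UMAP(
            n_components=2, n_neighbors=n_neighbors, random_state=seed
        )
        return np.asarray(reducer.fit_transform(Z), dtype=float)
    if method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(5.0, (n - 1) / 3.0))
        ts = TSNE(
            n_components=2, random_state=seed, perplexity=perplexity, init="pca"
        )
        return np.asarray(ts.fit_transform(Z), dtype=float)
    raise InvalidParameterError(f"unknown embedding method {method!r}")
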