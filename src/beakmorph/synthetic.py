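"""Synthetic bill-like shapes, class-structured trait tables, and clades.

Real bill scans (and the field measurements and phylogeny that accompany
them) are replaced here by a parametric family of watertight beak meshes so
that every downstream stage — preprocessing, SDF sampling, autodecoder
training, classification, phylogenetic signal — can be exercised with truth
known by construction.

The mesh family is a tapered solid with elliptical cross-sections that
shrink from base to tip, an optional dorsal bend (``curvature``), a tip
downturn (``hook``), and an ellipsoidal cap closing the base, mimicking a
trimmed-and-capped bill scan.  Meshes are emitted in canonical pose: base
center at the origin, tip on the +x axis, dorsal direction +z.

Shape traits evolve on a simulated pure-birth tree under Brownian motion
(sizes on log scale, so positivity is automatic), which makes phylogenetic
signal in downstream latent spaces a designed-in quantity rather than an
unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import InvalidParameterError, TriangleMesh

#: trait order used for clade simulation (sizes are BM on log scale)
TRAIT_NAMES = ("length", "width", "depth", "curvature", "hook")
SIZE_TRAITS = ("length", "width", "depth")

#: taper exponent of the cross-section profile g(t) = (1 - t^a)^(1/a)
TAPER_EXPONENT = 1.8


@dataclass(frozen=True)
class ShapeParams:
    """Parameters of one synthetic bill.

    length/width/depth are the bounding extents in model units; curvature
    is the dorsal bend of the centerline (0 = straight, in units of depth);
    hook in [0, 1] is the downturn of the tip; niche is a categorical label.
    """

    species_id: str
    length: float
    width: float
    depth: float
    curvature: float = 0.0
    hook: float = 0.0
    niche: str = "unassigned"

    def __post_init__(self) -> None:
        for name in SIZE_TRAITS:
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be a positive real")
        if not 0.0 <= self.hook <= 1.0:
            raise InvalidParameterError("hook must lie in [0, 1]")


def _profile(t: np.ndarray) -> np.ndarray:
    """Cross-section scale factor, 1 at the base and 0 at the tip."""
    a = TAPER_EXPONENT
    return (1.0 - np.clip(t, 0.0, 1.0) ** a) ** (1.0 / a)


def _centerline_z(t: np.ndarray, params: ShapeParams) -> np.ndarray:
    """Dorsal offset of the cross-section center at axial fraction t."""
    return params.depth * (
        params.curvature * t**2 - 0.6 * params.hook * t**4
    )


def make_beak_mesh(params: ShapeParams, resolution: int = 64) -> TriangleMesh:
    """Build a watertight bill mesh in canonical pose.

    ``resolution`` controls both the number of axial rings and the number
    of points around each ring.  The returned mesh has outward-facing
    normals, tip on the +x axis, the three orientation landmarks annotated,
    and axis-aligned bounding extents equal to (length, width, depth).
    """
    if resolution < 8:
        raise InvalidParameterError("resolution must be >= 8")
    L, W, D = params.length, params.width, params.depth
    n_axial = int(resolution)
    n_around = int(resolution) + (int(resolution) % 2)  # even, for y-symmetry
    n_cap = max(2, int(resolution) // 4)
    cap_depth = min(0.25 * min(W, D), 0.05 * L)

    phi = 2.0 * np.pi * np.arange(n_around) / n_around
    cos_p, sin_p = np.cos(phi), np.sin(phi)

    verts: list[np.ndarray] = []
    # rear pole of the base cap
    verts.append(np.array([[-cap_depth, 0.0, 0.0]]))
    # cap rings: ellipsoidal bulge from the pole up to the base ring plane
    rho = np.linspace(1.0, 0.0, n_cap + 1)[1:-1]  # exclude pole and base ring
    for r in rho:
        s = np.sqrt(max(0.0, 1.0 - r * r))
        ring = np.column_stack(
            [
                np.full(n_around, -cap_depth * r),
                0.5 * W * s * cos_p,
                0.5 * D * s * sin_p,
            ]
        )
        verts.append(ring)
    # body rings from base (t=0) toward the tip, excluding the tip point
    t_axial = np.linspace(0.0, 1.0, n_axial + 1)[:-1]
    for t in t_axial:
        g = float(_profile(np.array([t]))[0])
        zc = float(_centerline_z(np.array([t]), params)[0])
        ring = np.column_stack(
            [
                np.full(n_around, L * t),
                0.5 * W * g * cos_p,
                zc + 0.5 * D * g * sin_p,
            ]
        )
        verts.append(ring)
    # tip point
    tip_z = float(_centerline_z(np.array([1.0]), params)[0])
    verts.append(np.array([[L, 0.0, tip_z]]))

    vertices = np.vstack(verts)
    n_rings = (n_cap - 1) + n_axial
    tip_index = len(vertices) - 1

    faces: list[tuple[int, int, int]] = []

    def ring_start(k: int) -> int:
        return 1 + k * n_around

    # fan at the rear pole (pole sees ring 0); wind so normals face -x/outward
    s0 = ring_start(0)
    for j in range(n_around):
        a, b = s0 + j, s0 + (j + 1) % n_around
        faces.append((0, b, a))
    # strips between consecutive rings
    for k in range(n_rings - 1):
        sa, sb = ring_start(k), ring_start(k + 1)
        for j in range(n_around):
            j2 = (j + 1) % n_around
            faces.append((sa + j, sa + j2, sb + j))
            faces.append((sa + j2, sb + j2, sb + j))
    # fan at the tip
    sl = ring_start(n_rings - 1)
    for j in range(n_around):
        a, b = sl + j, sl + (j + 1) % n_around
        faces.append((a, b, tip_index))

    landmarks = {
        "tip": vertices[tip_index].copy(),
        "base_top": np.array([0.0, 0.0, 0.5 * D]),
        "base_bottom": np.array([0.0, 0.0, -0.5 * D]),
    }
    mesh = TriangleMesh(
        vertices=vertices,
        faces=np.asarray(faces, dtype=np.int64),
        landmarks=landmarks,
        provenance=[f"make_beak_mesh({params.species_id}, resolution={resolution})"],
    )
    mesh = _canonicalize(mesh, params)
    tm = mesh.to_trimesh()
    if tm.volume < 0:  # enforce outward orientation
        mesh.faces = mesh.faces[:, ::-1].copy()
    return mesh


def _canonicalize(mesh: TriangleMesh, params: ShapeParams) -> TriangleMesh:
    """Rotate tip onto +x, rescale bbox to (length, width, depth), center base."""
    from .meshprep import _landmark_frame

    lm = mesh.require_landmarks()
    rotation, translation = _landmark_frame(lm)
    out = mesh.transformed(rotation, translation, note="canonicalized")
    lo, hi = out.vertices.min(axis=0), out.vertices.max(axis=0)
    target = np.array([params.length, params.width, params.depth])
    scale = target / np.maximum(hi - lo, 1e-300)
    out.vertices = out.vertices * scale
    out.landmarks = {k: v * scale for k, v in out.landmarks.items()}
    # re-center: base center (midpoint of base landmarks) at the origin
    bc = 0.5 * (out.landmarks["base_top"] + out.landmarks["base_bottom"])
    out.vertices = out.vertices - bc
    out.landmarks = {k: v - bc for k, v in out.landmarks.items()}
    return out


def beak_body_volume(params: ShapeParams, n_quad: int = 4096) -> float:
    """Volume of the tapered body (base plane to tip) by 1-D quadrature.

    Independent of any mesh: integrates the elliptical cross-section area
    A(t) = pi * (W/2) g(t) * (D/2) g(t) along the axis.  Used as an oracle
    for mesh volume checks; the bend and hook shear cross-sections without
    changing their area, so they do not enter.
    """
    t = (np.arange(n_quad) + 0.5) / n_quad
    g2 = _profile(t) ** 2
    area = np.pi * 0.25 * params.width * params.depth * g2
    return float(area.mean() * params.length)


# ---------------------------------------------------------------------------
# class-structured parameter tables
# ---------------------------------------------------------------------------

def sample_class_params(
    class_spec: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Draw per-specimen shape parameters from per-class normal distributions.

    ``class_spec`` has one row per niche class with columns ``niche``,
    ``count`` and ``<trait>_mean`` / ``<trait>_sd`` for each trait in
    :data:`TRAIT_NAMES`.  Size traits are redrawn if a draw lands
    non-positive (specs should keep means several SDs above zero, so this
    truncation is negligible); hook is clipped to [0, 1].

    Returns a table with columns species_id, length, width, depth,
    curvature, hook, niche — one row per specimen, reproducible per seed.
    """
    required = {"niche", "count"} | {
        f"{t}_{s}" for t in TRAIT_NAMES for s in ("mean", "sd")
    }
    missing = required - set(class_spec.columns)
    if missing:
        raise InvalidParameterError(f"class_spec missing columns: {sorted(missing)}")
    if (class_spec["count"] < 1).any():
        raise InvalidParameterError("class counts must be >= 1")
    if any((class_spec[f"{t}_sd"] < 0).any() for t in TRAIT_NAMES):
        raise InvalidParameterError("trait SDs must be >= 0")

    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for rec in class_spec.itertuples():
        n = int(rec.count)
        draws = {}
        for t in TRAIT_NAMES:
            mu = getattr(rec, f"{t}_mean")
            sd = getattr(rec, f"{t}_sd")
            x = rng.normal(mu, sd, size=n)
            if t in SIZE_TRAITS:
                bad = x <= 0
                while bad.any():  # negligible-probability truncation
                    x[bad] = rng.normal(mu, sd, size=int(bad.sum()))
                    bad = x <= 0
            if t == "hook":
                x = np.clip(x, 0.0, 1.0)
            draws[t] = x
        for i in range(n):
            rows.append(
                {
                    "species_id": f"sp{idx:04d}",
                    **{t: float(draws[t][i]) for t in TRAIT_NAMES},
                    "niche": str(rec.niche),
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def params_from_row(row) -> ShapeParams:
    """Build a :class:`ShapeParams` from one row of a parameter table."""
    return ShapeParams(
        species_id=str(row["species_id"]),
        length=float(row["length"]),
        width=float(row["width"]),
        depth=float(row["depth"]),
        curvature=float(row["curvature"]),
        hook=float(row["hook"]),
        niche=str(row["niche"]),
    )


# ---------------------------------------------------------------------------
# clade simulation: pure-birth tree + Brownian-motion traits
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("children", "length", "label", "state")

    def __init__(self, length: float = 0.0, label: str | None = None):
        self.children: list[_Node] = []
        self.length = length
        self.label = label
        self.state: np.ndarray | None = None


@dataclass
class SimulatedClade:
    """A simulated tree plus trait values evolved on it.

    ``tip_traits`` holds the raw Brownian states (sizes on log scale) in
    :data:`TRAIT_NAMES` order; ``tip_params`` the back-transformed
    specimen table ready for :func:`make_beak_mesh`.
    """

    tree: "object"  # beakmorph.phylo.Phylogeny
    tip_params: pd.DataFrame
    tip_traits: pd.DataFrame
    sigma: np.ndarray
    root_state: np.ndarray
    newick: str = field(default="", repr=False)


def simulate_clade(
    n_tips: int,
    birth_rate: float = 1.0,
    sigma: np.ndarray | float = 0.1,
    root_state: np.ndarray | None = None,
    seed: int = 0,
    trait_names: tuple[str, ...] = TRAIT_NAMES,
) -> SimulatedClade:
    """Simulate a pure-birth ultrametric clade with BM-evolving traits.

    Size traits (length/width/depth) evolve on the log scale and are
    exponentiated at the tips; curvature and hook evolve on the raw scale
    (hook clipped to [0, 1] in the specimen table only).  ``sigma`` is the
    BM rate (SD per unit branch length) per trait; the same seed fixes both
    the topology and the trait increments bit-for-bit.
    """
    from .phylo import Phylogeny

    if n_tips < 3:
        raise InvalidParameterError("n_tips must be >= 3")
    if birth_rate <= 0:
        raise InvalidParameterError("birth_rate must be positive")
    p = len(trait_names)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (p,)).copy()
    if (sigma < 0).any():
        raise InvalidParameterError("sigma entries must be non-negative")
    if root_state is None:
        # modest default bill: length 4, width 1, depth 1, straight, no hook
        defaults = {"length": np.log(4.0), "width": 0.0, "depth": 0.0}
        root_state = np.array([defaults.get(t, 0.0) for t in trait_names])
    root_state = np.broadcast_to(np.asarray(root_state, dtype=float), (p,)).copy()

    rng = np.random.default_rng(seed)

    # forward-time Yule process: k active lineages wait Exp(k * birth_rate)
    root = _Node()
    active = [root]
    while len(active) < n_tips:
        k = len(active)
        wait = rng.exponential(1.0 / (k * birth_rate))
        for node in active:
            node.length += wait
        i = rng.integers(k)
        parent = active.pop(i)
        kids = [_Node(), _Node()]
        parent.children = kids
        active.extend(kids)
    # final stretch to the present
    wait = rng.exponential(1.0 / (len(active) * birth_rate))
    for node in active:
        node.length += wait
    for i, node in enumerate(active):
        node.label = f"t{i:04d}"

    # Brownian motion along branches (preorder)
    root.state = root_state.copy()
    stack = [root]
    while stack:
        node = stack.pop()
        for child in node.children:
            step = rng.normal(0.0, 1.0, size=p) * sigma * np.sqrt(child.length)
            child.state = node.state + step
            stack.append(child)

    newick = _to_newick(root) + ";"
    tree = Phylogeny.from_newick(newick)

    tips = [n for n in _iter_tips(root)]
    traits = pd.DataFrame(
        [n.state for n in tips], index=[n.label for n in tips], columns=trait_names
    )
    params_rows = []
    for label, row in traits.iterrows():
        rec = {"species_id": label}
        for t in trait_names:
            v = float(row[t])
            if t in SIZE_TRAITS:
                v = float(np.exp(v))
            if t == "hook":
                v = float(np.clip(v, 0.0, 1.0))
            rec[t] = v
        rec["niche"] = "unassigned"
        params_rows.append(rec)
    tip_params = pd.DataFrame(params_rows).set_index("species_id", drop=False)
    tip_params.index.name = None
    return SimulatedClade(
        tree=tree,
        tip_params=tip_params,
        tip_traits=traits,
        sigma=sigma,
        root_state=root_state,
        newick=newick,
    )


def _iter_tips(node: _Node):
    if not node.children:
        yield node
    for child in node.children:
        yield from _iter_tips(child)


def _to_newick(node: _Node) -> str:
    if not node.children:
        return f"{node.label}:{node.length:.17g}"
    inner = ",".join(_to_newick(c) for c in node.children)
    return f"({inner}):{node.length:.17g}"


def simulate_phylo_latents(
    n_tips: int = 96,
    n_dims: int = 16,
    signal_fraction: float = 0.3,
    seed: int = 0,
):
    """Isotropic latent codes with a known dose of phylogenetic signal.

    Each dimension is an independent BM trait on a shared pure-birth tree
    plus iid Gaussian noise; ``signal_fraction`` is the share of per-tip
    variance contributed by the tree (matched via the mean root-to-tip
    depth).  Emulates a latent space whose phylogenetic structure is
    spread evenly across dimensions.  Returns (tree, codes DataFrame in
    tip order).
    """
    if not 0.0 < signal_fraction < 1.0:
        raise InvalidParameterError("signal_fraction must lie in (0, 1)")
    clade = simulate_clade(
        n_tips,
        sigma=[1.0] * n_dims,
        root_state=np.zeros(n_dims),
        seed=seed,
        trait_names=tuple(f"dim{i}" for i in range(n_dims)),
    )
    tips = clade.tree.tip_labels
    depth = float(np.mean(list(clade.tree.depths().values())))
    noise_sd = np.sqrt(depth * (1.0 - signal_fraction) / signal_fraction)
    rng = np.random.default_rng(seed + 1)
    X = clade.tip_traits.loc[tips].values + rng.normal(
        0.0, noise_sd, size=(n_tips, n_dims)
    )
    return clade.tree, pd.DataFrame(
        X, index=tips, columns=[f"dim{i}" for i in range(n_dims)]
    )


def labels_from_clades(tree, n_classes: int) -> pd.Series:
    """Assign tips to ``n_classes`` labels by cutting the tree into clades.

    Produces labels that are maximally confounded with phylogeny (used to
    test what removing phylogenetically aligned axes does to
    classification).  Greedily splits the largest clade until the number of
    groups is reached; labels are 'clade0', 'clade1', ...
    """
    groups = [tree.tip_labels]
    clades = {frozenset(c) for c in tree.clades()}
    while len(groups) < n_classes:
        groups.sort(key=len, reverse=True)
        big = groups.pop(0)
        # find the largest proper clade inside `big`
        sub = max(
            (c for c in clades if c < frozenset(big) and 0 < len(c) < len(big)),
            key=len,
            default=None,
        )
        if sub is None:
            groups.append(big)
            break
        groups.append(sorted(sub))
        groups.append(sorted(set(big) - sub))
    labels = {}
    for i, grp in enumerate(sorted(groups, key=len, reverse=True)):
        for t in grp:
            labels[t] = f"clade{i}"
    return pd.Series(labels, name="niche")
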