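"""Four-step mesh preprocessing: clean, reorient, trim-and-cap, normalize.

Raw bill scans arrive as arbitrary-pose triangle soup attached to part of
the head, open at the back.  The pipeline makes them comparable and
watertight:

1. :func:`clean_mesh` — weld duplicates, drop degenerate/duplicate faces
   and debris components.
2. :func:`reorient_mesh` — rigid move into the canonical frame defined by
   the three orientation landmarks (+x base-center to tip, +z ventral to
   dorsal, right-handed).
3. :func:`trim_and_cap` — cut everything outside the minimal sphere
   enclosing five named hull points (tip; top, bottom, left, right of the
   base) and close the resulting hole with a cap on that sphere.
4. :func:`normalize_to_unit_sphere` — scale/translate into the unit ball,
   recording the transform so reconstructions map back to model units.

Only rotation+translation are ever applied in step 2 (no reflection or
scaling), so pairwise distances are preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import trimesh as _trimesh

from .core import (
    InvalidParameterError,
    MeshTopologyError,
    OrientationError,
    SuspiciousGeometryError,
    TriangleMesh,
)

#: components with fewer than this fraction of total faces are debris
COMPONENT_FACE_FRACTION = 0.01

#: thickness of the base slab (fraction of x-extent) used for hull points
BASE_SLAB_FRACTION = 0.05


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``v -> rotation @ v + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise InvalidParameterError("rotation must be 3x3 orthonormal")
        if np.linalg.det(R) < 0:
            raise InvalidParameterError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ np.asarray(self.rotation).T + np.asarray(
            self.translation, float
        )

    def inverse(self) -> "RigidTransform":
        R = np.asarray(self.rotation)
        return RigidTransform(R.T, -R.T @ np.asarray(self.translation))


# ---------------------------------------------------------------------------
# step 1: clean
# ---------------------------------------------------------------------------

def clean_mesh(mesh: TriangleMesh) -> TriangleMesh:
    """Weld duplicate vertices, drop bad faces and small debris components."""
    if len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise InvalidParameterError("mesh has no geometry")
    tm = mesh.to_trimesh()
    tm.merge_vertices(merge_tex=True, merge_norm=True)
    tm.update_faces(tm.nondegenerate_faces())
    tm.update_faces(tm.unique_faces())
    tm.remove_unreferenced_vertices()
    # debris removal: drop connected components below the face-count threshold
    components = tm.split(only_watertight=False)
    if len(components) > 1:
        keep = [
            c
            for c in components
            if len(c.faces) >= COMPONENT_FACE_FRACTION * len(tm.faces)
        ]
        if not keep:
            raise MeshTopologyError("all components below debris threshold")
        tm = _trimesh.util.concatenate(keep)
    edges = tm.edges_sorted
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if (counts > 2).any():
        raise MeshTopologyError(
            f"non-manifold topology: {int((counts > 2).sum())} edges shared "
            "by more than two faces after cleaning"
        )
    _trimesh.repair.fix_normals(tm)
    return TriangleMesh.from_trimesh(
        tm,
        landmarks=mesh.landmarks,
        provenance=mesh.provenance + ["clean_mesh"],
    )


# ---------------------------------------------------------------------------
# step 2: reorient
# ---------------------------------------------------------------------------

def _landmark_frame(
    landmarks: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Rotation/translation moving landmark geometry into canonical pose.

    Returns (R, t) such that ``v_canonical = R @ v + t``.
    """
    tip = np.asarray(landmarks["tip"], float)
    top = np.asarray(landmarks["base_top"], float)
    bot = np.asarray(landmarks["base_bottom"], float)
    base_center = 0.5 * (top + bot)
    x_axis = tip - base_center
    up = top - bot
    nx = np.linalg.norm(x_axis)
    cross = np.cross(x_axis, up)
    if nx < 1e-12 or np.linalg.norm(cross) < 1e-12 * max(
        nx * np.linalg.norm(up), 1e-300
    ):
        raise OrientationError("landmarks are collinear or coincident")
    x_axis = x_axis / nx
    z_axis = up - (up @ x_axis) * x_axis
    z_axis = z_axis / np.linalg.norm(z_axis)
    y_axis = np.cross(z_axis, x_axis)
    basis = np.column_stack([x_axis, y_axis, z_axis])  # canonical -> world
    rotation = basis.T
    translation = -rotation @ base_center
    return rotation, translation


def reorient_mesh(mesh: TriangleMesh) -> tuple[TriangleMesh, RigidTransform]:
    """Rigidly move the mesh into the landmark-defined canonical frame."""
    lm = mesh.require_landmarks()
    rotation, translation = _landmark_frame(lm)
    transform = RigidTransform(rotation, translation)
    out = mesh.transformed(rotation, translation, note="reorient_mesh")
    return out, transform


# ---------------------------------------------------------------------------
# step 3: trim and cap
# ---------------------------------------------------------------------------

def _circumsphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Smallest sphere through 1..4 affinely independent points."""
    pts = np.atleast_2d(points)
    n = len(pts)
    if n == 1:
        return pts[0].copy(), 0.0
    if n == 2:
        c = pts.mean(axis=0)
        return c, float(np.linalg.norm(pts[0] - c))
    # 3 or 4 points: solve |c - p_i|^2 = |c - p_0|^2.  Solving in
    # coordinates relative to p_0 makes the least-norm solution the
    # circumcenter inside the points' affine span (for 3 points the
    # solution set is the axis line; the point of it nearest p_0 is the
    # in-plane circumcenter).
    rel = pts[1:] - pts[0]
    A = 2.0 * rel
    b = (rel**2).sum(axis=1)
    c_rel, *_ = np.linalg.lstsq(A, b, rcond=None)
    c = pts[0] + c_rel
    return c, float(np.linalg.norm(c_rel))


def min_enclosing_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact minimal enclosing sphere of a handful of points.

    Checks all support subsets of size <= 4 (Welzl-style case analysis);
    intended for the five hull points, not for large point sets.
    """
    pts = np.asarray(points, dtype=float)
    best: tuple[np.ndarray, float] | None = None
    idx = range(len(pts))
    for k in (1, 2, 3, 4):
        for sub in combinations(idx, k):
            c, r = _circumsphere(pts[list(sub)])
            if not np.isfinite(r):
                continue
            d = np.linalg.norm(pts - c, axis=1)
            if (d <= r * (1 + 1e-9) + 1e-12).all():
                if best is None or r < best[1]:
                    best = (c, r)
        if best is not None:
            return best
    raise InvalidParameterError("could not compute enclosing sphere")


def hull_points(mesh: TriangleMesh) -> np.ndarray:
    """The five named hull points: tip; top, bottom, left, right of the base.

    Tip, base-top and base-bottom come from the landmarks; left/right are
    the extreme +-y vertices inside a thin slab around the base plane
    (x within BASE_SLAB_FRACTION of the x-extent of the base-to-tip span).
    Assumes canonical pose.
    """
    lm = mesh.require_landmarks()
    tip, top, bot = lm["tip"], lm["base_top"], lm["base_bottom"]
    base_x = 0.5 * (top[0] + bot[0])
    span = abs(tip[0] - base_x)
    if span <= 0:
        raise OrientationError("tip coincides with base plane")
    slab = np.abs(mesh.vertices[:, 0] - base_x) <= BASE_SLAB_FRACTION * span
    if not slab.any():
        raise OrientationError("no vertices in the base slab")
    sv = mesh.vertices[slab]
    left = sv[np.argmin(sv[:, 1])]
    right = sv[np.argmax(sv[:, 1])]
    return np.vstack([tip, top, bot, left, right])


def _boundary_loops(faces: np.ndarray) -> list[list[tuple[int, int]]]:
    """Directed boundary edges chained into closed loops."""
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    sort = np.sort(edges, axis=1)
    _, inv, counts = np.unique(sort, axis=0, return_inverse=True, return_counts=True)
    boundary = edges[counts[inv] == 1]
    succ = {int(a): int(b) for a, b in boundary}
    loops = []
    while succ:
        start, nxt = next(iter(succ.items()))
        loop = [(start, nxt)]
        del succ[start]
        while nxt != start:
            cur = nxt
            nxt = succ.pop(cur)
            loop.append((cur, nxt))
        loops.append(loop)
    return loops


def trim_and_cap(mesh: TriangleMesh) -> TriangleMesh:
    """Cut geometry outside the enclosing sphere and cap the holes on it.

    Faces crossing the sphere are cut at the exact edge-sphere
    intersections; every resulting boundary loop is projected radially onto
    the sphere and closed by a triangle fan to the loop centroid direction
    snapped onto the sphere.
    """
    pts = hull_points(mesh)
    center, radius = min_enclosing_sphere(pts)
    d = np.linalg.norm(mesh.vertices - center, axis=1) - radius
    tol = 1e-7 * radius

    if (d <= tol).all() and mesh.is_watertight():
        out = mesh.copy()
        out.provenance.append("trim_and_cap: already enclosed, unchanged")
        return out
    if "trim_and_cap" in " ".join(mesh.provenance) and mesh.is_watertight():
        out = mesh.copy()
        out.provenance.append("trim_and_cap: already trimmed, unchanged")
        return out

    inside = d <= tol
    fi = inside[mesh.faces]
    n_in = fi.sum(axis=1)
    keep_faces = mesh.faces[n_in == 3]
    crossing = mesh.faces[(n_in > 0) & (n_in < 3)]
    if len(keep_faces) < 0.1 * len(mesh.faces):
        raise SuspiciousGeometryError(
            f"trimming would remove {len(mesh.faces) - len(keep_faces)} of "
            f"{len(mesh.faces)} faces"
        )

    verts = [mesh.vertices.copy()]
    new_index: dict[tuple[int, int], int] = {}
    next_id = len(mesh.vertices)

    def cut_point(a: int, b: int) -> int:
        nonlocal next_id
        key = (a, b) if a < b else (b, a)
        if key in new_index:
            return new_index[key]
        p, q = mesh.vertices[a], mesh.vertices[b]
        u = q - p
        w = p - center
        # |w + t u|^2 = r^2
        aa = u @ u
        bb = 2 * w @ u
        cc = w @ w - radius**2
        disc = max(bb * bb - 4 * aa * cc, 0.0)
        roots = [(-bb - np.sqrt(disc)) / (2 * aa), (-bb + np.sqrt(disc)) / (2 * aa)]
        t = min((r for r in roots if -1e-9 <= r <= 1 + 1e-9), key=lambda r: abs(r - 0.5), default=None)
        if t is None:
            t = float(np.clip(roots[0], 0.0, 1.0))
        verts.append((p + np.clip(t, 0, 1) * u)[None, :])
        new_index[key] = next_id
        next_id += 1
        return next_id - 1

    cut_faces: list[tuple[int, int, int]] = []
    for tri in crossing:
        ins = [int(v) for v in tri if inside[v]]
        outs = [int(v) for v in tri if not inside[v]]
        if len(ins) == 1:
            a = ins[0]
            # preserve winding: rotate tri so it starts at a
            order = list(tri)
            k = order.index(a)
            _, b, c = order[k:] + order[:k]
            pab = cut_point(a, int(b))
            pca = cut_point(int(c), a)
            cut_faces.append((a, pab, pca))
        else:
            a, b = None, None
            order = list(int(v) for v in tri)
            k = order.index(outs[0])
            rot = order[k:] + order[:k]
            o, p, q = rot  # o outside; p, q may be inside
            if not inside[p]:  # two outside: o,p out, q in
                o2 = p
                pi = cut_point(q, o2)
                po = cut_point(o, q)
                cut_faces.append((q, po, pi))
            else:
                # one outside (o), p and q inside
                pop = cut_point(o, p)
                pqo = cut_point(q, o)
                cut_faces.append((p, q, pqo))
                cut_faces.append((p, pqo, pop))

    all_verts = np.vstack(verts)
    all_faces = np.vstack(
        [keep_faces] + ([np.asarray(cut_faces, dtype=np.int64)] if cut_faces else [])
    )

    # cap every boundary loop on the sphere
    loops = _boundary_loops(all_faces)
    extra_verts: list[np.ndarray] = []
    extra_faces: list[tuple[int, int, int]] = []
    vid = len(all_verts)

    def project(p: np.ndarray) -> np.ndarray:
        v = p - center
        n = np.linalg.norm(v)
        if n < 1e-12 * radius:
            v = np.array([radius, 0.0, 0.0])
            n = radius
        return center + v * (radius / n)

    for loop in loops:
        ids = [a for a, _ in loop]
        ring = all_verts[ids]
        proj = np.array([project(p) for p in ring])
        off_sphere = np.linalg.norm(proj - ring, axis=1).max() > 1e-6 * radius
        if off_sphere:
            ring_ids = list(range(vid, vid + len(ids)))
            extra_verts.append(proj)
            vid += len(ids)
            m = len(ids)
            for j in range(m):
                j2 = (j + 1) % m
                a, b = ids[j], ids[j2]
                a2, b2 = ring_ids[j], ring_ids[j2]
                # boundary edge is (a, b); new surface must traverse (b, a)
                extra_faces.append((b, a, a2))
                extra_faces.append((b, a2, b2))
            cap_ids = ring_ids
        else:
            cap_ids = ids
        centroid = project(all_verts[ids].mean(axis=0))
        extra_verts.append(centroid[None, :])
        apex = vid
        vid += 1
        m = len(cap_ids)
        for j in range(m):
            j2 = (j + 1) % m
            a, b = cap_ids[j], cap_ids[j2]
            extra_faces.append((b, a, apex))

    if extra_verts:
        all_verts = np.vstack([all_verts] + extra_verts)
        all_faces = np.vstack([all_faces, np.asarray(extra_faces, dtype=np.int64)])

    tm = _trimesh.Trimesh(vertices=all_verts, faces=all_faces, process=False)
    tm.merge_vertices(merge_tex=True, merge_norm=True)
    tm.update_faces(tm.nondegenerate_faces())
    tm.remove_unreferenced_vertices()
    _trimesh.repair.fix_normals(tm)
    out = TriangleMesh.from_trimesh(
        tm,
        landmarks=mesh.landmarks,
        provenance=mesh.provenance
        + [f"trim_and_cap(center={np.round(center, 6).tolist()}, radius={radius:.6g})"],
    )
    if not out.is_watertight():
        raise MeshTopologyError("trim_and_cap failed to produce a watertight mesh")
    return out


# ---------------------------------------------------------------------------
# step 4: normalize
# ---------------------------------------------------------------------------

def normalize_to_unit_sphere(
    mesh: TriangleMesh,
) -> tuple[TriangleMesh, float, np.ndarray]:
    """Center at the bounding-box midpoint and scale into the unit ball.

    Returns ``(mesh', scale, center)`` with ``v' = (v - center) * scale``;
    the inverse map ``v = v' / scale + center`` restores model units.
    """
    if len(mesh.vertices) == 0:
        raise InvalidParameterError("empty mesh")
    lo, hi = mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)
    center = 0.5 * (lo + hi)
    rmax = np.linalg.norm(mesh.vertices - center, axis=1).max()
    if rmax <= 0:
        raise InvalidParameterError("mesh has zero extent")
    scale = 1.0 / rmax
    out = mesh.copy()
    out.vertices = (mesh.vertices - center) * scale
    if out.landmarks is not None:
        out.landmarks = {k: (v - center) * scale for k, v in out.landmarks.items()}
    out.provenance.append(
        f"normalize_to_unit_sphere(scale={scale:.6g}, center={np.round(center, 6).tolist()})"
    )
    return out, float(scale), center


def preprocess(mesh: TriangleMesh) -> tuple[TriangleMesh, dict]:
    """Full pipeline: clean -> reorient -> trim_and_cap -> normalize.

    Returns the normalized mesh and a record with the rigid transform,
    scale and center needed to map results back to the input frame.
    """
    cleaned = clean_mesh(mesh)
    oriented, rigid = reorient_mesh(cleaned)
    capped = trim_and_cap(oriented)
    normalized, scale, center = normalize_to_unit_sphere(capped)
    return normalized, {"rigid": rigid, "scale": scale, "center": center}
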