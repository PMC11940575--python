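"""Shared mesh container and error types.

The package moves triangle meshes between its own stages (procedural
generation, preprocessing, SDF sampling, isosurface extraction) and the
`trimesh` library, which supplies format IO and topology checks.
:class:`TriangleMesh` is a thin immutable-ish carrier: vertex/face arrays,
optional named landmarks (``tip``, ``base_top``, ``base_bottom``) used for
orientation, and a free-text provenance trail of applied transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

LANDMARK_NAMES = ("tip", "base_top", "base_bottom")


class BeakmorphError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(BeakmorphError, ValueError):
    """A caller-supplied parameter violates a precondition."""


class MeshTopologyError(BeakmorphError):
    """Mesh topology prevents the requested operation (e.g. not watertight)."""


class OrientationError(BeakmorphError):
    """Landmarks missing or degenerate; canonical orientation undefined."""


class SuspiciousGeometryError(BeakmorphError):
    """An operation would discard implausibly much geometry."""


class EmptyIsosurfaceError(BeakmorphError):
    """A scalar grid contains no zero crossing to contour."""


class TrainingDivergedError(BeakmorphError):
    """Optimization produced non-finite values."""


@dataclass
class TriangleMesh:
    """Triangle mesh with optional orientation landmarks.

    Parameters
    ----------
    vertices : (N, 3) float array, model units.
    faces : (M, 3) int array of vertex indices.
    landmarks : mapping from landmark name to a 3-vector, or None.
    provenance : list of free-text records of transforms applied so far.
    """

    vertices: np.ndarray
    faces: np.ndarray
    landmarks: dict[str, np.ndarray] | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InvalidParameterError("vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise InvalidParameterError("faces must be (M, 3)")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise InvalidParameterError("face indices out of range")
        if self.landmarks is not None:
            self.landmarks = {
                k: np.asarray(v, dtype=float) for k, v in self.landmarks.items()
            }

    # -- conversions ----------------------------------------------------

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(
        cls,
        mesh: _trimesh.Trimesh,
        landmarks: dict[str, np.ndarray] | None = None,
        provenance: list[str] | None = None,
    ) -> "TriangleMesh":
        return cls(
            vertices=np.asarray(mesh.vertices, dtype=float),
            faces=np.asarray(mesh.faces, dtype=np.int64),
            landmarks=landmarks,
            provenance=list(provenance or []),
        )

    # -- convenience ----------------------------------------------------

    @property
    def extents(self) -> np.ndarray:
        """Axis-aligned bounding-box extents (3,)."""
        return self.vertices.max(axis=0) - self.vertices.min(axis=0)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            vertices=self.vertices.copy(),
            faces=self.faces.copy(),
            landmarks=None
            if self.landmarks is None
            else {k: v.copy() for k, v in self.landmarks.items()},
            provenance=list(self.provenance),
        )

    def transformed(
        self, rotation: np.ndarray, translation: np.ndarray, note: str = ""
    ) -> "TriangleMesh":
        """Apply ``v -> rotation @ v + translation`` to vertices and landmarks."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        out = self.copy()
        out.vertices = self.vertices @ rotation.T + translation
        if out.landmarks is not None:
            out.landmarks = {
                k: rotation @ v + translation for k, v in out.landmarks.items()
            }
        if note:
            out.provenance.append(note)
        return out

    def is_watertight(self) -> bool:
        tm = self.to_trimesh()
        return bool(tm.is_watertight and tm.is_winding_consistent)

    def require_landmarks(self) -> dict[str, np.ndarray]:
        if self.landmarks is None or not all(
            k in self.landmarks for k in LANDMARK_NAMES
        ):
            raise OrientationError(
                f"mesh must carry the landmarks {LANDMARK_NAMES}; "
                f"found {sorted(self.landmarks) if self.landmarks else None}"
            )
        return self.landmarks

    # -- IO -------------------------------------------------------------

    def export(self, path: str | Path) -> None:
        """Write the mesh; format from suffix (.ply binary, .obj, .stl)."""
        self.to_trimesh().export(str(path))

    @classmethod
    def load(cls, path: str | Path) -> "TriangleMesh":
        tm = _trimesh.load_mesh(str(path), process=False)
        return cls.from_trimesh(tm, provenance=[f"loaded from {path}"])


def save_landmarks_csv(meshes: dict[str, TriangleMesh], path: str | Path) -> None:
    """Write landmarks of several meshes as CSV (species_id, landmark_name, x, y, z)."""
    import pandas as pd

    rows = []
    for sid, mesh in meshes.items():
        if mesh.landmarks is None:
            continue
        for name, xyz in mesh.landmarks.items():
            rows.append((sid, name, *xyz))
    pd.DataFrame(
        rows, columns=["species_id", "landmark_name", "x", "y", "z"]
    ).to_csv(path, index=False)


def load_landmarks_csv(path: str | Path) -> dict[str, dict[str, np.ndarray]]:
    import pandas as pd

    df = pd.read_csv(path)
    out: dict[str, dict[str, np.ndarray]] = {}
    for sid, grp in df.groupby("species_id"):
        out[str(sid)] = {
            str(r.landmark_name): np.array([r.x, r.y, r.z], dtype=float)
            for r in grp.itertuples()
        }
    return out
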